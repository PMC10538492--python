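"""Synthetic strain collections and error-bearing long reads.

The generator emulates the structure of strain-level classification
benchmarks: a single ancestral sequence is mutated into per-class ancestors
at a *between-class* divergence, each class ancestor is mutated into its
member genomes at a *within-class* divergence, and long reads are drawn from
the genomes with a fixed per-base error rate (``1 - accuracy``).  Divergence
tiers range from "different genera" (low nucleotide identity between
classes) down to same-species strains (identity above 99%), the regime where
full document listing matters most.

The mutation and read-error processes are i.i.d. per site: an event is a
substitution, insertion, or deletion with probabilities given by
``error_split`` (default 50:25:25 of the event budget), and indel lengths
are geometric with mean 1.5.  The rates are *process* rates — the realized
mismatch fraction concentrates on the nominal rate (no back-mutation
correction at these magnitudes).  Everything is deterministic under the
seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .suffix_structures import DocumentCollection, DocumentError

#: divergence presets: (between_class, within_class) substitution+indel rate
#: per site.  Identity between classes ~ 1 - rate: "genus" ~ different
#: genera (80%), "species" ~ congeneric species (95%), "strain" ~
#: same-species strains (99.5%).
TIER_PRESETS: dict[str, tuple[float, float]] = {
    "genus": (0.20, 0.01),
    "species": (0.05, 0.005),
    "strain": (0.005, 0.002),
}

DEFAULT_ERROR_SPLIT = (0.5, 0.25, 0.25)  # substitution : insertion : deletion
INDEL_MEAN_LENGTH = 1.5

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class DatasetConfig:
    """Parameters of one synthetic dataset (collection + reads).

    Defaults are the strain-tier study conditions at desk scale: four
    single-genome classes at 99.5% between-class identity, 1 kb reads at 95%
    accuracy, 500 reads per class.
    """

    n_classes: int = 4
    docs_per_class: int = 1
    ancestor_length: int = 20_000
    between_class_divergence: float = 0.005
    within_class_divergence: float = 0.002
    read_length: int = 1_000
    reads_per_class: int = 500
    accuracy: float = 0.95
    seed: int = 0
    error_split: tuple[float, float, float] = DEFAULT_ERROR_SPLIT

    def __post_init__(self) -> None:
        if not (0.0 <= self.between_class_divergence <= 1.0
                and 0.0 <= self.within_class_divergence <= 1.0):
            raise DocumentError("divergences must lie in [0, 1]")
        if not 0.0 < self.accuracy <= 1.0:
            raise DocumentError("accuracy must lie in (0, 1]")
        for name in ("n_classes", "docs_per_class", "ancestor_length",
                     "read_length", "reads_per_class"):
            if getattr(self, name) < 1:
                raise DocumentError(f"{name} must be at least 1")
        if abs(sum(self.error_split) - 1.0) > 1e-9 or min(self.error_split) < 0:
            raise DocumentError("error_split must be a 3-way probability split")

    @classmethod
    def from_tier(cls, tier: str, **overrides) -> "DatasetConfig":
        try:
            between, within = TIER_PRESETS[tier]
        except KeyError:
            raise DocumentError(
                f"unknown tier {tier!r}; expected one of {sorted(TIER_PRESETS)}"
            ) from None
        overrides.setdefault("between_class_divergence", between)
        overrides.setdefault("within_class_divergence", within)
        return cls(**overrides)


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    true_class: str
    source_doc: int        # 1-based document index
    start: int             # 1-based start in the source document


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def mutate(
    sequence: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    split: tuple[float, float, float] = DEFAULT_ERROR_SPLIT,
) -> np.ndarray:
    """Apply i.i.d. per-site substitutions and short indels at ``rate``.

    Substitutions draw one of the three other bases; insertion/deletion
    lengths are geometric with mean 1.5 bases.
    """
    if rate <= 0.0:
        return sequence.copy()
    sub_p, ins_p, _ = split
    out: list[np.ndarray] = []
    n = len(sequence)
    hits = np.flatnonzero(rng.random(n) < rate)
    kinds = rng.random(len(hits))
    prev = 0
    p_geom = 1.0 / INDEL_MEAN_LENGTH
    for pos, kind in zip(hits, kinds):
        if pos < prev:  # site consumed by a previous deletion
            continue
        out.append(sequence[prev:pos])
        if kind < sub_p:  # substitution: one of the three other bases
            cur = sequence[pos]
            choices = _BASES[_BASES != cur]
            out.append(choices[rng.integers(0, 3)][None])
            prev = pos + 1
        elif kind < sub_p + ins_p:  # insertion before this base
            ins_len = rng.geometric(p_geom)
            out.append(_random_dna(rng, ins_len))
            out.append(sequence[pos][None])
            prev = pos + 1
        else:  # deletion starting at this base
            del_len = rng.geometric(p_geom)
            prev = min(pos + del_len, n)
    out.append(sequence[prev:])
    return np.concatenate(out) if out else sequence[:0].copy()


def generate_collection(config: DatasetConfig) -> DocumentCollection:
    """One document per class: the class's genomes joined with single ``N``s.

    The dataset shares one random ancestor; class ancestors diverge from it
    at ``between_class_divergence`` and genomes within a class at
    ``within_class_divergence``.  Joining a class's genomes with an ``N``
    keeps one document per class while preventing exact matches from
    spanning two genomes (reads essentially never contain ``N``).
    """
    if config.between_class_divergence > 0.75:
        warnings.warn(
            "between-class divergence so high that expected identity is "
            "below 25%: sequences are essentially saturated",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    ancestor = _random_dna(rng, config.ancestor_length)
    docs: list[str] = []
    labels: list[str] = []
    for ci in range(config.n_classes):
        class_ancestor = mutate(
            ancestor, config.between_class_divergence, rng, config.error_split
        )
        genomes = []
        for _ in range(config.docs_per_class):
            if config.docs_per_class == 1 and config.within_class_divergence == 0.0:
                genomes.append(class_ancestor)
            else:
                genomes.append(
                    mutate(class_ancestor, config.within_class_divergence, rng,
                           config.error_split)
                )
        joined = b"N".join(g.tobytes() for g in genomes).decode("ascii")
        docs.append(joined)
        labels.append(f"class{ci + 1}")
    return DocumentCollection(tuple(docs), tuple(labels))


def simulate_reads(
    collection: DocumentCollection, config: DatasetConfig
) -> list[SimulatedRead]:
    """Uniform-start reads with per-base error rate ``1 - accuracy``.

    Reads are drawn from the forward strand of a uniformly chosen document
    position; the error budget is split among substitutions, insertions and
    deletions per ``config.error_split``.  The true class label travels with
    the read.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    error_rate = 1.0 - config.accuracy
    reads: list[SimulatedRead] = []
    for j, (doc, label) in enumerate(zip(collection.docs, collection.labels), start=1):
        template = np.frombuffer(doc.encode("ascii"), dtype=np.uint8)
        if config.read_length > len(template):
            raise DocumentError(
                f"read_length {config.read_length} exceeds document {label!r}"
            )
        max_start = len(template) - config.read_length
        for k in range(config.reads_per_class):
            start = int(rng.integers(0, max_start + 1))
            chunk = template[start : start + config.read_length]
            seq = mutate(chunk, error_rate, rng, config.error_split)
            reads.append(
                SimulatedRead(
                    read_id=f"{label}_read{k + 1}",
                    sequence=seq.tobytes().decode("ascii"),
                    true_class=label,
                    source_doc=j,
                    start=start + 1,
                )
            )
    return reads


def write_dataset(
    outdir: str | Path,
    collection: DocumentCollection,
    reads: list[SimulatedRead],
    config: DatasetConfig,
) -> dict[str, Path]:
    """Write documents.fasta, reads.fastq, groups.tsv and a manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "documents.fasta"
    with fasta.open("w") as fh:
        for label, doc in zip(collection.labels, collection.docs):
            fh.write(f">{label} class={label}\n")
            for k in range(0, len(doc), 70):
                fh.write(doc[k : k + 70] + "\n")
    fastq = outdir / "reads.fastq"
    with fastq.open("w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id} class={read.true_class}\n")
            fh.write(read.sequence + "\n+\n" + "I" * len(read.sequence) + "\n")
    groups = outdir / "groups.tsv"
    with groups.open("w") as fh:
        for label in collection.labels:
            fh.write(f"{label}\t{label}\n")
    manifest = outdir / "manifest.json"
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(config).items()}
    manifest.write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
    return {"fasta": fasta, "fastq": fastq, "groups": groups, "manifest": manifest}
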