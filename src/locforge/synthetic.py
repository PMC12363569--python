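"""Synthetic localization corpora with planted sequence signals.

Real localization corpora have three statistical properties the pipeline
depends on: class-conditional sequence signal (targeting peptides and
compositional bias), a label hierarchy with multi-label annotations, and
families of homologous sequences that must not straddle fold boundaries.
The generator emulates all three at desk scale: uniform-background
random sequences receive a short class-specific motif for every label
they carry (a caricature of targeting signals), labels come from a small
two-level hierarchy (four main compartments, two sub-compartments each),
and a configurable number of families derive their members from a common
ancestor by point mutations.

Everything is driven by a single seed, so a bundle regenerates
byte-identically.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import LabelOntology, ProteinRecord, close_labels
from .descriptors import ALPHABET

__all__ = [
    "SyntheticSpec",
    "default_synthetic_ontology",
    "DEFAULT_MOTIFS",
    "generate_dataset",
    "make_benchmark_bundle",
]

_MAIN = ("Cytoplasm", "Extracellular", "Mitochondrion", "Nucleus")
_SUBS = {
    "Cytoplasm": ("Cytoskeleton", "Cytosol"),
    "Extracellular": ("Cell wall", "Secreted"),
    "Mitochondrion": ("Mitochondrion matrix", "Mitochondrion membrane"),
    "Nucleus": ("Chromosome", "Nucleolus"),
}

#: Planted motifs: each label gets a short repeat over a residue pair
#: that no other label's motif uses, so every class shifts a disjoint
#: slice of the composition (the nuclear motif is K/R-rich like a real
#: nuclear localization signal; the rest are chosen for detectability by
#: composition-sensitive descriptors, not biophysical realism).
DEFAULT_MOTIFS: dict[str, str] = {
    "Cytoplasm": "DEDDEDEDDE",
    "Extracellular": "FYFFYFYFFY",
    "Mitochondrion": "MSMMSMSMMS",
    "Nucleus": "KRKKRKRKKR",
    "Cytoskeleton": "WAWAWA",
    "Cytosol": "CNCNCN",
    "Cell wall": "HQHQHQ",
    "Secreted": "WNWNWN",
    "Mitochondrion matrix": "ILILIL",
    "Mitochondrion membrane": "VTVTVT",
    "Chromosome": "HGHGHG",
    "Nucleolus": "PQPQPQ",
}


def default_synthetic_ontology() -> LabelOntology:
    parent: dict[str, str | None] = {m: None for m in _MAIN}
    for main, subs in _SUBS.items():
        for sub in subs:
            parent[sub] = main
    return LabelOntology(parent)


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of a generated corpus.

    ``n_proteins`` includes family members; the first
    ``n_families * family_size`` records belong to homologous families
    whose members differ from a shared ancestor by point mutations at
    ``mutation_rate`` per site (motifs re-planted afterwards so class
    signal survives).  Each protein carries one main-compartment label,
    a second one with probability ``co_label_rate``, and refines each
    main label to one of its sub-compartments with probability
    ``sub_label_rate``.  Label sets are stored ancestor-closed.
    """

    n_proteins: int = 100
    length_range: tuple[int, int] = (40, 500)
    ontology: LabelOntology = field(default_factory=default_synthetic_ontology)
    motifs: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    insertion_prob: float = 1.0
    co_label_rate: float = 0.3
    sub_label_rate: float = 0.5
    n_families: int = 5
    family_size: int = 3
    mutation_rate: float = 0.05
    date_range: tuple[str, str] = ("2000-01-01", "2020-12-31")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length range")
        worst = max((len(m) for m in self.motifs.values()), default=0)
        # a record can carry two mains plus subs; demand headroom for two motifs
        if 2 * worst > self.length_range[0]:
            raise ValueError("motifs too long for the minimum sequence length")
        for p in (self.insertion_prob, self.co_label_rate, self.sub_label_rate, self.mutation_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_families * self.family_size > self.n_proteins:
            raise ValueError("family proteins exceed n_proteins")


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return [ALPHABET[i] for i in rng.integers(0, len(ALPHABET), size=length)]


def _plant(seq: list[str], motif: str, rng: np.random.Generator) -> None:
    pos = int(rng.integers(0, len(seq) - len(motif) + 1))
    seq[pos : pos + len(motif)] = list(motif)


def _draw_labels(spec: SyntheticSpec, rng: np.random.Generator) -> frozenset[str]:
    mains = sorted(spec.ontology.main_terms)
    chosen = [mains[int(rng.integers(0, len(mains)))]]
    if rng.random() < spec.co_label_rate:
        others = [m for m in mains if m not in chosen]
        chosen.append(others[int(rng.integers(0, len(others)))])
    labels: set[str] = set()
    for main in chosen:
        subs = sorted(t for t in spec.ontology.terms if spec.ontology.parent.get(t) == main)
        if subs and rng.random() < spec.sub_label_rate:
            labels.add(subs[int(rng.integers(0, len(subs)))])
        else:
            labels.add(main)
    return close_labels(labels, spec.ontology)


def _draw_date(spec: SyntheticSpec, rng: np.random.Generator) -> dt.date:
    start = dt.date.fromisoformat(spec.date_range[0])
    end = dt.date.fromisoformat(spec.date_range[1])
    return start + dt.timedelta(days=int(rng.integers(0, (end - start).days + 1)))


def generate_dataset(spec: SyntheticSpec) -> list[ProteinRecord]:
    """Generate a seeded, reproducible list of annotated protein records."""
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    counter = 0

    def make_record(seq: list[str], labels: frozenset[str]) -> ProteinRecord:
        nonlocal counter
        counter += 1
        for label in sorted(labels):
            motif = spec.motifs.get(label)
            if motif and rng.random() < spec.insertion_prob:
                _plant(seq, motif, rng)
        return ProteinRecord(
            id=f"SYN{counter:05d}",
            sequence="".join(seq),
            labels=labels,
            timestamp=_draw_date(spec, rng),
            organism="synthetic",
        )

    # homologous families first
    for _ in range(spec.n_families):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        ancestor = _random_sequence(rng, length)
        labels = _draw_labels(spec, rng)
        for member in range(spec.family_size):
            seq = list(ancestor)
            if member > 0 and spec.mutation_rate > 0:
                mask = rng.random(length) < spec.mutation_rate
                for pos in np.nonzero(mask)[0]:
                    seq[pos] = ALPHABET[int(rng.integers(0, len(ALPHABET)))]
            records.append(make_record(seq, labels))

    # independent proteins
    while len(records) < spec.n_proteins:
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        records.append(make_record(_random_sequence(rng, length), _draw_labels(spec, rng)))
    return records


def make_benchmark_bundle(
    spec: SyntheticSpec, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write the FASTA / annotation TSV / ontology TSV triple of a corpus.

    Returns the three paths; regeneration with the same spec is
    byte-identical, and the bundle round-trips losslessly through
    :func:`locforge.dataset.parse_records`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = generate_dataset(spec)
    fasta = out / "proteins.fasta"
    ann = out / "annotations.tsv"
    ont = out / "ontology.tsv"
    fasta.write_text("".join(f">{r.id}\n{r.sequence}\n" for r in records))
    ann.write_text(
        "".join(
            f"{r.id}\t{';'.join(sorted(r.labels))}\t{r.timestamp.isoformat()}\t{r.organism}\n"
            for r in records
        )
    )
    spec.ontology.to_tsv(ont)
    return fasta, ann, ont
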