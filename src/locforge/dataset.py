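"""Dataset curation, label ontology, and leakage-aware splitting.

Proteins arrive as a FASTA file plus a tab-separated annotation file
(id, semicolon-separated localization terms, ISO date of last sequence
modification, optional organism).  Curation follows the benchmark
conventions of sequence-based localization predictors:

* sequences shorter than 40 residues are excluded;
* labels live in a small hierarchy (main compartments with optional
  sub-compartments) and every record's label set is closed under the
  ancestor relation, so a protein annotated to a sub-compartment also
  counts for its parent;
* the fine-grained label space keeps only terms with more than 50
  annotated proteins, while the main task always uses the 10 major
  compartments;
* roughly the most recent 15% of proteins (by annotation timestamp)
  form a temporally independent test set;
* the remaining proteins are clustered at 30% sequence identity and
  whole clusters are distributed over 5 cross-validation folds, so no
  pair of homologous sequences straddles a fold boundary.
"""

from __future__ import annotations

import datetime as dt
import json
import math
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "LabelOntology",
    "SplitPlan",
    "MAIN_LOCATIONS",
    "default_ontology",
    "parse_fasta",
    "parse_records",
    "filter_records",
    "close_labels",
    "build_label_space",
    "temporal_split",
    "cluster_sequences",
    "assign_folds",
    "build_split_plan",
]

#: The 10 major subcellular compartments of the main prediction task.
MAIN_LOCATIONS = (
    "Cell membrane",
    "Cytoplasm",
    "Endoplasmic reticulum",
    "Extracellular",
    "Golgi apparatus",
    "Lysosome/Vacuole",
    "Mitochondrion",
    "Nucleus",
    "Peroxisome",
    "Plastid",
)

#: Mitochondrial sub-compartments shipped with the default ontology.
MITOCHONDRIAL_SUBTERMS = (
    "Mitochondrion matrix",
    "Mitochondrion membrane",
    "Mitochondrion inner membrane",
    "Mitochondrion outer membrane",
)


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    labels: frozenset[str] = frozenset()
    timestamp: dt.date | None = None
    organism: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabelOntology:
    """Acyclic parent map over localization terms, tagged main/sub."""

    parent: dict[str, str | None]

    def __post_init__(self) -> None:
        for term, par in self.parent.items():
            if par is not None and par not in self.parent:
                raise ValueError(f"parent {par!r} of {term!r} is not a term")
        for term in self.parent:
            seen = {term}
            cur = self.parent[term]
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle in ontology at {cur!r}")
                seen.add(cur)
                cur = self.parent[cur]

    @property
    def terms(self) -> set[str]:
        return set(self.parent)

    def level(self, term: str) -> str:
        return "main" if self.parent[term] is None else "sub"

    @property
    def main_terms(self) -> list[str]:
        return sorted(t for t in self.parent if self.parent[t] is None)

    def ancestors(self, term: str) -> list[str]:
        out = []
        cur = self.parent[term]
        while cur is not None:
            out.append(cur)
            cur = self.parent[cur]
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabelOntology":
        """Read a two-column child<TAB>parent table; '-' or empty = root."""
        parent: dict[str, str | None] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            child = parts[0].strip()
            par = parts[1].strip() if len(parts) > 1 else ""
            parent[child] = par if par and par != "-" else None
        return cls(parent)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{t}\t{self.parent[t] or '-'}" for t in sorted(self.parent)]
        Path(path).write_text("\n".join(lines) + "\n")


def default_ontology() -> LabelOntology:
    """The 10 major compartments plus the mitochondrial sub-compartments."""
    parent: dict[str, str | None] = {t: None for t in MAIN_LOCATIONS}
    for sub in MITOCHONDRIAL_SUBTERMS:
        parent[sub] = "Mitochondrion"
    return LabelOntology(parent)


def parse_fasta(path: str | Path) -> dict[str, str]:
    """Parse a FASTA file into an ordered id -> sequence map.

    Raises with a line number for structurally malformed files and on
    duplicate record ids.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ValueError(f"{path}:{lineno}: expected a '>' header before sequence data")
        break
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq)
    return sequences


def parse_records(
    fasta_path: str | Path,
    annotations_path: str | Path,
    ontology: LabelOntology,
) -> list[ProteinRecord]:
    """Join sequences with annotations into validated protein records.

    The annotation file is tab-separated: id, semicolon-separated label
    list, optional ISO date, optional organism.  Annotation ids must
    reference FASTA ids, and every label must be an ontology term.
    """
    sequences = parse_fasta(fasta_path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(annotations_path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        pid = parts[0].strip()
        if pid not in sequences:
            raise ValueError(
                f"{annotations_path}:{lineno}: annotation id {pid!r} not present in FASTA"
            )
        if pid in seen:
            raise ValueError(f"{annotations_path}:{lineno}: duplicate annotation for {pid!r}")
        seen.add(pid)
        labels = frozenset(
            lab.strip() for lab in parts[1].split(";") if lab.strip()
        ) if len(parts) > 1 and parts[1].strip() else frozenset()
        unknown = labels - ontology.terms
        if unknown:
            raise ValueError(
                f"{annotations_path}:{lineno}: unknown label(s) {sorted(unknown)}"
            )
        timestamp = None
        if len(parts) > 2 and parts[2].strip():
            timestamp = dt.date.fromisoformat(parts[2].strip())
        organism = parts[3].strip() if len(parts) > 3 and parts[3].strip() else None
        records.append(
            ProteinRecord(
                id=pid,
                sequence=sequences[pid],
                labels=labels,
                timestamp=timestamp,
                organism=organism,
            )
        )
    return records


def filter_records(records: Iterable[ProteinRecord], min_length: int = 40) -> list[ProteinRecord]:
    """Keep records whose sequence has at least ``min_length`` residues."""
    return [r for r in records if len(r.sequence) >= min_length]


def close_labels(labels: Iterable[str], ontology: LabelOntology) -> frozenset[str]:
    """Ancestor closure of a label set: child implies every parent."""
    out: set[str] = set()
    for term in labels:
        if term not in ontology.terms:
            raise ValueError(f"unknown ontology term {term!r}")
        out.add(term)
        out.update(ontology.ancestors(term))
    return frozenset(out)


def close_records(records: Sequence[ProteinRecord], ontology: LabelOntology) -> list[ProteinRecord]:
    """Return records with ancestor-closed label sets."""
    return [
        ProteinRecord(r.id, r.sequence, close_labels(r.labels, ontology), r.timestamp, r.organism)
        for r in records
    ]


def build_label_space(
    records: Sequence[ProteinRecord],
    ontology: LabelOntology,
    task: str = "main",
    min_count: int = 50,
) -> list[str]:
    """The ordered label list of a prediction task.

    ``task='main'`` always returns the main-level compartments; ``task='all'``
    returns every ontology term annotated on *strictly more than*
    ``min_count`` proteins, in deterministic (alphabetical) order.
    """
    if task == "main":
        return ontology.main_terms
    if task != "all":
        raise ValueError(f"unknown task {task!r}")
    counts: dict[str, int] = {t: 0 for t in ontology.terms}
    for rec in records:
        for lab in rec.labels:
            counts[lab] += 1
    labels = sorted(t for t, c in counts.items() if c > min_count)
    if not labels:
        raise ValueError(f"no label has more than {min_count} proteins")
    return labels


def temporal_split(
    records: Sequence[ProteinRecord], test_fraction: float = 0.15
) -> tuple[list[str], list[str]]:
    """Hold out the most recent ``ceil(test_fraction * N)`` records as a test set.

    Records are ordered by (timestamp, id); ties in timestamp are broken
    lexicographically by id.  Returns ``(cv_ids, test_ids)``.
    """
    for rec in records:
        if rec.timestamp is None:
            raise ValueError(f"record {rec.id!r} has no timestamp")
    n_test = math.ceil(test_fraction * len(records))
    ordered = sorted(records, key=lambda r: (r.timestamp, r.id))
    cv = [r.id for r in ordered[: len(records) - n_test]]
    test = [r.id for r in ordered[len(records) - n_test :]]
    return cv, test


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_identity(a: str, b: str, k: int = 5) -> float:
    """Containment of the shorter sequence's k-mers in the longer's.

    A fast proxy for alignment identity: near-identical sequences share
    almost all k-mers, unrelated random sequences share almost none.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    ks, kl = _kmer_set(short, k), _kmer_set(long_, k)
    if not ks:
        return 0.0
    return len(ks & kl) / len(ks)


def cluster_sequences(
    records: Sequence[ProteinRecord],
    identity_threshold: float = 0.30,
    engine: str = "internal",
    k: int = 5,
) -> list[list[str]]:
    """Partition record ids into sequence-similarity clusters.

    The internal engine is greedy incremental clustering in the style of
    CD-HIT: sequences are visited longest-first (ties by id) and each one
    joins the first existing cluster whose representative — its founding,
    longest member — has estimated identity >= the threshold, otherwise
    it founds a new cluster.  The ``psi-cd-hit`` engine shells out to the
    external PSI-CD-HIT tool and parses its ``.clstr`` output.
    """
    if not records:
        raise ValueError("no records to cluster")
    if engine == "psi-cd-hit":
        return _psi_cd_hit_clusters(records, identity_threshold)
    if engine != "internal":
        raise ValueError(f"unknown clustering engine {engine!r}")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[ProteinRecord] = []
    clusters: list[list[str]] = []
    for rec in ordered:
        for ci, rep in enumerate(reps):
            if kmer_identity(rec.sequence, rep.sequence, k=k) >= identity_threshold:
                clusters[ci].append(rec.id)
                break
        else:
            reps.append(rec)
            clusters.append([rec.id])
    return clusters


def _psi_cd_hit_clusters(
    records: Sequence[ProteinRecord], identity_threshold: float
) -> list[list[str]]:  # pragma: no cover - requires external binary
    exe = shutil.which("psi-cd-hit.pl")
    if exe is None:
        raise RuntimeError(
            "psi-cd-hit.pl not found on PATH; use engine='internal' for a "
            "download-free clustering"
        )
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fa"
        fasta.write_text("".join(f">{r.id}\n{r.sequence}\n" for r in records))
        out = Path(tmp) / "out"
        subprocess.run(
            [exe, "-i", str(fasta), "-o", str(out), "-c", str(identity_threshold)],
            check=True,
            capture_output=True,
        )
        return parse_clstr(Path(str(out) + ".clstr").read_text())


def parse_clstr(text: str) -> list[list[str]]:
    """Parse CD-HIT ``.clstr`` output into a list of id clusters."""
    clusters: list[list[str]] = []
    for line in text.splitlines():
        if line.startswith(">Cluster"):
            clusters.append([])
        elif line.strip():
            pid = line.split(">", 1)[1].split("...", 1)[0]
            clusters[-1].append(pid)
    return [c for c in clusters if c]


def assign_folds(clusters: Sequence[Sequence[str]], k: int = 5) -> dict[str, int]:
    """Greedily balance whole clusters over ``k`` folds by sequence count.

    Clusters are taken largest-first (ties by representative id) and each
    goes to the currently smallest fold (ties to the lowest fold index).
    Folds are numbered 1..k and clusters are never split.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    order = sorted(range(len(clusters)), key=lambda i: (-len(clusters[i]), min(clusters[i])))
    sizes = [0] * k
    fold_of: dict[str, int] = {}
    for ci in order:
        fold = min(range(k), key=lambda f: (sizes[f], f))
        sizes[fold] += len(clusters[ci])
        for pid in clusters[ci]:
            fold_of[pid] = fold + 1
    return fold_of


@dataclass
class SplitPlan:
    """A complete temporal + homology-aware split of a dataset."""

    test_ids: list[str]
    fold_of: dict[str, int]
    clusters: list[list[str]]

    def __post_init__(self) -> None:
        overlap = set(self.test_ids) & set(self.fold_of)
        if overlap:
            raise ValueError(f"ids in both test and CV sets: {sorted(overlap)[:5]}")
        for cluster in self.clusters:
            folds = {self.fold_of[pid] for pid in cluster if pid in self.fold_of}
            if len(folds) > 1:
                raise ValueError(f"cluster {cluster[:3]}... spans folds {sorted(folds)}")

    def fold_ids(self, fold: int) -> list[str]:
        return sorted(pid for pid, f in self.fold_of.items() if f == fold)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "test_ids": self.test_ids,
                    "fold_of": self.fold_of,
                    "clusters": self.clusters,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        return cls(
            test_ids=list(payload["test_ids"]),
            fold_of={k: int(v) for k, v in payload["fold_of"].items()},
            clusters=[list(c) for c in payload["clusters"]],
        )


def build_split_plan(
    records: Sequence[ProteinRecord],
    test_fraction: float = 0.15,
    identity_threshold: float = 0.30,
    folds: int = 5,
    engine: str = "internal",
) -> SplitPlan:
    """Temporal test split followed by homology-clustered fold assignment."""
    cv_ids, test_ids = temporal_split(records, test_fraction)
    cv_set = set(cv_ids)
    cv_records = [r for r in records if r.id in cv_set]
    clusters = cluster_sequences(cv_records, identity_threshold, engine=engine)
    fold_of = assign_folds(clusters, k=folds)
    return SplitPlan(test_ids=test_ids, fold_of=fold_of, clusters=clusters)
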