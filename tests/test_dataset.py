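"""Record parsing, curation filters, label closure, and leakage-aware splits."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locforge.dataset import (
    LabelOntology,
    ProteinRecord,
    SplitPlan,
    assign_folds,
    build_label_space,
    build_split_plan,
    close_labels,
    cluster_sequences,
    default_ontology,
    filter_records,
    kmer_identity,
    parse_clstr,
    parse_records,
    temporal_split,
)
from tests.conftest import random_sequence


def _write_bundle(tmp_path, fasta_text, ann_text):
    fasta = tmp_path / "in.fa"
    ann = tmp_path / "ann.tsv"
    fasta.write_text(fasta_text)
    ann.write_text(ann_text)
    return fasta, ann


class TestParsing:
    def test_three_records_round_trip(self, tmp_path, tiered_ontology):
        fasta, ann = _write_bundle(
            tmp_path,
            ">p1\nACDEF\n>p2\nGHIKL\n>p3\nMNPQR\n",
            "p1\tnucleus\t2001-01-01\thuman\n"
            "p2\tcentromere;cytoplasm\t2002-02-02\n"
            "p3\tchromosome\t2003-03-03\tyeast\n",
        )
        records = parse_records(fasta, ann, tiered_ontology)
        assert len(records) == 3
        assert records[1].labels == {"centromere", "cytoplasm"}
        assert records[0].timestamp == dt.date(2001, 1, 1)
        assert records[2].organism == "yeast"

    def test_orphan_annotation_names_id(self, tmp_path, tiered_ontology):
        fasta, ann = _write_bundle(tmp_path, ">p1\nACDEF\n", "ghost\tnucleus\n")
        with pytest.raises(ValueError, match="ghost"):
            parse_records(fasta, ann, tiered_ontology)

    def test_duplicate_fasta_id_rejected(self, tmp_path, tiered_ontology):
        fasta, ann = _write_bundle(tmp_path, ">p1\nACDEF\n>p1\nGHIKL\n", "p1\tnucleus\n")
        with pytest.raises(ValueError, match="duplicate"):
            parse_records(fasta, ann, tiered_ontology)

    def test_malformed_fasta_reports_line_number(self, tmp_path, tiered_ontology):
        fasta, ann = _write_bundle(tmp_path, "ACDEF\n>p1\nGHIKL\n", "p1\tnucleus\n")
        with pytest.raises(ValueError, match=":1:"):
            parse_records(fasta, ann, tiered_ontology)

    def test_unknown_label_rejected(self, tmp_path, tiered_ontology):
        fasta, ann = _write_bundle(tmp_path, ">p1\nACDEF\n", "p1\tmoon\n")
        with pytest.raises(ValueError, match="moon"):
            parse_records(fasta, ann, tiered_ontology)


class TestFilters:
    def test_length_boundary(self):
        records = [
            ProteinRecord("short", "A" * 39),
            ProteinRecord("exact", "A" * 40),
            ProteinRecord("long", "A" * 41),
        ]
        kept = {r.id for r in filter_records(records)}
        assert kept == {"exact", "long"}

    def test_empty_input(self):
        assert filter_records([]) == []


class TestOntology:
    def test_closure_walks_every_tier(self, tiered_ontology):
        closed = close_labels({"centromere"}, tiered_ontology)
        assert closed == {"centromere", "chromosome", "nucleus"}

    def test_root_is_fixed_point(self, tiered_ontology):
        assert close_labels({"nucleus"}, tiered_ontology) == {"nucleus"}

    def test_closure_idempotent(self, tiered_ontology):
        once = close_labels({"centromere", "cytoplasm"}, tiered_ontology)
        assert close_labels(once, tiered_ontology) == once

    def test_unknown_term_rejected(self, tiered_ontology):
        with pytest.raises(ValueError):
            close_labels({"ribosome"}, tiered_ontology)

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            LabelOntology({"a": "b", "b": "a"})

    def test_default_ontology_has_ten_main_terms(self):
        ontology = default_ontology()
        assert len(ontology.main_terms) == 10
        assert ontology.parent["Mitochondrion matrix"] == "Mitochondrion"

    def test_tsv_round_trip(self, tmp_path, tiered_ontology):
        path = tmp_path / "ont.tsv"
        tiered_ontology.to_tsv(path)
        assert LabelOntology.from_tsv(path).parent == tiered_ontology.parent


class TestLabelSpace:
    def _records_with_counts(self, ontology, count_a, count_b):
        records = []
        for i in range(count_a):
            records.append(ProteinRecord(f"a{i}", "A" * 50, frozenset({"nucleus"})))
        for i in range(count_b):
            records.append(ProteinRecord(f"b{i}", "A" * 50, frozenset({"cytoplasm"})))
        return records

    def test_min_count_is_strict(self, tiered_ontology):
        records = self._records_with_counts(tiered_ontology, 50, 51)
        labels = build_label_space(records, tiered_ontology, task="all", min_count=50)
        assert labels == ["cytoplasm"]  # 50 is dropped, 51 kept

    def test_main_task_ignores_min_count(self, tiered_ontology):
        records = self._records_with_counts(tiered_ontology, 1, 1)
        labels = build_label_space(records, tiered_ontology, task="main", min_count=50)
        assert labels == ["cytoplasm", "nucleus"]

    def test_main_task_on_default_ontology_yields_ten(self):
        labels = build_label_space([], default_ontology(), task="main")
        assert len(labels) == 10


class TestTemporalSplit:
    def _records(self, n, base_day=0):
        return [
            ProteinRecord(
                f"p{i:02d}", "A" * 50, frozenset(), dt.date(2000, 1, 1) + dt.timedelta(days=base_day + i)
            )
            for i in range(n)
        ]

    def test_twenty_records_three_test(self):
        cv, test = temporal_split(self._records(20))
        assert len(test) == 3  # ceil(0.15 * 20)
        assert test == ["p17", "p18", "p19"]  # the three newest

    def test_identical_timestamps_tie_break_by_id(self):
        records = [
            ProteinRecord(f"p{i}", "A" * 50, frozenset(), dt.date(2000, 1, 1))
            for i in range(10)
        ]
        cv, test = temporal_split(records)
        assert test == ["p8", "p9"]

    def test_partition_property(self):
        records = self._records(37)
        cv, test = temporal_split(records)
        assert set(cv) | set(test) == {r.id for r in records}
        assert set(cv) & set(test) == set()

    def test_missing_timestamp_names_record(self):
        records = [ProteinRecord("nodate", "A" * 50)]
        with pytest.raises(ValueError, match="nodate"):
            temporal_split(records)


class TestClustering:
    def test_identical_sequences_co_cluster(self, rng):
        seq = random_sequence(rng, 80)
        clusters = cluster_sequences(
            [ProteinRecord("a", seq), ProteinRecord("b", seq)]
        )
        assert clusters == [["a", "b"]]

    def test_unrelated_sequences_split(self, rng):
        a, b = random_sequence(rng, 100), random_sequence(rng, 100)
        assert kmer_identity(a, b) < 0.30
        clusters = cluster_sequences([ProteinRecord("a", a), ProteinRecord("b", b)])
        assert len(clusters) == 2

    def test_singleton(self, rng):
        clusters = cluster_sequences([ProteinRecord("only", random_sequence(rng, 60))])
        assert clusters == [["only"]]

    def test_deterministic(self, rng):
        records = [
            ProteinRecord(f"p{i}", random_sequence(rng, int(rng.integers(60, 120))))
            for i in range(20)
        ]
        assert cluster_sequences(records) == cluster_sequences(records)

    def test_clstr_parser(self):
        text = ">Cluster 0\n0\t100aa, >p1... *\n1\t90aa, >p2... at 95%\n>Cluster 1\n0\t80aa, >p3... *\n"
        assert parse_clstr(text) == [["p1", "p2"], ["p3"]]

    def test_external_engine_missing_raises_helpful_error(self, rng):
        with pytest.raises(RuntimeError, match="internal"):
            cluster_sequences(
                [ProteinRecord("a", random_sequence(rng, 60))], engine="psi-cd-hit"
            )


class TestFoldAssignment:
    def test_greedy_balancing_example(self):
        clusters = [["a"] * 4, ["b"] * 3, ["c"] * 2, ["d"], ["e"], ["f"], ["g"], ["h"]]
        clusters = [
            [f"{chr(97 + i)}{j}" for j in range(n)]
            for i, n in enumerate([4, 3, 2, 1, 1, 1, 1, 1])
        ]
        fold_of = assign_folds(clusters, k=5)
        sizes = sorted(
            [sum(1 for f in fold_of.values() if f == k) for k in range(1, 6)], reverse=True
        )
        assert sizes == [4, 3, 3, 2, 2]

    def test_five_singletons_one_per_fold(self):
        fold_of = assign_folds([["a"], ["b"], ["c"], ["d"], ["e"]], k=5)
        assert sorted(fold_of.values()) == [1, 2, 3, 4, 5]

    def test_clusters_never_split(self, rng):
        clusters = [
            [f"c{i}_{j}" for j in range(int(rng.integers(1, 6)))] for i in range(12)
        ]
        fold_of = assign_folds(clusters, k=5)
        for cluster in clusters:
            assert len({fold_of[pid] for pid in cluster}) == 1

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(min_value=1, max_value=20), min_size=1, max_size=30))
    def test_imbalance_bounded_by_largest_cluster(self, sizes):
        clusters = [[f"c{i}_{j}" for j in range(n)] for i, n in enumerate(sizes)]
        fold_of = assign_folds(clusters, k=5)
        counts = [sum(1 for f in fold_of.values() if f == k) for k in range(1, 6)]
        assert max(counts) - min(counts) <= max(sizes)


class TestSplitPlan:
    def test_full_plan_invariants(self, rng):
        records = []
        base = random_sequence(rng, 120)
        for i in range(4):  # a homologous family
            seq = list(base)
            for pos in rng.integers(0, 120, size=6):
                seq[pos] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(0, 20))]
            records.append(
                ProteinRecord(
                    f"fam{i}", "".join(seq), frozenset(),
                    dt.date(2005, 1, 1) + dt.timedelta(days=i),
                )
            )
        for i in range(26):
            records.append(
                ProteinRecord(
                    f"solo{i:02d}", random_sequence(rng, 100), frozenset(),
                    dt.date(2010, 1, 1) + dt.timedelta(days=i),
                )
            )
        plan = build_split_plan(records)
        assert set(plan.test_ids) & set(plan.fold_of) == set()
        assert len(plan.test_ids) == 5  # ceil(0.15 * 30)
        for cluster in plan.clusters:
            assert len({plan.fold_of[pid] for pid in cluster}) == 1

    def test_overlapping_test_and_cv_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan(test_ids=["x"], fold_of={"x": 1}, clusters=[["x"]])

    def test_spanning_cluster_rejected(self):
        with pytest.raises(ValueError, match="spans"):
            SplitPlan(
                test_ids=[], fold_of={"a": 1, "b": 2}, clusters=[["a", "b"]]
            )

    def test_json_round_trip(self, tmp_path):
        plan = SplitPlan(test_ids=["t1"], fold_of={"a": 1, "b": 2}, clusters=[["a"], ["b"]])
        path = tmp_path / "split.json"
        plan.to_json(path)
        loaded = SplitPlan.from_json(path)
        assert loaded.test_ids == plan.test_ids
        assert loaded.fold_of == plan.fold_of
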