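"""Descriptor registry: worked examples, brute-force oracles, invariants."""

import numpy as np
import pytest

from locforge.descriptors import (
    ALPHABET,
    CTD_ATTRIBUTES,
    DescriptorConfig,
    InvalidSequenceError,
    _scale_array,
    _standardize,
    compute_aac,
    compute_autocorrelation,
    compute_ctd,
    compute_descriptor_profile,
    compute_dpc,
    compute_paac,
    compute_qso,
    feature_table,
    profile_length,
    sanitize_sequence,
)
from tests.conftest import random_sequence


class TestComposition:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", {"AAC:A": 1.0}),
            ("ACDE", {"AAC:A": 0.25, "AAC:C": 0.25, "AAC:D": 0.25, "AAC:E": 0.25}),
            ("AAC", {"AAC:A": 2 / 3, "AAC:C": 1 / 3}),
        ],
    )
    def test_aac_examples(self, seq, expected):
        fv = compute_aac(seq)
        for name, value in expected.items():
            assert fv[name] == pytest.approx(value, abs=1e-12)
        others = sum(v for n, v in zip(fv.names, fv.values) if n not in expected)
        assert others == pytest.approx(0.0, abs=1e-12)

    def test_aac_rejects_empty(self):
        with pytest.raises(InvalidSequenceError):
            compute_aac("")

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAA", {"DPC:AA": 1.0}),
            ("ACAC", {"DPC:AC": 2 / 3, "DPC:CA": 1 / 3}),
            ("AC", {"DPC:AC": 1.0}),
        ],
    )
    def test_dpc_examples(self, seq, expected):
        fv = compute_dpc(seq)
        for name, value in expected.items():
            assert fv[name] == pytest.approx(value, abs=1e-12)
        assert fv.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dpc_rejects_single_residue(self):
        with pytest.raises(InvalidSequenceError):
            compute_dpc("A")

    def test_compositions_sum_to_one(self, rng):
        for _ in range(50):
            seq = random_sequence(rng, int(rng.integers(2, 200)))
            assert compute_aac(seq).values.sum() == pytest.approx(1.0, abs=1e-9)
            assert compute_dpc(seq).values.sum() == pytest.approx(1.0, abs=1e-9)


class TestAutocorrelation:
    def test_homopolymer_moran_is_zero(self):
        config = DescriptorConfig(autocorr_method="moran", autocorr_lag_max=5)
        fv = compute_autocorrelation("A" * 30, config)
        assert np.all(fv.values == 0.0)

    def test_moreau_broto_matches_explicit_summation(self):
        config = DescriptorConfig(
            autocorr_method="moreau-broto",
            autocorr_lag_max=2,
            autocorr_scales=("kyte_doolittle",),
        )
        seq = "ACACAC"
        fv = compute_autocorrelation(seq, config)
        scale = _standardize(_scale_array("kyte_doolittle"))
        p = [scale[ALPHABET.index(ch)] for ch in seq]
        for d in (1, 2):
            expected = sum(p[i] * p[i + d] for i in range(len(p) - d)) / (len(p) - d)
            assert fv[f"AUTOCORR:moreau-broto:kyte_doolittle:{d}"] == pytest.approx(expected)

    def test_geary_lag1_matches_hand_formula(self):
        config = DescriptorConfig(
            autocorr_method="geary", autocorr_lag_max=1, autocorr_scales=("hopp_woods",)
        )
        seq = "ARARAR"
        fv = compute_autocorrelation(seq, config)
        scale = _standardize(_scale_array("hopp_woods"))
        p = np.array([scale[ALPHABET.index(ch)] for ch in seq])
        L = len(p)
        num = ((p[:-1] - p[1:]) ** 2).sum() / (2 * (L - 1))
        den = ((p - p.mean()) ** 2).sum() / (L - 1)
        assert fv["AUTOCORR:geary:hopp_woods:1"] == pytest.approx(num / den)

    def test_rejects_too_short_sequence(self):
        config = DescriptorConfig(autocorr_lag_max=30)
        with pytest.raises(InvalidSequenceError, match="AUTOCORR"):
            compute_autocorrelation("ACDEFGHIKL", config)


class TestCTD:
    def test_single_class_sequence(self):
        # "LLLL": hydrophobic class of every attribute it belongs to
        fv = compute_ctd("LLLL")
        comp = [fv[f"CTD:hydrophobicity:C:{c}"] for c in (1, 2, 3)]
        assert comp == [0.0, 0.0, 1.0]
        for pair in ("12", "13", "23"):
            assert fv[f"CTD:hydrophobicity:T:{pair}"] == 0.0

    def test_transition_fraction(self):
        # A is neutral (class 2), R is polar (class 1): one 2->1 crossing in 5 pairs
        fv = compute_ctd("AAARRR")
        assert fv["CTD:hydrophobicity:T:12"] == pytest.approx(1 / 5)
        assert fv["CTD:hydrophobicity:T:13"] == 0.0

    def test_distribution_boundary_last_position(self):
        # hydrophobic residue (class 3) only at the final position
        fv = compute_ctd("AAAAC")
        for q in (0, 25, 50, 75, 100):
            assert fv[f"CTD:hydrophobicity:D:3:{q}"] == pytest.approx(100.0)

    def test_attribute_partitions_cover_alphabet(self):
        for attr, classes in CTD_ATTRIBUTES.items():
            merged = "".join(classes)
            assert sorted(merged) == sorted(ALPHABET), attr


class TestQSO:
    def test_small_weight_limit_recovers_aac(self):
        config = DescriptorConfig(qso_lag_max=3, qso_weight=1e-12)
        seq = "ACDEFGHIKLMNPQRSTVWY"
        fv = compute_qso(seq, config)
        aac = compute_aac(seq)
        for aa, expected in zip(ALPHABET, aac.values):
            assert fv[f"QSO:grantham:AAC:{aa}"] == pytest.approx(expected, abs=1e-6)

    def test_homopolymer_coupling_terms_vanish(self):
        config = DescriptorConfig(qso_lag_max=3)
        fv = compute_qso("A" * 40, config)
        for matrix in ("grantham", "physchem"):
            for d in (1, 2, 3):
                assert fv[f"QSO:{matrix}:tau:{d}"] == 0.0

    def test_coupling_matches_brute_force_double_loop(self, rng):
        from locforge.descriptors import grantham_distance_matrix

        config = DescriptorConfig(qso_lag_max=3, qso_weight=0.1)
        seq = random_sequence(rng, 25)
        fv = compute_qso(seq, config)
        G = grantham_distance_matrix()
        taus = []
        for d in (1, 2, 3):
            taus.append(
                sum(
                    G[ALPHABET.index(seq[i]), ALPHABET.index(seq[i + d])] ** 2
                    for i in range(len(seq) - d)
                )
            )
        denom = 1 + 0.1 * sum(taus)
        for d, tau in zip((1, 2, 3), taus):
            assert fv[f"QSO:grantham:tau:{d}"] == pytest.approx(0.1 * tau / denom)

    def test_each_block_is_normalized(self, rng):
        config = DescriptorConfig(qso_lag_max=5)
        seq = random_sequence(rng, 60)
        fv = compute_qso(seq, config)
        for matrix in ("grantham", "physchem"):
            block = [v for n, v in zip(fv.names, fv.values) if n.startswith(f"QSO:{matrix}:")]
            assert sum(block) == pytest.approx(1.0, abs=1e-9)


class TestPAAC:
    def test_small_weight_limit_recovers_aac(self):
        config = DescriptorConfig(paac_lambda=3, paac_weight=1e-12)
        seq = "ACDEFGHIKLMNPQRSTVWY"
        fv = compute_paac(seq, config)
        aac = compute_aac(seq)
        for aa, expected in zip(ALPHABET, aac.values):
            assert fv[f"PAAC:{aa}"] == pytest.approx(expected, abs=1e-6)

    def test_homopolymer_theta_vanishes(self):
        config = DescriptorConfig(paac_lambda=3)
        fv = compute_paac("A" * 40, config)
        for j in (1, 2, 3):
            assert fv[f"PAAC:theta:{j}"] == 0.0

    def test_theta1_matches_hand_double_loop(self):
        from locforge.descriptors import PAAC_SCALES

        config = DescriptorConfig(paac_lambda=1, paac_weight=0.05)
        seq = "ACACAC"
        fv = compute_paac(seq, config)
        scales = [_standardize(_scale_array(n)) for n in PAAC_SCALES]
        theta1 = 0.0
        for i in range(len(seq) - 1):
            a, b = ALPHABET.index(seq[i]), ALPHABET.index(seq[i + 1])
            theta1 += np.mean([(s[b] - s[a]) ** 2 for s in scales])
        theta1 /= len(seq) - 1
        denom = 1 + 0.05 * theta1
        assert fv["PAAC:theta:1"] == pytest.approx(0.05 * theta1 / denom)

    def test_apaac_has_two_tau_tracks(self):
        config = DescriptorConfig(paac_lambda=2)
        fv = compute_paac("ACDEFGHIKL" * 4, config, amphiphilic=True)
        assert len(fv) == 20 + 2 * 2


class TestProfile:
    def test_single_family_identity(self):
        config = DescriptorConfig(families=("AAC",))
        seq = "ACDEFG"
        profile = compute_descriptor_profile(seq, config)
        aac = compute_aac(seq)
        assert profile.names == aac.names
        np.testing.assert_array_equal(profile.values, aac.values)

    def test_default_profile_length_matches_documented_sum(self):
        config = DescriptorConfig()
        # AAC 20 + DPC 400 + autocorr 6*30 + CTD 7*21 + QSO 2*(20+30)
        # + PAAC (20+30) + APAAC (20+60)
        expected = 20 + 400 + 180 + 147 + 100 + 50 + 80
        assert profile_length(config) == expected
        seq = random_sequence(np.random.default_rng(0), 60)
        assert len(compute_descriptor_profile(seq, config)) == expected

    def test_family_permutation_permutes_blocks_only(self, short_config):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        a = compute_descriptor_profile(seq, short_config.with_families(("AAC", "CTD")))
        b = compute_descriptor_profile(seq, short_config.with_families(("CTD", "AAC")))
        assert set(a.names) == set(b.names)
        for name in a.names:
            assert a[name] == b[name]

    def test_error_names_offending_family(self, short_config):
        config = short_config.with_families(("AAC", "QSO"))
        with pytest.raises(InvalidSequenceError, match="QSO"):
            compute_descriptor_profile("AC", config)

    def test_determinism_bit_identical(self, short_config, rng):
        seq = random_sequence(rng, 50)
        a = compute_descriptor_profile(seq, short_config)
        b = compute_descriptor_profile(seq, short_config)
        assert a.names == b.names
        assert np.array_equal(a.values, b.values)

    def test_fuzz_descriptors_finite(self, rng):
        config = DescriptorConfig()
        min_len = config.min_sequence_length
        for _ in range(1000):
            seq = random_sequence(rng, int(rng.integers(min_len, min_len + 60)))
            fv = compute_descriptor_profile(seq, config)
            assert np.all(np.isfinite(fv.values))

    def test_feature_table_shape_and_order(self, short_config):
        table = feature_table(
            {"p1": "ACDEFGHIKLMNPQRSTVWY", "p2": "AAAACCCCDDDDEEEEFFFF"}, short_config
        )
        assert table.shape == (2, profile_length(short_config))
        assert list(table.index) == ["p1", "p2"]


class TestSanitization:
    def test_drops_noncanonical_and_uppercases(self):
        assert sanitize_sequence("acXdeBZJOU-") == "ACDE"

    def test_clean_sequence_unchanged(self):
        assert sanitize_sequence("ACDEFGHIKLMNPQRSTVWY") == ALPHABET
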