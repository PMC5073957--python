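import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chargescan import (
    Polarity,
    ProteinLabel,
    ProteinRecord,
    ScanConfig,
    binomial_tail,
    critical_count,
    encode_charge,
    estimate_background,
    flag_cpp_candidates,
    scan_protein,
    scan_proteome,
)

import oracles
from conftest import make_cluster, random_sequence


class TestEncodeCharge:
    @pytest.mark.parametrize(
        "sequence,polarity,expected",
        [
            ("KRDEA", Polarity.POSITIVE, [1, 1, 0, 0, 0]),
            ("KRDEA", Polarity.NEGATIVE, [0, 0, 1, 1, 0]),
            ("HXHX", Polarity.POSITIVE, [0, 0, 0, 0]),  # His and X are neutral
            ("BZUOJ", Polarity.NEGATIVE, [0] * 5),
        ],
    )
    def test_indicator(self, sequence, polarity, expected):
        assert encode_charge(sequence, polarity).tolist() == expected


class TestEstimateBackground:
    def test_proteome_pooled(self):
        records = [ProteinRecord(id="a", sequence="KA"), ProteinRecord(id="b", sequence="AA")]
        assert estimate_background(records, Polarity.POSITIVE) == pytest.approx(0.25)

    def test_single_record(self):
        records = [ProteinRecord(id="a", sequence="KKAA")]
        assert estimate_background(records, Polarity.POSITIVE) == pytest.approx(0.5)

    def test_per_protein(self):
        config = ScanConfig(background_mode="per_protein")
        records = [ProteinRecord(id="a", sequence="KKAA"), ProteinRecord(id="b", sequence="DDDA")]
        p0 = estimate_background(records, Polarity.NEGATIVE, config)
        assert p0 == {"a": 0.0, "b": pytest.approx(0.75)}

    def test_fixed_passthrough_and_missing(self, fixed_config):
        assert estimate_background([], Polarity.POSITIVE, fixed_config) == 0.05
        with pytest.raises(ValueError, match="fixed"):
            estimate_background([], Polarity.POSITIVE, ScanConfig(background_mode="fixed"))


class TestBinomialTail:
    def test_whole_support_is_one(self):
        assert binomial_tail(0, 20, 0.3) == 1.0

    def test_closed_form_all_successes(self):
        assert binomial_tail(20, 20, 0.5) == pytest.approx(0.5**20, rel=1e-12)

    @pytest.mark.parametrize("k,n,p", [(10, 20, 0.1), (5, 20, 0.02), (3, 7, 0.3), (50, 100, 0.4)])
    def test_matches_exact_summation(self, k, n, p):
        assert binomial_tail(k, n, p) == pytest.approx(oracles.tail_float(k, n, p), rel=1e-10)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            binomial_tail(5, 4, 0.1)
        with pytest.raises(ValueError):
            binomial_tail(1, 4, 1.5)


class TestCriticalCount:
    def test_degenerate_null(self):
        assert critical_count(20, 0.0, 1e-5) == 1

    @pytest.mark.parametrize("w,p0,alpha,expected", [(20, 0.1, 1e-5, 10), (20, 0.5, 1e-5, 20)])
    def test_reference_values(self, w, p0, alpha, expected):
        assert critical_count(w, p0, alpha) == expected
        assert oracles.brute_force_critical_count(w, p0, alpha) == expected

    def test_unattainable_returns_none(self):
        # even k = w has tail 0.9^3 = 0.729 > 1e-5
        assert critical_count(3, 0.9, 1e-5) is None

    def test_matches_oracle_on_grid(self):
        for p0 in (0.01, 0.05, 0.1, 0.2, 0.3, 0.5):
            for alpha in (1e-3, 1e-5, 1e-8):
                assert critical_count(20, p0, alpha) == oracles.brute_force_critical_count(
                    20, p0, alpha
                ), (p0, alpha)

    def test_monotone_in_alpha_and_p0(self):
        alphas = [1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8]
        p0s = [0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5]
        big = 10**9  # stand-in for the unattainable sentinel
        for p0 in p0s:
            ks = [critical_count(20, p0, a) for a in alphas]
            ks = [big if k is None else k for k in ks]
            assert ks == sorted(ks)  # k* non-increasing as alpha grows
        for alpha in alphas:
            ks = [critical_count(20, p0, alpha) for p0 in p0s]
            ks = [big if k is None else k for k in ks]
            assert ks == sorted(ks)  # k* non-decreasing in p0


class TestScanProtein:
    def test_planted_run_detected_and_trimmed(self, planted_record, fixed_config):
        (cluster,) = scan_protein(planted_record, Polarity.POSITIVE, 0.05, fixed_config)
        assert (cluster.start, cluster.end, cluster.length) == (11, 22, 12)
        assert cluster.charged_count == 12
        assert cluster.net_charge == 12
        assert cluster.min_window_p <= fixed_config.alpha

    def test_neutral_sequence_yields_nothing(self, fixed_config):
        record = ProteinRecord(id="n", sequence="A" * 40)
        assert scan_protein(record, Polarity.POSITIVE, 0.05, fixed_config) == []
        assert scan_protein(record, Polarity.NEGATIVE, 0.05, fixed_config) == []

    def test_short_protein_single_window(self, fixed_config):
        # length 10 < w: the whole sequence is the only window (width 10)
        record = ProteinRecord(id="s", sequence="AKKKKKKKKA")
        (cluster,) = scan_protein(record, Polarity.POSITIVE, 0.05, fixed_config)
        assert (cluster.start, cluster.end) == (2, 9)
        assert cluster.min_window_p == pytest.approx(
            oracles.tail_float(8, 10, 0.05), rel=1e-10
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        length=st.integers(10, 200),
        p_pos=st.floats(0.02, 0.3),
    )
    def test_matches_brute_force_oracle(self, seed, length, p_pos):
        config = ScanConfig(window_w=20, alpha=1e-5)
        rng = np.random.default_rng(seed)
        sequence = random_sequence(rng, length, p_pos, 0.1)
        record = ProteinRecord(id="r", sequence=sequence)
        clusters = scan_protein(record, Polarity.POSITIVE, p_pos, config)
        expected = oracles.brute_force_scan(
            sequence, oracles.POSITIVE, p_pos, config.window_w, config.alpha
        )
        assert [(c.start, c.end) for c in clusters] == expected
        for c in clusters:
            assert c.sequence[0] in "KR" and c.sequence[-1] in "KR"
            assert c.min_window_p <= config.alpha
        for a, b in zip(clusters, clusters[1:]):
            assert a.end < b.start  # disjoint, sorted


class TestScanProteome:
    def test_mixed_labels_and_counts(self, fixed_config):
        records = [
            ProteinRecord(id="mix", sequence="K" * 12 + "A" * 30 + "D" * 12),
            ProteinRecord(id="pos", sequence="K" * 12 + "A" * 30),
            ProteinRecord(id="neg", sequence="A" * 30 + "E" * 12),
            ProteinRecord(id="free", sequence="AG" * 30),
        ]
        clusters, classifications = scan_proteome(records, fixed_config)
        labels = {c.protein_id: c.label for c in classifications}
        assert labels == {
            "mix": ProteinLabel.MIXED,
            "pos": ProteinLabel.PCC_ONLY,
            "neg": ProteinLabel.NCC_ONLY,
            "free": ProteinLabel.CC_FREE,
        }
        assert sum(c.polarity is Polarity.POSITIVE for c in clusters) == 2
        assert sum(c.polarity is Polarity.NEGATIVE for c in clusters) == 2

    def test_neutral_proteome_all_cc_free(self, fixed_config):
        records = [ProteinRecord(id=f"p{i}", sequence="AGST" * 20) for i in range(5)]
        clusters, classifications = scan_proteome(records, fixed_config)
        assert clusters == []
        assert all(c.label is ProteinLabel.CC_FREE for c in classifications)

    def test_mixed_label_iff_both_polarities(self, fixed_config):
        rng = np.random.default_rng(7)
        records = [
            ProteinRecord(id=f"r{i}", sequence=random_sequence(rng, 300, 0.08, 0.08))
            for i in range(30)
        ]
        clusters, classifications = scan_proteome(records, fixed_config)
        pos = {c.protein_id for c in clusters if c.polarity is Polarity.POSITIVE}
        neg = {c.protein_id for c in clusters if c.polarity is Polarity.NEGATIVE}
        mixed = {c.protein_id for c in classifications if c.label is ProteinLabel.MIXED}
        assert mixed == pos & neg


class TestCppFlag:
    @pytest.mark.parametrize(
        "polarity,length,expected",
        [
            (Polarity.POSITIVE, 7, True),
            (Polarity.POSITIVE, 15, True),
            (Polarity.POSITIVE, 30, True),
            (Polarity.POSITIVE, 6, False),
            (Polarity.POSITIVE, 31, False),
            (Polarity.POSITIVE, 61, False),
            (Polarity.NEGATIVE, 15, False),
        ],
    )
    def test_length_window_and_polarity(self, polarity, length, expected):
        cluster = make_cluster(polarity=polarity, start=1, end=length)
        (flagged,) = flag_cpp_candidates([cluster])
        assert flagged.cpp_candidate is expected
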