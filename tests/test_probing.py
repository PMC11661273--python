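"""Probing simulator and distance/JSD/variance statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnaed.probing import (
    DistanceDistribution,
    ProbingRead,
    ReadSimConfig,
    distance_distribution,
    group_jsd,
    jsd,
    ned_correlation,
    read_distance,
    simulate_reads,
    state_variance,
)
from rnaed.thermo.fold import FoldTables, PairProbMatrix
from rnaed.thermo.model import EnergyModel

from conftest import random_rna


def _mk_read(rid, start, end, a_positions, modified):
    calls = tuple(1 if p in modified else 0 for p in a_positions)
    return ProbingRead(rid, start, end, tuple(a_positions), calls)


class TestSimulateReads:
    def test_zero_rates_give_no_calls(self, model, small_transcript):
        cfg = ReadSimConfig(n_reads=20, mod_rate_ss=0, mod_rate_ds=0,
                            min_length=30, seed=1)
        reads = simulate_reads(small_transcript.seq, model, cfg)
        assert all(sum(r.calls) == 0 for r in reads)

    def test_deterministic_rates_mark_unpaired_adenosines(self, model):
        # frozen ensemble: T -> 0 keeps every draw at the unique MFE structure
        seq = "GGGAAAACCCAAAA"
        cold = EnergyModel(temperature=5.0)
        cfg = ReadSimConfig(n_reads=10, mod_rate_ss=1.0, mod_rate_ds=0.0,
                            length_log_mean=math.log(len(seq)), length_log_sd=0.0,
                            min_length=len(seq), seed=2)
        reads = simulate_reads(seq, cold, cfg)
        mfe = FoldTables(seq, cold).mfe_structure()
        unpaired_a = {
            i for i, c in enumerate(seq) if c == "A" and not mfe.paired_mask()[i]
        }
        for r in reads:
            assert set(r.modified_positions) == unpaired_a

    def test_per_position_frequency_matches_pairedness_oracle(self, model):
        seq = "GCGCAAAAGCGCAAAAGGAUAUCC"
        cfg = ReadSimConfig(n_reads=10_000, min_length=len(seq),
                            length_log_mean=math.log(len(seq)),
                            length_log_sd=0.0, seed=3)
        reads = simulate_reads(seq, model, cfg)
        q = FoldTables(seq, model).pair_probabilities().q
        a_pos = [i for i, c in enumerate(seq) if c == "A"]
        counts = {p: 0 for p in a_pos}
        for r in reads:
            for p in r.modified_positions:
                counts[p] += 1
        for p in a_pos:
            expect = cfg.mod_rate_ss * (1 - q[p]) + cfg.mod_rate_ds * q[p]
            se = math.sqrt(expect * (1 - expect) / cfg.n_reads)
            assert abs(counts[p] / cfg.n_reads - expect) < 3 * se + 1e-9

    def test_unprobed_control_uses_background_rate_everywhere(self, model):
        seq = "GCGCAAAAGCGCAAAAGGAUAUCC"
        cfg = ReadSimConfig(n_reads=4000, probed=False, min_length=len(seq),
                            length_log_mean=math.log(len(seq)),
                            length_log_sd=0.0, seed=4)
        reads = simulate_reads(seq, model, cfg)
        n_a = sum(1 for c in seq if c == "A")
        rate = sum(sum(r.calls) for r in reads) / (n_a * cfg.n_reads)
        se = math.sqrt(cfg.mod_rate_ds * (1 - cfg.mod_rate_ds) / (n_a * cfg.n_reads))
        assert abs(rate - cfg.mod_rate_ds) < 4 * se

    def test_too_short_sequence_rejected(self, model):
        with pytest.raises(ValueError):
            simulate_reads("GAAAC", model, ReadSimConfig(min_length=50))


class TestReadDistance:
    def test_identical_reads(self):
        r = _mk_read("a", 0, 10, [1, 4, 7], {4})
        assert read_distance(r, r, min_overlap=1) == 0.0

    def test_complementary_calls(self):
        a = _mk_read("a", 0, 10, [1, 4, 7], {1, 4, 7})
        b = _mk_read("b", 0, 10, [1, 4, 7], set())
        assert read_distance(a, b, min_overlap=1) == 1.0

    def test_hand_counted_partial_overlap(self):
        # shared adenosines: 50..99 region -> positions 60, 75, 90
        a = _mk_read("a", 0, 100, [10, 30, 60, 75, 90], {10, 60})
        b = _mk_read("b", 50, 150, [60, 75, 90, 120], {75})
        # shared {60, 75, 90}: calls a=(1,0,0) b=(0,1,0) -> 2 of 3 differ
        assert read_distance(a, b, min_overlap=3) == pytest.approx(2 / 3)

    def test_insufficient_overlap_is_none_not_error(self):
        a = _mk_read("a", 0, 10, [1], set())
        b = _mk_read("b", 0, 10, [1], set())
        assert read_distance(a, b, min_overlap=2) is None

    def test_symmetry(self, rng):
        pos = sorted(rng.choice(100, 20, replace=False))
        a = _mk_read("a", 0, 100, pos, set(int(p) for p in pos[::2]))
        b = _mk_read("b", 0, 100, pos, set(int(p) for p in pos[::3]))
        assert read_distance(a, b, 5) == read_distance(b, a, 5)


class TestDistanceDistribution:
    def test_two_identical_reads(self):
        r1 = _mk_read("a", 0, 10, [1, 4, 7], {4})
        r2 = _mk_read("b", 0, 10, [1, 4, 7], {4})
        d = distance_distribution([r1, r2], top_k=2, min_overlap=1)
        assert d.values.tolist() == [0.0]

    def test_all_pairs_below_overlap_flagged(self):
        reads = [
            _mk_read("a", 0, 5, [1], set()),
            _mk_read("b", 5, 10, [7], set()),
        ]
        d = distance_distribution(reads, top_k=2, min_overlap=1)
        assert d.values.size == 0 and d.n_undefined == 1

    def test_pair_count_bookkeeping(self, model, small_transcript):
        cfg = ReadSimConfig(n_reads=60, min_length=30, seed=5)
        reads = simulate_reads(small_transcript.seq, model, cfg)
        d = distance_distribution(reads, top_k=60, min_overlap=5)
        assert d.values.size + d.n_undefined == 60 * 59 // 2

    def test_top_k_selects_longest(self, model, small_transcript):
        cfg = ReadSimConfig(n_reads=50, min_length=30, seed=6)
        reads = simulate_reads(small_transcript.seq, model, cfg)
        lengths = sorted((len(r) for r in reads), reverse=True)
        d = distance_distribution(reads, top_k=10, min_overlap=1)
        # pairs among the 10 longest only
        assert d.values.size + d.n_undefined == 45
        assert min(lengths[:10]) >= lengths[10]

    def test_fewer_than_two_reads_rejected(self):
        with pytest.raises(ValueError):
            distance_distribution([_mk_read("a", 0, 5, [1], set())])


class TestJSD:
    def test_identical_distributions(self):
        d = DistanceDistribution(np.array([0.1, 0.5, 0.9]))
        assert jsd(d, d) == 0.0

    def test_disjoint_support_is_one(self):
        a = DistanceDistribution(np.full(10, 0.05))
        b = DistanceDistribution(np.full(10, 0.95))
        assert jsd(a, b) == pytest.approx(1.0)

    def test_two_bin_closed_form(self):
        # histograms (0.5, 0.5) vs (1, 0) over two bins
        a = DistanceDistribution(np.array([0.2, 0.8]), bins=2)
        b = DistanceDistribution(np.array([0.2, 0.2]), bins=2)
        m = np.array([0.75, 0.25])
        kl_a = 0.5 * math.log2(0.5 / 0.75) + 0.5 * math.log2(0.5 / 0.25)
        kl_b = 1.0 * math.log2(1.0 / 0.75)
        expected = math.sqrt(0.5 * kl_a + 0.5 * kl_b)
        assert jsd(a, b) == pytest.approx(expected, rel=1e-12)

    def test_empty_distribution_rejected(self):
        a = DistanceDistribution(np.array([]))
        b = DistanceDistribution(np.array([0.5]))
        with pytest.raises(ValueError):
            jsd(a, b)

    def test_group_table(self):
        lo = [DistanceDistribution(np.full(20, v)) for v in (0.10, 0.12, 0.11)]
        hi = [DistanceDistribution(np.full(20, v)) for v in (0.80, 0.82, 0.81)]
        table = group_jsd({"low": lo, "high": hi})
        assert table.loc["low", "high"] > table.loc["low", "low"]
        assert table.loc["low", "high"] > table.loc["high", "high"]
        single = group_jsd({"only": [lo[0]]})
        assert math.isnan(single.loc["only", "only"])


class TestStateVariance:
    def test_binary_pairedness(self):
        p = np.zeros((6, 6))
        p[0, 5] = p[5, 0] = p[1, 4] = p[4, 1] = 1.0
        res = state_variance(PairProbMatrix(p))
        assert res.ed_hat == 0.0
        m = res.mean_pairedness
        assert res.variance == pytest.approx(m * (1 - m), abs=1e-15)

    def test_uniform_half_pairedness(self):
        p = np.zeros((8, 8))
        for i in range(4):
            j = 7 - i
            p[i, j] = p[j, i] = 0.5
        res = state_variance(PairProbMatrix(p))
        assert res.variance == pytest.approx(0.0, abs=1e-15)
        assert res.ed_hat / 8 == pytest.approx(0.25)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_identity_holds_to_machine_precision(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        # random valid-ish symmetric matrix with row sums <= 1
        p = np.triu(rng.random((n, n)), k=1)
        p = p + p.T
        p = p / np.maximum(1.0, p.sum(axis=1)).max()
        res = state_variance(PairProbMatrix(p))
        assert abs(res.identity_residual) < 1e-12

    def test_identity_on_real_ensembles(self, model, rng):
        for _ in range(5):
            seq = random_rna(rng, 60)
            P = FoldTables(seq, model).pair_probabilities()
            assert abs(state_variance(P).identity_residual) < 1e-12


class TestNedCorrelation:
    def test_perfect_linear(self):
        pairs = [
            (x, DistanceDistribution(np.full(10, 0.1 + 0.5 * x)))
            for x in (0.2, 0.4, 0.6, 0.8)
        ]
        r, p = ned_correlation(pairs)
        assert r == pytest.approx(1.0)

    def test_zero_variance_signalled(self):
        pairs = [(0.5, DistanceDistribution(np.full(10, 0.3)))] * 3
        with pytest.raises(ValueError, match="zero-variance"):
            ned_correlation(pairs)

    def test_requires_three_sequences(self):
        with pytest.raises(ValueError):
            ned_correlation([(0.1, DistanceDistribution(np.array([0.2])))] * 2)
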