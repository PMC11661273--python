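"""Ensemble engine vs the exhaustive enumeration oracle, plus closed forms."""

import math

import numpy as np
import pytest
from scipy import stats

from rnaed.thermo.exhaustive import (
    boltzmann_weights,
    count_structures,
    enumerate_structures,
)
from rnaed.thermo.fold import (
    FoldTables,
    PairProbMatrix,
    centroid_structure,
    cofold,
    ensemble_diversity,
    ensemble_summary,
    mfe_structure,
    partition_function,
    sample_structures,
)
from rnaed.thermo.model import EnergyModel, SecondaryStructure

from conftest import random_rna


@pytest.fixture(scope="module")
def gc_neutral_model():
    """e(GC) = 0 so GAAAC has exactly two equi-probable structures."""
    return EnergyModel(pair_energies={"GC": 0.0, "AU": -2.0, "GU": -1.0})


class TestClosedForms:
    def test_unpairable_chain(self, model):
        Z, G = partition_function("AAAA", model)
        assert Z == pytest.approx(1.0)
        assert G == pytest.approx(0.0, abs=1e-12)
        assert ensemble_diversity(FoldTables("AAAA", model).pair_probabilities()) == 0.0

    def test_two_structure_hairpin(self, model):
        # GAAAC: open chain or the single GC pair (min_hairpin = 3)
        w = math.exp(3.0 / model.RT)
        Z, G = partition_function("GAAAC", model)
        assert Z == pytest.approx(1 + w, rel=1e-12)
        P = FoldTables("GAAAC", model).pair_probabilities()
        assert P.p[0, 4] == pytest.approx(w / (1 + w), rel=1e-12)
        assert np.sum(P.p) == pytest.approx(2 * w / (1 + w))  # symmetric matrix

    def test_half_probability_pair_gives_ed_half(self, gc_neutral_model):
        P = FoldTables("GAAAC", gc_neutral_model).pair_probabilities()
        assert P.p[0, 4] == pytest.approx(0.5, rel=1e-12)
        assert ensemble_diversity(P) == pytest.approx(0.5, rel=1e-12)

    def test_ed_closed_form_on_synthetic_matrices(self):
        assert ensemble_diversity(np.zeros((6, 6))) == 0.0
        p = np.zeros((6, 6))
        p[0, 5] = p[5, 0] = 1.0  # deterministic pair: no diversity
        assert ensemble_diversity(p) == 0.0

    def test_mfe_trivial(self, model):
        s, e = mfe_structure("AAAA", model)
        assert (len(s.pairs), e) == (0, 0.0)
        s, e = mfe_structure("GAAAC", model)
        assert s.pairs == frozenset({(0, 4)})
        assert e == pytest.approx(-3.0)


class TestEnumerationOracle:
    def test_counts(self, model):
        assert len(enumerate_structures("AAAA", model)) == 1
        assert len(enumerate_structures("GAAAC", model)) == 2

    def test_count_recursion_matches_enumeration(self, model, rng):
        for _ in range(10):
            seq = random_rna(rng, int(rng.integers(4, 12)))
            assert len(enumerate_structures(seq, model)) == count_structures(seq, model)

    def test_length_guard(self, model):
        with pytest.raises(ValueError):
            enumerate_structures("A" * 25, model)


@pytest.mark.parametrize("stacking", [0.0, -0.5])
def test_dp_matches_enumeration(stacking, rng):
    """Z, p_ij, ED and MFE from the DP equal brute-force Boltzmann sums."""
    model = EnergyModel(stacking_bonus=stacking)
    for _ in range(12):
        n = int(rng.integers(4, 13))
        seq = random_rna(rng, n)
        structs = enumerate_structures(seq, model)
        w = boltzmann_weights(structs, model)
        e = np.array([en for _, en in structs])
        z_ref = np.exp(-e / model.RT).sum()

        t = FoldTables(seq, model)
        assert math.exp(t.log_Z) == pytest.approx(z_ref, rel=1e-9)
        assert t.mfe_energy == pytest.approx(e.min(), abs=1e-9)
        assert t.mfe_structure().energy(seq, model) == pytest.approx(e.min(), abs=1e-9)

        p_ref = np.zeros((n, n))
        for (s, _), wt in zip(structs, w):
            for i, j in s.pairs:
                p_ref[i, j] += wt
        p_ref = p_ref + p_ref.T
        P = t.pair_probabilities()
        assert np.max(np.abs(P.p - p_ref)) < 1e-9

        ed_ref = sum(
            wa * wb * len(sa.pairs ^ sb.pairs)
            for (sa, _), wa in zip(structs, w)
            for (sb, _), wb in zip(structs, w)
        )
        assert ensemble_diversity(P) == pytest.approx(ed_ref, abs=1e-9)


def test_centroid_minimizes_expected_distance_to_ensemble(model, rng):
    """Brute-force argmin over all enumerated candidates equals p > 1/2 rule."""
    for _ in range(8):
        seq = random_rna(rng, int(rng.integers(6, 12)))
        structs = enumerate_structures(seq, model)
        w = boltzmann_weights(structs, model)
        best = min(
            range(len(structs)),
            key=lambda c: sum(
                wt * len(structs[c][0].pairs ^ s.pairs)
                for (s, _), wt in zip(structs, w)
            ),
        )
        best_cost = sum(
            wt * len(structs[best][0].pairs ^ s.pairs)
            for (s, _), wt in zip(structs, w)
        )
        cen = centroid_structure(FoldTables(seq, model).pair_probabilities())
        cen_cost = sum(
            wt * len(cen.pairs ^ s.pairs) for (s, _), wt in zip(structs, w)
        )
        assert cen_cost <= best_cost + 1e-9


class TestSampling:
    def test_k_zero(self, model):
        assert sample_structures("GAAAC", model, 0, 1) == []

    def test_paired_fraction_matches_closed_form(self, gc_neutral_model):
        k = 10_000
        samples = sample_structures("GAAAC", gc_neutral_model, k, 42)
        frac = sum(len(s.pairs) for s in samples) / k
        sigma = math.sqrt(0.25 / k)
        assert abs(frac - 0.5) < 3 * sigma

    def test_frequencies_pass_chi2_vs_enumeration(self, model):
        seq = "GCAUCGAUGC"
        structs = enumerate_structures(seq, model)
        pb = boltzmann_weights(structs, model)
        idx = {s.pairs: i for i, (s, _) in enumerate(structs)}
        k = 20_000
        counts = np.zeros(len(structs))
        for s in sample_structures(seq, model, k, 7):
            counts[idx[s.pairs]] += 1
        expected = pb * k
        keep = expected >= 5
        chi2 = np.sum((counts[keep] - expected[keep]) ** 2 / expected[keep])
        assert stats.chi2.sf(chi2, keep.sum() - 1) > 0.01

    def test_seed_determinism(self, model):
        a = sample_structures("GCAUCGAUGC", model, 50, 3)
        b = sample_structures("GCAUCGAUGC", model, 50, 3)
        assert a == b


class TestCofold:
    def test_unpairable_dimer(self, model):
        r = cofold("AAAA", "AAAA", model)
        assert r.delta_G == pytest.approx(0.0, abs=1e-9)
        assert r.delta_ED == pytest.approx(0.0, abs=1e-9)

    def test_pure_interstrand_binding(self, model):
        r = cofold("GGG", "CCC", model)
        assert r.G_monomers == pytest.approx(0.0, abs=1e-9)
        assert r.delta_G < 0

    def test_two_strand_dp_matches_enumeration(self, model, rng):
        for _ in range(8):
            na, nb = int(rng.integers(2, 8)), int(rng.integers(2, 7))
            a, b = random_rna(rng, na), random_rna(rng, nb)
            structs = enumerate_structures(a + b, model, nick=na)
            e = np.array([en for _, en in structs])
            z_ref = np.exp(-e / model.RT).sum()
            t = FoldTables(a + b, model, nick=na)
            assert math.exp(t.log_Z) == pytest.approx(z_ref, rel=1e-9)
            w = boltzmann_weights(structs, model)
            p_ref = np.zeros((na + nb, na + nb))
            for (s, _), wt in zip(structs, w):
                for i, j in s.pairs:
                    p_ref[i, j] += wt
            assert np.max(np.abs(t.pair_probabilities().p - (p_ref + p_ref.T))) < 1e-9

    def test_homodimer_delta_g_never_positive(self, model, rng):
        for _ in range(5):
            seq = random_rna(rng, 40)
            assert cofold(seq, seq, model).delta_G <= 1e-9


class TestEnsembleProperties:
    def test_low_temperature_limit(self, rng):
        """As T -> 0, ED -> 0 and G -> MFE for unique-MFE sequences."""
        # unique MFE: the only nested 3-pair assignment is (0,9),(1,8),(2,7)
        seq = "GGGAAAACCC"
        cold = EnergyModel(temperature=5.0)
        t = FoldTables(seq, cold)
        assert t.G == pytest.approx(t.mfe_energy, rel=1e-3)
        assert ensemble_diversity(t.pair_probabilities()) < 1e-3

    def test_ed_bounded_by_length(self, model, rng):
        for _ in range(5):
            seq = random_rna(rng, int(rng.integers(20, 120)))
            t = FoldTables(seq, model)
            ed = ensemble_diversity(t.pair_probabilities())
            assert 0 <= ed <= len(seq)

    def test_partition_stable_for_long_sequences(self, model, rng):
        seq = random_rna(rng, 1200)
        t = FoldTables(seq, model)
        assert math.isfinite(t.G) and t.G < 0
        q = t.pair_probabilities().q
        assert np.all((q >= 0) & (q <= 1 + 1e-9))

    def test_summary_invariants(self, model, small_transcript):
        s = ensemble_summary(small_transcript.seq, model)
        assert s.log_Z >= 0 and s.G <= 0
        assert s.ED >= 0 and s.NED == pytest.approx(s.ED / s.n)
        assert s.mfe_energy <= 0
        assert set(s.centroid.dot_bracket()) <= set("().")


class TestSecondaryStructure:
    def test_dot_bracket_round_trip(self):
        db = "((...))..(...)"
        s = SecondaryStructure.from_dot_bracket(db)
        assert s.dot_bracket() == db

    def test_dimer_dot_bracket_uses_ampersand(self):
        s = SecondaryStructure([(0, 5)], 6, nick=3)
        assert s.dot_bracket() == "(..&..)"

    def test_pseudoknot_rejected(self):
        with pytest.raises(ValueError, match="cross"):
            SecondaryStructure([(0, 4), (2, 6)], 8)

    def test_shared_position_rejected(self):
        with pytest.raises(ValueError):
            SecondaryStructure([(0, 4), (4, 8)], 9)

    def test_basepair_distance_is_symmetric_difference(self):
        a = SecondaryStructure([(0, 5), (1, 4)], 8)
        b = SecondaryStructure([(0, 5), (2, 4)], 8)
        assert a.basepair_distance(b) == 2
        assert a.basepair_distance(a) == 0
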