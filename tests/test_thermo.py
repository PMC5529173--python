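import math
from collections import Counter

import numpy as np
import pytest

from ensemblemap import (
    EnergyModel,
    ReferenceEngine,
    SequenceRecord,
    ShapeProfile,
    enumerate_all_structures,
    exact_boltzmann_probabilities,
    get_engine,
    shape_pseudo_energy,
)
from ensemblemap.structures import SHAPE_MISSING


def exact_pair_marginals(seq, model=None):
    """Independent oracle: pair probabilities from exhaustive enumeration."""
    probs = exact_boltzmann_probabilities(seq, model=model)
    n = len(seq)
    P = np.zeros((n, n))
    for pt, p in probs.items():
        for i, j in enumerate(pt):
            if j > i + 1:
                P[i, j - 1] += p
                P[j - 1, i] += p
    return P


def helix_grammar_count(seq, min_hairpin=3, min_helix=2):
    """Independent recursive structure count (Nussinov-style, over helices)."""
    from functools import lru_cache

    from ensemblemap.thermo import ALLOWED_PAIRS

    s = seq.sequence

    @lru_cache(maxsize=None)
    def count(i, j):
        if j - i < min_hairpin + 1:
            return 1
        total = count(i + 1, j)
        for k in range(i + min_hairpin + 1, j + 1):
            total += helix(i, k) * count(k + 1, j)
        return total

    def helix(i, k):
        total = 0
        L = 0
        while True:
            a, b = i + L, k - L
            if b - a <= min_hairpin or (s[a], s[b]) not in ALLOWED_PAIRS:
                break
            L += 1
            if L >= min_helix:
                # interior must not extend the helix
                total += count(a + 1, b - 1) - helix(a + 1, b - 1)
        return total

    return count(0, len(s) - 1)


class TestPartitionFunction:
    def test_unpairable_sequence_gives_zero_matrix(self, engine):
        bppm = engine.compute_partition(SequenceRecord("x", "AAAAAA"))
        assert np.all(bppm.P == 0.0)

    @pytest.mark.parametrize("seq", [
        "GGGAAAACCC", "GGGGAAAACCCC", "ACGUACGUACGU", "CCCCAAAAGGGG",
    ])
    def test_matches_exhaustive_enumeration(self, engine, seq):
        rec = SequenceRecord("x", seq)
        P = engine.compute_partition(rec).P
        assert np.abs(P - exact_pair_marginals(rec)).max() <= 1e-9

    def test_matches_enumeration_with_lonely_pairs_allowed(self):
        model = EnergyModel(min_helix_length=1)
        rec = SequenceRecord("x", "GGGAAAACCC")
        P = ReferenceEngine(model).compute_partition(rec).P
        assert np.abs(P - exact_pair_marginals(rec, model=model)).max() <= 1e-9

    def test_invariants_hold(self, engine, toggle):
        bppm = engine.compute_partition(toggle)
        assert np.allclose(bppm.P, bppm.P.T)
        assert bppm.P.sum(axis=1).max() <= 1.0 + 1e-9
        assert np.all(np.diag(bppm.P) == 0.0)

    def test_shape_length_mismatch_rejected(self, engine, hairpin):
        bad = ShapeProfile("s", np.zeros(5))
        with pytest.raises(ValueError, match="length"):
            engine.compute_partition(hairpin, shape=bad)

    def test_shape_direction_matches_enumeration(self, engine):
        rec = SequenceRecord("x", "GGGGAAAACCCC")
        react = np.array([0.1, 1.5, 0.1, 0.1, 2.0, 2.0, SHAPE_MISSING, 2.0,
                          0.1, 0.1, 1.5, 0.1])
        shape = ShapeProfile("x", react)
        P = engine.compute_partition(rec, shape=shape).P
        probs = exact_boltzmann_probabilities(rec, shape=shape)
        n = len(rec)
        Pex = np.zeros((n, n))
        for pt, p in probs.items():
            for i, j in enumerate(pt):
                if j > i + 1:
                    Pex[i, j - 1] += p
                    Pex[j - 1, i] += p
        assert np.abs(P - Pex).max() <= 1e-9

    def test_raising_reactivity_never_increases_pairing(self, engine, hairpin):
        base = np.full(len(hairpin), 0.2)
        lowered = engine.compute_partition(
            hairpin, ShapeProfile("a", base)).pairing_probabilities()
        base2 = base.copy()
        base2[2] = 3.0  # make G3 look flexible
        raised = engine.compute_partition(
            hairpin, ShapeProfile("b", base2)).pairing_probabilities()
        assert raised[2] <= lowered[2] + 1e-12


class TestBoltzmannSampling:
    def test_zero_samples(self, engine, hairpin):
        assert engine.sample_boltzmann(hairpin, 0, seed=1) == []

    def test_seed_determinism(self, engine, hairpin):
        a = engine.sample_boltzmann(hairpin, 100, seed=11)
        b = engine.sample_boltzmann(hairpin, 100, seed=11)
        assert [s.pair_table for s in a] == [s.pair_table for s in b]
        c = engine.sample_boltzmann(hairpin, 100, seed=12)
        assert [s.pair_table for s in a] != [s.pair_table for s in c]

    def test_frequencies_match_exact_probabilities(self, engine):
        rec = SequenceRecord("x", "GGGAAAACCC")
        n = 10000
        probs = exact_boltzmann_probabilities(rec)
        counts = Counter(
            s.pair_table for s in engine.sample_boltzmann(rec, n, seed=5)
        )
        assert set(counts) <= set(probs)  # only legal structures sampled
        tv = 0.5 * sum(
            abs(counts.get(pt, 0) / n - p) for pt, p in probs.items()
        )
        assert tv < 0.03

    def test_marginals_converge_to_partition(self, engine):
        rec = SequenceRecord("x", "ACGUACGUACGU")
        n = 10000
        P = engine.compute_partition(rec).P
        freq = np.zeros_like(P)
        for s in engine.sample_boltzmann(rec, n, seed=2):
            for i, j in s.pairs():
                freq[i - 1, j - 1] += 1.0 / n
                freq[j - 1, i - 1] += 1.0 / n
        assert np.abs(freq - P).max() < 0.02


class TestShapePseudoEnergy:
    def test_zero_reactivity_gives_intercept(self):
        assert shape_pseudo_energy(0.0, m=1.8, b=-0.6) == pytest.approx(-0.6)

    def test_unit_log_point(self):
        assert shape_pseudo_energy(math.e - 1.0, m=1.8, b=-0.6) == \
            pytest.approx(1.2)

    def test_reactivity_at_or_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            shape_pseudo_energy(-1.0)
        with pytest.raises(ValueError):
            shape_pseudo_energy(SHAPE_MISSING)

    def test_missing_positions_contribute_nothing(self, engine, hairpin):
        all_missing = ShapeProfile(
            "m", np.full(len(hairpin), SHAPE_MISSING))
        with_shape = engine.compute_partition(hairpin, shape=all_missing)
        without = engine.compute_partition(hairpin)
        assert np.array_equal(with_shape.P, without.P)


class TestEnumeration:
    def test_unpairable_sequence_has_single_open_structure(self):
        structs = enumerate_all_structures(SequenceRecord("x", "AAAA"))
        assert len(structs) == 1
        assert not structs[0][0].pairs()

    def test_single_legal_pair_with_lonely_pairs_allowed(self):
        structs = enumerate_all_structures(
            SequenceRecord("x", "GAAAC"),
            model=EnergyModel(min_helix_length=1),
        )
        tables = sorted(st.pair_table for st, _ in structs)
        assert tables == [(0, 0, 0, 0, 0), (5, 0, 0, 0, 1)]

    def test_lonely_pair_excluded_by_default_model(self):
        structs = enumerate_all_structures(SequenceRecord("x", "GAAAC"))
        assert len(structs) == 1  # open chain only

    @pytest.mark.parametrize("seq", ["GGAAACC", "GGGAAAACCC", "ACGUACGUACGU"])
    def test_count_matches_independent_recursion(self, seq):
        rec = SequenceRecord("x", seq)
        assert len(enumerate_all_structures(rec)) == helix_grammar_count(rec)

    def test_guard_refuses_long_sequences(self):
        with pytest.raises(ValueError, match="refus"):
            enumerate_all_structures(SequenceRecord("x", "A" * 26))


class TestEngineSelection:
    def test_unknown_engine_rejected(self):
        with pytest.raises(ValueError):
            get_engine("nupack")

    def test_vienna_adapter_invariants_and_determinism(self, hairpin):
        vienna = get_engine("vienna")
        bppm = vienna.compute_partition(hairpin)
        assert np.allclose(bppm.P, bppm.P.T)
        assert bppm.P.sum(axis=1).max() <= 1.0 + 1e-6
        a = vienna.sample_boltzmann(hairpin, 20, seed=4)
        b = vienna.sample_boltzmann(hairpin, 20, seed=4)
        assert [s.pair_table for s in a] == [s.pair_table for s in b]
        assert all(len(s) == len(hairpin) for s in a)
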