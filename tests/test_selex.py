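"""Read processing, Markov background and CSI z-score computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csikit.selex import (
    ReadSet,
    compute_csi,
    count_kmers,
    demultiplex_and_trim,
    expected_counts,
    fit_markov_background,
    profile_from_rounds,
    top_sequences,
)
from csikit.seqcode import index_to_kmer, kmer_to_index, revcomp

from conftest import make_profile


class TestDemultiplex:
    def test_exact_barcode_match_assigns_and_trims(self):
        reads = ["AAAAAA" + "ACGT" * 5]
        out, stats = demultiplex_and_trim(reads, {"AAAAAA": "s1"})
        assert out["s1"].sequences() == ["ACGTACGTACGTACGTACGT"]
        assert stats.retained["s1"] == 1

    def test_single_mismatch_barcode_is_discarded(self):
        out, stats = demultiplex_and_trim(["AAAAAT" + "ACGT" * 5], {"AAAAAA": "s1"})
        assert "s1" not in out
        assert stats.discarded_barcode == 1

    def test_ambiguous_insert_discarded_with_count(self):
        reads = ["AAAAAA" + "ACGTNCGTACGTACGTACGT"]
        out, stats = demultiplex_and_trim(reads, {"AAAAAA": "s1"})
        assert "s1" not in out
        assert stats.discarded_ambiguous == 1

    def test_short_read_discarded(self):
        _, stats = demultiplex_and_trim(["AAAAAAACGT"], {"AAAAAA": "s1"})
        assert stats.discarded_too_short == 1

    def test_duplicate_barcode_is_configuration_error(self):
        with pytest.raises(ValueError):
            demultiplex_and_trim([], {"AAAAAA": "s1", "AAAAAa": "s2"})


class TestCountKmers:
    def test_window_count_per_read(self, toy_readset):
        counts = count_kmers(toy_readset, 10, "forward")
        assert counts.sum() == 20 - 10 + 1

    def test_collapsed_counts_are_strand_symmetric(self):
        rs = ReadSet.from_sequences("s", 3, ["AAAAAAAAAA"])
        counts = count_kmers(rs, 10, "collapsed")
        assert counts[kmer_to_index("AAAAAAAAAA")] == 1
        assert counts[kmer_to_index("TTTTTTTTTT")] == 1

    def test_hand_enumerated_windows(self):
        rs = ReadSet.from_sequences("s", 3, ["ACGTACGTACGT"])
        counts = count_kmers(rs, 10, "forward")
        nonzero = {index_to_kmer(i, 10) for i in np.flatnonzero(counts)}
        assert nonzero == {"ACGTACGTAC", "CGTACGTACG", "GTACGTACGT"}

    def test_k_larger_than_read_length_raises(self, toy_readset):
        with pytest.raises(ValueError):
            count_kmers(toy_readset, 21)


class TestMarkovBackground:
    def test_order0_degenerate_library(self):
        rs = ReadSet.from_sequences("lib", 0, ["AAAA"] * 3)
        m = fit_markov_background(rs, order=0, pseudocount=0)
        assert m.transitions[0, 0] == 1.0
        assert m.transitions[0, 1:].sum() == 0.0

    def test_order0_balanced_library_uniform(self):
        rs = ReadSet.from_sequences("lib", 0, ["ACGT", "CGTA", "GTAC", "TACG"])
        m = fit_markov_background(rs, order=0, pseudocount=0)
        np.testing.assert_allclose(m.transitions[0], 0.25)

    def test_order1_hand_counted_transitions(self):
        m = fit_markov_background(ReadSet.from_sequences("lib", 0, ["AACA"]), 1, 0)
        np.testing.assert_allclose(m.initial, [0.75, 0.25, 0, 0])
        np.testing.assert_allclose(m.transitions[0], [0.5, 0.5, 0, 0])  # after A
        np.testing.assert_allclose(m.transitions[1], [1.0, 0, 0, 0])  # after C

    def test_requires_round0(self, toy_readset):
        with pytest.raises(ValueError):
            fit_markov_background(toy_readset)

    def test_order_must_be_below_read_length(self):
        with pytest.raises(ValueError):
            fit_markov_background(ReadSet.from_sequences("lib", 0, ["ACGT"]), order=4)


def brute_force_expected(model, k, n_windows):
    """Independent oracle: enumerate every k-mer's chain-rule probability."""
    m = model.order
    out = np.zeros(4**k)
    for idx in range(4**k):
        kmer = index_to_kmer(idx, k)
        p = model.initial[kmer_to_index(kmer[:m])] if m else 1.0
        for i in range(m, k):
            ctx = kmer_to_index(kmer[i - m : i]) if m else 0
            p *= model.transitions[ctx, kmer_to_index(kmer[i])]
        out[idx] = p * n_windows
    return out


class TestExpectedCounts:
    def test_uniform_order0(self):
        rs = ReadSet.from_sequences("lib", 0, ["ACGT", "CGTA", "GTAC", "TACG"])
        m = fit_markov_background(rs, order=0, pseudocount=0)
        np.testing.assert_allclose(expected_counts(m, 2, 16), np.ones(16))

    def test_degenerate_model_concentrates_mass(self):
        m = fit_markov_background(ReadSet.from_sequences("lib", 0, ["AAAA"]), 0, 0)
        e = expected_counts(m, 3, 100)
        assert e[kmer_to_index("AAA")] == pytest.approx(100)
        assert e.sum() == pytest.approx(100)

    def test_toy_order1_matches_chain_rule(self):
        m = fit_markov_background(ReadSet.from_sequences("lib", 0, ["AACA"]), 1, 0)
        e = expected_counts(m, 2, 8)
        assert e[kmer_to_index("AC")] == pytest.approx(8 * 0.75 * 0.5)
        np.testing.assert_allclose(e, brute_force_expected(m, 2, 8), atol=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_matches_brute_force_enumeration(self, k, rng):
        reads = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(30)]
        m = fit_markov_background(ReadSet.from_sequences("lib", 0, reads), order=1)
        e = expected_counts(m, k, 1000)
        np.testing.assert_allclose(e, brute_force_expected(m, k, 1000), rtol=1e-9)
        assert e.sum() == pytest.approx(1000, rel=1e-9)

    def test_k_at_or_below_order_raises(self):
        m = fit_markov_background(ReadSet.from_sequences("lib", 0, ["ACGTACGT"]), 2)
        with pytest.raises(ValueError):
            expected_counts(m, 2, 10)


class TestComputeCsi:
    def test_hand_computed_population_zscores(self):
        p = compute_csi(np.array([0.0, 0, 0, 4]), np.ones(4), "forward")
        np.testing.assert_allclose(
            p.csi, [-1 / np.sqrt(3)] * 3 + [3 / np.sqrt(3)], atol=1e-12
        )

    def test_zero_variance_guard(self):
        p = compute_csi(np.full(16, 2.0), np.full(16, 2.0), "forward")
        np.testing.assert_array_equal(p.csi, 0.0)

    def test_standardization_over_full_table(self, rng):
        obs = rng.poisson(3.0, 4**5).astype(float)
        p = compute_csi(obs, np.full(4**5, 3.0), "forward")
        assert abs(p.csi.mean()) < 1e-6
        assert abs(p.csi.std() - 1) < 1e-6

    def test_collapsed_mode_exact_strand_symmetry(self, rng):
        obs = rng.poisson(3.0, 4**4).astype(float)
        p = compute_csi(obs, np.full(4**4, 3.0), "collapsed")
        for idx in range(4**4):
            w = index_to_kmer(idx, 4)
            assert p.csi[idx] == p.csi[kmer_to_index(revcomp(w))]

    def test_permutation_invariance(self, rng):
        obs = rng.poisson(3.0, 4**3).astype(float)
        exp = rng.uniform(1, 5, 4**3)
        base = compute_csi(obs, exp, "forward").csi
        perm = rng.permutation(4**3)
        permuted = compute_csi(obs[perm], exp[perm], "forward").csi
        np.testing.assert_allclose(permuted, base[perm], atol=1e-12)

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            compute_csi(np.ones(4), np.array([1.0, 0, 1, 1]), "forward")


class TestTopSequences:
    def test_argmax_and_lexicographic_ties(self, rng):
        csi = np.zeros(4**2)
        csi[kmer_to_index("GT")] = 5.0
        csi[kmer_to_index("CA")] = 5.0
        p = make_profile(csi, 2)
        assert top_sequences(p, 2) == ["CA", "GT"]
        assert p.top_kmer() == "CA"

    def test_n_out_of_range(self, rng):
        p = make_profile(np.zeros(16), 2)
        with pytest.raises(ValueError):
            top_sequences(p, 0)
        with pytest.raises(ValueError):
            top_sequences(p, 17)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(1, 8), st.integers(2, 6))
def test_window_count_invariant(n_reads, k):
    """Each read contributes L-k+1 forward windows, whatever its content."""
    rng = np.random.default_rng(n_reads * 100 + k)
    reads = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(n_reads)]
    rs = ReadSet.from_sequences("s", 1, reads)
    assert count_kmers(rs, k, "forward").sum() == n_reads * (12 - k + 1)


def test_null_selection_has_few_extreme_zscores():
    """Round-3 resampled from the round-0 model itself: the collapsed CSI
    distribution stays near-Gaussian, with |z| > 4 rarer than 1e-3."""
    from csikit.simulate import GroundTruthDimer, SimulationConfig, simulate_library, simulate_selex

    null = GroundTruthDimer(
        dimer_id="null", mode="emergent", emergent_site="TGACGCAT", peak_affinity=1.0
    )
    config = SimulationConfig(n_reads=200_000, rounds=3, rng_seed=7)
    library = simulate_library(config)
    rounds = simulate_selex(library, null, config)
    profile = profile_from_rounds(library, rounds[-1], k=10)
    assert np.mean(np.abs(profile.csi) > 4) < 1e-3
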