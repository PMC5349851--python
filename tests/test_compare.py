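"""Profile comparison, heterodimer assignment and motif-architecture calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csikit.compare import (
    assign_specificity,
    build_comparison_set,
    classify_architecture,
    cluster_dimers,
    correlation_matrix,
    enumerate_dimers,
    n_possible_dimers,
    percentage,
    score_site,
)
from csikit.selex import top_sequences
from csikit.seqcode import index_to_kmer, kmer_to_index, revcomp

from conftest import make_profile, random_profile

REPLICATE_RS = [0.7, 0.75, 0.8, 0.85, 0.9, 0.65, 0.85, 0.9]  # mean 0.8 +/- ~0.1


class TestDimerEnumeration:
    def test_counts_match_pair_formula(self):
        assert n_possible_dimers(53) == 1431
        assert n_possible_dimers(36) == 666

    def test_enumeration_agrees_with_count(self):
        monomers = [f"m{i}" for i in range(12)]
        pairs = enumerate_dimers(monomers)
        assert len(pairs) == n_possible_dimers(12)
        assert len(set(pairs)) == len(pairs)
        assert ("m0", "m0") in pairs  # homodimers included

    def test_percentages_of_printed_contingency_counts(self):
        assert round(percentage(73, 126)) == 58
        assert round(percentage(29, 144)) == 20
        assert round(percentage(6, 27)) == 22


class TestComparisonSet:
    def test_single_profile_yields_exactly_n(self, rng):
        p = random_profile(4, rng)
        assert len(build_comparison_set([p], n=50)) == 50

    def test_identical_profiles_union_unchanged(self, rng):
        p = random_profile(4, rng)
        assert len(build_comparison_set([p, p], n=50)) == 50

    def test_union_matches_brute_force(self, rng):
        profiles = [random_profile(3, rng) for _ in range(3)]
        cset = build_comparison_set(profiles, n=10)
        expected = []
        for p in profiles:
            for w in top_sequences(p, 10):
                if w not in expected:
                    expected.append(w)
        assert cset.kmers == expected  # forward mode: canonical == identity

    def test_collapsed_mode_uses_canonical_representatives(self, rng):
        p = random_profile(3, rng, strand_mode="collapsed")
        cset = build_comparison_set([p], n=10)
        assert len(cset) == 10
        assert all(w <= revcomp(w) for w in cset.kmers)

    def test_mixed_k_rejected(self, rng):
        with pytest.raises(ValueError):
            build_comparison_set([random_profile(3, rng), random_profile(4, rng)])


class TestCorrelationMatrix:
    def test_self_and_negation(self, rng):
        p = random_profile(3, rng)
        neg = p.replace(csi=-p.csi)
        cset = build_comparison_set([p], n=20)
        r = correlation_matrix([p, neg], cset)
        assert r[0, 0] == pytest.approx(1.0)
        assert r[0, 1] == pytest.approx(-1.0)
        np.testing.assert_allclose(r, r.T)

    def test_closed_form_pearson_on_toy_vectors(self):
        x = np.array([1.0, 2, 3, 5])
        y = np.array([2.0, 1, 4, 6])
        csi_x, csi_y = np.zeros(16), np.zeros(16)
        kmers = ["AA", "AC", "AG", "AT"]
        for w, a, b in zip(kmers, x, y):
            csi_x[kmer_to_index(w)] = a
            csi_y[kmer_to_index(w)] = b
        px, py = make_profile(csi_x, 2), make_profile(csi_y, 2)
        from csikit.compare import ComparisonSet

        cset = ComparisonSet(kmers=kmers, n_per_dimer=4)
        # closed-form Pearson computed independently
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert correlation_matrix([px, py], cset)[0, 1] == pytest.approx(expected)


class TestClustering:
    def test_identical_pair_merges_first(self, rng):
        p = random_profile(3, rng)
        cset = build_comparison_set([p], n=20)
        r = correlation_matrix([p, p, p.replace(csi=-p.csi)], cset)
        Z, _ = cluster_dimers(r)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(0.0)

    def test_permutation_invariant_topology(self, rng):
        profiles = [random_profile(3, rng) for _ in range(4)]
        cset = build_comparison_set(profiles, n=15)
        r = correlation_matrix(profiles, cset)
        Z1, _ = cluster_dimers(r)
        perm = [2, 0, 3, 1]
        Z2, _ = cluster_dimers(r[np.ix_(perm, perm)])
        np.testing.assert_allclose(np.sort(Z1[:, 2]), np.sort(Z2[:, 2]))

    def test_linkage_heights_match_hand_agglomeration(self):
        # complete-linkage agglomeration of 4 rows done by explicit loops
        rows = np.array(
            [[1.0, 0.9, 0.1, 0.0], [0.9, 1.0, 0.2, 0.1], [0.1, 0.2, 1.0, 0.8], [0.0, 0.1, 0.8, 1.0]]
        )
        Z, _ = cluster_dimers(rows)

        def dist(i, j):
            return float(np.sqrt(((rows[i] - rows[j]) ** 2).sum()))

        clusters = {i: [i] for i in range(4)}
        heights = []
        while len(clusters) > 1:
            best = None
            for a in sorted(clusters):
                for b in sorted(clusters):
                    if a >= b:
                        continue
                    d = max(dist(i, j) for i in clusters[a] for j in clusters[b])
                    if best is None or d < best[0]:
                        best = (d, a, b)
            d, a, b = best
            heights.append(d)
            clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
        np.testing.assert_allclose(np.sort(Z[:, 2]), np.sort(heights))

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            cluster_dimers(np.ones((1, 1)))


class TestAssignSpecificity:
    def _profiles_with_r(self, rng, target_r):
        """Two 4-mer profiles whose comparison-set correlation ~ target_r."""
        base = random_profile(4, rng)
        noise = random_profile(4, rng)
        mixed = base.replace(
            csi=target_r * base.csi + np.sqrt(1 - target_r**2) * noise.csi
        )
        return base, mixed

    def test_no_homodimer_reference_means_heterodimer(self, rng):
        p = random_profile(4, rng)
        cset = build_comparison_set([p], n=30)
        res = assign_specificity(p, None, REPLICATE_RS, cset)
        assert res.verdict == "heterodimer"

    def test_low_correlation_vs_replicates_is_heterodimer(self, rng):
        homo, het = self._profiles_with_r(rng, 0.1)
        cset = build_comparison_set([homo, het], n=40)
        res = assign_specificity(het, homo, REPLICATE_RS, cset)
        assert res.verdict == "heterodimer"
        assert res.p_value < 0.05
        assert res.r_het_homo < 0.5

    def test_correlation_at_replicate_mean_is_ambiguous(self, rng):
        p = random_profile(4, rng)
        cset = build_comparison_set([p], n=30)
        # identical profile: r = 1.0 > replicate mean -> not heterodimer
        res = assign_specificity(p, p, REPLICATE_RS, cset)
        assert res.verdict != "heterodimer"
        # r exactly at the replicate mean cannot be significant
        res2 = assign_specificity(p, p, [1.0, 1.0, 1.0], cset)
        assert res2.verdict == "ambiguous" or res2.verdict == "homodimer"

    def test_too_few_replicates_is_ambiguous(self, rng):
        homo, het = self._profiles_with_r(rng, 0.1)
        cset = build_comparison_set([homo, het], n=40)
        assert assign_specificity(het, homo, [0.8], cset).verdict == "ambiguous"

    def test_monotone_in_correlation(self, rng):
        """Lowering r_het_homo never flips heterodimer back to ambiguous."""
        verdicts = []
        for target in (0.7, 0.5, 0.3, 0.1):
            homo, het = self._profiles_with_r(np.random.default_rng(5), target)
            cset = build_comparison_set([homo, het], n=40)
            res = assign_specificity(het, homo, REPLICATE_RS, cset)
            verdicts.append((res.r_het_homo, res.verdict))
        seen_het = False
        for _, verdict in verdicts:
            if verdict == "heterodimer":
                seen_het = True
            elif seen_het:
                pytest.fail("heterodimer verdict flipped back at lower r")


class TestScoreSite:
    def test_full_length_site_is_exact_lookup(self, rng):
        p = random_profile(4, rng)
        assert score_site(p, "ACGT") == p.csi_of("ACGT")

    def test_matches_brute_force_containment_scan(self, rng):
        p = random_profile(5, rng)
        site = "AAAA"
        expected = max(
            p.csi[i]
            for i in range(4**5)
            if site in index_to_kmer(i, 5)
        )
        assert score_site(p, site) == pytest.approx(expected)

    def test_collapsed_mode_includes_reverse_complement(self, rng):
        p = random_profile(5, rng, strand_mode="collapsed")
        site = "ACGTA"
        both = max(
            p.csi[i]
            for i in range(4**5)
            if site in index_to_kmer(i, 5) or revcomp(site) in index_to_kmer(i, 5)
        )
        assert score_site(p, site) == pytest.approx(both)

    def test_invalid_letters_rejected(self, rng):
        with pytest.raises(ValueError):
            score_site(random_profile(4, rng), "TGAX")

    def test_site_longer_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            score_site(random_profile(3, rng), "ACGTA")


class TestArchitecture:
    def test_conjoined_cre_caat(self):
        arch = classify_architecture("ATGACGCAAG", "TGAC", "GCAA")
        assert arch.klass == "conjoined"
        assert arch.overlap == 0

    def test_variably_spaced_tre_caat(self):
        arch = classify_architecture("ATGAGCAAGT", "TGAG", "GCAA")
        assert arch.klass == "variably_spaced"
        assert arch.overlap == 1

    def test_emergent_site(self):
        assert classify_architecture("TGACGCATGG", "TGAC", "GTCA").klass == "emergent"

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 4**10 - 1))
    def test_orientation_invariance(self, idx):
        kmer = index_to_kmer(idx, 10)
        a = classify_architecture(kmer, "TGAC", "GCAA")
        b = classify_architecture(revcomp(kmer), "TGAC", "GCAA")
        assert a.klass == b.klass

    def test_half_site_length_validated(self):
        with pytest.raises(ValueError):
            classify_architecture("ACGTACGTAC", "AC", "GCAA")
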