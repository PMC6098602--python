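import itertools
import math

import numpy as np
import pytest

from conftest import make_random_haplotypes

from trild import (
    GenotypeTripletCounts,
    HaplotypeFrequencies,
    LDDecomposition,
    delta3_bounds,
    em_fit,
    genotype_probabilities,
    loglikelihood,
    lrt_full_vs_allele_only,
    params_to_haplotypes,
)
from trild.em_estimator import (
    allele_frequencies,
    read_counts_tsv,
    write_counts_tsv,
)
from trild.synth import sample_triplet_genotypes

CASE1_H = params_to_haplotypes(LDDecomposition(0.5, 0.5, 0.5, 0, 0, 0, 0.125))


class TestGenotypeProbabilities:
    def test_sums_to_one(self, rng):
        for _ in range(50):
            h = make_random_haplotypes(rng)
            assert genotype_probabilities(h).sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_triple_heterozygote(self):
        # 2 * (4 coupling/repulsion pairs) * (1/8)^2 = 1/8
        phi = genotype_probabilities(HaplotypeFrequencies.uniform())
        assert phi[2, 2, 2] == pytest.approx(0.125, abs=1e-15)

    def test_two_complementary_haplotypes(self):
        h = HaplotypeFrequencies.from_labels({"111": 0.5, "222": 0.5})
        phi = genotype_probabilities(h)
        assert phi[0, 0, 0] == pytest.approx(0.25)  # hom/hom/hom for allele 1
        assert phi[1, 1, 1] == pytest.approx(0.25)
        assert phi[2, 2, 2] == pytest.approx(0.5)  # triple heterozygote
        other = phi.sum() - phi[0, 0, 0] - phi[1, 1, 1] - phi[2, 2, 2]
        assert other == pytest.approx(0.0, abs=1e-15)

    def test_matches_exhaustive_enumeration(self, rng):
        # oracle: enumerate all 64 ordered haplotype pairs directly
        h = make_random_haplotypes(rng)
        f = h.freq
        phi = np.zeros((3, 3, 3))
        for a in itertools.product((0, 1), repeat=3):
            for b in itertools.product((0, 1), repeat=3):
                g = tuple(x if x == y else 2 for x, y in zip(a, b))
                phi[g] += f[a] * f[b]
        np.testing.assert_allclose(genotype_probabilities(h), phi, atol=1e-14)


class TestLoglikelihood:
    def test_single_triple_heterozygote(self):
        counts = GenotypeTripletCounts.from_codes([3], [3], [3])
        ll = loglikelihood(HaplotypeFrequencies.uniform(), counts)
        assert ll == pytest.approx(math.log(0.125), abs=1e-12)

    def test_linear_in_counts(self, rng):
        h = make_random_haplotypes(rng)
        counts = sample_triplet_genotypes(h, 100, 3)
        doubled = GenotypeTripletCounts(counts.counts * 2)
        assert loglikelihood(h, doubled) == pytest.approx(
            2 * loglikelihood(h, counts), rel=1e-12
        )

    def test_zero_probability_class_is_minus_inf(self):
        h = HaplotypeFrequencies.from_labels({"111": 1.0})
        counts = GenotypeTripletCounts.from_codes([2], [2], [2])
        assert loglikelihood(h, counts) == -math.inf

    def test_mle_beats_local_perturbations(self, rng):
        h = make_random_haplotypes(rng)
        counts = sample_triplet_genotypes(h, 500, 11)
        fit = em_fit(counts, tol=1e-12, max_iter=50000)
        base = fit.loglik
        f = fit.haplotypes.to_flat()
        for _ in range(50):
            noise = rng.normal(scale=1e-3, size=8)
            pert = np.clip(f + noise, 1e-12, None)
            pert /= pert.sum()
            ll = loglikelihood(HaplotypeFrequencies(pert.reshape(2, 2, 2)), counts)
            assert ll <= base + 1e-7


class TestEMFit:
    def test_expected_counts_self_consistency(self):
        # counts equal to N * phi(h*): the fixed point recovers h*
        phi = genotype_probabilities(CASE1_H)
        counts = GenotypeTripletCounts(np.round(phi * 10000))
        fit = em_fit(counts, tol=1e-10)
        assert fit.converged
        np.testing.assert_allclose(
            fit.haplotypes.to_flat(), CASE1_H.to_flat(), atol=1e-3
        )
        assert fit.decomposition.d123 == pytest.approx(0.125, abs=1e-3)

    def test_unambiguous_counts_equal_gamete_counting(self):
        # no individual with >= 2 heterozygous loci: every genotype resolves
        # to a unique haplotype pair, so the MLE is direct gamete counting
        codes = (
            [(1, 1, 1)] * 4  # 8 gametes 111
            + [(3, 1, 1)] * 2  # 2 x (111 + 211)
            + [(1, 3, 1)] * 1  # 111 + 121
            + [(2, 2, 2)] * 2  # 4 gametes 222
            + [(2, 2, 3)] * 1  # 221 + 222
        )
        g = np.array(codes)
        counts = GenotypeTripletCounts.from_codes(g[:, 0], g[:, 1], g[:, 2])
        fit = em_fit(counts, tol=1e-12)
        expected = {
            "111": 11 / 20,
            "211": 2 / 20,
            "121": 1 / 20,
            "222": 5 / 20,
            "221": 1 / 20,
        }
        got = fit.haplotypes.as_dict()
        for label in got:
            assert got[label] == pytest.approx(expected.get(label, 0.0), abs=1e-9)

    def test_single_genotype_class_monomorphic(self):
        counts = GenotypeTripletCounts.from_codes([1] * 50, [1] * 50, [1] * 50)
        fit = em_fit(counts)
        assert fit.haplotypes.as_dict()["111"] == pytest.approx(1.0, abs=1e-12)
        d = fit.decomposition
        assert (d.f1, d.f2, d.f3) == pytest.approx((1, 1, 1), abs=1e-12)
        assert (d.d12, d.d13, d.d23, d.d123) == pytest.approx((0, 0, 0, 0), abs=1e-12)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            em_fit(GenotypeTripletCounts(np.zeros((3, 3, 3))))

    def test_loglik_never_decreases(self, rng):
        for _ in range(20):
            h = make_random_haplotypes(rng)
            counts = sample_triplet_genotypes(h, 200, int(rng.integers(2**31)))
            fit = em_fit(counts)
            assert np.all(np.diff(fit.loglik_trace) >= -1e-9)

    def test_recovery_improves_with_sample_size(self, rng):
        h = make_random_haplotypes(rng)
        maes = []
        for n in (300, 3000, 30000):
            errs = []
            for _ in range(20):
                counts = sample_triplet_genotypes(h, n, int(rng.integers(2**31)))
                fit = em_fit(counts)
                errs.append(np.abs(fit.haplotypes.to_flat() - h.to_flat()).mean())
            maes.append(np.mean(errs))
        assert maes[0] > maes[1] > maes[2]

    def test_beats_coarse_grid_search(self, rng):
        # exhaustive oracle: all compositions of 6 over the 8 haplotypes
        h = make_random_haplotypes(rng)
        counts = sample_triplet_genotypes(h, 25, 5)
        fit = em_fit(counts, tol=1e-12, max_iter=50000)
        best = -math.inf
        for comp in itertools.combinations_with_replacement(range(8), 6):
            f = np.bincount(comp, minlength=8) / 6.0
            ll = loglikelihood(HaplotypeFrequencies(f.reshape(2, 2, 2)), counts)
            best = max(best, ll)
        assert fit.loglik >= best - 1e-6

    def test_estimate_satisfies_core_invariants(self, rng):
        for _ in range(20):
            h = make_random_haplotypes(rng, alpha=0.5)
            counts = sample_triplet_genotypes(h, 150, int(rng.integers(2**31)))
            fit = em_fit(counts)
            d = fit.decomposition
            assert fit.haplotypes.freq.min() >= -1e-12
            assert fit.haplotypes.freq.sum() == pytest.approx(1.0, abs=1e-9)
            b = delta3_bounds(d.f1, d.f2, d.f3, d.d12, d.d13, d.d23)
            assert b.lower - 1e-9 <= d.d123 <= b.upper + 1e-9

    def test_ambiguity_weights_reported(self):
        phi = genotype_probabilities(CASE1_H)
        counts = GenotypeTripletCounts(np.round(phi * 1000))
        fit = em_fit(counts)
        assert "333" in fit.weights
        w = fit.weights["333"]
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-9)
        assert len(w) == 4  # the four coupling/repulsion resolutions


class TestAlleleFrequencies:
    def test_gamete_counting(self):
        counts = GenotypeTripletCounts.from_codes(
            [1, 1, 3, 2], [3, 3, 3, 3], [2, 2, 2, 1]
        )
        f1, f2, f3 = allele_frequencies(counts)
        assert f1 == pytest.approx(5 / 8)
        assert f2 == pytest.approx(4 / 8)
        assert f3 == pytest.approx(2 / 8)


class TestLRT:
    def test_null_statistic_small(self, rng):
        null = HaplotypeFrequencies(
            np.einsum("i,j,k->ijk", [0.5, 0.5], [0.4, 0.6], [0.6, 0.4])
        )
        stats = []
        for _ in range(100):
            counts = sample_triplet_genotypes(null, 300, int(rng.integers(2**31)))
            res = lrt_full_vs_allele_only(counts)
            assert res.statistic >= -1e-8
            assert res.df == 4
            stats.append(res.statistic)
        # mean of a chi-square(4) is 4; boundary effects can only shrink it
        assert 2.0 < np.mean(stats) < 5.0

    def test_power_under_strong_third_order(self, rng):
        hits = 0
        for _ in range(50):
            counts = sample_triplet_genotypes(CASE1_H, 300, int(rng.integers(2**31)))
            if lrt_full_vs_allele_only(counts).statistic > 9.49:
                hits += 1
        assert hits == 50

    def test_monomorphic_locus_reduces_to_two_locus_test(self, rng):
        # independent oracle: brute-force two-locus EM on loci 1-2 only
        h2 = np.array([0.4, 0.1, 0.2, 0.3])  # 11, 12, 21, 22
        counts2 = _sample_two_locus(h2, 400, rng)
        stat2 = _two_locus_lrt(counts2)
        counts3 = np.zeros((3, 3, 3))
        counts3[:, :, 0] = counts2  # third locus fixed hom for allele 1
        res = lrt_full_vs_allele_only(GenotypeTripletCounts(counts3))
        assert res.statistic == pytest.approx(stat2, abs=1e-5)


# ---------------------------------------------------------------------------
# independent two-locus EM oracle (textbook implementation)


def _sample_two_locus(hap_freqs, n, rng):
    """3x3 genotype counts from HWE sampling of two-locus haplotypes."""
    alleles = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])
    draws = rng.choice(4, size=(n, 2), p=hap_freqs)
    a, b = alleles[draws[:, 0]], alleles[draws[:, 1]]
    codes = np.where(a == b, np.where(a == 0, 0, 1), 2)
    counts = np.zeros((3, 3))
    np.add.at(counts, (codes[:, 0], codes[:, 1]), 1.0)
    return counts


def _two_locus_phi(f):
    """9 genotype probabilities from 4 haplotype frequencies (11,12,21,22)."""
    p11, p12, p21, p22 = f
    phi = np.empty((3, 3))
    phi[0, 0] = p11**2
    phi[0, 1] = p12**2
    phi[0, 2] = 2 * p11 * p12
    phi[1, 0] = p21**2
    phi[1, 1] = p22**2
    phi[1, 2] = 2 * p21 * p22
    phi[2, 0] = 2 * p11 * p21
    phi[2, 1] = 2 * p12 * p22
    phi[2, 2] = 2 * p11 * p22 + 2 * p12 * p21
    return phi


def _two_locus_lrt(counts):
    n = counts.sum()
    f = np.full(4, 0.25)
    for _ in range(20000):
        # E-step: only the double heterozygote is ambiguous
        denom = f[0] * f[3] + f[1] * f[2]
        w_coupling = 0.5 if denom == 0 else f[0] * f[3] / denom
        ndh = counts[2, 2]
        gametes = np.array(
            [
                2 * counts[0, 0] + counts[0, 2] + counts[2, 0] + w_coupling * ndh,
                2 * counts[0, 1] + counts[0, 2] + counts[2, 1] + (1 - w_coupling) * ndh,
                2 * counts[1, 0] + counts[1, 2] + counts[2, 0] + (1 - w_coupling) * ndh,
                2 * counts[1, 1] + counts[1, 2] + counts[2, 1] + w_coupling * ndh,
            ]
        )
        f_new = gametes / (2 * n)
        if np.max(np.abs(f_new - f)) < 1e-12:
            f = f_new
            break
        f = f_new
    phi = _two_locus_phi(f)
    mask = counts > 0
    ll_full = np.sum(counts[mask] * np.log(phi[mask]))
    pa = f[0] + f[1]
    pb = f[0] + f[2]
    phi0 = _two_locus_phi(np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)]))
    ll0 = np.sum(counts[mask] * np.log(phi0[mask]))
    return 2 * (ll_full - ll0)


class TestCountsIO:
    def test_round_trip(self, tmp_path, rng):
        h = make_random_haplotypes(rng)
        counts = sample_triplet_genotypes(h, 200, 9)
        path = tmp_path / "counts.tsv"
        write_counts_tsv(path, counts)
        back = read_counts_tsv(path)
        np.testing.assert_array_equal(back.counts, counts.counts)

    def test_bad_code_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("1\t2\t4\t10\n")
        with pytest.raises(ValueError, match="codes"):
            read_counts_tsv(path)

    def test_negative_counts_rejected(self):
        arr = np.zeros((3, 3, 3))
        arr[0, 0, 0] = -1
        with pytest.raises(ValueError, match="negative"):
            GenotypeTripletCounts(arr)
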