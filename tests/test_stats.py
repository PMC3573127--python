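"""Spectra, diversity, AMOVA F_ST, PCA and distance profiles."""

import math
from collections import OrderedDict

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paleomt.haplotypes import PopulationSample, parse_motif
from paleomt.stats import (
    POOLED_CLASSES,
    HaplogroupSpectrum,
    distance_profile,
    haplogroup_spectrum,
    haplotype_diversity,
    pairwise_fst,
    pca_spectra,
    pooled_class,
)

# ---------------------------------------------------------------------------
# independent brute-force AMOVA oracle (explicit double loops over
# individuals; the implementation under test works from class counts)
# ---------------------------------------------------------------------------


def amova_fst_oracle(pop_a, pop_b, mode="haplotype_freq"):
    def dist2(x, y):
        sx = dict(x.resolved)
        sy = dict(y.resolved)
        if mode == "haplotype_freq":
            return 0.0 if sx == sy else 1.0
        return float(
            sum(1 for p in set(sx) | set(sy) if sx.get(p) != sy.get(p))
        )

    groups = [pop_a.haplotypes, pop_b.haplotypes]
    everyone = groups[0] + groups[1]
    n = [len(g) for g in groups]
    big_n = sum(n)
    ssd_t = sum(
        dist2(x, y) for x in everyone for y in everyone
    ) / (2 * big_n)
    ssd_w = sum(
        sum(dist2(x, y) for x in g for y in g) / (2 * len(g)) for g in groups
    )
    msd_a = ssd_t - ssd_w
    msd_w = ssd_w / (big_n - 2)
    n_c = big_n - (n[0] ** 2 + n[1] ** 2) / big_n
    sigma_a = (msd_a - msd_w) / n_c
    total = sigma_a + msd_w
    return 0.0 if abs(total) < 1e-15 else sigma_a / total


def _pop(label, motif_counts, age=0.0):
    members = []
    for motif, count in motif_counts:
        members.extend([(parse_motif(motif), "")] * count)
    return PopulationSample(label, members, age)


class TestSpectrum:
    def test_uzpo_pooled_counts(self, uzpo):
        spec = haplogroup_spectrum(uzpo)
        nonzero = {k: v for k, v in spec.counts.items() if v}
        assert nonzero == {"U4": 4, "C": 3, "U2": 2, "U5a": 1, "H": 1}
        assert spec.percentages()["C"] == 27
        assert spec.percentages()["U2"] == 18

    def test_boo_c_class_count(self, boo):
        spec = haplogroup_spectrum(boo)
        assert spec.counts["C"] == 8  # 6 C* + 2 C5
        assert spec.percentages()["C"] == 35

    def test_single_haplogroup_population(self):
        pop = _pop("toy", [("223T-290T-319A", 5)])
        spec = haplogroup_spectrum(
            PopulationSample("toy", [(h, "A") for h, _ in pop.members])
        )
        assert spec.freqs["EAS"] == 1.0
        assert sum(spec.freqs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_counts_conserved_under_pooling(self, uzpo, boo):
        for pop in (uzpo, boo):
            spec = haplogroup_spectrum(pop)
            assert sum(spec.counts.values()) == pop.n
            assert sum(spec.freqs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            haplogroup_spectrum(PopulationSample("empty", []))

    @pytest.mark.parametrize(
        "label,expected",
        [
            ("C1", "C"), ("C*", "C"), ("C5", "C"), ("U4a1", "U4"),
            ("U5a1", "U5a"), ("U2e", "U2"), ("Z1a", "Z"), ("T*", "T"),
            ("D*", "D"), ("HV1", "HV"), ("H1", "H"), ("N1a", "N1"),
            ("A", "EAS"), ("B4", "EAS"), ("Y1", "EAS"), ("L3", "misc"),
            ("M*", "misc"), ("U1", "misc"), ("U8", "misc"), ("N9", "misc"),
        ],
    )
    def test_pooling_rules(self, label, expected):
        assert pooled_class(label) == expected


class TestDiversity:
    def test_monomorphic_sample_has_zero_diversity(self):
        assert haplotype_diversity([7]) == 0.0

    def test_all_distinct_corrected_is_one(self):
        assert haplotype_diversity([1] * 12) == pytest.approx(1.0)

    def test_uzpo_hand_computation(self, uzpo):
        # class counts (3, 2, 3, 1, 1, 1): h = 11/10 * (1 - 25/121)
        assert haplotype_diversity(uzpo) == pytest.approx(
            11 / 10 * (1 - 25 / 121)
        )
        assert haplotype_diversity(uzpo) == pytest.approx(0.8727, abs=5e-5)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            haplotype_diversity([1], corrected=True)
        assert haplotype_diversity([1], corrected=False) == 0.0

    @given(st.lists(st.integers(1, 20), min_size=2, max_size=10))
    def test_relabelling_invariance_and_split_monotonicity(self, counts):
        h = haplotype_diversity(counts)
        assert h == pytest.approx(haplotype_diversity(counts[::-1]))
        # splitting one class into two never decreases diversity
        if counts[0] >= 2:
            split = [counts[0] - 1, 1] + list(counts[1:])
            assert haplotype_diversity(split) >= h - 1e-12


class TestFst:
    def test_same_fixed_haplotype_gives_zero(self):
        a = _pop("A", [("129C", 6)])
        b = _pop("B", [("129C", 9)])
        assert pairwise_fst(a, b) == 0.0

    def test_fixed_different_haplotypes_give_one(self):
        a = _pop("A", [("129C", 6)])
        b = _pop("B", [("356C", 9)])
        assert pairwise_fst(a, b) == pytest.approx(1.0)
        assert pairwise_fst(a, b, mode="pairwise_diff") == pytest.approx(1.0)

    def test_symmetry(self, uzpo, boo):
        for mode in ("haplotype_freq", "pairwise_diff"):
            assert pairwise_fst(uzpo, boo, mode) == pytest.approx(
                pairwise_fst(boo, uzpo, mode), abs=1e-12
            )

    def test_fixture_pair_matches_bruteforce_oracle(self, uzpo, boo):
        for mode in ("haplotype_freq", "pairwise_diff"):
            assert pairwise_fst(uzpo, boo, mode) == pytest.approx(
                amova_fst_oracle(uzpo, boo, mode), abs=1e-9
            )

    def test_random_small_populations_match_oracle(self):
        rng = np.random.default_rng(3)
        motifs = ["", "129C", "356C", "093C-356C", "189C-223T", "224C-311C"]
        for trial in range(8):
            a = _pop(
                "A",
                [(m, int(c)) for m, c in zip(motifs, rng.integers(0, 6, 6)) if c],
            )
            b = _pop(
                "B",
                [(m, int(c)) for m, c in zip(motifs, rng.integers(0, 6, 6)) if c],
            )
            if a.n < 2 or b.n < 2:
                continue
            for mode in ("haplotype_freq", "pairwise_diff"):
                assert pairwise_fst(a, b, mode) == pytest.approx(
                    amova_fst_oracle(a, b, mode), abs=1e-9
                ), (trial, mode)

    def test_empty_population_rejected(self, uzpo):
        with pytest.raises(ValueError):
            pairwise_fst(uzpo, PopulationSample("empty", []))

    def test_site_count_route_equals_class_route(self, uzpo, boo):
        # the per-site O(L) decomposition used inside simulation loops must
        # agree exactly with the class-based pairwise-difference AMOVA
        from paleomt.haplotypes import HVR1_START, reference_window
        from paleomt.stats import fst_from_site_counts

        base_idx = {b: i for i, b in enumerate("ACGT")}
        ref = reference_window()
        ref_idx = np.array([base_idx[c] for c in ref])

        def site_counts(pop):
            arr = np.zeros((len(ref), 4))
            for hap in pop.haplotypes:
                for p, b in hap.resolved:
                    arr[p - HVR1_START, base_idx[b]] += 1
            idx = np.arange(len(ref))
            arr[idx, ref_idx] += pop.n - arr.sum(axis=1)
            return arr

        got = fst_from_site_counts(
            site_counts(uzpo), uzpo.n, site_counts(boo), boo.n
        )
        assert got == pytest.approx(
            pairwise_fst(uzpo, boo, "pairwise_diff"), abs=1e-12
        )


class TestPca:
    @staticmethod
    def _toy_matrix():
        rng = np.random.default_rng(11)
        x = rng.dirichlet(np.ones(19), size=6)
        return x

    def test_variance_fractions_sum_to_one(self):
        res = pca_spectra(self._toy_matrix())
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_identical_rows_get_identical_scores(self):
        x = self._toy_matrix()
        x[1] = x[0]
        res = pca_spectra(x)
        assert np.allclose(res.scores[0], res.scores[1])

    def test_scores_match_sklearn_oracle(self):
        from sklearn.decomposition import PCA

        x = self._toy_matrix()
        res = pca_spectra(x)
        ref = PCA().fit(x)
        k = min(res.scores.shape[1], ref.components_.shape[0])
        assert np.allclose(
            np.abs(res.scores[:, :k]),
            np.abs(ref.transform(x)[:, :k]),
            atol=1e-9,
        )

    def test_reconstruction_from_all_components(self):
        x = self._toy_matrix()
        res = pca_spectra(x)
        back = res.scores @ res.loadings.T + res.mean
        assert np.allclose(back, x, atol=1e-9)

    def test_row_permutation_invariance_up_to_sign(self):
        x = self._toy_matrix()
        perm = [3, 1, 4, 0, 5, 2]
        a = pca_spectra(x)
        b = pca_spectra(x[perm])
        assert np.allclose(np.abs(a.scores[perm]), np.abs(b.scores), atol=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            pca_spectra(self._toy_matrix()[:2])
        with pytest.raises(ValueError):
            pca_spectra(np.tile(self._toy_matrix()[0], (4, 1)))


class TestDistanceProfile:
    @staticmethod
    def _spec(label, freqs):
        return HaplogroupSpectrum(label, OrderedDict(freqs))

    def test_identical_spectra_distance_zero(self):
        a = self._spec("a", {"C": 0.5, "H": 0.5})
        b = self._spec("b", {"C": 0.5, "H": 0.5})
        assert distance_profile(a, [b])["b"] == pytest.approx(0.0, abs=1e-12)

    def test_two_class_closed_form(self):
        a = self._spec("a", {"C": 1.0, "H": 0.0})
        b = self._spec("b", {"C": 0.5, "H": 0.5})
        expected = -math.log(0.5 / math.sqrt(1.0 * 0.5))
        assert distance_profile(a, [b])["b"] == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            fa = rng.dirichlet(np.ones(4))
            fb = rng.dirichlet(np.ones(4))
            a = self._spec("a", dict(zip("wxyz", fa)))
            b = self._spec("b", dict(zip("wxyz", fb)))
            for metric in ("nei", "euclidean"):
                assert distance_profile(a, [b], metric)["b"] == pytest.approx(
                    distance_profile(b, [a], metric)["a"]
                )

    def test_mismatched_variables_rejected(self):
        a = self._spec("a", {"C": 1.0})
        b = self._spec("b", {"H": 1.0})
        with pytest.raises(ValueError):
            distance_profile(a, [b])
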