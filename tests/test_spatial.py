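"""Tests for differentiation, geodesic distance and isolation by distance."""

import numpy as np
import pandas as pd
import pytest

from glacialsfs.core import Demography
from glacialsfs.simdata import simulate_genotype_matrix
from glacialsfs.spatial import (
    geodesic_km,
    ibd_regression,
    pairwise_fst,
    scaled_population_fst,
    wc_fst_two_pops,
)

from conftest import make_gm


def wc_oracle_single_site(n1, p1, h1, n2, p2, h2):
    """Independent transcription of the Weir-Cockerham (1984) variance
    components for r=2 populations, one locus."""
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


class TestPairwiseFst:
    def test_single_site_matches_variance_component_oracle(self):
        # pop1: 0/0, 0/1, 1/1, 0/1 ; pop2: 1/1, 1/1, 0/1, 1/1
        g1 = np.array([[0], [1], [2], [1]], dtype=np.int8)
        g2 = np.array([[2], [2], [1], [2]], dtype=np.int8)
        fst = wc_fst_two_pops(g1, g2)
        a, b, c = wc_oracle_single_site(4, 4 / 8, 2 / 4, 4, 7 / 8, 1 / 4)
        assert fst == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_panmictic_split_gives_near_zero(self):
        gm = simulate_genotype_matrix(
            Demography(((1e4, 0.0),)), n_ind=20, L=2e5, mu=1e-7, seed=41,
            pop_labels=["A"] * 10 + ["B"] * 10,
        )
        fst = pairwise_fst(gm)
        assert abs(fst.loc["A", "B"]) < 0.02

    def test_fixed_differences_give_one(self):
        g = np.vstack([np.zeros((4, 5)), np.full((4, 5), 2)]).astype(np.int8)
        gm = make_gm(g, pop=["A"] * 4 + ["B"] * 4)
        fst = pairwise_fst(gm)
        assert fst.loc["A", "B"] == pytest.approx(1.0)

    def test_matrix_symmetric_zero_diagonal(self):
        gm = simulate_genotype_matrix(
            Demography(((1e4, 0.0),)), n_ind=9, L=5e4, mu=1e-7, seed=42,
            pop_labels=["A", "B", "C"] * 3,
        )
        fst = pairwise_fst(gm)
        assert np.allclose(fst.values, fst.values.T)
        assert np.all(np.diag(fst.values) == 0)


class TestGeodesic:
    def test_identical_points(self):
        assert geodesic_km(48.0, 2.0, 48.0, 2.0) == 0.0

    def test_one_degree_on_equator(self):
        # R * 1 degree in radians
        assert geodesic_km(0, 0, 0, 1) == pytest.approx(111.195, abs=0.001)

    def test_symmetry(self):
        assert geodesic_km(40, -3, 60, 25) == geodesic_km(60, 25, 40, -3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            geodesic_km(95, 0, 0, 0)


def collinear_fixture(beta=0.015, alpha=-0.05, n=6):
    """Populations placed so FST/(1-FST) lies exactly on a line in ln(km)."""
    lats = np.linspace(40, 60, n)
    coords = pd.DataFrame({"pop": [f"p{i}" for i in range(n)], "lat": lats, "lon": 0.0})
    pops = list(coords["pop"])
    fst = pd.DataFrame(0.0, index=pops, columns=pops)
    for i in range(n):
        for j in range(i + 1, n):
            d = geodesic_km(lats[i], 0, lats[j], 0)
            y = beta * np.log(d) + alpha
            fst.iloc[i, j] = fst.iloc[j, i] = y / (1 + y)
    return fst, coords


class TestIbdRegression:
    def test_exact_recovery_on_collinear_pairs(self):
        fst, coords = collinear_fixture()
        fit = ibd_regression(fst, coords)
        assert fit.beta == pytest.approx(0.015, abs=1e-12)
        assert fit.alpha == pytest.approx(-0.05, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_residuals_sum_to_zero_and_reconstruct_inputs(self):
        rng = np.random.default_rng(5)
        fst, coords = collinear_fixture()
        # perturb off the line
        for i in range(len(fst)):
            for j in range(i + 1, len(fst)):
                fst.iloc[i, j] = fst.iloc[j, i] = fst.iloc[i, j] + rng.normal(0, 0.002)
        fit = ibd_regression(fst, coords)
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-10)
        y = fit.pairs["fst"] / (1 - fit.pairs["fst"])
        assert np.allclose(fit.fitted() + fit.residuals, y)

    def test_slope_zero_under_distance_permutation(self):
        fst, coords = collinear_fixture()
        rng = np.random.default_rng(7)
        betas = []
        pops = list(coords["pop"])
        for _ in range(100):
            perm = rng.permutation(len(pops))
            shuffled = coords.copy()
            shuffled[["lat", "lon"]] = coords[["lat", "lon"]].to_numpy()[perm]
            betas.append(ibd_regression(fst, shuffled).beta)
        betas = np.asarray(betas)
        assert abs(betas.mean()) < 2 * betas.std(ddof=1) / np.sqrt(len(betas))

    def test_invariant_to_population_relabeling(self):
        fst, coords = collinear_fixture()
        order = ["p3", "p0", "p5", "p1", "p4", "p2"]
        fit1 = ibd_regression(fst, coords)
        fit2 = ibd_regression(fst.loc[order, order], coords)
        assert fit1.beta == pytest.approx(fit2.beta)


def hudson_fst_from_joint(jsfs):
    """Oracle: 1 - Hw/Hb from the joint spectrum (folding-invariant)."""
    hw = hb = 0.0
    for i in range(jsfs.n1 + 1):
        for j in range(jsfs.n2 + 1):
            c = jsfs.counts[i, j]
            if c == 0 or (i == 0 and j == 0):
                continue
            p1, p2 = i / jsfs.n1, j / jsfs.n2
            hw += c * (p1 * (1 - p1) + p2 * (1 - p2))
            hb += c * (p1 * (1 - p2) + p2 * (1 - p1))
    return 1 - hw / hb if hb > 0 else 0.0


class TestSteppingStone:
    def test_ibd_slope_positive_under_distance_decaying_migration(self):
        """Populations on a line with migrant numbers decaying in distance
        show a positive isolation-by-distance slope in nearly all seeds."""
        from glacialsfs.core import DivergenceModel
        from glacialsfs.simdata import simulate_two_deme_sfs

        lats = np.array([40.0, 44.0, 50.0, 58.0])
        pops = [f"p{i}" for i in range(4)]
        coords = pd.DataFrame({"pop": pops, "lat": lats, "lon": 0.0})
        positive = 0
        n_seeds = 10
        for seed in range(n_seeds):
            fst = pd.DataFrame(0.0, index=pops, columns=pops)
            for i in range(4):
                for j in range(i + 1, 4):
                    d = geodesic_km(lats[i], 0, lats[j], 0)
                    nm = 2000.0 / d  # gene flow decays with distance
                    model = DivergenceModel(
                        npop1=1e4, npop2=1e4, ncur=1e4, tdiv=1e5,
                        n1m21=nm, n2m12=nm, has_migration=True,
                    )
                    js = simulate_two_deme_sfs(
                        model, 8, 8, 2e5, 1e-8, reps=150, seed=1000 * seed + 10 * i + j
                    )
                    fst.iloc[i, j] = fst.iloc[j, i] = hudson_fst_from_joint(js)
            positive += ibd_regression(fst, coords).beta > 0
        assert positive >= int(0.95 * n_seeds)


class TestScaledPopulationFst:
    def test_two_populations_share_the_value(self):
        coords = pd.DataFrame({"pop": ["a", "b"], "lat": [40.0, 50.0], "lon": [0.0, 0.0]})
        fst = pd.DataFrame([[0.0, 0.1], [0.1, 0.0]], index=["a", "b"], columns=["a", "b"])
        s = scaled_population_fst(fst, coords)
        d = geodesic_km(40, 0, 50, 0)
        assert s["a"] == s["b"] == pytest.approx(0.1 / d)

    def test_three_population_hand_computation_both_modes(self):
        coords = pd.DataFrame(
            {"pop": ["a", "b", "c"], "lat": [0.0, 0.0, 0.0], "lon": [0.0, 1.0, 3.0]}
        )
        fst = pd.DataFrame(
            [[0.0, 0.02, 0.06], [0.02, 0.0, 0.04], [0.06, 0.04, 0.0]],
            index=["a", "b", "c"], columns=["a", "b", "c"],
        )
        d_ab = geodesic_km(0, 0, 0, 1)
        d_ac = geodesic_km(0, 0, 0, 3)
        mor = scaled_population_fst(fst, coords, "mean_of_ratios_km")
        assert mor["a"] == pytest.approx((0.02 / d_ab + 0.06 / d_ac) / 2)
        rom = scaled_population_fst(fst, coords, "ratio_of_means_km")
        assert rom["a"] == pytest.approx((0.02 + 0.06) / 2 / ((d_ab + d_ac) / 2))

    def test_unknown_mode_rejected(self):
        coords = pd.DataFrame({"pop": ["a", "b"], "lat": [0.0, 1.0], "lon": [0.0, 0.0]})
        fst = pd.DataFrame([[0.0, 0.1], [0.1, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            scaled_population_fst(fst, coords, "geometric")
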