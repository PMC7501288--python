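"""Ratios, correlations, monomial fits, rank preservation, marker profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import omicounts as oc
from conftest import paired_from_truth


def _paired(rows):
    return pd.DataFrame(rows, columns=["orf_id", "mag_id", "time_h",
                                       "rna_molecules", "protein_molecules"])


class TestProteinRnaRatios:
    def test_single_orf(self):
        paired = _paired([("o1", "m1", 18.0, 2.0, 1000.0)])
        out = oc.protein_rna_ratios(paired, 18.0)
        assert out["median"].iloc[0] == pytest.approx(500.0)

    def test_median_of_three(self):
        paired = _paired([
            ("o1", "m1", 18.0, 1.0, 100.0),
            ("o2", "m1", 18.0, 1.0, 1000.0),
            ("o3", "m1", 18.0, 1.0, 10000.0),
        ])
        out = oc.protein_rna_ratios(paired, 18.0)
        assert out["median"].iloc[0] == pytest.approx(1000.0)
        assert out["n_genes"].iloc[0] == 3

    def test_zero_rna_is_error(self):
        paired = _paired([("o1", "m1", 18.0, 0.0, 10.0)])
        with pytest.raises(ValueError, match="non-positive RNA"):
            oc.protein_rna_ratios(paired, 18.0)

    def test_pooled_bacteria_row(self):
        paired = _paired([
            ("o1", "b1", 18.0, 1.0, 100.0),
            ("o2", "b2", 18.0, 1.0, 400.0),
            ("o3", "a1", 18.0, 1.0, 10000.0),
        ])
        out = oc.protein_rna_ratios(
            paired, 18.0, {"b1": "bacterial", "b2": "bacterial", "a1": "archaeal"}
        ).set_index("mag_id")
        assert out.loc["all_bacteria", "n_genes"] == 2
        assert out.loc["all_bacteria", "median"] == pytest.approx(250.0)

    def test_generator_target_recovered(self):
        """A bacterial MAG generated at median_ratio_target 1e3 with
        log10 noise 0.3 over 500 genes yields a median in [10^2.7, 10^3.3]."""
        mag = oc.MagSpec("b1", n_orfs=500,
                         true_k_per_timepoint=[0.7], median_ratio_target=1e3)
        cfg = oc.SimulationConfig(mags=[mag], n_timepoints=1, n_replicates=3,
                                  mp_noise_sd=0.3, seed=21)
        cat, truth = oc.generate_community(cfg, make_sequences=False)
        paired = paired_from_truth(truth, cat)
        out = oc.protein_rna_ratios(paired, cfg.t_start_h)
        assert 10**2.7 <= out["median"].iloc[0] <= 10**3.3


class TestGenewisePcc:
    def test_perfect_proportionality(self):
        rows = [("o1", "m1", t, 10.0 * 2**t, 20.0 * 2**t) for t in range(5)]
        records, median = oc.genewise_pcc(_paired(rows))
        assert records["pcc"].iloc[0] == pytest.approx(1.0)
        assert median == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        rna = [1e3, 1e4, 1e5, 1e6]
        rows = [("o1", "m1", t, r, 1e9 / r) for t, r in enumerate(rna)]
        records, _ = oc.genewise_pcc(_paired(rows))
        assert records["pcc"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_is_missing(self):
        rows = [("o1", "m1", t, 100.0, 5000.0) for t in range(4)]
        records, _ = oc.genewise_pcc(_paired(rows))
        assert np.isnan(records["pcc"].iloc[0])

    def test_too_few_timepoints_skipped(self):
        rows = [("o1", "m1", 0.0, 1.0, 2.0), ("o1", "m1", 1.0, 3.0, 4.0)]
        records, _ = oc.genewise_pcc(_paired(rows))
        assert records["skipped"].iloc[0]

    def test_independent_series_null(self):
        """1000 genes x 7 time points of independent levels: median PCC
        within +/-0.1 of zero (Monte-Carlo null)."""
        rng = np.random.default_rng(17)
        rows = []
        for g in range(1000):
            for t in range(7):
                rows.append((f"o{g:04d}", "m1", float(t),
                             10.0 ** rng.normal(6, 1), 10.0 ** rng.normal(9, 1)))
        _, median = oc.genewise_pcc(_paired(rows))
        assert abs(median) < 0.1


def _normal_equations_fit(x, y):
    """Independent OLS oracle via the 2x2 normal equations."""
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return intercept, slope


class TestFitMonomial:
    def test_noiseless_power_law_recovery(self):
        rng = np.random.default_rng(23)
        rna = 10.0 ** rng.uniform(4, 9, size=50)
        protein = 100.0 * rna**0.7
        fit = oc.fit_monomial(rna, protein)
        assert fit.k == pytest.approx(0.7, abs=1e-9)
        assert fit.a_log10 == pytest.approx(2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.a == pytest.approx(100.0, rel=1e-6)

    def test_identity_law(self):
        rna = np.array([1e3, 1e5, 1e7])
        fit = oc.fit_monomial(rna, rna)
        assert fit.k == pytest.approx(1.0, abs=1e-12)
        assert fit.a_log10 == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            oc.fit_monomial([1.0, 2.0], [1.0, 2.0])

    def test_zero_rna_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            oc.fit_monomial([10.0, 10.0, 10.0], [1.0, 2.0, 3.0])

    def test_nonpositive_values_error(self):
        with pytest.raises(ValueError):
            oc.fit_monomial([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(n=st.integers(3, 20), seed=st.integers(0, 5000))
    def test_equals_normal_equations_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(3, 10, size=n)
        if np.ptp(x) == 0:
            return
        y = rng.uniform(5, 14, size=n)
        fit = oc.fit_monomial(10.0**x, 10.0**y)
        intercept, slope = _normal_equations_fit(x, y)
        assert fit.k == pytest.approx(slope, abs=1e-8)
        assert fit.a_log10 == pytest.approx(intercept, abs=1e-8)


class TestPredictProteinChange:
    def test_doubling_at_full_linearity(self):
        assert oc.predict_protein_change(1.0, 2.0) == pytest.approx(2.0)

    def test_half_linearity_gives_sqrt2(self):
        # a doubling in RNA -> ~41.4% more protein (approximately 40%)
        assert oc.predict_protein_change(0.5, 2.0) == pytest.approx(2**0.5, rel=1e-12)

    def test_zero_linearity_is_flat(self):
        assert oc.predict_protein_change(0.0, 17.0) == 1.0

    def test_nonpositive_fold_change_is_error(self):
        with pytest.raises(ValueError):
            oc.predict_protein_change(0.5, 0.0)


class TestFitKTrajectory:
    def test_four_points_interpolate_exactly(self):
        t = np.array([13.0, 18.0, 23.0, 28.0])
        k = np.array([0.8, 0.6, 0.55, 0.4])
        traj = oc.fit_k_trajectory(t, k)
        np.testing.assert_allclose(traj.residuals, 0.0, atol=1e-9)
        np.testing.assert_allclose(traj.predict(t), k, atol=1e-9)

    def test_constant_k_gives_flat_cubic(self):
        t = np.linspace(13, 43, 7)
        traj = oc.fit_k_trajectory(t, np.full(7, 0.6))
        c0, c1, c2, c3 = traj.coefficients
        assert c0 == pytest.approx(0.6, abs=1e-9)
        for c in (c1, c2, c3):
            assert c == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError, match=">= 4"):
            oc.fit_k_trajectory([1, 2, 3], [0.1, 0.2, 0.3])

    def test_refuses_extrapolation(self):
        traj = oc.fit_k_trajectory([13, 18, 23, 28], [0.8, 0.7, 0.6, 0.5])
        with pytest.raises(ValueError, match="extrapolate"):
            traj.predict([50.0])

    def test_noisy_coefficient_recovery(self):
        """7 points from a known cubic + noise sd 0.01: coefficients come
        back within 3 standard errors (checked via the exact cubic values)."""
        rng = np.random.default_rng(29)
        t = np.linspace(13, 43, 7)
        true = 0.9 - 0.02 * t + 4e-4 * t**2 - 5e-6 * t**3
        hits = 0
        for _ in range(50):
            traj = oc.fit_k_trajectory(t, true + rng.normal(0, 0.01, 7))
            pred = traj.predict(t)
            hits += np.max(np.abs(pred - true)) < 0.05
        assert hits >= 45


def _brute_force_tau_b(x, y):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    n = len(x)
    nc = nd = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            nc += 1
        else:
            nd += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (nc - nd) / denom


class TestKendallRankPreservation:
    def test_identical_ranking(self):
        a = pd.Series([5, 4, 3, 2, 1], index=list("abcde"))
        res = oc.kendall_rank_preservation(a, a * 10)
        assert res.kendall_tau == pytest.approx(1.0)

    def test_reversed_ranking(self):
        a = pd.Series([5, 4, 3, 2, 1], index=list("abcde"))
        b = pd.Series([1, 2, 3, 4, 5], index=list("abcde"))
        res = oc.kendall_rank_preservation(a, b)
        assert res.kendall_tau == pytest.approx(-1.0)

    def test_mismatched_categories_error_lists_difference(self):
        a = pd.Series([1, 2], index=["x", "y"])
        b = pd.Series([1, 2], index=["x", "z"])
        with pytest.raises(ValueError, match="z"):
            oc.kendall_rank_preservation(a, b)

    def test_five_category_toy_table(self):
        a = pd.Series([10, 8, 6, 4, 2], index=list("abcde"))
        b = pd.Series([9, 10, 5, 6, 1], index=list("abcde"))
        res = oc.kendall_rank_preservation(a, b)
        assert res.kendall_tau == pytest.approx(
            _brute_force_tau_b(a.to_numpy(), b.to_numpy()), abs=1e-12
        )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(n=st.integers(2, 50), seed=st.integers(0, 5000),
           with_ties=st.booleans())
    def test_matches_pair_count_oracle(self, n, seed, with_ties):
        rng = np.random.default_rng(seed)
        if with_ties:
            x = rng.integers(0, max(2, n // 3), size=n).astype(float)
            y = rng.integers(0, max(2, n // 3), size=n).astype(float)
        else:
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return  # tau undefined for constant rankings
        idx = [f"c{i}" for i in range(n)]
        res = oc.kendall_rank_preservation(pd.Series(x, index=idx),
                                           pd.Series(y, index=idx))
        assert res.kendall_tau == pytest.approx(_brute_force_tau_b(x, y), abs=1e-8)


class TestAggregatePathwayMarkers:
    def _mt_and_samples(self):
        times = [13.0, 18.0, 23.0, 28.0, 33.0, 38.0, 43.0]
        samples = pd.DataFrame({
            "sample_id": [f"t{i + 2}A" for i in range(7)],
            "time_h": times, "replicate": ["A"] * 7,
        })
        rows = []
        for gid, scale in (("g1", 1e8), ("g2", 3e8)):
            for i, t in enumerate(times):
                rows.append({"orfg_id": gid, "sample_id": f"t{i + 2}A",
                             "molecules_sample": scale * (1 + i)})
        return pd.DataFrame(rows), samples

    def test_single_marker_equals_its_series(self):
        mt, samples = self._mt_and_samples()
        prof = oc.aggregate_pathway_markers(mt, samples, {"glycolysis": ["g1"]})
        series = mt[mt["orfg_id"] == "g1"].merge(samples)["molecules_sample"]
        np.testing.assert_allclose(prof["total_molecules"], series, rtol=1e-12)

    def test_two_markers_sum(self):
        mt, samples = self._mt_and_samples()
        prof = oc.aggregate_pathway_markers(mt, samples, {"p": ["g1", "g2"]})
        at13 = prof[prof["time_h"] == 13.0]["total_molecules"].iloc[0]
        assert at13 == pytest.approx(1e8 + 3e8)

    def test_cubic_smoothing_reproduces_cubic(self):
        """7 time points lying exactly on a cubic are reproduced exactly."""
        times = np.linspace(13, 43, 7)
        samples = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(7)],
            "time_h": times, "replicate": ["A"] * 7,
        })
        logv = 8.0 + 0.1 * times - 3e-3 * times**2 + 3e-5 * times**3
        mt = pd.DataFrame({
            "orfg_id": "g1", "sample_id": [f"s{i}" for i in range(7)],
            "molecules_sample": 10.0**logv,
        })
        prof = oc.aggregate_pathway_markers(mt, samples, {"p": ["g1"]})
        np.testing.assert_allclose(prof["smoothed_log10"], logv, atol=1e-8)

    def test_unknown_marker_warns_and_skips(self):
        mt, samples = self._mt_and_samples()
        with pytest.warns(UserWarning, match="unknown marker"):
            prof = oc.aggregate_pathway_markers(mt, samples,
                                                {"p": ["g1", "nope"]})
        assert prof["n_markers"].iloc[0] == 1


class TestParameterRecovery:
    def test_fitted_k_tracks_truth(self):
        """Across a 3-MAG community the fitted k per MAG x time has mean
        absolute error < 0.05 against the generating k (500 genes, noise 0.2)."""
        mags = [
            oc.MagSpec("b1", n_orfs=500,
                       true_k_per_timepoint=[0.8, 0.7, 0.6, 0.5, 0.4, 0.35, 0.3]),
            oc.MagSpec("b2", n_orfs=500,
                       true_k_per_timepoint=[0.6, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6]),
            oc.MagSpec("a1", "archaeal", n_orfs=500, median_ratio_target=1e4,
                       true_k_per_timepoint=[0.9, 0.85, 0.8, 0.75, 0.7, 0.65, 0.6]),
        ]
        cfg = oc.SimulationConfig(mags=mags, mp_noise_sd=0.2, seed=31)
        cat, truth = oc.generate_community(cfg, make_sequences=False)
        paired = paired_from_truth(truth, cat)
        fits = oc.fit_mag_timepoints(paired, min_points=30)
        merged = fits.merge(truth.params, on=["mag_id", "time_h"])
        assert len(merged) == 21
        mae = (merged["k"] - merged["true_k"]).abs().mean()
        assert mae < 0.05
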