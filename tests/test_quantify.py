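import numpy as np
import pandas as pd
import pytest

from xenomark import quantify as q
from xenomark import synthetic as syn
from xenomark.grid import WindowGrid
from xenomark.quantify import InterpolatedProfile, SampleCalibration, SaturatingProfile

from conftest import make_truth, flat_calibration


class TestLibraryFactors:
    def test_definition(self, flat_grid):
        counts = pd.DataFrame({"A": np.full(400, 5000)}, index=flat_grid.window_keys())
        s = q.estimate_library_factors(counts)
        assert s["A"] == pytest.approx(2.0)

    def test_identical_totals(self, flat_grid):
        rng = np.random.default_rng(0)
        a = rng.permutation(np.arange(400))
        counts = pd.DataFrame({"A": a, "B": a[::-1]}, index=flat_grid.window_keys())
        s = q.estimate_library_factors(counts)
        assert s["A"] == s["B"]

    def test_zero_sample_named(self, flat_grid):
        counts = pd.DataFrame(
            {"A": np.ones(400), "BAD": np.zeros(400)}, index=flat_grid.window_keys()
        )
        with pytest.raises(ValueError, match="BAD"):
            q.estimate_library_factors(counts)

    def test_normalized_means_equalized(self, flat_grid):
        # flat simulation: after scaling, per-sample mean normalized counts agree
        truth = make_truth(
            flat_grid, {s: np.full(400, 0.5) for s in ("A", "B", "C")}
        )
        cals = {
            "A": flat_calibration(s=1.0, dispersion=200.0),
            "B": flat_calibration(s=3.0, dispersion=200.0),
            "C": flat_calibration(s=0.5, dispersion=200.0),
        }
        counts = syn.simulate_medip_counts(truth, cals, seed=1)
        s = q.estimate_library_factors(counts)
        norm_means = (counts / s).mean(axis=0)
        assert norm_means.max() / norm_means.min() - 1 < 0.01


def _cnv_grid(n_mb=4, window=250):
    n = n_mb * 1_000_000 // window
    start = np.arange(n) * window
    rng = np.random.default_rng(42)
    cpg = rng.poisson(2.0, n)  # plenty of CpG-free windows
    return WindowGrid(
        chrom=np.full(n, "chr1", dtype=object),
        start=start,
        end=start + window,
        cpg_count=cpg,
        window_size=window,
    )


class TestCnv:
    def test_uniform_coverage_unity(self):
        grid = _cnv_grid(3)
        counts = pd.DataFrame({"A": np.full(grid.n_windows, 10)}, index=grid.window_keys())
        track = q.estimate_cnv(counts, grid)
        assert np.allclose(track.factors_for("A"), 1.0)

    def test_doubled_bin(self):
        grid = _cnv_grid(4)
        vals = np.full(grid.n_windows, 10.0)
        vals[grid.start < 1_000_000] = 20.0
        counts = pd.DataFrame({"A": vals}, index=grid.window_keys())
        track = q.estimate_cnv(counts, grid)
        first_bin = track.factors_for("A")[grid.start < 1_000_000]
        assert np.allclose(first_bin, 2.0)

    def test_no_cpg_free_windows_errors(self, flat_grid):
        counts = pd.DataFrame({"A": np.ones(400)}, index=flat_grid.window_keys())
        with pytest.raises(ValueError, match="CpG-free"):
            q.estimate_cnv(counts, flat_grid)

    def test_gain_recovery_from_simulation(self):
        # [DERIVED] 3-copy region (c = 1.5) recovered within 0.1 at ~30x
        grid = _cnv_grid(4)
        cnv_true = np.ones(grid.n_windows)
        gain = (grid.start >= 1_000_000) & (grid.start < 2_000_000)
        cnv_true[gain] = 1.5
        truth = make_truth(grid, {"A": np.full(grid.n_windows, 0.6)})
        cal = SampleCalibration(
            library_factor=1.0,
            background_rate=5.0,
            profile=SaturatingProfile(f_max=40.0, k=2.0),
            cnv=cnv_true,
            dispersion=50.0,
        )
        counts = syn.simulate_medip_counts(truth, {"A": cal}, seed=3)
        track = q.estimate_cnv(counts, grid)
        rec = track.factors_for("A")[gain]
        assert abs(rec.mean() - 1.5) < 0.1


def _calibration_setup(n_windows=6000, seed=0, f_max=50.0, k=3.0, o=2.0):
    """High-methylation windows across a range of CpG densities."""
    rng = np.random.default_rng(seed)
    start = np.arange(n_windows) * 250
    cpg = rng.integers(0, 12, n_windows)
    grid = WindowGrid(
        chrom=np.full(n_windows, "chr1", dtype=object),
        start=start,
        end=start + 250,
        cpg_count=cpg,
        window_size=250,
    )
    beta_true = np.clip(rng.normal(0.95, 0.01, n_windows), 0, 1)
    ref = pd.DataFrame({"mean": beta_true, "variance": np.full(n_windows, 0.01)})
    profile = SaturatingProfile(f_max=f_max, k=k)
    cals = {
        s: SampleCalibration(
            library_factor=1.0, background_rate=o, profile=profile, dispersion=np.inf
        )
        for s in ("A", "B")
    }
    truth = make_truth(grid, {s: beta_true for s in ("A", "B")})
    mu = q.expected_counts(truth.beta, cals, grid)
    return grid, ref, cals, mu, profile


class TestCalibrateEnrichment:
    def test_selection_rule_excludes_ineligible_windows(self):
        # 60% of windows are unmethylated (background-only counts) but carry a
        # misleading reference mean of 0.95 with variance 0.06: the fitted
        # profile is only correct if the variance rule excludes them
        grid, ref, cals, mu, profile = _calibration_setup()
        rng = np.random.default_rng(7)
        bad = rng.random(grid.n_windows) < 0.6
        ref = ref.copy()
        ref.loc[bad, "variance"] = 0.06
        counts = mu.copy()
        counts.loc[bad] = 2.0  # background only: true beta 0 on those windows
        fitted = q.calibrate_enrichment(counts, ref, grid)
        cal = fitted["A"]
        scale = 1e6 / counts["A"].sum()  # CPM normalization scale
        for cpg in range(2, 11):
            assert cal.profile(cpg) == pytest.approx(
                float(profile(cpg)) * scale, rel=0.05
            )

    def test_closed_loop_profile_recovery(self):
        # [DERIVED] noiseless counts from a known profile: recovery within 2%
        # (on the CPM-normalized scale implied by the library factors)
        grid, ref, cals, mu, profile = _calibration_setup()
        fitted = q.calibrate_enrichment(mu, ref, grid)
        cal = fitted["A"]
        scale = 1e6 / mu["A"].sum()
        assert cal.background_rate == pytest.approx(2.0 * scale, rel=0.02)
        knot_cpgs = cal.profile.knot_cpg[1:]  # skip the f(0)=0 anchor
        for c in knot_cpgs:
            assert cal.profile(c) == pytest.approx(
                float(profile(c)) * scale, rel=0.02
            )

    def test_too_few_calibration_windows(self):
        grid, ref, cals, mu, _ = _calibration_setup()
        bad_ref = ref.copy()
        bad_ref["mean"] = 0.5  # nothing passes the > 0.9 rule
        with pytest.raises(ValueError, match="0 calibration-eligible"):
            q.calibrate_enrichment(mu, bad_ref, grid)

    def test_single_cpg_value_underdetermined(self):
        n = 300
        start = np.arange(n) * 250
        grid = WindowGrid(
            chrom=np.full(n, "chr1", dtype=object),
            start=start,
            end=start + 250,
            cpg_count=np.full(n, 5),
            window_size=250,
        )
        ref = pd.DataFrame({"mean": np.full(n, 0.95), "variance": np.full(n, 0.01)})
        counts = pd.DataFrame({"A": np.full(n, 30.0), "B": np.full(n, 30.0)},
                              index=grid.window_keys())
        with pytest.raises(ValueError, match="underdetermined"):
            q.calibrate_enrichment(counts, ref, grid)

    def test_monotone_profile(self):
        grid, ref, cals, mu, _ = _calibration_setup()
        rng = np.random.default_rng(1)
        noisy = mu * rng.uniform(0.7, 1.3, size=mu.shape)
        fitted = q.calibrate_enrichment(noisy, ref, grid)
        knots = fitted["A"].profile.knot_f
        assert np.all(np.diff(knots) >= -1e-9)


class TestEstimateMethylation:
    def _one_window_grid(self, cpg=5):
        return WindowGrid(
            chrom=np.array(["chr1"], dtype=object),
            start=np.array([0]),
            end=np.array([250]),
            cpg_count=np.array([cpg]),
            window_size=250,
        )

    def test_direct_inversion(self):
        grid = self._one_window_grid()
        cal = {"A": flat_calibration(f=20.0, o=2.0, s=1.0)}
        counts = pd.DataFrame({"A": [12.0]}, index=grid.window_keys())
        meth = q.estimate_methylation(counts, cal, grid)
        assert meth.beta["A"].iloc[0] == pytest.approx(0.5)

    def test_clamped_at_zero_below_background(self):
        grid = self._one_window_grid()
        cal = {"A": flat_calibration(f=20.0, o=2.0)}
        counts = pd.DataFrame({"A": [1.0]}, index=grid.window_keys())
        meth = q.estimate_methylation(counts, cal, grid)
        assert meth.beta["A"].iloc[0] == 0.0

    def test_missing_where_no_cpg(self):
        grid = self._one_window_grid(cpg=0)
        cal = {"A": flat_calibration()}
        counts = pd.DataFrame({"A": [10.0]}, index=grid.window_keys())
        meth = q.estimate_methylation(counts, cal, grid)
        assert np.isnan(meth.beta["A"].iloc[0])

    def test_zero_profile_warns_and_missing(self):
        grid = self._one_window_grid(cpg=3)
        cal = {
            "A": SampleCalibration(
                library_factor=1.0,
                background_rate=1.0,
                profile=InterpolatedProfile(
                    knot_cpg=np.array([5.0, 10.0]), knot_f=np.array([0.0, 20.0])
                ),
            )
        }
        counts = pd.DataFrame({"A": [10.0]}, index=grid.window_keys())
        with pytest.warns(UserWarning, match="zero profile"):
            meth = q.estimate_methylation(counts, cal, grid)
        assert np.isnan(meth.beta["A"].iloc[0])

    def test_cnv_neutrality(self, flat_grid):
        # scaling one sample's counts is absorbed by its library factor
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            {"A": rng.integers(5, 60, flat_grid.n_windows)},
            index=flat_grid.window_keys(),
        )
        c1 = {"A": flat_calibration(f=20.0, o=2.0, s=1.0)}
        c2 = {"A": flat_calibration(f=20.0, o=2.0, s=3.0)}
        m1 = q.estimate_methylation(counts, c1, flat_grid)
        m2 = q.estimate_methylation(counts * 3, c2, flat_grid)
        pd.testing.assert_frame_equal(m1.beta, m2.beta)

    def test_monotone_in_raw_count(self, flat_grid):
        cal = {"A": flat_calibration(f=20.0, o=2.0)}
        counts = pd.DataFrame(
            {"A": np.arange(flat_grid.n_windows, dtype=float)},
            index=flat_grid.window_keys(),
        )
        meth = q.estimate_methylation(counts, cal, flat_grid)
        assert (np.diff(meth.beta["A"].to_numpy()) >= 0).all()

    def test_recovery_rmse_under_noise(self, flat_grid):
        # pooled across 8 replicate samples at moderate depth
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 1, flat_grid.n_windows)
        samples = [f"S{i}" for i in range(8)]
        truth = make_truth(flat_grid, {s: base for s in samples})
        cals = {s: flat_calibration(f=60.0, o=1.0, dispersion=50.0) for s in samples}
        counts = syn.simulate_medip_counts(truth, cals, seed=4)
        meth = q.estimate_methylation(counts, cals, flat_grid)
        pooled = meth.beta.mean(axis=1).to_numpy()
        assert np.sqrt(np.mean((pooled - base) ** 2)) < 0.05


class TestPca:
    def _meth(self, values, samples):
        n = values.shape[0]
        start = np.arange(n) * 250
        grid = WindowGrid(
            chrom=np.full(n, "chr1", dtype=object),
            start=start,
            end=start + 250,
            cpg_count=np.full(n, 5),
            window_size=250,
        )
        beta = pd.DataFrame(values, index=grid.window_keys(), columns=samples)
        return q.MethylationMatrix(grid=grid, beta=beta)

    def test_identical_samples_identical_coordinates(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(0, 1, 30)
        vals = np.column_stack([col, col, rng.uniform(0, 1, 30)])
        meth = self._meth(vals, ["A", "B", "C"])
        res = q.pca_promoter_methylation(meth, np.ones(30, dtype=bool), n_top=30)
        assert np.allclose(
            res.coordinates.loc["A"].to_numpy(), res.coordinates.loc["B"].to_numpy(),
            atol=1e-10,
        )

    def test_explained_variance_fractions(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, (40, 5))
        meth = self._meth(vals, list("ABCDE"))
        res = q.pca_promoter_methylation(meth, np.ones(40, dtype=bool), n_top=40)
        assert (res.explained_variance >= 0).all()
        assert res.explained_variance.sum() <= 1 + 1e-9

    def test_oracle_eigendecomposition(self):
        # [DERIVED] first component matches direct eigen-decomposition
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 1, (20, 5))
        meth = self._meth(vals, list("ABCDE"))
        res = q.pca_promoter_methylation(meth, np.ones(20, dtype=bool), n_top=20)
        x = vals.T - vals.T.mean(axis=0, keepdims=True)  # samples x windows
        cov = x @ x.T
        evals, evecs = np.linalg.eigh(cov)
        pc1_oracle = evecs[:, -1] * np.sqrt(evals[-1])
        pc1 = res.coordinates["PC1"].to_numpy()
        assert min(
            np.abs(pc1 - pc1_oracle).max(), np.abs(pc1 + pc1_oracle).max()
        ) < 1e-8

    def test_top_variance_selection(self):
        rng = np.random.default_rng(3)
        vals = np.full((50, 4), 0.5)
        vals[:10] = rng.uniform(0, 1, (10, 4))  # only 10 variable windows
        meth = self._meth(vals, list("ABCD"))
        res = q.pca_promoter_methylation(meth, np.ones(50, dtype=bool), n_top=10)
        assert res.n_windows_used == 10

    def test_errors(self):
        meth = self._meth(np.full((5, 3), np.nan), list("ABC"))
        with pytest.raises(ValueError, match="fewer than 2"):
            q.pca_promoter_methylation(meth, np.ones(5, dtype=bool))


class TestBsConcordance:
    def _setup(self):
        n = 40
        start = np.arange(n) * 250
        grid = WindowGrid(
            chrom=np.full(n, "chr1", dtype=object),
            start=start,
            end=start + 250,
            cpg_count=np.full(n, 5),
            window_size=250,
        )
        beta = pd.DataFrame(
            {"A": np.linspace(0.05, 0.95, n)}, index=grid.window_keys()
        )
        return grid, q.MethylationMatrix(grid=grid, beta=beta)

    def test_window_mean(self):
        grid, meth = self._setup()
        cpgs = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [10, 100],
                "level": [0.8, 0.6],
                "coverage": [25, 30],
            }
        )
        res = q.summarize_bs_concordance(cpgs, grid, meth, "A")
        assert res.window_means.iloc[0] == pytest.approx(0.7)

    def test_low_coverage_excluded(self):
        grid, meth = self._setup()
        cpgs = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [10, 100],
                "level": [0.8, 0.0],
                "coverage": [25, 19],
            }
        )
        res = q.summarize_bs_concordance(cpgs, grid, meth, "A")
        assert res.window_means.iloc[0] == pytest.approx(0.8)

    def test_high_concordance_on_shared_methylome(self):
        # [DERIVED] same methylome through both channels -> Spearman >= 0.9
        grid, meth = self._setup()
        rng = np.random.default_rng(5)
        truth_level = meth.beta["A"].to_numpy()
        rows = []
        for w in range(grid.n_windows):
            for c in range(3):
                rows.append(
                    {
                        "chrom": "chr1",
                        "pos": int(grid.start[w] + 10 + c * 50),
                        "level": float(
                            np.clip(truth_level[w] + rng.normal(0, 0.03), 0, 1)
                        ),
                        "coverage": 30,
                    }
                )
        res = q.summarize_bs_concordance(pd.DataFrame(rows), grid, meth, "A")
        assert res.spearman_rho >= 0.9

    def test_no_joint_windows_errors(self):
        grid, meth = self._setup()
        cpgs = pd.DataFrame(
            {"chrom": ["chrX"], "pos": [10], "level": [0.5], "coverage": [30]}
        )
        with pytest.raises(ValueError, match="jointly defined"):
            q.summarize_bs_concordance(cpgs, grid, meth, "A")
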