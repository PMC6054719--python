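"""Absolute methylation estimation from enrichment counts.

The estimation model for sample *i* and window *w* is

    E[count] = s_i * c_{i,w} * ( o_i + beta_{i,w} * f_i(cpg_w) )

with ``s`` the library-size factor, ``c`` the relative copy-number factor,
``o`` the background rate at beta = 0, and ``f`` a monotone CpG-density
enrichment profile (expected normalized count increment at beta = 1).
Methylation is recovered by direct inversion and clamped into [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from xenomark.grid import WindowGrid

__all__ = [
    "SaturatingProfile",
    "InterpolatedProfile",
    "SampleCalibration",
    "CnvTrack",
    "MethylationMatrix",
    "estimate_library_factors",
    "estimate_cnv",
    "calibrate_enrichment",
    "estimate_methylation",
    "expected_counts",
    "pca_promoter_methylation",
    "summarize_bs_concordance",
]


# ---------------------------------------------------------------------------
# enrichment profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SaturatingProfile:
    """Monotone saturating enrichment curve ``f(cpg) = f_max * cpg / (cpg + k)``.

    Saturation reflects antibody-capture physics: expected enrichment grows
    with local CpG density but levels off once capture is density-limited.
    """

    f_max: float
    k: float

    def __post_init__(self) -> None:
        if self.f_max <= 0 or self.k <= 0:
            raise ValueError("f_max and k must be positive")

    def __call__(self, cpg):
        cpg = np.asarray(cpg, dtype=float)
        return self.f_max * cpg / (cpg + self.k)

    def knots(self) -> pd.DataFrame:
        cpg = np.arange(0, 41)
        return pd.DataFrame({"cpg": cpg, "f": self(cpg)})


@dataclass(frozen=True)
class InterpolatedProfile:
    """Piecewise-linear enrichment profile through monotone knots.

    Evaluates by linear interpolation between knots and flat extrapolation
    beyond the last knot; ``f(0) = 0`` is always anchored.
    """

    knot_cpg: np.ndarray
    knot_f: np.ndarray

    def __post_init__(self) -> None:
        kc = np.asarray(self.knot_cpg, dtype=float)
        kf = np.asarray(self.knot_f, dtype=float)
        if kc.ndim != 1 or kc.shape != kf.shape or len(kc) < 1:
            raise ValueError("knots must be 1-D arrays of equal length")
        if np.any(np.diff(kc) <= 0):
            raise ValueError("knot cpg values must be strictly increasing")
        if np.any(np.diff(kf) < -1e-12):
            raise ValueError("profile knots must be non-decreasing")
        if kc[0] > 0:
            kc = np.concatenate([[0.0], kc])
            kf = np.concatenate([[0.0], kf])
        object.__setattr__(self, "knot_cpg", kc)
        object.__setattr__(self, "knot_f", kf)

    def __call__(self, cpg):
        cpg = np.asarray(cpg, dtype=float)
        return np.interp(cpg, self.knot_cpg, self.knot_f)

    def knots(self) -> pd.DataFrame:
        return pd.DataFrame({"cpg": self.knot_cpg, "f": self.knot_f})


# ---------------------------------------------------------------------------
# calibration containers
# ---------------------------------------------------------------------------


@dataclass
class SampleCalibration:
    """Per-sample parameters of the enrichment mean model.

    ``dispersion`` is the negative-binomial size parameter shared per dataset
    (variance = mu + mu**2 / dispersion); ``numpy.inf`` selects Poisson noise.
    ``cnv`` is a per-window relative copy factor aligned to the grid
    (``None`` means flat copy number).
    """

    library_factor: float
    background_rate: float
    profile: SaturatingProfile | InterpolatedProfile
    cnv: np.ndarray | None = None
    dispersion: float = np.inf

    def __post_init__(self) -> None:
        if self.library_factor <= 0:
            raise ValueError("library_factor must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")
        if self.cnv is not None:
            self.cnv = np.asarray(self.cnv, dtype=float)

    def cnv_for(self, grid: WindowGrid) -> np.ndarray:
        if self.cnv is None:
            return np.ones(grid.n_windows)
        if len(self.cnv) != grid.n_windows:
            raise ValueError("cnv track length does not match grid")
        return self.cnv


@dataclass
class CnvTrack:
    """Per-sample relative copy-number factors on coarse genomic bins."""

    bins: pd.DataFrame  # chrom, start, end, has_data + one factor column per sample
    sample_ids: list[str]
    window_factors: pd.DataFrame  # windows x samples, aligned to the grid

    def factors_for(self, sample: str) -> np.ndarray:
        return self.window_factors[sample].to_numpy()


@dataclass
class MethylationMatrix:
    """Windows x samples absolute methylation (beta) estimates in [0, 1].

    ``NaN`` marks windows without an estimate (CpG-free or degenerate profile).
    """

    grid: WindowGrid
    beta: pd.DataFrame  # index = window keys, columns = sample ids

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    def values_for(self, samples: list[str]) -> np.ndarray:
        return self.beta[samples].to_numpy()

    def to_tsv(self, path) -> None:
        self.beta.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def estimate_library_factors(counts: pd.DataFrame) -> pd.Series:
    """Counts-per-million library factors: total fragments / 1e6 per sample."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total count: {list(zero.index)}")
    return totals / 1e6


def estimate_cnv(
    counts: pd.DataFrame,
    grid: WindowGrid,
    bin_size: int = 1_000_000,
) -> CnvTrack:
    """Relative copy number from CpG-free window coverage in coarse bins.

    Per sample and bin, the factor is the mean CpG-free per-window count in
    the bin divided by the sample's median over informative bins; bins without
    CpG-free windows inherit factor 1 and are flagged. Factors are rescaled so
    that the per-sample median over all bins is exactly 1.
    """
    cpg_free = grid.cpg_count == 0
    if not cpg_free.any():
        raise ValueError("no CpG-free windows in grid; CNV cannot be estimated")
    bin_of = grid.bin_ids(bin_size)
    n_bins = int(bin_of.max()) + 1

    # bin coordinate table
    rows = []
    for b in range(n_bins):
        m = bin_of == b
        rows.append(
            {
                "chrom": grid.chrom[m][0],
                "start": int(grid.start[m].min()) // bin_size * bin_size,
                "end": (int(grid.start[m].max()) // bin_size + 1) * bin_size,
                "has_data": bool((m & cpg_free).any()),
            }
        )
    bins = pd.DataFrame(rows)

    samples = list(counts.columns)
    values = counts.to_numpy(dtype=float)
    factors = np.ones((n_bins, len(samples)))
    for b in range(n_bins):
        m = (bin_of == b) & cpg_free
        if m.any():
            factors[b] = values[m].mean(axis=0)
    informative = bins["has_data"].to_numpy()
    med = np.median(factors[informative], axis=0)
    med[med <= 0] = 1.0
    factors[informative] /= med
    # enforce median(all factors) == 1 per sample
    med_all = np.median(factors, axis=0)
    med_all[med_all <= 0] = 1.0
    factors = factors / med_all
    factors[~informative] = 1.0

    for j, s in enumerate(samples):
        bins[s] = factors[:, j]
    per_window = pd.DataFrame(
        factors[bin_of], index=grid.window_keys(), columns=samples
    )
    return CnvTrack(bins=bins, sample_ids=samples, window_factors=per_window)


def _monotone_pool(cpg: np.ndarray, f: np.ndarray, w: np.ndarray):
    """Pool adjacent violators so that f is non-decreasing in cpg (weighted)."""
    blocks = [[float(c), float(v), float(wt)] for c, v, wt in zip(cpg, f, w)]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][1] > blocks[i + 1][1] + 1e-12:
            c1, v1, w1 = blocks[i]
            c2, v2, w2 = blocks[i + 1]
            merged = [
                (c1 * w1 + c2 * w2) / (w1 + w2),
                (v1 * w1 + v2 * w2) / (w1 + w2),
                w1 + w2,
            ]
            blocks[i : i + 2] = [merged]
            i = max(i - 1, 0)
        else:
            i += 1
    out = np.array(blocks)
    return out[:, 0], out[:, 1]


def _estimate_dispersion(norm: np.ndarray, min_mean: float = 5.0) -> float:
    """Method-of-moments NB size from normalized counts, per-window then
    dataset-level median over windows with mean >= ``min_mean``; floored."""
    m = norm.mean(axis=1)
    v = norm.var(axis=1, ddof=1)
    ok = (m >= min_mean) & (v > m)
    if not ok.any():
        return np.inf
    size = m[ok] ** 2 / (v[ok] - m[ok])
    return float(max(np.median(size), 1e-6))


def calibrate_enrichment(
    counts: pd.DataFrame,
    reference_betas: pd.DataFrame,
    grid: WindowGrid,
    cnv: CnvTrack | None = None,
    min_windows: int = 50,
    min_cpg_bins: int = 5,
    mean_threshold: float = 0.90,
    var_threshold: float = 0.05,
) -> dict[str, SampleCalibration]:
    """Fit per-sample background and CpG-density enrichment profiles.

    Calibration windows are those whose reference methylation has mean above
    ``mean_threshold`` and variance below ``var_threshold``; on those windows
    the observed normalized signal is attributed to the reference mean level,
    binned by CpG count (width-2 bins merged until each holds >= 20 windows),
    summarised by the median, and made monotone by pooling adjacent violators.
    """
    for col in ("mean", "variance"):
        if col not in reference_betas.columns:
            raise ValueError(f"reference_betas must have a '{col}' column")
    ref_mean = reference_betas["mean"].to_numpy(dtype=float)
    ref_var = reference_betas["variance"].to_numpy(dtype=float)
    if len(ref_mean) != grid.n_windows:
        raise ValueError("reference_betas not aligned to grid")

    eligible = (ref_mean > mean_threshold) & (ref_var < var_threshold) & (grid.cpg_count > 0)
    n_elig = int(eligible.sum())
    cpg_elig = grid.cpg_count[eligible]
    n_bins_obs = len(np.unique(cpg_elig))
    if n_elig < min_windows:
        raise ValueError(
            f"only {n_elig} calibration-eligible windows (need >= {min_windows})"
        )
    if n_bins_obs < min_cpg_bins:
        raise ValueError(
            f"calibration windows span only {n_bins_obs} distinct cpg_count values "
            f"(need >= {min_cpg_bins}); profile underdetermined"
        )

    s = estimate_library_factors(counts)
    cpg_free = grid.cpg_count == 0
    values = counts.to_numpy(dtype=float)
    out: dict[str, SampleCalibration] = {}
    norm_all = np.empty_like(values)
    for j, sample in enumerate(counts.columns):
        c = cnv.factors_for(sample) if cnv is not None else np.ones(grid.n_windows)
        norm = values[:, j] / (s[sample] * c)
        norm_all[:, j] = norm
        o = float(norm[cpg_free].mean()) if cpg_free.any() else 0.0

        y = (norm[eligible] - o) / ref_mean[eligible]
        order = np.argsort(cpg_elig, kind="stable")
        cpg_sorted, y_sorted = cpg_elig[order], y[order]
        # one bin per distinct cpg value, greedily merged to >= 20 windows
        # each (keeps knots unbiased for curved profiles; a fixed-width-2
        # binning mixes two curve values per bin and shifts the median)
        knot_c, knot_f, knot_w = [], [], []
        buf_c, buf_y = [], []
        for i, (cc, yy) in enumerate(zip(cpg_sorted, y_sorted)):
            buf_c.append(cc)
            buf_y.append(yy)
            last = i == len(cpg_sorted) - 1
            boundary = last or cpg_sorted[i + 1] != cc
            if boundary and (len(buf_c) >= 20 or last):
                if last and len(buf_c) < 20 and knot_c:
                    # fold the undersized tail into the previous bin
                    prev_n = knot_w.pop()
                    kc, kf = knot_c.pop(), knot_f.pop()
                    knot_c.append(
                        (kc * prev_n + np.sum(buf_c)) / (prev_n + len(buf_c))
                    )
                    knot_f.append(kf)  # keep robust centre of the dominant bin
                    knot_w.append(prev_n + len(buf_c))
                else:
                    knot_c.append(np.mean(buf_c))
                    knot_f.append(np.median(buf_y))
                    knot_w.append(len(buf_c))
                buf_c, buf_y = [], []
        kc, kf = _monotone_pool(np.array(knot_c), np.array(knot_f), np.array(knot_w))
        kf = np.maximum(kf, 0.0)
        profile = InterpolatedProfile(knot_cpg=kc, knot_f=kf)
        out[sample] = SampleCalibration(
            library_factor=float(s[sample]),
            background_rate=o,
            profile=profile,
            cnv=c,
            dispersion=np.inf,  # filled below (shared per dataset)
        )

    dispersion = _estimate_dispersion(norm_all)
    for cal in out.values():
        cal.dispersion = dispersion
    return out


def expected_counts(
    beta: pd.DataFrame | np.ndarray,
    calibrations: dict[str, SampleCalibration],
    grid: WindowGrid,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Forward mean model: expected counts for given betas and calibrations."""
    if isinstance(beta, pd.DataFrame):
        samples = list(beta.columns)
        b = beta.to_numpy(dtype=float)
    else:
        if sample_ids is None:
            raise ValueError("sample_ids required when beta is an array")
        samples = list(sample_ids)
        b = np.asarray(beta, dtype=float)
    mu = np.empty_like(b)
    for j, sample in enumerate(samples):
        cal = calibrations[sample]
        f = cal.profile(grid.cpg_count)
        c = cal.cnv_for(grid)
        bj = np.nan_to_num(b[:, j], nan=0.0)
        mu[:, j] = cal.library_factor * c * (cal.background_rate + bj * f)
    return pd.DataFrame(mu, index=grid.window_keys(), columns=samples)


def estimate_methylation(
    counts: pd.DataFrame,
    calibrations: dict[str, SampleCalibration],
    grid: WindowGrid,
) -> MethylationMatrix:
    """Invert the enrichment mean model into clamped beta estimates.

    beta = clamp((count / (s * c) - o) / f(cpg), 0, 1); windows with
    cpg_count = 0 carry no estimate, and windows where the profile evaluates
    to 0 despite cpg_count > 0 are set missing with a warning.
    """
    values = counts.to_numpy(dtype=float)
    beta = np.full_like(values, np.nan)
    cpg = grid.cpg_count
    for j, sample in enumerate(counts.columns):
        cal = calibrations[sample]
        f = cal.profile(cpg)
        c = cal.cnv_for(grid)
        norm = values[:, j] / (cal.library_factor * c)
        with np.errstate(divide="ignore", invalid="ignore"):
            est = (norm - cal.background_rate) / f
        defined = cpg > 0
        degenerate = defined & (f <= 0)
        if degenerate.any():
            warnings.warn(
                f"{sample}: {int(degenerate.sum())} windows with zero profile "
                "value despite cpg_count > 0; set missing",
                stacklevel=2,
            )
        ok = defined & ~degenerate
        beta[ok, j] = np.clip(est[ok], 0.0, 1.0)
    return MethylationMatrix(
        grid=grid,
        beta=pd.DataFrame(beta, index=grid.window_keys(), columns=counts.columns),
    )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x (PC1, PC2)
    explained_variance: np.ndarray  # fractions for all components
    n_windows_used: int


def pca_promoter_methylation(
    meth: MethylationMatrix,
    promoter_mask: np.ndarray,
    n_top: int = 1000,
) -> PcaResult:
    """PCA of samples on the most variable promoter-overlapping windows.

    Restricts to promoter windows with defined beta in every sample, ranks by
    cross-sample variance, keeps the top ``n_top``, centers each window and
    decomposes; returns the first two component coordinates plus variance
    fractions of all components.
    """
    if meth.beta.shape[1] < 2:
        raise ValueError("PCA requires >= 2 samples")
    sub = meth.beta.loc[np.asarray(promoter_mask, dtype=bool)]
    sub = sub.dropna(axis=0, how="any")
    if sub.shape[0] < 2:
        raise ValueError("fewer than 2 promoter windows with complete beta")
    var = sub.var(axis=1, ddof=1)
    keep = var.sort_values(ascending=False, kind="stable").index[:n_top]
    x = sub.loc[keep].to_numpy().T  # samples x windows
    x = x - x.mean(axis=0, keepdims=True)
    u, sv, _ = np.linalg.svd(x, full_matrices=False)
    coords = u * sv
    total = float((sv**2).sum())
    frac = sv**2 / total if total > 0 else np.zeros_like(sv)
    coordinates = pd.DataFrame(
        coords[:, :2], index=meth.beta.columns, columns=["PC1", "PC2"]
    )
    return PcaResult(
        coordinates=coordinates, explained_variance=frac, n_windows_used=x.shape[1]
    )


@dataclass
class BsConcordance:
    window_means: pd.Series  # per-window bisulfite mean, NaN where undefined
    spearman_rho: float
    n_windows: int


def summarize_bs_concordance(
    cpg_level: pd.DataFrame,
    grid: WindowGrid,
    meth: MethylationMatrix,
    sample: str,
    min_coverage: int = 20,
) -> BsConcordance:
    """Window-average bisulfite methylation and its rank agreement with beta.

    ``cpg_level`` columns: chrom, pos, level, coverage. CpGs under
    ``min_coverage`` are excluded; remaining levels are averaged per window
    (unweighted) and compared to the MeDIP betas by Spearman correlation over
    jointly defined windows.
    """
    need = {"chrom", "pos", "level", "coverage"}
    if not need.issubset(cpg_level.columns):
        raise ValueError(f"cpg_level must have columns {sorted(need)}")
    keep = cpg_level[cpg_level["coverage"] >= min_coverage]
    means = pd.Series(np.nan, index=grid.window_keys(), dtype=float)
    keys = grid.window_keys()
    for chrom, sub in keep.groupby("chrom", sort=False):
        m = grid.chrom == chrom
        if not m.any():
            continue
        starts = grid.start[m]
        idx_local = np.searchsorted(starts, sub["pos"].to_numpy(), side="right") - 1
        in_window = (idx_local >= 0) & (
            sub["pos"].to_numpy() < grid.end[m][np.clip(idx_local, 0, None)]
        )
        global_idx = np.flatnonzero(m)[idx_local[in_window]]
        lv = sub["level"].to_numpy()[in_window]
        agg = pd.Series(lv).groupby(pd.Series(keys[global_idx])).mean()
        means.loc[agg.index] = agg.to_numpy()
    joint = pd.DataFrame({"bs": means, "medip": meth.beta[sample]}).dropna()
    if joint.empty:
        raise ValueError("no jointly defined windows between bisulfite and MeDIP")
    rho = float(stats.spearmanr(joint["bs"], joint["medip"]).statistic)
    return BsConcordance(window_means=means, spearman_rho=rho, n_windows=len(joint))
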