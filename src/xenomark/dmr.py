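"""Window-wise negative-binomial GLM likelihood-ratio testing.

Each window's counts follow mu_i = s_i * c_i * (o_i + beta * f_i(cpg)) with
negative-binomial noise at fixed dispersion. The group test compares one
shared methylation level against one level per group; the quantitative test
compares it against a clamped linear model on a per-sample predictor
(log relative tumor volume). p-values come from the chi-square(1) reference
distribution of 2 * (alt - null) log-likelihood, with Benjamini-Hochberg FDR
across all tested windows.

Also implements large-hypomethylated-block (LHB) calling on tiled beta
differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from xenomark.grid import WindowGrid
from xenomark.quantify import MethylationMatrix, SampleCalibration

__all__ = [
    "nb_loglik",
    "DmrResult",
    "test_group_dmr",
    "test_quantitative_rdmr",
    "log_tc_predictor",
    "adjust_fdr",
    "filter_dmrs",
    "call_lhbs",
    "compare_lhb_intensity",
]

_MU_FLOOR = 1e-12


def nb_loglik(y, mu, size):
    """Negative-binomial log-likelihood (size/mean parameterisation).

    ``var = mu + mu**2 / size``; ``size = inf`` gives the Poisson limit.
    Broadcasts over ``y`` and ``mu``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _MU_FLOOR)
    if np.isinf(size):
        return y * np.log(mu) - mu - gammaln(y + 1.0)
    r = float(size)
    return (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


# ---------------------------------------------------------------------------
# per-window likelihood machinery
# ---------------------------------------------------------------------------


def _window_loglik(y, a, o, f, size, beta):
    """Log-likelihood of one window at a (possibly vector of) shared beta."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    mu = a * (o + beta[:, None] * f)
    ll = nb_loglik(y[None, :], mu, size).sum(axis=1)
    return ll


def _maximize_shared_beta(y, a, o, f, size, coarse=51):
    """Maximum-likelihood shared beta on [0, 1]: coarse grid + local Brent."""
    grid = np.linspace(0.0, 1.0, coarse)
    ll = _window_loglik(y, a, o, f, size, grid)
    i = int(np.argmax(ll))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, coarse - 1)]
    res = optimize.minimize_scalar(
        lambda b: -_window_loglik(y, a, o, f, size, b)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-7},
    )
    best_b, best_ll = float(res.x), float(-res.fun)
    if ll[i] > best_ll:  # guard against optimizer hiccups
        best_b, best_ll = float(grid[i]), float(ll[i])
    return best_b, best_ll


def _maximize_linear_beta(y, a, o, f, size, x, n_b0=21, n_b1=21):
    """Maximum likelihood of beta_i = clamp(b0 + b1 * x_i, 0, 1).

    Coarse (b0, b1) grid evaluated in one broadcast pass, refined by
    Nelder-Mead on the clamped objective.
    """
    xr = float(x.max() - x.min())
    b1_max = 2.0 / max(xr, 1e-9)
    b0g = np.linspace(0.0, 1.0, n_b0)
    b1g = np.linspace(-b1_max, b1_max, n_b1)
    bb0, bb1 = np.meshgrid(b0g, b1g, indexing="ij")
    betas = np.clip(bb0.ravel()[:, None] + bb1.ravel()[:, None] * x[None, :], 0.0, 1.0)
    mu = a * (o + betas * f)
    ll = nb_loglik(y[None, :], mu, size).sum(axis=1)
    i = int(np.argmax(ll))
    start = np.array([bb0.ravel()[i], bb1.ravel()[i]])

    def neg(params):
        b = np.clip(params[0] + params[1] * x, 0.0, 1.0)
        return -float(nb_loglik(y, a * (o + b * f), size).sum())

    res = optimize.minimize(
        neg,
        start,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 300},
    )
    if -res.fun >= ll[i]:
        b0, b1 = float(res.x[0]), float(res.x[1])
        best_ll = float(-res.fun)
    else:
        b0, b1 = float(start[0]), float(start[1])
        best_ll = float(ll[i])
    return b0, b1, best_ll


def _model_arrays(counts, calibrations, grid):
    samples = list(counts.columns)
    n = grid.n_windows
    a = np.empty((n, len(samples)))
    o = np.empty(len(samples))
    f = np.empty((n, len(samples)))
    sizes = np.empty(len(samples))
    for j, s in enumerate(samples):
        cal: SampleCalibration = calibrations[s]
        a[:, j] = cal.library_factor * cal.cnv_for(grid)
        o[j] = cal.background_rate
        f[:, j] = cal.profile(grid.cpg_count)
        sizes[j] = cal.dispersion
    size = float(np.median(sizes))
    return samples, a, o, f, size


@dataclass
class DmrResult:
    """Per-window test records plus the skipped-window report."""

    records: pd.DataFrame
    skipped: pd.DataFrame


def _direction(delta: float) -> str:
    if delta > 0:
        return "hyper"
    if delta < 0:
        return "hypo"
    return "none"


def _finalize(rows, skipped_rows) -> DmrResult:
    records = pd.DataFrame(rows)
    if len(records):
        records["fdr"] = adjust_fdr(records["p_value"].to_numpy())
    skipped = pd.DataFrame(skipped_rows, columns=["window", "reason"])
    return DmrResult(records=records, skipped=skipped)


def test_group_dmr(
    counts: pd.DataFrame,
    calibrations: dict[str, SampleCalibration],
    groups: dict[str, str] | pd.Series,
    grid: WindowGrid,
    contrast: tuple[str, str] | None = None,
) -> DmrResult:
    """Likelihood-ratio test of one shared methylation level vs one per group.

    ``contrast = (alt, ref)`` sets the sign convention:
    ``delta_beta = beta_alt - beta_ref`` (default: labels in reverse sorted
    order, so ('pdx', 'normal') for the usual design).
    """
    groups = dict(groups)
    levels = sorted(set(groups[s] for s in counts.columns))
    if len(levels) != 2:
        raise ValueError(f"groups must have exactly 2 levels, got {levels}")
    if contrast is None:
        contrast = (levels[1], levels[0])
    alt_label, ref_label = contrast
    samples, a, o, f, size = _model_arrays(counts, calibrations, grid)
    idx_alt = np.array([j for j, s in enumerate(samples) if groups[s] == alt_label])
    idx_ref = np.array([j for j, s in enumerate(samples) if groups[s] == ref_label])
    if len(idx_alt) < 2 or len(idx_ref) < 2:
        raise ValueError("each group needs >= 2 samples")

    values = counts.to_numpy(dtype=float)
    keys = grid.window_keys()
    rows, skipped = [], []
    for w in range(grid.n_windows):
        if grid.cpg_count[w] == 0:
            continue
        y = values[w]
        if y.sum() == 0:
            skipped.append({"window": keys[w], "reason": "all_zero"})
            continue
        aw, fw = a[w], f[w]
        _, ll0 = _maximize_shared_beta(y, aw, o, fw, size)
        b_alt, ll_alt = _maximize_shared_beta(
            y[idx_alt], aw[idx_alt], o[idx_alt], fw[idx_alt], size
        )
        b_ref, ll_ref = _maximize_shared_beta(
            y[idx_ref], aw[idx_ref], o[idx_ref], fw[idx_ref], size
        )
        ll1 = ll_alt + ll_ref
        lrt = max(2.0 * (ll1 - ll0), 0.0)
        delta = b_alt - b_ref
        f_mean, o_mean = float(fw.mean()), float(o.mean())
        log2fc = float(
            np.log2(
                (o_mean + b_alt * f_mean + _MU_FLOOR)
                / (o_mean + b_ref * f_mean + _MU_FLOOR)
            )
        )
        rows.append(
            {
                "window": keys[w],
                "chrom": grid.chrom[w],
                "start": int(grid.start[w]),
                "end": int(grid.end[w]),
                "delta_beta": delta,
                "log2fc": log2fc,
                "null_loglik": ll0,
                "alt_loglik": ll1,
                "lrt_stat": lrt,
                "p_value": float(stats.chi2.sf(lrt, df=1)),
                "direction": _direction(delta),
            }
        )
    return _finalize(rows, skipped)


def log_tc_predictor(t_over_c: pd.Series, floor: float = 0.1) -> pd.Series:
    """Natural log of T/C percent, floored at ``floor`` percent."""
    return np.log(t_over_c.clip(lower=floor))


def test_quantitative_rdmr(
    counts: pd.DataFrame,
    calibrations: dict[str, SampleCalibration],
    predictor: pd.Series,
    grid: WindowGrid,
) -> DmrResult:
    """LRT of methylation depending linearly (clamped) on a sample predictor.

    H1: beta_i = clamp(b0 + b1 * x_i, 0, 1); H0: b1 = 0. ``delta_beta``
    carries the slope b1 (methylation change per predictor unit); direction
    is 'hyper' when methylation rises with the predictor.
    """
    x_full = pd.Series(predictor).reindex(counts.columns)
    if x_full.isna().any() or len(x_full) < 4:
        raise ValueError("need >= 4 samples with finite predictor values")
    x = x_full.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")

    samples, a, o, f, size = _model_arrays(counts, calibrations, grid)
    values = counts.to_numpy(dtype=float)
    keys = grid.window_keys()
    rows, skipped = [], []
    for w in range(grid.n_windows):
        if grid.cpg_count[w] == 0:
            continue
        y = values[w]
        if y.sum() == 0:
            skipped.append({"window": keys[w], "reason": "all_zero"})
            continue
        aw, fw = a[w], f[w]
        b0_null, ll0 = _maximize_shared_beta(y, aw, o, fw, size)
        b0, b1, ll1 = _maximize_linear_beta(y, aw, o, fw, size, x)
        ll1 = max(ll1, ll0)  # null is nested in the alternative
        lrt = max(2.0 * (ll1 - ll0), 0.0)
        f_mean, o_mean = float(fw.mean()), float(o.mean())
        beta_hi = float(np.clip(b0 + b1 * x.max(), 0, 1))
        beta_lo = float(np.clip(b0 + b1 * x.min(), 0, 1))
        log2fc = float(
            np.log2(
                (o_mean + beta_hi * f_mean + _MU_FLOOR)
                / (o_mean + beta_lo * f_mean + _MU_FLOOR)
            )
        )
        rows.append(
            {
                "window": keys[w],
                "chrom": grid.chrom[w],
                "start": int(grid.start[w]),
                "end": int(grid.end[w]),
                "delta_beta": b1,
                "intercept": b0,
                "log2fc": log2fc,
                "null_loglik": ll0,
                "alt_loglik": ll1,
                "lrt_stat": lrt,
                "p_value": float(stats.chi2.sf(lrt, df=1)),
                "direction": _direction(b1),
            }
        )
    return _finalize(rows, skipped)


# ---------------------------------------------------------------------------
# FDR and filtering
# ---------------------------------------------------------------------------


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def filter_dmrs(
    records: pd.DataFrame, fdr_max: float, min_abs_delta: float
) -> pd.DataFrame:
    """Keep records with fdr < ``fdr_max`` and |delta_beta| > ``min_abs_delta``."""
    keep = (records["fdr"] < fdr_max) & (records["delta_beta"].abs() > min_abs_delta)
    return records[keep].copy()


# ---------------------------------------------------------------------------
# large hypomethylated blocks
# ---------------------------------------------------------------------------


def call_lhbs(
    meth: MethylationMatrix,
    groups: dict[str, str],
    tile_size: int = 100_000,
    min_size: int = 1_000_000,
    min_drop: float = 0.20,
    contrast: tuple[str, str] = ("pdx", "normal"),
) -> pd.DataFrame:
    """Call blocks of >= ``min_size`` with mean beta reduced by >= ``min_drop``.

    Per ``tile_size`` tile the mean (alt - ref) beta difference is computed;
    maximal runs of consecutive tiles at or below ``-min_drop`` (no gap
    tolerance) whose span reaches ``min_size`` are emitted, with the mean
    difference recomputed over the constituent windows.
    """
    alt_label, ref_label = contrast
    alt = [s for s in meth.sample_ids if groups.get(s) == alt_label]
    ref = [s for s in meth.sample_ids if groups.get(s) == ref_label]
    if not alt or not ref:
        raise ValueError("both contrast groups must be non-empty")
    grid = meth.grid
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="Mean of empty slice")
        delta_w = np.nanmean(meth.values_for(alt), axis=1) - np.nanmean(
            meth.values_for(ref), axis=1
        )

    out = []
    for chrom in grid.chromosomes:
        m = grid.chrom_mask(chrom) & ~np.isnan(delta_w)
        if not m.any():
            continue
        tile = grid.start[m] // tile_size
        d = pd.Series(delta_w[m]).groupby(pd.Series(tile)).mean()
        tiles = d.index.to_numpy()
        vals = d.to_numpy()
        hit = vals <= -min_drop
        # maximal runs of consecutive tile ids that all pass
        runs = []
        i = 0
        while i < len(tiles):
            if hit[i]:
                j = i
                while j + 1 < len(tiles) and hit[j + 1] and tiles[j + 1] == tiles[j] + 1:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        for i0, i1 in runs:
            start = int(tiles[i0] * tile_size)
            end = int((tiles[i1] + 1) * tile_size)
            if end - start < min_size:
                continue
            wm = m & (grid.start >= start) & (grid.end <= end)
            out.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "mean_delta": float(np.mean(delta_w[wm])),
                    "n_windows": int(wm.sum()),
                }
            )
    return pd.DataFrame(out, columns=["chrom", "start", "end", "mean_delta", "n_windows"])


def compare_lhb_intensity(
    lhbs: pd.DataFrame,
    meth: MethylationMatrix,
    class_map: dict[str, str],
    normal_samples: list[str],
) -> pd.DataFrame:
    """Descriptive per-block mean beta drop split by response class.

    For each block and class, the mean over block windows of
    (class-mean beta - normal-mean beta). When exactly two classes are
    present, their difference (first minus second in sorted class order) is
    added.
    """
    import warnings as _warnings

    classes = sorted(set(class_map.values()))
    by_class = {
        c: [s for s, cl in class_map.items() if cl == c and s in meth.sample_ids]
        for c in classes
    }
    for c in list(by_class):
        if not by_class[c]:
            _warnings.warn(f"response class {c!r} has no samples; omitted", stacklevel=2)
            del by_class[c]
    classes = sorted(by_class)
    grid = meth.grid
    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="Mean of empty slice")
        normal_mean = np.nanmean(meth.values_for(list(normal_samples)), axis=1)
        cls_means = {
            c: np.nanmean(meth.values_for(by_class[c]), axis=1) for c in classes
        }
    rows = []
    for _, blk in lhbs.iterrows():
        wm = (
            (grid.chrom == blk["chrom"])
            & (grid.start >= blk["start"])
            & (grid.end <= blk["end"])
        )
        row = {"chrom": blk["chrom"], "start": blk["start"], "end": blk["end"]}
        for c in classes:
            d = cls_means[c][wm] - normal_mean[wm]
            row[c] = float(np.nanmean(d))
        if len(classes) == 2:
            row["difference"] = row[classes[0]] - row[classes[1]]
        rows.append(row)
    return pd.DataFrame(rows)
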