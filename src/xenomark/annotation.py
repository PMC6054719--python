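"""Region-of-interest annotation and enrichment odds ratios.

All intervals are 0-based, half-open; a window overlaps an ROI when they
share at least one base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from xenomark.grid import WindowGrid

__all__ = [
    "RoiSet",
    "build_promoters",
    "annotate_windows",
    "compute_enrichment",
    "genomic_distribution",
    "fisher_exact_p",
]


@dataclass
class RoiSet:
    """A named set of genomic intervals (chrom, start, end; half-open)."""

    name: str
    intervals: pd.DataFrame  # columns chrom, start, end (+ optional gene)

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end"}
        if not need.issubset(self.intervals.columns):
            raise ValueError(f"intervals must have columns {sorted(need)}")
        if (self.intervals["start"] >= self.intervals["end"]).any():
            raise ValueError("invalid interval with start >= end")

    @classmethod
    def from_bed(cls, path, name: str) -> "RoiSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.iloc[:, :3]
        df.columns = ["chrom", "start", "end"]
        return cls(name=name, intervals=df)

    def to_bed(self, path) -> None:
        self.intervals[["chrom", "start", "end"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping (not merely adjacent) intervals per chromosome."""
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "end"])
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:  # strict: touching intervals stay separate
                cur_e = max(cur_e, e)
            else:
                rows.append({"chrom": chrom, "start": cur_s, "end": cur_e})
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append({"chrom": chrom, "start": cur_s, "end": cur_e})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def build_promoters(
    tss_table: pd.DataFrame,
    flank: int = 2000,
    chrom_lengths: dict[str, int] | None = None,
) -> RoiSet:
    """Promoter intervals [TSS - flank, TSS + flank), merged per gene.

    The flank is symmetric, so strand does not change the interval. Intervals
    are clipped at 0 and, when ``chrom_lengths`` is given, at the chromosome
    end.
    """
    need = {"gene", "chrom", "pos"}
    if not need.issubset(tss_table.columns):
        raise ValueError(f"tss_table must have columns {sorted(need)}")
    if (tss_table["pos"] < 0).any():
        raise ValueError("TSS positions must be non-negative")
    df = tss_table.copy()
    df["start"] = (df["pos"] - flank).clip(lower=0)
    df["end"] = df["pos"] + flank
    if chrom_lengths is not None:
        lengths = df["chrom"].map(chrom_lengths)
        df["end"] = np.minimum(df["end"], lengths)
    merged = []
    for (gene, chrom), sub in df.groupby(["gene", "chrom"], sort=False):
        mg = _merge_intervals(sub[["chrom", "start", "end"]])
        mg["gene"] = gene
        merged.append(mg)
    out = pd.concat(merged, ignore_index=True)
    return RoiSet(name="promoter", intervals=out[["chrom", "start", "end", "gene"]])


def annotate_windows(grid: WindowGrid, rois: list[RoiSet]) -> pd.DataFrame:
    """Boolean overlap flags (>= 1 bp, half-open semantics) per window and ROI.

    ROI intervals on chromosomes absent from the grid are dropped with a
    warning.
    """
    flags = pd.DataFrame(index=grid.window_keys())
    grid_chroms = set(grid.chromosomes)
    for roi in rois:
        col = np.zeros(grid.n_windows, dtype=bool)
        unknown = set(roi.intervals["chrom"]) - grid_chroms
        if unknown:
            warnings.warn(
                f"ROI {roi.name!r}: dropping intervals on unknown chromosomes "
                f"{sorted(unknown)}",
                stacklevel=2,
            )
        merged = _merge_intervals(
            roi.intervals[roi.intervals["chrom"].isin(grid_chroms)]
        )
        for chrom, sub in merged.groupby("chrom", sort=False):
            m = grid.chrom_mask(chrom)
            istart = sub["start"].to_numpy()
            iend = sub["end"].to_numpy()
            # merged intervals are disjoint and sorted: the only candidate for
            # a window is the last interval starting before the window's end
            idx = np.searchsorted(istart, grid.end[m], side="left") - 1
            ok = idx >= 0
            hit = np.zeros(m.sum(), dtype=bool)
            hit[ok] = iend[idx[ok]] > grid.start[m][ok]
            col[np.flatnonzero(m)] = hit
        flags[roi.name] = col
    return flags


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables (with the observed
    margins) whose probability does not exceed the observed one.
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    return float(min(pmf[pmf <= p_obs * (1 + 1e-7)].sum(), 1.0))


def compute_enrichment(
    dmr_flags: pd.DataFrame,
    roi_flags: pd.DataFrame,
    background: str = "genome",
) -> pd.DataFrame:
    """Enrichment of DMR windows inside each ROI, per direction.

    With ``background='genome'`` the odds ratio contrasts the DMR fraction
    inside the ROI with the genome-wide DMR fraction (ROI included):
    OR = [p1/(1-p1)] / [p2/(1-p2)], p1 = dmr_in_roi / windows_in_roi,
    p2 = dmr_total / windows_total. ``background='exclusive'`` uses the
    classical 2x2 sample odds ratio against out-of-ROI windows. The Fisher
    p always comes from the exact 2x2 table (in/out of ROI x DMR/non-DMR).

    ROIs covering zero windows are omitted with a warning.
    """
    if background not in {"genome", "exclusive"}:
        raise ValueError("background must be 'genome' or 'exclusive'")
    windows_total = len(roi_flags)
    rows = []
    for roi in roi_flags.columns:
        in_roi = roi_flags[roi].to_numpy(dtype=bool)
        windows_in_roi = int(in_roi.sum())
        if windows_in_roi == 0:
            warnings.warn(f"ROI {roi!r} covers no windows; omitted", stacklevel=2)
            continue
        for direction in dmr_flags.columns:
            dmr = dmr_flags[direction].to_numpy(dtype=bool)
            dmr_total = int(dmr.sum())
            dmr_in_roi = int((dmr & in_roi).sum())
            p1 = dmr_in_roi / windows_in_roi
            p2 = dmr_total / windows_total
            if background == "genome":
                if p1 >= 1.0 or p2 >= 1.0:
                    odds = np.inf if p1 > p2 else 1.0
                elif p2 == 0.0:
                    odds = np.inf if p1 > 0 else np.nan
                else:
                    odds = (p1 / (1 - p1)) / (p2 / (1 - p2))
            else:
                a = dmr_in_roi
                b = windows_in_roi - dmr_in_roi
                c = dmr_total - dmr_in_roi
                d = (windows_total - windows_in_roi) - c
                odds = (a * d) / (b * c) if b * c > 0 else np.inf
            fisher = fisher_exact_p(
                dmr_in_roi,
                windows_in_roi - dmr_in_roi,
                dmr_total - dmr_in_roi,
                (windows_total - windows_in_roi) - (dmr_total - dmr_in_roi),
            )
            rows.append(
                {
                    "roi": roi,
                    "direction": direction,
                    "dmr_in_roi": dmr_in_roi,
                    "windows_in_roi": windows_in_roi,
                    "dmr_total": dmr_total,
                    "windows_total": windows_total,
                    "odds_ratio": float(odds),
                    "fisher_p": fisher,
                }
            )
    return pd.DataFrame(rows)


CATEGORY_PRIORITY = ("promoter", "exon", "intron", "intergenic")


def genomic_distribution(
    dmr_mask: np.ndarray, annotation: pd.DataFrame
) -> dict[str, float]:
    """Fraction of DMR windows per genomic category.

    Each DMR window is assigned exactly one category with priority
    promoter > exon > intron > intergenic; fractions sum to 1.
    """
    dmr_mask = np.asarray(dmr_mask, dtype=bool)
    n = int(dmr_mask.sum())
    counts = dict.fromkeys(CATEGORY_PRIORITY, 0)
    if n == 0:
        return {c: 0.0 for c in CATEGORY_PRIORITY}
    assigned = np.zeros(len(annotation), dtype=bool)
    for cat in CATEGORY_PRIORITY[:-1]:
        if cat in annotation.columns:
            hit = annotation[cat].to_numpy(dtype=bool) & dmr_mask & ~assigned
            counts[cat] = int(hit.sum())
            assigned |= hit
    counts["intergenic"] = int((dmr_mask & ~assigned).sum())
    return {c: counts[c] / n for c in CATEGORY_PRIORITY}
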