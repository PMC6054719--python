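"""Expression preparation and methylation/expression/response triage.

The triage cascade selects candidate predictive genes in three stages:
(1) genes with at least one promoter window whose methylation is associated
with the response predictor at uncorrected p < 0.01, (2) of those, genes
whose promoter methylation correlates with relative tumor volume
(Spearman p < 0.05), and (3) of those, genes whose expression correlates
with tumor volume (Spearman p < 0.05) in the opposite direction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from xenomark.quantify import MethylationMatrix

__all__ = [
    "collapse_probes",
    "compute_ders",
    "CorrelationResult",
    "spearman_with_p",
    "TriageResult",
    "triage_candidates",
]

QUALITY_KEEP = frozenset({"perfect", "good"})


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_annotation: pd.DataFrame,
    quality_keep: frozenset[str] = QUALITY_KEEP,
) -> pd.DataFrame:
    """One row per gene: keep the highest-mean surviving probe.

    Probes whose quality grade is not in ``quality_keep`` are removed first;
    probes without a gene mapping are dropped (count reported via warning).
    Ties in mean expression are broken by the lexicographically smallest
    probe id.
    """
    ann = probe_annotation.set_index("probe")
    known = probe_matrix.index.intersection(ann.index)
    n_unmapped = len(probe_matrix) - len(known)
    unmapped_gene = ann.loc[known, "gene"].isna()
    n_unmapped += int(unmapped_gene.sum())
    if n_unmapped:
        warnings.warn(f"dropped {n_unmapped} probes without gene mapping", stacklevel=2)
    keep = known[~unmapped_gene.to_numpy()]
    ann = ann.loc[keep]
    good = ann[ann["quality"].isin(quality_keep)]
    sub = probe_matrix.loc[good.index]
    means = sub.mean(axis=1)
    table = pd.DataFrame(
        {"gene": good["gene"].to_numpy(), "mean": means.to_numpy(),
         "probe": good.index.to_numpy()}
    ).sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
    winners = table.drop_duplicates("gene", keep="first")
    out = sub.loc[winners["probe"]]
    out.index = pd.Index(winners["gene"].to_numpy(), name="gene")
    return out.sort_index()


def compute_ders(expr: pd.DataFrame, normal_sample_ids: list[str]) -> pd.DataFrame:
    """Per-gene, per-tumor log2 ratio to the median of the normal samples."""
    normals = [s for s in normal_sample_ids if s in expr.columns]
    if not normals:
        raise ValueError("no normal samples present in expression matrix")
    tumor = [s for s in expr.columns if s not in set(normals)]
    ref = expr[normals].median(axis=1)
    return expr[tumor].sub(ref, axis=0)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def spearman_with_p(x, y, exact_max_n: int = 8) -> CorrelationResult:
    """Spearman correlation with exact permutation p for small n.

    Uses average ranks. For n <= ``exact_max_n`` the two-sided p is computed
    by full enumeration of the n! orderings (fraction of permutations whose
    |rho| reaches the observed |rho|); otherwise the t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired observations with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(x)

    def _rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    rho = _rho(rx, ry)
    if n <= exact_max_n:
        target = abs(rho) - 1e-12
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rho(rx, np.asarray(perm))) >= target:
                count += 1
        p = count / total
    else:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho**2, 1e-15))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p_value=min(p, 1.0), n=n)


@dataclass
class TriageResult:
    """Candidate table plus per-stage gene sets of the selection cascade."""

    candidates: pd.DataFrame
    stage1_genes: list[str]
    stage2_genes: list[str]
    stage3_genes: list[str]


def triage_candidates(
    promoter_rdmrs: pd.DataFrame,
    meth: MethylationMatrix,
    gene_promoter_windows: dict[str, np.ndarray],
    expr_ders: pd.DataFrame,
    t_over_c: pd.Series,
    rdmr_p_max: float = 0.01,
    meth_p_max: float = 0.05,
    expr_p_max: float = 0.05,
    meth_level: str = "gene",
) -> TriageResult:
    """Three-stage biomarker triage on promoter-associated response DMRs.

    ``promoter_rdmrs`` must carry columns ``gene`` and ``p_value`` (one row
    per promoter window test). Stage-2 methylation is the mean beta over the
    gene's promoter windows with defined values (``meth_level='gene'``), or
    the single best-p window (``meth_level='window'``). Samples used for the
    correlations are those with finite ``t_over_c`` present in both data
    types.
    """
    if meth_level not in {"gene", "window"}:
        raise ValueError("meth_level must be 'gene' or 'window'")
    tc = t_over_c.dropna()
    samples = [s for s in tc.index if s in meth.beta.columns and s in expr_ders.columns]
    if len(samples) < 6:
        raise ValueError("need >= 6 samples with methylation, expression and T/C")
    tc = tc[samples]

    # stage 1: any promoter window below the uncorrected rDMR p threshold
    stage1 = sorted(
        promoter_rdmrs.loc[promoter_rdmrs["p_value"] < rdmr_p_max, "gene"].unique()
    )

    rows = []
    stage2, stage3 = [], []
    for gene in stage1:
        widx = gene_promoter_windows.get(gene)
        if widx is None or len(widx) == 0:
            continue
        sub = meth.beta.iloc[widx][samples]
        if meth_level == "gene":
            gene_meth = sub.mean(axis=0, skipna=True)
        else:
            best = (
                promoter_rdmrs[promoter_rdmrs["gene"] == gene]
                .sort_values("p_value")
                .iloc[0]["window"]
            )
            gene_meth = meth.beta.loc[best, samples]
        if gene_meth.isna().any():
            continue
        try:
            meth_corr = spearman_with_p(gene_meth.to_numpy(), tc.to_numpy())
        except ValueError:
            continue
        if not meth_corr.p_value < meth_p_max:
            continue
        stage2.append(gene)
        if gene not in expr_ders.index:
            continue
        try:
            expr_corr = spearman_with_p(
                expr_ders.loc[gene, samples].to_numpy(), tc.to_numpy()
            )
        except ValueError:
            continue
        opposite = np.sign(expr_corr.rho) == -np.sign(meth_corr.rho)
        if expr_corr.p_value < expr_p_max and opposite:
            stage3.append(gene)
            gene_rdmr_p = float(
                promoter_rdmrs.loc[promoter_rdmrs["gene"] == gene, "p_value"].min()
            )
            rows.append(
                {
                    "gene": gene,
                    "promoter_rdmr_p": gene_rdmr_p,
                    "meth_vol_rho": meth_corr.rho,
                    "meth_vol_p": meth_corr.p_value,
                    "expr_vol_rho": expr_corr.rho,
                    "expr_vol_p": expr_corr.p_value,
                    "opposite_sign": True,
                }
            )
    candidates = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "promoter_rdmr_p",
            "meth_vol_rho",
            "meth_vol_p",
            "expr_vol_rho",
            "expr_vol_p",
            "opposite_sign",
        ],
    )
    if len(candidates):
        candidates = candidates.sort_values("expr_vol_p", kind="stable").reset_index(
            drop=True
        )
    return TriageResult(
        candidates=candidates,
        stage1_genes=stage1,
        stage2_genes=stage2,
        stage3_genes=stage3,
    )
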