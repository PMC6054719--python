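"""End-to-end orchestration: simulate -> quantify -> test -> triage -> validate.

Every stage reads and writes plain-text files inside one working directory so
that stages can be re-run in isolation; :func:`run_pipeline` chains them and
serializes a run report. All randomness derives from the single master seed
via named substreams, so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from xenomark import annotation, dmr, expression, synthetic, validation
from xenomark import quantify
from xenomark.grid import WindowGrid

logger = logging.getLogger("xenomark")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 17,
    "genome": {
        "chrom_lengths": {"chr1": 4_000_000, "chr2": 3_000_000},
        "window_size": 250,
        "cpg_model": {
            "background_mean": 2.0,
            "island_mean": 15.0,
            "island_rate": 0.8,
            "island_halfwidth": 1,
            "promoter_spacing": 20_000,
        },
    },
    "methylome": {
        "n_models": 10,
        "baseline_beta": 0.8,
        "island_beta": 0.1,
        "lhb": [{"chrom": "chr1", "start": 1_000_000, "end": 3_000_000, "delta": -0.35}],
        "n_focal_hyper": 5,
        "focal_delta": 0.6,
        "n_rdmr_genes": 3,
        "coupling_slope": 0.08,
        "rdmr_b0": 0.35,
        "noise_sd": 0.02,
    },
    "counts": {
        "depth": 30.0,
        "f_max": 60.0,
        "k": 2.0,
        "background_rate": 1.0,
        "dispersion": 50.0,
        "library_jitter": 0.1,
    },
    "expression": {"coupling": -4.0, "noise_sd": 0.15},
    "cohort": {
        "n_pairs": 20,
        "group_means": [7.4, 13.9],
        "group_sd": 3.0,
        "hazard_ratio": 3.0,
        "censor_rate": 0.2,
    },
    "thresholds": {
        "dmr_fdr": 1e-4,
        "dmr_delta": 0.20,
        "rdmr_p": 0.01,
        "corr_p": 0.05,
        "lhb_min_size": 1_000_000,
        "lhb_min_drop": 0.20,
        "lhb_tile_size": 100_000,
    },
}

_FLOAT_FMT = "%.8g"


def _check_thresholds(t: dict) -> None:
    for key, lo, hi in [
        ("dmr_fdr", 0, 1),
        ("dmr_delta", 0, 1),
        ("rdmr_p", 0, 1),
        ("corr_p", 0, 1),
        ("lhb_min_drop", 0, 1),
    ]:
        if not lo < t[key] <= hi:
            raise ValueError(f"threshold {key}={t[key]} outside ({lo}, {hi}]")
    if t["lhb_min_size"] <= 0 or t["lhb_tile_size"] <= 0:
        raise ValueError("LHB sizes must be positive")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (synthetic-generation mode)."""

    raw: dict
    seed: int

    @classmethod
    def from_dict(cls, d: dict, seed: int | None = None) -> "PipelineConfig":
        merged = _deep_merge(DEFAULT_CONFIG, d or {})
        if seed is not None:
            merged["seed"] = int(seed)
        _check_thresholds(merged["thresholds"])
        if "genome" not in merged:
            raise ValueError("config must contain a synthetic generation block")
        return cls(raw=merged, seed=int(merged["seed"]))

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {}, seed=seed)

    def __getitem__(self, key):
        return self.raw[key]


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunReport:
    seed: int
    stage_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "stage_counts": self.stage_counts,
                    "outputs": self.outputs,
                    "warnings": self.warnings,
                    "parameters": self.parameters,
                },
                fh,
                indent=2,
                sort_keys=True,
                default=str,
            )
            fh.write("\n")


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# calibration serialization (for stage isolation)
# ---------------------------------------------------------------------------


def save_calibrations(cals: dict[str, quantify.SampleCalibration], workdir: Path) -> None:
    rows, knot_rows, cnv_cols = [], [], {}
    for s, cal in cals.items():
        rows.append(
            {
                "sample": s,
                "library_factor": cal.library_factor,
                "background_rate": cal.background_rate,
                "dispersion": cal.dispersion,
            }
        )
        for _, kr in cal.profile.knots().iterrows():
            knot_rows.append({"sample": s, "cpg": kr["cpg"], "f": kr["f"]})
        if cal.cnv is not None:
            cnv_cols[s] = cal.cnv
    _write(pd.DataFrame(rows), workdir / "calibration_report.tsv")
    _write(pd.DataFrame(knot_rows), workdir / "calibration_profiles.tsv")
    if cnv_cols:
        _write(pd.DataFrame(cnv_cols), workdir / "cnv_windows.tsv", index=True)


def load_calibrations(workdir: Path) -> dict[str, quantify.SampleCalibration]:
    report = pd.read_csv(workdir / "calibration_report.tsv", sep="\t")
    knots = pd.read_csv(workdir / "calibration_profiles.tsv", sep="\t")
    cnv_path = workdir / "cnv_windows.tsv"
    cnv = pd.read_csv(cnv_path, sep="\t", index_col=0) if cnv_path.exists() else None
    out = {}
    for _, row in report.iterrows():
        s = row["sample"]
        k = knots[knots["sample"] == s].sort_values("cpg")
        out[s] = quantify.SampleCalibration(
            library_factor=row["library_factor"],
            background_rate=row["background_rate"],
            profile=quantify.InterpolatedProfile(
                knot_cpg=k["cpg"].to_numpy(), knot_f=k["f"].to_numpy()
            ),
            cnv=cnv[s].to_numpy() if cnv is not None and s in cnv else None,
            dispersion=row["dispersion"],
        )
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, workdir: Path) -> dict:
    g = cfg["genome"]
    cpg_model = synthetic.CpgModel(**g.get("cpg_model", {}))
    grid = synthetic.generate_window_grid(
        g["chrom_lengths"], g.get("window_size", 250), cpg_model, seed=cfg.seed
    )
    tss = synthetic.tss_table(g["chrom_lengths"], cpg_model)

    m = cfg["methylome"]
    phen = synthetic.generate_phenotypes(m["n_models"], seed=cfg.seed)
    pdx = phen[phen["tissue"] == "pdx"]
    log_tc = {
        r["sample_id"]: float(np.log(max(r["relative_tumor_volume"], 0.1)))
        for _, r in pdx.iterrows()
    }
    design = synthetic.MethylomeDesign(
        normal_samples=list(phen[phen["tissue"] == "normal"]["sample_id"]),
        pdx_samples=list(pdx["sample_id"]),
        baseline_beta=m["baseline_beta"],
        island_beta=m["island_beta"],
        lhb_regions=[synthetic.PlantedBlock(**b) for b in m.get("lhb", [])],
        n_focal_hyper=m["n_focal_hyper"],
        focal_delta=m["focal_delta"],
        n_rdmr_genes=m["n_rdmr_genes"],
        coupling_slope=m["coupling_slope"],
        rdmr_b0=m["rdmr_b0"],
        log_tc=log_tc,
        noise_sd=m["noise_sd"],
    )
    truth = synthetic.generate_methylomes(grid, design, seed=cfg.seed, tss=tss)

    c = cfg["counts"]
    cals = synthetic.default_calibrations(
        truth.sample_ids,
        f_max=c["f_max"],
        k=c["k"],
        background_rate=c["background_rate"],
        dispersion=c["dispersion"],
        library_jitter=c["library_jitter"],
        seed=cfg.seed,
    )
    cals = synthetic.calibrations_for_depth(cals, truth.beta, grid, c["depth"])
    counts = synthetic.simulate_medip_counts(truth, cals, seed=cfg.seed)

    e = cfg["expression"]
    panel = synthetic.generate_expression(
        truth, phen, coupling=e["coupling"], noise_sd=e["noise_sd"], seed=cfg.seed
    )
    co = cfg["cohort"]
    cohort = synthetic.generate_validation_cohort(
        co["n_pairs"],
        group_means=tuple(co["group_means"]),
        group_sd=co["group_sd"],
        hazard_ratio=co["hazard_ratio"],
        censor_rate=co["censor_rate"],
        seed=cfg.seed,
    )

    # reference betas for calibration: normal-sample truth summary (stands in
    # for the external 450k reference panel)
    normals = truth.samples_in("normal")
    ref = pd.DataFrame(
        {
            "mean": truth.beta[normals].mean(axis=1),
            "variance": truth.beta[normals].var(axis=1, ddof=1),
        }
    )

    grid.to_frame().to_csv(workdir / "grid.bed", sep="\t", header=False, index=False)
    _write(tss, workdir / "tss.tsv")
    _write(phen, workdir / "phenotypes.tsv")
    _write(counts, workdir / "counts.tsv", index=True)
    _write(truth.beta, workdir / "truth_beta.tsv", index=True)
    _write(ref, workdir / "reference_betas.tsv", index=True)
    _write(cohort, workdir / "cohort.tsv")
    _write(panel.probes, workdir / "expression_probes.tsv", index=True)
    _write(panel.annotation, workdir / "probe_annotation.tsv")
    pw_rows = [
        {"gene": g_, "window_index": int(w)}
        for g_, widx in sorted(truth.promoter_windows.items())
        for w in widx
    ]
    _write(pd.DataFrame(pw_rows), workdir / "promoter_windows.tsv")
    meta = {
        "groups": truth.groups,
        "lhb_regions": [
            {"chrom": b.chrom, "start": b.start, "end": b.end, "delta": b.delta}
            for b in truth.lhb_regions
        ],
        "focal_windows": [int(w) for w in truth.focal_windows],
        "rdmr_windows": [int(w) for w in truth.rdmr_windows],
        "coupled_genes": list(truth.coupled_genes),
        "coupling_slope": truth.coupling_slope,
        "log_tc": truth.log_tc,
    }
    with open(workdir / "truth_meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    save_calibrations(cals, workdir)
    return {
        "windows": grid.n_windows,
        "samples": len(truth.sample_ids),
        "genes": len(truth.promoter_windows),
        "cohort_patients": len(cohort),
    }


def _load_grid(workdir: Path) -> WindowGrid:
    return WindowGrid.from_bed4(workdir / "grid.bed")


def _load_groups(workdir: Path) -> dict[str, str]:
    with open(workdir / "truth_meta.yaml") as fh:
        return yaml.safe_load(fh)["groups"]


def stage_quantify(workdir: Path, n_top_pca: int = 1000) -> dict:
    grid = _load_grid(workdir)
    counts = pd.read_csv(workdir / "counts.tsv", sep="\t", index_col=0)
    ref = pd.read_csv(workdir / "reference_betas.tsv", sep="\t", index_col=0)
    cnv = quantify.estimate_cnv(counts, grid)
    cals = quantify.calibrate_enrichment(counts, ref, grid, cnv=cnv)
    meth = quantify.estimate_methylation(counts, cals, grid)
    meth.to_tsv(workdir / "methylation.tsv")
    _write(cnv.bins, workdir / "cnv_bins.tsv")

    tss = pd.read_csv(workdir / "tss.tsv", sep="\t")
    promoters = annotation.build_promoters(tss)
    flags = annotation.annotate_windows(grid, [promoters])
    pca = quantify.pca_promoter_methylation(
        meth, flags["promoter"].to_numpy(), n_top=n_top_pca
    )
    coords = pca.coordinates.copy()
    coords["explained_pc1"] = pca.explained_variance[0]
    coords["explained_pc2"] = pca.explained_variance[1]
    _write(coords, workdir / "pca.tsv", index=True)
    return {"methylation_windows": int(meth.beta.notna().any(axis=1).sum())}


def stage_dmr(workdir: Path, fdr_max: float, min_delta: float) -> dict:
    grid = _load_grid(workdir)
    counts = pd.read_csv(workdir / "counts.tsv", sep="\t", index_col=0)
    cals = load_calibrations(workdir)
    groups = _load_groups(workdir)
    res = dmr.test_group_dmr(counts, cals, groups, grid, contrast=("pdx", "normal"))
    _write(res.records, workdir / "dmrs.tsv")
    _write(res.skipped, workdir / "dmr_skipped.tsv")
    kept = dmr.filter_dmrs(res.records, fdr_max, min_delta)
    _write(kept, workdir / "dmrs_filtered.tsv")
    return {
        "windows_tested": len(res.records),
        "dmrs_significant": len(kept),
        "dmrs_hyper": int((kept["direction"] == "hyper").sum()),
        "dmrs_hypo": int((kept["direction"] == "hypo").sum()),
    }


def stage_rdmr(workdir: Path) -> dict:
    grid = _load_grid(workdir)
    counts = pd.read_csv(workdir / "counts.tsv", sep="\t", index_col=0)
    cals = load_calibrations(workdir)
    phen = pd.read_csv(workdir / "phenotypes.tsv", sep="\t")
    pdx = phen[phen["tissue"] == "pdx"].set_index("sample_id")
    predictor = dmr.log_tc_predictor(pdx["relative_tumor_volume"])
    res = dmr.test_quantitative_rdmr(
        counts[list(predictor.index)], cals, predictor, grid
    )
    _write(res.records, workdir / "rdmrs.tsv")
    _write(res.skipped, workdir / "rdmr_skipped.tsv")
    return {"windows_tested": len(res.records)}


def stage_lhb(workdir: Path, tile_size: int, min_size: int, min_drop: float) -> dict:
    grid = _load_grid(workdir)
    beta = pd.read_csv(workdir / "methylation.tsv", sep="\t", index_col=0, na_values="NA")
    meth = quantify.MethylationMatrix(grid=grid, beta=beta)
    groups = _load_groups(workdir)
    lhbs = dmr.call_lhbs(
        meth, groups, tile_size=tile_size, min_size=min_size, min_drop=min_drop
    )
    _write(lhbs, workdir / "lhbs.tsv")
    lhbs[["chrom", "start", "end", "mean_delta"]].to_csv(
        workdir / "lhbs.bed", sep="\t", header=False, index=False
    )
    return {"lhbs": len(lhbs)}


def stage_enrich(workdir: Path) -> dict:
    grid = _load_grid(workdir)
    tss = pd.read_csv(workdir / "tss.tsv", sep="\t")
    promoters = annotation.build_promoters(tss)
    rois = [promoters]
    if grid.is_island is not None and grid.is_island.any():
        isl = grid.to_frame()[grid.is_island][["chrom", "start", "end"]]
        rois.append(annotation.RoiSet(name="CGI", intervals=isl))
    flags = annotation.annotate_windows(grid, rois)

    dmrs = pd.read_csv(workdir / "dmrs_filtered.tsv", sep="\t")
    keys = grid.window_keys()
    dmr_flags = pd.DataFrame(index=keys)
    for direction in ("hyper", "hypo"):
        sel = set(dmrs.loc[dmrs["direction"] == direction, "window"])
        dmr_flags[direction] = [k in sel for k in keys]
    enr = annotation.compute_enrichment(dmr_flags, flags)
    _write(enr, workdir / "enrichment.tsv")

    rdmrs = pd.read_csv(workdir / "rdmrs.tsv", sep="\t")
    cand = set(rdmrs.loc[rdmrs["p_value"] < 0.01, "window"])
    mask = np.array([k in cand for k in keys])
    dist = annotation.genomic_distribution(mask, flags)
    _write(
        pd.DataFrame([{"category": k, "fraction": v} for k, v in dist.items()]),
        workdir / "genomic_distribution.tsv",
    )
    return {"enrichment_rows": len(enr), "rdmr_candidates": int(mask.sum())}


def stage_triage(workdir: Path, rdmr_p: float, corr_p: float) -> dict:
    grid = _load_grid(workdir)
    beta = pd.read_csv(workdir / "methylation.tsv", sep="\t", index_col=0, na_values="NA")
    meth = quantify.MethylationMatrix(grid=grid, beta=beta)
    pw = pd.read_csv(workdir / "promoter_windows.tsv", sep="\t")
    gene_windows = {
        g: sub["window_index"].to_numpy() for g, sub in pw.groupby("gene", sort=False)
    }
    keys = grid.window_keys()
    window_gene = {}
    for g, widx in gene_windows.items():
        for w in widx:
            window_gene[keys[w]] = g
    rdmrs = pd.read_csv(workdir / "rdmrs.tsv", sep="\t")
    promoter_rdmrs = rdmrs[rdmrs["window"].isin(window_gene)].copy()
    promoter_rdmrs["gene"] = promoter_rdmrs["window"].map(window_gene)

    probes = pd.read_csv(workdir / "expression_probes.tsv", sep="\t", index_col=0)
    ann = pd.read_csv(workdir / "probe_annotation.tsv", sep="\t")
    expr = expression.collapse_probes(probes, ann)
    phen = pd.read_csv(workdir / "phenotypes.tsv", sep="\t")
    normals = list(phen[phen["tissue"] == "normal"]["sample_id"])
    ders = expression.compute_ders(expr, normals)
    pdx = phen[phen["tissue"] == "pdx"].set_index("sample_id")
    result = expression.triage_candidates(
        promoter_rdmrs,
        meth,
        gene_windows,
        ders,
        pdx["relative_tumor_volume"],
        rdmr_p_max=rdmr_p,
        meth_p_max=corr_p,
        expr_p_max=corr_p,
    )
    _write(result.candidates, workdir / "candidates.tsv")
    _write(
        pd.DataFrame(
            {
                "stage": ["promoter_rdmr", "meth_volume", "expr_opposite"],
                "n_genes": [
                    len(result.stage1_genes),
                    len(result.stage2_genes),
                    len(result.stage3_genes),
                ],
            }
        ),
        workdir / "triage_stages.tsv",
    )
    return {
        "stage1": len(result.stage1_genes),
        "stage2": len(result.stage2_genes),
        "stage3": len(result.stage3_genes),
    }


def stage_validate(workdir: Path) -> dict:
    cohort = pd.read_csv(workdir / "cohort.tsv", sep="\t")
    pct = validation.normalize_qmsp(
        cohort["qmsp_raw"].to_numpy(), cohort["control_level"].to_numpy()
    )
    responder = cohort["responder"].astype(bool).to_numpy()
    mw = validation.compare_groups(pct, ~responder)
    ev = validation.select_threshold(pct, ~responder)
    high = pct >= ev.threshold
    rows = [
        {"metric": "mannwhitney_u", "value": mw.u_statistic},
        {"metric": "mannwhitney_p", "value": mw.p_value},
        {"metric": "threshold", "value": ev.threshold},
        {"metric": "sensitivity_pct", "value": ev.sensitivity_pct},
        {"metric": "specificity_pct", "value": ev.specificity_pct},
        {"metric": "accuracy", "value": float(ev.accuracy)},
    ]
    report = {}
    for endpoint in ("os", "pfs"):
        t = cohort[f"{endpoint}_time"].to_numpy()
        e = cohort[f"{endpoint}_event"].to_numpy(dtype=bool)
        lr = validation.logrank(t[high], e[high], t[~high], e[~high])
        rows.append({"metric": f"logrank_chi2_{endpoint}", "value": lr.chi_square})
        rows.append({"metric": f"logrank_p_{endpoint}", "value": lr.p_value})
        for label, mask in (("high", high), ("low", ~high)):
            curve = validation.km_estimate(t[mask], e[mask])
            _write(
                pd.DataFrame(
                    {
                        "time": curve.times,
                        "survival": curve.survival,
                        "at_risk": curve.at_risk,
                    }
                ),
                workdir / f"km_{endpoint}_{label}.tsv",
            )
        report[endpoint] = lr.p_value
    _write(pd.DataFrame(rows), workdir / "validation_report.tsv")
    return {
        "threshold": ev.threshold,
        "sensitivity_pct": ev.sensitivity_pct,
        "specificity_pct": ev.specificity_pct,
        "mannwhitney_p": mw.p_value,
        **{f"logrank_p_{k}": v for k, v in report.items()},
    }


def run_pipeline(cfg: PipelineConfig, outdir) -> RunReport:
    """Run all stages in order inside ``outdir`` and write a run report."""
    workdir = Path(outdir)
    workdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg.seed, parameters=cfg.raw)
    with open(workdir / "config_used.yaml", "w") as fh:
        yaml.safe_dump(cfg.raw, fh, sort_keys=True)

    t = cfg["thresholds"]
    stages = [
        ("simulate", lambda: stage_simulate(cfg, workdir)),
        ("quantify", lambda: stage_quantify(workdir)),
        ("dmr", lambda: stage_dmr(workdir, t["dmr_fdr"], t["dmr_delta"])),
        ("rdmr", lambda: stage_rdmr(workdir)),
        (
            "lhb",
            lambda: stage_lhb(
                workdir, t["lhb_tile_size"], t["lhb_min_size"], t["lhb_min_drop"]
            ),
        ),
        ("enrich", lambda: stage_enrich(workdir)),
        ("triage", lambda: stage_triage(workdir, t["rdmr_p"], t["corr_p"])),
        ("validate", lambda: stage_validate(workdir)),
    ]
    for name, fn in stages:
        logger.info("stage %s starting", name)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                report.stage_counts[name] = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            for w in caught:
                report.warnings.append(f"{name}: {w.message}")
        logger.info("stage %s done: %s", name, report.stage_counts[name])
    report.outputs = {
        p.name: str(p) for p in sorted(workdir.iterdir()) if p.suffix in {".tsv", ".bed"}
    }
    report.to_json(workdir / "run_report.json")
    return report
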