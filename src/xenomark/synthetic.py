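"""Synthetic input generation for the full pipeline.

Emulates the statistical structure of a paired PDX/normal methylome study:
CpG-density-dependent enrichment counts with background and copy-number
variation, planted large hypomethylated blocks and focal promoter
hypermethylation, response-coupled promoter windows, anti-correlated gene
expression, treated-to-control tumor-volume phenotypes, and a matched
validation cohort with group-shifted methylation and censored survival.

All generators are deterministic given their parameters and seed; a master
seed is split into named substreams (:func:`substream`).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from xenomark.grid import WindowGrid
from xenomark.quantify import (
    InterpolatedProfile,
    SampleCalibration,
    SaturatingProfile,
    expected_counts,
)

__all__ = [
    "substream",
    "CpgModel",
    "generate_window_grid",
    "tss_table",
    "PlantedBlock",
    "MethylomeDesign",
    "MethylomeTruth",
    "generate_methylomes",
    "TumorGrowthRecord",
    "ResponseModel",
    "generate_phenotypes",
    "classify_response",
    "default_calibrations",
    "calibrations_for_depth",
    "simulate_medip_counts",
    "ExpressionPanel",
    "generate_expression",
    "generate_validation_cohort",
]

RESPONSE_BOUNDS = (9.0, 30.0, 78.0)  # strong | intermediate | weak | non_responder


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one master seed."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# window grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CpgModel:
    """Mixture model for per-window CpG counts.

    Background windows draw from Poisson(``background_mean``). Promoter loci
    are placed every ``promoter_spacing`` bases; each carries a CpG-island
    with probability ``island_rate``, in which case the windows within
    ``island_halfwidth`` windows of the TSS window draw from
    Poisson(``island_mean``) and are flagged as island.
    """

    background_mean: float = 2.0
    island_mean: float = 15.0
    island_rate: float = 1.0
    island_halfwidth: int = 1
    promoter_spacing: int = 20_000


def tss_table(chrom_lengths: dict[str, int], cpg_model: CpgModel) -> pd.DataFrame:
    """Deterministic per-gene TSS table implied by the promoter spacing."""
    rows = []
    for chrom, length in chrom_lengths.items():
        n_genes = int(length) // cpg_model.promoter_spacing
        for g in range(n_genes):
            rows.append(
                {
                    "gene": f"G_{chrom}_{g:04d}",
                    "chrom": chrom,
                    "pos": g * cpg_model.promoter_spacing + cpg_model.promoter_spacing // 2,
                    "strand": "+" if g % 2 == 0 else "-",
                }
            )
    return pd.DataFrame(rows)


def generate_window_grid(
    chrom_lengths: dict[str, int],
    window_size: int = 250,
    cpg_model: CpgModel | None = None,
    seed: int = 0,
) -> WindowGrid:
    """Complete fixed-width tiling of each chromosome with sampled CpG counts.

    Chromosome lengths that are not multiples of ``window_size`` are
    truncated: the trailing partial window is dropped.
    """
    if cpg_model is None:
        cpg_model = CpgModel()
    if window_size < 50:
        raise ValueError("window_size must be >= 50")
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom!r}")

    rng = substream(seed, "window_grid")
    chroms, starts, cpgs, islands = [], [], [], []
    for chrom, length in chrom_lengths.items():
        n = int(length) // window_size
        if n == 0:
            continue
        start = np.arange(n, dtype=np.int64) * window_size
        cpg = rng.poisson(cpg_model.background_mean, size=n)
        isl = np.zeros(n, dtype=bool)
        n_genes = int(length) // cpg_model.promoter_spacing
        for g in range(n_genes):
            tss = g * cpg_model.promoter_spacing + cpg_model.promoter_spacing // 2
            w = tss // window_size
            if w >= n:
                continue
            if rng.random() < cpg_model.island_rate:
                lo = max(0, w - cpg_model.island_halfwidth)
                hi = min(n, w + cpg_model.island_halfwidth + 1)
                cpg[lo:hi] = rng.poisson(cpg_model.island_mean, size=hi - lo)
                isl[lo:hi] = True
        chroms.append(np.full(n, chrom, dtype=object))
        starts.append(start)
        cpgs.append(cpg)
        islands.append(isl)

    chrom_arr = np.concatenate(chroms)
    start_arr = np.concatenate(starts)
    return WindowGrid(
        chrom=chrom_arr,
        start=start_arr,
        end=start_arr + window_size,
        cpg_count=np.concatenate(cpgs),
        is_island=np.concatenate(islands),
        window_size=window_size,
    )


# ---------------------------------------------------------------------------
# methylome truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedBlock:
    """A planted large hypomethylated block (chrom, 0-based half-open span)."""

    chrom: str
    start: int
    end: int
    delta: float

    def __post_init__(self) -> None:
        if self.end - self.start < 1_000_000:
            raise ValueError("planted LHB must span >= 1 Mb")


@dataclass
class MethylomeDesign:
    """Sample layout and planted effects for :func:`generate_methylomes`."""

    normal_samples: list[str]
    pdx_samples: list[str]
    baseline_beta: float = 0.8
    island_beta: float = 0.1
    baseline_sd: float = 0.1  # between-window variation shared across samples
    lhb_regions: list[PlantedBlock] = field(default_factory=list)
    n_focal_hyper: int = 0
    focal_delta: float = 0.6
    n_rdmr_genes: int = 0
    coupling_slope: float = 0.0
    rdmr_b0: float = 0.4
    log_tc: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if len(self.normal_samples) < 2 or len(self.pdx_samples) < 2:
            raise ValueError("design needs >= 2 normal and >= 2 PDX samples")


@dataclass
class MethylomeTruth:
    """Ground-truth methylomes with explicit planted-effect bookkeeping."""

    grid: WindowGrid
    beta: pd.DataFrame  # windows x samples, true methylation in [0, 1]
    groups: dict[str, str]  # sample -> 'normal' | 'pdx'
    lhb_regions: list[PlantedBlock]
    focal_windows: np.ndarray  # window indices with planted focal hypermethylation
    rdmr_windows: np.ndarray  # window indices coupled to log T/C
    coupled_genes: list[str]
    promoter_windows: dict[str, np.ndarray]  # gene -> window indices (TSS +/- 2 kb)
    coupling_slope: float
    log_tc: dict[str, float]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]


def _promoter_window_map(
    grid: WindowGrid, tss: pd.DataFrame, flank: int = 2000
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for chrom, sub in tss.groupby("chrom", sort=False):
        m = grid.chrom == chrom
        if not m.any():
            continue
        idx = np.flatnonzero(m)
        starts, ends = grid.start[m], grid.end[m]
        for _, row in sub.iterrows():
            lo, hi = row["pos"] - flank, row["pos"] + flank
            sel = (starts < hi) & (ends > lo)
            if sel.any():
                out[row["gene"]] = idx[sel]
    return out


def generate_methylomes(
    grid: WindowGrid,
    design: MethylomeDesign,
    seed: int = 0,
    tss: pd.DataFrame | None = None,
) -> MethylomeTruth:
    """Plant LHBs, focal promoter hypermethylation and response-coupled
    windows on top of a normal baseline methylome, then add clamped noise.

    Normals sit at ``baseline_beta`` outside islands and ``island_beta``
    inside; PDX samples inherit the baseline, receive the planted block
    deltas and focal promoter gains, and have their response-coupled windows
    set to ``clamp(rdmr_b0 + coupling_slope * log(T/C), 0, 1)``.
    """
    rng = substream(seed, "methylomes")
    n = grid.n_windows
    samples = list(design.normal_samples) + list(design.pdx_samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample names in design")

    base = np.where(
        grid.is_island if grid.is_island is not None else np.zeros(n, bool),
        design.island_beta,
        design.baseline_beta,
    ).astype(float)
    if design.baseline_sd > 0:
        # window-level variation shared across samples, so a subset of
        # windows sits near full methylation (calibration-eligible regions)
        base = np.clip(base + rng.normal(0.0, design.baseline_sd, size=n), 0.0, 1.0)

    # planted block window masks (validated against chromosome bounds)
    lhb_mask = np.zeros(n, dtype=bool)
    for blk in design.lhb_regions:
        m = grid.chrom == blk.chrom
        if not m.any():
            raise ValueError(f"planted block on unknown chromosome {blk.chrom!r}")
        chrom_end = int(grid.end[m].max())
        if blk.start < 0 or blk.end > chrom_end:
            raise ValueError(
                f"planted block {blk.chrom}:{blk.start}-{blk.end} exceeds "
                f"chromosome bounds [0, {chrom_end})"
            )
        lhb_mask |= m & (grid.start >= blk.start) & (grid.end <= blk.end)

    # promoter bookkeeping for focal and coupled plants
    promoter_windows: dict[str, np.ndarray] = {}
    island_genes: list[str] = []
    if tss is not None:
        promoter_windows = _promoter_window_map(grid, tss)
        if grid.is_island is not None:
            island_genes = [
                g
                for g, widx in promoter_windows.items()
                if grid.is_island[widx].any() and not lhb_mask[widx].any()
            ]

    need = design.n_focal_hyper + design.n_rdmr_genes
    if need > len(island_genes):
        raise ValueError(
            f"cannot plant {need} promoter effects: only {len(island_genes)} "
            "island promoters outside planted blocks available (pass a tss table "
            "and an island-bearing grid)"
        )
    chosen = rng.choice(len(island_genes), size=need, replace=False) if need else []
    focal_genes = [island_genes[i] for i in chosen[: design.n_focal_hyper]]
    coupled_genes = [island_genes[i] for i in chosen[design.n_focal_hyper :]]
    focal_windows = (
        np.unique(np.concatenate([promoter_windows[g] for g in focal_genes]))
        if focal_genes
        else np.array([], dtype=int)
    )
    rdmr_windows = (
        np.unique(np.concatenate([promoter_windows[g] for g in coupled_genes]))
        if coupled_genes
        else np.array([], dtype=int)
    )
    assert not np.intersect1d(focal_windows, rdmr_windows).size

    if design.n_rdmr_genes:
        missing = [s for s in design.pdx_samples if s not in design.log_tc]
        if missing:
            raise ValueError(f"log_tc missing for PDX samples: {missing}")

    beta = np.empty((n, len(samples)))
    groups: dict[str, str] = {}
    for j, s in enumerate(samples):
        is_pdx = s in design.pdx_samples
        groups[s] = "pdx" if is_pdx else "normal"
        b = base.copy()
        if is_pdx:
            for blk in design.lhb_regions:
                m = (
                    (grid.chrom == blk.chrom)
                    & (grid.start >= blk.start)
                    & (grid.end <= blk.end)
                )
                b[m] = b[m] + blk.delta
            if focal_windows.size:
                b[focal_windows] = b[focal_windows] + design.focal_delta
            if rdmr_windows.size:
                b[rdmr_windows] = design.rdmr_b0 + design.coupling_slope * design.log_tc[s]
        if design.noise_sd > 0:
            b = b + rng.normal(0.0, design.noise_sd, size=n)
        beta[:, j] = np.clip(b, 0.0, 1.0)

    return MethylomeTruth(
        grid=grid,
        beta=pd.DataFrame(beta, index=grid.window_keys(), columns=samples),
        groups=groups,
        lhb_regions=list(design.lhb_regions),
        focal_windows=focal_windows,
        rdmr_windows=rdmr_windows,
        coupled_genes=coupled_genes,
        promoter_windows=promoter_windows,
        coupling_slope=design.coupling_slope,
        log_tc=dict(design.log_tc),
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TumorGrowthRecord:
    """Caliper tumor measurement; volume = 1/2 * length * width**2 (mm^3)."""

    length: float
    width: float
    volume: float

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("length and width must be positive")
        expected = 0.5 * self.length * self.width**2
        if not np.isclose(self.volume, expected, rtol=1e-9):
            raise ValueError("volume inconsistent with 1/2 * length * width^2")

    @classmethod
    def from_dimensions(cls, length: float, width: float) -> "TumorGrowthRecord":
        return cls(length=length, width=width, volume=0.5 * length * width**2)


def classify_response(t_over_c: float) -> str:
    """Response category from relative tumor volume T/C (percent).

    Half-open bins: [0, 9) strong, [9, 30) intermediate, [30, 78) weak,
    [78, inf) non_responder.
    """
    t = float(t_over_c)
    if not t > 0:
        raise ValueError("T/C must be positive")
    lo, mid, hi = RESPONSE_BOUNDS
    if t < lo:
        return "strong"
    if t < mid:
        return "intermediate"
    if t < hi:
        return "weak"
    return "non_responder"


@dataclass(frozen=True)
class ResponseModel:
    """Distribution of simulated treated-to-control outcomes."""

    log_tc_mean: float = float(np.log(30.0))  # natural log of T/C percent
    log_tc_sd: float = 1.0
    control_length_mean: float = 12.0
    control_length_sd: float = 2.0
    width_ratio: float = 0.7


def generate_phenotypes(
    n_models: int,
    response_distribution: ResponseModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired normal/PDX phenotype table with simulated endpoint T/C values.

    Control and treated endpoint volumes both go through the caliper volume
    formula; T/C = 100 * treated volume / control volume, categorised by
    :func:`classify_response`.
    """
    if n_models < 2:
        raise ValueError("n_models must be >= 2")
    rm = response_distribution or ResponseModel()
    rng = substream(seed, "phenotypes")
    rows = []
    for m in range(n_models):
        pid = f"P{m:03d}"
        length = max(rng.normal(rm.control_length_mean, rm.control_length_sd), 2.0)
        width = length * rm.width_ratio
        control = TumorGrowthRecord.from_dimensions(length, width)
        tc_frac = np.exp(rng.normal(rm.log_tc_mean, rm.log_tc_sd)) / 100.0
        scale = tc_frac ** (1.0 / 3.0)  # isotropic shrinkage of treated tumor
        treated = TumorGrowthRecord.from_dimensions(length * scale, width * scale)
        t_over_c = 100.0 * treated.volume / control.volume
        rows.append(
            {
                "sample_id": f"N{m:03d}",
                "patient_id": pid,
                "tissue": "normal",
                "relative_tumor_volume": np.nan,
                "response_category": "",
            }
        )
        rows.append(
            {
                "sample_id": f"X{m:03d}",
                "patient_id": pid,
                "tissue": "pdx",
                "relative_tumor_volume": t_over_c,
                "response_category": classify_response(t_over_c),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# enrichment counts
# ---------------------------------------------------------------------------


def default_calibrations(
    sample_ids: list[str],
    f_max: float = 60.0,
    k: float = 2.0,
    background_rate: float = 1.0,
    dispersion: float = 50.0,
    library_jitter: float = 0.0,
    seed: int = 0,
) -> dict[str, SampleCalibration]:
    """Convenience set of per-sample calibrations sharing one profile family."""
    rng = substream(seed, "calibrations")
    out = {}
    for s in sample_ids:
        lf = float(np.exp(rng.normal(0.0, library_jitter))) if library_jitter else 1.0
        out[s] = SampleCalibration(
            library_factor=lf,
            background_rate=background_rate,
            profile=SaturatingProfile(f_max=f_max, k=k),
            dispersion=dispersion,
        )
    return out


def _scaled_profile(profile, scale: float):
    if isinstance(profile, SaturatingProfile):
        return SaturatingProfile(f_max=profile.f_max * scale, k=profile.k)
    if isinstance(profile, InterpolatedProfile):
        return InterpolatedProfile(
            knot_cpg=profile.knot_cpg, knot_f=profile.knot_f * scale
        )
    raise TypeError(f"cannot scale profile of type {type(profile)!r}")


def calibrations_for_depth(
    calibrations: dict[str, SampleCalibration],
    beta: pd.DataFrame,
    grid: WindowGrid,
    depth: float,
) -> dict[str, SampleCalibration]:
    """Rescale background and profile so the overall mean count equals ``depth``.

    One global factor is applied, preserving relative library sizes.
    """
    mu = expected_counts(beta, calibrations, grid)
    scale = depth / float(mu.to_numpy().mean())
    return {
        s: SampleCalibration(
            library_factor=cal.library_factor,
            background_rate=cal.background_rate * scale,
            profile=_scaled_profile(cal.profile, scale),
            cnv=cal.cnv,
            dispersion=cal.dispersion,
        )
        for s, cal in calibrations.items()
    }


def simulate_medip_counts(
    truth: MethylomeTruth,
    calibrations: dict[str, SampleCalibration],
    seed: int = 0,
    depth: float | None = None,
) -> pd.DataFrame:
    """Draw enrichment counts from the negative-binomial forward model.

    mu(i, w) = s_i * c_{i,w} * (o_i + beta_true(i, w) * f_i(cpg_w)); counts
    are NB with the calibration's dispersion (size) parameter, or Poisson when
    dispersion is infinite. When ``depth`` is given the calibrations are first
    rescaled with :func:`calibrations_for_depth` (callers needing the scaled
    calibrations for estimation should call that function themselves).
    """
    if depth is not None:
        calibrations = calibrations_for_depth(calibrations, truth.beta, truth.grid, depth)
    mu = expected_counts(truth.beta, calibrations, truth.grid)
    rng = substream(seed, "medip_counts")
    counts = np.empty(mu.shape, dtype=np.int64)
    for j, s in enumerate(mu.columns):
        m = mu[s].to_numpy()
        r = calibrations[s].dispersion
        if np.isinf(r):
            counts[:, j] = rng.poisson(m)
        else:
            p = r / (r + np.maximum(m, 1e-12))
            counts[:, j] = rng.negative_binomial(r, p)
    return pd.DataFrame(counts, index=mu.index, columns=mu.columns)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionPanel:
    """Probe-level expression with its probe -> gene annotation table."""

    probes: pd.DataFrame  # probe ids x samples, log2 scale
    annotation: pd.DataFrame  # probe, gene, quality


def generate_expression(
    truth: MethylomeTruth,
    phenotypes: pd.DataFrame | None = None,
    coupling: float = -2.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    baseline: float = 8.0,
    extra_probe_rate: float = 0.0,
) -> ExpressionPanel:
    """Log2 expression anti-correlated with promoter methylation for coupled
    genes; pure noise around a per-gene baseline otherwise.

    For a coupled gene g the expected value in sample s is
    ``baseline_g + coupling * mean(promoter beta of g in s)``.
    """
    rng = substream(seed, "expression")
    genes = sorted(truth.promoter_windows)
    for g in truth.coupled_genes:
        if g not in truth.promoter_windows:
            raise ValueError(f"coupled gene {g!r} has no promoter windows in truth")
    samples = truth.sample_ids
    beta = truth.beta.to_numpy()
    coupled = set(truth.coupled_genes)

    rows, ann = [], []
    index = []
    for g in genes:
        widx = truth.promoter_windows[g]
        prom_beta = beta[widx].mean(axis=0)
        g_base = baseline + rng.normal(0.0, 0.5)
        signal = g_base + (
            coupling * prom_beta if g in coupled else np.zeros(len(samples))
        )
        n_probes = 1 + int(rng.random() < extra_probe_rate)
        for p in range(n_probes):
            probe = f"{g}_p{p + 1}"
            noise = rng.normal(0.0, noise_sd, size=len(samples)) if noise_sd > 0 else 0.0
            rows.append(signal + noise)
            index.append(probe)
            quality = "perfect" if p == 0 else rng.choice(["good", "bad"])
            ann.append({"probe": probe, "gene": g, "quality": quality})
    probes = pd.DataFrame(np.asarray(rows), index=pd.Index(index, name="probe"),
                          columns=samples)
    return ExpressionPanel(probes=probes, annotation=pd.DataFrame(ann))


# ---------------------------------------------------------------------------
# validation cohort
# ---------------------------------------------------------------------------


def generate_validation_cohort(
    n_pairs: int,
    group_means: tuple[float, float] = (7.4, 13.9),
    group_sd: float = 3.0,
    hazard_ratio: float = 3.0,
    censor_rate: float = 0.2,
    seed: int = 0,
    control_level: float = 0.5,
    baseline_hazard: float = 0.15,
) -> pd.DataFrame:
    """Matched responder/non-responder pairs with qMSP signal and survival.

    ``group_means`` is (responder %, non-responder %). Survival times are
    exponential; the methylation-high (non-responder) group's hazard is
    scaled by ``hazard_ratio``. Censored subjects (probability
    ``censor_rate``, independent per endpoint) have their time replaced by a
    uniform draw on (0, t).
    """
    if n_pairs < 3:
        raise ValueError("n_pairs must be >= 3")
    for gm in group_means:
        if not 0.0 <= gm <= 100.0:
            raise ValueError("group means must be in [0, 100]")
    rng = substream(seed, "validation_cohort")
    resp_mean, nonresp_mean = group_means
    rows = []
    for i in range(n_pairs):
        for responder in (True, False):
            mean = resp_mean if responder else nonresp_mean
            pct = float(np.clip(rng.normal(mean, group_sd), 0.0, 100.0))
            hazard = baseline_hazard * (1.0 if responder else hazard_ratio)
            rec = {
                "patient_id": f"{'R' if responder else 'NR'}{i:03d}",
                "matched_pair_id": i,
                "responder": responder,
                "qmsp_raw": pct / 100.0 * control_level,
                "control_level": control_level,
                "qmsp_pct": pct,
            }
            for endpoint, rate in (("os", hazard), ("pfs", hazard * 1.5)):
                t = float(rng.exponential(1.0 / rate))
                event = True
                if censor_rate > 0 and rng.random() < censor_rate:
                    t = float(t * rng.uniform(0.05, 1.0))
                    event = False
                rec[f"{endpoint}_time"] = max(t, 1e-6)
                rec[f"{endpoint}_event"] = event
            rows.append(rec)
    return pd.DataFrame(rows)
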