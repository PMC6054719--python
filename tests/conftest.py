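import numpy as np
import pandas as pd
import pytest

from xenomark import synthetic as syn
from xenomark.grid import WindowGrid
from xenomark.quantify import SampleCalibration, SaturatingProfile


@pytest.fixture
def small_grid():
    """2,000-window single-chromosome grid with islands and CpG-free windows."""
    return syn.generate_window_grid({"chr1": 500_000}, 250, syn.CpgModel(), seed=1)


@pytest.fixture
def flat_grid():
    """Uniform CpG grid (no islands): every window has cpg_count = 4."""
    n = 400
    start = np.arange(n) * 250
    return WindowGrid(
        chrom=np.full(n, "chr1", dtype=object),
        start=start,
        end=start + 250,
        cpg_count=np.full(n, 4),
        window_size=250,
    )


def make_truth(grid, beta_by_sample, groups=None):
    """Assemble a MethylomeTruth directly from per-sample beta vectors."""
    samples = list(beta_by_sample)
    beta = pd.DataFrame(
        {s: np.asarray(b, dtype=float) for s, b in beta_by_sample.items()},
        index=grid.window_keys(),
    )
    return syn.MethylomeTruth(
        grid=grid,
        beta=beta,
        groups=groups or {s: "pdx" for s in samples},
        lhb_regions=[],
        focal_windows=np.array([], dtype=int),
        rdmr_windows=np.array([], dtype=int),
        coupled_genes=[],
        promoter_windows={},
        coupling_slope=0.0,
        log_tc={},
    )


def flat_calibration(f=20.0, o=2.0, s=1.0, dispersion=np.inf, cnv=None):
    """Calibration with an effectively constant profile (k tiny => f(cpg>=1) ~ f)."""
    return SampleCalibration(
        library_factor=s,
        background_rate=o,
        profile=SaturatingProfile(f_max=f, k=1e-9),
        cnv=cnv,
        dispersion=dispersion,
    )
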