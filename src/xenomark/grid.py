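"""Fixed-width genomic window grids.

All coordinates are 0-based, half-open. A grid is an ordered, disjoint tiling
of each chromosome into equal-width windows, each annotated with the number of
CpG dinucleotides it contains (and, optionally, a CpG-island flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["WindowGrid"]


@dataclass(frozen=True)
class WindowGrid:
    """Ordered, disjoint, fixed-width genomic windows with per-window CpG counts.

    Parameters
    ----------
    chrom
        Chromosome label per window.
    start, end
        Window bounds, 0-based half-open. ``end - start`` must equal
        ``window_size`` for every window.
    cpg_count
        Non-negative CpG count per window.
    is_island
        Optional CpG-island membership flag per window.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    cpg_count: np.ndarray
    is_island: np.ndarray | None = None
    window_size: int = field(default=250)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", np.asarray(self.chrom, dtype=object))
        object.__setattr__(self, "start", np.asarray(self.start, dtype=np.int64))
        object.__setattr__(self, "end", np.asarray(self.end, dtype=np.int64))
        object.__setattr__(self, "cpg_count", np.asarray(self.cpg_count, dtype=np.int64))
        if self.is_island is not None:
            object.__setattr__(self, "is_island", np.asarray(self.is_island, dtype=bool))
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.cpg_count) == n):
            raise ValueError("grid column lengths differ")
        if np.any(self.cpg_count < 0):
            raise ValueError("cpg_count must be non-negative")
        if np.any(self.end - self.start != self.window_size):
            raise ValueError("all windows must have width == window_size")
        # sorted by (chrom, start) and disjoint within chromosome
        for c in self.chromosomes:
            s = self.start[self.chrom == c]
            if np.any(np.diff(s) < self.window_size):
                raise ValueError(f"windows on {c} overlap or are unsorted")

    @property
    def n_windows(self) -> int:
        return len(self.start)

    def __len__(self) -> int:
        return self.n_windows

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chrom == chrom

    def window_keys(self) -> pd.Index:
        """``chrom:start-end`` string key per window (stable row identifier)."""
        return pd.Index(
            [f"{c}:{s}-{e}" for c, s, e in zip(self.chrom, self.start, self.end)],
            name="window",
        )

    def bin_ids(self, bin_size: int) -> np.ndarray:
        """Integer id of the ``bin_size`` bin containing each window.

        Ids are globally unique across chromosomes (consecutive within a
        chromosome, ordered by grid chromosome order).
        """
        ids = np.empty(self.n_windows, dtype=np.int64)
        offset = 0
        for c in self.chromosomes:
            m = self.chrom == c
            local = self.start[m] // bin_size
            ids[m] = local + offset
            offset += int(local.max()) + 1 if m.any() else 0
        return ids

    def to_frame(self) -> pd.DataFrame:
        d = {
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "cpg_count": self.cpg_count,
        }
        if self.is_island is not None:
            d["is_island"] = self.is_island.astype(int)
        return pd.DataFrame(d)

    # -- BED4 round trip ---------------------------------------------------

    def to_bed4(self, path) -> None:
        """Write the grid as BED4 (chrom, start, end, cpg_count), TSV."""
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed4(cls, path, window_size: int | None = None) -> "WindowGrid":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        names = ["chrom", "start", "end", "cpg_count", "is_island"]
        df.columns = names[: df.shape[1]]
        ws = window_size
        if ws is None:
            ws = int((df["end"] - df["start"]).iloc[0])
        island = None
        if "is_island" in df.columns:
            island = df["is_island"].astype(int).to_numpy().astype(bool)
        return cls(
            chrom=df["chrom"].to_numpy(),
            start=df["start"].to_numpy(),
            end=df["end"].to_numpy(),
            cpg_count=df["cpg_count"].to_numpy(),
            is_island=island,
            window_size=ws,
        )
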