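"""The PmdSet container: the segmentation output shared across modules."""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConsistencyError

DOMAIN_COLUMNS = ["chrom", "start", "end", "score", "n_bins"]


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "score": pd.Series(dtype=float),
            "n_bins": pd.Series(dtype=np.int64),
        }
    )


@dataclass
class PmdSet:
    """A set of called domains: half-open, sorted, non-overlapping per chromosome.

    ``df`` has columns chrom, start, end, score (mean posterior of the PMD
    state over the run of bins) and n_bins (bins in the run before any
    boundary sharpening). ``bin_size`` records the bin width the segmentation
    used; ``sharpened``/``fdr_filtered`` record which post-processing steps
    have been applied.
    """

    df: pd.DataFrame = field(default_factory=_empty_frame)
    sample_id: str = ""
    bin_size: int | None = None
    sharpened: bool = False
    fdr_filtered: bool = False

    def __post_init__(self) -> None:
        if list(self.df.columns[:3]) != ["chrom", "start", "end"]:
            raise ConsistencyError("PmdSet frame must start with chrom, start, end")
        if "score" not in self.df.columns:
            self.df = self.df.assign(score=1.0)
        if "n_bins" not in self.df.columns:
            self.df = self.df.assign(n_bins=0)
        self.validate()

    def validate(self) -> None:
        for chrom, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(ends <= starts):
                raise ConsistencyError(f"{chrom}: empty or inverted interval")
            if np.any(np.diff(starts) < 0):
                raise ConsistencyError(f"{chrom}: intervals not sorted by start")
            if np.any(starts[1:] < ends[:-1]):
                raise ConsistencyError(f"{chrom}: overlapping intervals")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sizes(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def total_bp(self) -> int:
        return int(self.sizes.sum()) if len(self.df) else 0

    def chrom_intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.df[self.df["chrom"] == chrom]
        return sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)

    def with_df(self, df: pd.DataFrame, **flags) -> "PmdSet":
        new = replace(self, df=df.reset_index(drop=True))
        for k, v in flags.items():
            setattr(new, k, v)
        return new
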