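"""Bin-size selection and aggregation of per-CpG counts into HMM observations.

The unit of information is a read-level observation of one CpG: a bin
containing one CpG covered by 40 reads carries as much information as one
containing 40 CpGs covered once. A bin is "sufficient" when it holds at
least ``min_obs`` (default 40) such observations — 40 observations give an
80% exact binomial confidence interval of roughly 39–61% around an observed
level of 50%, wide enough to distinguish low, intermediate and high
methylation. The bin size used for segmentation is the smallest candidate
for which at least ``bin_fraction`` (default 80%) of eligible bins are
sufficient; eligible bins are those containing at least one CpG site, so
CpG-free stretches of the assembly do not dilute the criterion.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .errors import DataError
from .methylome_io import Methylome

logger = logging.getLogger(__name__)

DEFAULT_MIN_OBS = 40
DEFAULT_BIN_FRACTION = 0.80


@dataclass(frozen=True)
class Bin:
    """One fixed-width genomic bin with aggregated methylation counts."""

    chrom: str
    start: int
    end: int
    m: int       # methylated-read count
    n: int       # total-read count (the bin's observation count)
    n_cpgs: int  # CpG sites falling in the bin, covered or not


@dataclass
class BinnedChrom:
    """Contiguous bins tiling one chromosome; starts are implicit multiples
    of the bin size, the final bin is truncated at the chromosome end."""

    chrom: str
    chrom_len: int
    bin_size: int
    m: np.ndarray
    n: np.ndarray
    n_cpgs: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.n)

    def bin_at(self, index: int) -> Bin:
        start = index * self.bin_size
        end = min(start + self.bin_size, self.chrom_len)
        return Bin(self.chrom, start, end,
                   int(self.m[index]), int(self.n[index]), int(self.n_cpgs[index]))


@dataclass
class BinnedMethylome:
    """The HMM observation sequence: per-chromosome (m, n) over tiling bins."""

    bin_size: int
    chroms: dict[str, BinnedChrom]
    sufficiency_fraction: float

    @property
    def n_bins(self) -> int:
        return sum(c.n_bins for c in self.chroms.values())

    @property
    def total_m(self) -> int:
        return int(sum(c.m.sum() for c in self.chroms.values()))

    @property
    def total_n(self) -> int:
        return int(sum(c.n.sum() for c in self.chroms.values()))


def observation_count(bin: Bin) -> int:
    """Read-level observations in a bin: its total read count ``n``."""
    return bin.n


def bin_methylome(
    meth: Methylome, bin_size: int, min_obs: int = DEFAULT_MIN_OBS
) -> BinnedMethylome:
    """Aggregate per-CpG counts into non-overlapping ``bin_size``-bp bins.

    Counts are conserved: summed m and n over bins equal the methylome's
    summed methylated counts and coverages. Every chromosome in
    ``meth.chrom_sizes`` is tiled, including ones without sites.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    chroms: dict[str, BinnedChrom] = {}
    n_eligible = n_sufficient = 0
    for chrom, length in meth.chrom_sizes.items():
        nb = max(1, math.ceil(length / bin_size))
        if chrom in meth.sites:
            df = meth.sites[chrom]
            idx = df["pos"].to_numpy() // bin_size
            m = np.bincount(idx, weights=df["meth"].to_numpy(), minlength=nb).astype(np.int64)
            n = np.bincount(idx, weights=df["coverage"].to_numpy(), minlength=nb).astype(np.int64)
            ncp = np.bincount(idx, minlength=nb).astype(np.int64)
        else:
            m = np.zeros(nb, dtype=np.int64)
            n = np.zeros(nb, dtype=np.int64)
            ncp = np.zeros(nb, dtype=np.int64)
        chroms[chrom] = BinnedChrom(chrom, length, bin_size, m, n, ncp)
        eligible = ncp > 0
        n_eligible += int(eligible.sum())
        n_sufficient += int((n[eligible] >= min_obs).sum())
    frac = n_sufficient / n_eligible if n_eligible else 0.0
    return BinnedMethylome(bin_size, chroms, frac)


def select_bin_size(
    meth: Methylome,
    min_obs: int = DEFAULT_MIN_OBS,
    bin_fraction: float = DEFAULT_BIN_FRACTION,
    start: int = 1000,
    step: int = 1000,
    max_size: int = 100_000,
) -> int:
    """Smallest candidate bin size with >= ``bin_fraction`` of eligible bins
    holding >= ``min_obs`` observations.

    Candidates are ``start, start+step, ..., max_size``. If none qualifies
    the largest candidate is returned with a warning — segmentation then
    proceeds on whatever information exists.
    """
    if meth.total_coverage == 0:
        raise DataError("methylome has no covered sites; cannot choose a bin size")
    size = start
    while size <= max_size:
        binned = bin_methylome(meth, size, min_obs=min_obs)
        if binned.sufficiency_fraction >= bin_fraction:
            return size
        size += step
    logger.warning(
        "no bin size up to %d reached %.0f%% sufficient bins; using %d",
        max_size, 100 * bin_fraction, max_size,
    )
    return max_size


def min_obs_confidence_interval(
    n: int, m: int, level: float
) -> tuple[float, float]:
    """Exact (Clopper–Pearson) two-sided confidence interval for m/n.

    At n=40, m=20 the 80% interval spans roughly 0.39–0.61, the calibration
    behind the 40-observation sufficiency rule.
    """
    if n < 1:
        raise ValueError("confidence interval requires n >= 1")
    if not 0 <= m <= n:
        raise ValueError(f"m={m} outside [0, {n}]")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    ci = binomtest(m, n).proportion_ci(confidence_level=level, method="exact")
    return float(ci.low), float(ci.high)
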