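"""Sample-level decisions and comparisons over PMD segmentations.

Covers: the PMD-containing (PC) vs non-PC verdict from segmentation
summary statistics, basepair Jaccard comparison of two domain sets,
read-level downsampling of a methylome, the downsampling stability curve,
and multi-sample 50-kb conservation tracks.

A sample is called PC when the fraction of the genome segmented exceeds
5% — non-PC samples segment roughly the small fraction occupied by
hypomethylated regulatory features — and the mean segment size exceeds
50 kb, separating broad domains from kilobase-scale regulatory
hypomethylation. Both inequalities are strict.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import intervals
from .domains import PmdSet
from .errors import PmdscanError
from .methylome_io import Methylome

logger = logging.getLogger(__name__)

DEFAULT_FRAC_CUTOFF = 0.05
DEFAULT_SIZE_CUTOFF = 50_000


@dataclass
class SegmentationSummary:
    """The decision surface for one sample: fraction of the genome
    segmented, mean segment size, segment count and the PC verdict."""

    fraction_segmented: float
    mean_segment_size: float
    n_segments: int
    is_pc: bool
    sample_id: str = ""
    bin_size: int | None = None

    def as_row(self) -> dict:
        return {
            "sample": self.sample_id,
            "bin_size": self.bin_size,
            "fraction_segmented": self.fraction_segmented,
            "mean_size": self.mean_segment_size,
            "n_segments": self.n_segments,
            "verdict": "PC" if self.is_pc else "non-PC",
        }


def decide_pc(
    pmds: PmdSet,
    genome_size: int,
    frac_cutoff: float = DEFAULT_FRAC_CUTOFF,
    size_cutoff: int = DEFAULT_SIZE_CUTOFF,
) -> SegmentationSummary:
    """PC verdict: fraction segmented > ``frac_cutoff`` AND mean segment
    size > ``size_cutoff`` (both strict). The denominator is the total
    length of the chromosomes analysed."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    n = len(pmds)
    total = pmds.total_bp
    frac = total / genome_size
    mean_size = total / n if n else 0.0
    return SegmentationSummary(
        fraction_segmented=frac,
        mean_segment_size=mean_size,
        n_segments=n,
        is_pc=(frac > frac_cutoff and mean_size > size_cutoff),
        sample_id=pmds.sample_id,
        bin_size=pmds.bin_size,
    )


def _merged_by_chrom(pmds: PmdSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, sub in pmds.df.groupby("chrom", sort=False):
        out[chrom] = intervals.merge(sub["start"].to_numpy(), sub["end"].to_numpy())
    return out


def jaccard(a: PmdSet, b: PmdSet) -> float:
    """Basepair Jaccard index |A ∩ B| / |A ∪ B| of two domain sets.

    Defined as 0 (with a warning) when both sets are empty.
    """
    ma = _merged_by_chrom(a)
    mb = _merged_by_chrom(b)
    len_a = sum(intervals.total_length(*v) for v in ma.values())
    len_b = sum(intervals.total_length(*v) for v in mb.values())
    if len_a == 0 and len_b == 0:
        logger.warning("Jaccard of two empty domain sets defined as 0")
        return 0.0
    inter = 0
    for chrom in set(ma) & set(mb):
        inter += intervals.intersect_length(*ma[chrom], *mb[chrom])
    union = len_a + len_b - inter
    return inter / union


def downsample(meth: Methylome, retain: float, seed: int | None = None) -> Methylome:
    """Randomly thin read-level observations to a fraction ``retain``.

    Per site with coverage n and methylated count m, the retained coverage
    is Binomial(n, retain) and the retained methylated count follows the
    hypergeometric draw of that many reads from the m methylated / n - m
    unmethylated originals; levels are recomputed. Sites are kept even at
    zero retained coverage. Deterministic given ``seed``.
    """
    if not 0.0 <= retain <= 1.0:
        raise ValueError(f"retain must be in [0, 1], got {retain}")
    rng = np.random.default_rng(seed)
    new_sites = {}
    for chrom, df in meth.sites.items():
        cov = df["coverage"].to_numpy()
        m = df["meth"].to_numpy()
        if retain == 1.0:
            new_sites[chrom] = df.copy()
            continue
        k = rng.binomial(cov, retain)
        m_ret = np.zeros_like(k)
        draw = k > 0
        if draw.any():
            m_ret[draw] = rng.hypergeometric(m[draw], cov[draw] - m[draw], k[draw])
        level = np.where(k > 0, m_ret / np.maximum(k, 1), 0.0)
        new = df.copy()
        new["coverage"] = k
        new["meth"] = m_ret
        new["level"] = level
        new_sites[chrom] = new
    return Methylome(dict(meth.chrom_sizes), new_sites)


def stability_curve(
    meth: Methylome,
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    mode: str = "dynamic",
    seed: int | None = None,
    reference: PmdSet | None = None,
    **segment_kwargs,
) -> list[tuple[float, float]]:
    """Jaccard of downsampled segmentations against the full-coverage one.

    For each retention fraction the methylome is thinned, segmented
    end-to-end (bin size re-selected in ``dynamic`` mode, pinned to 1 kb in
    ``fixed-1kb`` mode) and compared to the full-coverage segmentation by
    basepair Jaccard. Per-fraction failures are recorded as NaN rather
    than aborting the sweep.
    """
    from .pipeline import segment_methylome  # local import to avoid a cycle

    if mode not in ("dynamic", "fixed-1kb"):
        raise ValueError(f"mode must be 'dynamic' or 'fixed-1kb', got {mode!r}")
    bin_size = None if mode == "dynamic" else 1000
    if reference is None:
        reference = segment_methylome(meth, bin_size=bin_size, seed=seed,
                                      **segment_kwargs).pmds
    out = []
    rng = np.random.default_rng(seed)
    for frac in fractions:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            thinned = downsample(meth, frac, seed=sub_seed)
            result = segment_methylome(thinned, bin_size=bin_size, seed=sub_seed,
                                       **segment_kwargs)
            out.append((float(frac), jaccard(result.pmds, reference)))
        except PmdscanError as exc:
            logger.warning("segmentation failed at retain=%.2f: %s", frac, exc)
            out.append((float(frac), float("nan")))
    return out


@dataclass
class ConservationTrack:
    """Per 50-kb window: in how many samples the window lies completely
    inside a PMD, plus each sample's mean methylation level there."""

    df: pd.DataFrame          # chrom, start, end, count
    levels: np.ndarray        # (n_windows, n_samples) mean methylation, NaN if no data
    sample_ids: list[str]

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.df.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.count}\n")


def conservation_track(
    pmd_sets: Sequence[PmdSet],
    meths: Sequence[Methylome],
    window: int = 50_000,
) -> ConservationTrack:
    """Count, per tiling window, the samples whose PMDs completely contain
    it; containment, not mere overlap, is required. Window mean methylation
    is the read-weighted mean level of each sample's sites in the window."""
    if len(pmd_sets) == 0 or len(pmd_sets) != len(meths):
        raise ValueError("need matching, non-empty lists of PmdSets and Methylomes")
    chrom_sizes = meths[0].chrom_sizes
    rows = []
    for chrom, length in chrom_sizes.items():
        for start in range(0, length, window):
            rows.append((chrom, start, min(start + window, length)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    counts = np.zeros(len(df), dtype=np.int64)
    levels = np.full((len(df), len(pmd_sets)), np.nan)
    for si, (pmds, meth) in enumerate(zip(pmd_sets, meths)):
        merged = _merged_by_chrom(pmds)
        for wi, row in enumerate(df.itertuples(index=False)):
            w_len = row.end - row.start
            if row.chrom in merged:
                covered = intervals.overlap_with(row.start, row.end, *merged[row.chrom])
                if covered == w_len:
                    counts[wi] += 1
            if row.chrom in meth.sites:
                sub = meth.sites[row.chrom]
                pos = sub["pos"].to_numpy()
                lo = np.searchsorted(pos, row.start)
                hi = np.searchsorted(pos, row.end)
                cov = sub["coverage"].to_numpy()[lo:hi]
                mm = sub["meth"].to_numpy()[lo:hi]
                if cov.sum() > 0:
                    levels[wi, si] = mm.sum() / cov.sum()
    df = df.assign(count=counts)
    return ConservationTrack(df, levels, [p.sample_id for p in pmd_sets])


def summaries_table(summaries: Iterable[SegmentationSummary]) -> pd.DataFrame:
    """Tab-delimited-ready table of per-sample decisions."""
    return pd.DataFrame([s.as_row() for s in summaries])
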