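"""Feature-level annotation of PMD calls.

Escapee genes are genes that evade the hypomethylation of their
neighbourhood: the gene body is less than 20% covered by a PMD while both
100-kb flanks are at least 80% covered. Observed/expected enrichment of
features against a region set uses midpoint membership and a two-tailed
exact binomial test, with Benjamini–Hochberg adjustment across feature
classes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, false_discovery_control

from . import intervals
from .domains import PmdSet
from .errors import DataError

FEATURE_COLUMNS = ["chrom", "start", "end", "name", "strand"]


def _empty_features() -> pd.DataFrame:
    return pd.DataFrame(columns=FEATURE_COLUMNS)


@dataclass
class FeatureSet:
    """Named half-open intervals (gene bodies, TSS points, windows...)."""

    df: pd.DataFrame = field(default_factory=_empty_features)

    def __post_init__(self) -> None:
        missing = [c for c in ("chrom", "start", "end") if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature frame missing columns: {missing}")
        if "name" not in self.df.columns:
            self.df = self.df.assign(
                name=[f"feature_{i+1}" for i in range(len(self.df))])
        if "strand" not in self.df.columns:
            self.df = self.df.assign(strand=".")
        if len(self.df) and np.any(self.df["end"].to_numpy() <= self.df["start"].to_numpy()):
            raise ValueError("features must satisfy end > start")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def names(self) -> list[str]:
        return self.df["name"].tolist()

    @classmethod
    def from_bed(cls, path: str | Path) -> "FeatureSet":
        from .methylome_io import read_bed_features

        return cls(read_bed_features(path))

    def to_bed(self, path: str | Path) -> None:
        cols = [c for c in ("chrom", "start", "end", "name", "count", "strand")
                if c in self.df.columns]
        self.df[cols].to_csv(path, sep="\t", header=False, index=False)


@dataclass
class EnrichmentResult:
    """Observed vs expected feature counts inside a region set."""

    feature_class: str
    observed: int
    expected: float
    ratio: float
    p_value: float
    q_value: float | None = None


def _region_arrays(regions) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    if isinstance(regions, PmdSet):
        df = regions.df
    elif isinstance(regions, FeatureSet):
        df = regions.df
    else:
        df = regions
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[chrom] = intervals.merge(np.sort(sub["start"].to_numpy()),
                                     sub["end"].to_numpy()[np.argsort(sub["start"].to_numpy())])
    return out


def _covered_fraction(chrom, start, end, merged) -> float:
    if end <= start:
        return 0.0
    if chrom not in merged:
        return 0.0
    return intervals.overlap_with(start, end, *merged[chrom]) / (end - start)


def find_escapees(
    genes: FeatureSet,
    pmds: PmdSet,
    flank: int = 100_000,
    body_max: float = 0.20,
    flank_min: float = 0.80,
    chrom_sizes: Mapping[str, int] | None = None,
) -> FeatureSet:
    """Genes with body PMD coverage < ``body_max`` and both ``flank``-bp
    flanks covered >= ``flank_min``.

    Genes whose flanks would run off a chromosome end are disqualified:
    a truncated flank makes the coverage criterion ill-defined. Coverage is
    computed against the merged PMD intervals, so splitting a PMD into
    abutting pieces does not change the result.
    """
    merged = _region_arrays(pmds)
    keep = []
    for row in genes.df.itertuples(index=False):
        left_lo = row.start - flank
        right_hi = row.end + flank
        if left_lo < 0:
            continue
        if chrom_sizes is not None and row.chrom in chrom_sizes \
                and right_hi > chrom_sizes[row.chrom]:
            continue
        body = _covered_fraction(row.chrom, row.start, row.end, merged)
        if body >= body_max:
            continue
        left = _covered_fraction(row.chrom, left_lo, row.start, merged)
        right = _covered_fraction(row.chrom, row.end, right_hi, merged)
        if left >= flank_min and right >= flank_min:
            keep.append(row)
    return FeatureSet(pd.DataFrame(keep, columns=genes.df.columns))


def recurrent_escapees(
    per_sample: Sequence[FeatureSet], min_samples: int = 2
) -> FeatureSet:
    """Features named in at least ``min_samples`` of the per-sample sets,
    annotated with their occurrence count."""
    if len(per_sample) == 0:
        raise ValueError("need at least one sample")
    counts: dict[str, int] = {}
    exemplar: dict[str, tuple] = {}
    for fs in per_sample:
        for row in fs.df.itertuples(index=False):
            counts[row.name] = counts.get(row.name, 0) + 1
            exemplar.setdefault(row.name, row)
    rows = []
    for name, c in counts.items():
        if c >= min_samples:
            row = exemplar[name]
            rows.append((row.chrom, row.start, row.end, name, row.strand, c))
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS[:4] + ["strand", "count"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return FeatureSet(df)


def obs_exp_enrichment(
    features: FeatureSet,
    regions,
    genome_size: int,
    feature_class: str = "features",
) -> EnrichmentResult:
    """Observed vs expected count of features inside a region set.

    A feature is inside when its midpoint is. The expected count under
    uniform placement is n * p0 with p0 the fraction of the genome covered
    by the regions; the p-value is the two-tailed exact binomial test of
    the observed count against Binomial(n, p0).
    """
    n = len(features)
    if n == 0:
        raise DataError("no features to test")
    merged = _region_arrays(regions)
    region_bp = sum(intervals.total_length(*v) for v in merged.values())
    if genome_size < region_bp:
        raise ValueError("genome_size smaller than total region length")
    observed = 0
    for chrom, sub in features.df.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2)
        observed += int(intervals.points_in(mids, *merged[chrom]).sum())
    p0 = region_bp / genome_size
    if p0 == 0.0:
        # degenerate: no region to fall into
        ratio = float("inf") if observed else float("nan")
        p = 1.0 if observed == 0 else 0.0
        return EnrichmentResult(feature_class, observed, 0.0, ratio, p)
    expected = n * p0
    p = binomtest(observed, n, p0, alternative="two-sided").pvalue
    return EnrichmentResult(feature_class, observed, expected, observed / expected, float(p))


def boundary_enrichment(
    points: FeatureSet,
    pmds: PmdSet,
    genome_size: int,
    half_window: int = 2500,
    feature_class: str = "boundary features",
) -> EnrichmentResult:
    """Enrichment of point features within +/- ``half_window`` bp of PMD
    boundaries (domain starts and ends), with overlapping windows merged."""
    rows = []
    for row in pmds.df.itertuples(index=False):
        for edge in (row.start, row.end):
            rows.append((row.chrom, max(0, edge - half_window), edge + half_window))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    windows = windows.sort_values(["chrom", "start"])
    return obs_exp_enrichment(points, windows, genome_size, feature_class=feature_class)


def adjust_bh(results: Sequence[EnrichmentResult]) -> list[EnrichmentResult]:
    """Benjamini–Hochberg adjustment across feature classes."""
    if not results:
        return []
    q = false_discovery_control([r.p_value for r in results], method="bh")
    return [replace(r, q_value=float(qi)) for r, qi in zip(results, q)]


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "class": r.feature_class,
                "observed": r.observed,
                "expected": r.expected,
                "ratio": r.ratio,
                "p": r.p_value,
                "q": r.q_value,
            }
            for r in results
        ]
    )
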