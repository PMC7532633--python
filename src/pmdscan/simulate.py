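"""Synthetic methylomes with planted PMD architecture.

The generator mirrors the segmentation model: a genome is partitioned
into highly methylated background and planted hypomethylated domains;
CpG positions follow geometric inter-site gaps; per-site coverage is
Poisson; methylated counts are beta-binomial under the site's true
state. Defaults describe a PMD-containing cancer-like methylome —
roughly a third of the genome in domains averaging 150 kb, PMD mean
methylation 0.45 against a 0.85 background, one CpG per ~100 bp and 30x
mean depth. The non-PC generator reuses the same machinery with small
(2 kb), rare (2% of the genome) hypomethylated features standing in for
CpG-island/promoter hypomethylation.

Output is deterministic per seed, including the written text files.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .domains import PmdSet
from .methylome_io import Methylome, make_methylome, write_chrom_sizes, write_methcounts

PMD_TRUE_STATE = 1
BACKGROUND_TRUE_STATE = 0


def _default_chroms() -> dict[str, int]:
    return {"chr1": 10_000_000}


@dataclass
class SimConfig:
    """Generative settings for one synthetic methylome."""

    chrom_sizes: dict[str, int] = field(default_factory=_default_chroms)
    pmd_fraction: float = 0.35          # target fraction of genome in domains
    domain_mean: int = 150_000          # mean planted-domain size (bp)
    domain_min: int = 20_000            # smallest planted domain (bp)
    pmd_level: float = 0.45             # mean methylation inside domains
    background_level: float = 0.85      # mean methylation outside
    pmd_precision: float = 10.0         # beta precision (alpha+beta) inside
    background_precision: float = 10.0  # and outside
    cpg_gap_mean: float = 100.0         # mean inter-CpG gap (bp)
    depth: float = 30.0                 # mean per-site coverage (Poisson)
    boundary_island_multiplier: float | None = None  # CpG-density boost at edges
    boundary_island_width: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.pmd_fraction <= 0.95:
            raise ValueError(f"infeasible target fraction {self.pmd_fraction}")
        for name in ("pmd_level", "background_level"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.cpg_gap_mean <= 0 or self.depth < 0:
            raise ValueError("rates must be positive")
        if self.domain_min < 1 or self.domain_mean < self.domain_min:
            raise ValueError("require 1 <= domain_min <= domain_mean")


@dataclass
class SyntheticTruth:
    """Planted domains, per-site true state, and the config that made them."""

    domains: pd.DataFrame                 # chrom, start, end
    site_states: dict[str, np.ndarray]    # 1 inside a planted domain
    config: SimConfig

    def as_pmdset(self, sample_id: str = "truth") -> PmdSet:
        df = self.domains.assign(score=1.0, n_bins=0)
        return PmdSet(df, sample_id=sample_id)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, row in enumerate(self.domains.itertuples(index=False), 1):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\ttrue_{i}\t1000\t.\n")


def _plant_domains(rng, length: int, fraction: float, mean: int, min_size: int):
    """Draw domain sizes until the target fraction is reached, then place
    them without overlap by splitting the leftover sequence into random
    gaps (Dirichlet stick-breaking)."""
    target = fraction * length
    sizes: list[int] = []
    while sum(sizes) < target:
        s = min_size + int(rng.exponential(max(mean - min_size, 1)))
        sizes.append(min(s, length // 2))
        if len(sizes) > length // min_size:
            break
    total = sum(sizes)
    if total > 0.97 * length:  # trim overshoot so gaps remain
        excess = total - int(0.95 * length)
        sizes[-1] = max(min_size, sizes[-1] - excess)
        total = sum(sizes)
    if not sizes:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    free = length - total
    gaps = rng.dirichlet(np.ones(len(sizes) + 1)) * free
    gaps = np.floor(gaps).astype(np.int64)
    starts = []
    cursor = 0
    for size, gap in zip(sizes, gaps[:-1]):
        cursor += int(gap)
        starts.append(cursor)
        cursor += size
    return np.asarray(starts, np.int64), np.asarray(starts, np.int64) + np.asarray(sizes, np.int64)


def _cpg_positions(rng, cfg: SimConfig, length: int, dom_s, dom_e) -> np.ndarray:
    gaps = rng.geometric(1.0 / cfg.cpg_gap_mean,
                         size=int(2.5 * length / cfg.cpg_gap_mean) + 10)
    pos = np.cumsum(gaps) - 1
    pos = pos[pos < length]
    if cfg.boundary_island_multiplier and len(dom_s):
        extra = []
        dense_gap = cfg.cpg_gap_mean / cfg.boundary_island_multiplier
        for edge in np.concatenate([dom_s, dom_e]):
            lo = max(0, edge - cfg.boundary_island_width // 2)
            hi = min(length, edge + cfg.boundary_island_width // 2)
            n_extra = rng.poisson((hi - lo) / dense_gap)
            extra.append(rng.integers(lo, hi, size=n_extra))
        pos = np.unique(np.concatenate([pos] + extra))
    return pos.astype(np.int64)


def simulate_methylome(cfg: SimConfig) -> tuple[Methylome, SyntheticTruth]:
    """Generate one synthetic methylome plus its planted truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    records = {}
    dom_rows = []
    site_states = {}
    for chrom, length in cfg.chrom_sizes.items():
        dom_s, dom_e = _plant_domains(
            rng, length, cfg.pmd_fraction, cfg.domain_mean, cfg.domain_min
        )
        for s, e in zip(dom_s, dom_e):
            dom_rows.append((chrom, int(s), int(e)))
        pos = _cpg_positions(rng, cfg, length, dom_s, dom_e)
        if len(dom_s):
            idx = np.searchsorted(dom_s, pos, side="right") - 1
            in_dom = (idx >= 0) & (pos < dom_e[np.clip(idx, 0, None)])
        else:
            in_dom = np.zeros(len(pos), dtype=bool)
        state = in_dom.astype(np.int8)
        coverage = rng.poisson(cfg.depth, size=len(pos))
        level_mean = np.where(in_dom, cfg.pmd_level, cfg.background_level)
        precision = np.where(in_dom, cfg.pmd_precision, cfg.background_precision)
        p_site = rng.beta(level_mean * precision, (1.0 - level_mean) * precision)
        meth = rng.binomial(coverage, p_site)
        level = np.where(coverage > 0, meth / np.maximum(coverage, 1), 0.0)
        records[chrom] = {"pos": pos, "level": level, "coverage": coverage}
        site_states[chrom] = state
    meth_obj = make_methylome(cfg.chrom_sizes, records)
    truth = SyntheticTruth(
        pd.DataFrame(dom_rows, columns=["chrom", "start", "end"]),
        site_states,
        cfg,
    )
    return meth_obj, truth


def simulate_nonpc(
    cfg: SimConfig | None = None,
    feature_size: int = 2000,
    feature_fraction: float = 0.02,
) -> tuple[Methylome, SyntheticTruth]:
    """A non-PC methylome: fully methylated background broken only by
    small, rare hypomethylated regulatory-like features."""
    cfg = cfg or SimConfig()
    cfg = replace(
        cfg,
        pmd_fraction=feature_fraction,
        domain_mean=feature_size,
        domain_min=max(200, feature_size // 2),
    )
    return simulate_methylome(cfg)


def simulate_binned_sequence(
    n_bins: int,
    n_per_bin: int,
    means: tuple[float, float],
    precisions: tuple[float, float],
    diag: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directly simulate an HMM observation sequence (m, n, true state).

    State 0 carries the first (lower) mean. Used for parameter-recovery
    checks where the binning stage is not under test.
    """
    rng = np.random.default_rng(seed)
    states = np.empty(n_bins, dtype=np.int8)
    states[0] = rng.integers(0, 2)
    stay = rng.random(n_bins) < diag
    for t in range(1, n_bins):
        states[t] = states[t - 1] if stay[t] else 1 - states[t - 1]
    mu = np.asarray(means)[states]
    s = np.asarray(precisions)[states]
    p = rng.beta(mu * s, (1 - mu) * s)
    n = np.full(n_bins, n_per_bin, dtype=np.int64)
    m = rng.binomial(n, p)
    return m, n, states


def write_simulated(
    meth: Methylome, truth: SyntheticTruth, prefix: str | Path
) -> dict[str, Path]:
    """Write methcounts + chrom.sizes + truth BED under a common prefix."""
    prefix = Path(prefix)
    paths = {
        "methcounts": prefix.with_suffix(".methcounts"),
        "chrom_sizes": prefix.with_suffix(".chrom.sizes"),
        "truth": prefix.with_suffix(".truth.bed"),
    }
    write_methcounts(meth, paths["methcounts"])
    write_chrom_sizes(meth.chrom_sizes, paths["chrom_sizes"])
    truth.to_bed(paths["truth"])
    return paths
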