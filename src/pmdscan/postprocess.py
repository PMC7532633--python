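"""Boundary sharpening and shuffle-based false-discovery filtering.

Posterior decoding places domain edges at bin boundaries. Sharpening
refines each edge to a single inter-CpG breakpoint by a likelihood scan:
within a window spanning one bin on either side of the edge, every
breakpoint between consecutive covered CpGs is scored as the summed
beta-binomial log-likelihood of the outside-side sites under the
background emission parameters plus the inside-side sites under the PMD
parameters, and the maximising breakpoint becomes the new edge. Edges
therefore never move more than one bin-width, and neighbouring domains
never come to overlap.

Small spurious domains are removed by an empirical false-discovery step:
the per-bin (m, n) observations are permuted genome-wide (coordinates
fixed), the shuffled sequence is decoded with the already-trained
parameters, and the resulting segment sizes form the null. Each observed
domain gets an empirical p-value for its size against that null, and
domains failing a Benjamini–Hochberg cutoff are dropped.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .binning import BinnedChrom, BinnedMethylome
from .domains import PmdSet
from .errors import ConsistencyError
from .methylome_io import Methylome
from .segmentation import (
    BACKGROUND_STATE,
    PMD_STATE,
    HmmParams,
    betabinom_logpmf,
    call_domains,
    posterior_decode,
)

logger = logging.getLogger(__name__)


@dataclass
class NullSizeDistribution:
    """Segment sizes obtained from decoding shuffled observations."""

    sizes: np.ndarray
    n_shuffles: int
    seed: int | None = None

    @property
    def empty(self) -> bool:
        return self.sizes.size == 0


def _site_logliks(df: pd.DataFrame, params: HmmParams):
    """Per covered site, log-likelihood under PMD and background emissions."""
    covered = df["coverage"].to_numpy() > 0
    pos = df["pos"].to_numpy()[covered]
    m = df["meth"].to_numpy()[covered]
    n = df["coverage"].to_numpy()[covered]
    ll_pmd = betabinom_logpmf(m, n, params.emis[PMD_STATE])
    ll_bg = betabinom_logpmf(m, n, params.emis[BACKGROUND_STATE])
    return pos, np.asarray(ll_pmd, dtype=float), np.asarray(ll_bg, dtype=float)


def _scan_edge(pos, ll_pmd, ll_bg, lo, hi, pmd_side: str):
    """Best breakpoint in window [lo, hi); sites on the PMD side score under
    PMD emissions, the rest under background. Returns the new edge
    coordinate, or None when the window holds no covered sites.

    ``pmd_side`` is "right" for a domain start and "left" for a domain end.
    The returned edge is placed at the first CpG on the PMD side (for an
    end edge: one past the last PMD-side CpG, keeping intervals half-open);
    when the scan assigns every site to the background the edge moves to
    the inner window limit, shrinking the domain.
    """
    i0 = int(np.searchsorted(pos, lo, side="left"))
    i1 = int(np.searchsorted(pos, hi, side="left"))
    if i1 <= i0:
        return None
    p = ll_pmd[i0:i1]
    b = ll_bg[i0:i1]
    k = i1 - i0
    # prefix[j] = sum of first j sites
    pref_p = np.concatenate([[0.0], np.cumsum(p)])
    pref_b = np.concatenate([[0.0], np.cumsum(b)])
    if pmd_side == "right":
        # breakpoint j: sites [0, j) outside (background), [j, k) inside (PMD)
        scores = pref_b[: k + 1] + (pref_p[k] - pref_p[: k + 1])
        j = int(np.argmax(scores))
        if j == k:  # everything background: shrink to inner limit
            return hi
        return int(pos[i0 + j])
    else:
        # breakpoint j: sites [0, j) inside (PMD), [j, k) outside (background)
        scores = pref_p[: k + 1] + (pref_b[k] - pref_b[: k + 1])
        j = int(np.argmax(scores))
        if j == 0:  # everything background: shrink to inner limit
            return lo
        return int(pos[i0 + j - 1]) + 1


def sharpen_boundaries(
    pmds: PmdSet, meth: Methylome, params: HmmParams, window_bins: int = 1
) -> PmdSet:
    """Refine every domain edge to single-basepair resolution.

    Each edge is re-placed by the breakpoint-likelihood scan described in
    the module docstring, scanning ``window_bins`` bin-widths to either
    side (one by default). Domains with no covered CpGs near an edge keep
    that edge at its bin boundary.
    """
    if pmds.bin_size is None:
        raise ConsistencyError("PmdSet carries no bin size; cannot sharpen")
    w = int(window_bins) * pmds.bin_size
    new_rows = []
    for chrom, sub in pmds.df.groupby("chrom", sort=False):
        if chrom not in meth.sites:
            new_rows.extend(sub.itertuples(index=False))
            continue
        pos, ll_pmd, ll_bg = _site_logliks(meth.sites[chrom], params)
        chrom_len = meth.chrom_sizes[chrom]
        starts = sub["start"].tolist()
        ends = sub["end"].tolist()
        scores = sub["score"].tolist()
        nbins = sub["n_bins"].tolist()
        prev_end = 0
        for i in range(len(starts)):
            s, e = int(starts[i]), int(ends[i])
            next_start = int(starts[i + 1]) if i + 1 < len(starts) else chrom_len
            mid = (s + e) // 2
            # start edge: window one bin out / one bin in, clamped so the
            # domain cannot invert or reach into its neighbours
            lo = max(s - w, prev_end, 0)
            hi = min(s + w, mid)
            new_s = _scan_edge(pos, ll_pmd, ll_bg, lo, hi, "right")
            if new_s is None:
                logger.warning("%s:%d start edge window has no covered CpGs", chrom, s)
                new_s = s
            # end edge
            lo_e = max(e - w, new_s + 1, mid)
            hi_e = min(e + w, next_start, chrom_len)
            new_e = _scan_edge(pos, ll_pmd, ll_bg, lo_e, hi_e, "left")
            if new_e is None:
                logger.warning("%s:%d end edge window has no covered CpGs", chrom, e)
                new_e = e
            new_s = max(min(new_s, e - 1), prev_end)
            new_e = max(new_e, new_s + 1)
            new_rows.append((chrom, new_s, new_e, scores[i], nbins[i]))
            prev_end = new_e
    df = pd.DataFrame(new_rows, columns=["chrom", "start", "end", "score", "n_bins"])
    return pmds.with_df(df, sharpened=True)


def build_null(
    binned: BinnedMethylome,
    params: HmmParams,
    n_shuffles: int = 1,
    seed: int | None = None,
    cutoff: float = 0.5,
    min_segments: int = 5000,
    max_shuffles: int = 256,
) -> NullSizeDistribution:
    """Decode shuffled copies of the observation sequence and pool the
    resulting segment sizes.

    The (m, n) pairs are permuted uniformly at random across all bins
    genome-wide, destroying spatial structure while preserving the marginal
    observation distribution; the already-trained parameters are reused
    without retraining. At least ``n_shuffles`` permutation passes are run;
    passes continue (up to ``max_shuffles``) until the null holds
    ``min_segments`` segments, because the empirical p-value floor is
    1/(1 + #null segments) — a null too small to resolve p-values below
    the FDR cutoff would veto every domain regardless of size. On genomes
    that bin into many thousands of bins a single pass suffices.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_names = list(binned.chroms)
    m_all = np.concatenate([binned.chroms[c].m for c in chrom_names])
    n_all = np.concatenate([binned.chroms[c].n for c in chrom_names])
    lengths = [binned.chroms[c].n_bins for c in chrom_names]
    offsets = np.cumsum([0] + lengths)
    sizes: list[int] = []
    n_done = 0
    while n_done < n_shuffles or (len(sizes) < min_segments and n_done < max_shuffles):
        n_done += 1
        perm = rng.permutation(len(m_all))
        chroms = {}
        for ci, c in enumerate(chrom_names):
            sl = perm[offsets[ci]: offsets[ci + 1]]
            src = binned.chroms[c]
            chroms[c] = BinnedChrom(c, src.chrom_len, src.bin_size,
                                    m_all[sl], n_all[sl], src.n_cpgs)
        shuffled = BinnedMethylome(binned.bin_size, chroms, binned.sufficiency_fraction)
        track = posterior_decode(shuffled, params)
        null_pmds = call_domains(track, shuffled, cutoff=cutoff)
        sizes.extend(null_pmds.sizes.tolist())
    if not sizes:
        logger.warning("shuffled decode produced no segments; null is empty")
    return NullSizeDistribution(np.asarray(sizes, dtype=np.int64), n_done, seed)


def fdr_filter(
    pmds: PmdSet, null: NullSizeDistribution, q_cutoff: float = 0.01
) -> PmdSet:
    """Remove domains whose size is unexceptional against the shuffle null.

    Each domain's empirical p-value is (1 + #null sizes >= domain size) /
    (1 + #null sizes); Benjamini–Hochberg adjusts across domains and
    domains with q above ``q_cutoff`` are dropped. An empty null retains
    everything with a warning.
    """
    if len(pmds) == 0:
        return pmds.with_df(pmds.df, fdr_filtered=True)
    if null.empty:
        logger.warning("empty null size distribution; retaining all domains")
        return pmds.with_df(pmds.df, fdr_filtered=True)
    sizes = pmds.sizes
    null_sorted = np.sort(null.sizes)
    n_null = len(null_sorted)
    n_ge = n_null - np.searchsorted(null_sorted, sizes, side="left")
    p = (1.0 + n_ge) / (1.0 + n_null)
    q = false_discovery_control(p, method="bh")
    keep = q <= q_cutoff
    return pmds.with_df(pmds.df[keep], fdr_filtered=True)
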