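"""End-to-end segmentation: bin-size selection through FDR filtering."""
from __future__ import annotations

import logging
from dataclasses import dataclass

from .binning import (
    DEFAULT_BIN_FRACTION,
    DEFAULT_MIN_OBS,
    BinnedMethylome,
    bin_methylome,
    select_bin_size,
)
from .decision_eval import (
    DEFAULT_FRAC_CUTOFF,
    DEFAULT_SIZE_CUTOFF,
    SegmentationSummary,
    decide_pc,
)
from .domains import PmdSet
from .methylome_io import Methylome
from .postprocess import NullSizeDistribution, build_null, fdr_filter, sharpen_boundaries
from .segmentation import HmmParams, PosteriorTrack, baum_welch, call_domains

logger = logging.getLogger(__name__)


@dataclass
class SegmentationResult:
    """Everything one segmentation run produces."""

    pmds: PmdSet
    params: HmmParams
    binned: BinnedMethylome
    track: PosteriorTrack
    null: NullSizeDistribution | None
    summary: SegmentationSummary


def segment_methylome(
    meth: Methylome,
    bin_size: int | None = None,
    min_obs: int = DEFAULT_MIN_OBS,
    bin_fraction: float = DEFAULT_BIN_FRACTION,
    posterior_cutoff: float = 0.5,
    sharpen: bool = True,
    fdr: float | None = 0.01,
    n_shuffles: int = 1,
    frac_cutoff: float = DEFAULT_FRAC_CUTOFF,
    size_cutoff: int = DEFAULT_SIZE_CUTOFF,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int | None = None,
    sample_id: str = "",
) -> SegmentationResult:
    """Run the full caller on one methylome.

    ``bin_size=None`` selects the bin size by the 40-observations rule;
    pass a value to pin it (e.g. 1000 for the fixed-bin comparison).
    ``fdr=None`` skips the shuffle-based size filter; ``sharpen=False``
    leaves edges at bin boundaries. The seed governs the shuffle only —
    training is deterministic.
    """
    if bin_size is None:
        bin_size = select_bin_size(meth, min_obs=min_obs, bin_fraction=bin_fraction)
        logger.info("selected bin size %d bp", bin_size)
    binned = bin_methylome(meth, bin_size, min_obs=min_obs)
    params, track = baum_welch(binned, max_iter=max_iter, tol=tol, seed=seed)
    logger.info(
        "Baum-Welch: %d iterations, log-likelihood %.2f, converged=%s",
        track.n_iter, track.log_likelihood, track.converged,
    )
    pmds = call_domains(track, binned, cutoff=posterior_cutoff, sample_id=sample_id)
    if sharpen:
        pmds = sharpen_boundaries(pmds, meth, params)
    null = None
    if fdr is not None:
        null = build_null(binned, params, n_shuffles=n_shuffles, seed=seed,
                          cutoff=posterior_cutoff)
        pmds = fdr_filter(pmds, null, q_cutoff=fdr)
    summary = decide_pc(pmds, meth.genome_size,
                        frac_cutoff=frac_cutoff, size_cutoff=size_cutoff)
    logger.info(
        "%d domains, fraction segmented %.4f, mean size %.0f bp, verdict %s",
        summary.n_segments, summary.fraction_segmented,
        summary.mean_segment_size, "PC" if summary.is_pc else "non-PC",
    )
    return SegmentationResult(pmds, params, binned, track, null, summary)
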