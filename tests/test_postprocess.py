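import numpy as np
import pandas as pd
import pytest

from pmdscan import (
    BetaBinomParams,
    HmmParams,
    NullSizeDistribution,
    PmdSet,
    betabinom_logpmf,
    build_null,
    default_init,
    fdr_filter,
    make_methylome,
    sharpen_boundaries,
)
from pmdscan.binning import bin_methylome
from tests.test_segmentation import make_binned


def _pmds(rows, bin_size=1000):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "n_bins"])
    return PmdSet(df, bin_size=bin_size)


def _step_methylome(break_pos=1000, lo_level=0.45, hi_level=0.85, spacing=100,
                    length=4000, coverage=20):
    """Background [0, break_pos), PMD [break_pos, length) at CpG resolution."""
    pos = np.arange(spacing // 2, length, spacing)
    level = np.where(pos < break_pos, hi_level, lo_level)
    return make_methylome(
        {"chr1": length},
        {"chr1": {"pos": pos, "level": level,
                  "coverage": np.full(len(pos), coverage)}},
    )


PARAMS = default_init()


def brute_force_breakpoint(meth, lo, hi, pmd_side):
    """Independent oracle: score every inter-CpG breakpoint directly."""
    df = meth.sites["chr1"]
    sel = df[(df["pos"] >= lo) & (df["pos"] < hi) & (df["coverage"] > 0)]
    pos = sel["pos"].to_numpy()
    lp = np.array([betabinom_logpmf(int(m), int(n), PARAMS.emis[0])
                   for m, n in zip(sel["meth"], sel["coverage"])])
    lb = np.array([betabinom_logpmf(int(m), int(n), PARAMS.emis[1])
                   for m, n in zip(sel["meth"], sel["coverage"])])
    best, best_score = None, -np.inf
    for j in range(len(pos) + 1):
        if pmd_side == "right":
            score = lb[:j].sum() + lp[j:].sum()
        else:
            score = lp[:j].sum() + lb[j:].sum()
        if score > best_score:
            best, best_score = j, score
    return best, pos


class TestSharpenBoundaries:
    def test_clean_step_recovered_exactly(self):
        meth = _step_methylome(break_pos=1000)
        # domain called at bin resolution: [1000, 4000) with 1-kb bins
        pmds = _pmds([("chr1", 1000, 4000, 0.95, 3)])
        sharpened = sharpen_boundaries(pmds, meth, PARAMS)
        j, pos = brute_force_breakpoint(meth, 0, 2000, "right")
        assert sharpened.df["start"].iloc[0] == pos[j]
        # the breakpoint is the first PMD-level CpG at/after 1000
        assert sharpened.df["start"].iloc[0] == 1050

    def test_off_by_a_bin_edge_pulled_back(self):
        # true boundary at 1450, domain called one bin late
        meth = _step_methylome(break_pos=1450)
        pmds = _pmds([("chr1", 2000, 4000, 0.95, 2)])
        sharpened = sharpen_boundaries(pmds, meth, PARAMS)
        assert sharpened.df["start"].iloc[0] == 1450

    def test_window_without_cpgs_leaves_edge(self):
        meth = make_methylome(
            {"chr1": 4000},
            {"chr1": {"pos": np.array([3500]), "level": np.array([0.45]),
                      "coverage": np.array([20])}},
        )
        pmds = _pmds([("chr1", 1000, 3000, 0.9, 2)])
        sharpened = sharpen_boundaries(pmds, meth, PARAMS)
        assert sharpened.df["start"].iloc[0] == 1000

    def test_uniform_background_window_shrinks_domain(self):
        # every site near the start edge is at background level
        meth = _step_methylome(break_pos=3000)
        pmds = _pmds([("chr1", 1000, 4000, 0.9, 3)])
        sharpened = sharpen_boundaries(pmds, meth, PARAMS)
        assert sharpened.df["start"].iloc[0] > 1000

    def test_edges_move_at_most_one_bin(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(20_000, size=400, replace=False))
        meth = make_methylome(
            {"chr1": 20_000},
            {"chr1": {"pos": pos, "level": rng.uniform(0, 1, len(pos)),
                      "coverage": rng.poisson(10, len(pos))}},
        )
        pmds = _pmds([("chr1", 3000, 8000, 0.9, 5), ("chr1", 9000, 15000, 0.9, 6)])
        sharpened = sharpen_boundaries(pmds, meth, PARAMS)
        for before, after in zip(pmds.df.itertuples(), sharpened.df.itertuples()):
            assert abs(after.start - before.start) <= 1000
            assert abs(after.end - before.end) <= 1000
        sharpened.validate()  # no overlaps, no inversions


class TestBuildNull:
    def test_null_smaller_than_observed_on_structured_input(self, pc_sample):
        meth, truth = pc_sample
        binned = bin_methylome(meth, 1000)
        from pmdscan import baum_welch, call_domains
        params, track = baum_welch(binned)
        observed = call_domains(track, binned)
        null = build_null(binned, params, seed=1)
        assert np.median(null.sizes) < np.median(observed.sizes)

    def test_zero_shuffles_rejected(self, pc_sample):
        meth, _ = pc_sample
        binned = bin_methylome(meth, 1000)
        with pytest.raises(ValueError):
            build_null(binned, default_init(), n_shuffles=0)

    def test_exchangeable_input_null_matches_observed(self):
        m = np.full(300, 10)
        n = np.full(300, 40)
        binned = make_binned(m, n)
        from pmdscan import posterior_decode, call_domains
        track = posterior_decode(binned, PARAMS)
        observed = call_domains(track, binned)
        null = build_null(binned, PARAMS, seed=0, min_segments=1)
        # identical bins: shuffling is a no-op, the decode calls everything PMD
        assert observed.total_bp == 300_000
        assert set(null.sizes.tolist()) == {300_000}


class TestFdrFilter:
    def test_hand_computed_empirical_p_and_bh(self):
        null = NullSizeDistribution(np.full(1000, 1000), 1, 0)
        pmds = _pmds([("chr1", 0, 500_000, 0.9, 500),
                      ("chr2", 0, 2000, 0.9, 2)])
        out = fdr_filter(pmds, null, q_cutoff=0.01)
        # p = (1 + #null >= size)/(1 + N): 1/1001 for both domains
        # (every null segment is 1 kb, smaller than either domain), and
        # BH-adjusted q = 1/1001 < 0.01 -> both survive
        assert len(out) == 2
        assert out.fdr_filtered

    def test_small_domains_dominated_by_null_are_dropped(self):
        rng = np.random.default_rng(0)
        null = NullSizeDistribution(rng.integers(1000, 50_000, size=2000), 1, 0)
        pmds = _pmds([("chr1", 0, 500_000, 0.9, 500),
                      ("chr2", 0, 2000, 0.9, 2)])
        out = fdr_filter(pmds, null, q_cutoff=0.01)
        assert out.df["end"].tolist() == [500_000]

    def test_null_larger_than_everything_removes_all(self):
        null = NullSizeDistribution(np.full(500, 10_000_000), 1, 0)
        pmds = _pmds([("chr1", 0, 100_000, 0.9, 100)])
        assert len(fdr_filter(pmds, null)) == 0

    def test_empty_null_retains_all(self):
        null = NullSizeDistribution(np.array([], dtype=np.int64), 1, 0)
        pmds = _pmds([("chr1", 0, 100_000, 0.9, 100)])
        out = fdr_filter(pmds, null)
        assert len(out) == 1

    def test_output_is_subset_and_p_monotone(self):
        rng = np.random.default_rng(3)
        null = NullSizeDistribution(rng.integers(1, 100_000, 3000), 1, 0)
        rows = []
        start = 0
        for size in rng.integers(1000, 400_000, 30):
            rows.append(("chr1", start, start + int(size), 0.9, 1))
            start += int(size) + 1000
        pmds = _pmds(rows)
        out = fdr_filter(pmds, null, q_cutoff=0.05)
        merged = pd.merge(out.df, pmds.df, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()
        # survivors are exactly the domains above some size threshold
        if len(out) and len(out) < len(pmds):
            kept_min = (out.df["end"] - out.df["start"]).min()
            dropped = pmds.df[~pmds.df["start"].isin(out.df["start"])]
            assert (dropped["end"] - dropped["start"]).max() <= kept_min
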