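# Methods

This note records the model, the defaults and why they are what they are,
the numerical choices, and the limits of what the bundled simulator can
show. It is the companion to the code, not a results report: every number
quoted here is recomputed by the test suite or by `scripts/acceptance.py`.

## Observation model and binning

The caller never sees reads; its input is the methcounts-style per-CpG
table of (position, methylation level, coverage). The methylated read
count at a site is recovered once, at read time, as
`round(level × coverage)`, and is the single source of truth thereafter.
Positions are 0-based; every interval in the package, BED output
included, is half-open `[start, end)`. Zero-coverage sites are retained:
they contribute no observations but do mark their bin as CpG-containing.

Bins of width *w* tile each chromosome; a bin's observation count is its
total read count *n*, so one CpG covered 40× and forty CpGs covered 1×
are equally informative. The sample's bin width is the smallest candidate
in {1000, 2000, …, 100000} bp for which ≥ 80% of *eligible* bins hold
≥ 40 observations. Two choices here deserve comment:

* **Eligibility.** The denominator counts bins containing at least one
  CpG site, covered or not. Counting CpG-free bins (assembly gaps,
  CpG deserts) would let unassayable sequence dominate the criterion.
* **The 40-observation floor.** An exact (Clopper–Pearson) 80% binomial
  interval at n = 40, m = 20 spans 0.388–0.612 — wide, but sufficient to
  separate low / intermediate / high methylation, which is all the
  emission model needs. The exact interval is used rather than a normal
  approximation, which is too narrow at n = 40.

If no candidate reaches 80% sufficiency the largest candidate is used
with a warning rather than failing; callers can still inspect the
sufficiency fraction on the returned object.

## The two-state beta-binomial HMM

Emissions are beta-binomial: the methylation level within a state is not
a constant but a Beta-distributed quantity, which absorbs biological
variability (methylation inside PMDs rises toward their boundaries) and
technical overdispersion. State 0 is the PMD state and is constrained,
by relabeling after training, to carry the lower emission mean.

Training is plain Baum–Welch over per-chromosome sequences sharing one
parameter set. Initialisation: PMD mean 0.45, background mean 0.85, both
with precision α+β = 10; transition diagonal 0.99; π = (0.5, 0.5). These
start values reflect the canonical contrast between partially methylated
domains and a highly methylated soma, and make post-training relabeling
rare; training is deterministic given them (the `seed` argument exists
for interface symmetry and governs only the shuffle null downstream).

Numerical choices:

* **Empty bins stay in the chain** with log-emission 0 in both states.
  Dropping them would splice genomically distant bins together and
  distort domain lengths through the transition geometry; retaining them
  lets sticky transitions carry state across coverage gaps.
* **M-step for (α, β)**: responsibilities are collapsed onto unique
  (m, n) pairs, then a weighted maximum-likelihood fit runs L-BFGS-B in
  (logit mean, log precision) with analytic digamma gradients, started
  from a method-of-moments estimate and from the incumbent parameters.
  The precision is bounded to [0.02, 10⁴]: an unbounded precision
  collapses the beta-binomial to a binomial and destabilises training on
  near-pure segments. If the optimiser fails to improve the expected
  complete-data log-likelihood the incumbent parameters are kept, which
  preserves the EM monotonicity guarantee exactly (the suite checks a
  1e-8 relative slack over 50 random instances).
* **Degenerate fits** (fewer than two effective observations, or no
  spread in observed proportions) fall back to the smoothed moment mean
  (Σm + ½)/(Σn + 1) with the precision floored at the ceiling.
* **Convergence**: relative log-likelihood change < 1e-6 or 100
  iterations; hitting the cap returns `converged=False`, not an error.
* Forward–backward uses per-position scaling; the 2-state recursion is
  written with scalar arithmetic, which outruns small-array numpy by an
  order of magnitude and handles genome-scale bin counts in
  milliseconds. Posteriors are validated against exhaustive path
  enumeration on short sequences to 1e-9.

Segmentation is posterior decoding with a strict cutoff: a bin belongs
to a domain when P(PMD) > 0.5, so exact ties go to the background.
Viterbi is deliberately not used — per-bin posteriors are what the
downstream scoring and sharpening consume.

## Boundary sharpening

Decoding leaves edges at bin boundaries. For each edge, within a window
of one bin-width on either side (clamped so domains cannot invert or
collide), every breakpoint between consecutive covered CpGs is scored as

    Σ log BetaBin(site | background params)   over sites outside
  + Σ log BetaBin(site | PMD params)          over sites inside

and the maximising breakpoint becomes the edge, placed at the first CpG
on the PMD side (for an end edge, one past the last PMD-side CpG). If
the scan assigns every window site to the background, the edge moves to
the inner window limit and the domain shrinks; a window with no covered
CpGs leaves the edge untouched with a warning. Because the scan reuses
exactly the trained emission parameters, it is exhaustively testable:
the suite checks it against an independent brute-force breakpoint scorer
and asserts edges never move more than one bin-width and never create
overlaps. This heuristic is this package's own reconstruction of
likelihood-based edge refinement; the window width is configurable.

## Shuffle null and size FDR

The false-discovery step permutes the (m, n) pairs uniformly across all
bins genome-wide — coordinates fixed, marginal observation distribution
preserved, spatial structure destroyed — and decodes the shuffled
sequence with the already-trained parameters (no retraining, for
determinism). Observed domains receive the empirical p-value
(1 + #null ≥ size)/(1 + #null), Benjamini–Hochberg is applied across
domains, and q > 0.01 is removed. The FDR level is a package default,
exposed as `--fdr`.

One pass is enough when the genome yields thousands of bins, but the
empirical p-value floor is 1/(1 + N): with coarse bins a single pass can
produce so few null segments that even the largest true domain cannot
reach q ≤ 0.01 after the BH correction, vetoing everything. Permutation
passes therefore repeat until the null holds ≥ 5000 segments (capped at
256 passes); the floor then sits safely below cutoff/·n for realistic
domain counts. A null that remains empty (exchangeable input) retains
all domains with a warning.

A residual limitation: when the selected bin width approaches the domain
scale (very low coverage), shuffled runs of PMD-like bins are themselves
domain-sized and the size test loses power honestly — the null then
overlaps the observed size distribution.

## PC / non-PC decision

Fraction segmented > 5% **and** mean segment size > 50 kb, both strict;
the denominator is the total length of the chromosomes analysed, not
merely the covered basepairs. Empty segmentations are non-PC with
fraction and mean size 0.

## Annotation

Escapee genes: body < 20% covered by merged PMDs while each 100-kb flank
is ≥ 80% covered. Flanks truncated by a chromosome end disqualify the
gene — a partial flank makes the 80% criterion ill-defined. Recurrent
escapees are those named in ≥ 2 samples. Observed/expected enrichment
counts a feature as inside a region set when its midpoint is (avoiding
double counting of partial overlaps; an any-overlap variant would be a
one-line change), tests the count two-tailed against
Binomial(n, region bp / genome bp), and BH-adjusts across feature
classes. Boundary enrichment builds ±2.5-kb windows around every domain
edge, merges overlaps, and applies the same machinery.

## The simulator

`simulate_methylome` mirrors the segmentation model: domain sizes are
exponential above a floor (mean 150 kb, min 20 kb) drawn until a target
fraction (default 35%) of the genome is reached, placed without overlap
via Dirichlet-distributed gaps; CpG positions follow geometric gaps
(mean 100 bp, matching genome-wide CpG density of roughly one per
hundred basepairs); coverage is Poisson (default 30×); methylated counts
are beta-binomial with means 0.45 (PMD) / 0.85 (background) and
precision 10. `simulate_nonpc` reuses the machinery with 2-kb features
covering 2% of the genome — the size and extent of regulatory
hypomethylation rather than PMDs. Output is bit-identical per seed.

What the simulator does *not* emulate — and what passing tests therefore
cannot show about real data: CpG clustering into islands (gaps are
memoryless), boundary CpG-density islands (available but off by
default), within-domain methylation gradients toward boundaries,
copy-number and mapping artefacts, incomplete bisulfite conversion, and
non-CpG contexts. Because its emissions match the HMM's family exactly,
segmentation accuracy on simulated data is an upper bound on real-data
accuracy. One concrete consequence: with correctly specified emissions
and empty-bin retention, a pinned 1-kb bin width degrades far more
gracefully here than misspecified real data suggests, so at 1× coverage
the measured advantage of dynamic bin sizing over fixed 1-kb bins is
positive in the median across replicates but small — fractions of a
percent of Jaccard — rather than dramatic.

## Problem sizes

The test and acceptance runs use 10-Mb single-chromosome genomes (about
100k CpGs, 10k bins at 1 kb), 20 replicates for parameter recovery
(10,000 bins each), 40 samples for the classification sweep and 5
replicate genomes for the dynamic-vs-fixed comparison — sizes at which
every quantity of interest (Jaccard, recovery error, classification
accuracy) is stable while a full run stays around a minute.
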