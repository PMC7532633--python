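"""Two-state beta-binomial HMM over binned methylation counts.

State 0 is the PMD state (lower mean methylation), state 1 the highly
methylated background. Each bin emits its methylated-read count m out of
n total reads under a state-specific beta-binomial, which absorbs the
overdispersion of methylation levels within a state. Transition and
emission parameters are learned by Baum–Welch (EM with forward–backward
E-step and a weighted maximum-likelihood M-step for the beta-binomial
shapes); segmentation uses posterior decoding, assigning each bin the
state with higher forward–backward posterior rather than the single best
Viterbi path.

Chromosomes are treated as independent observation sequences sharing one
parameter set. Bins without observations (n = 0) stay in the chain with a
flat emission (log-probability 0 in both states) so that domain lengths
respect genomic distance across coverage gaps.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

from .binning import BinnedMethylome
from .domains import PmdSet
from .errors import ConsistencyError, DataError

PMD_STATE = 0
BACKGROUND_STATE = 1

# Dispersion bounds for the beta-binomial precision s = alpha + beta.
# The ceiling keeps the model from collapsing to a plain binomial (which
# destabilises training on near-pure bins); the floor keeps shapes proper.
MIN_SHAPE = 1e-2
MAX_PRECISION = 1e4
MIN_PRECISION = 2 * MIN_SHAPE


@dataclass(frozen=True)
class BetaBinomParams:
    """Beta-binomial shape parameters for one state's emissions."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"shapes must be positive, got ({self.alpha}, {self.beta})")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def precision(self) -> float:
        return self.alpha + self.beta


@dataclass
class HmmParams:
    """Initial probabilities, transition matrix and per-state emissions.

    Index 0 is the PMD state; after training, states are relabeled if
    necessary so that the PMD state has the lower emission mean.
    """

    pi: np.ndarray
    A: np.ndarray
    emis: tuple[BetaBinomParams, BetaBinomParams]

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.pi.shape != (2,) or not math.isclose(self.pi.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("pi must be a length-2 probability vector")
        if self.A.shape != (2, 2) or not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("A must be a 2x2 stochastic matrix")
        if np.any(self.pi < 0) or np.any(self.A < 0):
            raise ValueError("probabilities must be non-negative")

    @property
    def pmd_mean(self) -> float:
        return self.emis[PMD_STATE].mean

    @property
    def background_mean(self) -> float:
        return self.emis[BACKGROUND_STATE].mean

    def relabeled(self) -> "HmmParams":
        """Swap states if the PMD slot does not hold the lower-mean state."""
        if self.pmd_mean <= self.background_mean:
            return self
        perm = [1, 0]
        return HmmParams(self.pi[perm], self.A[np.ix_(perm, perm)],
                         (self.emis[1], self.emis[0]))

    def to_json(self, path: str | Path, bin_size: int | None = None,
                log_likelihood: float | None = None) -> None:
        payload = {
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "pmd": {"alpha": self.emis[0].alpha, "beta": self.emis[0].beta},
            "background": {"alpha": self.emis[1].alpha, "beta": self.emis[1].beta},
            "bin_size": bin_size,
            "log_likelihood": log_likelihood,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "HmmParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.asarray(payload["pi"]), np.asarray(payload["A"]),
            (BetaBinomParams(**payload["pmd"]), BetaBinomParams(**payload["background"])),
        )


def default_init() -> HmmParams:
    """Starting point for training: PMD mean 0.45, background mean 0.85,
    both at precision 10; sticky transitions (diagonal 0.99)."""
    return HmmParams(
        pi=np.array([0.5, 0.5]),
        A=np.array([[0.99, 0.01], [0.01, 0.99]]),
        emis=(BetaBinomParams(4.5, 5.5), BetaBinomParams(8.5, 1.5)),
    )


@dataclass
class PosteriorTrack:
    """Per-bin posterior probability of the PMD state, aligned to a
    BinnedMethylome, plus training diagnostics."""

    posterior: dict[str, np.ndarray]
    log_likelihood: float
    n_iter: int
    converged: bool
    bin_size: int | None = None
    ll_history: list[float] = field(default_factory=list)

    def aligned_with(self, binned: BinnedMethylome) -> bool:
        return set(self.posterior) == set(binned.chroms) and all(
            len(self.posterior[c]) == binned.chroms[c].n_bins for c in self.posterior
        )


def betabinom_logpmf(m, n, params: BetaBinomParams):
    """log P(m | n) under BetaBinomial(alpha, beta); 0 when n = 0.

    Accepts scalars or arrays. Closed form:
    log C(n, m) + log B(m + a, n - m + b) - log B(a, b).
    """
    m_arr = np.asarray(m)
    n_arr = np.asarray(n)
    if np.any(m_arr < 0) or np.any(n_arr < 0) or np.any(m_arr > n_arr):
        raise ValueError("require 0 <= m <= n")
    a, b = params.alpha, params.beta
    out = (
        gammaln(n_arr + 1) - gammaln(m_arr + 1) - gammaln(n_arr - m_arr + 1)
        + gammaln(m_arr + a) + gammaln(n_arr - m_arr + b) - gammaln(n_arr + a + b)
        + gammaln(a + b) - gammaln(a) - gammaln(b)
    )
    if np.isscalar(m) and np.isscalar(n):
        return float(out)
    return out


def _aggregate_observations(ms, ns, weights):
    """Collapse (m, n) pairs to unique pairs with summed weights.

    Binned counts repeat heavily (n is near-constant at uniform coverage),
    so the emission M-step works on the unique pairs only.
    """
    ms = np.asarray(ms, dtype=np.int64)
    ns = np.asarray(ns, dtype=np.int64)
    weights = np.asarray(weights, dtype=float)
    key = ms * (ns.max() + 1) + ns
    _, idx, inv = np.unique(key, return_index=True, return_inverse=True)
    w = np.bincount(inv, weights=weights)
    return ms[idx], ns[idx], w


def _weighted_nll_and_grad(theta, mu, nu, w):
    """Negative weighted log-likelihood in (logit mean, log precision)."""
    lmu, ls = theta
    mean = 1.0 / (1.0 + math.exp(-lmu))
    s = math.exp(ls)
    a = mean * s
    b = (1.0 - mean) * s
    ll_terms = (
        gammaln(mu + a) + gammaln(nu - mu + b) - gammaln(nu + s)
        + gammaln(s) - gammaln(a) - gammaln(b)
    )
    nll = -float(np.dot(w, ll_terms))
    da = float(np.dot(w, digamma(mu + a) - digamma(nu + s) + digamma(s) - digamma(a)))
    db = float(np.dot(w, digamma(nu - mu + b) - digamma(nu + s) + digamma(s) - digamma(b)))
    # chain rule: a = mean*s, b = (1-mean)*s with mean = sigmoid(lmu), s = e^ls
    dmean = (da - db) * s
    dlmu = dmean * mean * (1.0 - mean)
    dls = (da * a + db * b)
    return nll, np.array([-dlmu, -dls])


def _clip_params(mean: float, s: float) -> BetaBinomParams:
    s = float(np.clip(s, MIN_PRECISION, MAX_PRECISION))
    a = float(np.clip(mean * s, MIN_SHAPE, None))
    b = float(np.clip((1.0 - mean) * s, MIN_SHAPE, None))
    return BetaBinomParams(a, b)


def fit_betabinom(ms, ns, weights=None, init: BetaBinomParams | None = None) -> BetaBinomParams:
    """Weighted maximum-likelihood beta-binomial fit.

    Method-of-moments initialisation followed by quasi-Newton refinement in
    (logit mean, log precision); the precision is kept in
    [MIN_PRECISION, MAX_PRECISION]. With fewer than two effective
    observations, or with no spread in the observed proportions, falls back
    to a smoothed moment estimate with the dispersion floored at the
    precision ceiling.
    """
    ms = np.asarray(ms, dtype=np.int64)
    ns = np.asarray(ns, dtype=np.int64)
    if ms.shape != ns.shape:
        raise ValueError("ms and ns must have the same length")
    if np.any(ms < 0) or np.any(ms > ns):
        raise ValueError("require 0 <= m <= n")
    if weights is None:
        weights = np.ones(len(ms))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    mask = (ns > 0) & (weights > 0)
    if not mask.any():
        raise DataError("no informative observations (all n = 0 or weight 0)")
    mu, nu, w = _aggregate_observations(ms[mask], ns[mask], weights[mask])

    w_sum = float(w.sum())
    mean_mom = float(np.dot(w, mu) / np.dot(w, nu))
    # effective number of distinct observations
    n_eff = w_sum ** 2 / float(np.dot(w, w))
    props = mu / nu
    var_mom = float(np.dot(w, (props - mean_mom) ** 2) / w_sum)
    smoothed_mean = float((np.dot(w, mu) + 0.5) / (np.dot(w, nu) + 1.0))
    if n_eff < 2.0 or var_mom <= 1e-12 or not 0 < mean_mom < 1:
        return _clip_params(smoothed_mean, MAX_PRECISION)

    # moment estimate of the intra-class correlation rho = 1/(s+1)
    inv_n = float(np.dot(w, 1.0 / nu) / w_sum)
    denom = mean_mom * (1.0 - mean_mom)
    rho = (var_mom / denom - inv_n) / max(1.0 - inv_n, 1e-9)
    rho = float(np.clip(rho, 1e-6, 0.95))
    s0 = np.clip(1.0 / rho - 1.0, MIN_PRECISION, MAX_PRECISION)

    starts = [(mean_mom, s0)]
    if init is not None:
        starts.append((init.mean, np.clip(init.precision, MIN_PRECISION, MAX_PRECISION)))
    best = None
    bounds = [(-12.0, 12.0), (math.log(MIN_PRECISION), math.log(MAX_PRECISION))]
    for mean_i, s_i in starts:
        theta0 = np.array([math.log(mean_i / (1.0 - mean_i)), math.log(s_i)])
        res = minimize(
            _weighted_nll_and_grad, theta0, args=(mu, nu, w), jac=True,
            method="L-BFGS-B", bounds=bounds, options={"maxiter": 200},
        )
        f0 = _weighted_nll_and_grad(theta0, mu, nu, w)[0]
        cand_theta, cand_f = (res.x, res.fun) if res.fun <= f0 else (theta0, f0)
        if best is None or cand_f < best[1]:
            best = (cand_theta, cand_f)
    lmu, ls = best[0]
    mean = 1.0 / (1.0 + math.exp(-lmu))
    return _clip_params(mean, math.exp(ls))


def _forward_backward(logB: np.ndarray, pi: np.ndarray, A: np.ndarray):
    """Scaled forward–backward for a 2-state chain.

    Returns (gamma, xi_sum, log_likelihood) with gamma the per-bin state
    posteriors and xi_sum the expected transition counts summed over time.
    Implemented with scalar recursions (list-based) — dominated by Python
    overhead but fast enough for genome-scale bin counts.
    """
    T = logB.shape[0]
    row_max = np.max(logB, axis=1)
    b = np.exp(logB - row_max[:, None])
    b0 = b[:, 0].tolist()
    b1 = b[:, 1].tolist()
    a00, a01 = float(A[0, 0]), float(A[0, 1])
    a10, a11 = float(A[1, 0]), float(A[1, 1])

    f0 = [0.0] * T
    f1 = [0.0] * T
    c = [0.0] * T
    x0 = float(pi[0]) * b0[0]
    x1 = float(pi[1]) * b1[0]
    s = x0 + x1
    if s <= 0.0:
        raise DataError("zero likelihood at first bin")
    c[0] = s
    f0[0] = x0 / s
    f1[0] = x1 / s
    for t in range(1, T):
        p0, p1 = f0[t - 1], f1[t - 1]
        x0 = (p0 * a00 + p1 * a10) * b0[t]
        x1 = (p0 * a01 + p1 * a11) * b1[t]
        s = x0 + x1
        c[t] = s
        f0[t] = x0 / s
        f1[t] = x1 / s

    g0 = [0.0] * T
    g1 = [0.0] * T
    xi00 = xi01 = xi10 = xi11 = 0.0
    r0, r1 = 1.0, 1.0  # scaled backward variables
    g0[T - 1] = f0[T - 1]
    g1[T - 1] = f1[T - 1]
    for t in range(T - 1, 0, -1):
        bt0 = b0[t] * r0 / c[t]
        bt1 = b1[t] * r1 / c[t]
        p0, p1 = f0[t - 1], f1[t - 1]
        xi00 += p0 * a00 * bt0
        xi01 += p0 * a01 * bt1
        xi10 += p1 * a10 * bt0
        xi11 += p1 * a11 * bt1
        r0 = a00 * bt0 + a01 * bt1
        r1 = a10 * bt0 + a11 * bt1
        g0[t - 1] = p0 * r0
        g1[t - 1] = p1 * r1

    gamma = np.column_stack([g0, g1])
    # guard against round-off: renormalise rows
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.array([[xi00, xi01], [xi10, xi11]])
    loglik = float(np.sum(np.log(c)) + np.sum(row_max))
    return gamma, xi_sum, loglik


def _emission_loglik(chrom_m: np.ndarray, chrom_n: np.ndarray, params: HmmParams) -> np.ndarray:
    logB = np.zeros((len(chrom_n), 2))
    informative = chrom_n > 0
    for s in range(2):
        logB[informative, s] = betabinom_logpmf(
            chrom_m[informative], chrom_n[informative], params.emis[s]
        )
    return logB


def posterior_decode(binned: BinnedMethylome, params: HmmParams) -> PosteriorTrack:
    """Forward–backward posteriors of the PMD state under fixed parameters."""
    posterior: dict[str, np.ndarray] = {}
    total_ll = 0.0
    for chrom, bc in binned.chroms.items():
        logB = _emission_loglik(bc.m, bc.n, params)
        gamma, _, ll = _forward_backward(logB, params.pi, params.A)
        posterior[chrom] = gamma[:, PMD_STATE]
        total_ll += ll
    return PosteriorTrack(posterior, total_ll, 0, True, bin_size=binned.bin_size)


def baum_welch(
    binned: BinnedMethylome,
    init: HmmParams | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int | None = None,
) -> tuple[HmmParams, PosteriorTrack]:
    """Train the two-state HMM by EM; returns relabeled parameters and the
    posterior track under them.

    The total log-likelihood is non-decreasing across iterations (the
    emission M-step falls back to the current parameters whenever the
    numerical optimiser fails to improve on them). Convergence is declared
    when the relative log-likelihood change drops below ``tol``; hitting
    ``max_iter`` first returns ``converged=False`` rather than raising.
    ``seed`` is accepted for interface symmetry — training is deterministic
    given the initial parameters.
    """
    del seed
    params = init or default_init()
    seqs = [(bc.m, bc.n) for bc in binned.chroms.values()]
    n_informative = sum(int((n > 0).sum()) for _, n in seqs)
    if n_informative < 2:
        raise DataError("need at least 2 bins with observations to train")

    prev_ll = -math.inf
    n_iter = 0
    converged = False
    history: list[float] = []
    for n_iter in range(1, max_iter + 1):
        gammas = []
        xi_total = np.zeros((2, 2))
        pi_acc = np.zeros(2)
        total_ll = 0.0
        for m, n in seqs:
            logB = _emission_loglik(m, n, params)
            gamma, xi_sum, ll = _forward_backward(logB, params.pi, params.A)
            gammas.append(gamma)
            xi_total += xi_sum
            pi_acc += gamma[0]
            total_ll += ll

        history.append(total_ll)
        if prev_ll > -math.inf and abs(prev_ll) > 0:
            if (total_ll - prev_ll) / abs(prev_ll) < tol:
                converged = True
                break
        prev_ll = total_ll

        # M-step
        pi_new = pi_acc / pi_acc.sum()
        row_sums = xi_total.sum(axis=1, keepdims=True)
        A_new = np.where(row_sums > 0, xi_total / np.where(row_sums > 0, row_sums, 1.0),
                         params.A)
        ms_all = np.concatenate([m for m, _ in seqs])
        ns_all = np.concatenate([n for _, n in seqs])
        gam_all = np.concatenate(gammas, axis=0)
        emis_new = list(params.emis)
        for s in range(2):
            w = gam_all[:, s]
            if w[ns_all > 0].sum() <= 1e-10:
                continue  # collapsed state: keep current emissions
            cand = fit_betabinom(ms_all, ns_all, weights=w, init=params.emis[s])
            # keep the EM guarantee: only accept if the expected emission
            # log-likelihood does not decrease
            informative = ns_all > 0
            old_ll = float(np.dot(w[informative], betabinom_logpmf(
                ms_all[informative], ns_all[informative], params.emis[s])))
            new_ll = float(np.dot(w[informative], betabinom_logpmf(
                ms_all[informative], ns_all[informative], cand)))
            if new_ll >= old_ll:
                emis_new[s] = cand
        params = HmmParams(pi_new, A_new, (emis_new[0], emis_new[1]))

    params = params.relabeled()
    track = posterior_decode(binned, params)
    track.n_iter = n_iter
    track.converged = converged
    track.ll_history = history
    return params, track


def call_domains(
    track: PosteriorTrack, binned: BinnedMethylome, cutoff: float = 0.5,
    sample_id: str = "",
) -> PmdSet:
    """Maximal runs of bins with posterior(PMD) strictly above ``cutoff``
    become half-open domains; ties at the cutoff go to the background.
    Runs never cross chromosome boundaries."""
    if not track.aligned_with(binned):
        raise ConsistencyError("posterior track does not align with binned methylome")
    rows = []
    bs = binned.bin_size
    for chrom, bc in binned.chroms.items():
        post = track.posterior[chrom]
        above = post > cutoff
        if not above.any():
            continue
        padded = np.concatenate([[False], above, [False]])
        d = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)  # exclusive bin index
        for rs, re in zip(run_starts, run_ends):
            start = int(rs) * bs
            end = min(int(re) * bs, bc.chrom_len)
            rows.append((chrom, start, end, float(post[rs:re].mean()), int(re - rs)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "n_bins"])
    return PmdSet(df, sample_id=sample_id, bin_size=bs)
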