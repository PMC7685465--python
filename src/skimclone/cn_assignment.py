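"""Copy-number state assignment for segments.

Two routes are provided and reconciled:

* a Bayesian hierarchical model over segment mean LogR values, sampling
  purity, ploidy and per-segment integer states with a Gibbs/MH scheme;
* a Poisson model over segment mean read counts anchored on the mean count
  of provisionally diploid segments.

The deterministic forward model is

    logr_expected(cn) = log2((2 (1 - rho) + rho cn) / psi)

and ``cn_from_logr`` is its exact algebraic inverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .segmentation import Segment

__all__ = [
    "CNModelParams",
    "PoissonFit",
    "BayesianFit",
    "logr_expected",
    "cn_from_logr",
    "fit_bayesian",
    "poisson_assign",
    "reconcile",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class CNModelParams:
    rho: float
    psi: int = 2
    sigma: float = 0.1
    max_cn: int = 9

    def __post_init__(self) -> None:
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        if self.psi not in (2, 4):
            raise ValueError("psi must be 2 or 4")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class PoissonFit:
    k_tilde: float
    expected_counts: np.ndarray        # r_n for n = 0..max_cn
    log_probs: np.ndarray              # (n_segments, max_cn + 1)
    states: np.ndarray                 # argmax state per segment


@dataclass
class BayesianFit:
    rho: float
    psi: int
    states: np.ndarray
    rho_interval: tuple[float, float]          # central 90% credible interval
    state_posterior: np.ndarray                # (n_segments, max_cn + 1)
    converged: bool
    rho_samples: np.ndarray = field(repr=False, default=None)


def logr_expected(cn: float, params: CNModelParams) -> float:
    """Expected segment LogR for a given copy-number state."""
    if cn < 0:
        raise ValueError("copy number must be >= 0")
    arg = (2.0 * (1.0 - params.rho) + params.rho * cn) / params.psi
    if arg <= 0:
        return NEG_INF
    return math.log2(arg)


def cn_from_logr(r_s: float, params: CNModelParams) -> float:
    """Continuous copy number from a segment LogR; exact inverse of
    :func:`logr_expected`. May return slightly negative values near CN0."""
    return (params.psi * 2.0**r_s - 2.0 * (1.0 - params.rho)) / params.rho


def _loglik_matrix(means: np.ndarray, weights: np.ndarray, rho: float, psi: int,
                   sigma: float, max_cn: int) -> np.ndarray:
    """(n_segments, max_cn+1) Gaussian log-likelihoods of segment means.

    Segment mean LogR ~ Normal(logr_expected(cn), sigma^2 / n_bins).
    """
    cns = np.arange(max_cn + 1, dtype=float)
    arg = (2.0 * (1.0 - rho) + rho * cns) / psi
    with np.errstate(divide="ignore"):
        mu = np.log2(arg)
    var = sigma**2 / weights[:, None]
    ll = -0.5 * (means[:, None] - mu[None, :]) ** 2 / var - 0.5 * np.log(var)
    ll[:, arg <= 0] = NEG_INF
    return ll


def _split_rhat(chains: np.ndarray) -> float:
    """Split-Rhat over (n_chains, n_draws) post-burn-in samples."""
    n = chains.shape[1] // 2
    if n < 2:
        return np.inf
    halves = np.concatenate([chains[:, :n], chains[:, n: 2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def fit_bayesian(
    segments: list[Segment],
    init_rho: float,
    sigma: float | None = None,
    max_cn: int = 9,
    psi_options: tuple[int, ...] = (2, 4),
    rho_concentration: float = 50.0,
    n_iter: int = 2000,
    burn_in: int = 500,
    n_chains: int = 4,
    seed: int = 0,
    rho_step: float = 0.03,
) -> BayesianFit:
    """Posterior sampling of {rho, psi, per-segment state}.

    Model: segment mean LogR ~ Normal(logr_expected(CN_s, rho, psi),
    sigma^2 / n_bins); CN_s uniform on {0..max_cn}; rho ~ Beta centred at
    ``init_rho`` with the given concentration; psi uniform on
    ``psi_options``. CN_s is Gibbs-sampled exactly; rho moves by random-walk
    Metropolis with states marginalised out; psi by a marginal Gibbs step.
    Deterministic for a fixed seed. Non-convergence (split-Rhat on rho
    above 1.1) is flagged, not raised.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments")
    means = np.array([s.mean_logr for s in segments])
    weights = np.array([max(s.n_bins, 1) for s in segments], dtype=float)
    if sigma is None:
        sigma = 0.5 / math.sqrt(max(np.median(weights), 1.0))
    a = init_rho * rho_concentration
    b = (1.0 - init_rho) * rho_concentration
    a, b = max(a, 1e-3), max(b, 1e-3)

    rng = np.random.default_rng(seed)
    n_seg = len(segments)
    K = max_cn + 1
    all_rho = np.zeros((n_chains, n_iter - burn_in))
    all_psi = []
    state_counts = np.zeros((n_seg, K))

    def marginal_logpost(rho, psi):
        if not 0 < rho < 1:
            return NEG_INF
        ll = _loglik_matrix(means, weights, rho, psi, sigma, max_cn)
        lp = float(np.sum(logsumexp(ll, axis=1))) - n_seg * math.log(K)
        lp += (a - 1) * math.log(rho) + (b - 1) * math.log(1 - rho)
        return lp

    for chain in range(n_chains):
        crng = np.random.default_rng(rng.integers(2**63))
        rho = float(np.clip(init_rho + 0.05 * crng.standard_normal(), 0.05, 1 - 1e-6))
        psi = psi_options[0]
        lp = marginal_logpost(rho, psi)
        for it in range(n_iter):
            # rho: random-walk MH on the state-marginalised posterior
            prop = rho + rho_step * crng.standard_normal()
            lp_prop = marginal_logpost(prop, psi)
            if math.log(crng.random()) < lp_prop - lp:
                rho, lp = prop, lp_prop
            # psi: marginal Gibbs over the option set
            if len(psi_options) > 1:
                lps = np.array([marginal_logpost(rho, p) for p in psi_options])
                probs = np.exp(lps - logsumexp(lps))
                psi = int(crng.choice(psi_options, p=probs))
                lp = lps[list(psi_options).index(psi)]
            if it >= burn_in:
                all_rho[chain, it - burn_in] = rho
                all_psi.append(psi)
                ll = _loglik_matrix(means, weights, rho, psi, sigma, max_cn)
                post = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
                state_counts += post

    rho_samples = all_rho.ravel()
    rho_hat = float(np.mean(rho_samples))
    psi_hat = int(np.bincount(all_psi).argmax())
    state_post = state_counts / state_counts.sum(axis=1, keepdims=True)
    states = state_post.argmax(axis=1)
    lo, hi = np.quantile(rho_samples, [0.05, 0.95])
    rhat = _split_rhat(all_rho)
    return BayesianFit(
        rho=rho_hat,
        psi=psi_hat,
        states=states,
        rho_interval=(float(lo), float(hi)),
        state_posterior=state_post,
        converged=rhat <= 1.1,
        rho_samples=rho_samples,
    )


def poisson_assign(
    segments: list[Segment],
    rho: float,
    provisional_cn2: np.ndarray | None = None,
    mode: str = "mixture",
    max_cn: int = 9,
) -> PoissonFit:
    """Poisson state assignment anchored on provisionally diploid segments.

    ``k_tilde`` is the mean per-bin read count over segments marked CN2 by
    ``provisional_cn2`` (default: segments whose ``cn_state`` is 2). Expected
    counts per state are ``k_tilde * n * rho / 2`` in ``mode="as_printed"``
    or ``k_tilde * (2 (1 - rho) + n rho) / 2`` in ``mode="mixture"``
    (default, host-dilution form; the modes coincide at rho = 1). Each
    segment takes the state maximising the Poisson log-pmf of its mean
    per-bin count.
    """
    if mode not in ("as_printed", "mixture"):
        raise ValueError(f"unknown mode {mode!r}")
    counts = np.array([s.mean_count for s in segments], dtype=float)
    if np.isnan(counts).any():
        raise ValueError("all segments need a mean per-bin count")
    if provisional_cn2 is None:
        provisional_cn2 = np.array([s.cn_state == 2 for s in segments])
    provisional_cn2 = np.asarray(provisional_cn2, dtype=bool)
    if not provisional_cn2.any():
        raise ValueError("no provisional-CN2 anchor segments; k_tilde undefined")
    k_tilde = float(counts[provisional_cn2].mean())

    ns = np.arange(max_cn + 1, dtype=float)
    if mode == "as_printed":
        r_n = k_tilde * ns * rho / 2.0
    else:
        r_n = k_tilde * (2.0 * (1.0 - rho) + ns * rho) / 2.0
    with np.errstate(divide="ignore"):
        log_r = np.log(r_n)
    log_probs = counts[:, None] * log_r[None, :] - r_n[None, :] - gammaln(counts + 1.0)[:, None]
    for j in np.nonzero(r_n <= 0)[0]:
        # degenerate Poisson(0): mass only at k = 0
        log_probs[:, j] = np.where(counts == 0, 0.0, NEG_INF)
    states = log_probs.argmax(axis=1)
    return PoissonFit(
        k_tilde=k_tilde, expected_counts=r_n, log_probs=log_probs, states=states
    )


def reconcile(
    bayes_states: np.ndarray,
    poisson_states: np.ndarray,
    segments: list[Segment],
    params: CNModelParams,
    subclonal_tol: float = 0.15,
) -> list[Segment]:
    """Combine the two state assignments into final segment states.

    Agreement takes the shared integer. Disagreement takes the Bayesian
    state and flags the segment, unless the continuous copy number lies
    within ``subclonal_tol`` of the half-integer midpoint between the two
    candidates, in which case the segment gets that half-integer state and
    a subclonal flag.
    """
    out = []
    for seg, bs, ps in zip(segments, bayes_states, poisson_states):
        seg.cn_state = float(bs)
        seg.subclonal = False
        seg.flagged = False
        if bs != ps:
            cont = max(cn_from_logr(seg.mean_logr, params), 0.0)
            mid = (bs + ps) / 2.0
            if abs(bs - ps) == 1 and abs(cont - mid) <= subclonal_tol:
                seg.cn_state = mid
                seg.subclonal = True
            else:
                seg.flagged = True
        out.append(seg)
    return out
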