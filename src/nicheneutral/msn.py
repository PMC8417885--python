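"""Multi-site neutral (MSN) model via a hierarchical Dirichlet process.

One subject's metacommunity is modeled as a two-level Dirichlet process:
the metacommunity relative-abundance vector is a stick-breaking draw with
fundamental biodiversity number ``theta``; local community ``i`` (one time
point, depth ``N_i``) draws its composition from a Dirichlet process with
concentration ``I_i`` (the immigration rate) around the metacommunity, and
the observed counts are multinomial.  ``I_i`` maps to a migration
probability ``m_i = I_i / (I_i + N_i - 1)``.

Fitting uses the standard direct-assignment HDP Gibbs sampler: ancestral
(table) counts follow Chinese-restaurant-table (CRT) conditionals, the
metacommunity vector a Dirichlet conditional, and both concentrations
``theta`` and ``I_i`` are resampled under Gamma priors with the classic
beta-gamma auxiliary-variable step.  Neutrality is assessed with
posterior-predictive Monte-Carlo tests at two levels (metacommunity and
local), producing pseudo P-values ``P_M`` and ``P_L``: the fraction of
parameter-matched neutral simulations whose likelihood does not exceed the
observed likelihood.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy.special import gammaln, digamma
from sklearn.base import BaseEstimator

from .data_model import AbundanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "log_antoniak_pmf", "sample_crt", "stick_breaking_sample",
    "dirichlet_multinomial_loglik", "migration_probability",
    "immigration_rate", "MSNPosterior", "NeutralityTestResult",
    "MultiSiteNeutralModel", "gibbs_fit", "neutrality_test",
]

# ---------------------------------------------------------------------------
# Stirling / Antoniak machinery

_STIRLING_ROWS: list[np.ndarray] = [np.array([0.0])]  # log s(0, 0) = 0


def _log_stirling1_row(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind s(n, k), k=0..n.

    Rows are built once by the recurrence s(n+1, k) = n*s(n, k) + s(n, k-1)
    in log space and cached for the life of the process.
    """
    while len(_STIRLING_ROWS) <= n:
        m = len(_STIRLING_ROWS) - 1
        prev = _STIRLING_ROWS[-1]
        row = np.full(m + 2, -np.inf)
        if m > 0:
            row[: m + 1] = np.log(m) + prev
        row[1:] = np.logaddexp(row[1:], prev)
        _STIRLING_ROWS.append(row)
    return _STIRLING_ROWS[n]


def log_antoniak_pmf(S: int, theta: float, N: int) -> float:
    """Log-probability of observing S species in N draws from a DP(theta).

    This is the Antoniak distribution
    ``P(S | theta, N) = s(N, S) * theta^S * Gamma(theta) / Gamma(theta + N)``
    with ``s(N, S)`` the unsigned Stirling number of the first kind.
    """
    S, N = int(S), int(N)
    if not 1 <= S <= N:
        raise ValueError(f"need 1 <= S <= N, got S={S}, N={N}")
    if theta <= 0:
        raise ValueError("theta must be positive")
    row = _log_stirling1_row(N)
    return float(row[S] + S * np.log(theta) + gammaln(theta)
                 - gammaln(theta + N))


def sample_crt(x: int, alpha: float, rng: np.random.Generator) -> int:
    """Sample a Chinese-restaurant table count for x customers at conc. alpha.

    Uses the exact representation ``t = sum_k Bernoulli(alpha/(alpha+k-1))``
    for k = 1..x, so the marginal of ``t`` is proportional to
    ``s(x, t) * alpha^t``.
    """
    x = int(x)
    if x < 1:
        raise ValueError("x must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    k = np.arange(x, dtype=float)
    return int((rng.random(x) < alpha / (alpha + k)).sum())


def stick_breaking_sample(theta: float, trunc_tol: float = 1e-10,
                          rng: np.random.Generator | None = None,
                          ) -> np.ndarray:
    """Draw metacommunity weights by stick breaking with concentration theta.

    Sticks ``V_k ~ Beta(1, theta)`` are broken until the remaining mass
    drops below ``trunc_tol``; the residual mass is folded into the final
    component so the weights sum to one exactly.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng() if rng is None else rng
    weights: list[np.ndarray] = []
    remaining = 1.0
    while remaining >= trunc_tol:
        v = rng.beta(1.0, theta, size=64)
        w = remaining * v * np.cumprod(np.concatenate(([1.0], 1.0 - v[:-1])))
        weights.append(w)
        remaining *= float(np.prod(1.0 - v))
    beta = np.concatenate(weights) if weights else np.array([1.0])
    beta[-1] += remaining
    return beta


def dirichlet_multinomial_loglik(x: Sequence[int], N: int,
                                 alpha: Sequence[float]) -> float:
    """Dirichlet-multinomial log-likelihood (nats) of counts x at depth N.

    ``log[ multinomial-coef * Gamma(A)/Gamma(A+N) *
    prod_j Gamma(alpha_j + x_j)/Gamma(alpha_j) ]`` with ``A = sum(alpha)``.
    This is the local-community likelihood of the MSN model with
    ``alpha = I_i * beta``.
    """
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if x.shape != alpha.shape:
        raise ValueError("x and alpha must have the same shape")
    if int(round(float(x.sum()))) != int(N):
        raise ValueError(f"N={N} does not match sum(x)={x.sum()}")
    if ((alpha <= 0) & (x > 0)).any():
        raise ValueError("alpha must be positive wherever x > 0")
    live = alpha > 0
    a, xv = alpha[live], x[live]
    A = a.sum()
    return float(
        gammaln(N + 1) - gammaln(xv + 1).sum()
        + gammaln(A) - gammaln(A + N)
        + (gammaln(a + xv) - gammaln(a)).sum()
    )


def migration_probability(I: float | np.ndarray, N: float | np.ndarray):
    """m_i = I_i / (I_i + N_i - 1): immigrant fraction of local community i."""
    return I / (I + N - 1.0)


def immigration_rate(m: float | np.ndarray, N: float | np.ndarray):
    """Inverse map I_i = m_i (N_i - 1) / (1 - m_i)."""
    return m * (N - 1.0) / (1.0 - m)


# ---------------------------------------------------------------------------
# Posterior containers

@dataclasses.dataclass
class MSNPosterior:
    """Retained Gibbs chains and summaries for one metacommunity fit.

    Full post-burn-in chains are kept for theta and the immigration rates;
    the thinned subset (every ``thin``-th draw, ``n_sets`` members) also
    retains the metacommunity vector and is what the neutrality tests use.
    """

    theta_chain: np.ndarray          # (n_keep,)
    I_chain: np.ndarray              # (n_keep, T)
    theta_thin: np.ndarray           # (n_sets,)
    I_thin: np.ndarray               # (n_sets, T)
    beta_thin: np.ndarray            # (n_sets, S_obs + 1), last col = unseen
    sample_sizes: np.ndarray         # (T,)
    n_iter: int
    n_burn: int
    thin: int

    @property
    def n_sets(self) -> int:
        return self.theta_thin.shape[0]

    @property
    def theta_median(self) -> float:
        return float(np.median(self.theta_chain))

    @property
    def m_chain(self) -> np.ndarray:
        return migration_probability(self.I_chain,
                                     self.sample_sizes[None, :])

    @property
    def M_value(self) -> float:
        """Average over local communities of the chain-median m_i."""
        return float(np.median(self.m_chain, axis=0).mean())

    def summaries(self) -> dict[str, dict[str, float | np.ndarray]]:
        def q(chain, axis=0):
            med = np.median(chain, axis=axis)
            lo, hi = np.quantile(chain, [0.025, 0.975], axis=axis)
            return {"median": med, "q025": lo, "q975": hi}

        return {"theta": q(self.theta_chain), "I": q(self.I_chain),
                "m": q(self.m_chain)}


@dataclasses.dataclass
class NeutralityTestResult:
    """Two-level Monte-Carlo neutrality test outcome.

    ``P = N_pass_sims / N`` is the pseudo P-value: the share of neutral
    simulations whose log-likelihood does not exceed the observed one
    (ties count).  The model passes at threshold ``P_t`` iff ``P > P_t``.
    """

    level: str                      # "metacommunity" or "local"
    L_0: float                      # median observed loglik over sets
    L_sim_median: float             # median simulated loglik
    N_pass_sims: int
    N: int
    P: float

    @classmethod
    def from_counts(cls, level: str, L_0: float, L_sim_median: float,
                    N_pass_sims: int, N: int) -> "NeutralityTestResult":
        if not 0 <= N_pass_sims <= N:
            raise ValueError("need 0 <= N_pass_sims <= N")
        return cls(level=level, L_0=L_0, L_sim_median=L_sim_median,
                   N_pass_sims=N_pass_sims, N=N, P=N_pass_sims / N)

    def passes(self, P_t: float = 0.05) -> bool:
        return self.P > P_t


# ---------------------------------------------------------------------------
# Gibbs sampler

def _resample_concentration(alpha: float, k: float, n: float, shape: float,
                            rate: float, rng: np.random.Generator) -> float:
    """Escobar-West beta-gamma auxiliary update for a DP concentration.

    ``k`` components were observed among ``n`` items; the prior is
    Gamma(shape, rate).  Degenerate inputs (n <= 1 or k < 1) fall back to
    the prior.
    """
    if n <= 1 or k < 1:
        return float(rng.gamma(shape, 1.0 / rate))
    eta = rng.beta(alpha + 1.0, n)
    b = rate - np.log(eta)
    w = (shape + k - 1.0) / (n * b)
    shape_post = shape + k if rng.random() < w / (1.0 + w) else shape + k - 1.0
    return float(rng.gamma(shape_post, 1.0 / b))


class MultiSiteNeutralModel(BaseEstimator):
    """Hierarchical-Dirichlet-process fit of the multi-site neutral model.

    Parameters
    ----------
    n_iter : total Gibbs iterations (study-scale default 50,000).
    n_burn : burn-in iterations discarded (default ``n_iter // 2``).
    thin : keep every ``thin``-th post-burn-in draw for the neutrality
        tests (default 10, i.e. 2,500 parameter sets at study scale).
    theta_prior, I_prior : (shape, rate) of the Gamma hyperpriors on the
        biodiversity number and the immigration rates; weakly informative
        defaults (1.0, 0.1).
    trunc_tol : stick-breaking truncation tolerance for simulation.
    random_state : int or :class:`numpy.random.Generator`.

    Attributes
    ----------
    posterior_ : :class:`MSNPosterior`
    theta_median_, theta_interval_ : chain median and (2.5%, 97.5%) bounds.
    I_median_, m_median_ : per-site chain medians.
    M_value_ : mean over sites of the median migration probability.
    """

    def __init__(self, n_iter: int = 50_000, n_burn: int | None = None,
                 thin: int = 10, theta_prior: tuple[float, float] = (1.0, 0.1),
                 I_prior: tuple[float, float] = (1.0, 0.1),
                 trunc_tol: float = 1e-10, random_state=None):
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.thin = thin
        self.theta_prior = theta_prior
        self.I_prior = I_prior
        self.trunc_tol = trunc_tol
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _as_counts(X) -> np.ndarray:
        if isinstance(X, AbundanceMatrix):
            return X.counts
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("expected a species x sample count matrix")
        AbundanceMatrix(X, [f"sp{i}" for i in range(X.shape[0])],
                        [f"s{j}" for j in range(X.shape[1])])
        return X.astype(np.int64)

    def _rng(self, random_state=None) -> np.random.Generator:
        rs = self.random_state if random_state is None else random_state
        return rs if isinstance(rs, np.random.Generator) \
            else np.random.default_rng(rs)

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y=None):
        counts = self._as_counts(X)
        rng = self._rng()
        S, T = counts.shape
        N = counts.sum(axis=0).astype(float)
        n_burn = self.n_iter // 2 if self.n_burn is None else self.n_burn
        n_keep = self.n_iter - n_burn
        if n_keep <= 0:
            raise ValueError("n_iter must exceed n_burn")
        if n_keep % self.thin:
            raise ValueError("(n_iter - n_burn) must be divisible by thin")
        n_sets = n_keep // self.thin

        # flat per-read layout for the vectorized CRT step
        rows, cols = np.nonzero(counts)
        xvals = counts[rows, cols]
        n_cells = xvals.size
        cell_id = np.repeat(np.arange(n_cells), xvals)
        starts = np.concatenate(([0], np.cumsum(xvals)[:-1]))
        kvals = np.arange(int(xvals.sum())) - np.repeat(starts, xvals)
        kvals = kvals.astype(float)

        theta_sh, theta_rt = self.theta_prior
        I_sh, I_rt = self.I_prior

        theta = float(S)
        I = np.full(T, 10.0)
        pooled = counts.sum(axis=1).astype(float)
        beta = np.empty(S + 1)
        beta[:S] = pooled / pooled.sum() * (1.0 - 1e-3)
        beta[S] = 1e-3

        theta_chain = np.empty(n_keep)
        I_chain = np.empty((n_keep, T))
        theta_thin = np.empty(n_sets)
        I_thin = np.empty((n_sets, T))
        beta_thin = np.empty((n_sets, S + 1))

        for it in range(self.n_iter):
            # (1) ancestral table counts t_ij ~ CRT(x_ij, I_i * beta_j)
            a_cell = I[cols] * np.maximum(beta[rows], 1e-300)
            a_pos = a_cell[cell_id]
            succ = rng.random(kvals.size) < a_pos / (a_pos + kvals)
            t_cell = np.bincount(cell_id, weights=succ, minlength=n_cells)
            t_species = np.bincount(rows, weights=t_cell, minlength=S)
            t_site = np.bincount(cols, weights=t_cell, minlength=T)

            # (2) metacommunity vector (beta_1..beta_S, beta_u)
            g = rng.gamma(np.concatenate((t_species, [theta])))
            g = np.maximum(g, 1e-300)
            beta = g / g.sum()

            # (3) biodiversity number theta given S occupied components
            #     among the total table count
            theta = _resample_concentration(theta, S, float(t_cell.sum()),
                                            theta_sh, theta_rt, rng)

            # (4) immigration rates given (t_i. tables, N_i customers),
            #     vectorized Escobar-West across sites
            eta = rng.beta(I + 1.0, N)
            b = I_rt - np.log(eta)
            w = (I_sh + t_site - 1.0) / (N * b)
            take_upper = rng.random(T) < w / (1.0 + w)
            I = rng.gamma(I_sh + t_site - (~take_upper), 1.0 / b)

            j = it - n_burn
            if j >= 0:
                theta_chain[j] = theta
                I_chain[j] = I
                if (j + 1) % self.thin == 0:
                    s = (j + 1) // self.thin - 1
                    theta_thin[s] = theta
                    I_thin[s] = I
                    beta_thin[s] = beta

        self.posterior_ = MSNPosterior(
            theta_chain=theta_chain, I_chain=I_chain, theta_thin=theta_thin,
            I_thin=I_thin, beta_thin=beta_thin, sample_sizes=N,
            n_iter=self.n_iter, n_burn=n_burn, thin=self.thin)
        self._counts_ = counts
        self.n_species_ = S
        self.sample_sizes_ = N
        self.theta_median_ = self.posterior_.theta_median
        q = self.posterior_.summaries()["theta"]
        self.theta_interval_ = (float(q["q025"]), float(q["q975"]))
        self.I_median_ = np.median(I_chain, axis=0)
        self.m_median_ = np.median(self.posterior_.m_chain, axis=0)
        self.M_value_ = self.posterior_.M_value
        return self

    # -- posterior-predictive neutrality tests -----------------------------
    def neutrality_test(self, level: str = "metacommunity",
                        random_state=None) -> NeutralityTestResult:
        if not hasattr(self, "posterior_"):
            raise RuntimeError("fit the model before testing")
        rng = self._rng(self._rng() if random_state is None else random_state)
        return neutrality_test(self._counts_, self.posterior_, level, rng,
                               trunc_tol=self.trunc_tol)


def _dm_loglik_sites(X: np.ndarray, alpha: np.ndarray) -> float:
    """Sum of Dirichlet-multinomial logliks over sites (rows of X).

    X and alpha are (T, C); columns with alpha == 0 must have zero counts.
    """
    N = X.sum(axis=1)
    live = alpha > 0
    a = np.where(live, alpha, 1.0)          # dummy where dead; terms masked
    A = np.where(live, alpha, 0.0).sum(axis=1)
    terms = np.where(live, gammaln(a + X) - gammaln(a) - gammaln(X + 1), 0.0)
    return float((gammaln(N + 1) + gammaln(A) - gammaln(A + N)
                  + terms.sum(axis=1)).sum())


def neutrality_test(data, posterior: MSNPosterior, level: str,
                    rng: np.random.Generator | None = None,
                    trunc_tol: float = 1e-10) -> NeutralityTestResult:
    """Monte-Carlo neutrality test at the metacommunity or local level.

    For each thinned parameter set k the observed log-likelihood ``L0_k``
    is evaluated under ``(I_k, beta_k)`` on the observed-species support
    plus one pooled "unseen" category.  The metacommunity-level test draws
    a fresh stick-breaking metacommunity from ``theta_k`` (components
    beyond the observed richness pooled into the unseen slot) and
    simulates Dirichlet-multinomial counts at the observed depths; the
    local-level test keeps the fitted (possibly non-neutral) metacommunity
    and only re-simulates the local sampling step.  ``P`` is the fraction
    of sets with simulated likelihood <= observed likelihood.
    """
    counts = data.counts if isinstance(data, AbundanceMatrix) \
        else np.asarray(data, dtype=np.int64)
    if level not in ("metacommunity", "local"):
        raise ValueError(f"unknown test level {level!r}")
    if posterior.n_sets == 0:
        raise ValueError("posterior holds no retained parameter sets")
    rng = np.random.default_rng() if rng is None else rng
    S, T = counts.shape
    Ns = counts.sum(axis=0)
    X_obs = np.concatenate((counts.T, np.zeros((T, 1), dtype=np.int64)),
                           axis=1)                      # (T, S+1)

    L0 = np.empty(posterior.n_sets)
    Lsim = np.empty(posterior.n_sets)
    for k in range(posterior.n_sets):
        beta_k = posterior.beta_thin[k]
        I_k = posterior.I_thin[k]
        alpha_obs = I_k[:, None] * beta_k[None, :]
        L0[k] = _dm_loglik_sites(X_obs, alpha_obs)

        if level == "metacommunity":
            sticks = stick_breaking_sample(posterior.theta_thin[k],
                                           trunc_tol, rng)
            beta_sim = np.zeros(S + 1)
            m = min(S, sticks.size)
            beta_sim[:m] = sticks[:m]
            beta_sim[S] = max(1.0 - beta_sim[:S].sum(), 0.0)
        else:
            beta_sim = beta_k
        alpha_sim = I_k[:, None] * beta_sim[None, :]
        X_sim = np.empty_like(X_obs)
        for i in range(T):
            g = rng.gamma(np.maximum(alpha_sim[i], 0.0))
            tot = g.sum()
            if tot <= 0:            # pathological underflow: put all mass
                g[np.argmax(alpha_sim[i])] = 1.0   # on the largest category
                tot = 1.0
            X_sim[i] = rng.multinomial(Ns[i], g / tot)
        # counts can land in the pooled unseen slot; likelihood is evaluated
        # on the same support as the observed data
        Lsim[k] = _dm_loglik_sites(X_sim, alpha_sim)

    n_pass = int((Lsim <= L0).sum())
    return NeutralityTestResult.from_counts(
        level=level, L_0=float(np.median(L0)),
        L_sim_median=float(np.median(Lsim)), N_pass_sims=n_pass,
        N=posterior.n_sets)


# ---------------------------------------------------------------------------
# Thin functional wrappers over the estimator

def gibbs_fit(data, config: dict | None = None,
              rng=None) -> MSNPosterior:
    """Fit the MSN model by Gibbs sampling and return the posterior.

    ``config`` accepts the :class:`MultiSiteNeutralModel` constructor
    arguments (n_iter, n_burn, thin, priors, trunc_tol).
    """
    config = dict(config or {})
    model = MultiSiteNeutralModel(random_state=rng, **config)
    return model.fit(data).posterior_


def expected_richness(theta: float, N: int) -> float:
    """Expected distinct species among N draws of a DP: theta*(psi(theta+N)-psi(theta))."""
    return float(theta * (digamma(theta + N) - digamma(theta)))
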