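"""Niche-neutral hybrid (NNH) model: per-niche neutral SAD fits.

Each time point of a subject's series is treated as one niche holding a
local community that follows its own neutral rules.  Within a niche the
species-abundance distribution is the stationary solution of a neutral
birth-death-immigration process with per-capita birth/death ratio
``x = b/d`` and immigration parameter ``gamma``:

    p(n) = (1 - x)^gamma / Gamma(gamma) * x^n / n! * Gamma(n + gamma)

a negative binomial, and the expected number of species of abundance n is

    <phi_n> = theta * x^n / n! * Gamma(n + gamma)

with ``theta`` the niche's biodiversity parameter.  The metacommunity
expectation is the sum of the K per-niche expectations; goodness of fit is
a chi-square over Preston-style abundance octaves, with R^2 on the same
bins, plus per-niche local neutrality tests.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator

from .data_model import AbundanceMatrix, ResultRowNNH

logger = logging.getLogger(__name__)

__all__ = [
    "VolkovParams", "BinnedSAD", "NNHFitResult", "volkov_pmf",
    "volkov_logpmf", "expected_sad", "fit_niche", "NicheNeutralHybridModel",
    "nnh_metacommunity_test", "local_neutrality_tests", "nnh_summary",
    "preston_octaves",
]


@dataclasses.dataclass
class VolkovParams:
    """Per-niche neutral SAD parameters (theta, x, gamma) plus niche size."""

    theta: float
    x: float
    gamma: float
    J: int | None = None          # individuals in the niche
    S: int | None = None          # observed species in the niche
    converged: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.x < 1.0:
            raise ValueError(f"x={self.x} must lie in (0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.theta <= 0:
            raise ValueError("theta must be positive")

    @property
    def m(self) -> float:
        """Migration coefficient m = gamma / (gamma + J - 1) (convention)."""
        if self.J is None:
            raise ValueError("J unknown for this fit")
        return self.gamma / (self.gamma + self.J - 1.0)


@dataclasses.dataclass
class BinnedSAD:
    """Observed vs expected species counts pooled into abundance classes."""

    bin_edges: np.ndarray        # len nbins+1; class b covers [e_b, e_{b+1})
    O: np.ndarray
    E: np.ndarray

    def __post_init__(self) -> None:
        if len(self.O) != len(self.E):
            raise ValueError("O and E must have the same number of bins")


@dataclasses.dataclass
class NNHFitResult:
    per_niche: list[VolkovParams]
    K: int
    chi2: float
    df: int
    P: float
    R2: float
    N_pass: int
    pct_pass: float
    binned: BinnedSAD | None
    local_P: np.ndarray
    summary: ResultRowNNH


def volkov_logpmf(n, x: float, gamma: float):
    if not 0.0 < x < 1.0:
        raise ValueError(f"x={x} must lie in (0, 1)")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    n = np.asarray(n)
    if (n < 0).any():
        raise ValueError("n must be non-negative")
    return (gamma * np.log1p(-x) - gammaln(gamma)
            + n * np.log(x) - gammaln(n + 1) + gammaln(n + gamma))


def volkov_pmf(n, x: float, gamma: float):
    """Stationary abundance pmf p(n) of the neutral birth-death model.

    Negative binomial with shape ``gamma`` and success probability ``x``;
    ``gamma = 1`` reduces to the geometric distribution ``(1-x) x^n``.
    """
    out = np.exp(volkov_logpmf(n, x, gamma))
    return float(out) if np.isscalar(n) or np.asarray(n).ndim == 0 else out


def expected_sad(n, params: VolkovParams | None = None, *, theta=None,
                 x=None, gamma=None):
    """Expected number of species with abundance n: theta x^n Gamma(n+gamma)/n!.

    Satisfies the ratio identity
    ``<phi_{n+1}>/<phi_n> = x (n + gamma) / (n + 1)``; any constant factor
    of the underlying sampling formula is absorbed into ``theta``.
    """
    if params is not None:
        theta, x, gamma = params.theta, params.x, params.gamma
    if not 0.0 < x < 1.0:
        raise ValueError(f"x={x} must lie in (0, 1)")
    if gamma <= 0 or theta <= 0:
        raise ValueError("theta and gamma must be positive")
    arr = np.asarray(n)
    if (arr < 1).any():
        raise ValueError("n must be >= 1")
    out = np.exp(np.log(theta) + arr * np.log(x) - gammaln(arr + 1)
                 + gammaln(arr + gamma))
    return float(out) if arr.ndim == 0 else out


def _log_expm1(y: float) -> float:
    """log(exp(y) - 1) for y > 0, stable for both tails."""
    if y > 30:
        return y
    return float(np.log(np.expm1(y)))


def _theta_from_richness(S: int, x: float, gamma: float) -> float:
    """theta matching sum_{n>=1} <phi_n> = S.

    The series sums to theta * Gamma(gamma) * ((1-x)^-gamma - 1).
    """
    log_series = gammaln(gamma) + _log_expm1(-gamma * np.log1p(-x))
    return float(max(np.exp(np.log(S) - log_series), 1e-300))


def fit_niche(abundances: Sequence[int], n_starts: int = 3,
              tol: float = 1e-8) -> VolkovParams:
    """Maximum-likelihood fit of (x, gamma) to one niche's abundances.

    The likelihood is the zero-truncated form of the neutral pmf (only
    species present in the niche are observed); optimization runs on
    (logit x, log gamma) from several starts.  ``theta`` is then set so
    the expected richness matches the observed species count.  Degenerate
    SADs (all singletons push x to the zero boundary) and failed
    optimizations are returned flagged (``converged=False``).
    """
    ns = np.asarray(abundances, dtype=float)
    if ns.size == 0 or (ns < 1).any():
        raise ValueError("abundances must be positive counts")
    S = int(ns.size)
    J = int(ns.sum())
    const = -gammaln(ns + 1).sum()

    def nll(params: np.ndarray) -> float:
        lx, lg = params
        x = 1.0 / (1.0 + np.exp(-lx))
        g = np.exp(lg)
        log_p0 = g * np.log1p(-x)
        ll = (ns * np.log(x) + gammaln(ns + g)).sum() \
            + S * (log_p0 - gammaln(g)) + const \
            - S * np.log(-np.expm1(log_p0))
        return -ll

    starts = [(0.0, 0.0), (2.2, -1.2), (-1.0, 1.0), (4.0, -2.0)][:max(n_starts, 1)]
    best = None
    for s in starts:
        try:
            res = optimize.minimize(nll, np.array(s), method="Nelder-Mead",
                                    options={"xatol": tol, "fatol": tol,
                                             "maxiter": 2000})
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    lx, lg = best.x
    x = float(1.0 / (1.0 + np.exp(-lx)))
    g = float(np.exp(lg))
    flagged = (not best.success) or x < 1e-4 or x > 1.0 - 1e-12 \
        or g < 1e-8 or g > 1e8
    x = float(np.clip(x, 1e-6, 1.0 - 1e-9))
    g = float(np.clip(g, 1e-6, 1e8))
    theta = _theta_from_richness(S, x, g)
    if flagged:
        logger.info("flagged niche fit: x=%.4g gamma=%.4g (S=%d, J=%d)",
                    x, g, S, J)
    return VolkovParams(theta=theta, x=x, gamma=g, J=J, S=S,
                        converged=not flagged)


# ---------------------------------------------------------------------------
# Binning and goodness of fit

def preston_octaves(max_n: int) -> np.ndarray:
    """Doubling abundance-class edges [1], [2-3], [4-7], ... covering max_n."""
    edges = [1]
    while edges[-1] <= max_n:
        edges.append(edges[-1] * 2)
    return np.asarray(edges)


def _binned_expectation(fits: Sequence[VolkovParams],
                        edges: np.ndarray) -> np.ndarray:
    """Sum of per-niche expected SADs pooled into the octave bins.

    The expected total over all n >= 1 equals the summed observed richness
    by construction of the theta estimates; mass beyond the last edge is
    assigned to the final bin so observed and expected totals agree.
    """
    n = np.arange(1, edges[-1])
    En = np.zeros(n.size)
    total = 0.0
    for p in fits:
        En += expected_sad(n, p)
        total += p.S if p.S is not None else 0.0
    bins = np.array([En[(n >= lo) & (n < hi)].sum()
                     for lo, hi in zip(edges[:-1], edges[1:])])
    bins[-1] += max(total - En.sum(), 0.0)
    return bins


def _pool_right(edges: np.ndarray, O: np.ndarray, E: np.ndarray,
                floor: float) -> BinnedSAD:
    """Merge bins from the right until every expected count >= floor."""
    edges, O, E = list(edges), list(O), list(E)
    while len(E) > 1 and min(E) < floor:
        j = int(np.argmin(E))
        k = j - 1 if j == len(E) - 1 else j + 1
        lo, hi = min(j, k), max(j, k)
        O[lo] += O.pop(hi)
        E[lo] += E.pop(hi)
        edges.pop(hi)
    return BinnedSAD(np.asarray(edges), np.asarray(O, dtype=float),
                     np.asarray(E, dtype=float))


def _chi2_test(binned: BinnedSAD) -> tuple[float, int, float, float]:
    O, E = binned.O, binned.E
    chi2 = float(((O - E) ** 2 / E).sum())
    df = len(O) - 1
    if df < 1:
        return chi2, df, float("nan"), float("nan")
    P = float(chi2_dist.sf(chi2, df))
    ss_tot = float(((O - O.mean()) ** 2).sum())
    ss_res = float(((O - E) ** 2).sum())
    R2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else
                                                   float("nan"))
    return chi2, df, P, R2


def _binned_sad(abundances: np.ndarray, fits: Sequence[VolkovParams],
                e_floor: float) -> BinnedSAD | None:
    if abundances.size == 0:
        return None
    edges = preston_octaves(int(abundances.max()))
    O = np.array([((abundances >= lo) & (abundances < hi)).sum()
                  for lo, hi in zip(edges[:-1], edges[1:])], dtype=float)
    E = _binned_expectation(fits, edges)
    return _pool_right(edges, O, E, e_floor)


class NicheNeutralHybridModel(BaseEstimator):
    """K-niche neutral hybrid fit with chi-square goodness of fit.

    Each column (time point) of the abundance matrix is one niche; its
    nonzero abundances get an independent zero-truncated neutral SAD fit.
    The metacommunity test compares the pooled observed SAD against the
    sum of per-niche expectations over Preston octaves (right tail pooled
    until every expected count reaches ``e_floor``); the local tests apply
    the same machinery niche by niche.

    Parameters
    ----------
    e_floor : minimum expected count per pooled bin (default 1.0).
    p_threshold : local-test pass threshold P_t (default 0.05).
    n_starts : optimizer multi-starts per niche.
    min_species : niches with fewer distinct species are excluded
        (flagged) rather than fitted (default 3).
    """

    def __init__(self, e_floor: float = 1.0, p_threshold: float = 0.05,
                 n_starts: int = 3, min_species: int = 3):
        self.e_floor = e_floor
        self.p_threshold = p_threshold
        self.n_starts = n_starts
        self.min_species = min_species

    def fit(self, X, y=None):
        counts = X.counts if isinstance(X, AbundanceMatrix) \
            else np.asarray(X, dtype=np.int64)
        subject = X.subject_id if isinstance(X, AbundanceMatrix) else ""
        S, T = counts.shape
        fits: list[VolkovParams | None] = []
        for i in range(T):
            col = counts[:, i]
            ab = col[col > 0]
            if ab.size < self.min_species:
                logger.info("niche %d: only %d species, excluded", i, ab.size)
                fits.append(None)
                continue
            p = fit_niche(ab, n_starts=self.n_starts)
            fits.append(p if p.converged else None)
        valid = [i for i, p in enumerate(fits) if p is not None]
        self.niche_fits_ = fits
        self.valid_niches_ = valid
        self.K_ = T

        vfits = [fits[i] for i in valid]
        if not vfits:
            logger.warning("no valid niche fits; empty NNH summary")
            self.result_ = None
            return self

        pooled = np.concatenate([counts[:, i][counts[:, i] > 0]
                                 for i in valid])
        binned = _binned_sad(pooled, vfits, self.e_floor)
        if binned is None or len(binned.O) < 2:
            chi2, df, P, R2 = float("nan"), 0, float("nan"), float("nan")
            logger.warning("metacommunity test undefined (<2 pooled bins)")
        else:
            chi2, df, P, R2 = _chi2_test(binned)

        local_P = np.full(T, np.nan)
        for i in valid:
            col = counts[:, i]
            b = _binned_sad(col[col > 0], [fits[i]], self.e_floor)
            if b is not None and len(b.O) >= 2:
                local_P[i] = _chi2_test(b)[2]
        valid_P = local_P[~np.isnan(local_P)]
        n_pass = int((valid_P > self.p_threshold).sum())
        pct = 100.0 * n_pass / valid_P.size if valid_P.size else 0.0

        summary = ResultRowNNH(
            subject_id=subject,
            J=float(np.mean([p.J for p in vfits])),
            S=float(np.mean([p.S for p in vfits])),
            theta=float(np.mean([p.theta for p in vfits])),
            m=float(np.mean([p.m for p in vfits])),
            x=float(np.mean([p.x for p in vfits])),
            gamma=float(np.mean([p.gamma for p in vfits])),
            R2=R2, chi2=chi2, P=P, N_pass=n_pass, pct_pass=pct)
        self.result_ = NNHFitResult(
            per_niche=vfits, K=T, chi2=chi2, df=df, P=P, R2=R2,
            N_pass=n_pass, pct_pass=pct, binned=binned, local_P=local_P,
            summary=summary)
        self.chi2_, self.df_, self.p_value_, self.r2_ = chi2, df, P, R2
        self.local_p_values_ = local_P
        self.n_pass_, self.pct_pass_ = n_pass, pct
        self.summary_ = summary
        return self

    def local_pass(self, P_t: float) -> tuple[int, float]:
        """(N_pass, pct_pass) of the per-niche tests at threshold P_t."""
        valid_P = self.local_p_values_[~np.isnan(self.local_p_values_)]
        if valid_P.size == 0:
            return 0, 0.0
        n = int((valid_P > P_t).sum())
        return n, 100.0 * n / valid_P.size


# ---------------------------------------------------------------------------
# Thin functional wrappers

def nnh_metacommunity_test(data, fits: Sequence[VolkovParams],
                           e_floor: float = 1.0) -> NNHFitResult:
    """Chi-square test of the summed per-niche SAD against the pooled data.

    ``fits`` must align with the columns of ``data`` (use None for
    excluded niches); convenience wrapper over the estimator.
    """
    model = NicheNeutralHybridModel(e_floor=e_floor)
    counts = data.counts if isinstance(data, AbundanceMatrix) \
        else np.asarray(data, dtype=np.int64)
    valid = [i for i, p in enumerate(fits) if p is not None]
    vfits = [fits[i] for i in valid]
    pooled = np.concatenate([counts[:, i][counts[:, i] > 0] for i in valid])
    binned = _binned_sad(pooled, vfits, e_floor)
    if binned is None or len(binned.O) < 2:
        raise ValueError("metacommunity test undefined: fewer than 2 bins")
    chi2, df, P, R2 = _chi2_test(binned)
    local_P = np.full(counts.shape[1], np.nan)
    summary = None
    return NNHFitResult(per_niche=list(vfits), K=counts.shape[1], chi2=chi2,
                        df=df, P=P, R2=R2, N_pass=0, pct_pass=0.0,
                        binned=binned, local_P=local_P, summary=summary)


def local_neutrality_tests(data, fits: Sequence[VolkovParams],
                           P_t: float = 0.05,
                           e_floor: float = 1.0) -> tuple[int, float]:
    """Per-niche chi-square tests; returns (N_pass, pct_pass) at P_t."""
    counts = data.counts if isinstance(data, AbundanceMatrix) \
        else np.asarray(data, dtype=np.int64)
    ps = []
    for i, p in enumerate(fits):
        if p is None:
            continue
        col = counts[:, i]
        b = _binned_sad(col[col > 0], [p], e_floor)
        if b is not None and len(b.O) >= 2:
            ps.append(_chi2_test(b)[2])
    if not ps:
        return 0, 0.0
    n_pass = int(sum(1 for p in ps if p > P_t))
    return n_pass, 100.0 * n_pass / len(ps)


def nnh_summary(fits: Sequence[VolkovParams], data=None,
                subject_id: str = "") -> ResultRowNNH:
    """Arithmetic means of per-niche (J, S, theta, m, x, gamma)."""
    vfits = [p for p in fits if p is not None]
    if not vfits:
        raise ValueError("no valid niche fits to summarize")
    return ResultRowNNH(
        subject_id=subject_id,
        J=float(np.mean([p.J for p in vfits])),
        S=float(np.mean([p.S for p in vfits])),
        theta=float(np.mean([p.theta for p in vfits])),
        m=float(np.mean([p.m for p in vfits])),
        x=float(np.mean([p.x for p in vfits])),
        gamma=float(np.mean([p.gamma for p in vfits])),
        R2=float("nan"), chi2=0.0, P=0.0, N_pass=0, pct_pass=0.0)
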