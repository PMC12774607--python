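"""Exact likelihoods for the gamma and gamma-sprinkling crossover models.

Model construction
------------------
Chiasmata on the four-strand bundle are a *stationary gamma renewal
process* with shape ``nu`` and rate ``2*nu*lam`` per Morgan, so the mean
inter-chiasma distance is ``1/(2*lam)`` Morgans. With no chromatid
interference each chiasma involves the transmitted chromatid independently
with probability 1/2, so the observed crossover process is the chiasma
process thinned by a fair coin. The thinned inter-arrival density is the
geometric mixture

    f*(y) = sum_{k>=1} 2^{-k} Gamma(y; k*nu, 2*nu*lam)

with matching CDF F*, and the stationary density of the first crossover
past the chromosome start is g*(y) = lam * (1 - F*(y)). The observed
process has intensity exactly ``lam`` crossovers per Morgan, so with
``lam = 1`` it reproduces the genetic map.

The gamma-sprinkling (Housworth-Stahl) model superposes an independent
homogeneous Poisson pathway of rate ``p`` per Morgan on an interfering
gamma pathway of rate ``lam = 1 - p``; the chromosome-level likelihood
sums over all 2^n assignments of the observed crossovers to the two
pathways.

All functions in this module work in **Morgans**; dataset-facing APIs
accept centimorgans and convert internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import special

from .data import CrossoverDataset, GroupScheme
from .errors import SeriesConvergenceError

__all__ = [
    "InterferenceParams",
    "NumericOptions",
    "thinned_interarrival",
    "stationary_first_point_logdensity",
    "prob_zero_observed",
    "gamma_pathway_loglik",
    "stahl_chromosome_loglik",
    "dataset_loglik",
]


@dataclass(frozen=True)
class InterferenceParams:
    """A (nu, p) pair for one group cell.

    ``nu`` is the unitless interference strength (nu = 1: no interference;
    larger nu: stronger interference). ``p`` is the proportion of
    crossovers from the non-interfering pathway; p = 0 is the pure gamma
    model.
    """

    nu: float
    p: float = 0.0

    def __post_init__(self):
        if not (self.nu > 0 and np.isfinite(self.nu)):
            raise ValueError(f"nu must be positive and finite, got {self.nu}")
        if not (0.0 <= self.p < 1.0):
            raise ValueError(f"p must lie in [0, 1), got {self.p}")


@dataclass(frozen=True)
class NumericOptions:
    """Numerical controls for the series and integral evaluations."""

    series_rel_tol: float = 1e-12
    series_max_terms: int = 500
    quad_rel_tol: float = 1e-8
    min_distance: float = 1e-6  # Morgans; matches the 1e-4 cM data rule

    def __post_init__(self):
        if min(self.series_rel_tol, self.quad_rel_tol, self.min_distance) <= 0:
            raise ValueError("all tolerances must be positive")
        if self.series_max_terms < 50:
            raise ValueError("series_max_terms must be >= 50")


_DEFAULT_OPTS = NumericOptions()


def _series_f_S(y, nu: float, lam: float, opts: NumericOptions):
    """Density f*(y) and survival S*(y) = 1 - F*(y) of the thinned
    inter-arrival distribution, vectorized over y.

    The survival series sum_k 2^{-k} Q(k*nu, b*y) is closed with its exact
    geometric tail once Q has saturated at 1; the density series is
    truncated when the running term no longer moves the sum.
    """
    y = np.asarray(y, dtype=float)
    b = 2.0 * nu * lam
    x = b * y
    logy = np.log(np.where(y > 0, y, 1.0))
    f = np.zeros_like(y)
    S = np.zeros_like(y)
    w = 1.0
    for k in range(1, opts.series_max_terms + 1):
        w *= 0.5
        a = k * nu
        Q = special.gammaincc(a, x)
        S += w * Q
        logpdf = a * math.log(b) - special.gammaln(a) + (a - 1.0) * logy - x
        term = w * np.exp(logpdf)
        f += term
        pdf_done = np.all(term <= opts.series_rel_tol * np.maximum(f, 1e-300))
        q_done = np.all(Q >= 1.0 - 1e-14)
        if pdf_done and q_done:
            S += w  # exact tail: sum_{j>k} 2^{-j} = 2^{-k}, with Q_j ~ 1
            return f, np.clip(S, 0.0, 1.0)
    raise SeriesConvergenceError(
        f"thinning series did not converge within {opts.series_max_terms} terms "
        f"(nu={nu}, lam={lam}, max y={float(np.max(y)) if y.size else 'NA'})"
    )


def thinned_interarrival(y, nu: float, lam: float = 1.0, opts: NumericOptions | None = None):
    """Log-density and CDF of the distance between successive observed
    crossovers (Morgans). At nu = 1 this is Exponential(lam)."""
    opts = opts or _DEFAULT_OPTS
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr <= 0):
        raise ValueError("inter-arrival distance must be positive")
    if not nu > 0:
        raise ValueError("nu must be positive")
    if not 0 < lam <= 1:
        raise ValueError("lam must lie in (0, 1]")
    f, S = _series_f_S(y_arr, nu, lam, opts)
    logf = np.log(np.maximum(f, 1e-300))
    cdf = 1.0 - S
    if np.isscalar(y) or np.asarray(y).ndim == 0:
        return float(logf), float(cdf)
    return logf, cdf


def _log_survival(y, nu: float, lam: float, opts: NumericOptions):
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    out = np.zeros_like(y_arr)
    pos = y_arr > 0
    if np.any(pos):
        _, S = _series_f_S(y_arr[pos], nu, lam, opts)
        out[pos] = np.log(np.maximum(S, 1e-300))
    return out


def stationary_first_point_logdensity(
    y, nu: float, lam: float = 1.0, opts: NumericOptions | None = None
):
    """Log-density of the first observed crossover past the chromosome
    start under the stationary renewal process: g*(y) = lam * (1 - F*(y))."""
    opts = opts or _DEFAULT_OPTS
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0):
        raise ValueError("position must be non-negative")
    res = math.log(lam) + _log_survival(y_arr, nu, lam, opts)
    if np.isscalar(y) or np.asarray(y).ndim == 0:
        return float(res[0])
    return res


def prob_zero_observed(L: float, nu: float, lam: float = 1.0, opts: NumericOptions | None = None) -> float:
    """Probability that a chromosome of length L Morgans carries no
    observed crossover from the gamma pathway:
    1 - int_0^L g*(t) dt = 1 - lam*L + lam * int_0^L F*(t) dt.

    The integral of F* is evaluated term by term in closed form:
    int_0^L P(a, b t) dt = L P(a, bL) - (a/b) P(a+1, bL).
    """
    opts = opts or _DEFAULT_OPTS
    if not L > 0:
        if L == 0:
            return 1.0
        raise ValueError("L must be positive")
    b = 2.0 * nu * lam
    x = b * L
    s = 0.0
    w = 1.0
    for k in range(1, opts.series_max_terms + 1):
        w *= 0.5
        a = k * nu
        P1 = special.gammainc(a, x)
        term = L * P1 - (a / b) * special.gammainc(a + 1.0, x)
        s += w * term
        if w * L * P1 < opts.series_rel_tol * max(s, 1e-300) and a > x:
            break
    else:
        raise SeriesConvergenceError(
            f"zero-probability series did not converge (nu={nu}, lam={lam}, L={L})"
        )
    p0 = 1.0 - lam * L + lam * s
    return float(min(max(p0, 1e-300), 1.0))


def gamma_pathway_loglik(
    positions, L: float, nu: float, lam: float = 1.0, opts: NumericOptions | None = None
) -> float:
    """Log-likelihood of sorted crossover positions (Morgans) on [0, L]
    under the stationary thinned gamma renewal process:
    log g*(y1) + sum log f*(gaps) + log(1 - F*(L - y_last)); the empty
    record contributes log of the zero-crossover probability."""
    opts = opts or _DEFAULT_OPTS
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        return math.log(prob_zero_observed(L, nu, lam, opts))
    if np.any(pos < 0) or np.any(pos > L):
        raise ValueError("positions must lie within [0, L]")
    if np.any(np.diff(pos) < opts.min_distance):
        raise ValueError("positions must be strictly increasing (min separation)")
    ll = stationary_first_point_logdensity(pos[0], nu, lam, opts)
    if pos.size > 1:
        logf, _ = thinned_interarrival(np.diff(pos), nu, lam, opts)
        ll += float(np.sum(logf))
    ll += float(_log_survival(L - pos[-1], nu, lam, opts)[0])
    return ll


def stahl_chromosome_loglik(
    positions,
    L: float,
    params: InterferenceParams,
    opts: NumericOptions | None = None,
    max_subset_n: int = 20,
) -> float:
    """Log-likelihood of one transmitted chromosome under the
    gamma-sprinkling model.

    Sums over all 2^n assignments of the observed crossovers to the
    interfering (gamma, rate 1-p) vs. non-interfering (Poisson, rate p)
    pathways, in log space. At p = 0 it reduces exactly to the pure gamma
    pathway with lam = 1.
    """
    opts = opts or _DEFAULT_OPTS
    pos = np.asarray(positions, dtype=float)
    nu, p = params.nu, params.p
    if p == 0.0:
        return gamma_pathway_loglik(pos, L, nu, 1.0, opts)
    lam = 1.0 - p
    n = pos.size
    if n > max_subset_n:
        raise ValueError(
            f"{n} crossovers on one chromosome exceeds the 2^n subset-sum guard "
            f"({max_subset_n}); not a biologically plausible record"
        )
    logp = math.log(p)
    terms = []
    for mask in range(1 << n):
        subset = pos[[bool(mask >> i & 1) for i in range(n)]]
        ll_gamma = gamma_pathway_loglik(subset, L, nu, lam, opts)
        terms.append(ll_gamma + (n - int(subset.size)) * logp)
    return float(special.logsumexp(terms) - p * L)


def dataset_loglik(
    data: CrossoverDataset,
    scheme: GroupScheme,
    params_by_group: Mapping[tuple[int, int], InterferenceParams],
    opts: NumericOptions | None = None,
    engine: str = "auto",
) -> float:
    """Total log-likelihood of a dataset: the sum of per-record
    gamma-sprinkling log-likelihoods, each with its sex-specific map length
    and its group cell's (nu, p).

    ``engine="exact"`` uses the scipy-based reference implementation above;
    ``engine="fast"`` uses the compiled kernel (identical model, different
    numerics: interpolation tables); ``"auto"`` picks the fast path for
    datasets with more than 200 records.
    """
    opts = opts or _DEFAULT_OPTS
    for rec in data.records:
        cell = scheme.cell_of(rec)
        if cell not in params_by_group:
            raise KeyError(f"no parameters supplied for group cell {cell}")
    if engine == "auto":
        engine = "fast" if len(data.records) > 200 else "exact"
    if engine == "fast":
        from .celldata import CellwiseData

        packed = CellwiseData.from_dataset(data, scheme)
        return sum(
            packed.cell_loglik(cell, params_by_group[cell].nu, params_by_group[cell].p)
            for cell in packed.cells
        )
    total = 0.0
    for rec in data.records:
        pars = params_by_group[scheme.cell_of(rec)]
        total += stahl_chromosome_loglik(
            rec.positions / 100.0, rec.length_cM / 100.0, pars, opts
        )
    return total
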