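"""Hierarchical group-effect model on link scales.

Interference strength and the non-interfering proportion vary across
groups of meioses (i = 1..m) and groups of chromosomes (j = 1..n) through
additive effects on link scales:

    log(nu_ij)  = beta0 + beta_i + beta_j
    logit(p_ij) = alpha0 + alpha_i + alpha_j

with independent normal priors: effects ~ N(0, sigma^2) (uncorrelated,
which shrinks them toward the shared intercept), intercepts ~ N(0,
intercept_sd^2). Without the sprinkling block (``include_sprinkling =
False``) p_ij = 0 exactly and the model reduces to the pure gamma model
with a single interference parameter per cell (nu0).

The additive parameterization is deliberately redundant (adding c to the
intercept and subtracting it from every group effect leaves every nu_ij
unchanged); the shrinkage prior is what makes the posterior proper along
that direction. A grouping dimension with a single level contributes an
effect that is wholly confounded with the intercept, so such effects are
fixed at zero and excluded from the sampled coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import CrossoverDataset, GroupScheme
from .likelihood import InterferenceParams, NumericOptions, dataset_loglik

__all__ = [
    "HierParams",
    "PriorSpec",
    "ParamLayout",
    "link_transform",
    "log_prior",
    "log_posterior",
]


@dataclass
class HierParams:
    """Intercepts and group effects on the link scales."""

    beta0: float
    beta_meiosis: np.ndarray
    beta_chrom: np.ndarray
    alpha0: float = 0.0
    alpha_meiosis: np.ndarray | None = None
    alpha_chrom: np.ndarray | None = None
    include_sprinkling: bool = True

    def __post_init__(self):
        self.beta_meiosis = np.asarray(self.beta_meiosis, dtype=float)
        self.beta_chrom = np.asarray(self.beta_chrom, dtype=float)
        if self.include_sprinkling:
            if self.alpha_meiosis is None:
                self.alpha_meiosis = np.zeros_like(self.beta_meiosis)
            if self.alpha_chrom is None:
                self.alpha_chrom = np.zeros_like(self.beta_chrom)
            self.alpha_meiosis = np.asarray(self.alpha_meiosis, dtype=float)
            self.alpha_chrom = np.asarray(self.alpha_chrom, dtype=float)
        vals = [self.beta0, self.beta_meiosis, self.beta_chrom]
        if self.include_sprinkling:
            vals += [self.alpha0, self.alpha_meiosis, self.alpha_chrom]
        for v in vals:
            if not np.all(np.isfinite(v)):
                raise ValueError("all hierarchical parameters must be finite")

    def validate_scheme(self, scheme: GroupScheme) -> None:
        if self.beta_meiosis.size != scheme.m or self.beta_chrom.size != scheme.n:
            raise ValueError(
                f"effect-vector lengths ({self.beta_meiosis.size}, "
                f"{self.beta_chrom.size}) do not match the scheme "
                f"(m={scheme.m}, n={scheme.n})"
            )
        if self.include_sprinkling and (
            self.alpha_meiosis.size != scheme.m or self.alpha_chrom.size != scheme.n
        ):
            raise ValueError("alpha effect-vector lengths do not match the scheme")


@dataclass(frozen=True)
class PriorSpec:
    """Prior scales (link scale): effects ~ N(0, sigma^2), intercepts
    ~ N(0, intercept_sd^2)."""

    sigma_nu: float = 1.0
    sigma_p: float = 1.0
    intercept_sd: float = 10.0

    def __post_init__(self):
        if min(self.sigma_nu, self.sigma_p, self.intercept_sd) <= 0:
            raise ValueError("prior scales must be positive")


def link_transform(h: HierParams, i: int, j: int) -> InterferenceParams:
    """Map link-scale parameters to the (nu, p) of cell (i, j)."""
    nu = math.exp(h.beta0 + h.beta_meiosis[i] + h.beta_chrom[j])
    if not h.include_sprinkling:
        return InterferenceParams(nu=nu, p=0.0)
    eta = h.alpha0 + h.alpha_meiosis[i] + h.alpha_chrom[j]
    p = 1.0 / (1.0 + math.exp(-eta))
    # logit^-1 maps R to (0, 1); clip away from 1 to keep lam > 0
    return InterferenceParams(nu=nu, p=min(p, 1.0 - 1e-12))


def params_by_group(h: HierParams, scheme: GroupScheme) -> dict[tuple[int, int], InterferenceParams]:
    h.validate_scheme(scheme)
    return {
        (i, j): link_transform(h, i, j)
        for i in range(scheme.m)
        for j in range(scheme.n)
    }


_LOG_2PI = math.log(2.0 * math.pi)


def _normal_logpdf_sum(values: np.ndarray, sd: float) -> float:
    values = np.atleast_1d(np.asarray(values, dtype=float))
    return float(
        -0.5 * np.sum((values / sd) ** 2)
        - values.size * (math.log(sd) + 0.5 * _LOG_2PI)
    )


def log_prior(h: HierParams, prior: PriorSpec) -> float:
    """Sum of independent normal log-densities over all parameters."""
    lp = _normal_logpdf_sum(np.array([h.beta0]), prior.intercept_sd)
    lp += _normal_logpdf_sum(h.beta_meiosis, prior.sigma_nu)
    lp += _normal_logpdf_sum(h.beta_chrom, prior.sigma_nu)
    if h.include_sprinkling:
        lp += _normal_logpdf_sum(np.array([h.alpha0]), prior.intercept_sd)
        lp += _normal_logpdf_sum(h.alpha_meiosis, prior.sigma_p)
        lp += _normal_logpdf_sum(h.alpha_chrom, prior.sigma_p)
    return lp


def log_posterior(
    h: HierParams,
    data: CrossoverDataset,
    scheme: GroupScheme,
    prior: PriorSpec | None = None,
    opts: NumericOptions | None = None,
    engine: str = "auto",
) -> float:
    """Unnormalized log-posterior: log_prior + dataset log-likelihood with
    cell parameters from the link transform."""
    prior = prior or PriorSpec()
    lp = log_prior(h, prior)
    if not data.records:
        return lp
    return lp + dataset_loglik(data, scheme, params_by_group(h, scheme), opts, engine)


@dataclass
class ParamLayout:
    """Mapping between HierParams and the flat coordinate vector the
    sampler and optimizer work on.

    Effect blocks for grouping dimensions with a single level are fixed at
    zero and carry no coordinates. ``reference_coding=True`` additionally
    pins the first effect of each sampled block to zero (the gauge used
    for maximum likelihood, where no prior breaks the additive redundancy).
    """

    m: int
    n: int
    include_sprinkling: bool
    reference_coding: bool = False
    names: list[str] = field(init=False)

    def __post_init__(self):
        lo = 1 if self.reference_coding else 0
        self._mb = list(range(lo, self.m)) if self.m > 1 else []
        self._nb = list(range(lo, self.n)) if self.n > 1 else []
        names = ["beta0"]
        names += [f"beta_m[{i}]" for i in self._mb]
        names += [f"beta_c[{j}]" for j in self._nb]
        if self.include_sprinkling:
            names += ["alpha0"]
            names += [f"alpha_m[{i}]" for i in self._mb]
            names += [f"alpha_c[{j}]" for j in self._nb]
        self.names = names

    @property
    def dim(self) -> int:
        return len(self.names)

    def unpack(self, theta: np.ndarray) -> HierParams:
        theta = np.asarray(theta, dtype=float)
        k = 0
        beta0 = theta[k]
        k += 1
        bm = np.zeros(self.m)
        for i in self._mb:
            bm[i] = theta[k]
            k += 1
        bc = np.zeros(self.n)
        for j in self._nb:
            bc[j] = theta[k]
            k += 1
        if not self.include_sprinkling:
            return HierParams(beta0, bm, bc, include_sprinkling=False)
        alpha0 = theta[k]
        k += 1
        am = np.zeros(self.m)
        for i in self._mb:
            am[i] = theta[k]
            k += 1
        ac = np.zeros(self.n)
        for j in self._nb:
            ac[j] = theta[k]
            k += 1
        return HierParams(beta0, bm, bc, alpha0, am, ac, include_sprinkling=True)

    def pack(self, h: HierParams) -> np.ndarray:
        out = [h.beta0]
        out += [h.beta_meiosis[i] for i in self._mb]
        out += [h.beta_chrom[j] for j in self._nb]
        if self.include_sprinkling:
            out += [h.alpha0]
            out += [h.alpha_meiosis[i] for i in self._mb]
            out += [h.alpha_chrom[j] for j in self._nb]
        return np.asarray(out, dtype=float)

    def default_init(self) -> np.ndarray:
        """Link-scale start: nu near typical mouse values (beta0 = log 10),
        all effects zero; alpha0 = 0 when sprinkling is on."""
        theta = np.zeros(self.dim)
        theta[0] = math.log(10.0)
        return theta
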