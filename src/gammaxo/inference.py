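"""Inference: Metropolis-coupled MCMC, posterior summaries, maximum
likelihood, model comparison, and group contrasts.

The sampler is a component-wise Gaussian random-walk Metropolis algorithm
run as several coupled chains at tempered posteriors (posterior^T with a
geometric temperature ladder), exchanging states by Metropolis swap
proposals; inference uses the unheated (cold) chain only. Proposal scales
adapt during burn-in only (Robbins-Monro on the log scale, targeting a
rejection rate of about 0.4) and are frozen afterwards, preserving
detailed balance for the retained draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .celldata import CellwiseData
from .data import CrossoverDataset, GroupScheme, assign_groups
from .hier import HierParams, ParamLayout, PriorSpec, link_transform, log_prior
from .likelihood import InterferenceParams, NumericOptions

__all__ = [
    "McmcOptions",
    "PosteriorSamples",
    "PosteriorSummary",
    "FitResult",
    "LrtResult",
    "CellPosterior",
    "CallableTarget",
    "run_mcmc",
    "summarize",
    "fit_ml",
    "lrt_aic",
    "posterior_contrasts",
    "fit_mcmc",
    "per_chromosome_nu",
    "nu_length_correlation",
]


@dataclass(frozen=True)
class McmcOptions:
    """Sampler controls. Defaults follow the genome-wide analysis:
    25,000 iterations with the first 5,000 discarded as burn-in, proposal
    scales tuned toward a rejection rate of about 0.4."""

    n_iter: int = 25_000
    burn_in: int = 5_000
    n_chains: int = 3
    temperatures: tuple[float, ...] | None = None  # default geometric 0.7^k
    target_rejection: float = 0.4
    swap_interval: int = 1
    seed: int = 0
    initial_scale: float = 0.1
    adapt_rate: float = 1.0
    adapt_decay: float = 0.6

    def __post_init__(self):
        if not 0 < self.burn_in < self.n_iter:
            raise ValueError("require 0 < burn_in < n_iter")
        if not 0 < self.target_rejection < 1:
            raise ValueError("target_rejection must be in (0, 1)")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        temps = self.ladder
        if temps[0] != 1.0:
            raise ValueError("the first (cold) temperature must be 1")
        if len(temps) != self.n_chains:
            raise ValueError("temperature ladder length must equal n_chains")

    @property
    def ladder(self) -> tuple[float, ...]:
        if self.temperatures is not None:
            return tuple(self.temperatures)
        return tuple(0.7 ** k for k in range(self.n_chains))


class CallableTarget:
    """Adapter exposing an arbitrary log-density as a sampling target
    (a single likelihood 'cell', no prior term)."""

    def __init__(self, logpdf: Callable[[np.ndarray], float], dim: int,
                 init: np.ndarray | None = None, names: Sequence[str] | None = None):
        self._logpdf = logpdf
        self.dim = dim
        self.names = list(names) if names else [f"x[{k}]" for k in range(dim)]
        self._init = np.zeros(dim) if init is None else np.asarray(init, float)

    @property
    def n_cells(self) -> int:
        return 1

    def default_init(self) -> np.ndarray:
        return self._init.copy()

    def log_prior(self, theta: np.ndarray) -> float:
        return 0.0

    def cell_loglik(self, cell_idx: int, theta: np.ndarray) -> float:
        return float(self._logpdf(theta))

    def coord_cells(self, k: int) -> list[int]:
        return [0]


class CellPosterior:
    """The hierarchical interference posterior, organized by group cell so
    that a component-wise proposal only re-evaluates the cells its
    coordinate touches."""

    def __init__(
        self,
        data: CrossoverDataset,
        scheme: GroupScheme,
        prior: PriorSpec | None = None,
        include_sprinkling: bool = True,
        opts: NumericOptions | None = None,
    ):
        self.scheme = scheme
        self.prior = prior or PriorSpec()
        self.layout = ParamLayout(scheme.m, scheme.n, include_sprinkling)
        self.packed = CellwiseData.from_dataset(data, scheme)
        self.cells = self.packed.cells
        self._cell_index = {c: k for k, c in enumerate(self.cells)}
        self.dim = self.layout.dim
        self.names = self.layout.names
        self._coord_cells = [
            self._cells_touched(name) for name in self.layout.names
        ]

    def _cells_touched(self, name: str) -> list[int]:
        if name in ("beta0", "alpha0"):
            return list(range(len(self.cells)))
        kind, idx = name.split("[")
        idx = int(idx.rstrip("]"))
        if kind.endswith("_m"):
            return [k for k, (i, _) in enumerate(self.cells) if i == idx]
        return [k for k, (_, j) in enumerate(self.cells) if j == idx]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def default_init(self) -> np.ndarray:
        return self.layout.default_init()

    def log_prior(self, theta: np.ndarray) -> float:
        return log_prior(self.layout.unpack(theta), self.prior)

    def cell_loglik(self, cell_idx: int, theta: np.ndarray) -> float:
        h = self.layout.unpack(theta)
        i, j = self.cells[cell_idx]
        pars = link_transform(h, i, j)
        return self.packed.cell_loglik((i, j), pars.nu, pars.p)

    def coord_cells(self, k: int) -> list[int]:
        return self._coord_cells[k]

    def hier_params(self, theta: np.ndarray) -> HierParams:
        return self.layout.unpack(theta)


@dataclass
class PosteriorSamples:
    """Post-burn-in cold-chain draws plus diagnostics."""

    draws: np.ndarray  # (n_draws, dim)
    names: list[str]
    acceptance_rate: np.ndarray  # per coordinate, cold chain, post burn-in
    swap_acceptance: float
    options: McmcOptions
    posterior: object | None = None

    @property
    def rejection_rate(self) -> np.ndarray:
        return 1.0 - self.acceptance_rate

    def derived_draws(self) -> dict[str, np.ndarray]:
        """Per-draw (nu, p) for every group cell, on the natural scale."""
        post = self.posterior
        if not isinstance(post, CellPosterior):
            raise ValueError("derived quantities need a CellPosterior-backed run")
        scheme = post.scheme
        out: dict[str, np.ndarray] = {}
        for (i, j) in post.cells:
            label = f"{scheme.meiosis_labels[i]},{scheme.chromosome_labels[j]}"
            nu = np.empty(len(self.draws))
            p = np.empty(len(self.draws))
            for d, theta in enumerate(self.draws):
                pars = link_transform(post.layout.unpack(theta), i, j)
                nu[d] = pars.nu
                p[d] = pars.p
            out[f"nu[{label}]"] = nu
            if post.layout.include_sprinkling:
                out[f"p[{label}]"] = p
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=self.names)
        if isinstance(self.posterior, CellPosterior):
            for k, v in self.derived_draws().items():
                df[k] = v
        return df


@dataclass
class _ChainState:
    theta: np.ndarray
    prior_lp: float
    cell_lls: np.ndarray
    log_scales: np.ndarray

    @property
    def logpost(self) -> float:
        return self.prior_lp + float(self.cell_lls.sum())


def run_mcmc(posterior, init: np.ndarray | None = None, opts: McmcOptions | None = None) -> PosteriorSamples:
    """Metropolis-coupled component-wise random-walk sampler.

    ``posterior`` is a target object (:class:`CellPosterior` or
    :class:`CallableTarget`). Fully reproducible given ``opts.seed``.
    """
    opts = opts or McmcOptions()
    rng = np.random.default_rng(np.random.SeedSequence(opts.seed))
    dim = posterior.dim
    theta0 = np.asarray(init, float) if init is not None else posterior.default_init()
    if theta0.size != dim:
        raise ValueError(f"init has dimension {theta0.size}, expected {dim}")

    ladder = opts.ladder
    chains: list[_ChainState] = []
    for _ in range(opts.n_chains):
        prior_lp = posterior.log_prior(theta0)
        cell_lls = np.asarray(
            [posterior.cell_loglik(c, theta0) for c in range(posterior.n_cells)]
        )
        lp = prior_lp + cell_lls.sum()
        if not np.isfinite(lp):
            raise ValueError(f"log-posterior not finite at the initial state ({lp})")
        chains.append(
            _ChainState(
                theta0.copy(), prior_lp, cell_lls,
                np.full(dim, math.log(opts.initial_scale)),
            )
        )

    n_keep = opts.n_iter - opts.burn_in
    draws = np.empty((n_keep, dim))
    acc_counts = np.zeros(dim)
    acc_total = np.zeros(dim)
    swap_acc = 0
    swap_tot = 0
    target_accept = 1.0 - opts.target_rejection

    for it in range(opts.n_iter):
        adapting = it < opts.burn_in
        gamma_t = opts.adapt_rate / (it + 1.0) ** opts.adapt_decay
        for c, state in enumerate(chains):
            temp = ladder[c]
            for k in range(dim):
                prop = state.theta.copy()
                prop[k] += math.exp(state.log_scales[k]) * rng.standard_normal()
                new_prior = posterior.log_prior(prop)
                touched = posterior.coord_cells(k)
                new_lls = state.cell_lls.copy()
                for cell in touched:
                    new_lls[cell] = posterior.cell_loglik(cell, prop)
                delta = (new_prior - state.prior_lp) + float(
                    new_lls[touched].sum() - state.cell_lls[touched].sum()
                )
                accept = math.log(rng.random()) < temp * delta
                if accept:
                    state.theta = prop
                    state.prior_lp = new_prior
                    state.cell_lls = new_lls
                if adapting:
                    state.log_scales[k] += gamma_t * ((1.0 if accept else 0.0) - target_accept)
                    if abs(state.log_scales[k]) > 30.0:
                        raise RuntimeError(
                            f"proposal-scale adaptation diverged on coordinate "
                            f"{posterior.names[k] if hasattr(posterior, 'names') else k} "
                            f"(log scale {state.log_scales[k]:.1f})"
                        )
                elif c == 0:
                    acc_total[k] += 1
                    if accept:
                        acc_counts[k] += 1
        if opts.n_chains > 1 and (it + 1) % opts.swap_interval == 0:
            a = int(rng.integers(0, opts.n_chains - 1))
            bidx = a + 1
            lp_a = chains[a].logpost
            lp_b = chains[bidx].logpost
            log_r = (ladder[a] - ladder[bidx]) * (lp_b - lp_a)
            swap_tot += 1
            if math.log(rng.random()) < log_r:
                chains[a], chains[bidx] = chains[bidx], chains[a]
                # proposal scales belong to the ladder position, not the state
                chains[a].log_scales, chains[bidx].log_scales = (
                    chains[bidx].log_scales, chains[a].log_scales,
                )
                swap_acc += 1
        if it >= opts.burn_in:
            draws[it - opts.burn_in] = chains[0].theta

    names = list(getattr(posterior, "names", [f"x[{k}]" for k in range(dim)]))
    return PosteriorSamples(
        draws=draws,
        names=names,
        acceptance_rate=np.where(acc_total > 0, acc_counts / np.maximum(acc_total, 1), np.nan),
        swap_acceptance=(swap_acc / swap_tot) if swap_tot else float("nan"),
        options=opts,
        posterior=posterior,
    )


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    q2_5: float
    q25: float
    q75: float
    q97_5: float
    hpdi_low: float
    hpdi_high: float
    ess: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def summarize(samples: np.ndarray, hdi_prob: float = 0.95) -> PosteriorSummary:
    """Posterior mean, central quantile intervals, shortest 95% HPDI, and
    effective sample size for one scalar's draws."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 100:
        raise ValueError(f"need at least 100 draws, got {x.size}")
    if np.allclose(x, x[0]):
        c = float(x[0])
        return PosteriorSummary(c, c, c, c, c, c, c, float(x.size))
    q = np.quantile(x, [0.025, 0.25, 0.75, 0.975])
    hdi = az.hdi(x, hdi_prob=hdi_prob)
    ess = float(az.ess(np.asarray(x)[None, :]))
    return PosteriorSummary(
        mean=float(x.mean()),
        q2_5=float(q[0]), q25=float(q[1]), q75=float(q[2]), q97_5=float(q[3]),
        hpdi_low=float(hdi[0]), hpdi_high=float(hdi[1]),
        ess=ess,
    )


def posterior_contrasts(
    samples: "PosteriorSamples | Mapping[str, np.ndarray]",
    pairs: Sequence[tuple[str, str]],
) -> dict[str, PosteriorSummary]:
    """Per-draw ratios between derived quantities (e.g. nu[M,all] /
    nu[F,all]), then summarized on the ratio scale. Accepts either a
    sampler result or a plain mapping of named draw vectors."""
    derived = samples if isinstance(samples, Mapping) else samples.derived_draws()
    out = {}
    for num, den in pairs:
        ratio = derived[num] / derived[den]
        out[f"{num}/{den}"] = summarize(ratio)
    return out


@dataclass
class FitResult:
    params: HierParams
    loglik: float
    n_params: int
    per_cell: dict[tuple[int, int], InterferenceParams]
    converged: bool

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


def fit_ml(
    data: CrossoverDataset,
    scheme: GroupScheme,
    model: str = "sprinkling",
    n_starts: int = 5,
    seed: int = 0,
    opts: NumericOptions | None = None,
) -> FitResult:
    """Maximum likelihood on the link scale (no prior), reference coding
    (first effect of each multi-level block pinned at 0), derivative-free
    Nelder-Mead from multiple seeded starts."""
    if model not in ("gamma", "sprinkling"):
        raise ValueError("model must be 'gamma' or 'sprinkling'")
    include_sprinkling = model == "sprinkling"
    layout = ParamLayout(scheme.m, scheme.n, include_sprinkling, reference_coding=True)
    packed = CellwiseData.from_dataset(data, scheme)
    cells = packed.cells

    def neg_loglik(theta: np.ndarray) -> float:
        if np.any(np.abs(theta) > 50):
            return 1e12
        h = layout.unpack(theta)
        total = 0.0
        for (i, j) in cells:
            pars = link_transform(h, i, j)
            total += packed.cell_loglik((i, j), pars.nu, pars.p)
        return -total if np.isfinite(total) else 1e12

    rng = np.random.default_rng(seed)
    start0 = layout.default_init()
    if include_sprinkling:
        start0[layout.names.index("alpha0")] = -4.0  # p ~ 0.018
    starts = [start0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(start0 + rng.normal(0.0, 0.5, size=layout.dim))

    best = None
    any_converged = False
    for s in starts:
        res = optimize.minimize(
            neg_loglik, s, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000 * layout.dim},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise RuntimeError("maximum-likelihood optimization failed from all starts")
    h = layout.unpack(best.x)
    per_cell = {(i, j): link_transform(h, i, j) for (i, j) in cells}
    return FitResult(
        params=h,
        loglik=-float(best.fun),
        n_params=layout.dim,
        per_cell=per_cell,
        converged=any_converged,
    )


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    pvalue: float
    delta_aic: float


def lrt_aic(fit_null: FitResult, fit_alt: FitResult) -> LrtResult:
    """Likelihood-ratio test of nested fits plus the AIC difference.

    statistic = -2 (l0 - l1); p from the chi-squared upper tail with
    df = difference in parameter count; delta_aic = statistic - 2 df.
    """
    df = fit_alt.n_params - fit_null.n_params
    if df <= 0:
        raise ValueError("alternative must have more parameters than the null")
    statistic = -2.0 * (fit_null.loglik - fit_alt.loglik)
    if statistic < -1e-4:
        raise ValueError(
            f"negative LRT statistic ({statistic:.6f}): the alternative fit is "
            "worse than the null, which signals optimizer failure"
        )
    statistic = max(statistic, 0.0)
    pvalue = float(stats.chi2.sf(statistic, df))
    return LrtResult(statistic, df, pvalue, statistic - 2.0 * df)


def fit_mcmc(
    data: CrossoverDataset,
    scheme: GroupScheme,
    model: str = "sprinkling",
    prior: PriorSpec | None = None,
    mcmc: McmcOptions | None = None,
    init: np.ndarray | None = None,
) -> PosteriorSamples:
    """Convenience wrapper: build the cell posterior and run the sampler."""
    post = CellPosterior(
        data, scheme, prior=prior, include_sprinkling=(model == "sprinkling")
    )
    return run_mcmc(post, init=init, opts=mcmc)


@dataclass
class NuLengthCorrelation:
    rho: float
    pvalue: float
    degenerate: bool


def nu_length_correlation(table: pd.DataFrame) -> NuLengthCorrelation:
    """Spearman rank correlation (average ranks for ties, t approximation)
    between per-chromosome nu estimates and sex-specific genetic length,
    over all sex x chromosome points."""
    nu = table["nu"].to_numpy(dtype=float)
    length = table["length_cM"].to_numpy(dtype=float)
    if np.allclose(nu, nu[0]) or np.allclose(length, length[0]):
        return NuLengthCorrelation(0.0, 1.0, True)
    rho, pval = stats.spearmanr(nu, length)
    return NuLengthCorrelation(float(rho), float(pval), False)


def per_chromosome_nu(
    data: CrossoverDataset,
    prior: PriorSpec | None = None,
    mcmc: McmcOptions | None = None,
) -> tuple[pd.DataFrame, NuLengthCorrelation]:
    """Per-(sex, chromosome) interference strength under the reduced
    (pure gamma) model — posterior means from the hierarchical model with
    one chromosome group per chromosome — and its rank correlation with
    sex-specific genetic map length over all sex x chromosome points."""
    scheme = assign_groups(data, "by_sex_and_chromosome")
    samples = fit_mcmc(data, scheme, model="gamma", prior=prior, mcmc=mcmc)
    derived = samples.derived_draws()
    rows = []
    for j, chrom in enumerate(scheme.chromosome_labels):
        for i, sex in enumerate(scheme.meiosis_labels):
            rows.append(
                {
                    "chromosome": chrom,
                    "sex": sex,
                    "length_cM": data.map.length(chrom, sex),
                    "nu": float(derived[f"nu[{sex},{chrom}]"].mean()),
                }
            )
    table = pd.DataFrame(rows)
    return table, nu_length_correlation(table)
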