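"""Crossover simulation under the gamma-sprinkling model.

The interfering pathway draws a chiasma train from a gamma renewal
process (shape nu, rate 2*nu*(1-p) per Morgan) started well before the
chromosome so the process is stationary at position 0, then thins it with
an independent fair coin per chiasma (no chromatid interference). The
non-interfering pathway adds a homogeneous Poisson process of rate p per
Morgan. The union has intensity exactly 1 crossover per Morgan, matching
the genetic map by construction.

This module doubles as the package's synthetic-data generator: the
default :class:`SimSpec` emulates the Collaborative Cross G2 data —
474 fully observed meioses per sex over 19 autosomes with sex-specific
map lengths totalling 1,355 cM (female) and 1,221 cM (male).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import (
    CrossoverDataset,
    GeneticMapTable,
    TransmittedChromosome,
    default_mouse_map,
)
from .likelihood import InterferenceParams

#: Length of the stationarity burn-in, in units of mean inter-chiasma
#: distances before position 0. After 20 renewal intervals the process at
#: the origin is stationary to well below simulation noise.
BURNIN_INTERVALS = 20

#: Published genome-wide sex-specific estimates (posterior means) used as
#: the generator's default parameters.
DEFAULT_PARAMS = {
    "F": InterferenceParams(nu=11.2, p=0.0094),
    "M": InterferenceParams(nu=18.6, p=0.027),
}


def simulate_chromosome(nu: float, p: float, L_cM: float, rng: np.random.Generator) -> np.ndarray:
    """Sorted crossover positions (cM) for one transmitted chromatid."""
    if not (nu > 0 and 0 <= p < 1 and L_cM > 0):
        raise ValueError("require nu > 0, 0 <= p < 1, L_cM > 0")
    L = L_cM / 100.0
    lam = 1.0 - p
    b = 2.0 * nu * lam
    mean_gap = nu / b  # = 1/(2*lam)
    T = BURNIN_INTERVALS * mean_gap
    out = []
    t = -T
    while True:
        t += rng.gamma(nu, 1.0 / b)
        if t >= L:
            break
        if t >= 0.0 and rng.random() < 0.5:
            out.append(t)
    if p > 0.0:
        n_extra = rng.poisson(p * L)
        out.extend(rng.uniform(0.0, L, n_extra).tolist())
    return np.sort(np.asarray(out)) * 100.0


def simulate_counts(
    nu: float,
    p: float,
    L_cM: float,
    n_rep: int,
    rng: np.random.Generator,
    batch: int = 100_000,
) -> np.ndarray:
    """Vectorized crossover *counts* for many replicate chromatids.

    Used for large Monte-Carlo checks against the likelihood (count-class
    frequencies at 1e6 replicates are impractical one chromatid at a
    time).
    """
    L = L_cM / 100.0
    lam = 1.0 - p
    b = 2.0 * nu * lam
    T = BURNIN_INTERVALS * (nu / b)
    span = T + L
    counts = np.empty(n_rep, dtype=np.int64)
    done = 0
    while done < n_rep:
        m = min(batch, n_rep - done)
        k = int(2.0 * lam * span + 12.0 * np.sqrt(2.0 * lam * span / min(nu, 1.0))) + 30
        gaps = rng.gamma(nu, 1.0 / b, size=(m, k))
        pos = np.cumsum(gaps, axis=1) - T
        while np.any(pos[:, -1] < L):
            extra = rng.gamma(nu, 1.0 / b, size=(m, k // 2 + 8))
            pos = np.concatenate([pos, pos[:, -1:] + np.cumsum(extra, axis=1)], axis=1)
        keep = (pos >= 0.0) & (pos < L) & (rng.random(pos.shape) < 0.5)
        c = keep.sum(axis=1)
        if p > 0.0:
            c = c + rng.poisson(p * L, size=m)
        counts[done : done + m] = c
        done += m
    return counts


@dataclass
class SimSpec:
    """Study design for the synthetic-data generator."""

    params: Mapping[str, InterferenceParams] = field(
        default_factory=lambda: dict(DEFAULT_PARAMS)
    )
    map_table: GeneticMapTable = field(default_factory=default_mouse_map)
    n_meioses_per_sex: int = 474
    seed: int = 0
    #: optional per-(sex, chromosome) overrides of the sex-level params
    chromosome_params: Mapping[tuple[str, str], InterferenceParams] | None = None

    def __post_init__(self):
        if self.n_meioses_per_sex < 1:
            raise ValueError("n_meioses_per_sex must be >= 1")


def simulate_dataset(spec: SimSpec) -> CrossoverDataset:
    """One :class:`CrossoverDataset` drawn from the generator: every
    meiosis x chromosome cell present, reproducible given the seed."""
    rng = np.random.default_rng(spec.seed)
    chroms = [c for c in spec.map_table.chromosomes if c != "X"]
    records = []
    for sex in spec.params:
        for idx in range(spec.n_meioses_per_sex):
            mid = f"{sex}{idx + 1:04d}"
            for chrom in chroms:
                pars = spec.params[sex]
                if spec.chromosome_params:
                    pars = spec.chromosome_params.get((sex, chrom), pars)
                L = spec.map_table.length(chrom, sex)
                pos = simulate_chromosome(pars.nu, pars.p, L, rng)
                records.append(TransmittedChromosome(mid, sex, chrom, L, pos))
    return CrossoverDataset(records, spec.map_table)


@dataclass
class PpcResult:
    """Posterior predictive comparison of inter-crossover distances."""

    table: pd.DataFrame  # columns: sex, bin_left_cM, observed_freq, simulated_freq
    discrepancy: dict[str, float]  # per sex: max |observed - simulated| bin freq
    replicate_discrepancies: dict[str, np.ndarray]  # per sex: same statistic
    # for each simulated replicate against the mean of the others


def _distances_by_sex(data: CrossoverDataset) -> dict[str, np.ndarray]:
    out: dict[str, list] = {}
    for rec in data.records:
        if rec.n_crossovers >= 2:
            out.setdefault(rec.sex, []).extend(np.diff(rec.positions).tolist())
    return {s: np.asarray(v) for s, v in out.items()}


def posterior_predictive_check(
    params: Mapping[str, InterferenceParams],
    data: CrossoverDataset,
    n_sim: int = 20,
    bin_width_cM: float = 2.0,
    seed: int = 0,
) -> PpcResult:
    """Simulate ``n_sim`` replicate datasets with the observed study
    structure at the given (posterior-mean) parameters and compare binned
    inter-crossover distance frequencies with the observed data."""
    obs = _distances_by_sex(data)
    sexes = sorted(obs)
    n_meioses = {s: 0 for s in sexes}
    for s in sexes:
        n_meioses[s] = sum(1 for mid in data.meioses if data.sex_of(mid) == s)
    max_d = max(float(v.max()) for v in obs.values() if v.size)
    edges = np.arange(0.0, max_d + 2 * bin_width_cM, bin_width_cM)

    sim_hists: dict[str, list] = {s: [] for s in sexes}
    for r in range(n_sim):
        spec = SimSpec(
            params={s: params[s] for s in sexes},
            map_table=data.map,
            n_meioses_per_sex=max(n_meioses.values()),
            seed=seed + 7919 * (r + 1),
        )
        rep = simulate_dataset(spec)
        rep_d = _distances_by_sex(rep)
        for s in sexes:
            d = rep_d.get(s, np.empty(0))
            h, _ = np.histogram(d, bins=edges)
            sim_hists[s].append(h / max(d.size, 1))

    rows = []
    discrepancy = {}
    rep_disc = {}
    for s in sexes:
        h_obs, _ = np.histogram(obs[s], bins=edges)
        f_obs = h_obs / max(obs[s].size, 1)
        sims = np.vstack(sim_hists[s])
        f_sim = sims.mean(axis=0)
        discrepancy[s] = float(np.max(np.abs(f_obs - f_sim)))
        rd = []
        for r in range(n_sim):
            others = np.delete(sims, r, axis=0).mean(axis=0)
            rd.append(float(np.max(np.abs(sims[r] - others))))
        rep_disc[s] = np.asarray(rd)
        for i, left in enumerate(edges[:-1]):
            rows.append(
                {
                    "sex": s,
                    "bin_left_cM": float(left),
                    "observed_freq": float(f_obs[i]),
                    "simulated_freq": float(f_sim[i]),
                }
            )
    return PpcResult(pd.DataFrame(rows), discrepancy, rep_disc)
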