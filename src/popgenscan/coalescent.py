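"""Hudson-style coalescent simulator and null distributions for D and H.

A single non-recombining locus is simulated under the standard coalescent
with piecewise-constant population size.  Time is measured in units of 4N0
generations (the ms convention): with k lineages in an epoch of relative
size lambda the waiting time to the next coalescence is exponential with
rate k(k-1)/lambda, and mutations fall on branches at rate theta per unit
branch length (theta = 4*N0*mu per locus), so that E[S] = theta * a_n and
E[T_MRCA] = 0.5 for n = 2 under constant size.

Two mutation modes are supported: ``theta`` (Poisson number of mutations)
and ``fixed_S`` (exactly S mutations placed multinomially in proportion to
branch length, Hudson's ``-s`` semantics — not identical to rejection
sampling of the theta model conditional on S, but the standard conditioning
used for window-wise null bands).  Mutations follow the infinite-sites
model; each one is fully described by the number of leaves its branch
subtends, which is all the SFS statistics need.

Bottleneck (or any piecewise-constant) demography can be given either as a
fixed :class:`DemographyModel` or as a table of posterior epoch-parameter
draws, one row sampled per replicate with replacement.
"""

from __future__ import annotations

import math
import random
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diversity import (NeutralityConstants, UndefinedStatisticError,
                        UnfoldedSFS, fay_wu_H_normalized, sfs_theta_pi,
                        tajimas_D)


@dataclass(frozen=True)
class DemographyModel:
    """Piecewise-constant population size, ms time units (4N0 generations).

    ``epochs`` is an ordered list of (start_time, relative_size); the first
    epoch starts at 0.  Sizes are N/N0 > 0.
    """

    epochs: tuple[tuple[float, float], ...] = ((0.0, 1.0),)

    def __post_init__(self) -> None:
        if self.epochs[0][0] != 0.0:
            raise ValueError("first epoch must start at time 0")
        times = [t for t, _ in self.epochs]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if any(s <= 0 for _, s in self.epochs):
            raise ValueError("all relative sizes must be > 0")


CONSTANT_SIZE = DemographyModel()


def demography_from_row(row: pd.Series | dict) -> DemographyModel:
    """Build a DemographyModel from one posterior-draw table row.

    Expected columns: ``start_1, size_1, start_2, size_2, ...`` for the
    epochs after the present-day epoch (which is implicitly (0, 1) unless a
    ``size_0`` column overrides its size).
    """
    row = dict(row)
    epochs = [(0.0, float(row.get("size_0", 1.0)))]
    k = 1
    while f"start_{k}" in row and not pd.isna(row[f"start_{k}"]):
        epochs.append((float(row[f"start_{k}"]), float(row[f"size_{k}"])))
        k += 1
    return DemographyModel(tuple(epochs))


def load_posterior_draws(path: str | Path) -> pd.DataFrame:
    """Read a TSV of demographic posterior draws (one epoch set per row)."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: empty posterior-draws table")
    return df


# ---------------------------------------------------------------------------
# genealogy simulation
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """One realized coalescent tree.

    ``branches`` holds the 2n-2 branches as (leaf_bitmask, length) pairs —
    bit i set means sampled leaf i descends from the branch — which is
    sufficient labeled history to assign mutations to lineage subsets.
    """

    n: int
    branches: list[tuple[int, float]]
    tmrca: float

    @property
    def total_length(self) -> float:
        return sum(length for _, length in self.branches)

    def leaf_count_branches(self) -> list[tuple[int, float]]:
        return [(m.bit_count(), length) for m, length in self.branches]


def simulate_genealogy(n: int, demography: DemographyModel,
                       rng: random.Random) -> Genealogy:
    """Simulate one standard-coalescent genealogy under *demography*.

    With k lineages in an epoch of relative size lambda, the waiting time to
    the next coalescence is exponential with rate k(k-1)/lambda (time in 4N0
    generations); epoch boundaries are handled by the memoryless restart.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    demography = demography or CONSTANT_SIZE
    epochs = demography.epochs
    masks = [1 << i for i in range(n)]
    births = [0.0] * n
    branches: list[tuple[int, float]] = []
    t = 0.0
    ei = 0
    k = n
    expo = rng.expovariate
    while k > 1:
        lam = epochs[ei][1]
        wait = expo(k * (k - 1) / lam)
        boundary = epochs[ei + 1][0] if ei + 1 < len(epochs) else math.inf
        if t + wait >= boundary:
            t = boundary
            ei += 1
            continue
        t += wait
        i = rng.randrange(k)
        j = rng.randrange(k - 1)
        if j >= i:
            j += 1
        if j < i:
            i, j = j, i
        branches.append((masks[i], t - births[i]))
        branches.append((masks[j], t - births[j]))
        masks[i] |= masks[j]
        births[i] = t
        masks[j] = masks[k - 1]
        births[j] = births[k - 1]
        masks.pop()
        births.pop()
        k -= 1
    return Genealogy(n=n, branches=branches, tmrca=t)


# ---------------------------------------------------------------------------
# mutation dropping
# ---------------------------------------------------------------------------

def drop_mutations(tree: Genealogy, mode: str, value: float,
                   rng: random.Random) -> np.ndarray:
    """Place mutations on a genealogy; return SFS counts xi_1..xi_{n-1}.

    ``mode='fixed_S'`` places exactly ``value`` mutations multinomially in
    proportion to branch length; ``mode='theta'`` draws a Poisson number
    with mean theta * total_length.  Infinite sites: every mutation is its
    own column, contributing to xi_i where i is the subtended leaf count.
    """
    n = tree.n
    leaf_counts = []
    cum = []
    acc = 0.0
    for m, length in tree.branches:
        c = m.bit_count()
        if 1 <= c <= n - 1:           # a branch subtending all n is invisible
            leaf_counts.append(c)
            acc += length
            cum.append(acc)
    total = acc
    xi = np.zeros(n - 1, dtype=np.int64)
    if mode == "fixed_S":
        nmut = int(value)
    elif mode == "theta":
        nmut = _poisson(value * total, rng)
    else:
        raise ValueError(f"unknown mutation mode {mode!r}")
    if total <= 0.0:
        if nmut > 0:
            raise ValueError("cannot place mutations on a zero-length tree")
        return xi
    for _ in range(nmut):
        b = bisect_right(cum, rng.random() * total)
        if b == len(cum):
            b -= 1
        xi[leaf_counts[b] - 1] += 1
    return xi


def _poisson(mean: float, rng: random.Random) -> int:
    """Poisson draw via inversion (small means) or normal tail handoff."""
    if mean <= 0.0:
        return 0
    if mean < 30.0:
        L = math.exp(-mean)
        k = 0
        p = 1.0
        while True:
            p *= rng.random()
            if p <= L:
                return k
            k += 1
    # split recursively: Poisson(m) = Poisson(m/2) + Poisson(m/2)
    half = mean / 2.0
    return _poisson(half, rng) + _poisson(half, rng)


# ---------------------------------------------------------------------------
# replicate statistics and null distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoalescentConfig:
    """Everything needed to reproduce one batch of replicate statistics."""

    n: int
    mode: str                       # 'fixed_S' or 'theta'
    value: float                    # S or theta (per locus)
    replicates: int
    seed: int
    demography: DemographyModel = CONSTANT_SIZE
    posterior_draws: pd.DataFrame | None = None   # overrides `demography`

    def __post_init__(self) -> None:
        if self.n < 2 or self.replicates < 1 or self.value < 0:
            raise ValueError(f"invalid config {self}")


def _statistic_from_sfs(xi: np.ndarray, n: int, statistic: str) -> float:
    S = int(xi.sum())
    if S == 0:
        return math.nan
    if statistic == "D":
        return tajimas_D(S, sfs_theta_pi(xi, n), n)
    if statistic == "H_norm":
        return fay_wu_H_normalized(UnfoldedSFS(n=n, xi=xi, sites_polarized=S))
    raise ValueError(f"unknown statistic {statistic!r}")


def replicate_statistics(cfg: CoalescentConfig, statistic: str) -> np.ndarray:
    """Simulate cfg.replicates values of D or H; NaN where undefined (S=0)."""
    rng = random.Random(cfg.seed)
    draws = cfg.posterior_draws
    if draws is not None:
        models = [demography_from_row(draws.iloc[rng.randrange(len(draws))])
                  for _ in range(cfg.replicates)]
    else:
        models = None
    out = np.empty(cfg.replicates)
    for r in range(cfg.replicates):
        demog = models[r] if models is not None else cfg.demography
        tree = simulate_genealogy(cfg.n, demog, rng)
        xi = drop_mutations(tree, cfg.mode, cfg.value, rng)
        out[r] = _statistic_from_sfs(xi, cfg.n, statistic)
    return out


@dataclass
class NullDistribution:
    """Simulated null of one statistic plus the observed value's placement.

    Empirical p-values use (1 + #{at least as extreme})/(R + 1) over the
    defined replicates.  The one-tailed p is taken in the direction of the
    observed deviation (lower tail for negative observed values, upper for
    positive); the two-tailed p doubles the smaller tail, capped at 1.
    """

    statistic: str
    values: np.ndarray
    observed: float
    n_undefined: int
    p_one_tailed: float
    p_two_tailed: float

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.values, q)


def empirical_p(values: np.ndarray, observed: float) -> tuple[float, float]:
    """(one-tailed, two-tailed) empirical p of `observed` within `values`."""
    R = len(values)
    p_low = (1 + int((values <= observed).sum())) / (R + 1)
    p_high = (1 + int((values >= observed).sum())) / (R + 1)
    p_one = p_low if observed < np.median(values) else p_high
    p_two = min(1.0, 2.0 * min(p_low, p_high))
    return p_one, p_two


def null_distribution(cfg: CoalescentConfig, statistic: str,
                      observed: float) -> NullDistribution:
    """Null distribution of D or H and empirical p-values for `observed`."""
    sims = replicate_statistics(cfg, statistic)
    defined = sims[~np.isnan(sims)]
    n_undef = int(np.isnan(sims).sum())
    if len(defined) == 0:
        raise UndefinedStatisticError(
            "all replicates produced undefined statistics (S = 0)")
    p_one, p_two = empirical_p(defined, observed)
    return NullDistribution(
        statistic=statistic,
        values=defined,
        observed=observed,
        n_undefined=n_undef,
        p_one_tailed=p_one,
        p_two_tailed=p_two,
    )


def window_confidence_bands(S_windows: list[int], n: int, statistic: str,
                            replicates: int, seed: int,
                            demography: DemographyModel = CONSTANT_SIZE,
                            posterior_draws: pd.DataFrame | None = None,
                            ) -> list[tuple[float, float]]:
    """Simulated 95% bands per window, conditioning on each window's S.

    Windows with S = 0 get (nan, nan) bands.  Windows sharing the same S
    share one simulated null (same seed derivation), so equal-S windows get
    identical bands by construction.
    """
    cache: dict[int, tuple[float, float]] = {}
    bands = []
    for S in S_windows:
        if S <= 0:
            bands.append((math.nan, math.nan))
            continue
        if S not in cache:
            cfg = CoalescentConfig(n=n, mode="fixed_S", value=S,
                                   replicates=replicates,
                                   seed=(seed + 1000003 * S) % (2**31),
                                   demography=demography,
                                   posterior_draws=posterior_draws)
            sims = replicate_statistics(cfg, statistic)
            defined = sims[~np.isnan(sims)]
            if len(defined) == 0:
                cache[S] = (math.nan, math.nan)
            else:
                lo, hi = np.quantile(defined, [0.025, 0.975])
                cache[S] = (float(lo), float(hi))
        bands.append(cache[S])
    return bands
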