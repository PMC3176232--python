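"""Synthetic coding alignments with an outgroup, under neutral, sweep-like
and balancing-like histories.

The study the package emulates surveyed 11-54 haplotypes per gene over
1035-3454 bp regions with 1-4 exons, with an outgroup at roughly 4-8%
synonymous divergence.  No sequence data were deposited, so this module
generates fully specified stand-ins: a coalescent genealogy per scenario,
infinite-sites mutations mapped onto a real codon structure (synonymous
changes accepted with probability 1, replacement changes with probability
omega, stop-creating changes always rejected), and an outgroup evolved on a
separate branch of configurable depth.  Every mutation's position, class and
derived count is recorded in a truth record so downstream statistics can be
checked against the generator's own bookkeeping.

The sweep and balancing scenarios are genealogy-shaping approximations, not
forward selection simulations:

* ``sweep(time, fraction)`` — a fraction of the sample coalesces in a star
  at a recent time (the haplotypes carried to high frequency by the sweep),
  the rest escape; the long internal branch subtending the swept class
  accumulates high-frequency derived variants (negative Fay & Wu's H).
* ``balanced(depth, fraction)`` — two clades are forbidden from coalescing
  with each other until an old split depth; the two deep branches accumulate
  intermediate-frequency variants (positive Tajima's D).

All randomness flows from the config seed; identical configs give
byte-identical FASTA output.
"""

from __future__ import annotations

import json
import math
import random
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import CodingAlignment, SiteMask, build_site_masks
from .coalescent import CONSTANT_SIZE, Genealogy, simulate_genealogy, _poisson
from .diversity import (CODON_TABLE, NeutralityConstants, divergence_by_class,
                        UndefinedStatisticError)

_NUCS = "ACGT"
_SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")


@dataclass(frozen=True)
class SyntheticGeneConfig:
    """Parameters of one synthetic gene.

    theta_site is the population mutation rate per site (4*N0*mu);
    t_outgroup the length of the outgroup-private branch in 4N0 units, so
    the expected synonymous divergence is ~ theta_site * t_outgroup;
    omega the acceptance probability of replacement mutations (purifying
    selection strength, 0 = no replacement changes survive).
    """

    gene_id: str = "synthetic_gene"
    n: int = 24
    L: int = 1500
    exons: tuple[tuple[int, int], ...] = ((150, 1350),)
    theta_site: float = 0.012
    t_outgroup: float = 4.0
    omega: float = 0.25
    scenario: str = "neutral"          # neutral | sweep | balanced
    sweep_time: float = 0.05           # 4N0 units since fixation
    sweep_fraction: float = 0.85       # fraction of sample in the swept class
    split_depth: float = 3.0           # balancing: age of the allelic split
    clade_fraction: float = 0.5        # balancing: size of the first clade
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_site < 0 or self.t_outgroup < 0 or self.omega < 0:
            raise ValueError("rates must be >= 0")
        if self.scenario not in ("neutral", "sweep", "balanced"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (0.0 < self.sweep_fraction < 1.0 and 0.0 < self.clade_fraction < 1.0):
            raise ValueError("scenario fractions must be in (0, 1)")
        total = sum(e - s for s, e in self.exons)
        if total % 3 != 0:
            raise ValueError("exon total must be divisible by 3")


@dataclass
class Mutation:
    """Truth record for one realized mutation."""

    column: int
    ancestral: str
    derived: str
    site_class: str            # 'syn' | 'rep' | 'noncoding'
    derived_count: int         # ingroup haplotypes carrying the derived state
    lineage: str               # 'ingroup' | 'outgroup'


# ---------------------------------------------------------------------------
# scenario genealogies
# ---------------------------------------------------------------------------

def _coalesce_pool(lineages: list[tuple[int, float]], t0: float,
                   rng: random.Random,
                   branches: list[tuple[int, float]],
                   t_stop: float | None = None) -> tuple[list[tuple[int, float]], float]:
    """Standard constant-size coalescent among *lineages* from time t0.

    Stops at t_stop (returning the surviving lineages) or at the MRCA.
    Returns (remaining lineages as (mask, birth) pairs, current time).
    """
    lineages = list(lineages)
    t = t0
    while len(lineages) > 1:
        k = len(lineages)
        wait = rng.expovariate(k * (k - 1))
        if t_stop is not None and t + wait >= t_stop:
            return lineages, t_stop
        t += wait
        i = rng.randrange(k)
        j = rng.randrange(k - 1)
        if j >= i:
            j += 1
        mi, bi = lineages[i]
        mj, bj = lineages[j]
        branches.append((mi, t - bi))
        branches.append((mj, t - bj))
        merged = (mi | mj, t)
        lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    return lineages, t


def scenario_genealogy(cfg: SyntheticGeneConfig, rng: random.Random) -> Genealogy:
    """Genealogy for the configured scenario (constant size background)."""
    n = cfg.n
    if cfg.scenario == "neutral":
        return simulate_genealogy(n, CONSTANT_SIZE, rng)

    branches: list[tuple[int, float]] = []
    if cfg.scenario == "sweep":
        m = max(2, min(n - 1, round(cfg.sweep_fraction * n)))
        t_s = cfg.sweep_time
        # swept class: star coalescence at t_s
        swept_mask = 0
        for i in range(m):
            branches.append((1 << i, t_s))
            swept_mask |= 1 << i
        pool = [(swept_mask, t_s)]
        # escapees survive to t_s untouched (no coalescence during the sweep)
        for i in range(m, n):
            pool.append((1 << i, 0.0))
        remaining, t = _coalesce_pool(pool, t_s, rng, branches)
        return Genealogy(n=n, branches=branches, tmrca=t)

    # balanced: two clades isolated until split_depth, then merged
    a = max(1, min(n - 1, round(cfg.clade_fraction * n)))
    clade_a = [(1 << i, 0.0) for i in range(a)]
    clade_b = [(1 << i, 0.0) for i in range(a, n)]
    rem_a, _ = _coalesce_pool(clade_a, 0.0, rng, branches, t_stop=cfg.split_depth)
    rem_b, _ = _coalesce_pool(clade_b, 0.0, rng, branches, t_stop=cfg.split_depth)
    remaining, t = _coalesce_pool(rem_a + rem_b, cfg.split_depth, rng, branches)
    return Genealogy(n=n, branches=branches, tmrca=t)


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

def _random_ancestral(cfg: SyntheticGeneConfig, rng: random.Random) -> list[str]:
    """Ancestral sequence: random sense codons in exons, random bases outside."""
    seq = [rng.choice(_NUCS) for _ in range(cfg.L)]
    cols = [c for s, e in cfg.exons for c in range(s, e)]
    for i in range(0, len(cols), 3):
        codon = rng.choice(_SENSE_CODONS)
        for k in range(3):
            seq[cols[i + k]] = codon[k]
    return seq


def _codon_context(column: int, seq: list[str],
                   codon_of_col: dict[int, tuple[int, ...]]) -> tuple[str, int] | None:
    """(codon string, position within codon) for a coding column, else None."""
    cols = codon_of_col.get(column)
    if cols is None:
        return None
    codon = "".join(seq[c] for c in cols)
    return codon, cols.index(column)


def _classify_change(column: int, old: str, new: str, seq: list[str],
                     codon_of_col: dict[int, tuple[int, ...]]) -> str | None:
    """'syn'/'rep'/'noncoding' for a proposed change, None if it creates a stop."""
    ctx = _codon_context(column, seq, codon_of_col)
    if ctx is None:
        return "noncoding"
    codon, pos = ctx
    mutant = codon[:pos] + new + codon[pos + 1:]
    if CODON_TABLE[mutant] == "*":
        return None
    return "syn" if CODON_TABLE[codon] == CODON_TABLE[mutant] else "rep"


def generate_gene(cfg: SyntheticGeneConfig) -> tuple[CodingAlignment, dict]:
    """Generate one synthetic gene; returns (alignment, truth record).

    The truth record holds the scenario, the realized genealogy summary and
    the list of accepted mutations (position, class, derived count, lineage).
    """
    rng = random.Random(cfg.seed)
    n, L = cfg.n, cfg.L
    theta_locus = cfg.theta_site * L
    exp_S = theta_locus * NeutralityConstants.from_n(n).a1
    if exp_S < 1.0:
        warnings.warn(
            f"{cfg.gene_id}: expected segregating sites {exp_S:.2f} < 1 "
            "for this configuration")

    ancestral = _random_ancestral(cfg, rng)
    codon_cols = [tuple(c) for c in
                  np.array([c for s, e in cfg.exons
                            for c in range(s, e)]).reshape(-1, 3)]
    codon_of_col = {c: cols for cols in codon_cols for c in cols}

    tree = scenario_genealogy(cfg, rng)
    # visible branches and their cumulative lengths for mutation placement
    vis = [(m, l) for m, l in tree.branches if 1 <= m.bit_count() <= n - 1]
    cum: list[float] = []
    acc = 0.0
    for _, l in vis:
        acc += l
        cum.append(acc)
    total_len = acc

    used_columns: set[int] = set()
    mutations: list[Mutation] = []
    haplotypes = [list(ancestral) for _ in range(n)]
    outgroup = list(ancestral)

    def propose_column() -> int | None:
        if len(used_columns) >= L:
            return None
        while True:
            col = rng.randrange(L)
            if col not in used_columns:
                return col

    def accept(col: int, target_seq: list[str]) -> tuple[str, str, str] | None:
        old = target_seq[col]
        new = rng.choice([b for b in _NUCS if b != old])
        cls = _classify_change(col, old, new, target_seq, codon_of_col)
        if cls is None:
            return None                      # would create a stop codon
        if cls == "rep" and rng.random() >= cfg.omega:
            return None                      # purged by purifying selection
        return old, new, cls

    # ingroup mutations along the genealogy (thinned by class acceptance)
    n_proposed = _poisson(cfg.theta_site * L * total_len, rng)
    for _ in range(n_proposed):
        b = bisect_right(cum, rng.random() * total_len)
        if b == len(cum):
            b -= 1
        col = propose_column()
        if col is None:
            break
        res = accept(col, ancestral)
        if res is None:
            continue
        old, new, cls = res
        mask = vis[b][0]
        used_columns.add(col)
        count = 0
        for i in range(n):
            if mask >> i & 1:
                haplotypes[i][col] = new
                count += 1
        mutations.append(Mutation(col, old, new, cls, count, "ingroup"))

    # outgroup mutations on its private branch
    n_proposed = _poisson(cfg.theta_site * L * cfg.t_outgroup, rng)
    for _ in range(n_proposed):
        col = propose_column()
        if col is None:
            break
        res = accept(col, outgroup)
        if res is None:
            continue
        old, new, cls = res
        used_columns.add(col)
        outgroup[col] = new
        mutations.append(Mutation(col, old, new, cls, 0, "outgroup"))

    aln = CodingAlignment(
        gene_id=cfg.gene_id,
        ingroup_ids=tuple(f"{cfg.gene_id}_hap{i:02d}" for i in range(n)),
        ingroup=tuple("".join(h) for h in haplotypes),
        outgroup_id=f"{cfg.gene_id}_outgroup",
        outgroup="".join(outgroup),
        exons=cfg.exons,
    )
    truth = {
        "config": asdict(cfg),
        "tmrca": tree.tmrca,
        "total_branch_length": total_len,
        "mutations": [asdict(m) for m in mutations],
    }
    return aln, truth


def truth_sfs(truth: dict, n: int) -> np.ndarray:
    """Unfolded SFS implied by the generator's own mutation bookkeeping."""
    xi = np.zeros(n - 1, dtype=np.int64)
    for m in truth["mutations"]:
        if m["lineage"] == "ingroup" and 1 <= m["derived_count"] <= n - 1:
            xi[m["derived_count"] - 1] += 1
    return xi


def write_gene(aln: CodingAlignment, truth: dict, outdir: str | Path) -> None:
    """Emit FASTA + BED + truth JSON; paths derive from the gene id."""
    from .alignment import write_coding_alignment
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_coding_alignment(aln, outdir / f"{aln.gene_id}.fasta",
                           outdir / f"{aln.gene_id}.bed")
    with open(outdir / f"{aln.gene_id}.truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)


# ---------------------------------------------------------------------------
# study-shaped fixture configs
# ---------------------------------------------------------------------------

def _exon_layout(L: int, coding: int, n_exons: int) -> tuple[tuple[int, int], ...]:
    """Evenly spaced exon layout with total coding length divisible by 3."""
    coding = 3 * (coding // 3)
    per = 3 * (coding // (3 * n_exons))
    last = coding - per * (n_exons - 1)
    noncoding = L - coding
    gap = noncoding // (n_exons + 1)
    exons = []
    pos = gap
    for i in range(n_exons):
        length = per if i < n_exons - 1 else last
        exons.append((pos, pos + length))
        pos += length + gap
    return tuple(exons)


#: Eight synthetic configs mirroring the study's gene shapes (sample size,
#: region length, coding length, exon count).  All data are synthetic.
TABLE1_LIKE_CONFIGS: dict[str, SyntheticGeneConfig] = {
    name: SyntheticGeneConfig(
        gene_id=f"syn_{name}", n=n, L=L, exons=_exon_layout(L, coding, ex),
        theta_site=0.012, t_outgroup=4.0, omega=0.25, scenario=scen, seed=i)
    for i, (name, n, L, coding, ex, scen) in enumerate([
        ("AOS5", 26, 1968, 1445, 1, "neutral"),
        ("CathL", 24, 1879, 1125, 4, "neutral"),
        ("GHf10", 24, 1035, 594, 4, "neutral"),
        ("NFXL1", 24, 3454, 3336, 1, "neutral"),
        ("PAL1", 24, 3249, 3142, 2, "neutral"),
        ("PPO1", 54, 1798, 1689, 1, "balanced"),
        ("PPO2", 26, 1506, 1506, 1, "sweep"),
        ("PPO3", 22, 1381, 1381, 1, "neutral"),
    ])
}


# ---------------------------------------------------------------------------
# reference panel and toy demography posterior
# ---------------------------------------------------------------------------

def generate_reference_panel(k: int, seed: int = 0,
                             template: SyntheticGeneConfig | None = None,
                             omega: float | None = None) -> pd.DataFrame:
    """Per-locus K_A/K_S values for *k* synthetic reference loci.

    omega is drawn per locus from a Gamma(2, 0.15) (mean 0.3) unless fixed;
    K_A and K_S are computed from the generated alignments by the divergence
    machinery, giving a panel file consumable by
    :func:`popgenscan.windows.kaks_cutoff_from_reference`.
    """
    if k < 1:
        raise ValueError("need k >= 1 loci")
    rng = random.Random(seed)
    base = template or SyntheticGeneConfig(L=900, exons=((0, 900),), n=16)
    rows = []
    for i in range(k):
        om = omega if omega is not None else min(2.0, rng.gammavariate(2.0, 0.15))
        cfg = SyntheticGeneConfig(
            gene_id=f"ref{i:03d}", n=base.n, L=base.L, exons=base.exons,
            theta_site=base.theta_site, t_outgroup=base.t_outgroup,
            omega=om, scenario="neutral", seed=rng.randrange(2**31))
        aln, _ = generate_gene(cfg)
        mask = build_site_masks(aln)
        try:
            ks = divergence_by_class(aln, mask, "syn")
            ka = divergence_by_class(aln, mask, "rep")
            ratio = ka / ks if ks > 0 else math.nan
        except UndefinedStatisticError:
            ka = ks = ratio = math.nan
        rows.append({"locus": cfg.gene_id, "omega": om,
                     "K_A": ka, "K_S": ks, "KA_KS": ratio})
    return pd.DataFrame(rows)


def toy_bottleneck_posterior(n_draws: int = 200, seed: int = 0) -> pd.DataFrame:
    """SYNTHETIC toy posterior for a 3-epoch bottleneck (non-biological).

    Stands in for a real demographic posterior, which is not distributed
    with the package: epoch 0 at size 1, a bottleneck of jittered severity
    starting around 0.05 (4N0 units), recovery to size ~1 afterwards.
    """
    rng = random.Random(seed)
    rows = []
    for _ in range(n_draws):
        t1 = rng.uniform(0.03, 0.08)
        sev = rng.uniform(0.02, 0.15)
        dur = rng.uniform(0.01, 0.05)
        rows.append({"start_1": t1, "size_1": sev,
                     "start_2": t1 + dur, "size_2": rng.uniform(0.8, 1.2)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenario signature check
# ---------------------------------------------------------------------------

def scenario_signature_check(n_replicates: int = 100, seed: int = 0,
                             base: SyntheticGeneConfig | None = None) -> dict:
    """Mean D and H per scenario over replicate genes, with standard errors.

    Documents (and lets tests assert) that the generators produce the SFS
    signatures they are meant to: balancing raises Tajima's D above the
    neutral mean, sweeps push Fay & Wu's H below it.
    """
    from dataclasses import replace as _replace
    from .diversity import (fay_wu_H_normalized, mean_pairwise_differences,
                            segregating_sites, tajimas_D, unfolded_sfs)

    base = base or SyntheticGeneConfig()
    out: dict[str, dict] = {}
    for scen_idx, scen in enumerate(("neutral", "sweep", "balanced")):
        Ds, Hs = [], []
        for r in range(n_replicates):
            cfg = _replace(base, gene_id=f"{scen}_{r:03d}", scenario=scen,
                           seed=(seed * 1_000_003 + scen_idx * 7919 + r) % (2**31))
            aln, _ = generate_gene(cfg)
            mask = build_site_masks(aln)
            S = segregating_sites(aln, mask)
            if S >= 1:
                Ds.append(tajimas_D(S, mean_pairwise_differences(aln, mask), aln.n))
            sfs = unfolded_sfs(aln, mask)
            if sfs.S >= 1:
                Hs.append(fay_wu_H_normalized(sfs))
        out[scen] = {
            "mean_D": float(np.mean(Ds)),
            "se_D": float(np.std(Ds, ddof=1) / math.sqrt(len(Ds))),
            "mean_H": float(np.mean(Hs)),
            "se_H": float(np.std(Hs, ddof=1) / math.sqrt(len(Hs))),
            "n_D": len(Ds),
            "n_H": len(Hs),
        }
    sep = lambda a, b, key: abs(out[a][f"mean_{key}"] - out[b][f"mean_{key}"]) / \
        math.hypot(out[a][f"se_{key}"], out[b][f"se_{key}"])
    out["separation"] = {
        "D_balanced_vs_neutral_se": sep("balanced", "neutral", "D"),
        "H_sweep_vs_neutral_se": sep("sweep", "neutral", "H"),
        "balanced_D_above_neutral": out["balanced"]["mean_D"] > out["neutral"]["mean_D"],
        "sweep_H_below_neutral": out["sweep"]["mean_H"] < out["neutral"]["mean_H"],
    }
    return out
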