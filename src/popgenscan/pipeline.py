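"""Per-gene orchestration: summary row, MK table, window tracks, nulls.

One run takes a set of genes (FASTA + exon annotation + outgroup id), builds
the shared site masks once per gene, and emits:

* a per-gene summary TSV/JSON (n, sites, S, pi triplet, K pair, D, H and
  their empirical p-values against the coalescent null);
* an MK table TSV (fixed/poly x syn/rep, -log10 NI, G with its chi-square p,
  Fisher's exact p);
* window tracks (synonymous pi at 75/8; D, H and both K_A/K_S ratios at
  250/25) with simulated 95% confidence bands for D and H;
* a manifest of all resolved parameters.

Each gene draws its RNG stream from (master seed, gene id), so per-gene
results do not depend on which other genes are in the run.  A failure in one
gene is logged and the remaining genes continue.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import CodingAlignment, SiteMask, build_site_masks, read_coding_alignment
from .coalescent import (CONSTANT_SIZE, CoalescentConfig, DemographyModel,
                         load_posterior_draws, null_distribution,
                         window_confidence_bands)
from .diversity import GeneSummary, UndefinedStatisticError, gene_summary
from .mk import MKTable, build_mk_table, mk_table_row
from .windows import (DEFAULT_KAKS_CUTOFF, WindowSpec, WindowTrack,
                      flag_outliers, kaks_cutoff_from_reference,
                      window_statistic_track)

logger = logging.getLogger("popgenscan")

DEFAULT_WINDOW_SPECS = (
    WindowSpec(75, 8, "pi_syn"),
    WindowSpec(250, 25, "D"),
    WindowSpec(250, 25, "H_norm"),
    WindowSpec(250, 25, "KA_KS_div"),
    WindowSpec(250, 25, "KA_KS_poly"),
)


@dataclass(frozen=True)
class GeneInput:
    fasta: str
    annotation: str
    outgroup_id: str
    gene_id: str | None = None


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    genes: tuple[GeneInput, ...]
    outdir: str
    seed: int = 1
    replicates: int = 10_000
    window_specs: tuple[WindowSpec, ...] = DEFAULT_WINDOW_SPECS
    demography_file: str | None = None     # posterior-draw TSV, else constant N
    panel_file: str | None = None          # per-locus K_A/K_S TSV
    kaks_cutoff: float | None = None       # overrides panel / default

    def resolve_cutoff(self) -> float:
        if self.kaks_cutoff is not None:
            return self.kaks_cutoff
        if self.panel_file:
            panel = pd.read_csv(self.panel_file, sep="\t")
            col = "KA_KS" if "KA_KS" in panel.columns else panel.columns[-1]
            return kaks_cutoff_from_reference(panel[col].dropna().to_numpy())
        return DEFAULT_KAKS_CUTOFF


def gene_seed(master_seed: int, gene_id: str) -> int:
    """Deterministic per-gene seed below 2^31, independent of run order."""
    digest = hashlib.sha256(f"{master_seed}:{gene_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class GeneResult:
    summary: GeneSummary
    mk: MKTable
    tracks: dict[str, WindowTrack]
    nulls: dict[str, object]


def run_gene(cfg: RunConfig, aln: CodingAlignment,
             posterior_draws: pd.DataFrame | None = None) -> GeneResult:
    """Analyse one gene end to end from a single shared mask build."""
    mask = build_site_masks(aln)
    seed = gene_seed(cfg.seed, aln.gene_id)
    logger.info("%s: n=%d, L=%d, usable=%d, polarized=%d, coding=%d",
                aln.gene_id, aln.n, aln.length,
                int(mask.usable_total.sum()),
                int(mask.usable_polarized.sum()),
                int((mask.coding & mask.usable_total).sum()))

    summary = gene_summary(aln, mask)
    mk = build_mk_table(aln, mask)

    demography = CONSTANT_SIZE
    nulls: dict[str, object] = {}
    for stat, observed, attr in (("D", summary.D, "p_D"),
                                 ("H_norm", summary.H_norm, "p_H")):
        if observed is None or summary.S < 1:
            continue
        # both nulls condition on the gene's sample size and observed S
        ccfg = CoalescentConfig(
            n=aln.n, mode="fixed_S", value=summary.S,
            replicates=cfg.replicates, seed=seed,
            demography=demography, posterior_draws=posterior_draws)
        try:
            nd = null_distribution(ccfg, stat, observed)
        except UndefinedStatisticError:
            continue
        nulls[stat] = nd
        setattr(summary, attr, nd.p_one_tailed)

    tracks: dict[str, WindowTrack] = {}
    cutoff = cfg.resolve_cutoff()
    for spec in cfg.window_specs:
        if aln.length < spec.width:
            logger.warning("%s: alignment shorter than %d bp window; "
                           "skipping %s track", aln.gene_id, spec.width,
                           spec.statistic)
            continue
        track = window_statistic_track(aln, mask, spec)
        if spec.statistic in ("D", "H_norm"):
            bands = window_confidence_bands(
                [int(s) for s in track.rows["S_window"]], aln.n,
                spec.statistic, cfg.replicates, seed,
                demography=demography, posterior_draws=posterior_draws)
            track.rows["ci_low"] = [b[0] for b in bands]
            track.rows["ci_high"] = [b[1] for b in bands]
        if spec.statistic == "KA_KS_div":
            track.rows["outlier"] = flag_outliers(track, cutoff)
            track.metadata["kaks_cutoff"] = cutoff
        tracks[spec.statistic] = track
    return GeneResult(summary=summary, mk=mk, tracks=tracks, nulls=nulls)


SUMMARY_COLUMNS = ["gene_id", "n", "sites", "coding_sites", "S", "pi_tot",
                   "pi_syn", "pi_rep", "K_syn", "K_rep", "H_norm", "D",
                   "p_D", "p_H"]


def summarize_run(results: list[GeneResult]) -> pd.DataFrame:
    """Cohort table plus unweighted and site-weighted average rows."""
    if not results:
        raise ValueError("no completed genes to summarize")
    rows = [r.summary.as_dict() for r in results]
    df = pd.DataFrame(rows)[SUMMARY_COLUMNS]
    stat_cols = ["pi_tot", "pi_syn", "pi_rep", "K_syn", "K_rep"]
    unweighted = {c: df[c].mean() for c in stat_cols}
    weights = df["sites"].to_numpy(dtype=float)
    weighted = {}
    for c in stat_cols:
        vals = df[c].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        weighted[c] = float(np.sum(vals[ok] * weights[ok]) / np.sum(weights[ok]))
    avg_rows = pd.DataFrame([
        {"gene_id": "average_unweighted", **unweighted},
        {"gene_id": "average_site_weighted", **weighted},
    ])
    return pd.concat([df, avg_rows], ignore_index=True)


def run(cfg: RunConfig) -> list[GeneResult]:
    """Run every gene, writing all outputs and a manifest under cfg.outdir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    posterior = (load_posterior_draws(cfg.demography_file)
                 if cfg.demography_file else None)
    results: list[GeneResult] = []
    failures: dict[str, str] = {}
    for gi in cfg.genes:
        gene_id = gi.gene_id or Path(gi.fasta).stem
        try:
            aln = read_coding_alignment(gi.fasta, gi.annotation,
                                        gi.outgroup_id, gene_id=gene_id)
            res = run_gene(cfg, aln, posterior_draws=posterior)
        except Exception as exc:               # keep other genes running
            logger.error("%s: failed: %s", gene_id, exc)
            failures[gene_id] = str(exc)
            continue
        results.append(res)
        _write_gene_outputs(res, outdir)
    if results:
        summarize_run(results).to_csv(outdir / "summary.tsv", sep="\t",
                                      index=False, float_format="%.6g")
        pd.DataFrame([mk_table_row(r.mk) for r in results]).to_csv(
            outdir / "mk_tables.tsv", sep="\t", index=False)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "replicates": cfg.replicates,
        "window_specs": [asdict(w) for w in cfg.window_specs],
        "kaks_cutoff": cfg.resolve_cutoff(),
        "demography": cfg.demography_file or "constant size",
        "genes": [asdict(g) for g in cfg.genes],
        "failures": failures,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return results


def _round_floats(obj, nd=10):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, nd) for v in obj]
    return obj


def _write_gene_outputs(res: GeneResult, outdir: Path) -> None:
    gid = res.summary.gene_id
    with open(outdir / f"{gid}_summary.json", "w") as fh:
        json.dump(_round_floats(res.summary.as_dict()), fh, indent=1)
    pd.DataFrame([mk_table_row(res.mk)]).to_csv(
        outdir / f"{gid}_mk.tsv", sep="\t", index=False)
    for stat, track in res.tracks.items():
        track.to_tsv(outdir / f"{gid}_track_{stat}.tsv")
    for stat, nd in res.nulls.items():
        pd.DataFrame({"replicate_value": nd.values}).to_csv(
            outdir / f"{gid}_null_{stat}.tsv", sep="\t", index=False,
            float_format="%.6g")
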