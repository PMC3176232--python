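"""Sliding-window scans across a gene alignment.

Windows run over alignment coordinates of the full sequenced region (introns
included); class-specific statistics use only the coding columns falling
inside each window.  Default geometries follow the study design: synonymous
diversity with a 75 bp window moved in 8 bp increments, Tajima's D, Fay &
Wu's H and K_A/K_S with a 250 bp window moved in 25 bp increments.  Only
full-width windows are emitted, so per-window segregating-site counts stay
comparable for the simulated confidence bands.

No multiple-testing correction is applied across windows (the scans are
exploratory); this is recorded in the track metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import CodingAlignment, SiteMask
from . import diversity
from .diversity import UndefinedStatisticError

#: Fallback K_A/K_S outlier cutoff when no reference panel is supplied:
#: the 95th percentile of the K_A/K_S distribution over a 76-locus
#: genome-wide reference panel.
DEFAULT_KAKS_CUTOFF = 1.14

STATISTICS = ("pi_syn", "D", "H_norm", "KA_KS_div", "KA_KS_poly")


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry and the statistic scanned with it."""

    width: int
    step: int
    statistic: str

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.width):
            raise ValueError(f"need 0 < step <= width, got {self}")
        if self.statistic not in STATISTICS:
            raise ValueError(
                f"unknown statistic {self.statistic!r}; expected one of {STATISTICS}")


def make_windows(L: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Full-width windows [start, start+width) with start = 0, step, 2*step...

    Exactly floor((L - width)/step) + 1 windows; an alignment shorter than
    one window is an error rather than a truncated window.
    """
    if L < spec.width:
        raise ValueError(
            f"alignment length {L} shorter than window width {spec.width}")
    starts = range(0, L - spec.width + 1, spec.step)
    return [(s, s + spec.width) for s in starts]


@dataclass
class WindowTrack:
    """Per-window values of one statistic, with optional confidence bands."""

    gene_id: str
    statistic: str
    spec: WindowSpec
    rows: pd.DataFrame      # start, end, mid, value, ci_low, ci_high, S_window
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        out = self.rows.copy()
        # 1-based inclusive coordinates in emitted tables
        out["start"] = out["start"] + 1
        out["mid"] = out["mid"] + 1
        out.insert(0, "stat", self.statistic)
        out.insert(0, "gene", self.gene_id)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _window_value(aln: CodingAlignment, wmask: SiteMask, statistic: str,
                  n: int) -> float | None:
    """One window's statistic, or None when undefined in that window."""
    try:
        if statistic == "pi_syn":
            return diversity.pairwise_pi(aln, wmask, "syn")
        if statistic == "D":
            S = diversity.segregating_sites(aln, wmask)
            if S == 0:
                return None
            pi = diversity.mean_pairwise_differences(aln, wmask)
            return diversity.tajimas_D(S, pi, n)
        if statistic == "H_norm":
            return diversity.fay_wu_H_normalized(diversity.unfolded_sfs(aln, wmask))
        if statistic == "KA_KS_div":
            ks = diversity.divergence_by_class(aln, wmask, "syn")
            ka = diversity.divergence_by_class(aln, wmask, "rep")
            if ks == 0.0:
                return None    # no synonymous divergence: ratio undefined
            return ka / ks
        if statistic == "KA_KS_poly":
            ps = diversity.pairwise_pi(aln, wmask, "syn")
            pr = diversity.pairwise_pi(aln, wmask, "rep")
            if ps == 0.0:
                return None
            return pr / ps
    except UndefinedStatisticError:
        return None
    raise ValueError(f"unknown statistic {statistic!r}")


def window_statistic_track(aln: CodingAlignment, mask: SiteMask,
                           spec: WindowSpec) -> WindowTrack:
    """Scan *aln* with *spec*; windows with no information emit null values."""
    records = []
    for start, end in make_windows(aln.length, spec):
        wmask = mask.restrict(start, end)
        s_win = diversity.segregating_sites(aln, wmask)
        value = _window_value(aln, wmask, spec.statistic, aln.n)
        records.append({
            "start": start,
            "end": end,
            "mid": (start + end - 1) / 2.0,
            "value": value,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "S_window": s_win,
        })
    rows = pd.DataFrame.from_records(records)
    return WindowTrack(
        gene_id=aln.gene_id,
        statistic=spec.statistic,
        spec=spec,
        rows=rows,
        metadata={
            "coordinates": "alignment columns of the provided alignment, "
                           "0-based half-open internally, 1-based in TSV",
            "multiple_testing_correction": "none (exploratory scan)",
        },
    )


def kaks_cutoff_from_reference(panel) -> float:
    """Empirical 95th percentile of per-locus K_A/K_S reference values.

    Linear interpolation between order statistics.  Use
    :data:`DEFAULT_KAKS_CUTOFF` when no panel is available.
    """
    values = np.asarray(panel, dtype=float)
    if values.size == 0:
        raise ValueError("empty reference panel")
    return float(np.percentile(values, 95, method="linear"))


def flag_outliers(track: WindowTrack, cutoff: float) -> pd.Series:
    """Boolean flag per window: ratio exceeds the reference cutoff."""
    vals = track.rows["value"]
    return vals.notna() & (vals > cutoff)
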