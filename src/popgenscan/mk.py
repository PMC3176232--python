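"""McDonald-Kreitman tables: counts, neutrality index, G test, Fisher's exact.

The MK test contrasts fixed differences from the outgroup against
within-species polymorphism, separately for synonymous and replacement
changes, in a 2x2 table (Ds, Ps / Dn, Pn).  Under neutrality the ratio of
replacement to synonymous changes is the same for fixations and
polymorphisms; the neutrality index NI = (Pn/Ps)/(Dn/Ds) measures the
departure (NI < 1: excess replacement fixation, i.e. adaptive protein
evolution).

Counting conventions (columns are classified inside their codon context with
Nei-Gojobori pathway averaging):

* a column with >= 2 ingroup states is polymorphic, even if it also differs
  from the outgroup (polymorphism takes precedence over divergence);
* a column monomorphic in the ingroup but different from the outgroup is a
  fixed difference;
* codon sites with > 2 ingroup codon variants contribute one change per
  derived variant (star decomposition from the most common codon) and the
  table is flagged as containing multi-allelic codons;
* pathway-averaged fractional counts are kept exact internally; table-style
  output rounds only for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alignment import CodingAlignment, SiteMask
from .diversity import classify_codon_differences, usable_codons


class UndefinedTestError(ValueError):
    """Test statistic undefined for this table (zero marginal etc.)."""


@dataclass
class MKTable:
    """2x2 fixed/polymorphic x synonymous/replacement contingency table."""

    gene_id: str
    Ds: float     # fixed synonymous
    Ps: float     # polymorphic synonymous
    Dn: float     # fixed replacement
    Pn: float     # polymorphic replacement
    multiallelic_codons: int = 0

    def counts(self) -> tuple[float, float, float, float]:
        return (self.Ds, self.Ps, self.Dn, self.Pn)

    @property
    def NI(self) -> float:
        return neutrality_index(self)[0]

    @property
    def neg_log10_NI(self) -> float:
        return neutrality_index(self)[1]

    @property
    def G(self) -> float:
        return g_statistic(self)

    @property
    def fisher_p(self) -> float:
        return fisher_exact_p(self)


def build_mk_table(aln: CodingAlignment, mask: SiteMask) -> MKTable:
    """Count fixed and polymorphic syn/rep changes at usable codons.

    Only codons fully usable including the outgroup enter the table, so fixed
    and polymorphic counts share one site denominators.
    """
    Ds = Ps = Dn = Pn = 0.0
    multi = 0
    for cd in usable_codons(aln, mask, require_outgroup=True):
        variants, counts = cd.variants, cd.counts
        # polymorphism: changes among observed ingroup codons
        if len(variants) > 1:
            major = variants[int(np.argmax(counts))]
            if len(variants) > 2:
                multi += 1
            for v in variants:
                if v == major:
                    continue
                s, r = classify_codon_differences(major, v)
                Ps += s
                Pn += r
        # fixation: ingroup-monomorphic positions differing from the outgroup
        consensus = variants[int(np.argmax(counts))]
        fixed_positions = [
            i for i in range(3)
            if all(v[i] == consensus[i] for v in variants)
            and cd.outgroup[i] != consensus[i]
        ]
        if fixed_positions:
            target = "".join(
                cd.outgroup[i] if i in fixed_positions else consensus[i]
                for i in range(3))
            s, r = classify_codon_differences(consensus, target)
            Ds += s
            Dn += r
    return MKTable(aln.gene_id, Ds, Ps, Dn, Pn, multiallelic_codons=multi)


def neutrality_index(t: MKTable) -> tuple[float, float]:
    """(NI, -log10 NI) with NI = (Pn/Ps)/(Dn/Ds)."""
    Ds, Ps, Dn, Pn = t.counts()
    if min(Ds, Ps, Dn, Pn) <= 0:
        raise UndefinedTestError(
            f"{t.gene_id}: NI undefined with a zero cell "
            f"(Ds={Ds}, Ps={Ps}, Dn={Dn}, Pn={Pn}); no continuity correction "
            "is applied by default")
    ni = (Pn / Ps) / (Dn / Ds)
    return ni, -float(np.log10(ni))


def g_statistic(t: MKTable) -> float:
    """Likelihood-ratio G = 2 sum O ln(O/E), no Williams/Yates correction.

    Expected counts come from the row/column marginals; cells with O = 0
    contribute 0.
    """
    obs = np.array([[t.Ds, t.Ps], [t.Dn, t.Pn]], dtype=float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row <= 0).any() or (col <= 0).any():
        raise UndefinedTestError(f"{t.gene_id}: G undefined with a zero marginal")
    exp = np.outer(row, col) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return float(2.0 * terms.sum())


def g_test_p(t: MKTable) -> float:
    """Chi-square (df=1) tail probability of the G statistic."""
    return float(stats.chi2.sf(g_statistic(t), df=1))


def fisher_exact_p(t: MKTable) -> float:
    """Two-tailed Fisher's exact p for the MK table.

    Sums hypergeometric probabilities of all tables (fixed marginals) whose
    probability does not exceed that of the observed table.  Fractional
    pathway counts are rounded to the nearest integer for the exact test.
    """
    obs = np.rint([[t.Ds, t.Ps], [t.Dn, t.Pn]]).astype(int)
    return float(stats.fisher_exact(obs, alternative="two-sided")[1])


def mk_table_row(t: MKTable) -> dict:
    """Display row in Table-2 style: integer counts, 2-decimal statistics."""
    def stat_or_none(fn):
        try:
            return fn(t)
        except UndefinedTestError:
            return None

    ni = stat_or_none(lambda x: neutrality_index(x)[1])
    g = stat_or_none(g_statistic)
    return {
        "gene": t.gene_id,
        "fixed_syn": int(round(t.Ds)),
        "poly_syn": int(round(t.Ps)),
        "fixed_rep": int(round(t.Dn)),
        "poly_rep": int(round(t.Pn)),
        "neg_log10_NI": None if ni is None else round(ni, 2),
        "G": None if g is None else round(g, 2),
        "fisher_p": fisher_exact_p(t),
        "multiallelic_codons": t.multiallelic_codons,
    }
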