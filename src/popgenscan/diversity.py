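"""Core population-genetic statistics on coding alignments.

Implements the per-gene summary machinery: segregating sites, pairwise
nucleotide diversity (total and partitioned into synonymous/replacement
classes by the Nei-Gojobori 1986 method with pathway averaging),
Jukes-Cantor-corrected divergence from the outgroup, the unfolded site
frequency spectrum, Tajima's (1989) D and the normalized Fay & Wu's H of
Zeng, Fu, Shi & Wu (2006).

Conventions
-----------
* Within-species diversity is uncorrected for multiple hits; between-species
  divergence is Jukes-Cantor corrected.
* Synonymous/replacement site counts are fractional (each codon position
  contributes the fraction of its three possible changes that are
  synonymous) and are averaged over all ingroup sequences — no privileged
  reference haplotype.  For divergence denominators the outgroup is included
  in the average.
* Codons containing any masked column are excluded whole, so the reading
  frame stays exact under complete deletion.
* Sites whose outgroup state is a third allele are excluded from the
  unfolded SFS (and hence from H) but still count toward S and D, which need
  no polarization.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .alignment import STOP_CODONS, CodingAlignment, SiteMask

_NUCS = "ACGT"

#: codon -> amino acid (one letter, '*' for stop), standard genetic code
CODON_TABLE: dict[str, str] = {
    "".join(c): str(Seq("".join(c)).translate())
    for c in itertools.product(_NUCS, repeat=3)
}


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for this input (e.g. S = 0, no class sites)."""


# ---------------------------------------------------------------------------
# Nei-Gojobori site and difference counting
# ---------------------------------------------------------------------------

def nei_gojobori_sites(codon: str) -> float:
    """Fractional number of synonymous sites in a sense codon.

    For each of the three positions, the fraction of the three possible
    single-nucleotide changes that preserve the amino acid; changes *to* a
    stop codon count as replacement.  The replacement site count is
    ``3 - nei_gojobori_sites(codon)``.
    """
    aa = CODON_TABLE[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no site decomposition")
    syn = 0.0
    for pos in range(3):
        for alt in _NUCS:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if CODON_TABLE[mutant] == aa:
                syn += 1.0 / 3.0
    return syn


_SYN_SITES: dict[str, float] = {
    c: nei_gojobori_sites(c) for c, aa in CODON_TABLE.items() if aa != "*"
}


def classify_codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, replacement) differences between codons.

    All orderings of the differing positions are enumerated; pathways passing
    through a stop codon are discarded and the synonymous/replacement step
    counts are averaged over the remaining pathways.  If every pathway passes
    through a stop, all pathways are used with stop steps counted as
    replacement (a warning is emitted).  The two counts always sum to the
    Hamming distance of the codons.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)

    def walk(order: tuple[int, ...], allow_stops: bool):
        syn = rep = 0.0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if CODON_TABLE[nxt] == "*" and not allow_stops:
                return None
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                syn += 1.0
            else:
                rep += 1.0
            cur = nxt
        return (syn, rep)

    orders = list(itertools.permutations(diff_pos))
    results = [r for r in (walk(o, False) for o in orders) if r is not None]
    if not results:
        warnings.warn(
            f"all mutational pathways between {codon_a} and {codon_b} pass "
            "through a stop codon; counting stop steps as replacement")
        results = [walk(o, True) for o in orders]
    syn = sum(r[0] for r in results) / len(results)
    rep = sum(r[1] for r in results) / len(results)
    return (syn, rep)


# ---------------------------------------------------------------------------
# codon bookkeeping under the masks
# ---------------------------------------------------------------------------

@dataclass
class _CodonData:
    """Observed codons at one usable codon site."""

    cols: np.ndarray                      # the 3 alignment columns
    variants: list[str]                   # distinct ingroup codons
    counts: list[int]                     # haplotypes carrying each variant
    outgroup: str | None                  # outgroup codon, if usable & sense


def usable_codons(aln: CodingAlignment, mask: SiteMask,
                  require_outgroup: bool = False) -> list[_CodonData]:
    """Codon sites usable under complete deletion.

    A codon is usable when all three of its columns are usable
    (``usable_total``, or ``usable_polarized`` when *require_outgroup*) and
    no observed ingroup codon is a stop.  The terminal stop codon of a full
    CDS is dropped here.  Outgroup codons that are stops are treated as
    missing for classification purposes.
    """
    mat = aln.ingroup_matrix()
    out = np.array(list(aln.outgroup))
    col_ok = mask.usable_polarized if require_outgroup else mask.usable_total
    result = []
    for cols in aln.codon_columns():
        if not col_ok[cols].all():
            continue
        sub = mat[:, cols]
        codon_strings = ["".join(row) for row in sub]
        variant_counts: dict[str, int] = {}
        for c in codon_strings:
            variant_counts[c] = variant_counts.get(c, 0) + 1
        variants = sorted(variant_counts)
        if any(CODON_TABLE[v] == "*" for v in variants):
            continue
        og = "".join(out[cols])
        if "-" in og or "N" in og or CODON_TABLE.get(og) == "*":
            og_codon = None
        else:
            og_codon = og
        if require_outgroup and og_codon is None:
            continue
        result.append(_CodonData(
            cols=cols,
            variants=variants,
            counts=[variant_counts[v] for v in variants],
            outgroup=og_codon,
        ))
    return result


@dataclass(frozen=True)
class SiteClassTotals:
    """Fractional synonymous/replacement site counts (Nei-Gojobori)."""

    syn_sites: float
    rep_sites: float
    n_codons: int


def site_class_totals(aln: CodingAlignment, mask: SiteMask,
                      include_outgroup: bool = False,
                      codons: list[_CodonData] | None = None) -> SiteClassTotals:
    """Class site counts averaged over the sample at the usable codons."""
    if codons is None:
        codons = usable_codons(aln, mask, require_outgroup=include_outgroup)
    syn = 0.0
    n_codons = len(codons)
    for cd in codons:
        total_w = sum(cd.counts) + (1 if include_outgroup else 0)
        s = sum(c * _SYN_SITES[v] for v, c in zip(cd.variants, cd.counts))
        if include_outgroup:
            s += _SYN_SITES[cd.outgroup]
        syn += s / total_w
    return SiteClassTotals(syn, 3.0 * n_codons - syn, n_codons)


# ---------------------------------------------------------------------------
# polymorphism statistics
# ---------------------------------------------------------------------------

def segregating_sites(aln: CodingAlignment, mask: SiteMask) -> int:
    """Number of usable columns with >= 2 distinct ingroup states."""
    mat = aln.ingroup_matrix()[:, mask.usable_total]
    if mat.shape[1] == 0:
        return 0
    return int(((mat != mat[0]).any(axis=0)).sum())


def mean_pairwise_differences(aln: CodingAlignment, mask: SiteMask) -> float:
    """Mean pairwise difference count over all C(n,2) ingroup pairs."""
    mat = aln.ingroup_matrix()[:, mask.usable_total]
    n = aln.n
    npairs = n * (n - 1) / 2.0
    total = 0.0
    for col in mat.T:
        _, counts = np.unique(col, return_counts=True)
        same = sum(c * (c - 1) / 2.0 for c in counts)
        total += npairs - same
    return total / npairs


def pairwise_pi(aln: CodingAlignment, mask: SiteMask,
                class_filter: str = "all") -> float:
    """Average pairwise diversity per site.

    ``class_filter='all'`` uses raw per-column mismatches over all usable
    columns; ``'syn'``/``'rep'`` use pathway-classified differences at usable
    codons divided by the corresponding fractional site totals.
    """
    n = aln.n
    npairs = n * (n - 1) / 2.0
    if class_filter == "all":
        denom = int(mask.usable_total.sum())
        if denom == 0:
            raise UndefinedStatisticError("no usable sites")
        return mean_pairwise_differences(aln, mask) / denom
    if class_filter not in ("syn", "rep"):
        raise ValueError(f"unknown class_filter {class_filter!r}")
    codons = usable_codons(aln, mask)
    totals = site_class_totals(aln, mask, codons=codons)
    denom = totals.syn_sites if class_filter == "syn" else totals.rep_sites
    if denom <= 0:
        raise UndefinedStatisticError(f"no {class_filter} sites")
    idx = 0 if class_filter == "syn" else 1
    diffs = 0.0
    for cd in codons:
        for (va, ca), (vb, cb) in itertools.combinations(
                zip(cd.variants, cd.counts), 2):
            diffs += ca * cb * classify_codon_differences(va, vb)[idx]
    return (diffs / npairs) / denom


@dataclass(frozen=True)
class UnfoldedSFS:
    """Derived-allele counts xi_1..xi_{n-1}, polarized by the outgroup."""

    n: int
    xi: np.ndarray                 # length n-1, xi[i-1] = count at frequency i
    sites_polarized: int           # usable polarized columns considered

    @property
    def S(self) -> int:
        return int(self.xi.sum())

    def __post_init__(self) -> None:
        assert len(self.xi) == self.n - 1
        assert (self.xi >= 0).all()


def unfolded_sfs(aln: CodingAlignment, mask: SiteMask) -> UnfoldedSFS:
    """Unfolded SFS over usable polarized columns.

    A column enters the SFS when the ingroup is biallelic and the outgroup
    carries one of the two ingroup alleles (the other is derived).  Columns
    with a third-state outgroup or >2 ingroup states are excluded.
    """
    n = aln.n
    xi = np.zeros(n - 1, dtype=np.int64)
    mat = aln.ingroup_matrix()
    out = np.array(list(aln.outgroup))
    cols = np.flatnonzero(mask.usable_polarized)
    for c in cols:
        col = mat[:, c]
        states, counts = np.unique(col, return_counts=True)
        if len(states) != 2:
            continue
        og = out[c]
        if og == states[0]:
            derived = counts[1]
        elif og == states[1]:
            derived = counts[0]
        else:
            continue  # third-state outgroup: cannot polarize
        xi[derived - 1] += 1
    return UnfoldedSFS(n=n, xi=xi, sites_polarized=len(cols))


# ---------------------------------------------------------------------------
# neutrality statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeutralityConstants:
    """Sample-size constants for Tajima's D and related estimators."""

    n: int
    a1: float   # sum_{i=1}^{n-1} 1/i
    a2: float   # sum_{i=1}^{n-1} 1/i^2
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def from_n(cls, n: int) -> "NeutralityConstants":
        if n < 2:
            raise ValueError("need n >= 2")
        i = np.arange(1, n)
        a1 = float((1.0 / i).sum())
        a2 = float((1.0 / i**2).sum())
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator S/a_n (per locus, count scale)."""
    return S / NeutralityConstants.from_n(n).a1


def tajimas_D(S: int, pi_count: float, n: int) -> float:
    """Tajima's (1989) D from S and mean pairwise differences (count form)."""
    if n < 4:
        raise UndefinedStatisticError("Tajima's D needs n >= 4")
    if S < 1:
        raise UndefinedStatisticError("Tajima's D undefined for S = 0")
    k = NeutralityConstants.from_n(n)
    var = k.e1 * S + k.e2 * S * (S - 1)
    return (pi_count - S / k.a1) / np.sqrt(var)


def fay_wu_H_normalized(sfs: UnfoldedSFS) -> float:
    """Normalized Fay & Wu's H (Zeng, Fu, Shi & Wu 2006).

    H = (theta_pi - theta_L) / sqrt(Var), with theta_L the high-frequency
    weighted estimator sum(i*xi_i)/(n-1).  Strongly negative when derived
    alleles segregate near fixation.
    """
    n = sfs.n
    if n < 3:
        raise UndefinedStatisticError("normalized H needs n >= 3")
    S = sfs.S
    if S < 1:
        raise UndefinedStatisticError("normalized H undefined with no polarized sites")
    i = np.arange(1, n)
    xi = sfs.xi
    theta_pi = float((xi * 2.0 * i * (n - i)).sum()) / (n * (n - 1))
    theta_L = float((xi * i).sum()) / (n - 1)
    k = NeutralityConstants.from_n(n)
    theta_W = S / k.a1
    theta_sq = S * (S - 1.0) / (k.a1**2 + k.a2)
    b_n1 = k.a2 + 1.0 / n**2      # sum_{i=1}^{n} 1/i^2
    var = (theta_W * (n - 2.0) / (6.0 * (n - 1.0))
           + theta_sq * (18.0 * n**2 * (3.0 * n + 2.0) * b_n1
                         - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0))
           / (9.0 * n * (n - 1.0)**2))
    return (theta_pi - theta_L) / np.sqrt(var)


def sfs_theta_pi(xi: np.ndarray, n: int) -> float:
    """Mean pairwise differences implied by an SFS (count form)."""
    i = np.arange(1, n)
    return float((xi * i * (n - i)).sum()) / (n * (n - 1) / 2.0)


# ---------------------------------------------------------------------------
# divergence
# ---------------------------------------------------------------------------

def jukes_cantor(p: float) -> float:
    """Jukes-Cantor correction K = -(3/4) ln(1 - 4p/3)."""
    if p >= 0.75:
        raise UndefinedStatisticError(
            f"proportion of differences p={p:.4f} >= 0.75 is outside the "
            "Jukes-Cantor domain")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def divergence_by_class(aln: CodingAlignment, mask: SiteMask,
                        class_filter: str) -> float:
    """Per-site Jukes-Cantor divergence from the outgroup, by codon class.

    p = mean over all ingroup x outgroup sequence pairs of (class
    differences)/(class sites), with class sites averaged over the ingroup
    sequences and the outgroup.
    """
    if class_filter not in ("syn", "rep"):
        raise ValueError(f"unknown class_filter {class_filter!r}")
    codons = usable_codons(aln, mask, require_outgroup=True)
    if not codons:
        raise UndefinedStatisticError("no usable codons with outgroup")
    totals = site_class_totals(aln, mask, include_outgroup=True, codons=codons)
    denom = totals.syn_sites if class_filter == "syn" else totals.rep_sites
    if denom <= 0:
        raise UndefinedStatisticError(f"no {class_filter} sites")
    idx = 0 if class_filter == "syn" else 1
    n = aln.n
    diffs = 0.0
    for cd in codons:
        for v, c in zip(cd.variants, cd.counts):
            diffs += c * classify_codon_differences(v, cd.outgroup)[idx]
    p = (diffs / n) / denom
    return jukes_cantor(p)


# ---------------------------------------------------------------------------
# per-gene summary
# ---------------------------------------------------------------------------

@dataclass
class GeneSummary:
    """One summary row per gene: n, sites, S, diversity, divergence, D, H."""

    gene_id: str
    n: int
    sites: int
    coding_sites: int
    S: int
    pi_tot: float
    pi_syn: float | None
    pi_rep: float | None
    K_syn: float | None
    K_rep: float | None
    D: float | None
    H_norm: float | None
    p_D: float | None = None      # empirical p, filled from a coalescent null
    p_H: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _try(fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except UndefinedStatisticError:
        return None


def gene_summary(aln: CodingAlignment, mask: SiteMask) -> GeneSummary:
    """Compute the full per-gene summary (empirical p-values left unset)."""
    S = segregating_sites(aln, mask)
    pi_count = mean_pairwise_differences(aln, mask)
    sfs = unfolded_sfs(aln, mask)
    return GeneSummary(
        gene_id=aln.gene_id,
        n=aln.n,
        sites=int(mask.usable_total.sum()),
        coding_sites=int((mask.usable_total & mask.coding).sum()),
        S=S,
        pi_tot=_try(pairwise_pi, aln, mask, "all"),
        pi_syn=_try(pairwise_pi, aln, mask, "syn"),
        pi_rep=_try(pairwise_pi, aln, mask, "rep"),
        K_syn=_try(divergence_by_class, aln, mask, "syn"),
        K_rep=_try(divergence_by_class, aln, mask, "rep"),
        D=_try(tajimas_D, S, pi_count, aln.n) if S >= 1 else None,
        H_norm=_try(fay_wu_H_normalized, sfs),
    )
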