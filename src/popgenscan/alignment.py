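"""Coding alignments with outgroup and exon annotation.

The unit of analysis is a multiple sequence alignment of ingroup haplotypes
plus a single outgroup sequence, annotated with the exon intervals that make
up the coding region.  Everything downstream (diversity, neutrality tests,
McDonald-Kreitman tables, window scans) consumes a :class:`CodingAlignment`
together with the shared :class:`SiteMask` built here.

Missing data are handled by complete deletion: an alignment column containing
a gap or ``N`` in *any* ingroup sequence is unusable for every statistic; a
gap/``N`` in the outgroup additionally removes the column from polarized
(outgroup-dependent) analyses only.  This keeps per-site denominators shared
across all statistics computed from one alignment.

Coordinates are 0-based half-open internally.  BED exon files are read as-is;
GFF3 (1-based inclusive) is converted on read.  Emitted tables use 1-based
inclusive coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = frozenset("ACGTN-")
_NUCS = "ACGT"

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class AlignmentError(ValueError):
    """Malformed alignment, annotation, or frame."""


@dataclass(frozen=True)
class CodingAlignment:
    """Aligned ingroup haplotypes, one outgroup, and an exon map.

    Parameters
    ----------
    gene_id : str
        Label used in all emitted tables.
    ingroup_ids, ingroup : tuple of str
        Haplotype names and their aligned sequences (A/C/G/T/N/-), all of
        identical length.
    outgroup_id, outgroup : str
        The single outgroup sequence (same length).
    exons : tuple of (start, end)
        Non-overlapping, sorted 0-based half-open intervals on alignment
        coordinates; their total length must be divisible by 3.
    """

    gene_id: str
    ingroup_ids: tuple[str, ...]
    ingroup: tuple[str, ...]
    outgroup_id: str
    outgroup: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.ingroup) < 2:
            raise AlignmentError(f"{self.gene_id}: need >= 2 ingroup haplotypes")
        if len(self.ingroup_ids) != len(self.ingroup):
            raise AlignmentError(f"{self.gene_id}: ids/sequences length mismatch")
        L = len(self.outgroup)
        for name, seq in zip(self.ingroup_ids + (self.outgroup_id,),
                             self.ingroup + (self.outgroup,)):
            if len(seq) != L:
                raise AlignmentError(
                    f"{self.gene_id}: sequence {name!r} has length {len(seq)}, "
                    f"expected {L} (ragged alignment)")
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"{self.gene_id}: sequence {name!r} contains invalid "
                    f"characters {sorted(bad)} (only A/C/G/T/N/- allowed)")
        prev_end = -1
        total = 0
        for start, end in self.exons:
            if not (0 <= start < end <= L):
                raise AlignmentError(
                    f"{self.gene_id}: exon [{start},{end}) outside [0,{L})")
            if start < prev_end:
                raise AlignmentError(
                    f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end
            total += end - start
        if total % 3 != 0:
            raise AlignmentError(
                f"{self.gene_id}: concatenated exon length {total} is not "
                f"divisible by 3 (frame error)")

    @property
    def length(self) -> int:
        return len(self.outgroup)

    @property
    def n(self) -> int:
        return len(self.ingroup)

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def coding_columns(self) -> np.ndarray:
        """Alignment columns belonging to exons, in transcript order."""
        if not self.exons:
            return np.empty(0, dtype=np.intp)
        return np.concatenate([np.arange(s, e) for s, e in self.exons])

    def codon_columns(self) -> np.ndarray:
        """(n_codons, 3) array mapping each codon position to its column."""
        return self.coding_columns().reshape(-1, 3)

    def ingroup_matrix(self) -> np.ndarray:
        """Ingroup sequences as an (n, L) array of single characters."""
        return np.array([list(s) for s in self.ingroup])


@dataclass
class SiteMask:
    """Per-column usability flags shared by every statistic.

    ``usable_total``
        no gap/N in any ingroup sequence;
    ``usable_polarized``
        additionally the outgroup is non-gap, non-N (implies usable_total);
    ``coding``
        column lies inside an exon.
    """

    usable_total: np.ndarray
    usable_polarized: np.ndarray
    coding: np.ndarray

    def __post_init__(self) -> None:
        L = len(self.usable_total)
        assert len(self.usable_polarized) == L and len(self.coding) == L
        assert not np.any(self.usable_polarized & ~self.usable_total), \
            "usable_polarized must imply usable_total"

    def restrict(self, start: int, end: int) -> "SiteMask":
        """Copy of the mask with every column outside [start, end) disabled.

        Lets the window engine reuse whole-gene statistic code unchanged.
        """
        keep = np.zeros_like(self.usable_total)
        keep[start:end] = True
        return SiteMask(self.usable_total & keep,
                        self.usable_polarized & keep,
                        self.coding.copy())


def build_site_masks(aln: CodingAlignment) -> SiteMask:
    """Complete-deletion site masks for *aln*."""
    mat = aln.ingroup_matrix()
    missing = (mat == "-") | (mat == "N")
    usable_total = ~missing.any(axis=0)
    out = np.array(list(aln.outgroup))
    out_ok = (out != "-") & (out != "N")
    coding = np.zeros(aln.length, dtype=bool)
    for s, e in aln.exons:
        coding[s:e] = True
    return SiteMask(usable_total, usable_total & out_ok, coding)


def _read_bed(path: Path) -> list[tuple[int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return [(int(r.start), int(r.end)) for r in df.itertuples()]


def _read_gff3(path: Path) -> list[tuple[int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["seqid", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"])
    df = df[df["type"].isin(["CDS", "exon"])]
    if (df["type"] == "CDS").any():
        df = df[df["type"] == "CDS"]
    # GFF3 is 1-based inclusive
    return [(int(r.start) - 1, int(r.end)) for r in df.itertuples()]


def read_exon_annotation(path: str | Path) -> list[tuple[int, int]]:
    """Read exon intervals, 0-based half-open; dialect chosen by extension."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        intervals = _read_bed(path)
    elif path.suffix.lower() in {".gff", ".gff3"}:
        intervals = _read_gff3(path)
    else:
        raise AlignmentError(
            f"unrecognised annotation extension {path.suffix!r} "
            "(expected .bed, .gff or .gff3)")
    return sorted(intervals)


def _check_stop_codons(aln: CodingAlignment) -> CodingAlignment:
    """Drop haplotypes with internal stop codons, warning by name.

    A stop in the *last* codon of the CDS is the normal terminal stop and is
    tolerated (that codon is excluded from codon-level statistics downstream).
    Codons containing gaps or N are not checked here; they are masked anyway.
    """
    codons = aln.codon_columns()
    if codons.shape[0] == 0:
        return aln
    internal = codons[:-1]
    keep_ids, keep_seqs = [], []
    for name, seq in zip(aln.ingroup_ids, aln.ingroup):
        arr = np.array(list(seq))
        bad = False
        for cols in internal:
            codon = "".join(arr[cols])
            if codon in STOP_CODONS:
                warnings.warn(
                    f"{aln.gene_id}: haplotype {name!r} carries an internal "
                    f"stop codon {codon} at alignment columns {list(cols)}; "
                    "haplotype excluded (likely frame/annotation error)")
                bad = True
                break
        if not bad:
            keep_ids.append(name)
            keep_seqs.append(seq)
    if len(keep_ids) == len(aln.ingroup_ids):
        return aln
    return replace(aln, ingroup_ids=tuple(keep_ids), ingroup=tuple(keep_seqs))


def read_coding_alignment(fasta_path: str | Path,
                          annotation_path: str | Path,
                          outgroup_id: str,
                          gene_id: str | None = None,
                          check_stops: bool = True) -> CodingAlignment:
    """Read a FASTA alignment plus exon annotation into a CodingAlignment.

    The record named *outgroup_id* becomes the outgroup; every other record
    is an ingroup haplotype (input order preserved).  Sequences are
    upper-cased; IUPAC ambiguity codes other than N are rejected.
    """
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) < 3:
        raise AlignmentError(f"{fasta_path}: need >= 3 records (2 ingroup + outgroup)")
    ids = [r.id for r in records]
    if outgroup_id not in ids:
        raise AlignmentError(
            f"{fasta_path}: outgroup {outgroup_id!r} not found among {ids}")
    outgroup = None
    in_ids, in_seqs = [], []
    for rec in records:
        seq = str(rec.seq).upper()
        if rec.id == outgroup_id:
            outgroup = seq
        else:
            in_ids.append(rec.id)
            in_seqs.append(seq)
    exons = read_exon_annotation(annotation_path)
    aln = CodingAlignment(
        gene_id=gene_id or fasta_path.stem,
        ingroup_ids=tuple(in_ids),
        ingroup=tuple(in_seqs),
        outgroup_id=outgroup_id,
        outgroup=outgroup,
        exons=tuple(exons),
    )
    if check_stops:
        aln = _check_stop_codons(aln)
    return aln


def write_coding_alignment(aln: CodingAlignment,
                           fasta_path: str | Path,
                           bed_path: str | Path) -> None:
    """Write FASTA + BED so that read_coding_alignment round-trips."""
    records = [SeqRecord(Seq(s), id=i, description="")
               for i, s in zip(aln.ingroup_ids, aln.ingroup)]
    records.append(SeqRecord(Seq(aln.outgroup), id=aln.outgroup_id, description=""))
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(bed_path, "w") as fh:
        for s, e in aln.exons:
            fh.write(f"{aln.gene_id}\t{s}\t{e}\n")
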