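"""Alignment of trimmed reads and extraction of polyadenylation-adjacent sites.

Two alignment routes feed the same site table:

* :class:`GenomeIndex` — a deliberately simple built-in exact mapper
  (seed on the first 16-mer, verify the full read, on both strands).  A
  read maps only when exactly one full-length exact locus exists; reads
  with zero loci or several are tallied, not placed.  Its MAPQ is fixed
  at 60 by convention.
* :func:`read_sam` — ingestion of primary mapped records from an external
  aligner's SAM/BAM, carrying real MAPQ through.

The polyadenylation-adjacent site is the genomic coordinate of the first
(5') base of the trimmed read: ``ref_start`` for a forward alignment,
``ref_end - 1`` for a reverse one.  Because the library is first-strand
cDNA (the leading poly-T is the complement of the poly(A) tail), a read is
antisense to its mRNA, so the site's strand defaults to the opposite of
the alignment strand (``orientation="antisense"``; ``"sense"`` flips the
convention for protocols producing mRNA-sense reads).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
import pysam

from .preprocess import Read

logger = logging.getLogger(__name__)

_RC = str.maketrans("ACGTN", "TGCAN")

SOFTCLIP_WARN_NT = 3
NAIVE_MAPQ = 60


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Alignment:
    read_id: str
    chrom: str
    align_strand: str  # strand of the genome the READ matches
    ref_start: int  # 0-based half-open
    ref_end: int
    mapq: int
    is_unique: bool = True

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError("empty alignment interval")


@dataclass(frozen=True)
class PolyASite:
    chrom: str
    position: int
    site_strand: str
    read_id: str
    sample_id: str
    mapq: int


@dataclass
class MapStats:
    n_reads: int = 0
    n_mapped: int = 0
    n_unmapped: int = 0
    n_multi: int = 0


class GenomeIndex:
    """Exact-match read placement over an in-memory genome.

    Ungapped, mismatch-free by design: the goal is auditable site
    extraction on simulated data, not a general aligner.  Reads shorter
    than the seed size (16 nt) are rejected upstream by the length filter.
    """

    SEED = 16

    def __init__(self, genome: dict[str, str]):
        self.genome = genome
        self._index: dict[str, list[tuple[str, int]]] = {}
        k = self.SEED
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((chrom, i))

    def _exact_loci(self, seq: str) -> list[tuple[str, int]]:
        out = []
        for chrom, i in self._index.get(seq[: self.SEED], ()):
            if self.genome[chrom][i : i + len(seq)] == seq:
                out.append((chrom, i))
        return out

    def map_read(self, read: Read, stats: Optional[MapStats] = None) -> Optional[Alignment]:
        """Unique exact alignment of the read or its reverse complement."""
        if len(read.sequence) < self.SEED:
            raise ValueError(f"read {read.read_id!r} shorter than {self.SEED} nt")
        if stats is not None:
            stats.n_reads += 1
        hits = [
            (chrom, "+", i) for chrom, i in self._exact_loci(read.sequence)
        ] + [
            (chrom, "-", i) for chrom, i in self._exact_loci(revcomp(read.sequence))
        ]
        if len(hits) == 1:
            chrom, strand, i = hits[0]
            if stats is not None:
                stats.n_mapped += 1
            return Alignment(
                read.read_id, chrom, strand, i, i + len(read.sequence),
                mapq=NAIVE_MAPQ, is_unique=True,
            )
        if stats is not None:
            if hits:
                stats.n_multi += 1
            else:
                stats.n_unmapped += 1
        return None


def pas_from_alignment(aln: Alignment, orientation: str = "antisense") -> tuple[int, str]:
    """(position, site_strand) of the polyadenylation-adjacent base.

    The site is the first sequenced base of the trimmed read:
    ``ref_start`` on a forward alignment, ``ref_end - 1`` on a reverse
    one.  With the default antisense orientation the site strand is the
    opposite of the alignment strand.
    """
    if orientation not in ("antisense", "sense"):
        raise ValueError("orientation must be 'antisense' or 'sense'")
    if aln.align_strand == "+":
        position = aln.ref_start
        site_strand = "-" if orientation == "antisense" else "+"
    else:
        position = aln.ref_end - 1
        site_strand = "+" if orientation == "antisense" else "-"
    return position, site_strand


def sites_from_reads(
    reads: Iterable[Read],
    index: GenomeIndex,
    sample_id: str,
    orientation: str = "antisense",
) -> tuple[list[PolyASite], MapStats]:
    """Map trimmed reads and convert each unique alignment to a site."""
    stats = MapStats()
    sites = []
    for read in reads:
        aln = index.map_read(read, stats)
        if aln is None:
            continue
        pos, strand = pas_from_alignment(aln, orientation)
        sites.append(
            PolyASite(aln.chrom, pos, strand, read.read_id, sample_id, aln.mapq)
        )
    return sites, stats


def read_sam(
    path: str | os.PathLike,
    sample_id: Optional[str] = None,
    rg_to_sample: Optional[dict[str, str]] = None,
) -> list[Alignment]:
    """Primary mapped alignments from a SAM/BAM file.

    Secondary, supplementary and unmapped records are skipped.  Soft
    clipping is honoured by taking the first *aligned* base (pysam's
    reference_start/reference_end already exclude clipped bases); clips
    longer than 3 nt are logged.
    """
    alignments = []
    with pysam.AlignmentFile(str(path), check_sq=True) as fh:
        if not fh.header.get("SQ"):
            raise ValueError(f"{path}: SAM header has no @SQ reference lines")
        n_unmapped = 0
        for rec in fh:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                continue
            cig = rec.cigartuples or []
            lead_clip = cig[0][1] if cig and cig[0][0] == 4 else 0
            tail_clip = cig[-1][1] if cig and cig[-1][0] == 4 else 0
            clip5 = tail_clip if rec.is_reverse else lead_clip
            if clip5 > SOFTCLIP_WARN_NT:
                logger.warning(
                    "read %s: %d nt soft-clipped at the 5' end", rec.query_name, clip5
                )
            alignments.append(
                Alignment(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    align_strand="-" if rec.is_reverse else "+",
                    ref_start=rec.reference_start,
                    ref_end=rec.reference_end,
                    mapq=rec.mapping_quality,
                    is_unique=True,
                )
            )
    if not alignments and n_unmapped:
        logger.warning("%s: all %d records unmapped", path, n_unmapped)
    return alignments


def sites_from_sam(
    path: str | os.PathLike,
    sample_id: Optional[str] = None,
    rg_to_sample: Optional[dict[str, str]] = None,
    orientation: str = "antisense",
) -> list[PolyASite]:
    """Site extraction from an external aligner's SAM/BAM output.

    The sample is taken from the record's read group when ``rg_to_sample``
    is given, else from ``sample_id`` (a per-file mapping in the design).
    """
    sites = []
    with pysam.AlignmentFile(str(path), check_sq=True) as fh:
        if not fh.header.get("SQ"):
            raise ValueError(f"{path}: SAM header has no @SQ reference lines")
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            aln = Alignment(
                rec.query_name,
                rec.reference_name,
                "-" if rec.is_reverse else "+",
                rec.reference_start,
                rec.reference_end,
                rec.mapping_quality,
            )
            pos, strand = pas_from_alignment(aln, orientation)
            if rg_to_sample is not None and rec.has_tag("RG"):
                sid = rg_to_sample[rec.get_tag("RG")]
            elif sample_id is not None:
                sid = sample_id
            else:
                raise ValueError("sample_id or rg_to_sample required")
            sites.append(PolyASite(aln.chrom, pos, strand, aln.read_id, sid, aln.mapq))
    return sites


def sites_to_frame(sites: Iterable[PolyASite]) -> pd.DataFrame:
    sites = list(sites)
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "position": [s.position for s in sites],
            "strand": [s.site_strand for s in sites],
            "read_id": [s.read_id for s in sites],
            "sample_id": [s.sample_id for s in sites],
            "mapq": [s.mapq for s in sites],
        }
    )


def write_site_bed(sites: Iterable[PolyASite], path: str | os.PathLike) -> None:
    """BED6(+1): chrom, start, end, read_id, mapq score, strand, sample_id."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t{s.read_id}\t"
                f"{s.mapq}\t{s.site_strand}\t{s.sample_id}\n"
            )


def read_site_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "position", "end", "read_id", "mapq", "strand", "sample_id"],
    )
    return df[["chrom", "position", "strand", "read_id", "sample_id", "mapq"]]
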