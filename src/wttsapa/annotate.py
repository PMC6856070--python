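"""Gene models and six-class annotation of predicted APA sites.

Each predicted APA site (a cluster of polyadenylation-adjacent read 5'
positions) is assigned to a same-strand transcript and classified into one
of six categories widely used for 3'-end data:

``Ex``
    exonic — the cluster span lies entirely inside exons.
``Di``
    distal — the representative coordinate sits at the annotated 3'
    terminus (within ``di_tolerance`` nt).
``Edi``
    extended distal — 1..``edi_max`` nt downstream of the 3' terminus.
``Eex``
    extended exonic — the span overlaps an exon and reaches at least
    ``eex_min_intronic`` nt into an adjacent intron.
``In``
    intronic — the span lies entirely inside one intron.
``An``
    antisense — no same-strand assignment exists, but the representative
    falls inside an exon of an opposite-strand transcript.

``Ex``/``Di``/``Edi`` are the conventional classes, the rest
non-conventional.  All internal coordinates are 0-based half-open; GFF3's
1-based closed convention is converted at the file boundary only.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

CLASS_CODES = ("Ex", "Di", "Edi", "Eex", "In", "An")
CONVENTIONAL = frozenset({"Ex", "Di", "Edi"})

# overlap-resolution priority among sense classes (lower wins)
_PRIORITY = {"Di": 0, "Ex": 1, "Eex": 2, "In": 3, "Edi": 4}


@dataclass(frozen=True)
class GeneModel:
    """A stranded transcript with exon structure.

    ``exons`` are 0-based half-open intervals sorted by start and
    non-overlapping.  ``tes`` is the genomic coordinate of the 3'-terminal
    base (strand-aware): the last exonic base for ``+``, the first for
    ``-``.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ex = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        if not ex:
            raise ValueError("transcript requires at least one exon")
        for (a, b), (c, _) in zip(ex, ex[1:]):
            if b > c:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        if any(a >= b for a, b in ex):
            raise ValueError("empty exon interval")
        object.__setattr__(self, "exons", ex)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
            if b_start > a_end
        )


@dataclass(frozen=True)
class AnnotParams:
    """Tolerances for the six-class assignment (all in nt)."""

    di_tolerance: int = 24
    edi_max: int = 2000
    eex_min_intronic: int = 10

    def __post_init__(self) -> None:
        if min(self.di_tolerance, self.edi_max, self.eex_min_intronic) < 0:
            raise ValueError("annotation tolerances must be >= 0")


@dataclass
class ClassifiedSite:
    cluster_id: str
    gene_id: Optional[str]
    transcript_id: Optional[str]
    class_code: str  # one of CLASS_CODES or "NA"

    @property
    def conventional(self) -> bool:
        return self.class_code in CONVENTIONAL


def write_gff3(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene/mRNA/exon features as GFF3 (1-based closed coordinates)."""
    lines = ["##gff-version 3"]
    for g in genes:
        s, e = g.start + 1, g.end
        common = f"{g.chrom}\twttsapa\t"
        lines.append(
            f"{common}gene\t{s}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        lines.append(
            f"{common}mRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
            f"ID={g.transcript_id};Parent={g.gene_id}"
        )
        for i, (a, b) in enumerate(g.exons, 1):
            lines.append(
                f"{common}exon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                f"ID={g.transcript_id}.exon{i};Parent={g.transcript_id}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_gff(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene/mRNA/exon features from GFF3 into :class:`GeneModel` list.

    GFF3 1-based closed intervals are converted to 0-based half-open.  An
    exon without a parent transcript is a format error.
    """
    with open(path) as fh:
        has_features = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_features:
        warnings.warn(f"GFF3 file {path} contains no features")
        return []
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    tx_gene: dict[str, str] = {}
    tx_meta: dict[str, tuple[str, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for mrna in db.features_of_type("mRNA"):
        parent = mrna.attributes.get("Parent", [mrna.id])[0]
        tx_gene[mrna.id] = parent
        tx_meta[mrna.id] = (mrna.seqid, mrna.strand)
        exons[mrna.id] = []
    for ex in db.features_of_type("exon"):
        parents = ex.attributes.get("Parent", [])
        if not parents or parents[0] not in exons:
            raise ValueError(
                f"exon {ex.id!r} at {ex.seqid}:{ex.start} has no parent mRNA"
            )
        exons[parents[0]].append((ex.start - 1, ex.end))
    out = []
    for tx_id, ex_list in exons.items():
        chrom, strand = tx_meta[tx_id]
        out.append(
            GeneModel(
                gene_id=tx_gene[tx_id],
                transcript_id=tx_id,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(ex_list)),
            )
        )
    out.sort(key=lambda g: (g.chrom, g.start, g.transcript_id))
    return out


class AnnotationIndex:
    """Interval indexes over transcripts for fast candidate lookup.

    Sense candidates for a site are same-strand transcripts whose window
    ``[gene span .. tes + edi_max]`` (strand-aware) contains the
    representative; antisense lookups use exon intervals directly.
    """

    def __init__(self, genes: Sequence[GeneModel], params: AnnotParams):
        self.params = params
        self.genes = list(genes)
        self._sense: dict[str, IntervalTree] = {}
        self._exonic: dict[str, IntervalTree] = {}
        for g in self.genes:
            if g.strand == "+":
                lo, hi = g.start, g.tes + params.edi_max + 1
            else:
                lo, hi = g.tes - params.edi_max, g.end
            self._sense.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g)
            for a, b in g.exons:
                self._exonic.setdefault(g.chrom, IntervalTree()).addi(a, b, g)

    def sense_candidates(self, chrom: str, strand: str, pos: int) -> list[GeneModel]:
        tree = self._sense.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos) if iv.data.strand == strand]

    def antisense_exonic(self, chrom: str, strand: str, pos: int) -> list[GeneModel]:
        tree = self._exonic.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos) if iv.data.strand != strand]


def _span_composition(tx: GeneModel, lo: int, hi: int) -> tuple[int, int]:
    """Exonic and intronic base counts of the inclusive span [lo, hi]."""
    exonic = sum(
        max(0, min(hi + 1, b) - max(lo, a)) for a, b in tx.exons
    )
    intronic = sum(
        max(0, min(hi + 1, b) - max(lo, a)) for a, b in tx.introns
    )
    return exonic, intronic


def _sense_class(
    tx: GeneModel, rep: int, span_lo: int, span_hi: int, params: AnnotParams
) -> Optional[str]:
    """Class of the site w.r.t. one same-strand transcript, or None."""
    if abs(rep - tx.tes) <= params.di_tolerance:
        return "Di"
    span_len = span_hi - span_lo + 1
    exonic, intronic = _span_composition(tx, span_lo, span_hi)
    if exonic == span_len:
        return "Ex"
    if exonic > 0 and intronic >= params.eex_min_intronic:
        return "Eex"
    if intronic == span_len:
        return "In"
    downstream = rep - tx.tes if tx.strand == "+" else tx.tes - rep
    if 1 <= downstream <= params.edi_max:
        return "Edi"
    return None


def classify_site(
    cluster,
    index: AnnotationIndex,
    params: Optional[AnnotParams] = None,
) -> ClassifiedSite:
    """Assign one APA cluster to a gene and one of the six classes.

    Sense classes are resolved with priority Di > Ex > Eex > In > Edi; when
    several transcripts qualify, the one whose 3' terminus is nearest the
    representative wins (ties by transcript_id).  ``An`` is considered only
    when no sense assignment exists; otherwise the code is ``NA``.
    """
    params = params or index.params
    rep = cluster.representative
    lo, hi = cluster.span
    best: Optional[tuple[int, int, str, GeneModel, str]] = None
    for tx in index.sense_candidates(cluster.chrom, cluster.strand, rep):
        code = _sense_class(tx, rep, lo, hi, params)
        if code is None:
            continue
        key = (_PRIORITY[code], abs(rep - tx.tes), tx.transcript_id)
        if best is None or key < (best[0], best[1], best[4]):
            best = (key[0], key[1], code, tx, tx.transcript_id)
    if best is not None:
        _, _, code, tx, _ = best
        return ClassifiedSite(cluster.cluster_id, tx.gene_id, tx.transcript_id, code)
    anti = index.antisense_exonic(cluster.chrom, cluster.strand, rep)
    if anti:
        tx = min(anti, key=lambda t: (abs(rep - t.tes), t.transcript_id))
        return ClassifiedSite(cluster.cluster_id, tx.gene_id, tx.transcript_id, "An")
    return ClassifiedSite(cluster.cluster_id, None, None, "NA")


def classify_all(
    clusters: Sequence,
    genes: Sequence[GeneModel],
    params: Optional[AnnotParams] = None,
) -> tuple[list[ClassifiedSite], dict[str, int]]:
    """Classify every cluster; returns sites and a per-code tally."""
    params = params or AnnotParams()
    index = AnnotationIndex(genes, params)
    sites = [classify_site(c, index, params) for c in clusters]
    tally = {code: 0 for code in CLASS_CODES + ("NA",)}
    for s in sites:
        tally[s.class_code] += 1
    return sites, tally


def classified_to_frame(sites: Sequence[ClassifiedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [s.cluster_id for s in sites],
            "gene_id": [s.gene_id for s in sites],
            "transcript_id": [s.transcript_id for s in sites],
            "class_code": [s.class_code for s in sites],
            "conventional": [s.conventional for s in sites],
        }
    )
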