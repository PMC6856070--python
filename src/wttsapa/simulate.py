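"""Synthetic 3'-end sequencing data with a known truth table.

The generator builds a toy genome, places non-overlapping stranded gene
models with clear 2 kb+ flanks, plants polyadenylation sites whose
geometry satisfies one of the six annotation classes by construction, and
emits WTTS-seq-like reads: a leading poly-T tract (the sequenced
complement of the poly(A) tail) followed by first-strand cDNA — the
reverse complement of the mRNA 3' end read from the site into the
transcript body.  A read from a ``+`` strand site therefore aligns to the
``-`` genomic strand and vice versa.

Per-site, per-sample read counts are drawn from a negative binomial with
``variance = mean + dispersion * mean**2``; a fixed seed makes every
output byte-identical across runs.  Extended-exonic (Eex) truth sites are
planted as a two-position cluster (a dominant exonic representative plus
a lower-count intronic satellite 10+ nt into the intron) because a
single-position cluster has no span to extend.

What this emulates — and what it does not: read counts, poly-T tracts,
substitution errors and per-class geometry are modelled; RNA secondary
structure, internal priming, fragment-length effects, PCR duplicates and
platform-specific (flow-space) errors are not.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import CLASS_CODES, GeneModel, write_gff3
from .mapping import revcomp

_BASES = np.array(list("ACGT"))

# rng stream ids, one per generation stage, so adding a stage never
# perturbs the others
_STAGE_GENOME, _STAGE_GENES, _STAGE_TRUTH, _STAGE_READS = 0, 1, 2, 3


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the simulation.

    Defaults mirror the design the pipeline targets: 8 samples per
    condition, a 24-nt-window-safe site layout (same-strand sites >= 25 nt
    apart), poly-T tracts of 5-15 nt, constant Q30 base qualities, and
    per-site expected counts well above the 16-read expression cutoff.
    """

    seed: int
    n_chrom: int = 1
    chrom_length: int = 120_000
    n_genes: int = 12
    exons_per_gene: tuple[int, int] = (3, 5)
    n_sites: int = 60
    class_fractions: tuple[tuple[str, float], ...] = tuple(
        (c, 1.0 / 6.0) for c in CLASS_CODES
    )
    samples_per_condition: int = 8
    polyt_range: tuple[int, int] = (5, 15)
    read_length: int = 50
    substitution_error_rate: float = 0.0
    nb_dispersion: float = 0.05
    mean_count: float = 60.0
    n_de_sites: int = 0
    log2_effect: float = 0.0
    low_quality_fraction: float = 0.0
    qual_high: int = 30
    qual_low: int = 2
    min_read_after_trim: int = 16

    def __post_init__(self) -> None:
        if self.n_chrom <= 0 or self.chrom_length <= 0:
            raise ValueError("n_chrom and chrom_length must be positive")
        if self.n_genes <= 0 or self.samples_per_condition <= 0:
            raise ValueError("n_genes and samples_per_condition must be positive")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        fr = dict(self.class_fractions)
        if set(fr) - set(CLASS_CODES):
            raise ValueError(f"unknown class codes in fractions: {set(fr) - set(CLASS_CODES)}")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        lo, hi = self.polyt_range
        if not (1 <= lo <= hi):
            raise ValueError("polyt_range must be 1 <= lo <= hi")
        if self.read_length < self.min_read_after_trim + hi:
            raise ValueError(
                f"read_length {self.read_length} cannot host a {hi} nt poly-T tract "
                f"and still leave {self.min_read_after_trim} nt for mapping"
            )
        if not 0 <= self.substitution_error_rate < 1:
            raise ValueError("substitution_error_rate must be in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        n = self.samples_per_condition
        return [f"C{i + 1}" for i in range(n)] + [f"T{i + 1}" for i in range(n)]

    @property
    def conditions(self) -> dict[str, str]:
        n = self.samples_per_condition
        return {s: ("control" if i < n else "treated")
                for i, s in enumerate(self.sample_ids)}


@dataclass(frozen=True)
class TruthRecord:
    """One planted polyadenylation site with its expected read support."""

    site_id: str
    chrom: str
    strand: str
    position: int
    gene_id: Optional[str]
    true_class: str
    expected_counts: tuple[float, ...]
    nb_dispersion: float
    log2_effect: float
    satellites: tuple[int, ...] = ()  # secondary member positions (Eex)


def _rng(params: SimParams, stage: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stage])


def nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Negative-binomial counts with var = mean + dispersion * mean**2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


def generate_genome(params: SimParams) -> dict[str, str]:
    """Random ACGT chromosomes, chr1..chrN, deterministic under the seed."""
    rng = _rng(params, _STAGE_GENOME)
    return {
        f"chr{i + 1}": "".join(
            _BASES[rng.integers(0, 4, params.chrom_length)]
        )
        for i in range(params.n_chrom)
    }


_EDGE_MARGIN = 1700  # room for 1.5 kb Edi placement plus read payload
_GENE_GAP = 3000  # keeps neighbouring 2 kb downstream windows disjoint


def generate_annotation(
    genome: dict[str, str], params: SimParams
) -> list[GeneModel]:
    """Place non-overlapping multi-exon genes on alternating strands."""
    if not genome:
        raise ValueError("genome is empty")
    rng = _rng(params, _STAGE_GENES)
    genes: list[GeneModel] = []
    chroms = list(genome)
    ci = 0
    cursor = _EDGE_MARGIN
    lo_ex, hi_ex = params.exons_per_gene
    for gi in range(params.n_genes):
        n_ex = int(rng.integers(lo_ex, hi_ex + 1))
        ex_lens = rng.integers(150, 401, n_ex)
        in_lens = rng.integers(250, 601, max(0, n_ex - 1))
        span = int(ex_lens.sum() + in_lens.sum())
        while ci < len(chroms) and cursor + span + _EDGE_MARGIN > len(
            genome[chroms[ci]]
        ):
            ci += 1
            cursor = _EDGE_MARGIN
        if ci >= len(chroms):
            raise ValueError(
                f"genome too small: placed {gi} of {params.n_genes} genes"
            )
        exons = []
        pos = cursor
        for k in range(n_ex):
            exons.append((pos, pos + int(ex_lens[k])))
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                pos += int(in_lens[k])
        strand = "+" if gi % 2 == 0 else "-"
        gid = f"gene{gi + 1:04d}"
        genes.append(
            GeneModel(gid, f"{gid}.t1", chroms[ci], strand, tuple(exons))
        )
        cursor = pos + _GENE_GAP + int(rng.integers(0, 500))
    return genes


def _class_counts(params: SimParams) -> dict[str, int]:
    fr = dict(params.class_fractions)
    counts = {c: int(round(fr.get(c, 0.0) * params.n_sites)) for c in CLASS_CODES}
    # fix rounding drift deterministically, largest fractions first
    drift = params.n_sites - sum(counts.values())
    order = sorted(CLASS_CODES, key=lambda c: -fr.get(c, 0.0))
    i = 0
    while drift != 0:
        c = order[i % len(order)]
        step = 1 if drift > 0 else -1
        if counts[c] + step >= 0:
            counts[c] += step
            drift -= step
        i += 1
    return counts


def _site_position(gene: GeneModel, code: str) -> tuple[int, tuple[int, ...], str]:
    """(position, satellite positions, site strand) for one planted class."""
    ex = gene.exons
    if gene.strand == "+":
        if code == "Ex":
            a, b = ex[0]
            return (a + b) // 2, (), "+"
        if code == "Di":
            return gene.tes, (), "+"
        if code == "In":
            a, b = gene.introns[0]
            return (a + b) // 2, (), "+"
        if code == "Eex":
            e = ex[0][1]
            return e - 6, (e + 14,), "+"
        if code == "An":
            a, b = ex[len(ex) // 2]
            return (a + b) // 2, (), "-"
        raise ValueError(code)  # Edi handled by caller (needs rng)
    else:
        if code == "Ex":
            a, b = ex[-1]
            return (a + b) // 2, (), "-"
        if code == "Di":
            return gene.tes, (), "-"
        if code == "In":
            a, b = gene.introns[-1]
            return (a + b) // 2, (), "-"
        if code == "Eex":
            s = ex[-1][0]
            return s + 6, (s - 14,), "-"
        if code == "An":
            a, b = ex[len(ex) // 2]
            return (a + b) // 2, (), "+"
        raise ValueError(code)


def plant_truth_sites(
    genome: dict[str, str], genes: Sequence[GeneModel], params: SimParams
) -> tuple[list[TruthRecord], dict[str, str]]:
    """Plant truth sites and return (records, genome with fixed site bases).

    Each record's geometry satisfies its class under the classifier's
    rules; same-strand sites sit > 24 nt apart so clustering cannot merge
    them.  The base at each planted position is adjusted when necessary so
    the first post-poly-T read base is never 'T' (leading-T trimming would
    otherwise shift the site).
    """
    rng = _rng(params, _STAGE_TRUTH)
    counts = _class_counts(params)
    n_samples = 2 * params.samples_per_condition
    with_introns = [g for g in genes if g.introns]
    for code in ("In", "Eex"):
        if counts.get(code, 0) > 0 and not with_introns:
            raise ValueError(
                f"cannot plant {code} sites: no gene has an intron "
                "(exons_per_gene must allow >= 2 exons)"
            )
    for code, n in counts.items():
        pool = with_introns if code in ("In", "Eex") else genes
        if n > len(pool):
            raise ValueError(
                f"cannot place {n} {code} sites with only {len(pool)} host genes"
            )
    records: list[TruthRecord] = []
    mutable = {c: list(s) for c, s in genome.items()}
    site_no = 0
    de_assigned = 0
    for code in CLASS_CODES:
        pool = with_introns if code in ("In", "Eex") else list(genes)
        for k in range(counts[code]):
            gene = pool[k % len(pool)]
            if code == "Edi":
                d = int(rng.integers(100, 1501))
                pos = gene.tes + d if gene.strand == "+" else gene.tes - d
                sats: tuple[int, ...] = ()
                strand = gene.strand
            else:
                pos, sats, strand = _site_position(gene, code)
            site_no += 1
            lfc = 0.0
            if de_assigned < params.n_de_sites:
                lfc = params.log2_effect * (1 if de_assigned % 2 == 0 else -1)
                de_assigned += 1
            base = params.mean_count
            expected = tuple(
                [base] * params.samples_per_condition
                + [base * 2.0 ** lfc] * params.samples_per_condition
            )
            assert len(expected) == n_samples
            for p in (pos, *sats):
                cur = mutable[gene.chrom][p]
                if strand == "+" and cur == "A":
                    mutable[gene.chrom][p] = "G"
                elif strand == "-" and cur == "T":
                    mutable[gene.chrom][p] = "C"
            records.append(
                TruthRecord(
                    site_id=f"S{site_no:04d}",
                    chrom=gene.chrom,
                    strand=strand,
                    position=pos,
                    gene_id=gene.gene_id,
                    true_class=code,
                    expected_counts=expected,
                    nb_dispersion=params.nb_dispersion,
                    log2_effect=lfc,
                    satellites=sats,
                )
            )
    fixed = {c: "".join(s) for c, s in mutable.items()}
    return records, fixed


def _read_payload(genome: dict[str, str], chrom: str, pos: int, strand: str,
                  length: int) -> str:
    """Genomic payload of a read whose 5' (post-poly-T) base sits at pos."""
    seq = genome[chrom]
    if strand == "+":
        # mRNA sense ends at pos; first-strand cDNA aligns to the - strand
        return revcomp(seq[pos - length + 1 : pos + 1])
    return seq[pos : pos + length]


def simulate_reads(
    genome: dict[str, str],
    truth: Sequence[TruthRecord],
    params: SimParams,
    outdir: str | os.PathLike,
) -> dict[str, Path]:
    """Write per-sample FASTQ files plus truth and design TSVs.

    Per sample and site, the read count is a negative-binomial draw around
    the site's expected count; each read is poly-T + payload, truncated to
    ``read_length``, with substitution errors at the configured rate
    (never inside the poly-T tract).  Base qualities are constant Q30
    except for an optional fraction of uniformly low-quality (Q2) reads
    used to exercise the quality filter.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(params, _STAGE_READS)
    lo_t, hi_t = params.polyt_range
    paths: dict[str, Path] = {}
    bases = "ACGT"
    for si, sample in enumerate(params.sample_ids):
        path = outdir / f"{sample}.fastq"
        paths[sample] = path
        with open(path, "w") as fh:
            for rec in truth:
                n_total = int(nb_draw(rng, rec.expected_counts[si], rec.nb_dispersion))
                n_sat = n_total // 3 if rec.satellites else 0
                per_pos = [(rec.position, n_total - n_sat)] + [
                    (p, n_sat // len(rec.satellites)) for p in rec.satellites
                ]
                for pos, n in per_pos:
                    for i in range(n):
                        t_len = int(rng.integers(lo_t, hi_t + 1))
                        pay_len = params.read_length - t_len
                        payload = _read_payload(
                            genome, rec.chrom, pos, rec.strand, pay_len
                        )
                        if params.substitution_error_rate > 0:
                            plist = list(payload)
                            hits = np.flatnonzero(
                                rng.random(pay_len) < params.substitution_error_rate
                            )
                            for j in hits:
                                alt = bases.replace(plist[j], "")
                                plist[j] = alt[int(rng.integers(0, 3))]
                            payload = "".join(plist)
                        seq = "T" * t_len + payload
                        q = params.qual_high
                        if (
                            params.low_quality_fraction > 0
                            and rng.random() < params.low_quality_fraction
                        ):
                            q = params.qual_low
                        qual = chr(q + 33) * len(seq)
                        rid = f"{rec.site_id}|{sample}|{pos}|{i}"
                        fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    truth_path = outdir / "truth.tsv"
    write_truth_table(truth, params.sample_ids, truth_path)
    design_path = outdir / "design.tsv"
    write_design(params, design_path)
    paths["truth"] = truth_path
    paths["design"] = design_path
    return paths


def write_truth_table(
    truth: Sequence[TruthRecord], sample_ids: Sequence[str], path: str | os.PathLike
) -> None:
    rows = []
    for r in truth:
        row = {
            "site_id": r.site_id,
            "chrom": r.chrom,
            "position": r.position,
            "strand": r.strand,
            "gene_id": r.gene_id,
            "true_class": r.true_class,
            "log2_effect": r.log2_effect,
            "nb_dispersion": r.nb_dispersion,
            "satellites": ",".join(map(str, r.satellites)),
        }
        for s, e in zip(sample_ids, r.expected_counts):
            row[f"expected_{s}"] = e
        rows.append(row)
    cols = [
        "site_id", "chrom", "position", "strand", "gene_id", "true_class",
        "log2_effect", "nb_dispersion", "satellites",
        *[f"expected_{s}" for s in sample_ids],
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_design(params: SimParams, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "sample_id": params.sample_ids,
            "condition": [params.conditions[s] for s in params.sample_ids],
        }
    ).to_csv(path, sep="\t", index=False)


def write_fasta(genome: dict[str, str], path: str | os.PathLike) -> None:
    recs = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def simulate_dataset(params: SimParams, outdir: str | os.PathLike) -> dict:
    """Full generation: genome FASTA, GFF3, per-sample FASTQs, truth, design.

    Returns a dict with in-memory objects (genome, genes, truth) and all
    output paths.  Byte-identical across runs with the same params.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(params)
    genes = generate_annotation(genome, params)
    truth, genome = plant_truth_sites(genome, genes, params)
    fasta = outdir / "genome.fa"
    write_fasta(genome, fasta)
    gff = outdir / "annotation.gff3"
    write_gff3(genes, gff)
    paths = simulate_reads(genome, truth, params, outdir)
    return {
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "fasta": fasta,
        "gff": gff,
        "fastq": {s: paths[s] for s in params.sample_ids},
        "truth_tsv": paths["truth"],
        "design_tsv": paths["design"],
    }


def simulate_count_matrix(
    n_sites: int,
    n_per_group: int,
    dispersion: float,
    seed: int,
    mean_range: tuple[float, float] = (20.0, 500.0),
    n_de: int = 0,
    log2_effect: float = 0.0,
    lib_size_range: tuple[float, float] = (0.7, 1.4),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Count-level NB simulation for differential-testing studies.

    Returns (counts [n_sites x 2*n_per_group], treated mask over samples,
    true per-site log2 fold changes).  Site base means are log-uniform over
    ``mean_range``; the first ``n_de`` sites carry ``log2_effect`` with
    alternating sign; per-sample library-size factors are uniform over
    ``lib_size_range``.
    """
    rng = np.random.default_rng([seed, 4])
    n_samples = 2 * n_per_group
    means = np.exp(
        rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), n_sites)
    )
    lfc = np.zeros(n_sites)
    if n_de:
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        lfc[:n_de] = log2_effect * signs
    treated = np.zeros(n_samples, dtype=bool)
    treated[n_per_group:] = True
    lib = rng.uniform(*lib_size_range, n_samples)
    mu = np.tile(means[:, None], (1, n_samples))
    mu[:, treated] *= 2.0 ** lfc[:, None]
    mu *= lib[None, :]
    counts = nb_draw(rng, mu, dispersion)
    return counts.astype(int), treated, lfc
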