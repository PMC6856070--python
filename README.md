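# wttsapa

Alternative polyadenylation (APA) analysis for 3′-end sequencing data of
the WTTS-seq kind: libraries whose reads start at the poly(A) junction
with a leading poly-T tract (the sequenced complement of the tail)
followed by first-strand cDNA of the mRNA 3′ end.

The package takes such reads from FASTQ to:

1. **Read filtration** — keep reads with ≥ 50% of bases at Phred ≥ 10,
   trim the maximal leading run of T, require ≥ 16 nt for mapping.
2. **Site extraction** — align each trimmed read (built-in exact mapper
   or external SAM/BAM) and record the genomic coordinate of its first
   base: the polyadenylation-adjacent site. Because the read is
   first-strand cDNA, the site strand is the opposite of the alignment
   strand.
3. **APA site calling** — single-linkage clustering of sites within a
   24-nt window per chromosome and strand, a modal representative
   coordinate (ties to the 3′-most position), and a 16-read expression
   cutoff summed over all samples.
4. **Six-class annotation** against a GFF3 gene model, with priority
   Di > Ex > Eex > In > Edi > An:
   - `Ex` exonic, `Di` distal (at the annotated 3′ terminus ± 24 nt),
     `Edi` extended distal (1–2000 nt downstream) — the *conventional*
     classes;
   - `Eex` extended exonic (≥ 10 nt into an adjacent intron), `In`
     intronic, `An` antisense (inside an exon of an opposite-strand
     gene) — *non-conventional*.
5. **Differential APA** between two conditions with a compact
   negative-binomial pipeline: median-of-ratios size factors
   `s_j = median_i (k_ij / (∏_j k_ij)^(1/m))`, per-site
   method-of-moments dispersion `α̂ = (s² − m̄)/m̄²` shrunk toward a
   mean trend, a Wald test of
   `log2 FC = log2((μ_T + ½)/(μ_C + ½))` with delta-method SE from the
   NB variance `μ + αμ²`, Benjamini–Hochberg adjustment, a MAPQ ≥ 70
   gate, and signed fold changes (positive = treated/control ratio when
   treated is higher, negative = control/treated otherwise).
6. **Category statistics** — class tallies of up- vs down-regulated
   sites and Pearson chi-square tests of the conventional (2×2) and
   full (2×6) class distributions.

A first-class synthetic-data module generates a toy genome, gene
annotation, planted truth sites per class, and per-sample FASTQ reads
with negative-binomial counts, so every stage can be validated against
known truth without any download.

## Worked example

```bash
python examples/02_end_to_end_pipeline.py
```

prints, for the default simulated study (60 planted sites, 10 per
class, 8 control vs 8 treated samples, error-free reads):

```
C1: 3676 reads in, 3676 kept (3676 poly-T trimmed)
predicted APA sites: 60
class tally        : {'Ex': 10, 'Di': 10, 'Edi': 10, 'Eex': 10, 'In': 10, 'An': 10, 'NA': 0}
sites recovered at the planted coordinate with the correct class: 60/60
```

Every read survives filtration (clean simulated qualities), all 60
planted sites come back as exactly one cluster each, the representative
coordinate equals the planted position, and the annotator reproduces
the planted class for all of them.

`examples/03_differential_apa.py` runs the NB test on a 500-site count
matrix with 50 planted 4-fold shifts and reports, among other things:

```
planted shifts detected at adjusted p < 0.1: 50/50; false positives among nulls: 6/450
```

The other examples cover dataset simulation and the category
chi-square statistics. A thin `wttsapa` CLI exposes each stage
(`simulate`, `preprocess`, `sites`, `cluster`, `classify`, `de`,
`catstats`) for shell pipelines; see `wttsapa --help`.

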