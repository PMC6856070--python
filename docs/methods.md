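# Methods

## The problem

3′-end sequencing protocols of the WTTS-seq family prime reverse
transcription from the poly(A) tail, so each read begins at the
cleavage/polyadenylation junction: a run of T (the complement of the
tail), then first-strand cDNA reading from the junction into the
transcript body. Counting reads per junction coordinate measures usage
of alternative polyadenylation (APA) sites; comparing those counts
between two conditions finds differentially used sites; locating each
site against a gene model says whether the transcript 3′ end is
annotated (exonic/distal), extended, intronic, or antisense. This
package implements that whole chain, plus a simulator that provides
ground truth for every stage.

## Read model and preprocessing

A read is modelled as `T^k + payload`, with `k` uniform in [5, 15] by
default (the protocol's tail-derived tract length is not standardized;
the range is configurable) and the payload the reverse complement of
the mRNA 3′ end at the site, truncated so the whole read is
`read_length` (50 nt default). Filtration applies, in order:

1. quality: ≥ `qual_fraction` (0.5) of bases at Phred ≥ `qual_threshold`
   (10). Q10 corresponds to 90% base-call accuracy, which is how the
   two common phrasings of this filter ("Q10" and "90% identity")
   coincide. The boundary (exactly 50%) passes. `N` bases always count
   as failing, a deliberately conservative choice. The filter is
   per-base, not windowed.
2. trimming: the maximal leading run of exact `T` (no mixed T/N runs).
3. length: ≥ `min_length_after_trim` (16 nt), inclusive.

The report conserves reads exactly:
`n_input = n_failed_quality + n_failed_length + n_kept`.

## Site extraction

The built-in mapper is an exact, ungapped substring search (16-mer seed,
full-read verification, both strands): a read maps only if exactly one
full-length exact locus exists; zero or multiple loci are tallied.
MAPQ is fixed at 60 by convention. This mapper is intentionally minimal
and auditable — reads carrying simulated substitution errors simply drop
out, which costs depth, not positional accuracy. Real aligner output
enters through SAM/BAM ingestion (primary mapped records only, MAPQ
carried through, soft clips excluded from the aligned interval and
logged when the 5′ clip exceeds 3 nt).

The polyadenylation-adjacent site is the first (5′) base of the trimmed
read: `ref_start` on a forward alignment, `ref_end − 1` on a reverse
one. Because the library is first-strand cDNA, a read is antisense to
its mRNA, so the site strand defaults to the opposite of the alignment
strand; protocols producing sense reads can flip this with
`orientation="sense"`.

## APA site calling

Within each (chromosome, strand), positions are clustered by positional
single linkage: two positions share a cluster iff a chain of gaps each
≤ 24 nt connects them, with the boundary inclusive (gap of exactly
24 nt merges). Single linkage was chosen over fixed tiles or
seed-and-absorb because it is order-independent and has a clean
brute-force oracle (connected components of the ≤ 24 nt adjacency
graph), against which the implementation is property-tested. An
`anchor` mode (iteratively absorb within ± window of the most abundant
remaining position) is available for comparison. Clusters are never
split; spans over 200 nt only log a warning.

The representative coordinate is the highest-count member position,
ties broken toward the cluster's 3′ end (largest coordinate on `+`,
smallest on `-`). The expression cutoff keeps clusters whose read total
across **all** samples is ≥ 16 (inclusive); the cutoff is intentionally
not per-sample.

## Six-class annotation

Internal coordinates are 0-based half-open everywhere; GFF3's 1-based
closed intervals are converted at the file boundary only. For a site
with representative `r` and inclusive span `[lo, hi]`, same-strand
transcripts whose window `[gene start, tes + 2000]` (strand-aware)
contains `r` are evaluated with priority:

1. `Di` if `|r − tes| ≤ 24` — the tolerance around the annotated 3′
   terminus is set equal to the clustering window, since positional
   scatter of junction reads is the same phenomenon in both places;
   configurable.
2. `Ex` if the span lies entirely in exons.
3. `Eex` if the span overlaps an exon and covers ≥ 10 intronic bases.
   The rule is evaluated on the cluster span, not single reads — a
   single point cannot "extend", so singleton clusters are never `Eex`.
4. `In` if the span lies entirely within one intron.
5. `Edi` if `r` is 1..2000 nt downstream of the terminus (strand-aware).

Among transcripts qualifying at the same priority, the one whose
terminus is nearest `r` wins (ties by transcript id, for determinism).
`An` is assigned only when no sense assignment exists and `r` falls in
an exon of an opposite-strand transcript; otherwise `NA`. The priority
order resolves overlaps (a site at a terminus inside the last exon is
`Di`, not `Ex`) and guarantees each cluster exactly one code.
`Ex`/`Di`/`Edi` are flagged conventional, the rest non-conventional.

The symmetry the classifier is tested for is reflection + strand flip:
mirroring all coordinates about the chromosome while flipping every
gene and site strand leaves all class codes unchanged. (A strand flip
alone moves the 3′ terminus to the other end of each gene and cannot
preserve terminus-relative classes.)

## Differential testing

The testing engine is a compact NB pipeline written for transparency:

- **Normalization**: median-of-ratios. Per-site reference = geometric
  mean across samples over sites with all-positive counts; size factor
  = median ratio to the reference. Verified against the DESeq2
  reference implementation to 1e−10 in tests. Factors are invariant
  under global count scaling and equivariant under single-sample
  scaling; the statistics downstream depend only on normalized counts.
- **Dispersion**: per-site method-of-moments on normalized counts,
  `raw = (s² − m̄)/m̄²` with `s²` pooled within conditions, kept
  *unclipped*; a trend (binned medians of `raw` against log mean,
  clipped at 0, linearly interpolated) supplies shrinkage:
  `α = max(floor, (raw + trend)/2)` with `floor = 1e−8`. Keeping `raw`
  unclipped before shrinkage is what makes the estimator honest near
  zero: under Poisson data both the median raw estimate and the trend
  sit at ~0, so the median dispersion lands on the floor instead of
  being inflated by one-sided clipping.
- **Wald test**: `log2 FC = log2((μ_T + pc)/(μ_C + pc))` with
  pseudocount 0.5 (real data contain zero-mean cells; the ratio
  convention is undefined at 0 without it), standard error from the
  delta method with `Var(μ̂_g) = (μ_g + αμ_g²)/n_g`, two-sided p from
  the normal reference. All-zero sites return (0, 1). Empirical type-I
  error at nominal 0.05 on null NB data (8+8 samples, α = 0.1) is
  ~0.06 — slightly liberal, as expected from a normal reference at
  these group sizes, and inside the tested [0.03, 0.07] band.
- **Multiple testing**: Benjamini–Hochberg step-up (statsmodels).
- **MAPQ gate**: per predicted site, mean MAPQ of supporting reads
  ≥ 70 to pass; significant failures are listed as removed. The
  built-in mapper's constant MAPQ 60 would fail this gate wholesale, so
  the pipeline wrapper defaults to `mapq_min = 0` for naive-mapped
  data; the 70 threshold is meant for real aligner MAPQs.
- **Reporting**: signed fold change (+(T+pc)/(C+pc) if T ≥ C, else
  −(C+pc)/(T+pc); equality maps to +1 for determinism), plus both raw
  and normalized condition means. Two significance surfaces are
  reported side by side — raw p < 0.01 and BH-adjusted p < 0.1 —
  because both conventions are in common use; the package does not
  pick one.

## Category statistics

Up- and down-regulated significant sites are tallied over the six
classes; the conventional/non-conventional collapse gives a 2×2 table
and the full distribution a 2×6 table, each tested with Pearson's
chi-square (`Σ(O−E)²/E`, no continuity correction by default — matching
base-R only applying Yates to 2×2 when asked; the flag is exposed).
Zero margins raise (the test is undefined); expected counts below 5
log a warning. Classes absent from both groups are dropped from the
2×6 comparison.

## The simulator

`SimParams` defaults define the study conditions: 1 × 120 kb
chromosome, 12 genes (3–5 exons of 150–400 nt, introns 250–600 nt,
alternating strands, ≥ 3 kb inter-gene gaps so 2 kb downstream windows
never collide), 60 sites at 10 per class, 8 samples per condition,
expected count 60 per site per sample, NB dispersion 0.05, poly-T
5–15 nt, 50 nt reads, no substitution errors, constant Q30 qualities.
Same-strand sites are planted > 24 nt apart so the clustering window
cannot merge distinct truth sites. `Eex` sites are planted as a
dominant exonic representative plus one intronic satellite 15 nt into
the intron, within the window, carrying a third of the reads — the only
class that needs a multi-position cluster. Where a planted site's
genomic base would make the first payload base a `T` (which trimming
would eat, shifting the site by one), the generator substitutes that
base before writing the genome.

Count noise is NB with `variance = mean + dispersion·mean²`
(`dispersion = 0` degenerates to Poisson). A separate count-level
simulator (`simulate_count_matrix`) drives the differential-testing
studies (log-uniform site means over [20, 500], uniform library-size
factors over [0.7, 1.4], planted log2 effects with alternating sign)
— read-level simulation at 2000 sites × 20 seeds would add nothing but
runtime to a counts-level question.

Not modelled: RNA secondary structure, internal priming artifacts,
fragment-length effects, PCR duplicates, platform-specific error
profiles, spliced (gapped) payloads. Passing tests therefore
demonstrate the pipeline's correctness on its own model of the data,
not robustness to those real-data artifacts; the SAM ingestion path
exists precisely so a real aligner can absorb them.

## Problem sizes and determinism

Default validation sizes — 60 sites × 16 samples (~58k reads)
end-to-end, 500 random clustering instances, 20 × 2000-site null
matrices — were chosen so the full suite completes in well under a
minute while keeping Monte-Carlo bands tight. Every stochastic step
draws from `numpy` generators seeded per stage
(`default_rng([seed, stage])`), so outputs are byte-identical across
runs and adding a stage never perturbs the others.

## Known limitations

- The exact mapper tolerates no mismatches; with substitution errors it
  loses depth rather than accuracy. Use external alignments for real
  data.
- Dispersion shrinkage is a fixed 50/50 blend, not an empirical-Bayes
  posterior; with very few sites the trend is a constant median.
- The Wald normal reference is mildly liberal at small group sizes
  (~0.06 at nominal 0.05 for 8 vs 8).
- The classifier trusts the annotation's transcript termini; it does
  not re-estimate them from data.
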