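"""Generate a synthetic 3'-end sequencing study with known truth.

Builds a 120 kb genome with 12 genes, plants 60 polyadenylation sites
(10 per annotation class), and writes per-sample FASTQ reads for an
8 vs 8 two-condition design.  The truth table records where every site
was planted and what class the annotator should assign it.
"""

from collections import Counter
from pathlib import Path

from wttsapa import SimParams, simulate_dataset

params = SimParams(seed=7)
out = simulate_dataset(params, Path("scratch_example_sim"))

print(f"chromosomes : {list(out['genome'])}")
print(f"genes       : {len(out['genes'])}")
print(f"truth sites : {len(out['truth'])}")
print(f"per class   : {dict(Counter(t.true_class for t in out['truth']))}")
print(f"samples     : {params.sample_ids}")
print(f"files       : {out['fasta'].name}, {out['gff'].name}, "
      f"{len(out['fastq'])} FASTQ, {out['truth_tsv'].name}, {out['design_tsv'].name}")
# Each truth site will later be recovered as one cluster whose
# representative coordinate equals the planted position.
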