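"""Simulate a small RAD-seq experiment and discover SNPs de novo.

Generates barcoded 50-nt reads for 18 tea accessions, cleans and
demultiplexes them, assembles per-accession stacks, and builds the
cross-accession catalog of bi-allelic SNPs.
"""

from radpop import SimulationConfig, summarize_snps
from radpop.pipeline import run_pipeline

config = SimulationConfig(n_fragments=300, seed=42)
result = run_pipeline(config)

pre = result.preprocess
print(f"reads simulated     : {pre.n_input:,}")
print(f"reads retained      : {pre.n_assigned:,} ({100 * pre.retention:.1f}%)")
print(f"discards by reason  : {dict(pre.discarded)}")
print(f"catalog SNP loci    : {result.matrix.n_loci}")
print(f"excluded entries    : {dict(result.selection_log.reasons)}")

summary = summarize_snps(result.matrix)
ratio = f"{summary.titv:.2f}" if summary.titv is not None else "undefined"
print(
    f"transitions/transversions: {summary.n_transitions}/"
    f"{summary.n_transversions} (TI/TV = {ratio})"
)
# The retention rate is the 'clean data' fraction; catalog loci are tags
# genotyped in >=14 accessions with exactly one bi-allelic SNP in the
# 36-nt variable region. TI/TV near the planted 1.5 indicates the
# substitution spectrum survived discovery unbiased.
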