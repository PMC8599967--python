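"""Generate a synthetic plaque study with planted ground truth.

Emulates the study design: 5 stable vs 5 unstable samples, a small genome
with multi-exon coding genes, planted antisense/intergenic/intronic
lncRNAs, circRNAs emitting back-splice junction reads, NB counts with
planted fold changes, and an LFQ protein table with a concordant subset.
"""

from plaqomics import SimConfig, simulate_all

cfg = SimConfig(seed=1, genome_length=50_000, n_coding_genes=10,
                n_lncrnas_per_class=2, n_circrnas=5, n_linear_reads=500,
                n_features=500)
genome, annotation, reads, counts, proteins, truth = simulate_all(
    cfg, outdir="example_data"
)

print(f"genome: {genome.total_length:,} bp")
print(f"annotation: {len(annotation)} transcripts "
      f"({sum(t.biotype == 'lncRNA' for t in annotation)} planted lncRNAs)")
print(f"reads: {len(reads)} "
      f"({sum(r.read_id.startswith('bsj|') for r in reads)} span back-splices)")
print(f"counts: {counts.values.shape[0]} features x "
      f"{counts.values.shape[1]} samples; "
      f"{len(truth.de_features)} planted DE features")
print(f"proteins: {proteins.values.shape[0]} with "
      f"{len(truth.protein_concordant)} planted mRNA-concordant DE proteins")
# The truth set (example_data/truth.json) records every planted signal so
# downstream stages can be scored for exact recovery.
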