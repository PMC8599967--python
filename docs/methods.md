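# Methods

This note documents the models, algorithms and design choices behind
`plaqomics`, in the order the pipeline runs them. Nothing here reports an
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design emulated by the synthetic data

The toolkit targets a two-group bulk multi-omics design: 5 stable vs 5
unstable plaque samples, single-end 100 nt RNA-seq reads, gene-level count
matrices, and a label-free (LFQ) protein intensity table. The synthetic
generator (`plaqomics.simulate`) produces every pipeline input with planted
ground truth under exactly these defaults (`n_samples_per_group=5`,
`read_length=100`). Key generator parameters, all on `SimConfig`:

| parameter | default | meaning |
|---|---|---|
| `genome_length` | 100,000 bp | uniform-composition random genome (one chromosome) |
| `n_coding_genes` | 20 | non-overlapping 3-exon loci (exons 150–250 bp, introns 300–500 bp) |
| `n_lncrnas_per_class` | 3 | planted antisense (x), intergenic (u), intronic (i) lncRNAs |
| `n_circrnas` | 10 | planted circles spanning exons 2–3 of host genes |
| `junction_reads_per_circ` | 3 | reads spanning each back-splice |
| `n_features`, `frac_de`, `planted_lfc` | 2,000 / 0.10 / 2.0 | NB count matrix with planted effects (random sign) |
| `nb_dispersion` | 0.1 | NB dispersion α in Var = μ + αμ² |
| `count_base_mean` | 200 | log-normal(σ=1) feature base means |
| `protein_noise_sd` | 0.3 | sd of log2 LFQ intensities within group |
| `error_rate` | 0 | per-base substitution rate (clean reads by default) |

Planted lncRNAs are built to pass the expression filter (length > 200 nt,
≥ 2 exons, coverage > 3) so classification accuracy isolates the class-code
logic. Planted circles get three genome edits: AG is written immediately
upstream of the acceptor and GT immediately downstream of the donor; each
20 bp junction anchor is re-drawn until genome-unique; and the first/last
circle bases are pinned away from `G` so a junction read's anchor
extensions cannot run past the true split. The last edit makes breakpoint
localization unique and hence coordinate recovery deterministic — it
extends the anchor-uniqueness re-draw rationale from collisions to
extension ties. Reads from minus-strand circles are emitted
reverse-complemented (transcript orientation), exercising both strand paths
of the caller.

What the generator does **not** emulate: paired-end libraries, sequencing
error profiles and quality-score realism, isoform mixtures, multi-mapping
repeat structure, GC or positional coverage bias, and missing-not-at-random
protein dropout. Passing tests therefore demonstrate algorithmic
correctness on clean, planted signals — not robustness to every artifact of
real libraries.

## Linear triage and anchor mapping

`mapper.KmerIndex` hashes every genomic k-mer (k = 20, the anchor length)
on both strands; `map_linear` seeds at non-overlapping read offsets and
verifies full-length contiguous matches, returning *all* placements
(complete whenever `max_mismatches` < number of seeds; the default is exact
matching, 0 mismatches, because synthetic reads are error-free and spliced
alignment is out of scope). Ambiguous bases never match. Minus-strand hits
are reported against the forward coordinate of the match start so every
placement has a single unambiguous 0-based coordinate. Reads with at least
one placement are "mapped"; the rest are back-splice candidates.

## Back-splice junction calling

For an unmapped read of length L the caller takes the first and last 20 bp
as 5′ and 3′ anchors and requires each to place **uniquely** (multi-mapping
anchors are rejected as `ambiguous` — the standard guard against
combinatorial false positives in anchor methods) on the same chromosome and
strand. A back-splice requires the 5′ anchor *downstream* of the 3′ anchor;
anchors in genomic order are `collinear` (linear or spliced reads) and
never yield a call — splice-junction reads from multi-exon transcripts are
rejected exactly this way, which is why the synthetic fixtures produce zero
false positives. Both anchors are extended toward the read interior until
mismatch; every split s with prefix `read[:s]` matching at the 5′ anchor
and suffix `read[s:]` matching at the 3′ anchor is a breakpoint candidate
`(acceptor, donor)`. Candidates whose flanks read AG (two bases 5′ of the
acceptor) and GT (two bases 3′ of the donor) are preferred; among several,
the smallest 5′ extension wins (deterministic). With `require_signal` on
(default) a read with no signal-consistent split is rejected `no-signal`;
otherwise the first candidate is emitted with `signal_ok=False`.

The flank convention is configurable (`signal = "AG-GT" | "GT-AG" | "off"`)
because the canonical GT–AG intron, written acceptor-first, reads "AG-GT";
the default follows that acceptor-first reading. `max_span` defaults to
100 kb and `min_support` to 1 (no read-support threshold is imposed by
default; common practice of ≥ 2 is one flag away). Identical calls are
collapsed per sample with support = read count. TPM uses the genomic span
of the circle as effective length by default — the length term for a
circRNA is not well defined from junction reads alone — with a
`junction_length_mode` that sets all lengths to 1, making TPM proportional
to junction support.

## lncRNA class codes and filter

Codes are assigned with fixed precedence for determinism: same-strand
exonic overlap with the reference forces `other`; otherwise antisense
exonic overlap gives `x`; otherwise containment within a *single* intron of
one reference transcript (straddling an exon–intron boundary disqualifies —
the strictest reading of "intronic") gives `i`; no overlap with any
reference gene span gives `u`; everything else is `other`. A transcript on
a chromosome absent from the reference is `u` with a warning. The
expressed-lncRNA filter keeps length > 200 (strict), exons ≥ 2 (inclusive),
code ∈ {x,u,i}, coverage > 3 (strict). "Length" is the spliced transcript
length (summed exons), not the genomic span; transcript assembly itself is
out of scope — transcripts and their coverage arrive via GTF, with novel
entries using the assembler-style `MSTRG` prefix.

## Differential expression

**Counts (mRNA / lncRNA / circRNA layers).** Size factors are
median-of-ratios over features positive in all samples, rescaled to
geometric mean 1 (library-size fallback with a warning when no such feature
exists). Per feature, with normalized group means m₁, m₂ (n₁ = n₂ = 5) and
pseudocount c = 0.5 (avoids infinite fold changes for group-exclusive
features; configurable):

- log2FC = log2((m₂+c)/(m₁+c)), unstable vs stable;
- dispersion α from pooled method-of-moments, α_g = (s²_g − m_g)/m_g²
  averaged across groups with weights n_g − 1, floored at 10⁻⁸;
- Wald statistic z = (ln(m₂+c) − ln(m₁+c)) / SE with the delta-method
  variance SE² = (1/(m₁+c)+α)/n₁ + (1/(m₂+c)+α)/n₂ under Var = μ + αμ²;
- two-sided p from a **t distribution with n₁+n₂−2 df**. With the
  dispersion estimated from 10 samples, the normal reference is
  anticonservative; the t reference restores type-I calibration, which the
  acceptance suite verifies directly (null fraction p < 0.05 within the
  99% binomial CI at 5,000 features) rather than by matching any legacy
  package. All-zero features get p = 1, lfc = 0.

The DE call is exactly |log2FC| > 1.0 **and raw p < 0.05** (strict
inequalities); BH q-values are reported for transparency but do not enter
the call.

**Proteins.** Intensities are log2-transformed with zeros treated as
missing (no imputation; missing-at-random is assumed for the test). Each
protein gets a Welch two-sample t test — the declared stand-in where the
original criterion names no test — with log2FC the difference of group
means in log2 space. Proteins with < 2 observations in a group are flagged
`low_n`, given p = 1, and excluded from the BH computation.

**qPCR.** ΔCt = Ct_target − Ct_reference per sample; ΔΔCt = mean ΔCt
difference vs the control group; fold = 2^(−ΔΔCt) with the control group
at 1 by construction. Samples missing either Ct are dropped with a warning.

## Interval links

Gene span = min exon start to max exon end of the gene's longest transcript
(ties broken by transcript id). A lncRNA links every coding gene whose span
gap is ≤ the window (default 1,000 bp), strand-ignored, measured from the
whole lncRNA span; the gap is the count of bases strictly between the
spans, so overlapping **or abutting** intervals are at distance 0 and
`window=0` selects exactly those — a gene starting 1,001 positions past the
lncRNA end (1,000 intervening bases) sits exactly at the default limit.
Origin genes: a circle links every gene with ≥ 1 bp of exonic overlap with
[acceptor, donor], strand-agnostic by default (`stranded` flag available
since junction strand can be unreliable for unstranded libraries); one
circle spanning exons of two genes yields two links. Output ordering is a
deterministic sort, independent of input order.

## Integration and enrichment

Gene symbols are harmonized by uppercasing only (no alias resolution — no
external database dependency). The consistency report intersects DE mRNAs,
cis-targets and origin genes with the DE proteins and flags per-gene sign
concordance of the two log2 fold changes. Over-representation uses the
hypergeometric upper tail P[X ≥ k] with the expression universe (all genes
in the matrix, not the whole annotation — standard practice, configurable)
as background; sets are intersected with the universe first, K = 0 sets are
skipped, significance mirrors the raw p < 0.05 convention with q alongside.

## ceRNA networks and MCODE

Machine-learned target scores are out of reach without the underlying
model, so binding is predicted by canonical seed classes — a deliberate,
deterministic, testable stand-in: 7mer-m8 = match of the reverse complement
of miRNA positions 2–8; 8mer = 7mer-m8 plus A in the target opposite
position 1; 7mer-A1 = positions 2–7 plus the A, only when the upstream base
does not also pair position 8 (otherwise the alignment is the interior of
the longer site). U ≡ T so DNA and RNA alphabets mix; other characters
never match. Sponge edges (lncRNA/circRNA → miRNA) and targeting edges
(miRNA → mRNA 3′UTR) require ≥ 1 site; multiple sites collapse to one edge
with a site count.

MCODE clustering: vertex weight = (highest k-core of the closed
neighborhood) × (density of that core); complexes grow greedily from the
highest-weighted unassigned vertex through neighbors with weight ≥
(1 − cutoff) × seed weight (cutoff 0.2); haircut (iterative removal of
singly-connected members) is on and fluff off by default, mirroring the
original tool's defaults; clusters need ≥ 3 members and a 2-core; score =
density × size. All ties break on node id, so output is independent of
edge-list order. The PPI graph arrives as a user TSV edge list — no
interaction-database retrieval.

## Pipeline, determinism and problem sizes

`pipeline.run_all` executes simulate → map → circ → lncrna → de → links →
integrate → cerna from one YAML-configurable `PipelineConfig`; a single
top-level seed drives every random stream (each generator op draws from
`default_rng([seed, stage])`, so results are independent of call order),
and reruns are byte-identical. The manifest records package version, seed,
input SHA-256 hashes and per-stage counts; any stage failure aborts with
the stage name attached (GTF errors additionally carry the offending line
number).

Test and acceptance problem sizes were chosen as the smallest that make the
statistical checks sharp: 100 kb / 20 circles / 2,000 linear reads for
caller recovery, 50 kb / 1,000 reads for the mapper oracle, 5,000 features
for DE calibration (99% binomial CI half-width ≈ 0.008 around 0.05),
500 × 500 intervals for the link oracle, and 200 random ≤ 8-node graphs for
the MCODE oracle. The whole suite runs in seconds on one CPU.

## Known limitations

- The caller resolves one junction per read and assumes unique anchors;
  repeat-rich genomes would shift reads into the `ambiguous` bin rather
  than produce wrong calls.
- MoM dispersion is pooled per feature with no shrinkage across features;
  at n = 5 + 5 this is noisier than empirical-Bayes approaches, traded for
  a self-contained, simulation-calibrated test.
- Seed matching ignores binding free energy, conservation and 3′
  supplementary pairing; edge sets are a deterministic approximation of
  miRNA targeting, not a reproduction of any database's predictions.
- The cis-link window is measured from the transcript span, not the TSS;
  with a stated window of ±1 kb the difference is small but real for long
  lncRNAs.
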