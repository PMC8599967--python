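"""Synthetic multi-omics data with planted ground truth.

Generates every input the plaque pipeline consumes: a small random genome,
a gene annotation with multi-exon coding genes and planted antisense /
intergenic / intronic lncRNAs, back-splice junction reads from planted
circRNAs (with AG/GT-compatible flanks engineered into the genome),
negative-binomial two-group count matrices with planted log2 fold changes,
a log-normal protein intensity table with a planted mRNA-concordant DE
subset, plus small gene-set (GMT), miRNA and PPI inputs for the downstream
stages.  The default study design is 5 stable vs 5 unstable samples.

Every operation draws from a generator seeded by ``(cfg.seed, stage)`` so
results are deterministic per configuration and independent of call order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .de import GROUP_STABLE, GROUP_UNSTABLE, OmicsMatrix
from .genome import GenomeRef, reverse_complement
from .models import BackspliceJunction, TranscriptModel, write_gtf

_BASES = np.array(list("ACGT"))

# stage salts for per-operation random streams
_S_GENOME, _S_ANN, _S_READS, _S_COUNTS, _S_PROT, _S_AUX = range(6)


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    seed: int = 0
    genome_length: int = 100_000
    chrom: str = "chr1"
    n_coding_genes: int = 20
    n_lncrnas_per_class: int = 3
    n_circrnas: int = 10
    read_length: int = 100
    anchor_len: int = 20
    junction_reads_per_circ: int = 3
    n_linear_reads: int = 2000
    n_samples_per_group: int = 5
    n_features: int = 2000
    frac_de: float = 0.1
    planted_lfc: float = 2.0
    nb_dispersion: float = 0.1
    count_base_mean: float = 200.0
    error_rate: float = 0.0
    n_proteins: int = 400
    n_concordant_proteins: int = 2
    n_protein_only_de: int = 20
    protein_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10,000")
        if self.read_length < 2 * self.anchor_len:
            raise ValueError("read_length must be >= twice the anchor length")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        for name in (
            "n_coding_genes", "n_lncrnas_per_class", "n_circrnas",
            "junction_reads_per_circ", "n_linear_reads", "n_samples_per_group",
            "n_features", "n_proteins", "n_concordant_proteins",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TruthSet:
    """Planted ground truth for recovery testing."""

    circ_junctions: List[BackspliceJunction] = field(default_factory=list)
    lnc_labels: Dict[str, str] = field(default_factory=dict)
    de_features: Dict[str, float] = field(default_factory=dict)
    protein_de: Dict[str, float] = field(default_factory=dict)
    protein_concordant: List[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "circ_junctions": [
                {
                    "chrom": j.chrom, "acceptor": j.acceptor, "donor": j.donor,
                    "strand": j.strand, "support": j.support,
                    "signal_ok": j.signal_ok,
                }
                for j in self.circ_junctions
            ],
            "lnc_labels": self.lnc_labels,
            "de_features": self.de_features,
            "protein_de": self.protein_de,
            "protein_concordant": self.protein_concordant,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            circ_junctions=[
                BackspliceJunction(**j) for j in payload["circ_junctions"]
            ],
            lnc_labels=payload["lnc_labels"],
            de_features=payload["de_features"],
            protein_de=payload["protein_de"],
            protein_concordant=payload["protein_concordant"],
        )

    def merged(self, other: "TruthSet") -> "TruthSet":
        return TruthSet(
            circ_junctions=self.circ_junctions + other.circ_junctions,
            lnc_labels={**self.lnc_labels, **other.lnc_labels},
            de_features={**self.de_features, **other.de_features},
            protein_de={**self.protein_de, **other.protein_de},
            protein_concordant=self.protein_concordant + other.protein_concordant,
        )


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


# ----------------------------------------------------------------- genome

def gen_genome(cfg: SimConfig) -> GenomeRef:
    """Uniform-composition random genome of the configured length."""
    rng = _rng(cfg, _S_GENOME)
    seq = "".join(rng.choice(_BASES, size=cfg.genome_length))
    return GenomeRef({cfg.chrom: seq})


# ------------------------------------------------------------- annotation

def _count_occurrences(genome: GenomeRef, kmer: str) -> int:
    n = 0
    for _, seq in genome.items():
        n += seq.count(kmer) + seq.count(reverse_complement(kmer))
    return n


def _resample_until_unique(
    seq: List[str], genome: GenomeRef, chrom: str, start: int, k: int,
    rng: np.random.Generator,
) -> None:
    """Rewrite genome[start:start+k] until that k-mer is genome-unique."""
    for _ in range(50):
        genome.sequences[chrom] = "".join(seq)
        kmer = genome.sequences[chrom][start : start + k]
        if _count_occurrences(genome, kmer) == 1:
            return
        fresh = rng.choice(_BASES, size=k)
        seq[start : start + k] = list(fresh)
    raise RuntimeError("could not plant a genome-unique anchor")


def gen_annotation(
    genome: GenomeRef, cfg: SimConfig
) -> Tuple[List[TranscriptModel], TruthSet]:
    """Plant coding genes, class-labelled lncRNAs and circRNA junctions.

    Coding genes are laid out in non-overlapping loci.  One lncRNA cohort
    overlaps coding exons antisense (label ``x``), one sits in gene deserts
    at least 2 kb from any coding gene (``u``), one strictly inside a coding
    intron (``i``); all planted lncRNAs have spliced length > 200 nt, at
    least two exons and coverage > 3 so they survive the expression filter.
    CircRNA junctions are planted on coding exon boundaries; the genome is
    edited so each junction's flanks read AG (upstream of the acceptor) and
    GT (downstream of the donor) and each 20 bp anchor is genome-unique.

    Mutates ``genome`` in place (junction flanks/anchors) and returns the
    annotation plus the planted truth.
    """
    rng = _rng(cfg, _S_ANN)
    chrom = cfg.chrom
    L = genome.length(chrom)
    transcripts: List[TranscriptModel] = []
    truth = TruthSet()

    # --- coding gene loci, evenly pitched with jitter ---
    n_genes = cfg.n_coding_genes
    if n_genes < 1:
        raise ValueError("need at least one coding gene")
    # each locus: 3 exons (~150-250 bp) and 2 introns (~300-500 bp)
    max_gene_span = 3 * 250 + 2 * 500
    # reserve the first ~60% of the genome for genes when deserts are needed
    coding_region = int(L * 0.6) if cfg.n_lncrnas_per_class > 0 else L - 200
    pitch = (coding_region - 200) // n_genes
    if pitch < max_gene_span + 100:
        raise ValueError(
            f"genome too small: {L} bp cannot hold {n_genes} coding loci"
        )
    genes: List[TranscriptModel] = []
    for g in range(n_genes):
        locus_start = 100 + g * pitch + int(rng.integers(0, 50))
        pos = locus_start
        exons = []
        for e in range(3):
            elen = int(rng.integers(150, 251))
            exons.append((pos + 1, pos + elen))  # 1-based inclusive
            pos += elen
            if e < 2:
                pos += int(rng.integers(300, 501))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene_{g + 1:04d}"
        t = TranscriptModel(
            transcript_id=f"{gid}.t1", gene_id=gid, chrom=chrom,
            strand=strand, exons=exons, biotype="protein_coding",
            coverage=float(rng.uniform(5, 50)),
        )
        genes.append(t)
        transcripts.append(t)

    # --- planted lncRNAs, one cohort per class code ---
    n_lnc = cfg.n_lncrnas_per_class
    lnc_counter = 0
    if n_lnc > 0:
        if n_lnc > n_genes:
            raise ValueError("need at least one coding gene per x/i lncRNA")
        # antisense (x): two exons, the first overlapping a coding exon on
        # the opposite strand
        for k in range(n_lnc):
            host = genes[k]
            ex1_start, _ = host.exons[0]
            e1 = (ex1_start, ex1_start + 149)
            e2 = (e1[1] + 51, e1[1] + 200)
            lnc_counter += 1
            tid = f"MSTRG.{lnc_counter}.1"
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid, gene_id=f"MSTRG.{lnc_counter}",
                    chrom=chrom, strand="-" if host.strand == "+" else "+",
                    exons=[e1, e2], biotype="lncRNA",
                    coverage=float(rng.uniform(4, 30)),
                )
            )
            truth.lnc_labels[tid] = "x"
        # intronic (i): strictly inside the first intron of a coding gene
        for k in range(n_lnc):
            host = genes[n_genes - 1 - k]  # distinct from x hosts when possible
            intron = host.introns[0]
            ilen = intron[1] - intron[0] + 1
            # two 110 bp exons + 60 bp gap = 280 bp span, 1 bp margins
            if ilen < 284:
                raise ValueError("host intron too short for intronic lncRNA")
            s = intron[0] + 1
            e1 = (s, s + 109)
            e2 = (s + 170, s + 279)
            lnc_counter += 1
            tid = f"MSTRG.{lnc_counter}.1"
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid, gene_id=f"MSTRG.{lnc_counter}",
                    chrom=chrom, strand="+" if rng.random() < 0.5 else "-",
                    exons=[e1, e2], biotype="lncRNA",
                    coverage=float(rng.uniform(4, 30)),
                )
            )
            truth.lnc_labels[tid] = "i"
        # intergenic (u): in the gene desert past the coding region,
        # >= 2 kb from any coding gene
        last_gene_end = max(t.span[1] for t in genes)
        pos = max(last_gene_end + 2000, int(L * 0.6) + 2000)
        for k in range(n_lnc):
            e1 = (pos + 1, pos + 150)
            e2 = (pos + 251, pos + 400)
            if e2[1] + 2000 > L:
                raise ValueError("genome too small for requested u lncRNAs")
            lnc_counter += 1
            tid = f"MSTRG.{lnc_counter}.1"
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid, gene_id=f"MSTRG.{lnc_counter}",
                    chrom=chrom, strand="+" if rng.random() < 0.5 else "-",
                    exons=[e1, e2], biotype="lncRNA",
                    coverage=float(rng.uniform(4, 30)),
                )
            )
            truth.lnc_labels[tid] = "u"
            pos = e2[1] + 500

    # --- planted circRNA junctions on coding exon boundaries ---
    if cfg.n_circrnas > n_genes:
        raise ValueError("n_circrnas must not exceed n_coding_genes")
    seq = list(genome.sequences[chrom])
    k = cfg.anchor_len
    for c in range(cfg.n_circrnas):
        host = genes[c]
        # circle spans exon 2 start .. exon 3 end (multi-exon circle)
        acceptor = host.exons[1][0]
        donor = host.exons[2][1]
        if donor - acceptor + 1 < cfg.read_length:
            raise ValueError("planted circle shorter than read_length")
        a0, d0 = acceptor - 1, donor - 1  # 0-based
        # engineer canonical flanks: AG upstream of acceptor, GT downstream
        seq[a0 - 2 : a0] = ["A", "G"]
        seq[d0 + 1 : d0 + 3] = ["G", "T"]
        genome.sequences[chrom] = "".join(seq)
        # anchors of the junction read must be genome-unique
        _resample_until_unique(seq, genome, chrom, d0 - k + 1, k, rng)
        _resample_until_unique(seq, genome, chrom, a0, k, rng)
        # pin the breakpoint: the junction read's halves must not extend
        # past the true split by chance, so the first circle base must
        # differ from the base after the donor ('G') and the last circle
        # base from the base before the acceptor ('G')
        for pos in (a0, d0):
            while seq[pos] == "G":
                seq[pos] = str(rng.choice(np.array(list("ACT"))))
                genome.sequences[chrom] = "".join(seq)
                if _count_occurrences(
                    genome, genome.sequences[chrom][a0 : a0 + k]
                ) != 1 or _count_occurrences(
                    genome, genome.sequences[chrom][d0 - k + 1 : d0 + 1]
                ) != 1:
                    seq[pos] = "G"  # rare collision: retry with another base
                    genome.sequences[chrom] = "".join(seq)
                    _resample_until_unique(seq, genome, chrom, a0, k, rng)
                    _resample_until_unique(seq, genome, chrom, d0 - k + 1, k, rng)
        truth.circ_junctions.append(
            BackspliceJunction(
                chrom=chrom, acceptor=acceptor, donor=donor,
                strand=host.strand, support=cfg.junction_reads_per_circ,
                signal_ok=True,
            )
        )
    genome.sequences[chrom] = "".join(seq)
    return transcripts, truth


# ------------------------------------------------------------------ reads

@dataclass
class SimRead:
    read_id: str
    sequence: str


def simulate_reads(
    genome: GenomeRef,
    annotation: Sequence[TranscriptModel],
    truth: TruthSet,
    cfg: SimConfig,
) -> List[SimRead]:
    """Linear reads from spliced transcripts plus back-splice junction reads.

    Junction reads are read_length/2 genomic bases ending at the donor
    followed by the remainder starting at the acceptor, i.e. they span the
    head-to-tail junction and have no contiguous genomic placement.  Read
    ids encode provenance (``lin|transcript|n`` / ``bsj|circ|n``).
    """
    rng = _rng(cfg, _S_READS)
    rl = cfg.read_length
    reads: List[SimRead] = []

    templates = [
        (t.transcript_id, t.spliced_sequence(genome))
        for t in annotation
        if t.length >= rl
    ]
    if cfg.n_linear_reads > 0 and not templates:
        raise ValueError("no transcript long enough for linear reads")
    for i in range(cfg.n_linear_reads):
        tid, tseq = templates[int(rng.integers(0, len(templates)))]
        start = int(rng.integers(0, len(tseq) - rl + 1))
        reads.append(SimRead(f"lin|{tid}|{i}", tseq[start : start + rl]))

    half = rl // 2
    for j in truth.circ_junctions:
        if j.span < rl:
            raise ValueError(f"circle {j.name} shorter than read_length")
        a0, d0 = j.acceptor - 1, j.donor - 1
        head = genome.slice(j.chrom, d0 - half + 1, d0 + 1)
        tail = genome.slice(j.chrom, a0, a0 + (rl - half))
        bsj_read = head + tail
        if j.strand == "-":
            # minus-strand circle: the read is sequenced from the
            # transcript, i.e. the reverse complement of the forward-
            # coordinate junction sequence
            bsj_read = reverse_complement(bsj_read)
        for i in range(cfg.junction_reads_per_circ):
            reads.append(SimRead(f"bsj|{j.name}|{i}", bsj_read))

    if cfg.error_rate > 0:
        for r in reads:
            mask = rng.random(rl) < cfg.error_rate
            if mask.any():
                s = list(r.sequence)
                for pos in np.flatnonzero(mask):
                    s[pos] = str(rng.choice(_BASES[_BASES != s[pos]]))
                r.sequence = "".join(s)
    return reads


def write_fastq(reads: Sequence[SimRead], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> List[SimRead]:
    return [
        SimRead(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]


# ----------------------------------------------------------------- counts

def _sample_ids(cfg: SimConfig) -> Tuple[List[str], List[str]]:
    n = cfg.n_samples_per_group
    return (
        [f"{GROUP_STABLE}_{i + 1}" for i in range(n)],
        [f"{GROUP_UNSTABLE}_{i + 1}" for i in range(n)],
    )


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float, size
) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size=size)


def simulate_counts(cfg: SimConfig) -> Tuple[OmicsMatrix, TruthSet]:
    """Two-group NB count matrix with planted log2 fold changes.

    Feature base means are log-normal around ``count_base_mean``; a
    ``frac_de`` fraction of features has the unstable-group mean scaled by
    2^(+-planted_lfc) (random sign).  Truth records feature id -> signed
    planted lfc.
    """
    if cfg.n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = _rng(cfg, _S_COUNTS)
    nf = cfg.n_features
    feature_ids = [f"feat_{i + 1:05d}" for i in range(nf)]
    base_mu = rng.lognormal(mean=np.log(cfg.count_base_mean), sigma=1.0, size=nf)

    n_de = int(round(cfg.frac_de * nf))
    de_idx = rng.choice(nf, size=n_de, replace=False)
    lfc = np.zeros(nf)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc[de_idx] = signs * cfg.planted_lfc

    stable_ids, unstable_ids = _sample_ids(cfg)
    n = cfg.n_samples_per_group
    mu_stable = np.repeat(base_mu[:, None], n, axis=1)
    mu_unstable = np.repeat((base_mu * 2.0**lfc)[:, None], n, axis=1)
    counts = np.concatenate(
        [
            _nb_draw(rng, mu_stable, cfg.nb_dispersion, mu_stable.shape),
            _nb_draw(rng, mu_unstable, cfg.nb_dispersion, mu_unstable.shape),
        ],
        axis=1,
    )
    values = pd.DataFrame(
        counts, index=pd.Index(feature_ids, name="feature_id"),
        columns=stable_ids + unstable_ids,
    )
    groups = pd.Series(
        [GROUP_STABLE] * n + [GROUP_UNSTABLE] * n,
        index=stable_ids + unstable_ids,
    )
    truth = TruthSet(
        de_features={feature_ids[i]: float(lfc[i]) for i in sorted(de_idx)}
    )
    return OmicsMatrix(values=values, groups=groups, layer="mrna"), truth


# --------------------------------------------------------------- proteins

def simulate_proteins(
    counts_truth: TruthSet, cfg: SimConfig
) -> Tuple[OmicsMatrix, TruthSet]:
    """Log-normal LFQ intensity table sharing feature ids with the counts.

    Exactly ``n_concordant_proteins`` of the planted mRNA-DE features are
    also planted DE at the protein level with the same sign; the remaining
    protein DE features are drawn from non-DE mRNA features, so the two
    planted DE sets intersect exactly in the concordant subset.
    """
    rng = _rng(cfg, _S_PROT)
    mrna_de = sorted(counts_truth.de_features)
    if cfg.n_concordant_proteins > len(mrna_de):
        raise ValueError(
            "concordant subset larger than the planted mRNA DE set"
        )
    all_feats = [f"feat_{i + 1:05d}" for i in range(cfg.n_features)]
    non_de = [f for f in all_feats if f not in counts_truth.de_features]

    concordant = [
        mrna_de[i]
        for i in rng.choice(len(mrna_de), cfg.n_concordant_proteins, replace=False)
    ] if cfg.n_concordant_proteins else []
    n_only = min(cfg.n_protein_only_de, len(non_de))
    protein_only = [
        non_de[i] for i in rng.choice(len(non_de), n_only, replace=False)
    ]

    # protein panel: all planted-DE proteins plus background drawn from the
    # remaining mRNA features
    background_pool = [
        f for f in all_feats if f not in set(concordant) | set(protein_only)
    ]
    n_background = max(0, cfg.n_proteins - len(concordant) - len(protein_only))
    background = [
        background_pool[i]
        for i in rng.choice(
            len(background_pool), min(n_background, len(background_pool)),
            replace=False,
        )
    ]
    panel = sorted(set(concordant) | set(protein_only) | set(background))

    prot_lfc = {f: 0.0 for f in panel}
    for f in concordant:
        prot_lfc[f] = float(np.sign(counts_truth.de_features[f]) * cfg.planted_lfc)
    for f in protein_only:
        prot_lfc[f] = float(rng.choice([-1.0, 1.0]) * cfg.planted_lfc)

    stable_ids, unstable_ids = _sample_ids(cfg)
    n = cfg.n_samples_per_group
    base_log2 = rng.normal(20.0, 2.0, size=len(panel))
    lfc_vec = np.array([prot_lfc[f] for f in panel])
    log2_stable = base_log2[:, None] + rng.normal(
        0, cfg.protein_noise_sd, size=(len(panel), n)
    )
    log2_unstable = (base_log2 + lfc_vec)[:, None] + rng.normal(
        0, cfg.protein_noise_sd, size=(len(panel), n)
    )
    values = pd.DataFrame(
        np.power(2.0, np.concatenate([log2_stable, log2_unstable], axis=1)),
        index=pd.Index(panel, name="feature_id"),
        columns=stable_ids + unstable_ids,
    )
    groups = pd.Series(
        [GROUP_STABLE] * n + [GROUP_UNSTABLE] * n,
        index=stable_ids + unstable_ids,
    )
    truth = TruthSet(
        protein_de={f: v for f, v in prot_lfc.items() if v != 0.0},
        protein_concordant=sorted(concordant),
    )
    return OmicsMatrix(values=values, groups=groups, layer="protein"), truth


# ------------------------------------------------- auxiliary pipeline inputs

def gen_gene_sets(
    counts_truth: TruthSet, cfg: SimConfig, n_sets: int = 10, set_size: int = 30
) -> Dict[str, List[str]]:
    """Small gene-set collection over the count features: one set enriched
    for planted DE features, the rest random draws from the universe."""
    rng = _rng(cfg, _S_AUX)
    universe = [f"feat_{i + 1:05d}" for i in range(cfg.n_features)]
    de = sorted(counts_truth.de_features)
    sets: Dict[str, List[str]] = {}
    if de:
        n_hit = min(set_size // 2, len(de))
        hits = [de[i] for i in rng.choice(len(de), n_hit, replace=False)]
        fill = [
            universe[i]
            for i in rng.choice(len(universe), set_size - n_hit, replace=False)
        ]
        sets["planted_pathway"] = sorted(set(hits) | set(fill))
    for s in range(n_sets - len(sets)):
        members = [
            universe[i]
            for i in rng.choice(len(universe), set_size, replace=False)
        ]
        sets[f"random_set_{s + 1:02d}"] = sorted(set(members))
    return sets


def write_gmt(sets: Dict[str, List[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def gen_mirnas(cfg: SimConfig, n_mirnas: int = 5, length: int = 22) -> Dict[str, str]:
    """Random RNA-alphabet miRNA sequences (5'->3')."""
    rng = _rng(cfg, _S_AUX + 10)
    bases = np.array(list("ACGU"))
    return {
        f"miR-sim-{i + 1}": "".join(rng.choice(bases, size=length))
        for i in range(n_mirnas)
    }


def write_mirna_fasta(mirnas: Dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in mirnas.items()],
        str(path),
        "fasta",
    )


def gen_ppi_edges(
    protein_truth: TruthSet, cfg: SimConfig, n_extra: int = 40
) -> List[Tuple[str, str]]:
    """PPI edge list over the planted DE proteins: one dense clique among
    the first few DE proteins plus a sparse random background."""
    rng = _rng(cfg, _S_AUX + 20)
    nodes = sorted(protein_truth.protein_de)
    if len(nodes) < 4:
        return []
    clique = nodes[:5]
    edges = {
        (a, b) for i, a in enumerate(clique) for b in clique[i + 1 :]
    }
    for _ in range(n_extra):
        i, j = rng.choice(len(nodes), 2, replace=False)
        a, b = sorted((nodes[i], nodes[j]))
        edges.add((a, b))
    return sorted(edges)


def gen_integration_case(
    cfg: SimConfig,
    n_concordant: int = 2,
    n_lnc_target_overlap: int = 2,
    n_origin_overlap: int = 1,
    n_background_genes: int = 40,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, Dict[str, List[str]]]:
    """Cross-layer integration fixture with planted overlaps.

    Builds harmonized-gene-symbol DE tables and a link table in which
    exactly ``n_concordant`` genes are DE in both the mRNA and protein
    layers (same sign), ``n_lnc_target_overlap`` DE proteins are lncRNA
    cis-targets, and ``n_origin_overlap`` DE proteins are circRNA origin
    genes — the five-gene pattern the consistency report is designed to
    surface.  Returns ``(de_mrna, de_protein, links, truth_sets)``.
    """
    rng = _rng(cfg, _S_AUX + 30)
    genes = [f"GENE{i + 1:03d}" for i in range(n_background_genes)]
    it = iter(genes)
    concordant = [next(it) for _ in range(n_concordant)]
    lnc_overlap = [next(it) for _ in range(n_lnc_target_overlap)]
    origin_overlap = [next(it) for _ in range(n_origin_overlap)]
    mrna_only = [next(it) for _ in range(5)]
    protein_rest = lnc_overlap + origin_overlap

    def _table(de_genes: Dict[str, float]) -> pd.DataFrame:
        rows = []
        for g in genes:
            lfc = de_genes.get(g, float(rng.normal(0, 0.2)))
            is_de = g in de_genes
            p = float(rng.uniform(0.001, 0.04)) if is_de else float(
                rng.uniform(0.2, 0.99)
            )
            rows.append((g, abs(lfc) * 50 + 10, lfc, p, is_de))
        return pd.DataFrame(
            rows,
            columns=["feature_id", "baseMean", "log2FoldChange", "pvalue", "is_de"],
        ).set_index("feature_id")

    sign = lambda: float(rng.choice([-1.0, 1.0]))
    mrna_de = {g: sign() * cfg.planted_lfc for g in concordant + mrna_only}
    protein_de = {g: np.sign(mrna_de[g]) * cfg.planted_lfc for g in concordant}
    protein_de.update({g: sign() * cfg.planted_lfc for g in protein_rest})
    de_mrna = _table(mrna_de)
    de_protein = _table(protein_de)

    link_rows = [
        (f"MSTRG.{i + 1}.1", g, "cis_target", int(rng.integers(0, 1000)))
        for i, g in enumerate(lnc_overlap)
    ] + [
        (f"circ:chr1:{1000 * (i + 1)}-{1000 * (i + 1) + 500}:+", g, "origin", 0)
        for i, g in enumerate(origin_overlap)
    ]
    links = pd.DataFrame(
        link_rows, columns=["source_id", "target_gene", "link_type", "distance_bp"]
    )
    truth_sets = {
        "mrna_protein": sorted(concordant),
        "lnc_targets_protein": sorted(lnc_overlap),
        "circ_origin_protein": sorted(origin_overlap),
    }
    return de_mrna, de_protein, links, truth_sets


# ---------------------------------------------------------------- driver

def simulate_all(cfg: SimConfig, outdir: Optional[str | Path] = None):
    """Run every generator; optionally write all pipeline inputs to disk.

    Returns ``(genome, annotation, reads, counts, proteins, truth)`` with
    ``truth`` the merged planted ground truth across layers.
    """
    genome = gen_genome(cfg)
    annotation, ann_truth = gen_annotation(genome, cfg)
    reads = simulate_reads(genome, annotation, ann_truth, cfg)
    counts, counts_truth = simulate_counts(cfg)
    proteins, prot_truth = simulate_proteins(counts_truth, cfg)
    truth = ann_truth.merged(counts_truth).merged(prot_truth)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        genome.to_fasta(out / "genome.fa")
        write_gtf(annotation, out / "annotation.gtf")
        write_fastq(reads, out / "reads.fq")
        counts.to_tsv(out / "counts.tsv", out / "samples.tsv")
        proteins.to_tsv(out / "proteins.tsv")
        truth.to_json(out / "truth.json")
        write_gmt(gen_gene_sets(counts_truth, cfg), out / "gene_sets.gmt")
        write_mirna_fasta(gen_mirnas(cfg), out / "mirnas.fa")
        ppi = gen_ppi_edges(prot_truth, cfg)
        pd.DataFrame(ppi, columns=["protein_a", "protein_b"]).to_csv(
            out / "ppi_edges.tsv", sep="\t", index=False
        )
    return genome, annotation, reads, counts, proteins, truth
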