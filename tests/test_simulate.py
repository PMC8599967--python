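"""The synthetic-data generator: contracts, determinism, planted truth."""

import numpy as np
import pytest

from plaqomics.genome import reverse_complement
from plaqomics.simulate import (
    SimConfig,
    gen_annotation,
    gen_genome,
    gen_integration_case,
    simulate_all,
    simulate_counts,
    simulate_proteins,
    simulate_reads,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(genome_length=5000),
            dict(read_length=30),
            dict(frac_de=1.5),
            dict(nb_dispersion=-0.1),
            dict(n_circrnas=-1),
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)


class TestGenome:
    def test_length_and_alphabet(self):
        g = gen_genome(SimConfig(seed=1, genome_length=10_000))
        seq = g["chr1"]
        assert len(seq) == 10_000
        assert set(seq) <= set("ACGT")

    def test_deterministic_per_seed(self):
        a = gen_genome(SimConfig(seed=1, genome_length=10_000))
        b = gen_genome(SimConfig(seed=1, genome_length=10_000))
        assert a.sequences == b.sequences

    def test_different_seeds_differ(self):
        a = gen_genome(SimConfig(seed=1, genome_length=10_000))
        b = gen_genome(SimConfig(seed=2, genome_length=10_000))
        assert a.sequences != b.sequences


class TestAnnotation:
    def test_coding_gene_construction_contract(self, small_cfg, small_genome):
        _, annotation, _ = small_genome
        coding = [t for t in annotation if t.biotype == "protein_coding"]
        assert len(coding) == small_cfg.n_coding_genes
        assert all(t.n_exons >= 2 for t in coding)
        spans = sorted(t.span for t in coding)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2, "coding loci must not overlap"

    def test_planted_lncrnas_pass_expression_filter(self, small_genome):
        _, annotation, truth = small_genome
        lncs = {t.transcript_id: t for t in annotation if t.biotype == "lncRNA"}
        assert set(truth.lnc_labels) == set(lncs)
        for t in lncs.values():
            assert t.length > 200
            assert t.n_exons >= 2
            assert t.coverage > 3

    def test_u_lncrnas_far_from_coding_genes(self, small_genome):
        _, annotation, truth = small_genome
        coding = [t for t in annotation if t.biotype == "protein_coding"]
        by_id = {t.transcript_id: t for t in annotation}
        for tid, label in truth.lnc_labels.items():
            if label != "u":
                continue
            s, e = by_id[tid].span
            for c in coding:
                cs, ce = c.span
                gap = max(cs - e, s - ce) - 1
                assert gap >= 2000

    def test_i_lncrnas_strictly_inside_one_intron(self, small_genome):
        _, annotation, truth = small_genome
        coding = [t for t in annotation if t.biotype == "protein_coding"]
        by_id = {t.transcript_id: t for t in annotation}
        for tid, label in truth.lnc_labels.items():
            if label != "i":
                continue
            s, e = by_id[tid].span
            hosts = [
                c for c in coding
                for intron in c.introns
                if intron[0] <= s and e <= intron[1]
            ]
            assert hosts, f"{tid} not contained in any intron"

    def test_x_lncrnas_overlap_coding_exons_antisense(self, small_genome):
        _, annotation, truth = small_genome
        coding = [t for t in annotation if t.biotype == "protein_coding"]
        by_id = {t.transcript_id: t for t in annotation}
        for tid, label in truth.lnc_labels.items():
            if label != "x":
                continue
            t = by_id[tid]
            assert any(
                c.strand != t.strand
                and any(
                    es <= ce and cs <= ee
                    for es, ee in t.exons
                    for cs, ce in c.exons
                )
                for c in coding
            )

    def test_planted_junction_flanks_are_ag_gt(self, small_genome):
        genome, _, truth = small_genome
        for j in truth.circ_junctions:
            a0, d0 = j.acceptor - 1, j.donor - 1
            assert genome.slice(j.chrom, a0 - 2, a0) == "AG"
            assert genome.slice(j.chrom, d0 + 1, d0 + 3) == "GT"

    def test_planted_anchors_unique_genome_wide(self, small_cfg, small_genome):
        genome, _, truth = small_genome
        seq = genome["chr1"]
        rc = reverse_complement(seq)
        k = small_cfg.anchor_len
        for j in truth.circ_junctions:
            a0, d0 = j.acceptor - 1, j.donor - 1
            for anchor in (seq[a0 : a0 + k], seq[d0 - k + 1 : d0 + 1]):
                assert seq.count(anchor) + rc.count(anchor) == 1

    def test_genome_too_small_raises(self):
        cfg = SimConfig(seed=1, genome_length=10_000, n_coding_genes=50)
        with pytest.raises(ValueError):
            gen_annotation(gen_genome(cfg), cfg)


class TestReads:
    def test_junction_read_count(self, small_cfg, small_reads):
        bsj = [r for r in small_reads if r.read_id.startswith("bsj|")]
        assert len(bsj) == small_cfg.n_circrnas * small_cfg.junction_reads_per_circ

    def test_junction_reads_have_no_contiguous_genomic_match(
        self, small_genome, small_reads
    ):
        # brute-force substring search over the genome and its reverse
        # complement: a back-splice-spanning read must occur in neither
        genome, _, _ = small_genome
        seq = genome["chr1"]
        rc = reverse_complement(seq)
        for r in small_reads:
            if r.read_id.startswith("bsj|"):
                assert r.sequence not in seq
                assert r.sequence not in rc

    def test_without_circles_every_read_is_contiguous_somewhere(self):
        cfg = SimConfig(
            seed=3, genome_length=30_000, n_coding_genes=6,
            n_lncrnas_per_class=0, n_circrnas=0, n_linear_reads=100,
        )
        genome = gen_genome(cfg)
        annotation, truth = gen_annotation(genome, cfg)
        reads = simulate_reads(genome, annotation, truth, cfg)
        templates = [t.spliced_sequence(genome) for t in annotation]
        templates += [genome["chr1"], reverse_complement(genome["chr1"])]
        for r in reads:
            assert any(r.sequence in t for t in templates)

    def test_deterministic(self, small_cfg, small_genome):
        genome, annotation, truth = small_genome
        a = simulate_reads(genome, annotation, truth, small_cfg)
        b = simulate_reads(genome, annotation, truth, small_cfg)
        assert [(r.read_id, r.sequence) for r in a] == [
            (r.read_id, r.sequence) for r in b
        ]


class TestCounts:
    def test_no_de_features_when_frac_de_zero(self):
        _, truth = simulate_counts(SimConfig(seed=5, frac_de=0.0, n_features=50))
        assert truth.de_features == {}

    def test_null_group_means_converge(self):
        # law of large numbers: with no planted effects the per-group mean
        # ratio approaches 1 across 5,000 features
        om, _ = simulate_counts(
            SimConfig(seed=5, frac_de=0.0, n_features=5000, nb_dispersion=0.1)
        )
        m1 = om.group_values("stable").to_numpy().mean()
        m2 = om.group_values("unstable").to_numpy().mean()
        assert abs(m2 / m1 - 1) < 0.05

    def test_deterministic(self):
        a, _ = simulate_counts(SimConfig(seed=6, n_features=100))
        b, _ = simulate_counts(SimConfig(seed=6, n_features=100))
        assert a.values.equals(b.values)

    def test_planted_lfc_shifts_group_mean(self):
        cfg = SimConfig(seed=7, n_features=2000, frac_de=0.2, planted_lfc=2.0)
        om, truth = simulate_counts(cfg)
        up = [f for f, l in truth.de_features.items() if l > 0]
        ratio = (
            om.group_values("unstable").loc[up].to_numpy().mean()
            / om.group_values("stable").loc[up].to_numpy().mean()
        )
        assert ratio == pytest.approx(4.0, rel=0.25)


class TestProteins:
    def test_concordant_subset_planted_exactly(self):
        cfg = SimConfig(seed=8, n_features=300, frac_de=0.1,
                        n_concordant_proteins=2)
        _, counts_truth = simulate_counts(cfg)
        _, prot_truth = simulate_proteins(counts_truth, cfg)
        assert len(prot_truth.protein_concordant) == 2
        for f in prot_truth.protein_concordant:
            assert f in counts_truth.de_features
            assert np.sign(prot_truth.protein_de[f]) == np.sign(
                counts_truth.de_features[f]
            )
        other_de = set(prot_truth.protein_de) - set(prot_truth.protein_concordant)
        assert other_de.isdisjoint(counts_truth.de_features)

    def test_zero_concordant_gives_disjoint_de_sets(self):
        cfg = SimConfig(seed=9, n_features=300, frac_de=0.1,
                        n_concordant_proteins=0)
        _, counts_truth = simulate_counts(cfg)
        _, prot_truth = simulate_proteins(counts_truth, cfg)
        assert set(prot_truth.protein_de).isdisjoint(counts_truth.de_features)

    def test_intensities_positive(self):
        cfg = SimConfig(seed=10, n_features=300, frac_de=0.1)
        _, counts_truth = simulate_counts(cfg)
        lfq, _ = simulate_proteins(counts_truth, cfg)
        assert (lfq.values.to_numpy() > 0).all()

    def test_oversized_concordant_subset_rejected(self):
        cfg = SimConfig(seed=11, n_features=50, frac_de=0.02,
                        n_concordant_proteins=10)
        _, counts_truth = simulate_counts(cfg)
        with pytest.raises(ValueError):
            simulate_proteins(counts_truth, cfg)


class TestIntegrationCase:
    def test_planted_pattern_sizes(self):
        de_mrna, de_prot, links, truth = gen_integration_case(SimConfig(seed=12))
        assert len(truth["mrna_protein"]) == 2
        assert len(truth["lnc_targets_protein"]) == 2
        assert len(truth["circ_origin_protein"]) == 1
        assert set(links["link_type"]) == {"cis_target", "origin"}


def test_simulate_all_outputs_byte_identical_across_runs(tmp_path):
    cfg = SimConfig(
        seed=13, genome_length=20_000, n_coding_genes=4,
        n_lncrnas_per_class=1, n_circrnas=2, n_linear_reads=50,
        n_features=60, n_proteins=30,
    )
    out1, out2 = tmp_path / "a", tmp_path / "b"
    simulate_all(cfg, outdir=out1)
    simulate_all(cfg, outdir=out2)
    for f in sorted(out1.iterdir()):
        assert (out2 / f.name).read_bytes() == f.read_bytes()
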