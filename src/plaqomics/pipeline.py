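"""End-to-end pipeline orchestration with a machine-readable run manifest.

Stages run in dependency order: simulate -> map -> circ -> lncrna -> de ->
links -> integrate -> cerna.  Every source of randomness flows from the
single top-level seed.  A failure in any stage aborts with a
:class:`PipelineError` naming the stage; the manifest records, per stage,
the files written and their row counts, plus input hashes, the seed and
the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .circ import CircParams, detect_circrnas, tpm_quantify
from .cerna import build_cerna, write_sif
from .de import OmicsMatrix, nb_test, protein_test
from .enrich import hypergeom_enrich, overlap_sets, read_gmt
from .genome import GenomeRef
from .links import cis_targets, origin_genes
from .lncrna import classification_table
from .mcode import clusters_table, mcode_cluster
from .models import read_gtf, write_junctions_bed
from .simulate import (
    SimConfig,
    TruthSet,
    gen_mirnas,
    read_fastq,
    simulate_all,
)

logger = logging.getLogger("plaqomics")

STAGES = [
    "simulate", "map", "circ", "lncrna", "de", "links", "integrate", "cerna",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """One config to drive the whole analysis.

    Threshold defaults are the printed analysis criteria: 20 bp anchors,
    lncRNA length > 200 nt with >= 2 exons and coverage > 3, DE at
    |log2FC| > 1.0 and p < 0.05, and a +-1 kb cis window.
    """

    outdir: str = "plaqomics_run"
    seed: int = 0
    anchor_len: int = 20
    max_span: int = 100_000
    signal: str = "AG-GT"
    min_support: int = 1
    lnc_min_length: int = 200
    lnc_min_exons: int = 2
    lnc_min_coverage: float = 3.0
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    cis_window: int = 1000
    log_level: str = "INFO"
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        for name in (
            "anchor_len", "max_span", "lnc_min_length", "lnc_min_exons",
            "lfc_threshold", "p_threshold", "cis_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        # the single top-level seed drives the simulator too
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _line_count(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for _ in fh)


def run_all(config: PipelineConfig) -> Dict:
    """Execute all stages; return the manifest (also written to
    ``outdir/manifest.json``)."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "inputs": {},
    }

    def record(stage: str, t0: float, counts: Dict[str, int]) -> None:
        logger.info("[%s] done: %s", stage, counts)
        manifest["stages"].append(
            {
                "name": stage,
                "seconds": round(time.time() - t0, 3),
                "counts": counts,
            }
        )

    state: Dict = {}

    def run_stage(stage: str, fn) -> None:
        t0 = time.time()
        logger.info("[%s] starting", stage)
        try:
            counts = fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise PipelineError(stage, exc) from exc
        record(stage, t0, counts)

    # ---------------------------------------------------------- simulate
    def _simulate() -> Dict[str, int]:
        genome, annotation, reads, counts, proteins, truth = simulate_all(
            config.sim, outdir=out
        )
        state.update(
            genome=genome, annotation=annotation, reads=reads,
            counts=counts, proteins=proteins, truth=truth,
        )
        for name in ("genome.fa", "annotation.gtf", "reads.fq", "counts.tsv",
                     "proteins.tsv", "gene_sets.gmt", "mirnas.fa",
                     "ppi_edges.tsv"):
            manifest["inputs"][name] = _sha256(out / name)
        return {
            "transcripts": len(annotation),
            "reads": len(reads),
            "count_features": counts.values.shape[0],
            "proteins": proteins.values.shape[0],
        }

    # ------------------------------------------------------- map + circ
    def _map() -> Dict[str, int]:
        from .mapper import KmerIndex, map_linear

        index = KmerIndex(state["genome"], config.anchor_len)
        state["index"] = index
        unmapped = []
        mapped = 0
        for r in state["reads"]:
            if map_linear(index, r.sequence):
                mapped += 1
            else:
                unmapped.append(r)
        state["unmapped"] = unmapped
        (out / "unmapped_reads.txt").write_text(
            "".join(r.read_id + "\n" for r in unmapped)
        )
        return {"mapped": mapped, "unmapped": len(unmapped)}

    def _circ() -> Dict[str, int]:
        params = CircParams(
            anchor_len=config.anchor_len, max_span=config.max_span,
            signal=config.signal, min_support=config.min_support,
        )
        junctions, tally = detect_circrnas(
            state["genome"], state["unmapped"], params, index=state["index"]
        )
        state["junctions"] = junctions
        write_junctions_bed(junctions, out / "circ.bed")
        quant = tpm_quantify(junctions)
        quant.to_csv(out / "circ_quant.tsv", sep="\t", index=False)
        return {"junctions": len(junctions), **tally}

    # ------------------------------------------------------------ lncrna
    def _lncrna() -> Dict[str, int]:
        annotation = read_gtf(out / "annotation.gtf")
        coding = [t for t in annotation if t.biotype == "protein_coding"]
        novel = [t for t in annotation if t.biotype != "protein_coding"]
        table = classification_table(
            novel, coding,
            min_length=config.lnc_min_length,
            min_exons=config.lnc_min_exons,
            min_coverage=config.lnc_min_coverage,
        )
        table.to_csv(out / "lnc_classification.tsv", sep="\t", index=False)
        state["coding"] = coding
        state["lnc_kept"] = [
            t for t in novel if t.transcript_id in set(table[table["kept"]]["transcript_id"])
        ]
        return {"novel": len(novel), "kept": len(state["lnc_kept"])}

    # ---------------------------------------------------------------- de
    def _de() -> Dict[str, int]:
        de_mrna = nb_test(
            state["counts"], lfc_threshold=config.lfc_threshold,
            p_threshold=config.p_threshold,
        )
        de_prot = protein_test(
            state["proteins"], lfc_threshold=config.lfc_threshold,
            p_threshold=config.p_threshold,
        )
        de_mrna.to_csv(out / "de_mrna.tsv", sep="\t")
        de_prot.to_csv(out / "de_protein.tsv", sep="\t")
        state["de_mrna"] = de_mrna
        state["de_protein"] = de_prot
        return {
            "de_mrna": int(de_mrna["is_de"].sum()),
            "de_protein": int(de_prot["is_de"].sum()),
        }

    # ------------------------------------------------------------- links
    def _links() -> Dict[str, int]:
        cis = cis_targets(
            state["lnc_kept"], state["coding"], window=config.cis_window
        )
        origin = origin_genes(state["junctions"], state["coding"])
        links = pd.concat([cis, origin], ignore_index=True)
        links.to_csv(out / "links.tsv", sep="\t", index=False)
        state["links"] = links
        return {"cis_links": len(cis), "origin_links": len(origin)}

    # --------------------------------------------------------- integrate
    def _integrate() -> Dict[str, int]:
        report = overlap_sets(
            state["de_mrna"], state["de_protein"], state["links"]
        )
        report.mrna_protein.to_csv(
            out / "overlap_mrna_protein.tsv", sep="\t", index=False
        )
        (out / "overlap_links_protein.json").write_text(
            json.dumps(
                {
                    "lnc_targets_protein": report.lnc_targets_protein,
                    "circ_origin_protein": report.circ_origin_protein,
                },
                indent=2,
            )
        )
        collection = read_gmt(out / "gene_sets.gmt")
        universe = [str(f) for f in state["counts"].feature_ids]
        query = [
            str(f) for f in state["de_mrna"].index[state["de_mrna"]["is_de"]]
        ]
        enrichment = hypergeom_enrich(query, collection, universe)
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        return {
            "mrna_protein_overlap": len(report.mrna_protein),
            "enriched_sets": int((enrichment["pvalue"] < 0.05).sum())
            if not enrichment.empty else 0,
        }

    # ------------------------------------------------------------- cerna
    def _cerna() -> Dict[str, int]:
        genome = state["genome"]
        sponge_seqs = {
            t.transcript_id: t.spliced_sequence(genome)
            for t in state["lnc_kept"]
        }
        for j in state["junctions"]:
            sponge_seqs[j.name] = genome.slice(
                j.chrom, j.acceptor - 1, j.donor
            )
        mirnas = gen_mirnas(config.sim)
        utrs = {
            t.gene_id: t.spliced_sequence(genome)[-200:]
            for t in state["coding"]
        }
        edges = build_cerna(sponge_seqs, mirnas, utrs)
        edges.to_csv(out / "cerna_edges.tsv", sep="\t", index=False)
        write_sif(edges, out / "cerna.sif")
        ppi = pd.read_csv(out / "ppi_edges.tsv", sep="\t")
        clusters = mcode_cluster(
            ppi.itertuples(index=False, name=None)
        ) if len(ppi) else []
        clusters_table(clusters).to_csv(
            out / "ppi_clusters.tsv", sep="\t", index=False
        )
        return {"cerna_edges": len(edges), "ppi_clusters": len(clusters)}

    run_stage("simulate", _simulate)
    run_stage("map", _map)
    run_stage("circ", _circ)
    run_stage("lncrna", _lncrna)
    run_stage("de", _de)
    run_stage("links", _links)
    run_stage("integrate", _integrate)
    run_stage("cerna", _cerna)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
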