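"""Stage orchestration: reproducible runs with config, seeds and provenance.

Each stage is a thin wrapper over the library modules; all file handoffs
go through the TSV/GMT/RNK formats in :mod:`exonsi.counts_io`.  Every run
writes a ``provenance.json`` capturing the full configuration, the root
seed and the package version, so any output can be regenerated from the
provenance file alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, counts_io, diffstats, enrichment, phospho, splicing
from .errors import ParameterError
from .simulate import SimConfig, make_differential_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "exonusage", "diff", "enrich", "pps")


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the analysis defaults."""

    stages: list[str] = field(default_factory=list)
    outdir: str = "exonsi_run"
    seed: int = 0
    # thresholds
    min_reads: int = splicing.DEFAULT_MIN_READS
    fano_max: float = splicing.DEFAULT_FANO_MAX
    s0: float = diffstats.DEFAULT_S0
    q_max: float = diffstats.DEFAULT_Q_MAX
    fc_threshold: float = 0.5
    pseudocount: float = splicing.DEFAULT_PSEUDOCOUNT
    n_perm: int = 1000
    scheme: str = "label-permutation"
    # inputs (stage-dependent; simulate fills the count paths itself)
    exon_counts: str | None = None
    gene_counts: str | None = None
    conditions: str | None = None
    gmt: str | None = None
    phospho_table: str | None = None
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ParameterError(f"unknown stages {unknown}; choose from {STAGES}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a summary dict.

    Deterministic given the seed: all randomness flows from
    ``config.seed``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    provenance = {"config": dataclasses.asdict(config),
                  "package": "exonsi", "version": __version__,
                  "seed": config.seed}
    with open(outdir / "provenance.json", "w") as handle:
        json.dump(provenance, handle, indent=2, sort_keys=True)

    exon_path = config.exon_counts
    gene_path = config.gene_counts
    cond_path = config.conditions

    for stage in config.stages:
        t0 = time.perf_counter()
        if stage == "simulate":
            sim_cfg = SimConfig(seed=config.seed, **config.sim)
            exon_ct, gene_ct, truth = make_differential_dataset(sim_cfg)
            exon_path = str(outdir / "exon_counts.tsv")
            gene_path = str(outdir / "gene_counts.tsv")
            cond_path = str(outdir / "conditions.tsv")
            exon_ct.write(exon_path, cond_path)
            gene_ct.write(gene_path, outdir / "conditions_gene.tsv")
            counts_io.write_results(truth, outdir / "truth.tsv")
            summary["n_exons_simulated"] = len(truth)
        elif stage == "exonusage":
            exon_ct, gene_ct = _load_counts(exon_path, gene_path, cond_path, stage)
            table = splicing.compute_splicing_index(
                exon_ct, gene_ct, pseudocount=config.pseudocount,
                min_reads=config.min_reads, fano_max=config.fano_max)
            out = table.summary.reset_index().rename(columns={"index": "exon_id",
                                                              "feature_id": "exon_id"})
            counts_io.write_results(out, outdir / "splicing_table.tsv")
            summary["n_exons_kept"] = int(table.summary["kept"].sum())
            summary["_splicing_table"] = table
        elif stage == "diff":
            table = summary.get("_splicing_table")
            if table is None:
                raise ParameterError("diff stage requires the exonusage stage")
            kept = table.summary.index[table.summary["kept"]]
            labels = [table.conditions[s] for s in table.si.columns]
            result = diffstats.exon_differential(
                table.si.loc[kept], labels, s0=config.s0, scheme=config.scheme,
                seed=config.seed, log2fc=table.summary.loc[kept, "log2fc"])
            up, down = diffstats.call_significant(result, q_max=config.q_max)
            result["significant"] = result["q"] < config.q_max
            result["direction"] = ["up" if i in up else "down" if i in down
                                   else "ns" for i in result.index]
            counts_io.write_results(result.reset_index(names="exon_id"),
                                    outdir / "diff_results.tsv")
            counts_io.write_rnk(
                enrichment.RankedList(ids=result.index.to_numpy(),
                                      scores=result["log2fc"].to_numpy()),
                outdir / "exon_log2fc.rnk")
            summary["n_up"] = len(up)
            summary["n_down"] = len(down)
            summary["_diff_result"] = result
        elif stage == "enrich":
            result = summary.get("_diff_result")
            if result is None or config.gmt is None:
                raise ParameterError("enrich stage requires diff results and a GMT")
            ranked = enrichment.RankedList(ids=result.index.to_numpy(),
                                          scores=result["log2fc"].to_numpy())
            sets = counts_io.read_gmt(config.gmt)
            enr = enrichment.nes_and_fdr(ranked, sets, n_perm=config.n_perm,
                                         seed=config.seed)
            enrichment.write_enrichment(enr, outdir / "enrichment.tsv")
            summary["n_sets"] = len(enr)
        elif stage == "pps":
            if config.phospho_table is None:
                raise ParameterError("pps stage requires a phosphosite table")
            sites = phospho.read_phospho_table(config.phospho_table)
            pps = phospho.compute_pps(sites)
            phospho.write_pps(pps, outdir / "pps.tsv")
            counts_io.write_rnk(phospho.rank_by_pps(pps), outdir / "pps.rnk")
            summary["n_proteins"] = len(pps)
        logger.info("stage %-10s done in %.2fs", stage, time.perf_counter() - t0)

    # in-memory intermediates are not part of the on-disk summary
    return {k: v for k, v in summary.items() if not k.startswith("_")}


def _load_counts(exon_path, gene_path, cond_path, stage):
    if not (exon_path and gene_path and cond_path):
        raise ParameterError(f"stage {stage!r}: exon, gene and condition "
                             "tables are required")
    for p in (exon_path, gene_path, cond_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"stage {stage!r}: missing input {p}")
    exon_ct = counts_io.read_count_table(exon_path, cond_path)
    gene_ct = counts_io.read_count_table(gene_path, cond_path)
    return exon_ct, gene_ct
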