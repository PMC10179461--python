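"""End-to-end orchestration of the analysis chain.

Stages: simulate (or ingest) counts -> CPM ratio tables, histograms and
chromosome medians -> DE calling -> positional classification of
differential lncRNAs -> cis/trans target prediction -> network build,
centrality suite and hub selection -> optional over-representation
analysis -> summary JSON.  Every intermediate artifact is written under
``output_dir`` with a fixed name; identical configuration and seed give
an identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import diffexp, enrichment, network, ratios, targets
from .expression import CountMatrix, cpm, expression_ratio
from .simulate import CLOSURE_CHROM, SimulationConfig, simulate_dataset

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    output_dir: str = "lncdosage_out"
    # inputs: either a simulation config or paths to real data
    simulation: SimulationConfig | None = None
    annotation_path: str | None = None
    counts_path: str | None = None
    design_path: str | None = None
    de_table_path: str | None = None  # externally computed DE results
    term_map_path: str | None = None  # 2-column (term, gene) TSV for ORA
    # stage parameters (defaults are the field-standard thresholds)
    min_cpm: float = 1.0
    bin_width: float = 0.05
    histogram_cap: float = 3.0
    lfc_min: float = 1.0
    alpha: float = 0.05
    cis_window: int = 10_000
    r_min: float = 0.95
    trans_alpha: float = 0.01
    min_mcc: float = 30.0
    nes_min: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None and (self.counts_path is None or self.annotation_path is None):
            self.simulation = SimulationConfig(seed=self.seed)
        if not 0 < self.alpha < 1 or not 0 < self.trans_alpha < 1:
            raise ValueError("significance thresholds must be in (0, 1)")
        if not 0 < self.r_min < 1:
            raise ValueError("r_min must be in (0, 1)")
        if self.cis_window < 0 or self.bin_width <= 0:
            raise ValueError("cis_window must be >= 0 and bin_width > 0")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        sim = data.pop("simulation", None)
        cfg = cls(**data)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # partial outputs stay on disk
                raise StageError(name, type(exc).__name__, str(exc)) from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return result

        return wrapper

    return decorator


@_stage("input")
def _load_inputs(config: PipelineConfig, out: Path):
    if config.counts_path and config.annotation_path:
        records = ann.read_gtf(config.annotation_path)
        counts = CountMatrix.from_tsv(config.counts_path, config.design_path)
        truth = None
    else:
        sim = config.simulation
        dataset = simulate_dataset(sim)
        dataset.write(out / "simulated")
        records, counts, truth = dataset.annotation, dataset.counts, dataset
    return records, counts, truth


@_stage("ratio")
def _ratio_stage(config: PipelineConfig, records, counts, out: Path):
    table = expression_ratio(counts, records, min_cpm=config.min_cpm)
    table.to_csv(out / "ratios.tsv", sep="\t", index=False, float_format="%.6g")
    medians = ratios.chromosome_medians(table)
    medians.to_csv(out / "chromosome_medians.tsv", sep="\t", index=False, float_format="%.6g")
    hist_summaries = {}
    for (chrom, biotype), sub in table.groupby(["chrom", "biotype"], observed=True):
        if chrom == CLOSURE_CHROM or len(sub) == 0:
            continue
        hist = ratios.histogram(sub["ratio"].to_numpy(), config.bin_width, config.histogram_cap)
        hist.to_tsv(out / f"hist_{chrom}_{biotype}.tsv")
        hist_summaries[f"{chrom}/{biotype}"] = ratios.modal_bin(hist)
    return table, medians, hist_summaries


@_stage("de")
def _de_stage(config: PipelineConfig, records, counts, out: Path):
    if config.de_table_path:
        results = diffexp.read_de_table(config.de_table_path)
    else:
        results = diffexp.nb_wald_test(counts, records)
    called = diffexp.call_de(results, lfc_min=config.lfc_min, alpha=config.alpha)
    called.to_csv(out / "de.tsv", sep="\t", index=False, float_format="%.6g")
    return called


@_stage("classify-lnc")
def _classify_stage(records, dels: list[str], out: Path):
    by_id = {g.gene_id: g for g in records}
    lncs = [by_id[g] for g in dels if g in by_id and by_id[g].biotype == "lncRNA"]
    coding = [g for g in records if g.biotype == "coding"]
    classes = ann.classify_positions(lncs, coding)
    ann.write_position_classes(classes, out / "del_classes.tsv")
    return classes


@_stage("targets")
def _targets_stage(config: PipelineConfig, records, counts, dels, out: Path):
    by_id = {g.gene_id: g for g in records}
    del_lncs = [by_id[g] for g in dels if g in by_id and by_id[g].biotype == "lncRNA"]
    coding = [g for g in records if g.biotype == "coding"]
    cis = targets.cis_targets(del_lncs, coding, window=config.cis_window)
    norm = cpm(counts)
    lnc_ids = [g.gene_id for g in del_lncs if g.gene_id in norm.index]
    coding_ids = [g.gene_id for g in coding if g.gene_id in norm.index]
    trans = []
    if lnc_ids and coding_ids and norm.shape[1] >= 3:
        trans = targets.trans_targets(
            norm.loc[lnc_ids], norm.loc[coding_ids], r_min=config.r_min, alpha=config.trans_alpha
        )
    pairs = cis + trans
    targets.write_pairs(pairs, out / "targets.tsv")
    return pairs


@_stage("network")
def _network_stage(config: PipelineConfig, pairs, out: Path):
    g = network.build_network(pairs)
    network.write_sif(g, out / "network.sif")
    table = network.centrality_suite(g, network.CentralityConfig(seed=config.seed))
    table.to_csv(out / "centrality.tsv", sep="\t", float_format="%.6g")
    hubs, sub = network.select_hubs(table, min_mcc=config.min_mcc, graph=g)
    if sub is not None:
        network.write_sif(sub, out / "hubs.sif")
    else:
        (out / "hubs.sif").write_text("")
    return g, table, hubs


@_stage("enrich")
def _enrich_stage(config: PipelineConfig, study: list[str], universe: list[str], out: Path):
    path = out / "enrichment.tsv"
    if not config.term_map_path or not study:
        pd.DataFrame(columns=["term_id", "term_name", "category", "k", "K", "n", "N", "p", "padj"]).to_csv(
            path, sep="\t", index=False
        )
        return None
    term_map = enrichment.read_term_map(config.term_map_path)
    result = enrichment.hypergeom_ora(study, term_map, universe)
    result.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the summary dictionary (also saved as JSON)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, counts, truth = _load_inputs(config, out)

    ratio_table, medians, hist_modes = _ratio_stage(config, records, counts, out)
    called = _de_stage(config, records, counts, out)
    de_summary = diffexp.summarize_de(called)

    sig = called[called["status"] != "ns"]
    lnc_ids = {r.gene_id for r in records if r.biotype == "lncRNA"}
    dels = [g for g in sig["gene_id"] if g in lnc_ids]
    classes = _classify_stage(records, dels, out)
    class_counts: dict[str, int] = {}
    for c in classes.values():
        class_counts[c] = class_counts.get(c, 0) + 1

    pairs = _targets_stage(config, records, counts, dels, out)
    g, table, hubs = _network_stage(config, pairs, out)

    universe = [r.gene_id for r in records if r.biotype == "coding"]
    study = sorted({p.target_id for p in pairs})
    study = [s for s in study if s in set(universe)]
    _enrich_stage(config, study, universe, out)

    summary = {
        "n_genes": len(records),
        "n_samples": counts.counts.shape[1],
        "modal_bins": hist_modes,
        "de": de_summary,
        "n_dels": len(dels),
        "del_position_classes": class_counts,
        "n_cis_pairs": sum(1 for p in pairs if p.mode == "cis"),
        "n_trans_pairs": sum(1 for p in pairs if p.mode == "trans"),
        "hubs": list(hubs),
        "seed": config.seed,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
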