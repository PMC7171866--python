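"""End-to-end orchestration: preprocess -> phylogenetic signal -> process
quantification -> beta-diversity / interaction-adjusted indices -> spatial
statistics, all deterministic under one master seed.

Each stage writes a TSV into the output directory with a header comment
recording the tool version, master seed and stage parameters.  Stage
failures are isolated: a failing stage is logged and downstream stages that
do not depend on it still run.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beta as beta_mod
from . import interactions, simulate, spatial
from .assembly import (ProcessThresholds, bnti, classify_processes,
                       phylo_signal_correlogram, raup_crick_bray)
from .distances import DistanceMatrix
from ._utils import output_header
from .table import (OtuTable, SampleMetadata, filter_low_abundance, rarefy,
                    read_metadata, read_otu_table, write_otu_table)
from .tree import read_tree, write_tree

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs; mirror of the YAML config file."""

    # either explicit inputs ...
    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    table_orientation: str = "taxa-as-rows"
    # ... or a simulation regime
    simulate_regime: str | None = None
    simulation: dict = field(default_factory=dict)

    rarefaction_depth: int | None = 4060
    min_total_reads: int = 100
    thresholds: ProcessThresholds = field(default_factory=ProcessThresholds)
    beta_metrics: tuple[str, ...] = ("bray_curtis", "gunifrac")
    gunifrac_alpha: float = 0.5
    tina_estimator: str = "pearson"
    abrupt_threshold: float = 0.8
    distance_class_km: float = 1000.0
    phylo_signal_variable: str = "temperature"
    permanova_terms: tuple[str, ...] = ("temperature", "province")
    n_perm: int = 999
    seed: int = 0
    out_dir: str = "assemblage_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = ProcessThresholds(**thr)
        return cfg


def _write_df(df: pd.DataFrame, path: Path, seed, params: dict) -> None:
    with open(path, "w") as fh:
        fh.write(output_header(seed, params) + "\n")
        df.to_csv(fh, sep="\t")


def _load_inputs(config: PipelineConfig):
    if config.simulate_regime:
        table, tree, meta, truth = simulate.simulate_regime(
            config.simulate_regime, seed=config.seed, **config.simulation)
        return table, tree, meta, truth
    errors = []
    if not config.table_path:
        errors.append("table_path is required")
    if "gunifrac" in config.beta_metrics and not config.tree_path:
        errors.append("tree_path is required for gUniFrac")
    if not config.metadata_path:
        errors.append("metadata_path is required")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    table = read_otu_table(config.table_path, config.table_orientation)
    tree = read_tree(config.tree_path) if config.tree_path else None
    meta = read_metadata(config.metadata_path)
    return table, tree, meta, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a dict of in-memory results per stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    results: dict = {}
    failures: dict[str, str] = {}

    table, tree, meta, truth = _load_inputs(config)

    # -- preprocessing ------------------------------------------------------
    log_lines = [f"input: {table.n_samples} samples x {table.n_taxa} taxa"]
    if config.rarefaction_depth:
        depth = min(config.rarefaction_depth, int(table.sample_totals().min()))
        if depth < config.rarefaction_depth:
            log_lines.append(f"rarefaction depth reduced to {depth} "
                             f"(shallowest sample)")
        table = rarefy(table, depth, seed=seed)
        log_lines.append(f"rarefied to {depth} reads: "
                         f"{table.n_samples} samples x {table.n_taxa} taxa")
    if config.min_total_reads and table.taxon_totals().max() > config.min_total_reads:
        table = filter_low_abundance(table, config.min_total_reads)
        log_lines.append(f"filtered taxa <= {config.min_total_reads} reads: "
                         f"{table.n_taxa} taxa retained")
    meta = meta.aligned_to(table.sample_ids)
    results["table"] = table
    (out / "preprocessing.log").write_text(
        output_header(seed, {"stage": "preprocess"}) + "\n" + "\n".join(log_lines) + "\n")
    write_otu_table(table, out / "table_preprocessed.tsv", seed=seed)
    if truth is not None:
        _write_df(truth.to_dataframe(), out / "truth.tsv", seed, {"stage": "truth"})
        write_tree(tree, out / "tree.nwk")

    def stage(name, fn):
        try:
            results[name] = fn()
        except Exception as exc:  # stage isolation is deliberate
            failures[name] = str(exc)
            logger.error("stage %s failed: %s", name, exc)

    # -- phylogenetic signal ------------------------------------------------
    if tree is not None:
        def _signal():
            env = meta.data[config.phylo_signal_variable]
            corr = phylo_signal_correlogram(table, env, tree,
                                            n_perm=config.n_perm, seed=seed)
            _write_df(corr, out / "phylo_signal.tsv", seed,
                      {"stage": "phylo_signal", "variable": config.phylo_signal_variable})
            first = corr.dropna(subset=["p_corrected"]).head(1)
            if first.empty or not (first["mantel_r"].iat[0] > 0
                                   and first["p_corrected"].iat[0] < 0.05):
                logger.warning(
                    "no significant phylogenetic signal in the shortest distance "
                    "class; selection inferences from betaNTI should be read "
                    "with caution")
            return corr
        stage("phylo_signal", _signal)

    # -- process quantification --------------------------------------------
    if tree is not None:
        def _processes():
            thr = config.thresholds
            ss = np.random.SeedSequence(seed).generate_state(2) % (2 ** 31)
            b = bnti(table, tree, n_null=thr.n_null_bnti, seed=int(ss[0]))
            rc = raup_crick_bray(table, n_null=thr.n_null_rc, seed=int(ss[1]))
            calls, summary = classify_processes(b.pairs, rc, thr)
            _write_df(calls, out / "process_calls.tsv", seed,
                      {"stage": "processes", "n_null_bnti": thr.n_null_bnti,
                       "n_null_rc": thr.n_null_rc})
            _write_df(summary.to_series().to_frame(), out / "process_summary.tsv",
                      seed, {"stage": "process_summary", "n_pairs": summary.n_pairs})
            return calls, summary
        stage("processes", _processes)

    # -- beta diversity -----------------------------------------------------
    def _beta():
        mats = {}
        if "bray_curtis" in config.beta_metrics:
            mats["bray_curtis"] = beta_mod.bray_curtis(table)
        if "gunifrac" in config.beta_metrics and tree is not None:
            mats["gunifrac"] = beta_mod.gunifrac(table, tree, config.gunifrac_alpha)
        for name, dm in mats.items():
            dm.write(out / f"beta_{name}.tsv", seed, {"stage": "beta", "metric": name})
        return mats
    stage("beta", _beta)

    # -- interaction-adjusted ----------------------------------------------
    def _tina():
        assoc = interactions.taxon_associations(table, config.tina_estimator)
        sim = interactions.tina(table, assoc)
        sim.to_dissimilarity().write(out / "tina_dissimilarity.tsv", seed,
                                     {"stage": "tina", "estimator": assoc.estimator})
        mats = {"tina": sim}
        if tree is not None:
            psim = interactions.pina(table, tree)
            psim.to_dissimilarity().write(out / "pina_dissimilarity.tsv", seed,
                                          {"stage": "pina"})
            mats["pina"] = psim
        return mats
    stage("tina", _tina)

    # -- spatial statistics -------------------------------------------------
    geo = spatial.haversine_distances(meta)
    beta_dm: DistanceMatrix | None = None
    if "beta" in results and results["beta"]:
        beta_dm = results["beta"].get("bray_curtis") or next(iter(results["beta"].values()))

    if beta_dm is not None:
        def _permanova():
            terms = [t for t in config.permanova_terms if t in meta.data.columns]
            res = spatial.permanova(beta_dm, meta, terms,
                                    n_perm=config.n_perm, seed=seed)
            _write_df(res, out / "permanova.tsv", seed,
                      {"stage": "permanova", "terms": ",".join(terms)})
            return res
        stage("permanova", _permanova)

        def _varpart():
            env_vars = [v for v in meta.env_vars if v in meta.data.columns]
            geo_vars = [v for v in meta.group_vars if v in meta.data.columns]
            vp = spatial.variance_partition(beta_dm, meta, env_vars, geo_vars)
            _write_df(pd.Series(vp.as_dict(), name="fraction").to_frame(),
                      out / "variance_partition.tsv", seed, {"stage": "varpart"})
            return vp
        stage("varpart", _varpart)

        def _decay():
            corr = spatial.mantel_correlogram(geo, beta_dm,
                                              class_width=config.distance_class_km,
                                              n_perm=config.n_perm, seed=seed)
            _write_df(corr, out / "distance_decay.tsv", seed,
                      {"stage": "distance_decay",
                       "class_km": config.distance_class_km})
            return corr
        stage("distance_decay", _decay)

        def _sequential():
            res = beta_mod.sequential_beta(beta_dm, meta, config.abrupt_threshold)
            _write_df(res.entries.set_index("station"), out / "sequential_beta.tsv",
                      seed, {"stage": "sequential_beta",
                             "threshold": config.abrupt_threshold})
            return res
        stage("sequential_beta", _sequential)

    def _lcbd():
        res = spatial.lcbd(table, n_perm=config.n_perm, seed=seed)
        df = pd.concat([res.values, res.p_values], axis=1)
        _write_df(df, out / "lcbd.tsv", seed,
                  {"stage": "lcbd", "ss_total": round(res.ss_total, 6)})
        return res
    stage("lcbd", _lcbd)

    results["failures"] = failures
    return results
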