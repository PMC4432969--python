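"""Run configuration and stage orchestration.

Stages communicate through files in the output directory and run in
dependency order (simulate -> ora -> network -> rank -> screen -> synergy
-> report).  Every written table gets a JSON sidecar (stage, config hash,
seed, row count), outputs carry fixed float formatting, and reruns with an
identical configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import druggability, network, ora, screen, synergy
from .io import (ConfigError, InputError, read_comparison_table,
                 read_drug_targets, read_gmt, read_sif,
                 write_comparison_table, write_drug_targets, write_gmt,
                 write_sif)
from .simulate import (SimulationConfig, simulate_combination,
                       simulate_drug_targets, simulate_expression,
                       simulate_ppi, simulate_screen_plate)

__all__ = ["RunConfig", "STAGES", "run_pipeline", "build_heatmap_matrix"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ora", "network", "rank", "screen", "synergy", "report")


@dataclass
class RunConfig:
    """Validated pipeline configuration; ``simulation`` nests the generator."""

    outdir: str = "emtkit_results"
    seed: int = 0
    q_de: float = 0.05            # DE-count threshold
    q_ora: float = 0.01           # ORA DE-status threshold
    alpha: float = 0.05
    fdr_network: float = 0.001    # BUM-FDR level defining tau
    ci_thresholds: tuple = synergy.DEFAULT_CI_THRESHOLDS
    min_maps: int = 6
    chi2_variant: str = "contingency_2x2"
    network_comparisons: tuple = ("468_EGF", "468_HPX")
    screen_plates: tuple = ((("KIN-1"), "EGF", "MDA-MB-468"),)
    combo_drugs: tuple = ("KIN-1", "KIN-2")
    heatmap_n_genes: int = 20
    top_n_druggable: int = 30
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        for name in ("q_de", "q_ora", "alpha", "fdr_network"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        low, high = self.ci_thresholds
        if not (0.0 < low < high):
            raise ConfigError("ci_thresholds must satisfy 0 < low < high")
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        if self.simulation.seed != self.seed:
            self.simulation = dataclasses.replace(self.simulation,
                                                  seed=self.seed)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def config_hash(self) -> str:
        def default(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            if isinstance(obj, (set, frozenset)):
                return sorted(obj)
            raise TypeError(type(obj).__name__)
        payload = dataclasses.asdict(self)
        payload.pop("outdir")  # hash the analysis, not the output location
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Artifact helpers
# ---------------------------------------------------------------------------

def _sidecar(path: Path, stage: str, config: RunConfig, n_rows: int) -> None:
    meta = {"stage": stage, "config_hash": config.config_hash(),
            "seed": config.seed, "n_rows": int(n_rows)}
    Path(str(path) + ".meta.json").write_text(
        json.dumps(meta, sort_keys=True) + "\n")


def _write_table(df: pd.DataFrame, path: Path, stage: str,
                 config: RunConfig, sep: str = "\t", index=False) -> None:
    df.to_csv(path, sep=sep, index=index, float_format="%.10g")
    _sidecar(path, stage, config, len(df))


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise InputError(
            f"stage {needed_by!r} needs {path.name}, produced by stage "
            f"{stage!r}; run that stage first")
    return path


def _plate_tag(compound: str, condition: str, cell_line: str) -> str:
    return f"{cell_line}_{condition}_{compound}".replace("/", "-")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, outdir: Path) -> None:
    sim = simulate_expression(config.simulation)
    for comparison, table in sim.tables.items():
        path = outdir / f"expression_{comparison}.tsv"
        write_comparison_table(table, path)
        _sidecar(path, "simulate", config, len(table))
    write_gmt(sim.pathways, outdir / "pathways.gmt")
    _sidecar(outdir / "pathways.gmt", "simulate", config, len(sim.pathways))

    ppi = simulate_ppi(config.simulation, sim)
    write_sif(ppi.graph, outdir / "network.sif")
    _sidecar(outdir / "network.sif", "simulate", config,
             ppi.graph.number_of_edges())

    targets = simulate_drug_targets(config.simulation, ppi.graph)
    write_drug_targets(targets, outdir / "drug_targets.tsv")
    _sidecar(outdir / "drug_targets.tsv", "simulate", config, len(targets))

    truth = {"planted_module": sorted(ppi.planted_module),
             "signal_genes": {c: sorted(g)
                              for c, g in sim.signal_genes.items()}}
    for compound, condition, cell_line in config.screen_plates:
        plate = simulate_screen_plate(config.simulation, compound, condition,
                                      cell_line)
        tag = _plate_tag(compound, condition, cell_line)
        _write_table(plate.cells, outdir / f"plate_{tag}_cells.csv",
                     "simulate", config, sep=",")
        _write_table(plate.wells, outdir / f"plate_{tag}_wells.csv",
                     "simulate", config, sep=",")
        truth[f"plate_{tag}"] = {k: v for k, v in plate.truth.items()
                                 if k != "cell_vim_labels"}
    combo = simulate_combination(config.simulation, *config.combo_drugs)
    _write_table(combo.single_agent, outdir / "combination_single_agent.csv",
                 "simulate", config, sep=",")
    _write_table(combo.combination, outdir / "combination_grid.csv",
                 "simulate", config, sep=",")
    truth["combination"] = combo.truth
    (outdir / "truth.json").write_text(
        json.dumps(truth, sort_keys=True, indent=1) + "\n")
    _sidecar(outdir / "truth.json", "simulate", config, len(truth))


def _load_tables(config: RunConfig, outdir: Path, needed_by: str) -> dict:
    tables = {}
    for comparison in config.simulation.comparisons:
        path = _require(outdir / f"expression_{comparison}.tsv", "simulate",
                        needed_by)
        tables[comparison] = read_comparison_table(path, dialect="generic")
    return tables


def stage_ora(config: RunConfig, outdir: Path) -> None:
    tables = _load_tables(config, outdir, "ora")
    pathways = read_gmt(_require(outdir / "pathways.gmt", "simulate", "ora"))
    all_results = []
    de_rows = []
    for comparison, table in tables.items():
        results = ora.ora_chisq(table, pathways, q_threshold=config.q_ora,
                                variant=config.chi2_variant)
        results = ora.bonferroni_adjust(results, pathways, alpha=config.alpha)
        all_results.extend(results)
        de_rows.append({"comparison": comparison,
                        "n_de": ora.count_de(table, config.q_de),
                        "q_threshold": config.q_de})
    frame = ora.ora_results_frame(all_results)
    _write_table(frame, outdir / "ora_results.tsv", "ora", config)
    _write_table(pd.DataFrame(de_rows), outdir / "de_counts.tsv", "ora",
                 config)
    membership = ora.component_frequency(pathways, pathways.signalling_ids,
                                         min_maps=config.min_maps)
    out = membership.matrix.astype(int).copy()
    out.insert(0, "n_maps", membership.counts)
    _write_table(out, outdir / "component_frequency.tsv", "ora", config,
                 index=True)


def stage_network(config: RunConfig, outdir: Path) -> None:
    tables = _load_tables(config, outdir, "network")
    graph = read_sif(_require(outdir / "network.sif", "simulate", "network"))
    subs = {}
    for comparison in config.network_comparisons:
        if comparison not in tables:
            raise InputError(f"network comparison {comparison!r} has no "
                             "expression table")
        pvals = tables[comparison].pvalues()
        fit = network.fit_bum(list(pvals.values()))
        scores = network.score_nodes(fit, config.fdr_network,
                                     {g: p for g, p in pvals.items()
                                      if g in graph})
        sub = network.find_max_subnetwork(graph, scores)
        subs[comparison] = sub
        write_sif(graph.subgraph(sub.nodes),
                  outdir / f"subnetwork_{comparison}.sif")
        _sidecar(outdir / f"subnetwork_{comparison}.sif", "network", config,
                 len(sub.nodes))
    (a, b) = config.network_comparisons[:2]
    merged = network.merge_networks(subs[a], subs[b], graph,
                                    label_a=a, label_b=b)
    write_sif(merged.graph, outdir / "merged_network.sif")
    _sidecar(outdir / "merged_network.sif", "network", config,
             merged.graph.number_of_edges())
    rows = [{"gene": v, "origin": merged.origin[v],
             "degree": merged.degree[v]} for v in sorted(merged.nodes)]
    _write_table(pd.DataFrame(rows), outdir / "merged_nodes.tsv", "network",
                 config)


def _load_merged(config: RunConfig, outdir: Path,
                 needed_by: str) -> network.MergedNetwork:
    graph = read_sif(_require(outdir / "merged_network.sif", "network",
                              needed_by))
    nodes = pd.read_csv(_require(outdir / "merged_nodes.tsv", "network",
                                 needed_by), sep="\t")
    for v in nodes["gene"]:
        graph.add_node(v)
    origin = dict(zip(nodes["gene"], nodes["origin"]))
    degree = {v: int(graph.degree(v)) for v in graph.nodes}
    return network.MergedNetwork(graph=graph, origin=origin, degree=degree)


def stage_rank(config: RunConfig, outdir: Path) -> None:
    merged = _load_merged(config, outdir, "rank")
    targets = read_drug_targets(_require(outdir / "drug_targets.tsv",
                                         "simulate", "rank"))
    flags = druggability.flag_druggable(merged, targets)
    ranking = druggability.rank_druggable(merged, flags,
                                          top_n=config.top_n_druggable)
    _write_table(ranking, outdir / "druggable_ranking.tsv", "rank", config)


def stage_screen(config: RunConfig, outdir: Path) -> None:
    rows = []
    summaries = []
    for compound, condition, cell_line in config.screen_plates:
        tag = _plate_tag(compound, condition, cell_line)
        cells = pd.read_csv(_require(outdir / f"plate_{tag}_cells.csv",
                                     "simulate", "screen"))
        wells = pd.read_csv(_require(outdir / f"plate_{tag}_wells.csv",
                                     "simulate", "screen"))
        out = screen.quantify_plate(cells, wells)
        (outdir / f"classifier_{tag}.json").write_text(
            out["classifier"].to_json() + "\n")
        _sidecar(outdir / f"classifier_{tag}.json", "screen", config, 1)
        summ = out["summaries"].copy()
        summ.insert(0, "plate", tag)
        summaries.append(summ)
        for readout, fit in out["results"].items():
            rows.append({
                "compound": compound, "condition": condition,
                "cell_line": cell_line, "readout": readout,
                "bottom": fit.bottom, "top": fit.top, "hill": fit.hill,
                "midpoint_uM": fit.midpoint, "ic50_uM": str(fit.ic50),
                "converged": fit.converged, "residual_norm":
                fit.residual_norm, "note": fit.note})
    _write_table(pd.concat(summaries, ignore_index=True),
                 outdir / "well_summaries.tsv", "screen", config)
    _write_table(pd.DataFrame(rows), outdir / "screen_results.tsv", "screen",
                 config)


def stage_synergy(config: RunConfig, outdir: Path) -> None:
    single = pd.read_csv(_require(outdir / "combination_single_agent.csv",
                                  "simulate", "synergy"))
    combo = pd.read_csv(_require(outdir / "combination_grid.csv", "simulate",
                                 "synergy"))
    drug_a, drug_b = config.combo_drugs
    fits = {}
    fit_rows = []
    for drug in (drug_a, drug_b):
        series = single[single["drug"] == drug]
        if series.empty:
            raise InputError(f"no single-agent series for {drug!r}")
        fits[drug] = synergy.fit_median_effect(series["dose_uM"],
                                               series["fa"])
        fit_rows.append({"drug": drug, "m": fits[drug].m,
                         "dm_uM": fits[drug].dm, "r2": fits[drug].r2,
                         "n_points_used": fits[drug].n_points_used,
                         "n_excluded": fits[drug].n_excluded})
    table = synergy.analyze_combination(combo, fits[drug_a], fits[drug_b],
                                        thresholds=config.ci_thresholds)
    _write_table(pd.DataFrame(fit_rows), outdir / "median_effect_fits.tsv",
                 "synergy", config)
    _write_table(table, outdir / "synergy_ci.tsv", "synergy", config)


def build_heatmap_matrix(tables, gene_list, q_threshold: float = 0.05):
    """Genes x comparisons matrices: log2fc, significance (q < threshold)
    and a detected mask; row order follows ``gene_list`` exactly, genes
    absent from a comparison are masked (NaN / False)."""
    if isinstance(tables, dict):
        tables = list(tables.values())
    comparisons = [t.comparison for t in tables]
    log2fc = pd.DataFrame(np.nan, index=pd.Index(gene_list, name="gene"),
                          columns=comparisons)
    sig = pd.DataFrame(False, index=log2fc.index, columns=comparisons)
    detected = pd.DataFrame(False, index=log2fc.index, columns=comparisons)
    for table in tables:
        df = table.data.set_index("gene")
        present = [g for g in gene_list if g in df.index]
        sub = df.loc[present]
        det = sub["detected"].astype(bool)
        detected.loc[present, table.comparison] = det
        log2fc.loc[present, table.comparison] = sub["log2fc"].where(det)
        sig.loc[present, table.comparison] = \
            (sub["q"] < q_threshold).fillna(False) & det
    return log2fc, sig, detected


def stage_report(config: RunConfig, outdir: Path) -> None:
    tables = _load_tables(config, outdir, "report")
    # default gene panel: strongest consistent movers (smallest min q)
    min_q = None
    for table in tables.values():
        q = table.data.set_index("gene")["q"]
        min_q = q if min_q is None else np.minimum(min_q, q)
    panel = sorted(min_q.nsmallest(config.heatmap_n_genes).index)
    log2fc, sig, detected = build_heatmap_matrix(tables, panel,
                                                 q_threshold=config.q_de)
    _write_table(log2fc, outdir / "heatmap_log2fc.tsv", "report", config,
                 index=True)
    _write_table(sig.astype(int), outdir / "heatmap_significant.tsv",
                 "report", config, index=True)
    _write_table(detected.astype(int), outdir / "heatmap_detected.tsv",
                 "report", config, index=True)
    artifacts = sorted(p.name for p in outdir.iterdir()
                       if p.is_file() and not p.name.endswith(".meta.json"))
    (outdir / "report_index.json").write_text(
        json.dumps({"artifacts": artifacts}, indent=1, sort_keys=True) + "\n")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "ora": stage_ora,
    "network": stage_network,
    "rank": stage_rank,
    "screen": stage_screen,
    "synergy": stage_synergy,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages=None) -> Path:
    """Run the requested stages in dependency order; returns the outdir."""
    stages = set(STAGES if stages is None else stages)
    unknown = stages - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_resolved.json").write_text(
        json.dumps(dataclasses.asdict(config), sort_keys=True, indent=1,
                   default=lambda o: sorted(o) if isinstance(o, (set, frozenset))
                   else str(o)) + "\n")
    for stage in STAGES:
        if stage in stages:
            logger.info("running stage %s", stage)
            _STAGE_FUNCS[stage](config, outdir)
    return outdir
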