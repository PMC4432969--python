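"""Synthetic-data generators for every pipeline input, with recorded truth.

The study the pipeline emulates has no deposited data, so each stage is fed
from a generator with known ground truth:

* differential-expression tables whose p-values follow a beta-uniform
  mixture (uniform nulls, Beta(a, 1) signal) with planted pathway-level
  enrichment;
* a connected scale-free protein-interaction network with a planted,
  predominantly-signal connected module;
* a drug-target table partially overlapping the network;
* 384-well high-content screen plates (16 positive + 16 negative control
  wells, an 11-point 1:2 dose series from 10 uM) with per-cell vimentin and
  pERK intensities from two-component log-normal mixtures and
  negative-binomial cell counts, both driven by 4PL curves of dose;
* drug-combination responses generated from the median-effect equation with
  a planted combination index.

Cell-line calibration follows the two breast-cancer models: ~10% of
unstimulated PMC42-LA cells and ~5% of unstimulated MDA-MB-468 cells are
vimentin-positive, rising to a common stimulated fraction under EGF or
hypoxia.  All generators draw from per-generator random streams split from
one master seed, so identical (seed, config) gives byte-identical outputs
and adding a generator does not perturb the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import (ComparisonTable, ConfigError, DEFAULT_COMPARISONS, InputError,
                 Pathway, PathwayCollection, adjust_bh)
from .screen import logistic4

__all__ = [
    "SimulationConfig",
    "ExpressionSim",
    "PPISim",
    "PlateSim",
    "CombinationSim",
    "simulate_bum_pvalues",
    "simulate_pathways",
    "simulate_expression",
    "simulate_ppi",
    "ba_edge_count",
    "simulate_drug_targets",
    "simulate_screen_plate",
    "simulate_combination",
]

# stream indices: a fixed namespace per generator under the master seed
_STREAMS = {"pathways": 0, "expression": 1, "ppi": 2, "drugs": 3,
            "plate": 4, "combo": 5}


def _rng(config: "SimulationConfig", stream: str, *extra: str) -> np.random.Generator:
    tag = zlib.crc32("|".join(extra).encode()) if extra else 0
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(config.seed, _STREAMS[stream], tag)))


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters; defaults encode the emulated study design."""

    seed: int = 0
    # --- expression / pathways ---
    n_genes: int = 4000
    comparisons: tuple = DEFAULT_COMPARISONS
    de_fraction: float = 0.10          # signal fraction = 1 - bum_lambda
    bum_a: float = 0.2                 # Beta(a,1) shape of the signal component
    n_pathways: int = 30
    n_signalling_pathways: int = 22    # the Bonferroni family size
    pathway_size_range: tuple = (40, 200)
    enriched_pathways: tuple = (("PW001", 4.0),)  # (pathway id, odds multiplier)
    de_log2fc_mean: float = 2.0
    de_log2fc_sd: float = 0.5
    null_log2fc_sd: float = 0.1
    undetected_fraction: float = 0.02
    # --- PPI network ---
    network_size: int = 400
    attachment_parameter: int = 2      # edges per new node (preferential attachment)
    planted_module_size: int = 15
    module_comparison: str = "468_EGF"  # whose signal genes seed the module
    module_signal_fraction: float = 0.9
    # --- drug targets ---
    n_drugs: int = 30
    max_targets_per_drug: int = 3
    drug_on_network_fraction: float = 0.7
    # --- screen plates ---
    plate_layout: tuple = (16, 24)
    n_pos_controls: int = 16
    n_neg_controls: int = 16
    n_doses: int = 11
    top_dose: float = 10.0             # uM
    dilution_factor: float = 2.0
    replicates_per_dose: int = 4
    mean_cells_per_well: float = 220.0
    count_dispersion: float = 50.0     # negative-binomial size (CV ~16% at 150 cells)
    count_inhibition_floor: float = 0.25  # bottom of the count 4PL, x top
    baseline_vim_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"PMC42-LA": 0.10, "PMC42-ET": 0.60,
                                 "MDA-MB-468": 0.05})
    stim_vim_fraction: float = 0.60
    truth_ic50: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "KIN-1": {"pct_vim_pos": 0.5, "cell_count": 2.0},
            "KIN-2": {"pct_vim_pos": 1.5, "cell_count": 4.0},
        })
    hill: float = 1.5
    # per-cell intensity model (log scale)
    vim_log_mu_neg: float = math.log(50.0)
    vim_log_mu_pos: float = math.log(1000.0)
    vim_log_sigma: float = 0.45
    area_log_mu: float = math.log(300.0)
    area_log_sigma: float = 0.30
    perk_log_mu_stim: float = math.log(400.0)
    perk_log_mu_inhib: float = math.log(80.0)
    perk_log_sigma: float = 0.40
    # --- combinations ---
    median_effect_truth: Mapping[str, tuple] = field(
        default_factory=lambda: {"KIN-1": (1.5, 0.5), "KIN-2": (2.0, 1.0)})
    combo_interaction: str = "additive"
    combo_ci_targets: Mapping[str, float] = field(
        default_factory=lambda: {"synergistic": 0.5, "additive": 1.0,
                                 "antagonistic": 1.5})
    combo_noise_sd: float = 0.005  # replicate-averaged fa precision
    combo_n_ratio_points: int = 7

    def __post_init__(self):
        def check(cond, msg):
            if not cond:
                raise ConfigError(msg)
        check(self.n_genes >= 1 and self.network_size >= 1, "counts must be >= 1")
        for name in ("de_fraction", "undetected_fraction",
                     "module_signal_fraction", "drug_on_network_fraction",
                     "stim_vim_fraction", "count_inhibition_floor"):
            v = getattr(self, name)
            check(0.0 <= v <= 1.0, f"{name} must lie in [0, 1]")
        for cl, v in self.baseline_vim_fraction.items():
            check(0.0 <= v <= 1.0, f"baseline_vim_fraction[{cl}] not in [0, 1]")
        check(0.0 < self.bum_a < 1.0, "bum_a must lie strictly in (0, 1)")
        # de_fraction = 0 (pure null, bum_lambda = 1) is allowed for
        # calibration runs; de_fraction = 1 would leave no uniform component
        check(self.de_fraction < 1.0, "de_fraction must be < 1")
        check(self.dilution_factor > 1.0, "dilution_factor must exceed 1")
        check(self.n_doses >= 2, "n_doses must be >= 2")
        check(self.top_dose > 0.0, "top_dose must be positive")
        check(1 <= self.planted_module_size <= self.network_size,
              "need network_size >= planted_module_size >= 1")
        check(1 <= self.attachment_parameter < self.network_size,
              "attachment_parameter must be in [1, network_size)")
        check(self.n_signalling_pathways <= self.n_pathways,
              "n_signalling_pathways cannot exceed n_pathways")
        check(self.combo_interaction in self.combo_ci_targets,
              f"unknown combo_interaction {self.combo_interaction!r}")
        ids = {f"PW{i + 1:03d}" for i in range(self.n_pathways)}
        for pid, mult in self.enriched_pathways:
            check(pid in ids, f"enriched pathway {pid!r} does not exist")
            check(mult > 0, "enrichment odds multiplier must be positive")

    @property
    def bum_lambda(self) -> float:
        """Uniform-component weight implied by the signal fraction."""
        return 1.0 - self.de_fraction

    @property
    def doses(self) -> np.ndarray:
        """The serial-dilution dose series, highest first (uM)."""
        return self.top_dose / self.dilution_factor ** np.arange(self.n_doses)

    def gene_symbols(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]

    def pathway_ids(self) -> list[str]:
        return [f"PW{i + 1:03d}" for i in range(self.n_pathways)]


# ---------------------------------------------------------------------------
# Expression and pathways
# ---------------------------------------------------------------------------

def simulate_bum_pvalues(n: int, lam: float, a: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw n p-values from the mixture f(p) = lam + (1-lam)*a*p^(a-1)."""
    signal = rng.random(n) >= lam
    p = rng.random(n)
    p[signal] = rng.beta(a, 1.0, size=int(signal.sum()))
    return p


def simulate_pathways(config: SimulationConfig) -> PathwayCollection:
    """Random gene sets; the first ``n_signalling_pathways`` are flagged
    as the signalling family."""
    rng = _rng(config, "pathways")
    genes = np.array(config.gene_symbols())
    lo, hi = config.pathway_size_range
    hi = min(hi, config.n_genes)
    lo = min(lo, hi)
    pathways = {}
    for i, pid in enumerate(config.pathway_ids()):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        pathways[pid] = Pathway(
            pathway_id=pid, name=f"synthetic pathway {i + 1}",
            genes=frozenset(members),
            is_signalling=i < config.n_signalling_pathways)
    return PathwayCollection(pathways)


@dataclass
class ExpressionSim:
    """Simulated DE tables plus the generating truth."""

    tables: dict                      # comparison -> ComparisonTable
    pathways: PathwayCollection
    signal_genes: dict                # comparison -> frozenset of signal genes

    def table(self, comparison: str) -> ComparisonTable:
        return self.tables[comparison]


def simulate_expression(config: SimulationConfig,
                        pathways: PathwayCollection | None = None
                        ) -> ExpressionSim:
    """Per-comparison DE tables with BUM-mixture p-values.

    Signal genes are drawn per gene with base odds de_fraction/(1-de_fraction),
    multiplied by the configured odds multiplier inside enriched pathways;
    signal p-values come from Beta(a, 1), nulls from Uniform(0, 1).
    Q-values are Benjamini-Hochberg over the detected genes of each table.
    """
    if pathways is None:
        pathways = simulate_pathways(config)
    rng = _rng(config, "expression")
    genes = config.gene_symbols()
    mult = np.ones(config.n_genes)
    index = {g: i for i, g in enumerate(genes)}
    for pid, m in config.enriched_pathways:
        if pid not in pathways:
            raise ConfigError(f"enriched pathway {pid!r} not in collection")
        for g in pathways[pid].genes:
            if g in index:
                mult[index[g]] = max(mult[index[g]], m)

    d = config.de_fraction
    if d <= 0.0:
        p_signal = np.zeros(config.n_genes)
    elif d >= 1.0:
        p_signal = np.ones(config.n_genes)
    else:
        odds = d / (1.0 - d) * mult
        p_signal = odds / (1.0 + odds)

    tables, signal_sets = {}, {}
    for comparison in config.comparisons:
        signal = rng.random(config.n_genes) < p_signal
        p = rng.random(config.n_genes)
        n_sig = int(signal.sum())
        if n_sig:
            p[signal] = rng.beta(config.bum_a, 1.0, size=n_sig)
        sign = rng.choice([-1.0, 1.0], size=config.n_genes)
        log2fc = rng.normal(0.0, config.null_log2fc_sd, size=config.n_genes)
        if n_sig:
            log2fc[signal] = (sign[signal] *
                              rng.normal(config.de_log2fc_mean,
                                         config.de_log2fc_sd, size=n_sig))
        detected = rng.random(config.n_genes) >= config.undetected_fraction
        q = np.full(config.n_genes, np.nan)
        q[detected] = adjust_bh(p[detected])
        df = pd.DataFrame({
            "gene": genes,
            "log2fc": np.where(detected, log2fc, np.nan),
            "p": np.where(detected, p, np.nan),
            "q": q,
            "detected": detected,
        })
        tables[comparison] = ComparisonTable(comparison=comparison, data=df)
        signal_sets[comparison] = frozenset(np.array(genes)[signal & detected])
    return ExpressionSim(tables=tables, pathways=pathways,
                         signal_genes=signal_sets)


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

def ba_edge_count(n: int, m: int) -> int:
    """Closed-form edge count of the preferential-attachment scheme used
    (an m-edge star seed, then m edges per new node): m*(n-m)."""
    return m * (n - m)


@dataclass
class PPISim:
    graph: nx.Graph
    planted_module: frozenset

    @property
    def nodes(self):
        return self.graph.nodes


def simulate_ppi(config: SimulationConfig,
                 expression: ExpressionSim) -> PPISim:
    """Connected scale-free PPI over gene symbols with a planted module.

    Topology is Barabasi-Albert preferential attachment.  A connected set of
    ``planted_module_size`` nodes grown from the seed hub is labelled with
    (predominantly) signal genes of ``module_comparison`` — the most
    strongly dysregulated ones (smallest p-values), emulating a coherent
    perturbed core — so the module is recoverable by p-value-driven
    subnetwork search.
    """
    rng = _rng(config, "ppi")
    n, m = config.network_size, config.attachment_parameter
    if n > config.n_genes:
        raise ConfigError("network_size cannot exceed n_genes")
    graph = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2 ** 31)))
    if config.module_comparison not in expression.signal_genes:
        raise ConfigError(
            f"module_comparison {config.module_comparison!r} not simulated")

    # connected module: BFS from node 0 (part of the dense seed)
    module_nodes = []
    for node in nx.bfs_tree(graph, 0):
        module_nodes.append(node)
        if len(module_nodes) >= config.planted_module_size:
            break

    signal = expression.signal_genes[config.module_comparison]
    pvals = expression.tables[config.module_comparison].pvalues()
    # strongest signal genes first; ties broken by symbol for determinism
    ranked = sorted(signal, key=lambda g: (pvals.get(g, 1.0), g))
    n_sig_in_module = int(round(config.module_signal_fraction
                                * len(module_nodes)))
    n_sig_in_module = min(n_sig_in_module, len(ranked))
    module_signal = [str(g) for g in ranked[:n_sig_in_module]]
    other_genes = sorted(set(config.gene_symbols()) - set(module_signal))
    n_fill = n - n_sig_in_module
    if n_fill > len(other_genes):
        raise ConfigError("not enough genes to label the network")
    fill = [str(g) for g in rng.choice(other_genes, size=n_fill,
                                       replace=False)]
    labels = {}
    fill_iter = iter(fill)
    sig_iter = iter(module_signal)
    module_set = set(module_nodes)
    for node in range(n):
        if node in module_set and n_sig_in_module > 0:
            try:
                labels[node] = next(sig_iter)
                continue
            except StopIteration:
                pass
        labels[node] = next(fill_iter)
    relabelled = nx.relabel_nodes(graph, labels)
    nx.set_edge_attributes(relabelled, "pp", "relation")
    return PPISim(graph=relabelled,
                  planted_module=frozenset(labels[v] for v in module_nodes))


# ---------------------------------------------------------------------------
# Drug targets
# ---------------------------------------------------------------------------

_MECHANISMS = ("inhibitor", "antagonist", "agonist", "")


def simulate_drug_targets(config: SimulationConfig,
                          network: nx.Graph) -> pd.DataFrame:
    """Synthetic drug-target TSV rows: a configured fraction of targets are
    network nodes (sampled without global replacement while they last),
    the remainder off-network symbols."""
    if network.number_of_nodes() == 0:
        raise InputError("network is empty")
    rng = _rng(config, "drugs")
    pool = sorted(network.nodes)
    rng.shuffle(pool)
    pool_iter = iter(pool)
    rows = []
    off_counter = 0
    for i in range(config.n_drugs):
        drug_id = f"DRUG-{i + 1:03d}"
        n_targets = int(rng.integers(1, config.max_targets_per_drug + 1))
        seen = set()
        for _ in range(n_targets):
            on_network = rng.random() < config.drug_on_network_fraction
            target = None
            if on_network:
                target = next(pool_iter, None)
            if target is None:
                off_counter += 1
                target = f"OFFNET{off_counter:04d}"
            if target in seen:
                continue
            seen.add(target)
            rows.append({
                "drug_id": drug_id,
                "drug_name": f"compound {i + 1}",
                "target_gene": target,
                "mechanism": _MECHANISMS[int(rng.integers(len(_MECHANISMS)))],
            })
    return pd.DataFrame(rows, columns=["drug_id", "drug_name", "target_gene",
                                       "mechanism"])


# ---------------------------------------------------------------------------
# Screen plates
# ---------------------------------------------------------------------------

@dataclass
class PlateSim:
    """One simulated 384-well plate: per-cell table, well metadata, truth."""

    cells: pd.DataFrame
    wells: pd.DataFrame
    truth: dict                       # curve parameters and per-cell labels

    @property
    def plate_id(self) -> str:
        return self.wells["plate_id"].iloc[0]


def _well_name(row: int, col: int) -> str:
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def _plate_wells(config: SimulationConfig, compound: str,
                 stimulus: str, plate_id: str) -> pd.DataFrame:
    """Assign roles to the 16x24 grid: positive then negative controls fill
    the first columns, dose wells (column-major, replicates over rows) come
    next, the remainder is empty."""
    n_rows, n_cols = config.plate_layout
    total = n_rows * n_cols
    n_dose_wells = config.n_doses * config.replicates_per_dose
    if config.n_pos_controls + config.n_neg_controls + n_dose_wells > total:
        raise ConfigError("plate layout cannot hold controls plus dose wells")
    doses = config.doses
    records = []
    k = 0
    for col in range(n_cols):
        for row in range(n_rows):
            if k < config.n_pos_controls:
                role, dose, cmpd = "pos_ctrl", 1.0, "REFERENCE-INHIBITOR"
                if stimulus == "HPX":
                    # stimulus-free growth is the full-reversion reference
                    role, dose, cmpd = "pos_ctrl", 0.0, "NORMOXIC-VEHICLE"
            elif k < config.n_pos_controls + config.n_neg_controls:
                role, dose, cmpd = "neg_ctrl", 0.0, "VEHICLE"
            elif k < config.n_pos_controls + config.n_neg_controls + n_dose_wells:
                j = (k - config.n_pos_controls - config.n_neg_controls) \
                    // config.replicates_per_dose
                role, dose, cmpd = "dose", float(doses[j]), compound
            else:
                role, dose, cmpd = "empty", 0.0, ""
            records.append({"plate_id": plate_id,
                            "well": _well_name(row, col), "row": row,
                            "col": col, "role": role, "compound": cmpd,
                            "dose_uM": dose, "stimulus": stimulus})
            k += 1
    return pd.DataFrame.from_records(records)


def simulate_screen_plate(config: SimulationConfig, compound: str,
                          condition: str, cell_line: str = "MDA-MB-468"
                          ) -> PlateSim:
    """Simulate one plate for ``compound`` under stimulus ``condition``.

    ``condition`` is one of ``"EGF"``, ``"HPX"`` or ``"unstimulated"``.  On
    stimulated plates the vimentin-positive mixing weight of dose wells
    follows a 4PL of dose from ``stim_vim_fraction`` down to the cell line's
    baseline fraction (midpoint = the compound's planted %vim+ IC50), and
    the negative-binomial cell-count mean follows its own 4PL (midpoint =
    the count IC50).  Positive controls sit at the full-effect plateau of
    both readouts, negative controls at the no-effect plateau.  On
    unstimulated plates every well is at the baseline vimentin fraction.
    """
    if compound not in config.truth_ic50:
        raise InputError(f"no planted IC50s for compound {compound!r}")
    if condition not in ("EGF", "HPX", "unstimulated"):
        raise InputError(f"unknown condition {condition!r}")
    if cell_line not in config.baseline_vim_fraction:
        raise InputError(f"no baseline vimentin fraction for {cell_line!r}")
    rng = _rng(config, "plate", compound, condition, cell_line)
    plate_id = f"{cell_line}_{condition}_{compound}"
    wells = _plate_wells(config, compound, condition, plate_id)

    base_f = config.baseline_vim_fraction[cell_line]
    stim_f = config.stim_vim_fraction
    ic50_vim = config.truth_ic50[compound]["pct_vim_pos"]
    ic50_cnt = config.truth_ic50[compound]["cell_count"]
    top_cells = config.mean_cells_per_well
    floor_cells = config.count_inhibition_floor * top_cells
    stimulated = condition != "unstimulated"

    def well_truth(role: str, dose: float):
        """(vim+ mixing weight, expected cell count) for one well."""
        if not stimulated:
            vim = base_f
        elif role == "neg_ctrl":
            vim = stim_f
        elif role == "pos_ctrl":
            vim = base_f
        else:  # dose well: inhibition rises with dose
            inhib = logistic4(dose, 0.0, 1.0, config.hill, ic50_vim)
            vim = stim_f + (base_f - stim_f) * float(inhib)
        if role == "neg_ctrl":
            count = top_cells
        elif role == "pos_ctrl":
            count = floor_cells
        else:
            inhib = logistic4(dose, 0.0, 1.0, config.hill, ic50_cnt)
            count = top_cells + (floor_cells - top_cells) * float(inhib)
        return vim, count

    def perk_mu(role: str, dose: float) -> float:
        if not stimulated or role == "pos_ctrl":
            return config.perk_log_mu_inhib
        if role == "neg_ctrl":
            return config.perk_log_mu_stim
        inhib = logistic4(dose, 0.0, 1.0, config.hill, ic50_vim)
        return (config.perk_log_mu_stim
                + (config.perk_log_mu_inhib - config.perk_log_mu_stim)
                * float(inhib))

    cell_rows = []
    labels = []
    disp = config.count_dispersion
    for rec in wells.itertuples(index=False):
        if rec.role == "empty":
            continue
        vim_f, mean_count = well_truth(rec.role, rec.dose_uM)
        n_cells = int(rng.negative_binomial(disp, disp / (disp + mean_count)))
        if n_cells == 0:
            continue
        is_pos = rng.random(n_cells) < vim_f
        mu = np.where(is_pos, config.vim_log_mu_pos, config.vim_log_mu_neg)
        vim_mean = np.exp(rng.normal(mu, config.vim_log_sigma))
        area = np.exp(rng.normal(config.area_log_mu, config.area_log_sigma,
                                 size=n_cells))
        perk = np.exp(rng.normal(perk_mu(rec.role, rec.dose_uM),
                                 config.perk_log_sigma, size=n_cells))
        for i in range(n_cells):
            cell_rows.append((rec.plate_id, rec.well, rec.row, rec.col,
                              rec.role, rec.compound, rec.dose_uM,
                              rec.stimulus, f"{rec.well}-{i + 1:04d}",
                              vim_mean[i], vim_mean[i] * area[i], perk[i]))
        labels.extend(bool(v) for v in is_pos)
    cells = pd.DataFrame(cell_rows, columns=[
        "plate_id", "well", "row", "col", "role", "compound", "dose_uM",
        "stimulus", "cell_id", "vim_mean", "vim_total", "perk_mean"])
    truth = {
        "cell_line": cell_line,
        "condition": condition,
        "compound": compound,
        "baseline_vim_fraction": base_f,
        "stim_vim_fraction": stim_f,
        "ic50": dict(config.truth_ic50[compound]),
        "hill": config.hill,
        "cell_vim_labels": labels,
        "bayes_log_threshold": 0.5 * (config.vim_log_mu_neg
                                      + config.vim_log_mu_pos),
    }
    return PlateSim(cells=cells, wells=wells, truth=truth)


# ---------------------------------------------------------------------------
# Drug combinations
# ---------------------------------------------------------------------------

@dataclass
class CombinationSim:
    """Single-agent series plus a combination dose grid with planted CI."""

    single_agent: pd.DataFrame        # drug, dose_uM, fa
    combination: pd.DataFrame         # drug_a, dose_a_uM, drug_b, dose_b_uM, fa
    truth: dict


def _median_effect_fa(dose: float, m: float, dm: float) -> float:
    return 1.0 / (1.0 + (dm / dose) ** m)


def _combo_fa(da: float, db: float, ma: float, dma: float, mb: float,
              dmb: float, ci: float) -> float:
    """Affected fraction at (da, db) such that the CI-scaled Loewe sum holds:
    da/DxA(fa) + db/DxB(fa) = ci, with Dx_i = Dm_i (fa/fu)^(1/m_i)."""

    def g(log_r):
        r = math.exp(log_r)
        return (da / (dma * r ** (1.0 / ma))
                + db / (dmb * r ** (1.0 / mb)) - ci)

    lo, hi = -60.0, 60.0
    if g(lo) < 0:      # even fa ~ 0 undershoots: essentially unaffected
        return 1e-12
    if g(hi) > 0:      # fa ~ 1
        return 1.0 - 1e-12
    r = math.exp(brentq(g, lo, hi, xtol=1e-13))
    return r / (1.0 + r)


def simulate_combination(config: SimulationConfig, drug_a: str, drug_b: str
                         ) -> CombinationSim:
    """Generate single-agent and constant-ratio combination responses.

    Single-agent affected fractions follow the median-effect equation
    fa/fu = (D/Dm)^m exactly (plus optional Gaussian noise on fa).  The
    combination grid runs both drugs at their Dm ratio over a geometric
    scale; the affected fraction at each point is constructed so the
    downstream combination index recovers the planted target CI.
    """
    for drug in (drug_a, drug_b):
        if drug not in config.median_effect_truth:
            raise InputError(f"no median-effect truth for drug {drug!r}")
    ma, dma = config.median_effect_truth[drug_a]
    mb, dmb = config.median_effect_truth[drug_b]
    ci = config.combo_ci_targets[config.combo_interaction]
    rng = _rng(config, "combo", drug_a, drug_b)

    def noisy(fa: float) -> float:
        if config.combo_noise_sd > 0:
            fa = fa + rng.normal(0.0, config.combo_noise_sd)
        return float(np.clip(fa, 1e-6, 1.0 - 1e-6))

    single_rows = []
    for drug, (m, dm) in ((drug_a, (ma, dma)), (drug_b, (mb, dmb))):
        for dose in config.doses:
            single_rows.append({"drug": drug, "dose_uM": float(dose),
                                "fa": noisy(_median_effect_fa(dose, m, dm))})
    # span roughly ED20-ED80 around the median-effect doses: outside that
    # window small fa noise dominates the combination index
    scales = np.geomspace(0.25, 4.0, config.combo_n_ratio_points)
    combo_rows = []
    for s in scales:
        da, db = float(dma * s), float(dmb * s)
        fa = _combo_fa(da, db, ma, dma, mb, dmb, ci)
        combo_rows.append({"drug_a": drug_a, "dose_a_uM": da,
                           "drug_b": drug_b, "dose_b_uM": db,
                           "fa": noisy(fa)})
    return CombinationSim(
        single_agent=pd.DataFrame(single_rows),
        combination=pd.DataFrame(combo_rows),
        truth={"m": {drug_a: ma, drug_b: mb},
               "dm_uM": {drug_a: dma, drug_b: dmb},
               "target_ci": ci, "interaction": config.combo_interaction})
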