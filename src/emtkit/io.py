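"""Data model and I/O for differential-expression tables, gene sets, networks
and drug-target tables, plus multiple-testing utilities.

Gene identity throughout the package is the bare HGNC-style symbol,
uppercased on ingest.  Undetected transcripts (e.g. CuffDiff rows whose test
status is not ``OK``) are retained with ``detected=False`` and excluded from
every p-value-based computation downstream; they are never silently dropped.
Duplicate gene symbols within one comparison are an error: tables must be
pre-collapsed to one row per gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EmtkitError",
    "ConfigError",
    "ParseError",
    "InputError",
    "NumericalError",
    "ComparisonTable",
    "Pathway",
    "PathwayCollection",
    "DEFAULT_COMPARISONS",
    "COMPARISON_COLUMNS",
    "DRUG_TARGET_COLUMNS",
    "adjust_bh",
    "read_comparison_table",
    "write_comparison_table",
    "read_gmt",
    "write_gmt",
    "read_sif",
    "write_sif",
    "read_drug_targets",
    "write_drug_targets",
    "validate_drug_targets",
    "normalize_gene",
]


class EmtkitError(Exception):
    """Base class for all package errors."""


class ConfigError(EmtkitError):
    """Invalid configuration (CLI exit code 2)."""


class InputError(EmtkitError):
    """Missing or inconsistent input data (CLI exit code 3)."""


class ParseError(InputError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path or '<input>'}" + (f":{line}" if line is not None else "")
        super().__init__(f"{loc}: {message}")
        self.path = path
        self.line = line


class NumericalError(EmtkitError):
    """Numerical failure, e.g. a degenerate fit (CLI exit code 4)."""


def normalize_gene(symbol: str) -> str:
    """Uppercase and strip a gene symbol; matching is exact afterwards."""
    return str(symbol).strip().upper()


#: The seven condition comparisons of the two-cell-line EMT study design:
#: per-model stimulated-vs-unstimulated contrasts plus three inter-model ones.
DEFAULT_COMPARISONS = (
    "ET_EGF",        # PMC42-ET +/- EGF
    "LA_EGF",        # PMC42-LA +/- EGF
    "468_EGF",       # MDA-MB-468 +/- EGF
    "468_HPX",       # MDA-MB-468 +/- hypoxia
    "ET_vs_LA",      # inter-model, unstimulated
    "ET_vs_LA_EGF",  # inter-model, +EGF
    "468_HPX_vs_EGF",
)

COMPARISON_COLUMNS = ("gene", "log2fc", "p", "q", "detected")


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Parameters
    ----------
    pvalues : array-like of float in [0, 1]

    Returns
    -------
    ndarray of q-values, same order as the input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

@dataclass
class ComparisonTable:
    """Per-gene differential-expression statistics for one condition comparison.

    ``data`` holds one row per gene with columns ``gene`` (uppercased symbol),
    ``log2fc``, ``p``, ``q`` and ``detected``.  Undetected rows may carry NaN
    statistics; detected rows must have p and q in [0, 1].
    """

    comparison: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.data.reset_index(drop=True).copy()
        missing = [c for c in COMPARISON_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"comparison table missing columns: {missing}")
        df = df[list(COMPARISON_COLUMNS)]
        df["gene"] = df["gene"].map(normalize_gene)
        df["detected"] = df["detected"].astype(bool)
        for col in ("log2fc", "p", "q"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        dup = df["gene"].duplicated()
        if dup.any():
            raise InputError(
                f"duplicate gene symbols in comparison {self.comparison!r}: "
                f"{sorted(df.loc[dup, 'gene'].unique())[:5]}"
            )
        det = df.loc[df["detected"]]
        for col in ("p", "q"):
            vals = det[col].to_numpy()
            if np.any(~np.isfinite(vals)) or np.any(vals < 0) or np.any(vals > 1):
                raise InputError(
                    f"{col}-values of detected genes must lie in [0, 1] "
                    f"(comparison {self.comparison!r})"
                )
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def detected(self) -> pd.DataFrame:
        """Rows with a usable measurement (the analysis universe)."""
        return self.data.loc[self.data["detected"]]

    def pvalues(self) -> dict[str, float]:
        """Map gene -> raw p-value over detected genes."""
        det = self.detected
        return dict(zip(det["gene"], det["p"]))


def write_comparison_table(table: ComparisonTable, path) -> None:
    df = table.data.copy()
    df.insert(0, "comparison", table.comparison)
    df["detected"] = df["detected"].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


_CUFFDIFF_COLUMNS = (
    "test_id", "gene_id", "gene", "locus", "sample_1", "sample_2", "status",
    "value_1", "value_2", "log2(fold_change)", "test_stat", "p_value",
    "q_value", "significant",
)


def read_comparison_table(path, dialect: str = "generic",
                          comparison: str | None = None) -> ComparisonTable:
    """Read a differential-expression table.

    ``dialect="generic"`` expects columns comparison/gene/log2fc/p/q/detected;
    ``dialect="cuffdiff"`` accepts CuffDiff ``gene_exp.diff`` output, mapping
    test status != "OK" to ``detected=False``.  Malformed rows raise
    :class:`ParseError` naming the line.
    """
    path = Path(path)
    if dialect not in ("generic", "cuffdiff"):
        raise ConfigError(f"unknown dialect {dialect!r}")
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise InputError(f"no such file: {path}") from None
    if dialect == "generic":
        expected = ("comparison",) + COMPARISON_COLUMNS
        if tuple(raw.columns) != expected:
            raise ParseError(
                f"expected header {list(expected)}, got {list(raw.columns)}",
                path, line=1)
        rows = _parse_generic_rows(raw, path)
        labels = {r["comparison"] for r in rows}
    else:
        missing = [c for c in _CUFFDIFF_COLUMNS if c not in raw.columns]
        if missing:
            raise ParseError(f"CuffDiff header missing columns {missing}",
                             path, line=1)
        rows = _parse_cuffdiff_rows(raw, path)
        labels = {r["comparison"] for r in rows}
    if comparison is None:
        if len(labels) > 1:
            raise InputError(
                f"{path}: multiple comparison labels {sorted(labels)}; "
                "pass comparison= explicitly")
        comparison = next(iter(labels)) if labels else "unnamed"
    df = pd.DataFrame(rows, columns=("comparison",) + COMPARISON_COLUMNS) \
        if rows else pd.DataFrame(columns=("comparison",) + COMPARISON_COLUMNS)
    df = df.drop(columns=["comparison"])
    return ComparisonTable(comparison=comparison, data=df)


def _parse_float(text: str, *, path, line: int, column: str,
                 allow_blank: bool) -> float:
    if text.strip() in ("", "NA", "nan", "-"):
        if allow_blank:
            return math.nan
        raise ParseError(f"missing value in column {column!r}", path, line)
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"malformed numeric field {text!r} in column {column!r}",
            path, line) from None


def _parse_generic_rows(raw: pd.DataFrame, path) -> list[dict]:
    rows = []
    for i, rec in enumerate(raw.itertuples(index=False)):
        line = i + 2  # header is line 1
        detected_text = rec.detected.strip().lower()
        if detected_text in ("1", "true", "yes"):
            detected = True
        elif detected_text in ("0", "false", "no"):
            detected = False
        else:
            raise ParseError(f"malformed detected flag {rec.detected!r}",
                             path, line)
        rows.append({
            "comparison": rec.comparison,
            "gene": rec.gene,
            "log2fc": _parse_float(rec.log2fc, path=path, line=line,
                                   column="log2fc", allow_blank=not detected),
            "p": _parse_float(rec.p, path=path, line=line, column="p",
                              allow_blank=not detected),
            "q": _parse_float(rec.q, path=path, line=line, column="q",
                              allow_blank=not detected),
            "detected": detected,
        })
    return rows


def _parse_cuffdiff_rows(raw: pd.DataFrame, path) -> list[dict]:
    rows = []
    for i, rec in enumerate(raw.itertuples(index=False)):
        line = i + 2
        d = dict(zip(raw.columns, rec))
        detected = d["status"].strip() == "OK"
        rows.append({
            "comparison": f"{d['sample_1']}_vs_{d['sample_2']}",
            "gene": d["gene"],
            "log2fc": _parse_float(d["log2(fold_change)"], path=path,
                                   line=line, column="log2(fold_change)",
                                   allow_blank=not detected),
            "p": _parse_float(d["p_value"], path=path, line=line,
                              column="p_value", allow_blank=not detected),
            "q": _parse_float(d["q_value"], path=path, line=line,
                              column="q_value", allow_blank=not detected),
            "detected": detected,
        })
    return rows


# ---------------------------------------------------------------------------
# Pathway gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    genes: frozenset
    is_signalling: bool


_SIGNALLING_TAG = "[signalling]"


@dataclass
class PathwayCollection:
    """Named gene sets with a signalling-pathway flag; the ORA universe."""

    pathways: dict[str, Pathway]

    def __post_init__(self):
        for pid, pw in self.pathways.items():
            if pid != pw.pathway_id:
                raise InputError(f"pathway key {pid!r} != id {pw.pathway_id!r}")
            if not pw.genes:
                raise InputError(f"pathway {pid!r} has an empty gene set")

    def __len__(self):
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.values())

    def __getitem__(self, pid: str) -> Pathway:
        return self.pathways[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self.pathways

    @property
    def signalling_ids(self) -> list[str]:
        return sorted(p.pathway_id for p in self if p.is_signalling)


def read_gmt(path) -> PathwayCollection:
    """Read gene sets from GMT (id <TAB> description <TAB> gene...).

    A description containing the ``[signalling]`` tag marks the set as a
    member of the signalling-pathway family used for Bonferroni correction.
    """
    path = Path(path)
    pathways: dict[str, Pathway] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    "GMT line needs id, description and >=1 gene", path, lineno)
            pid, desc = parts[0], parts[1]
            if pid in pathways:
                raise ParseError(f"duplicate pathway id {pid!r}", path, lineno)
            genes = frozenset(normalize_gene(g) for g in parts[2:] if g.strip())
            if not genes:
                raise ParseError(f"pathway {pid!r} has no genes", path, lineno)
            is_sig = _SIGNALLING_TAG in desc
            name = desc.replace(_SIGNALLING_TAG, "").strip()
            pathways[pid] = Pathway(pid, name, genes, is_sig)
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(collection.pathways):
            pw = collection[pid]
            desc = pw.name + (f" {_SIGNALLING_TAG}" if pw.is_signalling else "")
            fh.write("\t".join([pid, desc.strip()] + sorted(pw.genes)) + "\n")


# ---------------------------------------------------------------------------
# Protein-protein interaction networks (SIF)
# ---------------------------------------------------------------------------

def read_sif(path, relation_default: str = "pp") -> nx.Graph:
    """Read an undirected simple graph from SIF (node <TAB> relation <TAB> node).

    The relation token is preserved as an edge attribute but ignored for
    topology; reciprocal lines symmetrize onto a single undirected edge.
    Self-loops are rejected.  Lines with a single column declare an isolated
    node.
    """
    path = Path(path)
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                graph.add_node(normalize_gene(parts[0]))
                continue
            if len(parts) < 3:
                raise ParseError("SIF line needs 1 or >=3 tab-separated "
                                 "fields", path, lineno)
            src = normalize_gene(parts[0])
            rel = parts[1].strip() or relation_default
            for tgt in parts[2:]:
                tgt = normalize_gene(tgt)
                if not tgt:
                    raise ParseError("empty target node", path, lineno)
                if src == tgt:
                    raise ParseError(f"self-loop on {src!r}", path, lineno)
                graph.add_edge(src, tgt, relation=rel)
    return graph


def write_sif(graph: nx.Graph, path, relation_default: str = "pp") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            rel = graph.edges[u, v].get("relation", relation_default)
            fh.write(f"{u}\t{rel}\t{v}\n")
        for node in sorted(n for n in graph.nodes if graph.degree(n) == 0):
            fh.write(f"{node}\n")


# ---------------------------------------------------------------------------
# Drug-target tables
# ---------------------------------------------------------------------------

DRUG_TARGET_COLUMNS = ("drug_id", "drug_name", "target_gene", "mechanism")


def validate_drug_targets(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DRUG_TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"drug-target table missing columns: {missing}")
    df = df[list(DRUG_TARGET_COLUMNS)].copy()
    df["target_gene"] = df["target_gene"].map(normalize_gene)
    df["mechanism"] = df["mechanism"].fillna("")
    dup = df.duplicated(subset=["drug_id", "target_gene"])
    if dup.any():
        pairs = df.loc[dup, ["drug_id", "target_gene"]].itertuples(index=False)
        raise InputError(
            f"duplicate (drug, target) pairs: {[tuple(p) for p in pairs][:5]}")
    return df.reset_index(drop=True)


def read_drug_targets(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise InputError(f"no such file: {path}") from None
    return validate_drug_targets(df)


def write_drug_targets(df: pd.DataFrame, path) -> None:
    validate_drug_targets(df).to_csv(path, sep="\t", index=False)
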