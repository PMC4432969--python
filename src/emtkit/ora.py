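"""Pathway over-representation analysis of differential expression.

For each pathway map the observed number of differentially expressed
transcripts among the measured (detected) genes is compared with the number
expected under homogeneity using a 1-df Pearson chi-square on the 2x2
contingency (in-pathway vs not) x (DE vs not), without continuity
correction.  Raw p-values are Bonferroni-corrected over the family of
signalling-pathway maps (multiplier = family size; 22 in the emulated
design).  Two DE thresholds coexist deliberately: transcript counting
defaults to q < 0.05 and ORA DE status to q < 0.01.

A goodness-of-fit chi-square variant (observed vs expected in-pathway
counts only) is available behind ``variant="goodness_of_fit"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import ComparisonTable, ConfigError, InputError, PathwayCollection

__all__ = [
    "OraResult",
    "MembershipMatrix",
    "count_de",
    "ora_chisq",
    "bonferroni_adjust",
    "component_frequency",
    "ora_results_frame",
]

EXPECTED_FLOOR = 5.0


@dataclass
class OraResult:
    """One (pathway, comparison) enrichment cell."""

    pathway_id: str
    comparison: str
    n_pathway_measured: int
    n_pathway_de: int
    expected_de: float
    chi2_stat: float
    p_raw: float
    p_adj: float | None = None
    family_size: int | None = None
    significant: bool | None = None
    flag: str = ""


def count_de(table: ComparisonTable, q_threshold: float = 0.05) -> int:
    """Number of detected transcripts with q strictly below the threshold."""
    if not (0.0 < q_threshold < 1.0):
        raise ConfigError("q_threshold must lie in (0, 1)")
    det = table.detected
    return int((det["q"].to_numpy() < q_threshold).sum())


def _pearson_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """1-df Pearson chi-square without continuity correction on
    [[a, b], [c, d]]; homogeneous or degenerate margins give (0, 1)."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / denom
    return float(stat), float(chi2.sf(stat, df=1))


def ora_chisq(table: ComparisonTable, pathways: PathwayCollection,
              q_threshold: float = 0.01, de_field: str = "q",
              variant: str = "contingency_2x2",
              expected_floor: float = EXPECTED_FLOOR) -> list[OraResult]:
    """Chi-square over-representation of DE transcripts per pathway.

    The universe is the set of detected genes in the comparison.  DE status
    is ``table[de_field] < q_threshold`` (strict); ``de_field="p"`` supports
    calibration runs where BH q-values would be degenerate.  Pathways whose
    expected DE count falls below ``expected_floor`` are reported with a
    ``low_count`` flag, not dropped; pathways with no measured genes get an
    undefined (NaN) statistic and a ``no_genes`` flag.
    """
    if not (0.0 < q_threshold < 1.0):
        raise ConfigError("q_threshold must lie in (0, 1)")
    if de_field not in ("q", "p"):
        raise ConfigError(f"de_field must be 'q' or 'p', got {de_field!r}")
    if variant not in ("contingency_2x2", "goodness_of_fit"):
        raise ConfigError(f"unknown chi-square variant {variant!r}")
    det = table.detected
    universe = set(det["gene"])
    n_universe = len(universe)
    de_genes = set(det.loc[det[de_field].to_numpy() < q_threshold, "gene"])
    n_de = len(de_genes)
    results = []
    for pid in sorted(pathways.pathways):
        members = pathways[pid].genes & universe
        n_measured = len(members)
        n_in_de = len(members & de_genes)
        if n_universe == 0 or n_measured == 0:
            results.append(OraResult(pid, table.comparison, n_measured,
                                     n_in_de, 0.0, float("nan"), float("nan"),
                                     flag="no_genes"))
            continue
        expected = n_measured * n_de / n_universe
        if variant == "contingency_2x2":
            a = n_in_de
            b = n_measured - n_in_de
            c = n_de - n_in_de
            d = (n_universe - n_measured) - c
            stat, p = _pearson_2x2(a, b, c, d)
        else:
            exp_out = n_measured - expected
            if expected == 0 or exp_out == 0:
                stat, p = 0.0, 1.0
            else:
                obs_out = n_measured - n_in_de
                stat = ((n_in_de - expected) ** 2 / expected
                        + (obs_out - exp_out) ** 2 / exp_out)
                stat, p = float(stat), float(chi2.sf(stat, df=1))
        flag = "low_count" if expected < expected_floor else ""
        results.append(OraResult(pid, table.comparison, n_measured, n_in_de,
                                 float(expected), stat, p, flag=flag))
    return results


def bonferroni_adjust(results: Iterable[OraResult],
                      pathways: PathwayCollection,
                      alpha: float = 0.05) -> list[OraResult]:
    """Bonferroni-correct raw p-values over the signalling-map family.

    Family members get ``p_adj = min(1, p_raw * family size)`` and a
    significance call at ``alpha``; non-members are passed through with
    ``p_adj=None``.  The family size is recorded on each adjusted result.
    """
    family = set(pathways.signalling_ids)
    if not family:
        raise InputError("empty signalling-pathway family")
    k = len(family)
    out = []
    for res in results:
        if res.pathway_id in family and np.isfinite(res.p_raw):
            res.p_adj = min(1.0, res.p_raw * k)
            res.family_size = k
            res.significant = res.p_adj < alpha
        out.append(res)
    return out


@dataclass
class MembershipMatrix:
    """Genes x pathway-maps boolean membership, restricted to genes present
    in at least ``min_maps`` of the chosen maps, sorted by descending
    membership count then symbol."""

    matrix: pd.DataFrame              # bool, index gene, columns pathway ids
    counts: pd.Series = field(default=None)
    min_maps: int = 1

    def __post_init__(self):
        if self.counts is None:
            self.counts = self.matrix.sum(axis=1)


def component_frequency(pathways: PathwayCollection,
                        subset: Sequence[str],
                        min_maps: int = 6) -> MembershipMatrix:
    """Cross-map frequency of pathway components.

    Restricts to genes appearing in >= ``min_maps`` of the ``subset`` maps —
    the analysis behind "present within at least N of the perturbed
    signalling maps".
    """
    if not subset:
        raise InputError("pathway subset is empty")
    if min_maps < 1:
        raise ConfigError("min_maps must be >= 1")
    unknown = [pid for pid in subset if pid not in pathways]
    if unknown:
        raise InputError(f"unknown pathway ids in subset: {unknown}")
    subset = list(subset)
    union = sorted(set().union(*(pathways[pid].genes for pid in subset)))
    matrix = pd.DataFrame(
        {pid: [g in pathways[pid].genes for g in union] for pid in subset},
        index=pd.Index(union, name="gene"))
    counts = matrix.sum(axis=1)
    keep = counts[counts >= min_maps]
    # descending count, ties lexicographic by symbol
    order = sorted(keep.index, key=lambda g: (-keep[g], g))
    return MembershipMatrix(matrix=matrix.loc[order],
                            counts=counts.loc[order], min_maps=min_maps)


def ora_results_frame(results: Iterable[OraResult]) -> pd.DataFrame:
    """Long-format table (pathway, comparison, observed, expected, chi2,
    p_raw, p_adj, flag) mirroring a per-comparison enrichment table when
    pivoted."""
    rows = [{
        "pathway_id": r.pathway_id, "comparison": r.comparison,
        "n_measured": r.n_pathway_measured, "observed_de": r.n_pathway_de,
        "expected_de": r.expected_de, "chi2": r.chi2_stat, "p_raw": r.p_raw,
        "p_adj": r.p_adj if r.p_adj is not None else np.nan,
        "family_size": r.family_size if r.family_size is not None else 0,
        "significant": bool(r.significant) if r.significant is not None else False,
        "flag": r.flag,
    } for r in results]
    return pd.DataFrame(rows)
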