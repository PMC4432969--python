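"""Druggable-target overlay and degree ranking on the merged network.

Drug-target annotations are mapped onto merged-network nodes by exact gene
symbol (after case normalization); druggable nodes are then ranked by their
degree in the merged graph — the number of interaction partners whose
transcripts changed significantly — with ties sharing a degree ordered
lexicographically.
"""

from __future__ import annotations

import logging

import pandas as pd

from .io import ConfigError, validate_drug_targets
from .network import MergedNetwork

__all__ = ["flag_druggable", "rank_druggable", "RANKING_COLUMNS"]

logger = logging.getLogger(__name__)

RANKING_COLUMNS = ("rank", "gene", "degree", "n_drugs", "drug_ids",
                   "mechanisms")


def flag_druggable(merged: MergedNetwork,
                   targets: pd.DataFrame) -> dict:
    """Map gene -> sorted list of (drug_id, mechanism) for targeted nodes.

    A node is flagged iff its symbol appears as a target gene; targets with
    no matching node are logged, never an error.
    """
    targets = validate_drug_targets(targets)
    nodes = set(merged.nodes)
    flags: dict[str, list] = {}
    unmatched = []
    for row in targets.itertuples(index=False):
        if row.target_gene in nodes:
            flags.setdefault(row.target_gene, []).append(
                (row.drug_id, row.mechanism))
        else:
            unmatched.append((row.drug_id, row.target_gene))
    if unmatched:
        logger.info("%d drug-target rows had no matching network node",
                    len(unmatched))
    return {gene: sorted(entries) for gene, entries in flags.items()}


def rank_druggable(merged: MergedNetwork, flags: dict,
                   top_n: int = 30,
                   mechanism_pattern: str | None = None) -> pd.DataFrame:
    """Rank druggable nodes by merged-graph degree.

    Returns at most ``top_n`` rows (rank, gene, degree, n_drugs, drug_ids,
    mechanisms), sorted by degree descending then gene ascending, ranks
    consecutive from 1.  A node targeted by several drugs appears once with
    the drug list aggregated.  ``mechanism_pattern`` optionally restricts to
    drugs whose mechanism string matches the regex.
    """
    if top_n < 1:
        raise ConfigError("top_n must be >= 1")
    import re
    pattern = re.compile(mechanism_pattern) if mechanism_pattern else None
    rows = []
    for gene in sorted(set(flags) & set(merged.nodes)):
        entries = flags[gene]
        if pattern is not None:
            entries = [e for e in entries if pattern.search(e[1] or "")]
        if not entries:
            continue
        rows.append({
            "gene": gene,
            "degree": merged.degree[gene],
            "n_drugs": len({d for d, _ in entries}),
            "drug_ids": ";".join(sorted({d for d, _ in entries})),
            "mechanisms": ";".join(sorted({m for _, m in entries if m})),
        })
    if not rows:
        logger.warning("no druggable nodes in the merged network")
        return pd.DataFrame(columns=list(RANKING_COLUMNS))
    frame = pd.DataFrame(rows).sort_values(
        ["degree", "gene"], ascending=[False, True]).head(top_n)
    frame.insert(0, "rank", range(1, len(frame) + 1))
    return frame.reset_index(drop=True)
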