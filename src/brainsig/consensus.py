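"""Cross-dataset consensus rankings of cell-type signatures.

Per-dataset signature tables are aggregated per (cell type, measure):
log2 fold changes (specificity/enrichment) by their median (or mean)
across the datasets that contain the gene, expression by the grand
median of within-dataset ranks.  A gene enters the consensus only when
its symbol is present in strictly more than half of the in-scope
datasets; a combined human+mouse consensus additionally requires the
symbol in at least one dataset of each species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_SPECIES = ("human", "mouse")


@dataclass
class DatasetSignature:
    """One dataset's SignatureTable plus its identity and species."""

    dataset_id: str
    species: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.species not in VALID_SPECIES:
            raise ValueError(f"species must be one of {VALID_SPECIES}")


def _in_scope(sig: DatasetSignature, scope: str) -> bool:
    return scope == "combined" or sig.species == scope


def build_consensus(
    sigs: list[DatasetSignature],
    measure: str,
    cell_type: str,
    scope: str = "combined",
    agg: str = "median",
) -> pd.DataFrame:
    """Aggregate per-dataset signatures into one consensus ranking.

    Returns a ConsensusSignature frame with columns gene_id, cell_type,
    measure, agg_stat, n_present, consensus_rank.  Fold-change measures
    order by agg_stat descending, expression by grand-median rank
    ascending; ties break by (n_present desc, gene_id asc).
    """
    if agg not in ("median", "mean"):
        raise ValueError("agg must be 'median' or 'mean'")
    if scope not in ("human", "mouse", "combined"):
        raise ValueError("scope must be human, mouse, or combined")
    ids = [s.dataset_id for s in sigs]
    if len(set(ids)) != len(ids):
        raise ValueError("dataset_ids must be unique")
    scoped = [s for s in sigs if _in_scope(s, scope)]
    per_dataset: dict[str, pd.Series] = {}
    species_of: dict[str, str] = {}
    for s in scoped:
        t = s.table
        rows = t[(t["cell_type"] == cell_type) & (t["measure"] == measure)]
        if rows.empty:
            continue
        col = "rank" if measure == "expression" else "stat"
        per_dataset[s.dataset_id] = rows.set_index("gene_id")[col].astype(float)
        species_of[s.dataset_id] = s.species
    if not per_dataset:
        raise ValueError(
            f"cell type {cell_type!r} (measure {measure!r}) absent from all in-scope datasets"
        )
    # dataset_id order is irrelevant downstream: aggregation is symmetric
    wide = pd.DataFrame(per_dataset)
    n_present = wide.notna().sum(axis=1)
    n_datasets = wide.shape[1]
    keep = n_present > n_datasets / 2
    if scope == "combined":
        human_cols = [d for d in wide.columns if species_of[d] == "human"]
        mouse_cols = [d for d in wide.columns if species_of[d] == "mouse"]
        if human_cols and mouse_cols:
            keep &= wide[human_cols].notna().any(axis=1) & wide[mouse_cols].notna().any(axis=1)
    wide = wide[keep]
    n_present = n_present[keep]
    if wide.empty:
        raise ValueError("no genes satisfy the presence rules")
    if measure == "expression":
        # grand median of within-dataset expression ranks, best first
        agg_stat = wide.median(axis=1)
        ascending = True
    else:
        agg_stat = wide.median(axis=1) if agg == "median" else wide.mean(axis=1)
        ascending = False
    out = pd.DataFrame(
        {
            "gene_id": wide.index,
            "cell_type": cell_type,
            "measure": measure,
            "agg_stat": agg_stat.to_numpy(),
            "n_present": n_present.astype(int).to_numpy(),
        }
    )
    out = out.sort_values(
        ["agg_stat", "n_present", "gene_id"],
        ascending=[ascending, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["consensus_rank"] = np.arange(1, len(out) + 1)
    logger.info(
        "consensus %s/%s (%s, agg=%s): %d genes from %d datasets",
        cell_type,
        measure,
        scope,
        agg,
        len(out),
        n_datasets,
    )
    return out


def top_n(consensus: pd.DataFrame, n: int) -> list[str]:
    """First n genes by consensus rank; fewer with a warning if the
    table is short."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = consensus.sort_values("consensus_rank", kind="mergesort")["gene_id"].tolist()
    if n > len(ordered):
        logger.warning("requested top %d but only %d genes available", n, len(ordered))
        return ordered
    return ordered[:n]
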