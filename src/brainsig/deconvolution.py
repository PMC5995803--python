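"""Surrogate cell-type proportions from bulk expression via SVD.

For each cell type, the bulk matrix is subset to that type's marker
genes, each marker is (optionally) centered and unit-variance scaled
across samples, and the first right singular vector of the marker
submatrix is taken as the surrogate proportion variable (SPV): a
relative, per-sample abundance score for the cell type.  SVD's sign
ambiguity is fixed by requiring positive correlation between the SPV
and the per-sample mean of the (scaled) marker rows.  SPVs carry no
absolute-fraction meaning and are not constrained to a simplex.

Residualizing every gene on the SPVs (plus an intercept) removes
cell-composition effects from a bulk matrix ("deconvolution" in the
adjustment sense).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class DeconvolutionParams:
    """n_markers: markers used per cell type (default 50);
    scale_genes: z-scale each marker across samples before SVD."""

    n_markers: int = 50
    scale_genes: bool = True

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")


@dataclass
class ProportionEstimate:
    """SPVs (samples x cell types, unit-norm columns), the markers
    actually found per cell type, and whether the sign was flipped."""

    spv: pd.DataFrame
    markers_used: dict[str, list[str]] = field(default_factory=dict)
    sign_flipped: dict[str, bool] = field(default_factory=dict)


def select_markers(consensus: pd.DataFrame, n: int, available_genes) -> pd.DataFrame:
    """Top-n ranked markers per cell type, restricted to genes present.

    ``consensus`` may be a ConsensusSignature table (gene_id,
    cell_type, consensus_rank) or any MarkerList-shaped frame with a
    ``rank`` column.  Rank order is preserved; a cell type with fewer
    than n available markers keeps them all with a warning, and zero
    available markers is an error.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rank_col = "consensus_rank" if "consensus_rank" in consensus.columns else "rank"
    avail = set(available_genes)
    out = []
    seen: dict[str, str] = {}
    for ct, grp in consensus.groupby("cell_type", sort=False):
        grp = grp.sort_values(rank_col, kind="mergesort")
        present = grp[grp["gene_id"].isin(avail)].head(n)
        if present.empty:
            raise ValueError(f"zero markers available for cell type {ct!r}")
        if len(present) < n:
            logger.warning(
                "cell type %s: only %d of %d requested markers available",
                ct,
                len(present),
                n,
            )
        for g in present["gene_id"]:
            if g in seen:
                logger.warning(
                    "marker %s assigned to both %s and %s (kept in both)", g, seen[g], ct
                )
            else:
                seen[g] = ct
        out.append(
            pd.DataFrame(
                {
                    "cell_type": ct,
                    "gene_id": present["gene_id"].to_numpy(),
                    "rank": np.arange(1, len(present) + 1),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def _scale_rows(x: np.ndarray) -> np.ndarray:
    centered = x - x.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return centered / sd


def estimate_proportions(
    bulk: pd.DataFrame,
    markers: pd.DataFrame,
    params: DeconvolutionParams | None = None,
) -> ProportionEstimate:
    """Estimate one SPV per cell type from a normalized bulk matrix.

    ``bulk`` is genes x samples, assumed already normalized (log-scale
    recommended); integer-looking matrices with large maxima trigger a
    raw-counts warning but are not re-normalized.
    """
    params = params or DeconvolutionParams()
    if bulk.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    vals = bulk.to_numpy(dtype=float)
    if np.allclose(vals, np.round(vals)) and np.nanmax(vals) > 1e4:
        logger.warning("bulk matrix looks like raw counts; expected normalized values")
    spvs: dict[str, np.ndarray] = {}
    used: dict[str, list[str]] = {}
    flipped: dict[str, bool] = {}
    for ct, grp in markers.groupby("cell_type", sort=False):
        genes = [
            g
            for g in grp.sort_values("rank", kind="mergesort")["gene_id"].head(params.n_markers)
            if g in bulk.index
        ]
        if len(genes) < 2:
            raise ValueError(f"fewer than 2 markers of {ct!r} present in bulk matrix")
        sub = bulk.loc[genes].to_numpy(dtype=float)
        if np.allclose(sub.std(axis=1), 0):
            raise ValueError(f"degenerate markers for {ct!r}: constant submatrix")
        x = _scale_rows(sub) if params.scale_genes else sub
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        spv = vt[0]
        mean_marker = x.mean(axis=0)
        r = np.corrcoef(spv, mean_marker)[0, 1]
        flip = bool(np.isfinite(r) and r < 0)
        if flip:
            spv = -spv
        spvs[ct] = spv
        used[ct] = genes
        flipped[ct] = flip
    spv_df = pd.DataFrame(spvs, index=bulk.columns)
    return ProportionEstimate(spv=spv_df, markers_used=used, sign_flipped=flipped)


def cumulative_marker_curve(
    bulk: pd.DataFrame,
    markers: pd.DataFrame,
    reference: pd.Series,
    max_n: int | None = None,
    scale_genes: bool = True,
) -> dict[str, pd.DataFrame]:
    """Spearman correlation of the SPV with a reference, as markers accrue.

    For each cell type and each n = 2..max_n, the SPV is re-estimated
    from the top-n markers and correlated (Spearman) with the
    per-sample reference vector; per-gene individual correlations are
    reported alongside.  A constant reference makes the correlation
    undefined; those entries are NaN with a warning.
    """
    reference = reference.reindex(bulk.columns)
    const_ref = reference.nunique() <= 1
    if const_ref:
        logger.warning("constant reference vector: correlations undefined, reported NaN")
    out: dict[str, pd.DataFrame] = {}
    for ct, grp in markers.groupby("cell_type", sort=False):
        genes = [
            g
            for g in grp.sort_values("rank", kind="mergesort")["gene_id"]
            if g in bulk.index
        ]
        top = len(genes) if max_n is None else min(max_n, len(genes))
        rows = []
        for n in range(2, top + 1):
            sub_markers = pd.DataFrame(
                {"cell_type": ct, "gene_id": genes[:n], "rank": np.arange(1, n + 1)}
            )
            est = estimate_proportions(
                bulk,
                sub_markers,
                DeconvolutionParams(n_markers=n, scale_genes=scale_genes),
            )
            if const_ref:
                rho = np.nan
            else:
                rho = stats.spearmanr(est.spv[ct].to_numpy(), reference.to_numpy()).statistic
            rows.append({"n_markers": n, "spearman": rho})
        curve = pd.DataFrame(rows)
        gene_rows = []
        for g in genes[:top]:
            rho = (
                np.nan
                if const_ref
                else stats.spearmanr(bulk.loc[g].to_numpy(), reference.to_numpy()).statistic
            )
            gene_rows.append({"gene_id": g, "spearman": rho})
        out[ct] = curve.merge(
            pd.DataFrame(gene_rows).assign(n_markers=np.arange(1, top + 1)),
            on="n_markers",
            how="outer",
            suffixes=("_cumulative", "_gene"),
        )
    return out


def adjust_expression(bulk: pd.DataFrame, est: ProportionEstimate) -> pd.DataFrame:
    """Residualize every gene on the SPVs, keeping the gene's mean.

    Ordinary least squares of each gene's expression on all SPV columns
    plus an intercept; the residual plus the gene mean is returned, so
    output dimensions equal input and composition effects are removed.
    """
    if not est.spv.index.equals(bulk.columns):
        est_spv = est.spv.reindex(bulk.columns)
        if est_spv.isna().any().any():
            raise ValueError("SPVs were not computed on the same samples as the bulk matrix")
    else:
        est_spv = est.spv
    n_samples, k = est_spv.shape
    if n_samples <= k + 1:
        raise ValueError("insufficient degrees of freedom: need #samples > #cell types + 1")
    design = np.column_stack([np.ones(n_samples), est_spv.to_numpy(dtype=float)])
    y = bulk.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    adjusted = resid.T + bulk.to_numpy(dtype=float).mean(axis=1, keepdims=True)
    return pd.DataFrame(adjusted, index=bulk.index, columns=bulk.columns)
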