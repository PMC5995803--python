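"""Cell-type association signatures from labeled count matrices.

Three per-gene measures relate a gene's expression to a target cell
type:

* **enrichment** — shrunken log2 fold change of the target versus all
  other (reference) cell types pooled, with a negative-binomial
  likelihood-ratio test per gene;
* **specificity** — the minimum shrunken log2 fold change over each
  reference cell type individually, so a gene scores high only if it is
  elevated against *every* other type;
* **absolute expression** — within-cell-type mean RPKM after quantile
  normalization, with its within-type rank.

Fold changes are shrunk by adding a pseudocount proportional to each
sample's relative library size before computing group-mean CPM ratios
(the predictive-fold-change convention): the augmented count is
``y + prior * libsize_s / mean(libsize)`` and the effective library
size is inflated by twice the same pseudocount, so fold changes of
low-count genes are pulled toward zero.

Oligodendrocytes (MOL) and their precursors (OPC) are mutually excluded
from each other's reference set — their expression programs are too
similar for the contrast to be meaningful.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from brainsig.io import LabeledCountMatrix

logger = logging.getLogger(__name__)

LOG2_FC4 = 2.0  # log2 of the fold-change-4 volcano threshold


@dataclass
class NormalizationParams:
    """Shrinkage and filtering parameters.

    prior_count
        Pseudocount added per observation relative to library size
        before fold-change computation (default 10, a heavy shrinkage
        suited to noisy cell-type contrasts).
    min_mean_count
        A gene is kept when its arithmetic-mean raw count reaches this
        value in at least one cell type (default 5).
    """

    prior_count: float = 10.0
    min_mean_count: float = 5.0
    log_base: int = 2

    def __post_init__(self) -> None:
        if self.prior_count < 0 or self.min_mean_count < 0:
            raise ValueError("prior_count and min_mean_count must be >= 0")
        if self.log_base != 2:
            raise ValueError("log_base is fixed at 2")


@dataclass
class ReferenceCellSet:
    """The cell types a target is contrasted against."""

    target: str
    reference: tuple[str, ...]

    def __post_init__(self) -> None:
        self.reference = tuple(self.reference)
        if self.target in self.reference:
            raise ValueError("target must not be in its own reference set")
        if self.target == "MOL" and "OPC" in self.reference:
            raise ValueError("OPC must be excluded from the MOL reference set")
        if self.target == "OPC" and "MOL" in self.reference:
            raise ValueError("MOL must be excluded from the OPC reference set")


def make_reference_set(target: str, available: list[str]) -> ReferenceCellSet:
    """Default reference set: all other available types, honoring the
    MOL/OPC mutual exclusion."""
    ref = [t for t in available if t != target]
    if target == "MOL":
        ref = [t for t in ref if t != "OPC"]
    if target == "OPC":
        ref = [t for t in ref if t != "MOL"]
    return ReferenceCellSet(target=target, reference=tuple(ref))


# ---------------------------------------------------------------------------
# filtering and normalization


def filter_expressed(
    m: LabeledCountMatrix, params: NormalizationParams | None = None
) -> LabeledCountMatrix:
    """Keep genes whose mean raw count is >= ``min_mean_count`` in at
    least one cell type (boundary inclusive)."""
    params = params or NormalizationParams()
    labels = m.cell_type.to_numpy()
    group_means = pd.DataFrame(
        {ct: m.counts.loc[:, labels == ct].mean(axis=1) for ct in m.cell_types()}
    )
    keep = group_means.max(axis=1) >= params.min_mean_count
    if not keep.any():
        raise ValueError("no genes pass filter")
    logger.info("filter_expressed: kept %d / %d genes", int(keep.sum()), m.n_genes)
    return m.subset_genes(m.gene_ids[keep])


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean of sorted columns.

    Tied values within a column receive the mean of the target values
    their positions span, so the map is well defined under ties.
    """
    arr = df.to_numpy(dtype=float)
    n = arr.shape[0]
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="mergesort")
        sorted_vals = arr[order, j]
        new_group = np.r_[True, sorted_vals[1:] != sorted_vals[:-1]]
        starts = np.flatnonzero(new_group)
        sizes = np.diff(np.r_[starts, n])
        group_means = np.add.reduceat(ref, starts) / sizes
        out[order, j] = group_means[np.cumsum(new_group) - 1]
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def shrunken_group_logfc(
    m: LabeledCountMatrix | pd.DataFrame,
    group_a,
    group_b,
    params: NormalizationParams | None = None,
) -> pd.Series:
    """Per-gene shrunken log2 fold change of group_a over group_b.

    Each sample's count is augmented by ``prior_count * libsize_s /
    mean(libsize)`` and its effective library size by twice that amount;
    the statistic is the log2 ratio of group means of augmented CPM.
    The mean library size is taken over the samples being compared.
    """
    params = params or NormalizationParams()
    counts = m.counts if isinstance(m, LabeledCountMatrix) else m
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    sel = a + b
    # library sizes come from the full gene complement of `counts`
    lib = counts.sum(axis=0).astype(float).loc[sel]
    if lib.loc[a].sum() == 0 or lib.loc[b].sum() == 0:
        raise ValueError("group with zero total counts")
    rel = (lib / lib.mean()).to_numpy()
    aug = counts[sel].to_numpy(dtype=float) + params.prior_count * rel
    eff = lib.to_numpy() + 2.0 * params.prior_count * rel
    cpm = aug / eff * 1e6
    na = len(a)
    with np.errstate(divide="ignore"):
        logfc = np.log2(cpm[:, :na].mean(axis=1)) - np.log2(cpm[:, na:].mean(axis=1))
    return pd.Series(logfc, index=counts.index, name="log2fc")


# ---------------------------------------------------------------------------
# negative-binomial testing machinery


def estimate_dispersions(
    counts: pd.DataFrame, groups: pd.Series, lib: pd.Series, prior_df: float = 20.0
) -> np.ndarray:
    """Per-gene NB dispersion (alpha in var = mu + alpha*mu^2).

    A method-of-moments (Pearson-residual) estimate per gene is shrunk
    toward a mean-dispersion trend fitted by lowess across genes, a
    light empirical-Bayes compromise between per-gene noise and a
    common trend.  ``prior_df`` controls the pull toward the trend.
    """
    y = counts.to_numpy(dtype=float)
    libv = lib.to_numpy(dtype=float)
    mu = np.zeros_like(y)
    labels = groups.to_numpy()
    uniq = pd.unique(labels)
    for g in uniq:
        idx = labels == g
        denom = libv[idx].sum()
        q = y[:, idx].sum(axis=1) / denom if denom > 0 else np.zeros(y.shape[0])
        mu[:, idx] = q[:, None] * libv[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = ((y - mu) ** 2 - mu) / mu**2
    finite = np.isfinite(contrib)
    n_eff = finite.sum(axis=1)
    raw = np.where(finite, contrib, 0.0).sum(axis=1) / np.maximum(n_eff - len(uniq), 1)
    raw = np.clip(raw, 1e-8, 10.0)
    mean_cpm = (y / libv).mean(axis=1) * 1e6
    lx = np.log(mean_cpm + 1e-8)
    if len(lx) >= 10 and np.ptp(lx) > 0:
        trend = np.exp(lowess(np.log(raw), lx, frac=0.5, return_sorted=False))
    else:
        trend = np.full_like(raw, np.exp(np.log(raw).mean()))
    n = counts.shape[1]
    shrunk = (n * raw + prior_df * trend) / (n + prior_df)
    return np.clip(shrunk, 1e-8, 10.0)


def _covariate_design(
    m: LabeledCountMatrix, sample_ids: list[str], covariates
) -> pd.DataFrame:
    """Build numeric covariate columns for the model; missing or
    incomplete covariates are dropped with a warning."""
    cols: dict[str, np.ndarray] = {}
    for name in covariates or []:
        if m.covariates is None or name not in m.covariates.columns:
            logger.warning("covariate %r not available; excluded from model", name)
            continue
        s = m.covariates.loc[sample_ids, name]
        if s.isna().any():
            logger.warning("covariate %r has missing values; excluded from model", name)
            continue
        if pd.api.types.is_numeric_dtype(s):
            cols[name] = s.to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(s, prefix=name, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy()
    return pd.DataFrame(cols, index=sample_ids)


def _check_design(group: np.ndarray, cov: pd.DataFrame) -> None:
    base = np.column_stack([np.ones(len(group)), group])
    rank = np.linalg.matrix_rank(base)
    for name in cov.columns:
        cand = np.column_stack([base, cov[name].to_numpy()])
        if np.linalg.matrix_rank(cand) <= rank:
            raise ValueError(f"singular design: covariate {name!r} is confounded with the group")
        base, rank = cand, np.linalg.matrix_rank(cand)


def nb_lrt(
    counts: pd.DataFrame,
    group: np.ndarray,
    lib: pd.Series,
    dispersions: np.ndarray,
    cov: pd.DataFrame | None = None,
) -> np.ndarray:
    """Per-gene likelihood-ratio test of the group coefficient in an NB
    GLM with log library-size offset and fixed dispersion."""
    n = len(group)
    cov_arr = cov.to_numpy(dtype=float) if cov is not None and cov.shape[1] else np.empty((n, 0))
    x_red = np.column_stack([np.ones(n), cov_arr])
    x_full = np.column_stack([np.ones(n), group.astype(float), cov_arr])
    offset = np.log(lib.to_numpy(dtype=float))
    y_all = counts.to_numpy(dtype=float)
    pvals = np.empty(counts.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(counts.shape[0]):
            y = y_all[i]
            fam = sm.families.NegativeBinomial(alpha=max(dispersions[i], 1e-8))
            try:
                full = sm.GLM(y, x_full, family=fam, offset=offset).fit(maxiter=100)
                red = sm.GLM(y, x_red, family=fam, offset=offset).fit(maxiter=100)
                lrt = max(2.0 * (full.llf - red.llf), 0.0)
                pvals[i] = stats.chi2.sf(lrt, 1)
            except Exception:  # non-convergence on degenerate genes
                pvals[i] = np.nan
    return pvals


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjustment; NaN p-values pass through as NaN."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _assign_ranks(df: pd.DataFrame, ascending: bool = False) -> pd.Series:
    """Deterministic 1..n ranks by (stat, gene_id asc) tie-break."""
    order = df.sort_values(
        ["stat", "gene_id"], ascending=[ascending, True], kind="mergesort"
    ).index
    ranks = pd.Series(0, index=df.index, dtype=int)
    ranks.loc[order] = np.arange(1, len(df) + 1)
    return ranks


def _signature_frame(gene_ids, cell_type, measure, stat, p, adj) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "cell_type": cell_type,
            "measure": measure,
            "stat": np.asarray(stat, dtype=float),
            "p_value": p,
            "adj_p": adj,
        }
    )
    df["rank"] = _assign_ranks(df, ascending=False)
    return df.sort_values("rank").reset_index(drop=True)


# ---------------------------------------------------------------------------
# the three measures


def enrichment(
    m: LabeledCountMatrix,
    target: str,
    refset: ReferenceCellSet | None = None,
    params: NormalizationParams | None = None,
    covariates=None,
    compute_pvalues: bool = True,
) -> pd.DataFrame:
    """Cell-type enrichment: target versus all reference types pooled.

    Returns SignatureTable rows (measure="enrichment") with the
    shrunken log2 fold change, an NB LRT p-value for the group term
    (covariates additive on the log-mean scale), BH-adjusted p, and the
    within-measure rank.
    """
    params = params or NormalizationParams()
    refset = refset or make_reference_set(target, m.cell_types())
    tgt = m.samples_of(target)
    if len(tgt) < 2:
        raise ValueError(f"target {target!r} has fewer than 2 samples")
    ref = [s for r in refset.reference for s in m.samples_of(r)]
    if not ref:
        raise ValueError("empty reference sample set")
    stat = shrunken_group_logfc(m, tgt, ref, params)
    p = adj = np.full(m.n_genes, np.nan)
    if compute_pvalues:
        sel = tgt + ref
        sub = m.counts[sel]
        lib = m.counts.sum(axis=0).astype(float).loc[sel]
        group = np.array([1.0 if s in set(tgt) else 0.0 for s in sel])
        cov = _covariate_design(m, sel, covariates)
        _check_design(group, cov)
        disp = estimate_dispersions(sub, m.cell_type.loc[sel], lib)
        p = nb_lrt(sub, group, lib, disp, cov)
        adj = bh_adjust(p)
    return _signature_frame(m.gene_ids, target, "enrichment", stat, p, adj)


def specificity(
    m: LabeledCountMatrix,
    target: str,
    refset: ReferenceCellSet | None = None,
    params: NormalizationParams | None = None,
    covariates=None,
    compute_pvalues: bool = True,
) -> pd.DataFrame:
    """Cell-type specificity: minimum pairwise fold change.

    The statistic is the minimum shrunken log2 fold change over each
    reference cell type individually; the p-value is that of the
    contrast attaining the minimum.
    """
    params = params or NormalizationParams()
    refset = refset or make_reference_set(target, m.cell_types())
    tgt = m.samples_of(target)
    if len(tgt) < 2:
        raise ValueError(f"target {target!r} has fewer than 2 samples")
    pairwise = {}
    for r in refset.reference:
        rs = m.samples_of(r)
        if not rs:
            continue
        pairwise[r] = shrunken_group_logfc(m, tgt, rs, params)
    if not pairwise:
        raise ValueError("no reference cell types with samples")
    fc = pd.DataFrame(pairwise)
    stat = fc.min(axis=1)
    argmin = fc.idxmin(axis=1)
    p = np.full(m.n_genes, np.nan)
    if compute_pvalues:
        lib_all = m.counts.sum(axis=0).astype(float)
        gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
        for r, genes in argmin.groupby(argmin).groups.items():
            sel = tgt + m.samples_of(r)
            sub = m.counts.loc[list(genes), sel]
            lib = lib_all.loc[sel]
            group = np.array([1.0 if s in set(tgt) else 0.0 for s in sel])
            cov = _covariate_design(m, sel, covariates)
            _check_design(group, cov)
            disp = estimate_dispersions(sub, m.cell_type.loc[sel], lib)
            pv = nb_lrt(sub, group, lib, disp, cov)
            for g, v in zip(genes, pv):
                p[gene_pos[g]] = v
    adj = bh_adjust(p)
    df = _signature_frame(m.gene_ids, target, "specificity", stat, p, adj)
    return df


def absolute_expression(
    m: LabeledCountMatrix,
    lengths: pd.Series,
    target: str | None = None,
) -> pd.DataFrame:
    """Within-cell-type absolute expression as mean RPKM.

    Counts are quantile-normalized across samples, converted to RPKM
    using gene length (kb) and library size (millions), then averaged
    within the cell type; the standard error of that mean and the
    within-type rank (1 = highest) are reported.  Genes without a
    length are dropped with a warning.
    """
    have = m.gene_ids.intersection(lengths.index)
    missing = m.gene_ids.difference(lengths.index)
    if len(missing):
        logger.warning("dropping %d genes without length annotation", len(missing))
    if not len(have):
        raise ValueError("no genes with length annotation")
    sub = m.subset_genes(have)
    norm = quantile_normalize(sub.counts)
    lib = norm.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size after normalization")
    kb = lengths.loc[have].astype(float) / 1e3
    rpkm = norm.div(kb, axis=0).div(lib / 1e6, axis=1)
    targets = [target] if target is not None else sub.cell_types()
    frames = []
    for ct in targets:
        cols = sub.samples_of(ct)
        if not cols:
            raise ValueError(f"cell type {ct!r} has no samples")
        vals = rpkm[cols]
        mean = vals.mean(axis=1)
        sem = vals.std(axis=1, ddof=1) / np.sqrt(len(cols)) if len(cols) > 1 else pd.Series(np.nan, index=have)
        df = _signature_frame(have, ct, "expression", mean, np.nan, np.nan)
        df = df.merge(
            pd.DataFrame({"gene_id": have, "sem": sem.to_numpy()}), on="gene_id", how="left"
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def volcano_flags(rows: pd.DataFrame) -> pd.Series:
    """Significance flag at the standard volcano thresholds:
    BH-adjusted p strictly below 0.05 and log2 fold change >= 2
    (fold change >= 4, boundary inclusive on the fold change)."""
    return (rows["adj_p"] < 0.05) & (rows["stat"] >= LOG2_FC4)
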