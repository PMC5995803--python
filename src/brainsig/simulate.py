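"""Seeded synthetic data with known ground truth.

Two generators give every other module a test surface:

* :func:`simulate_cells` — a single-cell-like count matrix with
  disjoint planted marker genes per cell type (negative-binomial
  counts, multiplicative marker effect, log-normal library-size
  variation);
* :func:`simulate_bulk` — bulk mixtures whose expected expression is a
  Dirichlet-weighted convex combination of per-cell-type mean profiles,
  with NB counting noise around the expectation.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from brainsig.io import CANONICAL_CELL_TYPES, LabeledCountMatrix


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generators.

    dispersion is the NB dispersion alpha (variance = mu + alpha*mu^2);
    larger alpha means noisier counts.  marker_log2_effect is the
    planted log2 expression shift of a marker gene in its own cell
    type.  libsize_cv is the coefficient of variation of log-normal
    per-sample library-size factors.
    """

    n_genes: int = 2000
    cell_types: tuple[str, ...] = CANONICAL_CELL_TYPES
    cells_per_type: int = 50
    n_markers_per_type: int = 50
    marker_log2_effect: float = 4.0
    baseline_mean: float = 100.0
    dispersion: float = 0.25
    libsize_cv: float = 0.3
    dropout: float = 0.0
    n_bulk_samples: int = 40
    dirichlet_alpha: float | tuple[float, ...] = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.cells_per_type <= 0 or self.baseline_mean <= 0:
            raise ValueError("count parameters must be positive")
        if self.n_markers_per_type * len(self.cell_types) > self.n_genes:
            raise ValueError("too many markers for n_genes")
        if self.dispersion < 0 or self.libsize_cv < 0:
            raise ValueError("dispersion and libsize_cv must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class GroundTruth:
    """What the generator planted: marker assignments, per-cell labels,
    and (for bulk) the true mixing proportions on the simplex."""

    marker_assignments: dict[str, str] = field(default_factory=dict)
    cell_labels: pd.Series | None = None
    bulk_proportions: pd.DataFrame | None = None


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB sample with var = mu + alpha*mu^2; Poisson when alpha == 0."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        p = size / (size + mean)
    p = np.where(mean > 0, p, 1.0)
    return rng.negative_binomial(size, p)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def expected_profiles(cfg: SimulationConfig) -> pd.DataFrame:
    """Expected per-cell-type mean expression (genes x cell types)
    implied by the planted-marker design, before library-size effects."""
    genes = _gene_ids(cfg.n_genes)
    prof = pd.DataFrame(
        cfg.baseline_mean, index=genes, columns=list(cfg.cell_types), dtype=float
    )
    boost = 2.0**cfg.marker_log2_effect
    for k, ct in enumerate(cfg.cell_types):
        start = k * cfg.n_markers_per_type
        prof.iloc[start : start + cfg.n_markers_per_type, k] *= boost
    return prof


def marker_truth(cfg: SimulationConfig) -> dict[str, str]:
    """gene -> cell type for the planted (disjoint) markers."""
    genes = _gene_ids(cfg.n_genes)
    out: dict[str, str] = {}
    for k, ct in enumerate(cfg.cell_types):
        start = k * cfg.n_markers_per_type
        for g in genes[start : start + cfg.n_markers_per_type]:
            out[g] = ct
    return out


def simulate_cells(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[LabeledCountMatrix, GroundTruth]:
    """Simulate a labeled count matrix with planted markers.

    Counts are NB with mean ``baseline * 2^effect[gene, type] *
    libsize_factor`` and the configured dispersion.  Marker blocks are
    disjoint across cell types by construction.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    prof = expected_profiles(cfg)
    truth = GroundTruth(marker_assignments=marker_truth(cfg))
    labels, cols = [], []
    blocks = []
    for ct in cfg.cell_types:
        n = cfg.cells_per_type
        if cfg.libsize_cv > 0:
            sigma = np.sqrt(np.log1p(cfg.libsize_cv**2))
            factors = rng.lognormal(-(sigma**2) / 2, sigma, size=n)
        else:
            factors = np.ones(n)
        mean = prof[ct].to_numpy()[:, None] * factors[None, :]
        block = _nb_draw(rng, mean, cfg.dispersion)
        if cfg.dropout > 0:
            keep = rng.random(block.shape) >= cfg.dropout
            block = block * keep
        blocks.append(block)
        labels += [ct] * n
        cols += [f"{ct}_{i + 1}" for i in range(n)]
    counts = pd.DataFrame(
        np.hstack(blocks), index=prof.index, columns=cols, dtype=np.int64
    )
    cell_type = pd.Series(labels, index=cols)
    truth.cell_labels = cell_type
    covariates = pd.DataFrame(
        {"total_features": (counts > 0).sum(axis=0).astype(float)}, index=cols
    )
    return LabeledCountMatrix(counts, cell_type, covariates), truth


def simulate_bulk(
    cfg: SimulationConfig,
    profiles: pd.DataFrame | None = None,
    seed: int | None = None,
    noise: bool = True,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate bulk mixtures of cell-type profiles.

    Each sample's proportions are Dirichlet-distributed; its expected
    expression is the proportion-weighted combination of the per-type
    profiles.  With ``noise=True`` counts are drawn NB around the
    expectation; with ``noise=False`` the exact convex combination is
    returned (useful as a rank-1-per-marker-block oracle).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    from_cfg = profiles is None
    if profiles is None:
        profiles = expected_profiles(cfg)
    if (profiles.to_numpy() < 0).any():
        raise ValueError("profiles must be non-negative")
    k = profiles.shape[1]
    alpha = cfg.dirichlet_alpha
    alpha_vec = np.full(k, float(alpha)) if np.isscalar(alpha) else np.asarray(alpha, float)
    if len(alpha_vec) != k:
        raise ValueError("dirichlet_alpha length must match number of cell types")
    props = rng.dirichlet(alpha_vec, size=cfg.n_bulk_samples)
    expected = profiles.to_numpy() @ props.T
    if noise:
        mat = _nb_draw(rng, expected, cfg.dispersion).astype(float)
    else:
        mat = expected
    samples = [f"B{i + 1:03d}" for i in range(cfg.n_bulk_samples)]
    bulk = pd.DataFrame(mat, index=profiles.index, columns=samples)
    truth = GroundTruth(
        marker_assignments=marker_truth(cfg) if from_cfg else {},
        bulk_proportions=pd.DataFrame(props, index=samples, columns=profiles.columns),
    )
    return bulk, truth
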