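"""Reading and writing expression matrices, labels, and gene sets.

Matrices are gene-major: rows are genes, columns are samples.  Sample
annotations (cell-type labels, covariates) live in a sidecar TSV named
``<stem>.samples.tsv`` with mandatory columns ``sample_id`` and
``cell_type``; any further columns are covariates.  MatrixMarket input
uses companion ``<stem>.rows.txt`` / ``<stem>.cols.txt`` name files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

#: Canonical vocabulary of major brain cell types.  Free-form extras are
#: allowed; these six are the ones the reference-set logic knows about.
CANONICAL_CELL_TYPES = ("AST", "END", "MIC", "NEU", "MOL", "OPC")


class MatrixParseError(ValueError):
    """Raised when an expression matrix file cannot be parsed."""


@dataclass
class LabeledCountMatrix:
    """Integer gene-by-sample counts with per-sample cell-type labels.

    Parameters
    ----------
    counts
        Non-negative integer counts, genes x samples.  The index holds
        gene identifiers, the columns hold sample identifiers.
    cell_type
        One label per sample (index aligned with ``counts.columns``).
    covariates
        Optional numeric or categorical per-sample covariates
        (e.g. total detected features), samples x covariates.
    """

    counts: pd.DataFrame
    cell_type: pd.Series
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.is_unique:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if not self.counts.columns.is_unique:
            raise ValueError("duplicate sample ids")
        self.cell_type = pd.Series(self.cell_type, dtype=object)
        if len(self.cell_type) != self.counts.shape[1]:
            raise ValueError(
                f"label vector length {len(self.cell_type)} != "
                f"number of samples {self.counts.shape[1]}"
            )
        if not self.cell_type.index.equals(self.counts.columns):
            self.cell_type = self.cell_type.reindex(self.counts.columns)
            if self.cell_type.isna().any():
                missing = self.cell_type.index[self.cell_type.isna()].tolist()
                raise ValueError(f"samples missing a cell_type label: {missing}")
        if self.covariates is not None:
            self.covariates = self.covariates.reindex(self.counts.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def cell_types(self) -> list[str]:
        """Cell types present, in order of first appearance."""
        return list(dict.fromkeys(self.cell_type))

    def samples_of(self, cell_type: str) -> list[str]:
        return list(self.counts.columns[(self.cell_type == cell_type).to_numpy()])

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0).astype(float)

    def subset_genes(self, gene_ids) -> "LabeledCountMatrix":
        return LabeledCountMatrix(
            self.counts.loc[list(gene_ids)], self.cell_type, self.covariates
        )

    def subset_samples(self, sample_ids) -> "LabeledCountMatrix":
        sample_ids = list(sample_ids)
        return LabeledCountMatrix(
            self.counts[sample_ids],
            self.cell_type.loc[sample_ids],
            None if self.covariates is None else self.covariates.loc[sample_ids],
        )


@dataclass
class HarmonizeResult:
    """Outcome of symbol harmonization.

    ``mapping`` maps each input symbol to its harmonized form;
    ``symbols`` is the deduplicated harmonized list (first occurrence
    survives a collision); ``collisions`` lists, per surviving key, the
    input symbols that collided onto it.
    """

    mapping: dict[str, str]
    symbols: list[str]
    collisions: dict[str, list[str]] = field(default_factory=dict)


def harmonize_symbols(gene_ids, mode: str = "uppercase") -> HarmonizeResult:
    """Harmonize gene symbols so human and mouse tables intersect.

    Mouse symbols are conventionally title-case (``Aqp4``) while human
    symbols are upper-case (``AQP4``); ``mode="uppercase"`` folds both
    to upper case so cross-species tables can be merged on symbol.
    Collisions after folding are reported, not silently resolved.
    """
    if mode not in ("uppercase", "none"):
        raise ValueError(f"unknown mode {mode!r}")
    mapping: dict[str, str] = {}
    seen: dict[str, str] = {}
    collisions: dict[str, list[str]] = {}
    symbols: list[str] = []
    for g in gene_ids:
        h = g.upper() if mode == "uppercase" else g
        mapping[g] = h
        if h in seen:
            collisions.setdefault(h, [seen[h]]).append(g)
        else:
            seen[h] = g
            symbols.append(h)
    for key, members in collisions.items():
        logger.warning(
            "symbol collision after harmonization: %s -> %s (keeping first occurrence)",
            members,
            key,
        )
    return HarmonizeResult(mapping=mapping, symbols=symbols, collisions=collisions)


def harmonize_matrix(m: LabeledCountMatrix, mode: str = "uppercase") -> LabeledCountMatrix:
    """Apply :func:`harmonize_symbols` to a matrix, keeping the first row
    among colliding symbols."""
    res = harmonize_symbols(m.counts.index, mode=mode)
    counts = m.counts.copy()
    counts.index = [res.mapping[g] for g in counts.index]
    counts = counts[~counts.index.duplicated(keep="first")]
    return LabeledCountMatrix(counts, m.cell_type, m.covariates)


def _read_sidecar(stem: Path, sample_ids) -> tuple[pd.Series, pd.DataFrame | None]:
    sidecar = stem.with_suffix(stem.suffix + ".samples.tsv") if stem.suffix else None
    candidates = [Path(str(stem) + ".samples.tsv"), stem.with_suffix(".samples.tsv")]
    path = next((c for c in candidates if c.exists()), None)
    if path is None:
        raise FileNotFoundError(
            f"annotation sidecar not found (tried {[str(c) for c in candidates]})"
        )
    ann = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "cell_type"):
        if col not in ann.columns:
            raise MatrixParseError(f"{path}: sidecar missing mandatory column {col!r}")
    ann = ann.set_index("sample_id")
    missing = [s for s in sample_ids if s not in ann.index]
    if missing:
        raise MatrixParseError(f"{path}: no annotation for samples {missing}")
    ann = ann.loc[list(sample_ids)]
    cov_cols = [c for c in ann.columns if c != "cell_type"]
    covariates = ann[cov_cols] if cov_cols else None
    return ann["cell_type"], covariates


def read_matrix(path, format: str | None = None) -> LabeledCountMatrix:
    """Read a labeled count matrix from TSV, CSV, or MatrixMarket MTX.

    TSV/CSV layout: first column gene_id, header row of sample ids.
    MTX layout: coordinate integer file with ``<stem>.rows.txt`` and
    ``<stem>.cols.txt`` holding gene and sample names.  All formats
    require the ``<stem>.samples.tsv`` annotation sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from {path.suffix!r}")
    stem = path.with_suffix("")
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise MatrixParseError(f"{path}: {exc}") from exc
        if not df.index.is_unique:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise MatrixParseError(f"{path}: duplicate gene ids: {dups}")
        counts = df
    elif format == "mtx":
        rows_file = Path(str(stem) + ".rows.txt")
        cols_file = Path(str(stem) + ".cols.txt")
        for f in (rows_file, cols_file):
            if not f.exists():
                raise FileNotFoundError(f"companion name file missing: {f}")
        try:
            mat = spio.mmread(path)
        except ValueError as exc:
            raise MatrixParseError(f"{path}: {exc}") from exc
        genes = rows_file.read_text().split()
        samples = cols_file.read_text().split()
        if sparse.issparse(mat):
            mat = mat.toarray()
        counts = pd.DataFrame(np.asarray(mat), index=genes, columns=samples)
        if not counts.index.is_unique:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise MatrixParseError(f"{path}: duplicate gene ids: {dups}")
    else:
        raise ValueError(f"unknown format {format!r}")
    counts = counts.astype(np.int64)
    cell_type, covariates = _read_sidecar(stem, counts.columns)
    logger.info("read %s: %d genes x %d samples", path, *counts.shape)
    return LabeledCountMatrix(counts, cell_type, covariates)


def write_matrix(m: LabeledCountMatrix, path, format: str | None = None) -> None:
    """Write a matrix plus its annotation sidecar; inverse of read_matrix."""
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}[path.suffix.lower()]
    stem = path.with_suffix("")
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        out = m.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep=sep)
    elif format == "mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(m.counts.to_numpy()), field="integer")
        Path(str(stem) + ".rows.txt").write_text("\n".join(m.counts.index) + "\n")
        Path(str(stem) + ".cols.txt").write_text("\n".join(m.counts.columns) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    ann = pd.DataFrame({"sample_id": m.counts.columns, "cell_type": m.cell_type.to_numpy()})
    if m.covariates is not None:
        ann = pd.concat([ann, m.covariates.reset_index(drop=True)], axis=1)
    ann.to_csv(str(stem) + ".samples.tsv", sep="\t", index=False)


def read_gene_lengths(path) -> pd.Series:
    """Read a two-column TSV (gene_id, length_bp) into a Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise MatrixParseError(f"{path}: expected columns gene_id, length_bp")
    df.columns = ["gene_id", "length_bp", *df.columns[2:]]
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise MatrixParseError(f"{path}: duplicate gene ids: {dups}")
    lengths = df.set_index("gene_id")["length_bp"].astype(int)
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1 bp")
    return lengths


def read_marker_table(path) -> pd.DataFrame:
    """Read a marker-list TSV with columns gene, cell type, optional rank."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower().strip(): c for c in df.columns}
    gene_col = next((cols[k] for k in ("gene", "gene_id", "markers") if k in cols), None)
    type_col = next((cols[k] for k in ("cell_type", "cell", "celltype") if k in cols), None)
    if gene_col is None or type_col is None:
        raise MatrixParseError(f"{path}: need gene and cell-type columns")
    out = pd.DataFrame({"gene_id": df[gene_col], "cell_type": df[type_col]})
    rank_col = cols.get("rank")
    if rank_col is not None:
        out["rank"] = df[rank_col].astype(int)
    else:
        out["rank"] = out.groupby("cell_type", sort=False).cumcount() + 1
    return out


def write_marker_table(markers: pd.DataFrame, path) -> None:
    markers.to_csv(path, sep="\t", index=False)


def read_signature_table(path) -> pd.DataFrame:
    """Read a serialized SignatureTable TSV."""
    return pd.read_csv(path, sep="\t")


def write_signature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise MatrixParseError(f"{path}:{lineno}: GMT line needs >= 3 fields")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "") -> None:
    lines = [
        "\t".join([name, description, *sorted(members)]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def default_markers() -> pd.DataFrame:
    """Bundled curated marker list (canonical brain markers) for smoke tests."""
    path = Path(__file__).parent / "data" / "default_markers.tsv"
    return read_marker_table(path)
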