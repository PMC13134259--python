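"""Data model and I/O for single-cell expression matrices and gene tables.

The central container is :class:`CellExpressionDataset`: a cells x genes
raw-count matrix with cell annotations (``cell_type`` required; ``stage`` and
``organ`` optional) and, after :func:`normalize_log1p`, a log-normalized layer
on the same axes.  All public contracts address matrices by cell/gene ID, never
by position.  Readers cover the Matrix Market triplet bundle
(matrix.mtx + genes.tsv + barcodes.tsv + cell-metadata TSV) and h5ad.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ContractError, DegenerateInputError, FormatError, SchemaError

logger = logging.getLogger(__name__)

DEFAULT_TARGET_SUM = 10_000.0
DEFAULT_MIN_GENES_PER_CELL = 200
DEFAULT_MIN_CELLS_PER_GENE = 3


@dataclass
class CellExpressionDataset:
    """Raw counts plus (optionally) log-normalized expression for one dataset.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells x genes (CSR).
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    obs
        Per-cell annotation indexed by ``cell_ids``; must contain
        ``cell_type``, may contain ``stage`` and ``organ``.
    normalized
        Log-normalized layer, populated by :func:`normalize_log1p`.
    """

    counts: sp.csr_matrix
    cell_ids: pd.Index
    gene_ids: pd.Index
    obs: pd.DataFrame
    normalized: sp.csr_matrix | None = None
    dataset_label: str = ""

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = pd.Index(self.cell_ids, dtype=object)
        self.gene_ids = pd.Index(self.gene_ids, dtype=object)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.cell_ids.has_duplicates:
            raise FormatError("duplicate cell identifiers")
        if self.gene_ids.has_duplicates:
            raise FormatError("duplicate gene identifiers")
        if "cell_type" not in self.obs.columns:
            raise SchemaError("cell metadata lacks required column 'cell_type'")
        if self.normalized is not None:
            self.normalized = sp.csr_matrix(self.normalized)
            if self.normalized.shape != self.counts.shape:
                raise FormatError("normalized layer shape differs from counts")
        self.obs = self.obs.loc[self.cell_ids]

    # -- basic views ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_type(self) -> pd.Series:
        return self.obs["cell_type"]

    @property
    def stage(self) -> pd.Series | None:
        return self.obs["stage"] if "stage" in self.obs.columns else None

    @property
    def organ(self) -> pd.Series | None:
        return self.obs["organ"] if "organ" in self.obs.columns else None

    def require_normalized(self) -> sp.csr_matrix:
        if self.normalized is None:
            raise DegenerateInputError(
                "normalized layer not populated; run normalize_log1p first"
            )
        return self.normalized

    def gene_indexer(self, genes: Iterable[str]) -> np.ndarray:
        """Positions of ``genes`` in this dataset's gene axis (all must map)."""
        idx = self.gene_ids.get_indexer(list(genes))
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise KeyError(f"genes not in dataset: {missing[:5]}...")
        return idx

    def subset(
        self,
        cells: np.ndarray | None = None,
        genes: np.ndarray | None = None,
    ) -> "CellExpressionDataset":
        """Positional subset along either axis, keeping layers aligned."""
        counts = self.counts
        normalized = self.normalized
        cell_ids, gene_ids, obs = self.cell_ids, self.gene_ids, self.obs
        if cells is not None:
            counts = counts[cells]
            normalized = normalized[cells] if normalized is not None else None
            cell_ids = cell_ids[cells]
            obs = obs.iloc[np.asarray(cells).nonzero()[0]] if np.asarray(cells).dtype == bool else obs.iloc[cells]
        if genes is not None:
            counts = counts[:, genes]
            normalized = normalized[:, genes] if normalized is not None else None
            gene_ids = gene_ids[genes]
        return CellExpressionDataset(
            counts=counts,
            cell_ids=cell_ids,
            gene_ids=gene_ids,
            obs=obs,
            normalized=normalized,
            dataset_label=self.dataset_label,
        )

    def to_anndata(self):
        """Export as :class:`anndata.AnnData` (counts in ``layers['counts']``)."""
        import anndata as ad

        X = self.normalized if self.normalized is not None else self.counts
        adata = ad.AnnData(
            X=X.copy(),
            obs=self.obs.copy(),
            var=pd.DataFrame(index=self.gene_ids),
        )
        adata.obs_names = self.cell_ids
        adata.layers["counts"] = self.counts.copy()
        return adata


@dataclass
class GeneSet:
    """A curated disease gene set with HGNC symbols and Ensembl IDs."""

    entries: pd.DataFrame  # columns: hgnc_symbol, ensembl_id, evidence, inheritance
    name: str = "gene_set"

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise SchemaError(f"gene set '{self.name}' is empty")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def symbols(self) -> list[str]:
        return self.entries["hgnc_symbol"].tolist()

    @property
    def ensembl_ids(self) -> list[str]:
        return self.entries["ensembl_id"].tolist()

    def map_to(self, gene_ids: pd.Index) -> tuple[list[str], list[str]]:
        """Resolve members against a dataset gene axis.

        Ensembl IDs take priority; HGNC symbols are the fallback.  Returns
        ``(mapped_dataset_ids, unmapped_labels)``; unmapped members are
        reported, not fatal — the pipeline proceeds on the mapped subset.
        """
        mapped: list[str] = []
        unmapped: list[str] = []
        seen: set[str] = set()
        universe = set(gene_ids)
        for _, row in self.entries.iterrows():
            ens = row.get("ensembl_id")
            sym = row.get("hgnc_symbol")
            hit = None
            if isinstance(ens, str) and ens in universe:
                hit = ens
            elif isinstance(sym, str) and sym in universe:
                hit = sym
            if hit is None:
                unmapped.append(sym if isinstance(sym, str) else str(ens))
            elif hit not in seen:
                seen.add(hit)
                mapped.append(hit)
        if unmapped:
            logger.warning(
                "%d/%d gene-set members not found in dataset: %s%s",
                len(unmapped),
                len(self.entries),
                ", ".join(unmapped[:8]),
                "..." if len(unmapped) > 8 else "",
            )
        return mapped, unmapped


@dataclass
class GeneAnnotation:
    """Gene-level annotation: length in bp (and optionally symbol)."""

    lengths: pd.Series  # gene_id -> length (bp)
    symbols: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        self.lengths = self.lengths.astype(float)
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][:5].tolist()
            raise SchemaError(f"non-positive gene lengths for {bad}")

    def coverage(self, gene_ids: pd.Index) -> float:
        """Fraction of ``gene_ids`` with a length entry."""
        return float(gene_ids.isin(self.lengths.index).mean())


@dataclass
class QCReport:
    """Cells/genes removed by :func:`qc_filter`."""

    n_cells_removed: int
    n_genes_removed: int
    min_genes_per_cell: int
    min_cells_per_gene: int


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_single_column(path: str | Path) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


def read_mtx_dataset(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    cell_meta_path: str | Path,
    dataset_label: str = "",
) -> CellExpressionDataset:
    """Read a CellRanger-style MTX triplet plus a cell-metadata TSV.

    The matrix is stored genes x cells (CellRanger convention) and transposed
    to cells x genes on read.  Cells without a metadata row are dropped with a
    logged count; a missing ``cell_type`` column is a schema error.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"cannot parse {matrix_path} as Matrix Market: {exc}") from exc
    genes = _read_single_column(genes_path)
    barcodes = _read_single_column(barcodes_path)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix is {mat.shape[0]} genes x {mat.shape[1]} cells but "
            f"genes.tsv has {len(genes)} rows and barcodes.tsv {len(barcodes)}"
        )
    counts = sp.csr_matrix(mat.T)
    meta = pd.read_csv(cell_meta_path, sep="\t", index_col=0, comment="#")
    if "cell_type" not in meta.columns:
        raise SchemaError(
            f"{cell_meta_path} lacks required column 'cell_type' "
            f"(found {list(meta.columns)})"
        )
    keep = pd.Index(barcodes).isin(meta.index)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d cells without metadata rows", n_dropped)
    barcodes_kept = pd.Index(barcodes)[keep]
    return CellExpressionDataset(
        counts=counts[np.flatnonzero(keep)],
        cell_ids=barcodes_kept,
        gene_ids=pd.Index(genes),
        obs=meta.loc[barcodes_kept],
        dataset_label=dataset_label,
    )


def write_mtx_dataset(ds: CellExpressionDataset, out_dir: str | Path) -> Path:
    """Write the MTX triplet bundle consumed by :func:`read_mtx_dataset`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(ds.counts.T), field="integer")
    (out / "genes.tsv").write_text("\n".join(ds.gene_ids) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(ds.cell_ids) + "\n")
    ds.obs.to_csv(out / "cell_meta.tsv", sep="\t", index_label="barcode")
    return out


def read_h5ad_dataset(path: str | Path, dataset_label: str = "") -> CellExpressionDataset:
    """Read an h5ad file; counts are taken from ``layers['counts']`` or X."""
    import anndata as ad

    adata = ad.read_h5ad(str(path))
    if "cell_type" not in adata.obs.columns:
        raise SchemaError(f"{path}: obs lacks required column 'cell_type'")
    counts = adata.layers.get("counts", adata.X)
    return CellExpressionDataset(
        counts=sp.csr_matrix(counts),
        cell_ids=pd.Index(adata.obs_names),
        gene_ids=pd.Index(adata.var_names),
        obs=adata.obs.copy(),
        dataset_label=dataset_label or str(path),
    )


_SYMBOL_COLS = ("hgnc_symbol", "symbol", "gene_symbol", "gene")
_ENSEMBL_COLS = ("ensembl_id", "ensembl", "ensembl_gene_id")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a disease gene-set TSV with symbol and/or Ensembl-ID columns.

    Rows are deduplicated on Ensembl ID (falling back to symbol); duplicates
    are logged.  An empty file is a schema error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty:
        raise SchemaError(f"{path} contains no gene rows")
    cols = {c.lower(): c for c in df.columns}
    sym_col = next((cols[c] for c in _SYMBOL_COLS if c in cols), None)
    ens_col = next((cols[c] for c in _ENSEMBL_COLS if c in cols), None)
    if sym_col is None and ens_col is None:
        raise SchemaError(
            f"{path} has neither a symbol column ({_SYMBOL_COLS}) nor an "
            f"Ensembl column ({_ENSEMBL_COLS})"
        )
    entries = pd.DataFrame(
        {
            "hgnc_symbol": df[sym_col] if sym_col else pd.Series([None] * len(df)),
            "ensembl_id": df[ens_col] if ens_col else pd.Series([None] * len(df)),
        }
    )
    for extra in ("evidence", "inheritance"):
        if extra in cols:
            entries[extra] = df[cols[extra]]
    key = entries["ensembl_id"].where(entries["ensembl_id"].notna(), entries["hgnc_symbol"])
    dup = key.duplicated()
    if dup.any():
        logger.warning("%d duplicate gene rows in %s dropped", int(dup.sum()), path)
    entries = entries[~dup].reset_index(drop=True)
    return GeneSet(entries=entries, name=name or Path(path).stem)


def load_cakut_gene_set() -> GeneSet:
    """Load the packaged CAKUT gene-set fixture.

    This is a reconstructed stand-in for the published curated list (synthetic
    Ensembl placeholder IDs; symbols assembled from the CAKUT genetics
    literature), shipped so the pipeline is exercisable without downloads.
    """
    with resources.as_file(
        resources.files("screlmap.data") / "cakut_genes_synthetic.tsv"
    ) as p:
        return read_gene_set(p, name="CAKUT")


def read_gene_lengths(path: str | Path) -> GeneAnnotation:
    """Read a gene-length TSV with columns ``gene_id`` and ``length_bp``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    if "gene_id" not in cols or "length_bp" not in cols:
        raise SchemaError(f"{path} must have columns gene_id and length_bp")
    lengths = df.set_index(cols["gene_id"])[cols["length_bp"]].astype(float)
    symbols = (
        df.set_index(cols["gene_id"])[cols["symbol"]]
        if "symbol" in cols
        else pd.Series(dtype=object)
    )
    return GeneAnnotation(lengths=lengths, symbols=symbols)


def lengths_from_gtf(path: str | Path, feature: str = "exon") -> GeneAnnotation:
    """Union-exon gene lengths from a GTF file.

    Per gene, overlapping exon intervals are merged and their total span
    summed — union-exon length tracks transcript detectability better than
    genomic span.  A user-supplied length table overrides this helper.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature:
                continue
            attrs = f[8]
            gid = None
            for piece in attrs.split(";"):
                piece = piece.strip()
                if piece.startswith("gene_id"):
                    gid = piece.split(" ", 1)[1].strip().strip('"')
                    break
            if gid is None:
                continue
            spans.setdefault(gid, []).append((int(f[3]), int(f[4])))
    if not spans:
        raise SchemaError(f"no '{feature}' features with gene_id found in {path}")
    lengths = {}
    for gid, ivals in spans.items():
        ivals.sort()
        total, cur_s, cur_e = 0, *ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
        lengths[gid] = total
    return GeneAnnotation(lengths=pd.Series(lengths, dtype=float))


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def qc_filter(
    ds: CellExpressionDataset,
    min_genes_per_cell: int = DEFAULT_MIN_GENES_PER_CELL,
    min_cells_per_gene: int = DEFAULT_MIN_CELLS_PER_GENE,
) -> tuple[CellExpressionDataset, QCReport]:
    """Remove low-quality cells, then rarely detected genes.

    Cells with fewer than ``min_genes_per_cell`` detected genes are removed
    first; genes detected in fewer than ``min_cells_per_gene`` of the
    remaining cells are removed second.  Idempotent at fixed thresholds.
    """
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise ContractError("QC thresholds must be non-negative")
    detected = ds.counts > 0
    genes_per_cell = np.asarray(detected.sum(axis=1)).ravel()
    keep_cells = genes_per_cell >= min_genes_per_cell
    if not keep_cells.any():
        raise DegenerateInputError(
            f"QC removed all {ds.n_cells} cells at min_genes_per_cell="
            f"{min_genes_per_cell}"
        )
    cells_per_gene = np.asarray(detected[np.flatnonzero(keep_cells)].sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= min_cells_per_gene
    out = ds.subset(cells=np.flatnonzero(keep_cells), genes=np.flatnonzero(keep_genes))
    report = QCReport(
        n_cells_removed=int((~keep_cells).sum()),
        n_genes_removed=int((~keep_genes).sum()),
        min_genes_per_cell=min_genes_per_cell,
        min_cells_per_gene=min_cells_per_gene,
    )
    if report.n_cells_removed or report.n_genes_removed:
        logger.info(
            "QC removed %d cells and %d genes",
            report.n_cells_removed,
            report.n_genes_removed,
        )
    return out, report



def normalize_log1p(
    ds: CellExpressionDataset, target_sum: float = DEFAULT_TARGET_SUM
) -> CellExpressionDataset:
    """Library-size normalize to ``target_sum`` counts per cell, then log1p.

    normalized[i, g] = ln(1 + counts[i, g] * target_sum / total_i).  The
    counts layer is untouched.  Cells with zero total counts are a degenerate
    input: run :func:`qc_filter` first.
    """
    totals = np.asarray(ds.counts.sum(axis=1)).ravel().astype(float)
    if (totals <= 0).any():
        n = int((totals <= 0).sum())
        raise DegenerateInputError(
            f"{n} cells have zero total counts; apply qc_filter before "
            "normalization"
        )
    scaled = sp.csr_matrix(ds.counts, dtype=float)
    scale = target_sum / totals
    scaled = sp.diags(scale) @ scaled
    normalized = scaled.copy()
    normalized.data = np.log1p(normalized.data)
    return replace(ds, normalized=sp.csr_matrix(normalized))


def write_result_tsv(
    df: pd.DataFrame,
    path: str | Path,
    params: Mapping[str, object] | None = None,
    index_label: str | None = None,
) -> Path:
    """Write a result table with ``#``-prefixed header lines recording
    parameters and seed for provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (params or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None, index_label=index_label)
    return path
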