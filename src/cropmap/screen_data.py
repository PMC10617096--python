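"""Data model, readers and QC filters for single-cell CRISPR screen inputs.

The central container is :class:`ScreenMatrix`: a sparse cell x gene UMI count
matrix plus a per-cell metadata frame (barcode, QC statistics, guide
assignment, culture condition).  Readers consume the CellRanger v3 triplet
dialect (MatrixMarket ``matrix.mtx`` with ``features.tsv`` / ``barcodes.tsv``,
optionally gzipped) and plain TSV tables for the guide library and per-cell
sgRNA assignments.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "GuideEntry",
    "GuideLibrary",
    "LibrarySummary",
    "ScreenMatrix",
    "FormatError",
    "read_counts_mtx",
    "read_guide_assignments",
    "qc_filter_cells",
    "select_unique_sgrna_cells",
    "normalize_log",
    "summarize_library",
]

NT_TARGET = "NT"


class FormatError(ValueError):
    """An input file violates the expected on-disk dialect."""


# ---------------------------------------------------------------------------
# Guide library
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GuideEntry:
    sgrna_id: str
    target_gene: str | None
    is_nt: bool

    def __post_init__(self) -> None:
        if self.is_nt and self.target_gene:
            raise ValueError(f"NT guide {self.sgrna_id!r} must not carry a target gene")
        if not self.is_nt and not self.target_gene:
            raise ValueError(f"targeting guide {self.sgrna_id!r} needs a target gene")


class LibrarySummary(NamedTuple):
    n_targeting: int
    n_nt: int
    n_total: int
    n_genes: int


@dataclass
class GuideLibrary:
    """The sgRNA library: targeting guides (several per gene) plus NT controls."""

    entries: list[GuideEntry]

    def __post_init__(self) -> None:
        ids = [e.sgrna_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sgRNA ids in library: {dup}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, sgrna_id: str) -> bool:
        return sgrna_id in self._by_id

    @property
    def _by_id(self) -> dict[str, GuideEntry]:
        return {e.sgrna_id: e for e in self.entries}

    def target_of(self, sgrna_id: str) -> str | None:
        return self._by_id[sgrna_id].target_gene

    def is_nt(self, sgrna_id: str) -> bool:
        return self._by_id[sgrna_id].is_nt

    @property
    def target_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            if not e.is_nt and e.target_gene not in seen:
                seen[e.target_gene] = None
        return list(seen)

    def summarize(self) -> LibrarySummary:
        return summarize_library(self)

    @classmethod
    def from_table(cls, path: str | Path) -> "GuideLibrary":
        """Read a tab-separated library table (columns: sgrna_id, target_gene, is_nt)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sgrna_id", "target_gene", "is_nt"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        entries = []
        for row in df.itertuples(index=False):
            is_nt = str(row.is_nt).strip().lower() in {"1", "true", "yes", "nt"}
            target = None if is_nt else str(row.target_gene)
            entries.append(GuideEntry(str(row.sgrna_id), target, is_nt))
        return cls(entries)

    def to_table(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "sgrna_id": [e.sgrna_id for e in self.entries],
                "target_gene": [e.target_gene or NT_TARGET for e in self.entries],
                "is_nt": [str(e.is_nt).lower() for e in self.entries],
            }
        ).to_csv(path, sep="\t", index=False)


def summarize_library(lib: GuideLibrary) -> LibrarySummary:
    """Count targeting guides, NT controls and distinct target genes.

    The gene count is always derived from the table itself, never assumed
    from the nominal design.
    """
    n_nt = sum(e.is_nt for e in lib.entries)
    n_targeting = len(lib.entries) - n_nt
    n_genes = len({e.target_gene for e in lib.entries if not e.is_nt})
    return LibrarySummary(n_targeting, n_nt, n_targeting + n_nt, n_genes)


# ---------------------------------------------------------------------------
# Screen matrix
# ---------------------------------------------------------------------------


@dataclass
class ScreenMatrix:
    """Sparse cell x gene UMI counts with per-cell metadata.

    ``obs`` is indexed by barcode and carries at least ``n_genes_detected``,
    ``total_umi`` and ``mito_fraction``; ``sgrna_id`` / ``target_gene`` /
    ``is_nt`` appear after unique-sgRNA selection and ``condition`` when
    supplied.  ``normalized``, when present, is the log1p CP-scaled matrix of
    identical shape.
    """

    counts: sp.csr_matrix
    genes: pd.Index
    obs: pd.DataFrame
    normalized: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = pd.Index(self.genes)
        if self.counts.shape != (len(self.obs), len(self.genes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.obs)} cells x {len(self.genes)} genes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.normalized is not None and self.normalized.shape != self.counts.shape:
            raise ValueError("normalized layer shape mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> pd.Index:
        return self.obs.index

    def subset_cells(self, mask_or_barcodes) -> "ScreenMatrix":
        if isinstance(mask_or_barcodes, (pd.Index, list, np.ndarray)) and not (
            isinstance(mask_or_barcodes, np.ndarray) and mask_or_barcodes.dtype == bool
        ):
            idx = self.obs.index.get_indexer(pd.Index(mask_or_barcodes))
            if (idx < 0).any():
                raise KeyError("unknown barcodes in selection")
        else:
            idx = np.flatnonzero(np.asarray(mask_or_barcodes))
        return ScreenMatrix(
            counts=self.counts[idx],
            genes=self.genes,
            obs=self.obs.iloc[idx].copy(),
            normalized=None if self.normalized is None else self.normalized[idx],
        )

    def subset_genes(self, mask_or_names) -> "ScreenMatrix":
        if isinstance(mask_or_names, np.ndarray) and mask_or_names.dtype == bool:
            idx = np.flatnonzero(mask_or_names)
        else:
            idx = self.genes.get_indexer(pd.Index(mask_or_names))
            if (idx < 0).any():
                raise KeyError("unknown genes in selection")
        obs = self.obs.copy()
        return ScreenMatrix(
            counts=self.counts[:, idx],
            genes=self.genes[idx],
            obs=obs,
            normalized=None if self.normalized is None else self.normalized[:, idx],
        )

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=self.obs.copy(),
            var=pd.DataFrame(index=self.genes),
        )
        if self.normalized is not None:
            adata.layers["lognorm"] = self.normalized.copy()
        return adata


def compute_qc_metrics(m: ScreenMatrix, mito_prefix: str = "mt-") -> ScreenMatrix:
    """(Re)compute per-cell QC columns: genes detected, total UMI, mito fraction."""
    counts = m.counts
    n_genes_detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    total = np.asarray(counts.sum(axis=1)).ravel()
    is_mito = np.asarray(m.genes.str.lower().str.startswith(mito_prefix.lower()), dtype=bool)
    mito = np.asarray(counts[:, is_mito].sum(axis=1)).ravel() if is_mito.any() else np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    obs = m.obs.copy()
    obs["n_genes_detected"] = n_genes_detected.astype(int)
    obs["total_umi"] = total.astype(int)
    obs["mito_fraction"] = frac
    return replace(m, obs=obs)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_tsv_column(path: Path, which: str) -> list[str]:
    with _open_maybe_gz(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if which == "barcode":
        return [r[0] for r in rows]
    # CellRanger v3 features file: id, symbol, feature_type; symbol is column 2
    # when present, otherwise the single column is the symbol.
    return [r[1] if len(r) >= 2 else r[0] for r in rows]


def _dedup_symbols(symbols: Sequence[str]) -> pd.Index:
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return pd.Index(out)


def read_counts_mtx(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    mito_prefix: str = "mt-",
) -> ScreenMatrix:
    """Read a CellRanger-style MTX triplet into a cell x gene :class:`ScreenMatrix`.

    The on-disk matrix may be oriented either way; orientation is resolved
    against the features/barcodes lengths.  Duplicate gene symbols are
    deduplicated deterministically with ``.1``, ``.2`` suffixes in file order.
    """
    matrix_path, features_path, barcodes_path = map(Path, (matrix_path, features_path, barcodes_path))
    genes = _read_tsv_column(features_path, "symbol")
    barcodes = _read_tsv_column(barcodes_path, "barcode")
    with _open_maybe_gz(matrix_path, "rb" if str(matrix_path).endswith(".gz") else "r") as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.coo_matrix(mat)
    n_r, n_c = mat.shape
    if (n_r, n_c) == (len(genes), len(barcodes)):
        mat = mat.T  # CellRanger writes genes x cells
    elif (n_r, n_c) == (len(barcodes), len(genes)):
        pass
    else:
        raise FormatError(
            f"{matrix_path}: matrix is {n_r}x{n_c} but features has "
            f"{len(genes)} rows and barcodes has {len(barcodes)} rows"
        )
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{matrix_path}: UMI counts must be integers")
    counts = sp.csr_matrix(mat).astype(np.int64)
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    m = ScreenMatrix(counts=counts, genes=_dedup_symbols(genes), obs=obs)
    return compute_qc_metrics(m, mito_prefix=mito_prefix)


def read_guide_assignments(
    table_path: str | Path, library: GuideLibrary
) -> dict[str, list[str]]:
    """Read the per-cell sgRNA assignment table (columns barcode, sgrna_id).

    Returns barcode -> list of sgRNA ids, preserving one list entry per table
    row (so multiplicity of detection is kept).  Every sgRNA id must exist in
    the library.
    """
    df = pd.read_csv(table_path, sep="\t", dtype=str)
    missing_cols = {"barcode", "sgrna_id"} - set(df.columns)
    if missing_cols:
        raise FormatError(f"{table_path}: missing columns {sorted(missing_cols)}")
    known = {e.sgrna_id for e in library.entries}
    unknown = sorted(set(df["sgrna_id"]) - known)
    if unknown:
        raise ValueError(f"sgRNA ids absent from the guide library: {unknown}")
    mapping: dict[str, list[str]] = {}
    for bc, sg in zip(df["barcode"], df["sgrna_id"]):
        mapping.setdefault(bc, []).append(sg)
    return mapping


# ---------------------------------------------------------------------------
# Filters and normalization
# ---------------------------------------------------------------------------


def qc_filter_cells(
    m: ScreenMatrix,
    min_genes: int = 200,
    max_genes: int = 6000,
    max_mito: float = 0.10,
    mito_prefix: str = "mt-",
) -> ScreenMatrix:
    """Retain cells with min_genes < genes detected < max_genes and
    mitochondrial fraction < max_mito (all bounds strict)."""
    if "n_genes_detected" not in m.obs:
        m = compute_qc_metrics(m, mito_prefix=mito_prefix)
    ng = m.obs["n_genes_detected"].to_numpy()
    mito = m.obs["mito_fraction"].to_numpy()
    keep = (ng > min_genes) & (ng < max_genes) & (mito < max_mito)
    if not keep.any():
        warnings.warn("QC filtering removed every cell", stacklevel=2)
    return m.subset_cells(keep)


def select_unique_sgrna_cells(
    m: ScreenMatrix,
    assignments: Mapping[str, Sequence[str]],
    library: GuideLibrary,
) -> ScreenMatrix:
    """Keep only cells assigned exactly one distinct sgRNA; annotate guide and target.

    Cells absent from ``assignments`` (no guide detected) are dropped here,
    as are cells with two or more distinct guides.
    """
    keep_barcodes, sgrnas = [], []
    for bc in m.barcodes:
        guides = set(assignments.get(bc, ()))
        if len(guides) == 1:
            keep_barcodes.append(bc)
            sgrnas.append(next(iter(guides)))
    out = m.subset_cells(pd.Index(keep_barcodes))
    out.obs["sgrna_id"] = sgrnas
    out.obs["target_gene"] = [library.target_of(g) or NT_TARGET for g in sgrnas]
    out.obs["is_nt"] = [library.is_nt(g) for g in sgrnas]
    return out


def normalize_log(m: ScreenMatrix, scale: float = 1e4, base: float | None = None) -> ScreenMatrix:
    """Depth-normalize to ``scale`` counts per cell and log1p-transform.

    normalized[c, g] = log(1 + counts[c, g] * scale / total_umi[c]), natural
    log by default.  Zero-total cells must have been removed by QC first.
    """
    total = np.asarray(m.counts.sum(axis=1)).ravel()
    if (total == 0).any():
        raise ValueError("zero-total cells present; run qc_filter_cells first")
    norm = sp.csr_matrix(m.counts, dtype=np.float64, copy=True)
    norm = sp.diags(scale / total) @ norm
    norm.data = np.log1p(norm.data)
    if base is not None:
        norm.data /= np.log(base)
    return replace(m, normalized=sp.csr_matrix(norm))


def cp_scale_matrix(m: ScreenMatrix, scale: float = 1e4) -> sp.csr_matrix:
    """Linear depth-normalized matrix (counts-per-``scale``), without the log."""
    total = np.asarray(m.counts.sum(axis=1)).ravel()
    if (total == 0).any():
        raise ValueError("zero-total cells present; run qc_filter_cells first")
    return sp.csr_matrix(sp.diags(scale / total) @ sp.csr_matrix(m.counts, dtype=np.float64))


# ---------------------------------------------------------------------------
# Writers (the simulator round-trips through these)
# ---------------------------------------------------------------------------


def write_counts_mtx(m: ScreenMatrix, out_dir: str | Path) -> None:
    """Write matrix.mtx / features.tsv / barcodes.tsv (genes x cells on disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(m.counts.T), field="integer")
    with open(out / "features.tsv", "w") as fh:
        for g in m.genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(out / "barcodes.tsv", "w") as fh:
        for b in m.barcodes:
            fh.write(f"{b}\n")


def write_guide_assignments(
    assignments: Mapping[str, Sequence[str]], path: str | Path
) -> None:
    rows = [(bc, sg) for bc in assignments for sg in assignments[bc]]
    pd.DataFrame(rows, columns=["barcode", "sgrna_id"]).to_csv(path, sep="\t", index=False)
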