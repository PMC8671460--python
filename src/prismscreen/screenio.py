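"""Readers, writers and containers for pooled-screen and expression data.

The screen matrix dialect follows the DepMap repurposing release: a CSV with
one row per screened compound (row label = screen id), one column per cell
line, and log fold-change (logFC) of barcode abundance relative to the DMSO
vehicle as values.  More negative logFC means more cell killing.  Cell-line
and compound annotations arrive as separate tables keyed on the same ids.

Expression matrices follow the CCLE dialect: log2(TPM+1) values with gene
headers written as ``"SYMBOL (entrezID)"``.  GCT 1.2 and GMT are supported as
the exchange formats used by enrichment tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DrugResponseMatrix",
    "CATEGORIES",
    "read_logfc_matrix",
    "collapse_replicates",
    "read_expression",
    "parse_gene_header",
    "read_gct",
    "write_gct",
    "read_gmt",
]

#: Closed set of compound categories used throughout the analysis.
CATEGORIES = frozenset({"targeted cancer", "chemotherapy", "non-oncology"})


@dataclass
class DrugResponseMatrix:
    """Compounds x cell-lines logFC matrix with optional annotations.

    Parameters
    ----------
    values
        DataFrame indexed by compound id, columns = cell-line ids, float
        logFC values; NaN marks a missing (not screened) data point.
    compound_info
        Optional DataFrame indexed by compound id with columns such as
        ``name``, ``category``, ``moa``, ``target``, ``phase``.
    line_info
        Optional DataFrame indexed by line id with columns such as
        ``lineage`` and ``subtype``.
    """

    values: pd.DataFrame
    compound_info: pd.DataFrame | None = None
    line_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate compound ids after collapsing")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate cell line ids")
        vals = self.values.to_numpy(dtype=float, copy=False)
        finite_or_nan = np.isfinite(vals) | np.isnan(vals)
        if not finite_or_nan.all():
            raise ValueError("non-finite logFC values present")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def restrict_lines(self, line_ids) -> "DrugResponseMatrix":
        keep = [l for l in self.values.columns if l in set(line_ids)]
        line_info = self.line_info.loc[keep] if self.line_info is not None else None
        return DrugResponseMatrix(self.values[keep], self.compound_info, line_info)


def collapse_replicates(values: pd.DataFrame, identity: pd.Series | None = None) -> pd.DataFrame:
    """Average replicate rows that share a compound identity.

    ``identity`` maps the raw row id to the compound identity used for the
    collapse (typically the compound name); rows without an identity keep
    their own id.  Missing values are ignored in the mean, so a value present
    in only one replicate survives.
    """
    if identity is None:
        key = values.index.to_series()
    else:
        key = values.index.to_series().map(identity).fillna(values.index.to_series())
    collapsed = values.groupby(key.to_numpy()).mean()
    collapsed.index.name = values.index.name
    return collapsed.sort_index()


def _pick_column(frame: pd.DataFrame, candidates: tuple[str, ...]) -> str | None:
    for c in candidates:
        if c in frame.columns:
            return c
    return None


def read_logfc_matrix(
    matrix_file,
    line_info_file=None,
    compound_info_file=None,
    lineage: str | None = None,
) -> DrugResponseMatrix:
    """Read a screen logFC CSV with optional line / compound annotation joins.

    Cell-line columns that cannot be mapped through ``line_info_file`` are
    dropped with a warning; two screen columns mapping to the same line name
    is an error.  Replicate compound rows (same annotated name) are collapsed
    by the per-line arithmetic mean.  ``lineage`` optionally restricts the
    columns to lines of that lineage (e.g. ``"upper_aerodigestive"``).
    """
    raw = pd.read_csv(matrix_file, index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)

    line_info = None
    if line_info_file is not None:
        li = pd.read_csv(line_info_file)
        id_col = _pick_column(li, ("row_name", "column_name", "line_id")) or li.columns[0]
        name_col = _pick_column(li, ("ccle_name", "name", "cell_line_name")) or id_col
        li = li.drop_duplicates(subset=id_col).set_index(id_col)
        mapped, unmapped = [], []
        for col in raw.columns:
            (mapped if col in li.index else unmapped).append(col)
        if unmapped:
            warnings.warn(
                f"dropping {len(unmapped)} screen column(s) with no cell-line mapping: "
                + ", ".join(unmapped[:5]),
                stacklevel=2,
            )
        raw = raw[mapped]
        names = li.loc[mapped, name_col].astype(str)
        if names.duplicated().any():
            dupes = sorted(set(names[names.duplicated()]))
            raise ValueError(f"duplicate cell line id(s) after mapping: {dupes}")
        raw.columns = names.to_numpy()
        line_info = li.loc[mapped].set_index(names.to_numpy())

    identity = None
    compound_info = None
    if compound_info_file is not None:
        ci = pd.read_csv(compound_info_file)
        id_col = _pick_column(ci, ("column_name", "broad_id", "compound_id")) or ci.columns[0]
        name_col = _pick_column(ci, ("name", "compound_name"))
        ci = ci.drop_duplicates(subset=id_col).set_index(id_col)
        if name_col is not None:
            identity = ci[name_col].astype(str)
        compound_info = ci

    collapsed = collapse_replicates(raw, identity)

    if compound_info is not None and identity is not None:
        # re-key annotations on the collapsed (name-level) identity, first hit wins
        ann = compound_info.copy()
        ann.index = identity.reindex(ann.index).fillna(ann.index.to_series())
        ann = ann[~ann.index.duplicated(keep="first")]
        compound_info = ann.reindex(collapsed.index)

    drm = DrugResponseMatrix(collapsed, compound_info, line_info)
    if lineage is not None:
        if drm.line_info is None or "lineage" not in drm.line_info.columns:
            raise ValueError("lineage filter requires line annotations with a 'lineage' column")
        keep = drm.line_info.index[drm.line_info["lineage"] == lineage]
        drm = drm.restrict_lines(keep)
    return drm


def parse_gene_header(header: str) -> str:
    """Extract the gene symbol from a ``"SYMBOL (entrezID)"`` header cell."""
    return header.split(" (")[0].strip()


def read_expression(file) -> pd.DataFrame:
    """Read a log2(TPM+1) expression CSV, returning a genes x lines DataFrame.

    Accepts either orientation: if the column headers carry the
    ``"SYMBOL (entrez)"`` dialect the matrix is lines x genes (the CCLE
    layout) and is transposed.  Symbols duplicated after parsing keep the
    first occurrence.  Negative values violate the log2(TPM+1) >= 0 contract
    and raise.
    """
    frame = pd.read_csv(file, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)

    cols_look_like_genes = any(" (" in c for c in frame.columns)
    rows_look_like_genes = any(" (" in r for r in frame.index)
    if cols_look_like_genes and not rows_look_like_genes:
        frame = frame.T  # lines x genes -> genes x lines

    frame.index = [parse_gene_header(g) for g in frame.index]
    if pd.Index(frame.index).has_duplicates:
        warnings.warn("duplicate gene symbols after parsing; keeping first", stacklevel=2)
        frame = frame[~pd.Index(frame.index).duplicated(keep="first")]

    vals = frame.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("negative expression value: log2(TPM+1) must be >= 0")
    return frame


def write_gct(expr: pd.DataFrame, path) -> None:
    """Write a genes x lines matrix as GCT 1.2 (NAME, Description, lines...)."""
    path = Path(path)
    n_genes, n_lines = expr.shape
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_genes}\t{n_lines}\n")
        fh.write("NAME\tDescription\t" + "\t".join(map(str, expr.columns)) + "\n")
        for gene, row in expr.iterrows():
            fields = [str(gene), "na"] + [format(v, ".6g") for v in row.to_numpy()]
            fh.write("\t".join(fields) + "\n")


def read_gct(path) -> pd.DataFrame:
    """Read a GCT 1.2 file back into a genes x lines DataFrame."""
    path = Path(path)
    with path.open() as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ValueError(f"unsupported GCT version line: {version!r}")
        counts = fh.readline().split()
        if len(counts) < 2:
            raise ValueError("malformed GCT count line")
        try:
            n_genes, n_lines = int(counts[0]), int(counts[1])
        except ValueError as exc:
            raise ValueError("malformed GCT count line") from exc
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != n_lines + 2:
            raise ValueError("GCT header inconsistent with declared column count")
        lines = header[2:]
        genes, rows = [], []
        for ln in fh:
            if not ln.strip():
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) != n_lines + 2:
                raise ValueError("GCT data row inconsistent with declared column count")
            genes.append(fields[0])
            rows.append([float(v) for v in fields[2:]])
    if len(genes) != n_genes:
        raise ValueError(f"GCT declares {n_genes} rows but contains {len(genes)}")
    return pd.DataFrame(rows, index=genes, columns=lines, dtype=float)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into an ordered name -> gene-list map.

    Genes are de-duplicated within a set (first occurrence kept); lines with
    fewer than three fields are skipped with a warning.
    """
    sets: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for i, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) < 3:
                warnings.warn(f"skipping GMT line {i}: fewer than 3 fields", stacklevel=2)
                continue
            name = fields[0]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
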