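"""Single-cell DEG hygiene: expression prefilter and ambient-RNA exclusion.

Droplet single-cell libraries carry cell-free (ambient) transcripts that
make highly expressed markers of one cell type appear differentially
expressed in others.  Downstream of model-based decontamination, a
conservative heuristic removes the remaining suspects: a DEG of cell type
*c* is excluded iff it is BOTH (1) among the top 5 markers of a *different*
cell type and (2) among the top 50 most highly expressed genes of the whole
dataset.  Either criterion alone does not exclude.

The module also implements the upstream gene prefilter (expressed in
> 1% of cells and > 1 UMI in > 5 cells) and the dataset-wide expression
ranking the exclusion rule consumes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .sig_io import GerosigError

MARKER_COLUMNS = ("cell_type", "gene", "rank", "statistic")


def _as_dense(counts) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        return counts
    raise GerosigError("counts must be a genes x cells DataFrame")


def prefilter_genes(
    counts: pd.DataFrame,
    min_frac: float = 0.01,
    min_cells: int = 5,
    min_umi: int = 1,
) -> list[str]:
    """Genes passing the single-cell expression prefilter.

    A gene (row) is kept iff the fraction of cells with any count exceeds
    ``min_frac`` AND the number of cells with more than ``min_umi`` counts
    exceeds ``min_cells`` — both strict, matching the "> 0.01 of cells" and
    "> 5 cells with > 1 UMIs" convention.
    """
    counts = _as_dense(counts)
    n_cells = counts.shape[1]
    if n_cells == 0:
        raise GerosigError("counts matrix has zero cells")
    if (counts.to_numpy() < 0).any():
        raise GerosigError("counts must be nonnegative")
    detected_frac = (counts > 0).sum(axis=1) / n_cells
    cells_above = (counts > min_umi).sum(axis=1)
    keep = (detected_frac > min_frac) & (cells_above > min_cells)
    return list(counts.index[keep])


def rank_expression(
    counts: pd.DataFrame,
    normalize: bool = True,
) -> pd.Series:
    """Dataset-wide expression rank per gene (1 = most highly expressed).

    Totals are summed over all cells after per-cell library-size
    normalization (unless ``normalize=False``).  Ties are broken by gene
    symbol so the ranking is a deterministic permutation of 1..n_genes.
    """
    counts = _as_dense(counts)
    mat = counts.to_numpy(dtype=float)
    if normalize:
        libsize = mat.sum(axis=0)
        libsize[libsize == 0] = 1.0
        mat = mat / libsize
    totals = pd.Series(mat.sum(axis=1), index=counts.index)
    order = totals.to_frame("total").assign(gene=totals.index)
    order = order.sort_values(["total", "gene"], ascending=[False, True])
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index,
                      name="rank")
    return ranks.reindex(counts.index)


def validate_markers(markers: pd.DataFrame) -> pd.DataFrame:
    """Check a marker table (cell_type, gene, rank, statistic)."""
    missing = set(MARKER_COLUMNS[:3]) - set(markers.columns)
    if missing:
        raise GerosigError(f"marker table missing columns {sorted(missing)}")
    for ct, grp in markers.groupby("cell_type"):
        if grp["rank"].duplicated().any():
            raise GerosigError(f"duplicate marker rank in cell type {ct!r}")
    return markers


def filter_ambient_degs(
    degs: Iterable[str],
    cell_type: str,
    markers: pd.DataFrame,
    expr_ranks: pd.Series,
    top_markers: int = 5,
    top_expressed: int = 50,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the two-criteria ambient-RNA exclusion to one cell type's DEGs.

    A DEG is excluded iff it is a rank <= ``top_markers`` marker of some
    cell type other than ``cell_type`` AND its dataset-wide expression rank
    is <= ``top_expressed`` (both inclusive — "among the top 5" includes
    the 5th).  Returns the retained genes (input order) and an exclusion
    record naming, per excluded gene, the offending cell type and both
    ranks.
    """
    markers = validate_markers(markers)
    if cell_type not in set(markers["cell_type"]):
        raise GerosigError(f"cell type {cell_type!r} absent from marker table")
    other_top = markers[
        (markers["cell_type"] != cell_type) & (markers["rank"] <= top_markers)
    ].sort_values(["gene", "rank", "cell_type"])
    # best (lowest) offending marker rank per gene
    best = other_top.drop_duplicates("gene").set_index("gene")
    retained, rows = [], []
    for g in degs:
        expr_rank = expr_ranks.get(g, np.inf)
        if g in best.index and expr_rank <= top_expressed:
            rows.append((g, best.at[g, "cell_type"], int(best.at[g, "rank"]),
                         int(expr_rank)))
        else:
            retained.append(g)
    excluded = pd.DataFrame(
        rows, columns=["gene", "marker_cell_type", "marker_rank",
                       "expression_rank"])
    return retained, excluded


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_marker_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"cell_type": str, "gene": str})
    return validate_markers(df)


def write_marker_table(markers: pd.DataFrame, path: str | Path) -> None:
    validate_markers(markers).to_csv(path, sep="\t", index=False)


def read_counts(
    path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> pd.DataFrame:
    """Read a genes x cells count matrix.

    ``.mtx`` files need row/column name sidecars (one name per line);
    anything else is parsed as dense tab-separated with a gene index column.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise GerosigError("MTX input needs genes/cells sidecar files")
        mat = scipy.io.mmread(path)
        genes = [l.strip() for l in open(genes_path) if l.strip()]
        cells = [l.strip() for l in open(cells_path) if l.strip()]
        dense = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        return pd.DataFrame(dense, index=genes, columns=cells)
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")
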