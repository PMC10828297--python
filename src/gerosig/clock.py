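"""Linear transcriptomic-clock application with cross-species plumbing.

A transcriptional clock predicts a sample's age in years as

    age = intercept + sum_g  w_g * t_g

where t_g is a transformed, length- and depth-normalized abundance of
clock gene g (by default log2(FPKM + 1)).  Applying a human-trained clock
to mouse data requires mapping mouse symbols to human homologs first; UMI
count matrices, which carry no meaningful gene-length information, use a
fixed effective length of 10,000 bases for every gene.

Coefficients always come from a user-supplied table; no trained weights
are bundled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sig_io import GerosigError

logger = logging.getLogger("gerosig")

#: effective gene length (bases) substituted for every gene of a UMI matrix
UMI_GENE_LENGTH = 10_000


@dataclass(frozen=True)
class ClockTransform:
    """Expression transform applied before the linear model:
    log(abundance + pseudocount) in the given base."""

    pseudocount: float = 1.0
    log_base: float = 2.0

    def __call__(self, abundance: np.ndarray) -> np.ndarray:
        return np.log(np.asarray(abundance, dtype=float) + self.pseudocount) \
            / np.log(self.log_base)

    def at_zero(self) -> float:
        """Transformed value of zero abundance (imputation for missing genes)."""
        return float(np.log(self.pseudocount) / np.log(self.log_base))


@dataclass
class ClockModel:
    """Intercept + per-gene weights of a linear transcriptomic clock."""

    intercept: float
    coefficients: pd.Series  # human gene symbol -> years per transformed unit
    transform: ClockTransform = field(default_factory=ClockTransform)
    tissue: str = "pan-tissue"

    def __post_init__(self) -> None:
        self.coefficients = self.coefficients.astype(float)
        if not (self.coefficients != 0).any():
            raise GerosigError("clock needs at least one nonzero coefficient")
        if self.coefficients.index.duplicated().any():
            raise GerosigError("duplicate gene in clock coefficients")


@dataclass
class ExpressionMatrix:
    """Genes x samples nonnegative abundance matrix with clock metadata."""

    values: pd.DataFrame
    lengths: pd.Series | None = None  # per-gene length, bases
    units: Literal["counts", "UMI"] = "counts"
    groups: pd.Series | None = None  # sample -> group label

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise GerosigError("abundances must be nonnegative")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.values.index)
            if self.lengths.isna().any() or (self.lengths <= 0).any():
                raise GerosigError("gene lengths must be positive and complete")
        if self.units not in ("counts", "UMI"):
            raise GerosigError(f"units must be counts/UMI, got {self.units!r}")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.values.columns)


# ---------------------------------------------------------------------------
# homolog mapping
# ---------------------------------------------------------------------------

def map_homologs(
    expr: ExpressionMatrix,
    homolog_map: pd.DataFrame,
    collision_policy: Literal["sum", "max", "error"] = "sum",
) -> ExpressionMatrix:
    """Rename expression rows from source to target symbols.

    ``homolog_map`` needs columns ``source`` and ``target``.  Source genes
    absent from the map are dropped (count logged).  A source gene with
    several targets is assigned to its first listed target (logged).
    Several sources mapping to one target are resolved per
    ``collision_policy``: summed (default, conserves total abundance),
    row-wise max, or an error naming the genes.
    """
    if not {"source", "target"} <= set(homolog_map.columns):
        raise GerosigError("homolog map needs 'source' and 'target' columns")
    if len(homolog_map) == 0:
        raise GerosigError("homolog map is empty")
    if (homolog_map["source"].eq("") | homolog_map["target"].eq("")).any():
        raise GerosigError("homolog map contains empty symbols")
    one_to_many = homolog_map["source"].duplicated().sum()
    if one_to_many:
        logger.info("map_homologs: %d one-to-many source gene(s), "
                    "first-listed target used", one_to_many)
    first = homolog_map.drop_duplicates("source").set_index("source")["target"]
    present = expr.values.index.intersection(first.index)
    dropped = len(expr.values.index) - len(present)
    if dropped:
        logger.info("map_homologs: dropped %d unmapped gene(s)", dropped)
    vals = expr.values.loc[present]
    targets = first.loc[present]
    collided = targets[targets.duplicated(keep=False)]
    if collision_policy == "error" and len(collided):
        raise GerosigError(
            "homolog collisions for target(s) "
            f"{sorted(set(collided))[:5]} with policy='error'")
    if collision_policy not in ("sum", "max", "error"):
        raise GerosigError(f"unknown collision_policy {collision_policy!r}")
    agg = "sum" if collision_policy == "sum" else "max"
    out_vals = vals.groupby(targets.to_numpy()).agg(agg)
    lengths = None
    if expr.lengths is not None:
        # merged rows keep the first-listed source's length
        lengths = (expr.lengths.loc[present]
                   .groupby(targets.to_numpy()).first())
    return ExpressionMatrix(out_vals, lengths, expr.units, expr.groups)


# ---------------------------------------------------------------------------
# normalization and clock evaluation
# ---------------------------------------------------------------------------

def normalize_for_clock(
    expr: ExpressionMatrix,
    transform: ClockTransform = ClockTransform(),
) -> pd.DataFrame:
    """Length- and depth-normalize to FPKM-like abundance, then transform.

    UMI matrices use a fixed effective length of 10,000 bases for every
    gene; counts matrices require real lengths.  A sample with zero total
    counts transforms to the pseudocount floor everywhere.
    """
    if expr.units == "UMI":
        lengths = pd.Series(float(UMI_GENE_LENGTH), index=expr.values.index)
    else:
        if expr.lengths is None:
            raise GerosigError("counts matrix requires gene lengths")
        lengths = expr.lengths.astype(float)
    mat = expr.values.to_numpy(dtype=float)
    libsize = mat.sum(axis=0)
    libsize[libsize == 0] = 1.0  # all-zero sample -> zeros stay zeros
    fpkm = mat * 1e9 / (lengths.to_numpy()[:, None] * libsize[None, :])
    return pd.DataFrame(transform(fpkm), index=expr.values.index,
                        columns=expr.values.columns)


def apply_clock(expr_t: pd.DataFrame, clock: ClockModel) -> pd.Series:
    """Per-sample predicted age (years) from a transformed matrix.

    Clock genes missing from the matrix are imputed at the transform of
    zero abundance (logged); if no clock gene is present at all, that is
    an error.
    """
    coef = clock.coefficients
    present = coef.index.intersection(expr_t.index)
    if len(present) == 0:
        raise GerosigError("no clock gene present in expression matrix")
    n_missing = len(coef.index) - len(present)
    baseline = 0.0
    if n_missing:
        logger.info("apply_clock: %d clock gene(s) missing, imputed at "
                    "transform of zero", n_missing)
        missing = coef.index.difference(expr_t.index)
        baseline = float(coef.loc[missing].sum()) * clock.transform.at_zero()
    ages = clock.intercept + baseline \
        + expr_t.loc[present].T.to_numpy() @ coef.loc[present].to_numpy()
    return pd.Series(ages, index=expr_t.columns, name="age_years")


def scale_ages(
    ages: pd.Series,
    method: Literal["zscore", "minmax", "none"] = "zscore",
    panels: pd.Series | None = None,
) -> pd.Series:
    """Scale predicted ages for presentation, within panels.

    ``zscore`` uses the population standard deviation (so two samples map
    to -1/+1); ``minmax`` maps each panel to [0, 1]; ``none`` is the
    identity.  A constant panel scales to all zeros with a warning.
    """
    if method == "none":
        return ages.copy()
    if method not in ("zscore", "minmax"):
        raise GerosigError(f"unknown scaling method {method!r}")
    if panels is None:
        panels = pd.Series("all", index=ages.index)
    out = pd.Series(np.nan, index=ages.index, name="scaled_age")
    for panel, idx in ages.groupby(panels.reindex(ages.index)).groups.items():
        vals = ages.loc[idx].to_numpy(dtype=float)
        if len(vals) < 2:
            raise GerosigError(
                f"panel {panel!r} needs >=2 samples for scaling")
        if method == "zscore":
            sd = vals.std()  # population convention
            if sd == 0:
                warnings.warn(f"constant ages in panel {panel!r}; scaled to 0")
                scaled = np.zeros_like(vals)
            else:
                scaled = (vals - vals.mean()) / sd
        else:
            rng = vals.max() - vals.min()
            if rng == 0:
                warnings.warn(f"constant ages in panel {panel!r}; scaled to 0")
                scaled = np.zeros_like(vals)
            else:
                scaled = (vals - vals.min()) / rng
        out.loc[idx] = scaled
    return out


def compare_groups(
    ages: pd.Series,
    groups: pd.Series,
    order: tuple[str, str] | None = None,
) -> tuple[float, float]:
    """Difference of group means and exact two-sided rank-sum p-value.

    ``order=(reference, test)`` fixes the sign: the delta is
    mean(test) - mean(reference).  Defaults to the sorted group labels.
    Exact (Mann-Whitney) enumeration is used when both groups are small
    and tie-free; the asymptotic tie-corrected p otherwise.
    """
    groups = groups.reindex(ages.index)
    labels = sorted(groups.dropna().unique()) if order is None else list(order)
    if len(labels) != 2:
        raise GerosigError(f"need exactly 2 groups, got {labels}")
    ref = ages[groups == labels[0]].to_numpy(dtype=float)
    test = ages[groups == labels[1]].to_numpy(dtype=float)
    if len(ref) < 2 or len(test) < 2:
        raise GerosigError("each group needs >= 2 samples")
    delta = float(test.mean() - ref.mean())
    pooled = np.concatenate([ref, test])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "asymptotic" if has_ties or len(pooled) > 24 else "exact"
    p = float(stats.mannwhitneyu(test, ref, alternative="two-sided",
                                 method=method).pvalue)
    return delta, p


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_clock_model(path: str | Path) -> ClockModel:
    """Read a clock file: a ``#``-prefixed header line with
    ``intercept=.. pseudocount=.. log_base=.. tissue=..`` followed by a
    tab-separated (gene, coefficient) table."""
    meta = {"intercept": 0.0, "pseudocount": 1.0, "log_base": 2.0,
            "tissue": "pan-tissue"}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if not first.startswith("#"):
            raise GerosigError(f"{path}: expected '#' metadata header line")
        for tok in first.lstrip("#").split():
            k, _, v = tok.partition("=")
            if k not in meta:
                raise GerosigError(f"{path}: unknown clock header key {k!r}")
            meta[k] = v if k == "tissue" else float(v)
        df = pd.read_csv(fh, sep="\t", dtype={"gene": str})
    coef = pd.Series(df["coefficient"].to_numpy(dtype=float),
                     index=pd.Index(df["gene"].to_numpy()))
    return ClockModel(meta["intercept"], coef,
                      ClockTransform(meta["pseudocount"], meta["log_base"]),
                      meta["tissue"])


def write_clock_model(clock: ClockModel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# intercept={clock.intercept!r} "
                 f"pseudocount={clock.transform.pseudocount!r} "
                 f"log_base={clock.transform.log_base!r} "
                 f"tissue={clock.tissue}\n")
        fh.write("gene\tcoefficient\n")
        for g, c in clock.coefficients.items():
            fh.write(f"{g}\t{c!r}\n")


def read_homolog_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"source", "target"} <= set(df.columns):
        raise GerosigError(f"{path}: needs 'source' and 'target' columns")
    return df


def read_expression(
    path: str | Path,
    lengths_path: str | Path | None = None,
    units: str = "counts",
    groups: pd.Series | None = None,
) -> ExpressionMatrix:
    """Read a dense tab-separated genes x samples abundance matrix, with an
    optional (gene, length) sidecar table."""
    vals = pd.read_csv(path, sep="\t", index_col=0)
    lengths = None
    if lengths_path is not None:
        ldf = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = ldf.iloc[:, 0].astype(float)
    return ExpressionMatrix(vals, lengths, units, groups)
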