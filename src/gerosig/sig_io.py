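"""Reading, writing and thresholding of differential-expression signatures.

A *signature* is the per-gene table of differential-expression statistics
(log2 fold-change, raw p, BH-adjusted p) for one contrast — e.g. old vs
young liver, or senolytic-treated vs untreated lung.  Every signature is
addressed by a :class:`ContextKey` carrying study / group / organ-or-cell-type
metadata plus its biological role in the meta-analysis (geroprotective
intervention, aging reference, young parabiont, chronic-inflammation model).

File dialects handled here: tab-separated signature tables
(``gene	log2fc	pvalue	fdr``), GMT gene-set libraries, signed gene lists
(``gene	direction``) and the context manifest tying files to metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("gerosig")

MODALITIES = ("bulk", "single_cell")
ROLES = ("GI", "AGING", "YPAR", "CI", "OTHER")

#: canonical column order of a signature table file
SIGNATURE_COLUMNS = ("gene", "log2fc", "pvalue", "fdr")

Direction = Literal["up", "down", "both"]


class GerosigError(ValueError):
    """Base class for domain validation errors."""


# ---------------------------------------------------------------------------
# context metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class ContextKey:
    """Metadata addressing one differential-expression contrast.

    Parameters
    ----------
    study_id
        Source study label (e.g. ``"senolysis"``, ``"tms"``).
    group
        Contrast label within the study (e.g. ``"treated-vs-old"``).
    unit
        Organ (bulk) or cell type (single-cell) the contrast was run in.
    modality
        ``"bulk"`` or ``"single_cell"``.
    role
        Biological role in the meta-analysis: ``GI`` (geroprotective
        intervention), ``AGING`` (aging reference), ``YPAR`` (young
        heterochronic parabiont, which recapitulates aging), ``CI``
        (chronic-inflammation disease model) or ``OTHER``.
    intervention
        Intervention label for GI contexts (empty otherwise).
    """

    study_id: str
    group: str
    unit: str
    modality: str = "bulk"
    role: str = "OTHER"
    intervention: str = ""

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise GerosigError(
                f"modality {self.modality!r} not in {MODALITIES}")
        if self.role not in ROLES:
            raise GerosigError(f"role {self.role!r} not in {ROLES}")
        for f in ("study_id", "group", "unit"):
            if not getattr(self, f):
                raise GerosigError(f"ContextKey.{f} must be non-empty")

    @property
    def label(self) -> str:
        """Unique human-readable identifier ``study|group|unit``."""
        return f"{self.study_id}|{self.group}|{self.unit}"


# ---------------------------------------------------------------------------
# signature tables
# ---------------------------------------------------------------------------

@dataclass
class SignatureTable:
    """One context's per-gene differential-expression statistics.

    ``data`` has columns ``gene`` (unique symbols), ``log2fc`` (finite),
    ``pvalue`` and ``fdr`` (both in [0, 1]).  Externally supplied ``fdr``
    columns are accepted as-is; when absent they are filled by
    Benjamini–Hochberg adjustment of ``pvalue``.
    """

    context: ContextKey
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SIGNATURE_COLUMNS if c not in df.columns]
        if missing:
            raise GerosigError(f"signature table missing columns {missing}")
        dup = df["gene"][df["gene"].duplicated()]
        if len(dup):
            raise GerosigError(
                f"duplicate gene symbol(s) in {self.context.label}: "
                f"{sorted(set(dup))[:5]}")
        for col in ("log2fc", "pvalue", "fdr"):
            v = pd.to_numeric(df[col], errors="coerce")
            if v.isna().any():
                bad = df.loc[v.isna(), "gene"].iloc[0]
                raise GerosigError(
                    f"non-numeric {col} for gene {bad!r} in {self.context.label}")
            df[col] = v.astype(float)
        if not np.isfinite(df["log2fc"]).all():
            raise GerosigError("log2fc must be finite")
        for col in ("pvalue", "fdr"):
            if ((df[col] < 0) | (df[col] > 1)).any():
                raise GerosigError(f"{col} outside [0, 1]")
        self.data = df.loc[:, list(SIGNATURE_COLUMNS)].reset_index(drop=True)

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.data["gene"])

    def log2fc(self, genes: Iterable[str]) -> np.ndarray:
        """log2 fold-changes for ``genes`` (must all be present)."""
        s = self.data.set_index("gene")["log2fc"]
        return s.loc[list(genes)].to_numpy()


@dataclass(frozen=True)
class DEGThresholds:
    """Differential-expression selection thresholds.

    ``min_abs_fc`` is on the *linear* fold-change scale and is applied as a
    strict inequality ``2**|log2fc| > min_abs_fc``; ``max_fdr`` is a strict
    upper bound on the BH-adjusted p-value.  Defaults: fold-change 1.25,
    FDR 0.05.
    """

    min_abs_fc: float = 1.25
    max_fdr: float = 0.05

    def __post_init__(self) -> None:
        if not self.min_abs_fc > 1:
            raise GerosigError("min_abs_fc must exceed 1")
        if not 0 < self.max_fdr < 1:
            raise GerosigError("max_fdr must lie in (0, 1)")


@dataclass(frozen=True)
class GeneSetLibrary:
    """Named gene sets plus the background universe they are tested against."""

    sets: Mapping[str, frozenset]
    background: frozenset

    def __post_init__(self) -> None:
        for sid, members in self.sets.items():
            stray = members - self.background
            if stray:
                raise GerosigError(
                    f"set {sid!r} has members outside background: "
                    f"{sorted(stray)[:5]}")
            if not members:
                raise GerosigError(f"set {sid!r} is empty")

    def restricted_to(self, genes: Iterable[str]) -> "GeneSetLibrary":
        """Intersect background and all sets with ``genes``; drop sets
        that become empty."""
        universe = self.background & frozenset(genes)
        sets = {
            sid: members & universe
            for sid, members in self.sets.items()
        }
        return GeneSetLibrary(
            {sid: m for sid, m in sets.items() if m}, universe)


@dataclass(frozen=True)
class SignedGeneList:
    """A fixed reference list of genes partitioned by direction of change,
    e.g. a published set of globally age-upregulated / downregulated genes."""

    up: frozenset
    down: frozenset

    def __post_init__(self) -> None:
        both = self.up & self.down
        if both:
            raise GerosigError(
                f"genes listed both up and down: {sorted(both)[:5]}")

    def genes(self, direction: str) -> frozenset:
        if direction == "up":
            return self.up
        if direction == "down":
            return self.down
        raise GerosigError(f"direction must be 'up' or 'down', got {direction!r}")


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Input order is preserved; values are monotone-enforced and capped at 1.
    Raises on any input outside [0, 1].
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise GerosigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DEG selection
# ---------------------------------------------------------------------------

def select_degs(
    table: SignatureTable,
    thr: DEGThresholds = DEGThresholds(),
    direction: Direction = "both",
) -> pd.Series:
    """Differentially expressed genes of ``table`` at thresholds ``thr``.

    A gene is selected iff ``2**|log2fc| > thr.min_abs_fc`` (strict) and
    ``fdr < thr.max_fdr`` (strict), and its sign matches ``direction``.

    Returns
    -------
    pandas.Series
        Indexed by gene symbol, values +1 (up) or -1 (down).
    """
    df = table.data
    passed = (
        (np.exp2(np.abs(df["log2fc"])) > thr.min_abs_fc)
        & (df["fdr"] < thr.max_fdr)
    )
    sign = np.sign(df["log2fc"]).astype(int)
    if direction == "up":
        passed &= sign > 0
    elif direction == "down":
        passed &= sign < 0
    elif direction != "both":
        raise GerosigError(f"unknown direction {direction!r}")
    out = pd.Series(sign[passed].to_numpy(),
                    index=pd.Index(df.loc[passed, "gene"]), name="sign")
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_signature_table(
    path: str | Path,
    context: ContextKey,
    fc_scale: Literal["log2", "linear"] = "log2",
    uppercase: bool = False,
) -> SignatureTable:
    """Read a tab-separated signature table.

    The file needs a header with at least ``gene``, ``log2fc`` and
    ``pvalue``; a missing ``fdr`` column is filled by BH adjustment of
    ``pvalue``.  ``fc_scale="linear"`` declares that the fold-change column
    is on the linear scale and converts it to log2 at read time.
    ``uppercase`` normalizes gene symbols for cross-species joins.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = {"gene", "log2fc", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise GerosigError(f"{path}: missing column(s) {sorted(missing)}")
    if uppercase:
        df["gene"] = df["gene"].str.upper()
    if fc_scale == "linear":
        fc = pd.to_numeric(df["log2fc"], errors="coerce")
        if (fc <= 0).any():
            raise GerosigError(f"{path}: linear fold-changes must be positive")
        df["log2fc"] = np.log2(fc)
    elif fc_scale != "log2":
        raise GerosigError(f"unknown fc_scale {fc_scale!r}")
    if "fdr" not in df.columns:
        df["fdr"] = bh_adjust(pd.to_numeric(df["pvalue"], errors="raise"))
    return SignatureTable(context, df)


def write_signature_table(table: SignatureTable, path: str | Path) -> None:
    """Write a signature table in the canonical tab-separated dialect."""
    table.data.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path, background: Iterable[str] | None = None) -> GeneSetLibrary:
    """Read a GMT gene-set file (set id, description, members...).

    Members are deduplicated per set.  Unless an explicit ``background`` is
    given, the background universe is the union of all members.
    """
    sets: dict[str, frozenset] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GerosigError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}")
            sid = fields[0]
            if sid in sets:
                raise GerosigError(f"{path}:{lineno}: duplicate set id {sid!r}")
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise GerosigError(f"{path}:{lineno}: set {sid!r} is empty")
            sets[sid] = members
    if background is None:
        bg: frozenset = frozenset().union(*sets.values()) if sets else frozenset()
    else:
        bg = frozenset(background)
    return GeneSetLibrary(sets, bg)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid in sorted(library.sets):
            members = "\t".join(sorted(library.sets[sid]))
            fh.write(f"{sid}\tna\t{members}\n")


def read_gene_list(path: str | Path) -> SignedGeneList:
    """Read a signed reference gene list (``gene	direction``,
    direction in {up, down})."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "direction"} <= set(df.columns):
        raise GerosigError(f"{path}: needs columns 'gene' and 'direction'")
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise GerosigError(f"{path}: invalid direction value(s) {sorted(bad)}")
    up = frozenset(df.loc[df["direction"] == "up", "gene"])
    down = frozenset(df.loc[df["direction"] == "down", "gene"])
    return SignedGeneList(up, down)


def write_gene_list(genes: SignedGeneList, path: str | Path) -> None:
    rows = [(g, "up") for g in sorted(genes.up)]
    rows += [(g, "down") for g in sorted(genes.down)]
    pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(
        path, sep="\t", index=False)


MANIFEST_COLUMNS = (
    "study_id", "group", "unit", "modality", "role", "intervention", "path")


def read_manifest(path: str | Path) -> list[tuple[ContextKey, Path]]:
    """Read the context manifest: one row per signature table file."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise GerosigError(f"{path}: manifest missing columns {sorted(missing)}")
    base = Path(path).parent
    out = []
    seen = set()
    for _, row in df.iterrows():
        ctx = ContextKey(row["study_id"], row["group"], row["unit"],
                         row["modality"], row["role"], row["intervention"])
        key = (ctx.study_id, ctx.group, ctx.unit)
        if key in seen:
            raise GerosigError(f"duplicate manifest context {ctx.label}")
        seen.add(key)
        p = Path(row["path"])
        out.append((ctx, p if p.is_absolute() else base / p))
    return out


def write_manifest(entries: Iterable[tuple[ContextKey, str | Path]],
                   path: str | Path) -> None:
    rows = [
        (c.study_id, c.group, c.unit, c.modality, c.role, c.intervention,
         str(p))
        for c, p in entries
    ]
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        path, sep="\t", index=False)


def read_tables(manifest_path: str | Path, **kwargs) -> dict[ContextKey, SignatureTable]:
    """Load every signature table listed in a manifest."""
    return {
        ctx: read_signature_table(p, ctx, **kwargs)
        for ctx, p in read_manifest(manifest_path)
    }
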