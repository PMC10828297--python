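"""Trend-aware intersection of intervention, parabiosis and aging DEG sets.

Each geroprotective intervention contributes one direction-specific DEG set,
built with an intervention-specific context-count rule (a gene must be a
DEG in at least ``min_contexts`` distinct organs or cell types).  Two
opposing trends are then intersected across six sets:

* ``gi_down_aging_up`` — DEGs *down* under the four interventions, *up* in
  the young parabiont, and *up* in the global aging reference;
* ``gi_up_aging_down`` — the mirror image.

Genes shared by >= k of the six sets (default 3) form the convergent
signature report.  A gene qualifying for both opposing trends is flagged,
never silently merged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sig_io import (ContextKey, DEGThresholds, GerosigError, SignatureTable,
                     SignedGeneList, select_degs)

TRENDS = ("gi_down_aging_up", "gi_up_aging_down")

#: default per-intervention context-count requirements
DEFAULT_MIN_CONTEXTS = {
    "senolysis": 1,
    "caloric_restriction": 2,
    "reprogramming": 2,
    "parabiosis": 3,
}

#: the young-parabiont set uses the same >=3-cell-type rule as parabiosis
YPAR_MIN_CONTEXTS = 3


@dataclass(frozen=True)
class InterventionRule:
    """Context-count rule for one intervention's direction-specific DEG set."""

    intervention: str
    min_contexts: int
    direction: str  # "up" or "down"

    def __post_init__(self) -> None:
        if self.min_contexts < 1:
            raise GerosigError("min_contexts must be >= 1")
        if self.direction not in ("up", "down"):
            raise GerosigError(f"direction must be up/down, got {self.direction!r}")


def default_rules(direction: str,
                  min_contexts: Mapping[str, int] = DEFAULT_MIN_CONTEXTS,
                  ) -> dict[str, InterventionRule]:
    return {name: InterventionRule(name, k, direction)
            for name, k in min_contexts.items()}


def intervention_deg_set(
    tables: Sequence[SignatureTable],
    rule: InterventionRule,
    thr: DEGThresholds = DEGThresholds(),
) -> frozenset:
    """Genes that are ``rule.direction`` DEGs in >= ``rule.min_contexts``
    distinct units of one intervention.

    All tables must carry the rule's intervention label.  A gene DEG up in
    one organ and down in another is tallied toward each direction
    independently.
    """
    units_per_gene: dict[str, set] = {}
    for t in tables:
        if t.context.intervention != rule.intervention:
            raise GerosigError(
                f"table {t.context.label} has intervention "
                f"{t.context.intervention!r}, rule expects {rule.intervention!r}")
        for g in select_degs(t, thr, rule.direction).index:
            units_per_gene.setdefault(g, set()).add(t.context.unit)
    return frozenset(g for g, units in units_per_gene.items()
                     if len(units) >= rule.min_contexts)


def ypar_deg_set(
    tables: Sequence[SignatureTable],
    direction: str,
    thr: DEGThresholds = DEGThresholds(),
    min_contexts: int = YPAR_MIN_CONTEXTS,
) -> frozenset:
    """Young-parabiont DEG set: DEG in >= min_contexts distinct cell types."""
    units_per_gene: dict[str, set] = {}
    for t in tables:
        for g in select_degs(t, thr, direction).index:
            units_per_gene.setdefault(g, set()).add(t.context.unit)
    return frozenset(g for g, units in units_per_gene.items()
                     if len(units) >= min_contexts)


def trend_intersection(
    gi_sets: Mapping[str, frozenset],
    ypar_set: frozenset,
    aging_list: SignedGeneList,
    trend: str,
) -> pd.DataFrame:
    """Per-gene membership over the six sets of one trend.

    ``gi_sets`` maps the four intervention names to their direction-specific
    DEG sets (GI-down sets for trend ``gi_down_aging_up``, GI-up otherwise);
    ``ypar_set`` and the signed aging reference enter with the opposite
    direction, which this function resolves from ``trend``.

    Returns a frame indexed by gene with one boolean column per set id
    (the intervention names, ``ypar``, ``aging``), plus ``n_sets`` and
    ``trend``.  Every gene in at least one set is retained.
    """
    if trend not in TRENDS:
        raise GerosigError(f"trend must be one of {TRENDS}")
    aging_dir = "up" if trend == "gi_down_aging_up" else "down"
    sets: dict[str, frozenset] = dict(gi_sets)
    sets["ypar"] = frozenset(ypar_set)
    sets["aging"] = aging_list.genes(aging_dir)
    genes = sorted(frozenset().union(*sets.values()))
    df = pd.DataFrame(
        {sid: [g in members for g in genes] for sid, members in sets.items()},
        index=pd.Index(genes, name="gene"),
    )
    df["n_sets"] = df.sum(axis=1).astype(int)
    df["trend"] = trend
    return df


def flag_trend_conflicts(memberships: pd.DataFrame) -> pd.DataFrame:
    """Add a ``conflict`` column marking genes present in both trends."""
    counts = memberships.groupby(level=0)["trend"].nunique()
    out = memberships.copy()
    out["conflict"] = counts.reindex(out.index).gt(1).to_numpy()
    return out


def shared_gene_report(
    memberships: pd.DataFrame,
    k: int = 3,
    tables: Sequence[SignatureTable] | None = None,
) -> pd.DataFrame:
    """Genes shared by >= k of the six sets, with per-context fold-changes.

    ``memberships`` is the output of :func:`trend_intersection` (one trend,
    or both concatenated).  Rows are sorted by (trend, descending n_sets,
    gene).  When ``tables`` is given, a log2 fold-change column is appended
    per context, NaN where the gene was not measured there.
    """
    if k < 1:
        raise GerosigError("k must be >= 1")
    rep = memberships[memberships["n_sets"] >= k].copy()
    rep = flag_trend_conflicts(rep)
    rep = rep.reset_index().rename(columns={"index": "gene"})
    rep = rep.sort_values(
        ["trend", "n_sets", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)
    if tables is not None:
        for t in tables:
            fc = t.data.set_index("gene")["log2fc"]
            rep[t.context.label] = rep["gene"].map(fc)
    return rep


def venn_counts(memberships: pd.DataFrame) -> pd.DataFrame:
    """Count genes per Venn region (unique membership pattern) and trend.

    Region counts partition the retained genes: they sum to the number of
    membership rows.
    """
    set_cols = [c for c in memberships.columns
                if c not in ("n_sets", "trend", "conflict")]
    pat = memberships[set_cols].apply(
        lambda row: "&".join(sorted(c for c in set_cols if row[c])) or "none",
        axis=1)
    out = (memberships.assign(region=pat)
           .groupby(["trend", "region"]).size()
           .rename("n_genes").reset_index())
    return out.sort_values(["trend", "region"]).reset_index(drop=True)


def direction_consistency(
    gene: str,
    tables: Sequence[SignatureTable],
    thr: DEGThresholds = DEGThresholds(),
) -> float:
    """Fraction of a gene's DEG calls that agree with its majority direction.

    Always in [0.5, 1].  Raises if the gene is a DEG in no table.
    """
    n_up = n_down = 0
    for t in tables:
        s = select_degs(t, thr, "both")
        if gene in s.index:
            if s[gene] > 0:
                n_up += 1
            else:
                n_down += 1
    total = n_up + n_down
    if total == 0:
        raise GerosigError(f"gene {gene!r} is a DEG in no table")
    return max(n_up, n_down) / total


def direction_consistency_summary(
    tables: Sequence[SignatureTable],
    thr: DEGThresholds = DEGThresholds(),
    min_tables: int = 2,
) -> pd.Series:
    """Direction consistency for every gene that is a DEG in >= min_tables
    tables (consistency is trivially 1 for single-table DEGs)."""
    counts: dict[str, list[int]] = {}
    for t in tables:
        s = select_degs(t, thr, "both")
        for g, sign in s.items():
            c = counts.setdefault(g, [0, 0])
            c[0 if sign > 0 else 1] += 1
    vals = {g: max(u, d) / (u + d) for g, (u, d) in counts.items()
            if u + d >= min_tables}
    return pd.Series(vals, name="consistency").sort_index()
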