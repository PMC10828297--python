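"""Gene-set over-representation and weighted pathway/gene rank scoring.

Over-representation is the upper-tail hypergeometric test of a DEG list
against each set of a library, filtered MetaScape-style: minimum overlap 2,
p < 0.01, fold enrichment >= 1.5.  BH-FDR is computed across all tested
sets within one (context, direction) list.

Rank scores aggregate significant hits across contexts: a whole-organ
(bulk) hit contributes 1 point, a parabiosis cell-type (single-cell) hit
0.5 points.  Chronic-inflammation (CI) score maps instead count signed
hits (+1 upregulated, -1 downregulated) separately for bulk and
single-cell contexts, giving each gene or pathway a 2-D coordinate.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import _spearman
from .sig_io import (ContextKey, DEGThresholds, GeneSetLibrary, GerosigError,
                     SignatureTable, bh_adjust, select_degs)

logger = logging.getLogger("gerosig")

ENRICHMENT_COLUMNS = ("set_id", "overlap", "list_size", "set_size",
                      "background_size", "fold_enrichment", "pvalue", "fdr")

#: default per-modality weights for pathway rank scores
DEFAULT_SCORE_WEIGHTS = {"bulk": 1.0, "single_cell": 0.5}


def ora_test(
    deg_list: Iterable[str],
    library: GeneSetLibrary,
    min_overlap: int = 2,
    p_cutoff: float = 0.01,
    min_enrichment: float = 1.5,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a DEG list in a set library.

    Genes outside the library background are dropped (logged).  Every set
    is tested and BH-FDR is computed across all of them; the returned frame
    keeps only results passing all three filters: overlap >= ``min_overlap``,
    p < ``p_cutoff`` (strict), fold enrichment >= ``min_enrichment``.

    Fold enrichment is ``(overlap/list_size) / (set_size/background_size)``.
    """
    if not library.background:
        raise GerosigError("empty background universe")
    degs = set(deg_list)
    dropped = degs - library.background
    if dropped:
        logger.info("ora_test: dropped %d gene(s) outside background",
                    len(dropped))
    degs &= library.background
    M = len(library.background)
    N = len(degs)
    rows = []
    for sid in sorted(library.sets):
        members = library.sets[sid]
        n = len(members)
        k = len(degs & members)
        # upper tail P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if N else 1.0
        fe = (k / N) / (n / M) if N and k else 0.0
        rows.append((sid, k, N, n, M, fe, p))
    df = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS
                                     if c != "fdr"])
    df["fdr"] = bh_adjust(df["pvalue"]) if len(df) else []
    keep = ((df["overlap"] >= min_overlap)
            & (df["pvalue"] < p_cutoff)
            & (df["fold_enrichment"] >= min_enrichment))
    return (df[keep].sort_values(["pvalue", "set_id"])
            .reset_index(drop=True))


def pathway_rank_scores(
    results: Mapping[ContextKey, pd.DataFrame],
    fdr_cutoff: float = 0.01,
    weights: Mapping[str, float] = DEFAULT_SCORE_WEIGHTS,
) -> pd.Series:
    """Weighted count of contexts in which each pathway is enriched.

    ``results`` maps each context to its filtered :func:`ora_test` output.
    A hit (result row with fdr < ``fdr_cutoff``, strict) contributes the
    weight of the context's modality: 1 point for a whole organ (bulk),
    0.5 for a parabiosis-style cell type (single-cell).
    """
    scores: dict[str, float] = {}
    for ctx, df in results.items():
        w = weights[ctx.modality]
        for sid in df.loc[df["fdr"] < fdr_cutoff, "set_id"]:
            scores[sid] = scores.get(sid, 0.0) + w
    # sets tested but never a hit appear with score 0
    for df in results.values():
        for sid in df["set_id"]:
            scores.setdefault(sid, 0.0)
    return pd.Series(scores, name="score").sort_index()


def rank_score_correlation(
    scores_a: pd.Series,
    scores_b: pd.Series,
) -> tuple[float, float, int]:
    """Spearman correlation between two rank-score tables.

    Computed over the union of items scored in either table, with absent
    items scored 0.  Raises when fewer than 3 items are available.
    """
    idx = scores_a.index.union(scores_b.index)
    if len(idx) < 3:
        raise GerosigError("need at least 3 scored items")
    a = scores_a.reindex(idx, fill_value=0.0).to_numpy(dtype=float)
    b = scores_b.reindex(idx, fill_value=0.0).to_numpy(dtype=float)
    return _spearman(a, b)


def ci_gene_scores(
    tables: Sequence[SignatureTable],
    thr: DEGThresholds = DEGThresholds(),
) -> pd.DataFrame:
    """Signed per-gene DEG counts in chronic-inflammation contexts.

    For every gene measured in any table, ``bulk_score`` is the number of
    bulk contexts where it is an upregulated DEG minus the number where it
    is downregulated; ``sc_score`` likewise over single-cell contexts.
    Scores are integers bounded by the context counts per modality.
    """
    genes = sorted(set().union(*(set(t.genes) for t in tables))) if tables else []
    out = pd.DataFrame(0, index=pd.Index(genes, name="gene"),
                       columns=["bulk_score", "sc_score"], dtype=int)
    for t in tables:
        col = "bulk_score" if t.context.modality == "bulk" else "sc_score"
        s = select_degs(t, thr, "both")
        out.loc[s.index, col] += s.astype(int)
    return out


def ci_pathway_scores(
    results: Mapping[tuple[ContextKey, str], pd.DataFrame],
    fdr_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Signed per-pathway enrichment counts by modality.

    ``results`` maps (context, direction) — enrichment run separately on
    the up- and down-regulated DEG lists of each CI context — to filtered
    :func:`ora_test` output.  An up-list hit (fdr < cutoff) scores +1, a
    down-list hit -1, accumulated into ``bulk_score`` / ``sc_score`` by the
    context's modality.
    """
    scores: dict[str, list[int]] = {}
    for (ctx, direction), df in results.items():
        if direction not in ("up", "down"):
            raise GerosigError(f"direction must be up/down, got {direction!r}")
        sign = 1 if direction == "up" else -1
        col = 0 if ctx.modality == "bulk" else 1
        hit_ids = df.loc[df["fdr"] < fdr_cutoff, "set_id"]
        for sid in df["set_id"]:
            scores.setdefault(sid, [0, 0])
        for sid in hit_ids:
            scores[sid][col] += sign
    out = pd.DataFrame.from_dict(scores, orient="index",
                                 columns=["bulk_score", "sc_score"])
    out.index.name = "set_id"
    return out.sort_index()


def overlay_report(
    scores: pd.DataFrame,
    highlight: pd.Series | None = None,
) -> pd.DataFrame:
    """Join highlight/trend annotation onto a 2-D score table.

    ``highlight`` maps items (genes or set ids) to a trend label.  Items
    highlighted but absent from ``scores`` are appended with zero scores,
    so every highlighted item appears in the output.
    """
    out = scores.copy()
    out["trend"] = pd.Series(dtype=object)
    out["highlighted"] = False
    if highlight is None or len(highlight) == 0:
        return out
    missing = highlight.index.difference(out.index)
    if len(missing):
        pad = pd.DataFrame(0, index=missing, columns=scores.columns)
        pad["trend"] = pd.Series(dtype=object)
        pad["highlighted"] = False
        out = pd.concat([out, pad])
    out.loc[highlight.index, "trend"] = highlight
    out.loc[highlight.index, "highlighted"] = True
    out.index.name = scores.index.name
    return out.sort_index()
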