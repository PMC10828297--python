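"""Pairwise signature correlation across contexts.

For every pair of contexts, the genes that are DEGs in *both* tables are
collected and the Spearman rank correlation of their log2 fold-changes is
computed.  Pairs sharing fewer than ``min_shared`` DEGs (default 10) are
excluded; correlations are flagged presentable only when p < alpha
(default 0.05).  Inverse correlations between intervention and aging
signatures are the core readout.

P-values are exact for small overlaps: for n <= 10 shared genes the full
permutation distribution of rho is enumerated; larger overlaps use the
standard t approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sig_io import ContextKey, DEGThresholds, GerosigError, SignatureTable, select_degs

#: largest n for which the exact permutation p-value is used
EXACT_PERMUTATION_MAX_N = 10


def shared_degs(
    a: SignatureTable,
    b: SignatureTable,
    thr: DEGThresholds = DEGThresholds(),
) -> list[str]:
    """Genes that pass DEG selection (either direction) in both tables."""
    da = set(select_degs(a, thr, "both").index)
    db = set(select_degs(b, thr, "both").index)
    return sorted(da & db)


@lru_cache(maxsize=None)
def _all_permutations(n: int) -> np.ndarray:
    """All n! permutations of range(n), shape (n!, n), built iteratively."""
    a = np.zeros((1, 1), dtype=np.int8)
    for k in range(2, n + 1):
        m = a.shape[0]
        out = np.empty((m * k, k), dtype=np.int8)
        for i in range(k):
            blk = out[i * m:(i + 1) * m]
            blk[:, :i] = a[:, :i]
            blk[:, i] = k - 1
            blk[:, i + 1:] = a[:, i:]
        a = out
    return a


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Spearman rho with average-rank ties and a two-sided p-value.

    Exact permutation enumeration for n <= EXACT_PERMUTATION_MAX_N,
    t approximation above.  Constant input yields (nan, nan, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2 or x.size != y.size:
        raise GerosigError("need two equal-length vectors with n >= 2")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    if denom == 0:  # constant vector: rho undefined
        return (float("nan"), float("nan"), n)
    rho = float((rxc * ryc).sum() / denom)
    if n <= EXACT_PERMUTATION_MAX_N:
        perms = _all_permutations(n)
        null = (ryc[perms].astype(np.float32) @ rxc.astype(np.float32)) / denom
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        # t approximation; rho = +-1 gives p = 0
        with np.errstate(divide="ignore"):
            t = rho * np.sqrt((n - 2) / max(1.0 - rho * rho, 0.0)) \
                if abs(rho) < 1 else np.inf * np.sign(rho)
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return (rho, min(p, 1.0), n)


def spearman_pair(
    a: SignatureTable,
    b: SignatureTable,
    genes: Sequence[str],
) -> tuple[float, float, int]:
    """Spearman correlation of log2 fold-changes of ``genes`` in two tables.

    Returns ``(rho, pvalue, n)``; rho is nan when a fold-change vector is
    constant (rank correlation undefined).
    """
    if len(genes) < 2:
        raise GerosigError("need at least 2 shared genes")
    return _spearman(a.log2fc(genes), b.log2fc(genes))


@dataclass
class CorrelationMatrix:
    """Symmetric all-pairs correlation structure over an ordered context list.

    ``rho``/``pvalue`` hold NaN for excluded pairs (fewer than ``min_shared``
    shared DEGs); ``n_shared`` is always recorded so exclusions are
    auditable; ``mask`` is True where the correlation is presentable
    (computed and p < alpha).
    """

    contexts: list[ContextKey]
    rho: pd.DataFrame
    pvalue: pd.DataFrame
    n_shared: pd.DataFrame
    mask: pd.DataFrame

    def to_pairs(self) -> pd.DataFrame:
        """Long-format table of the unique unordered pairs (incl. diagonal)."""
        labels = [c.label for c in self.contexts]
        rows = []
        for i, la in enumerate(labels):
            for j in range(i, len(labels)):
                lb = labels[j]
                rows.append((la, lb, self.rho.iat[i, j], self.pvalue.iat[i, j],
                             int(self.n_shared.iat[i, j]),
                             bool(self.mask.iat[i, j])))
        return pd.DataFrame(
            rows, columns=["context_a", "context_b", "rho", "pvalue",
                           "n_shared", "masked"])


def correlation_matrix(
    tables: Sequence[SignatureTable],
    thr: DEGThresholds = DEGThresholds(),
    min_shared: int = 10,
    alpha: float = 0.05,
) -> CorrelationMatrix:
    """All-pairs Spearman correlation of shared-DEG fold-changes.

    Each unordered pair is evaluated once.  Pairs with fewer than
    ``min_shared`` shared DEGs get NaN rho/p (the shared count is still
    recorded); the mask marks correlations with p < ``alpha``.  The diagonal
    is the self-correlation (rho 1, masked).
    """
    if len(tables) < 2:
        raise GerosigError("need at least 2 tables")
    contexts = [t.context for t in tables]
    labels = [c.label for c in contexts]
    if len(set(labels)) != len(labels):
        raise GerosigError("duplicate context labels")
    k = len(tables)
    deg_sets = [set(select_degs(t, thr, "both").index) for t in tables]
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    nsh = np.zeros((k, k), dtype=int)
    mask = np.zeros((k, k), dtype=bool)
    for i in range(k):
        nsh[i, i] = len(deg_sets[i])
        rho[i, i] = 1.0
        pval[i, i] = 0.0
        mask[i, i] = True
        for j in range(i + 1, k):
            genes = sorted(deg_sets[i] & deg_sets[j])
            nsh[i, j] = nsh[j, i] = len(genes)
            if len(genes) < min_shared:
                continue
            r, p, _ = spearman_pair(tables[i], tables[j], genes)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
            mask[i, j] = mask[j, i] = bool(np.isfinite(p) and p < alpha)

    def _df(arr, dtype=None):
        return pd.DataFrame(arr, index=labels, columns=labels, dtype=dtype)

    return CorrelationMatrix(contexts, _df(rho), _df(pval), _df(nsh), _df(mask))


def block_summary(matrix: CorrelationMatrix, by: str = "role") -> pd.DataFrame:
    """Summarize off-diagonal correlations by pairs of a metadata field.

    For every unordered pair of values of ``by`` (e.g. GI x AGING), reports
    the number of computed correlations, their mean rho, and — among the
    significant (masked) ones — the fractions positive and negative.
    Blocks with no computed correlation report NaN means.
    """
    groups: dict[tuple[str, str], list[tuple[float, bool]]] = {}
    k = len(matrix.contexts)
    for i in range(k):
        for j in range(i + 1, k):
            key = tuple(sorted((getattr(matrix.contexts[i], by),
                                getattr(matrix.contexts[j], by))))
            groups.setdefault(key, []).append(
                (matrix.rho.iat[i, j], bool(matrix.mask.iat[i, j])))
    rows = []
    for (ga, gb), vals in sorted(groups.items()):
        rhos = np.array([v for v, _ in vals], dtype=float)
        avail = rhos[np.isfinite(rhos)]
        sig = np.array([v for v, m in vals if m and np.isfinite(v)])
        rows.append({
            f"{by}_a": ga, f"{by}_b": gb,
            "n_pairs": len(vals),
            "n_computed": len(avail),
            "mean_rho": float(avail.mean()) if len(avail) else float("nan"),
            "n_significant": len(sig),
            "frac_positive": float((sig > 0).mean()) if len(sig) else float("nan"),
            "frac_negative": float((sig < 0).mean()) if len(sig) else float("nan"),
        })
    return pd.DataFrame(rows)
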