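"""One-tailed hypergeometric GO over-representation.

For a term annotating K of the N expressed universe genes, with a DEG set of
size n overlapping the term in k genes, the over-representation p-value is
the exact upper tail P(X >= k) of Hypergeometric(N, K, n).  Terms with fewer
than ``min_term_size`` expressed genes are dropped before testing; BH
adjustment runs across the surviving terms; a term is significant at
``padj < alpha``.  Annotations are taken as a flat gene -> term map (no GO
graph propagation); depletion is not tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import ContractError


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ContractError(f"invalid hypergeometric instance k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


class HypergeometricEnrichment(BaseEstimator):
    """GO term over-representation, sklearn-style.

    ``fit(degs, universe, go_map)`` computes ``results_``: one row per tested
    term with K, N, n, k, pvalue, padj and a significance flag, ordered by
    (padj, term id).
    """

    def __init__(self, min_term_size: int = 5, alpha: float = 0.05):
        self.min_term_size = min_term_size
        self.alpha = alpha

    def fit(
        self,
        degs: set[str] | pd.Index,
        universe: set[str] | pd.Index,
        go_map: pd.DataFrame,
    ) -> "HypergeometricEnrichment":
        degs = set(degs)
        universe = set(universe)
        if not degs <= universe:
            bad = sorted(degs - universe)[:3]
            raise ContractError(f"DEG set is not a subset of the universe, e.g. {bad}")
        N = len(universe)
        n = len(degs)
        in_universe = go_map[go_map["gene_id"].isin(universe)]
        rows = []
        for term, genes in in_universe.groupby("term_id")["gene_id"]:
            term_genes = set(genes)
            K = len(term_genes)
            if K < self.min_term_size:
                continue
            k = len(term_genes & degs)
            p = hypergeom_pvalue(k, K, n, N)
            rows.append({"term_id": term, "K": K, "N": N, "n": n, "k": k, "pvalue": p})
        res = pd.DataFrame(rows, columns=["term_id", "K", "N", "n", "k", "pvalue"])
        if len(res):
            from .diffexpr import bh_adjust

            res["padj"] = bh_adjust(res["pvalue"].to_numpy())
            res["significant"] = res["padj"] < self.alpha
            res = res.sort_values(["padj", "term_id"], kind="mergesort").reset_index(drop=True)
        else:
            res["padj"] = np.array([], dtype=float)
            res["significant"] = np.array([], dtype=bool)
        self.results_ = res
        return self


def enrich(
    degs: set[str] | pd.Index,
    universe: set[str] | pd.Index,
    go_map: pd.DataFrame,
    min_term_size: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Functional wrapper over :class:`HypergeometricEnrichment`."""
    est = HypergeometricEnrichment(min_term_size=min_term_size, alpha=alpha)
    return est.fit(degs, universe, go_map).results_
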