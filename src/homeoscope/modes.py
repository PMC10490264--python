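"""Nine-mode classification of homoeolog expression.

Each analyzed 1:1 homoeolog pair gets an A-vs-D ratio call in the parents
(the in-silico parental Mix) and in the allotetraploid progeny, under the same
condition.  The cross-classification of the two calls defines nine modes in
four regulation types:

===== ========= ========= ============
mode  parents   progeny   regulation
===== ========= ========= ============
1     A > D     A > D     conserved
2     A < D     A < D     conserved
3     A = D     A = D     conserved
4     A > D     A = D     convergent
5     A < D     A = D     convergent
6     A = D     A > D     divergent
7     A = D     A < D     divergent
8     A > D     A < D     reversed
9     A < D     A > D     reversed
===== ========= ========= ============

"Conserved" means the parental relationship is transmitted unchanged;
"convergent" means a parental difference is lost after allopolyploidization
(a common trans environment pulling the copies together); "divergent" means a
difference is gained (cis-driven); "reversed" means the sign flips.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, ContractError

RATIO_STATES = ("A>D", "A<D", "A=D")

#: (parental call, progeny call) -> mode number
MODE_TABLE: dict[tuple[str, str], int] = {
    ("A>D", "A>D"): 1,
    ("A<D", "A<D"): 2,
    ("A=D", "A=D"): 3,
    ("A>D", "A=D"): 4,
    ("A<D", "A=D"): 5,
    ("A=D", "A>D"): 6,
    ("A=D", "A<D"): 7,
    ("A>D", "A<D"): 8,
    ("A<D", "A>D"): 9,
}

#: mode number -> (parental call, progeny call)
MODE_STATES: dict[int, tuple[str, str]] = {v: k for k, v in MODE_TABLE.items()}

REGULATION: dict[int, str] = {
    1: "conserved",
    2: "conserved",
    3: "conserved",
    4: "convergent",
    5: "convergent",
    6: "divergent",
    7: "divergent",
    8: "reversed",
    9: "reversed",
}

REGULATION_TYPES = ("conserved", "convergent", "divergent", "reversed")

#: swapping the subgenome labels (A <-> D) permutes the modes
SWAP_MODE: dict[int, int] = {1: 2, 2: 1, 3: 3, 4: 5, 5: 4, 6: 7, 7: 6, 8: 9, 9: 8}


def classify_mode(parent_call: str, progeny_call: str) -> tuple[int, str]:
    """Map a (parental, progeny) pair of A-vs-D calls to (mode, regulation)."""
    if parent_call not in RATIO_STATES or progeny_call not in RATIO_STATES:
        raise ContractError(
            f"ratio calls must be one of {RATIO_STATES}, got "
            f"({parent_call!r}, {progeny_call!r})"
        )
    mode = MODE_TABLE[(parent_call, progeny_call)]
    return mode, REGULATION[mode]


def ratio_call(log2fc: float, padj: float, alpha: float = 0.05) -> str:
    """A-vs-D call from a copy contrast: significant positive log2FC(A/D) is
    A>D, significant negative is A<D, otherwise A=D."""
    if padj < alpha:
        return "A>D" if log2fc > 0 else "A<D"
    return "A=D"


def call_modes(
    de_parent: pd.DataFrame,
    de_progeny: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify every analyzed pair from two copy-contrast DE tables.

    Parameters
    ----------
    de_parent, de_progeny
        A-copy vs D-copy differential-expression tables (columns
        ``log2FoldChange``, ``padj``) indexed by pair id, for the parental Mix
        and the progeny line respectively, same condition.  BH adjustment must
        already have been applied within each contrast across all analyzed
        pairs (the copy-contrast engine does this).
    """
    if set(de_parent.index) != set(de_progeny.index):
        missing = set(de_parent.index).symmetric_difference(de_progeny.index)
        raise ConsistencyError(
            f"parent/progeny contrasts cover different pairs, e.g. {sorted(missing)[:3]}"
        )
    de_progeny = de_progeny.loc[de_parent.index]
    parent_calls = [
        ratio_call(l, p, alpha)
        for l, p in zip(de_parent["log2FoldChange"], de_parent["padj"])
    ]
    progeny_calls = [
        ratio_call(l, p, alpha)
        for l, p in zip(de_progeny["log2FoldChange"], de_progeny["padj"])
    ]
    modes = [MODE_TABLE[(a, b)] for a, b in zip(parent_calls, progeny_calls)]
    return pd.DataFrame(
        {
            "parent_call": parent_calls,
            "progeny_call": progeny_calls,
            "mode": modes,
            "regulation": [REGULATION[m] for m in modes],
            "parent_log2FoldChange": de_parent["log2FoldChange"].to_numpy(),
            "parent_padj": de_parent["padj"].to_numpy(),
            "progeny_log2FoldChange": de_progeny["log2FoldChange"].to_numpy(),
            "progeny_padj": de_progeny["padj"].to_numpy(),
        },
        index=de_parent.index,
    )


def _percent(count: int, total: int) -> float:
    """Percentage rounded half-up to two decimals (table formatting)."""
    if total == 0:
        return 0.0
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def mode_summary_table(mode_counts: pd.Series | dict[int, int]) -> pd.DataFrame:
    """Summary for one (line, condition): counts and percentages per mode with
    regulation subtotals and a grand total.

    ``mode_counts`` maps mode number (1..9) to the number of analyzed pairs in
    that mode; missing modes count as zero.
    """
    counts = {m: int(pd.Series(mode_counts).get(m, 0)) for m in range(1, 10)}
    total = sum(counts.values())
    rows = []
    for reg in REGULATION_TYPES:
        reg_modes = [m for m in range(1, 10) if REGULATION[m] == reg]
        for m in reg_modes:
            rows.append(
                {
                    "row": f"Mode {m}",
                    "regulation": reg,
                    "parents": MODE_STATES[m][0],
                    "progeny": MODE_STATES[m][1],
                    "count": counts[m],
                    "percent": _percent(counts[m], total),
                }
            )
        sub = sum(counts[m] for m in reg_modes)
        rows.append(
            {
                "row": "Subtotal",
                "regulation": reg,
                "parents": "",
                "progeny": "",
                "count": sub,
                "percent": _percent(sub, total),
            }
        )
    rows.append(
        {
            "row": "Total",
            "regulation": "",
            "parents": "",
            "progeny": "",
            "count": total,
            "percent": _percent(total, total),
        }
    )
    return pd.DataFrame(rows)


def summarize_modes(mode_calls: dict[tuple[str, str], pd.DataFrame]) -> pd.DataFrame:
    """Stack per-(line, condition) mode summaries into one long table.

    ``mode_calls`` maps (line, condition) to the output of :func:`call_modes`.
    """
    parts = []
    for (line, condition), calls in mode_calls.items():
        tab = mode_summary_table(calls["mode"].value_counts())
        tab.insert(0, "condition", condition)
        tab.insert(0, "line", line)
        parts.append(tab)
    if not parts:
        return mode_summary_table({}).iloc[0:0]
    return pd.concat(parts, ignore_index=True)


def change_call(log2fc: float, padj: float, alpha: float = 0.05) -> str:
    """Per-copy progeny-vs-Mix call: up / down / unchanged."""
    if padj < alpha:
        return "up" if log2fc > 0 else "down"
    return "unchanged"


def attribute_mode_changes(
    mode_calls: pd.DataFrame,
    pairs: pd.DataFrame,
    de_genes: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attribute each pair's mode to per-copy expression changes vs Mix.

    Parameters
    ----------
    mode_calls
        Output of :func:`call_modes`, indexed by pair id.
    pairs
        Pair table with ``pair_id``, ``a_gene``, ``d_gene`` covering the index
        of ``mode_calls``.
    de_genes
        Gene-level progeny-vs-Mix DE table (``log2FoldChange``, ``padj``)
        indexed by gene id; must cover both copies of every analyzed pair.

    Returns
    -------
    (per_pair, crosstab)
        ``per_pair`` adds ``a_change``/``d_change`` columns; ``crosstab``
        counts pairs per mode x (A-copy change, D-copy change).
    """
    pairs = pairs.set_index("pair_id") if "pair_id" in pairs.columns else pairs
    missing = [p for p in mode_calls.index if p not in pairs.index]
    if missing:
        raise ConsistencyError(f"pairs missing from pair table: {missing[:3]}")
    sub = pairs.loc[mode_calls.index]
    for col in ("a_gene", "d_gene"):
        unknown = [g for g in sub[col] if g not in de_genes.index]
        if unknown:
            raise ConsistencyError(
                f"copy genes missing from gene-level DE table: {unknown[:3]}"
            )
    a_de = de_genes.loc[sub["a_gene"]]
    d_de = de_genes.loc[sub["d_gene"]]
    per_pair = mode_calls.copy()
    per_pair["a_change"] = [
        change_call(l, p, alpha) for l, p in zip(a_de["log2FoldChange"], a_de["padj"])
    ]
    per_pair["d_change"] = [
        change_call(l, p, alpha) for l, p in zip(d_de["log2FoldChange"], d_de["padj"])
    ]
    crosstab = (
        per_pair.groupby(["mode", "a_change", "d_change"], observed=True)
        .size()
        .rename("n_pairs")
        .reset_index()
    )
    return per_pair, crosstab
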