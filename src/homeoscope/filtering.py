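"""Gene- and pair-level exclusion rules applied before any statistics.

Rule order (fixed, and recorded in the :class:`FilterReport`):

1. genes overlapping a known HE region of the HE-carrying line by >= 1 bp are
   excluded (their copy number is duplicated or deleted there, which would
   imbalance DEG counts); applied identically to every genotype's analysis so
   DEG universes stay comparable;
2. genes on unplaced scaffolds are excluded;
3. genes with mean raw count over *all* samples below 10 or above 5000 are
   excluded (the retained interval [10, 5000] is closed: the thresholds read
   as removal conditions);
4. pairs with a transcript-length disparity above 10% of the longer
   transcript are excluded;
5. pairs with no copy expressed (mean raw count >= 10, rule 3's lower bound)
   in either subgenome are excluded.

`MeanCountFilter` exposes rule 3 as a scikit-learn style selector so it can
sit in sklearn pipelines; the module-level functions are the primary surface.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import io as hio
from .exceptions import ConsistencyError, ContractError


@dataclass
class FilterReport:
    """Tally of removals per rule; each entry is an exact partition of its
    input (removed + surviving = input)."""

    steps: list[dict] = field(default_factory=list)

    def record(self, rule: str, n_input: int, n_removed: int) -> None:
        self.steps.append(
            {
                "rule": rule,
                "n_input": n_input,
                "n_removed": n_removed,
                "n_surviving": n_input - n_removed,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def removed(self, rule: str) -> int:
        for s in self.steps:
            if s["rule"] == rule:
                return s["n_removed"]
        raise KeyError(rule)


# ---------------------------------------------------------------------------
# gene-level rules


def he_overlap_mask(catalog: pd.DataFrame, he_intervals: pd.DataFrame, line: str = "X190") -> pd.Series:
    """True for genes overlapping (>=1 bp, half-open intervals) an HE region
    of ``line``."""
    known_chroms = set(catalog["chromosome"])
    mask = pd.Series(False, index=catalog.index)
    for row in he_intervals.itertuples(index=False):
        if row.line != line:
            continue
        # guard against a naming-scheme mismatch between the two files; a
        # chromosome merely absent from a catalog subset is fine
        if row.chromosome not in known_chroms and not re.fullmatch(
            r"Chr\d+[AD]", row.chromosome
        ):
            raise ConsistencyError(
                f"HE interval chromosome {row.chromosome!r} unknown to the catalog"
            )
        hit = (
            (catalog["chromosome"] == row.chromosome)
            & (catalog["start"] < row.end)
            & (catalog["end"] > row.start)
        )
        mask |= hit
    return mask


def exclude_he_genes(
    catalog: pd.DataFrame,
    he_intervals: pd.DataFrame,
    line: str = "X190",
    report: FilterReport | None = None,
) -> tuple[pd.Index, FilterReport]:
    """Drop genes in HE regions of ``line`` and genes on unplaced scaffolds."""
    report = report if report is not None else FilterReport()
    he = he_overlap_mask(catalog, he_intervals, line)
    keep = catalog.index[~he]
    report.record("he_region", len(catalog), int(he.sum()))
    unplaced = catalog.loc[keep, "chromosome"] == hio.UNPLACED
    report.record("unplaced_scaffold", len(keep), int(unplaced.sum()))
    return keep[~unplaced], report


class MeanCountFilter(BaseEstimator):
    """Retain genes whose mean raw count over all samples lies in
    ``[min_mean, max_mean]`` (both bounds inclusive).

    sklearn-style selector: ``fit`` computes ``support_`` over the rows of a
    genes x samples count frame; ``transform`` subsets the rows.
    """

    def __init__(self, min_mean: float = 10.0, max_mean: float = 5000.0):
        self.min_mean = min_mean
        self.max_mean = max_mean

    def fit(self, counts: pd.DataFrame, y=None) -> "MeanCountFilter":
        if counts.shape[0] == 0 or counts.shape[1] == 0:
            raise ContractError("count matrix must be non-empty")
        means = counts.mean(axis=1)
        self.means_ = means
        self.support_ = ((means >= self.min_mean) & (means <= self.max_mean)).to_numpy()
        self.n_features_in_ = counts.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, counts: pd.DataFrame) -> pd.DataFrame:
        return counts.loc[self.support_]

    def fit_transform(self, counts: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(counts).transform(counts)


def filter_by_mean_count(
    counts: pd.DataFrame,
    min_mean: float = 10.0,
    max_mean: float = 5000.0,
    report: FilterReport | None = None,
) -> tuple[pd.Index, FilterReport]:
    """Gene ids with mean raw count in the closed interval [min_mean, max_mean]."""
    report = report if report is not None else FilterReport()
    flt = MeanCountFilter(min_mean=min_mean, max_mean=max_mean).fit(counts)
    keep = counts.index[flt.get_support()]
    means = flt.means_
    low = means < min_mean
    report.record("mean_count_low", len(counts), int(low.sum()))
    report.record("mean_count_high", int((~low).sum()), int((means > max_mean).sum()))
    return keep, report


def filter_genes(
    catalog: pd.DataFrame,
    he_intervals: pd.DataFrame,
    counts: pd.DataFrame,
    line: str = "X190",
    min_mean: float = 10.0,
    max_mean: float = 5000.0,
) -> tuple[pd.Index, FilterReport]:
    """Full gene-level screen: HE regions, unplaced scaffolds, mean count."""
    report = FilterReport()
    keep, report = exclude_he_genes(catalog, he_intervals, line, report)
    sub = counts.loc[keep]
    means = sub.mean(axis=1)
    low = means < min_mean
    report.record("mean_count_low", len(sub), int(low.sum()))
    high = means > max_mean
    report.record("mean_count_high", int((~low).sum()), int((high & ~low).sum()))
    return sub.index[~(low | high)], report


# ---------------------------------------------------------------------------
# pair-level rules


def length_disparity(len_a: np.ndarray, len_d: np.ndarray, denominator: str = "longer") -> np.ndarray:
    """Relative transcript-length difference; by default |lA - lD| / max."""
    len_a = np.asarray(len_a, dtype=float)
    len_d = np.asarray(len_d, dtype=float)
    if denominator == "longer":
        den = np.maximum(len_a, len_d)
    elif denominator == "mean":
        den = (len_a + len_d) / 2
    else:
        raise ContractError(f"unknown denominator {denominator!r}")
    return np.abs(len_a - len_d) / den


def filter_pairs_by_length(
    pairs: pd.DataFrame,
    catalog: pd.DataFrame,
    max_disparity: float = 0.10,
    denominator: str = "longer",
    report: FilterReport | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep pairs whose transcript lengths differ by at most ``max_disparity``."""
    report = report if report is not None else FilterReport()
    for col in ("a_gene", "d_gene"):
        unknown = ~pairs[col].isin(catalog.index)
        if unknown.any():
            raise ConsistencyError(
                f"transcript length unknown for {pairs.loc[unknown, col].iloc[0]!r}"
            )
    la = catalog.loc[pairs["a_gene"], "transcript_length"].to_numpy()
    ld = catalog.loc[pairs["d_gene"], "transcript_length"].to_numpy()
    disp = length_disparity(la, ld, denominator)
    keep = disp <= max_disparity
    report.record("length_disparity", len(pairs), int((~keep).sum()))
    return pairs.loc[keep].reset_index(drop=True), report


def filter_pairs_by_expression(
    pairs: pd.DataFrame,
    counts: pd.DataFrame,
    min_mean: float = 10.0,
    report: FilterReport | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep pairs expressed in at least one subgenome, operationalized as mean
    raw count >= ``min_mean`` (over all samples) for at least one copy."""
    report = report if report is not None else FilterReport()
    means = counts.mean(axis=1)
    ma = means.reindex(pairs["a_gene"]).fillna(0).to_numpy()
    md = means.reindex(pairs["d_gene"]).fillna(0).to_numpy()
    keep = (ma >= min_mean) | (md >= min_mean)
    report.record("not_expressed", len(pairs), int((~keep).sum()))
    return pairs.loc[keep].reset_index(drop=True), report


def filter_pairs(
    pairs: pd.DataFrame,
    catalog: pd.DataFrame,
    counts: pd.DataFrame,
    he_intervals: pd.DataFrame,
    line: str = "X190",
    max_disparity: float = 0.10,
    min_mean: float = 10.0,
) -> tuple[pd.DataFrame, FilterReport]:
    """Full pair-level screen: HE/unplaced members, length disparity,
    expressed-in-at-least-one-subgenome."""
    report = FilterReport()
    kept_genes, _ = exclude_he_genes(catalog, he_intervals, line)
    kept = set(kept_genes)
    ok = pairs["a_gene"].isin(kept) & pairs["d_gene"].isin(kept)
    report.record("he_or_unplaced_member", len(pairs), int((~ok).sum()))
    pairs = pairs.loc[ok].reset_index(drop=True)
    pairs, report = filter_pairs_by_length(pairs, catalog, max_disparity, report=report)
    pairs, report = filter_pairs_by_expression(pairs, counts, min_mean, report=report)
    return pairs, report
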