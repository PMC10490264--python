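"""Per-subgenome DEG summaries and chromosomal distribution tracks.

"Up-regulated" always means higher in the tetraploid line than in the
parental Mix.  DEG proportions use the post-filter expressed-gene universe of
the same subgenome as the denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError


def summarize_degs(
    degs: pd.DataFrame,
    catalog: pd.DataFrame,
    expressed: pd.Index,
) -> pd.DataFrame:
    """Count up/down DEGs per subgenome and their proportions.

    Parameters
    ----------
    degs
        DEG table indexed by gene id with a ``direction`` column
        (see :func:`homeoscope.diffexpr.call_degs`).
    catalog
        Joint gene catalog (maps genes to subgenomes).
    expressed
        Post-filter expressed gene universe (denominator source).
    """
    unknown = [g for g in degs.index if g not in catalog.index]
    if unknown:
        raise ConsistencyError(f"DEGs missing from the catalog: {unknown[:3]}")
    expressed_sub = catalog.loc[catalog.index.intersection(expressed), "subgenome"]
    rows = []
    for sub in ("A", "D"):
        n_expr = int((expressed_sub == sub).sum())
        sub_degs = degs[catalog.loc[degs.index, "subgenome"] == sub]
        n_up = int((sub_degs["direction"] == "up").sum())
        n_down = int((sub_degs["direction"] == "down").sum())
        rows.append(
            {
                "subgenome": sub,
                "n_expressed": n_expr,
                "n_up": n_up,
                "n_down": n_down,
                "n_deg": n_up + n_down,
                "prop_up": n_up / n_expr if n_expr else 0.0,
                "prop_down": n_down / n_expr if n_expr else 0.0,
                "prop_deg": (n_up + n_down) / n_expr if n_expr else 0.0,
            }
        )
    return pd.DataFrame(rows)


def chromosome_tracks(
    degs: pd.DataFrame,
    catalog: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plottable per-chromosome DEG tracks plus per-chromosome up/down counts.

    Only placed genes enter the track (unplaced genes are excluded upstream
    anyway).  Rows are ordered by chromosome then position.
    """
    unknown = [g for g in degs.index if g not in catalog.index]
    if unknown:
        raise ConsistencyError(f"DEGs missing from the catalog: {unknown[:3]}")
    sub = catalog.loc[degs.index]
    placed = sub["chromosome"] != "unplaced"
    tracks = pd.DataFrame(
        {
            "gene_id": degs.index[placed],
            "chromosome": sub.loc[placed, "chromosome"].to_numpy(),
            "position": sub.loc[placed, "start"].to_numpy(),
            "log2FoldChange": degs.loc[placed, "log2FoldChange"].to_numpy(),
            "direction": degs.loc[placed, "direction"].to_numpy(),
        }
    ).sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)
    counts = (
        tracks.groupby(["chromosome", "direction"], observed=True)
        .size()
        .rename("n_degs")
        .reset_index()
        .pivot(index="chromosome", columns="direction", values="n_degs")
        .fillna(0)
        .astype(int)
    )
    for col in ("up", "down"):
        if col not in counts.columns:
            counts[col] = 0
    counts = counts[["up", "down"]]
    counts["total"] = counts["up"] + counts["down"]
    return tracks, counts


def plot_tracks(tracks: pd.DataFrame, path: str) -> None:  # pragma: no cover
    """Thin, replaceable rendering layer for the chromosome tracks."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted(tracks["chromosome"].unique())
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 0.8 * len(chroms)), sharex=True)
    if len(chroms) == 1:
        axes = [axes]
    lim = max(1.0, np.abs(tracks["log2FoldChange"]).max())
    for ax, chrom in zip(np.atleast_1d(axes), chroms):
        sub = tracks[tracks["chromosome"] == chrom]
        ax.vlines(sub["position"], 0, 1, colors=plt.cm.coolwarm(
            (sub["log2FoldChange"] + lim) / (2 * lim)))
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center")
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
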