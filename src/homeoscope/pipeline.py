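"""End-to-end orchestration: simulate/load -> filter -> DE -> modes ->
summaries -> enrichment.

Every stage writes its outputs as TSV files in the run directory, so any
stage can be re-run in isolation; there is no hidden state.  A run log
records the seed, configuration hash, package version and the exact filter
tallies.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from . import io as hio
from .diffexpr import call_degs, copy_contrast, estimate_size_factors, wald_test
from .enrichment import enrich
from .exceptions import HomeoscopeError
from .filtering import filter_genes, filter_pairs
from .modes import attribute_mode_changes, call_modes, summarize_modes
from .simulate import SimulatedDataset, SimulationConfig, simulate_dataset, write_dataset
from .summary import chromosome_tracks, summarize_degs


@dataclass
class PipelineConfig:
    """Inputs and constants of one analysis run.

    Either ``input_dir`` points at an existing dataset (counts.tsv,
    design.tsv, genes_A.bed, genes_D.bed, pairs.tsv, he_regions.bed,
    go_map.tsv) or ``simulation`` requests a synthetic one.
    """

    out_dir: str
    seed: int = 0
    input_dir: str | None = None
    simulation: SimulationConfig | None = None
    alpha: float = 0.05
    min_mean: float = 10.0
    max_mean: float = 5000.0
    max_length_disparity: float = 0.10
    min_term_size: int = 5
    he_line: str = "X190"
    lines: tuple[str, ...] = ("EUP", "X190")
    conditions: tuple[str, ...] = hio.CONDITIONS
    run_enrichment: bool = True

    def digest(self) -> str:
        payload = json.dumps(
            {k: repr(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle mirroring the files written to the run directory."""

    config: PipelineConfig
    filter_report: pd.DataFrame
    expressed_genes: pd.Index
    analyzed_pairs: pd.DataFrame
    de_tables: dict[tuple[str, str], pd.DataFrame]
    deg_summary: pd.DataFrame
    tracks: dict[tuple[str, str], pd.DataFrame]
    chrom_counts: dict[tuple[str, str], pd.DataFrame]
    mode_calls: dict[tuple[str, str], pd.DataFrame]
    mode_summary: pd.DataFrame
    attribution: pd.DataFrame
    enrichment: pd.DataFrame
    dataset: SimulatedDataset | None = None
    log: dict = field(default_factory=dict)


class _Stage:
    """Context manager that renames any error with its stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, Exception):
            raise HomeoscopeError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def _load_inputs(input_dir: str):
    counts = hio.read_counts(os.path.join(input_dir, "counts.tsv"))
    design = hio.read_design(os.path.join(input_dir, "design.tsv"))
    hio.check_design_matches_counts(design, counts)
    cat_a = hio.tag_subgenome(hio.read_genes(os.path.join(input_dir, "genes_A.bed")), "A")
    cat_d = hio.tag_subgenome(hio.read_genes(os.path.join(input_dir, "genes_D.bed")), "D")
    catalog = hio.merge_catalogs(cat_a, cat_d)
    pairs = hio.read_pairs(os.path.join(input_dir, "pairs.tsv"))
    if "pair_id" not in pairs.columns:
        pairs.insert(0, "pair_id", [f"p{i}" for i in range(len(pairs))])
    hio.check_pairs_resolve(pairs, catalog)
    he = hio.read_intervals(os.path.join(input_dir, "he_regions.bed"))
    go_path = os.path.join(input_dir, "go_map.tsv")
    go_map = hio.read_go(go_path) if os.path.exists(go_path) else None
    return counts, design, catalog, pairs, he, go_map


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle to ``config.out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    dataset = None

    with _Stage("load"):
        if config.simulation is not None:
            dataset = simulate_dataset(config.simulation)
            write_dataset(dataset, os.path.join(config.out_dir, "inputs"))
            counts, design = dataset.counts, dataset.design
            catalog, pairs, he = dataset.catalog, dataset.pairs, dataset.he_regions
            go_map = dataset.go_map
        elif config.input_dir is not None:
            counts, design, catalog, pairs, he, go_map = _load_inputs(config.input_dir)
        else:
            raise HomeoscopeError("config must give input_dir or a simulation block")

    with _Stage("filter"):
        expressed, gene_report = filter_genes(
            catalog, he, counts, line=config.he_line,
            min_mean=config.min_mean, max_mean=config.max_mean,
        )
        analyzed_pairs, pair_report = filter_pairs(
            pairs, catalog, counts, he, line=config.he_line,
            max_disparity=config.max_length_disparity, min_mean=config.min_mean,
        )
        gene_frame = gene_report.to_frame().assign(scope="genes")
        pair_frame = pair_report.to_frame().assign(scope="pairs")
        filter_report = pd.concat([gene_frame, pair_frame], ignore_index=True)
        filter_report.to_csv(
            os.path.join(config.out_dir, "filter_report.tsv"), sep="\t", index=False
        )

    # Size factors are estimated per contrast: the pure parents carry
    # structural zeros for the other subgenome's genes, so a single
    # median-of-ratios fit across all genotypes is undefined.  Each tested
    # sample subset expresses (nearly) all genes and normalizes cleanly.
    def _sf(samples: list[str]) -> pd.Series:
        return estimate_size_factors(counts[samples])

    de_tables: dict[tuple[str, str], pd.DataFrame] = {}
    deg_rows = []
    tracks: dict[tuple[str, str], pd.DataFrame] = {}
    chrom_counts: dict[tuple[str, str], pd.DataFrame] = {}
    with _Stage("diffexpr"):
        expressed_counts = counts.loc[expressed]
        for line in config.lines:
            for cond in config.conditions:
                cols = design[
                    (design["condition"] == cond)
                    & design["genotype"].isin(["Mix", line])
                ]
                res = wald_test(
                    expressed_counts[cols.index],
                    cols,
                    contrast=("Mix", line),
                    size_factors=_sf(cols.index.tolist()),
                    alpha=config.alpha,
                )
                de_tables[(line, cond)] = res
                res.to_csv(
                    os.path.join(config.out_dir, f"de_{line}_{cond}.tsv"),
                    sep="\t", index_label="gene_id",
                )
                degs = call_degs(res, config.alpha)
                summ = summarize_degs(degs, catalog, expressed)
                summ.insert(0, "condition", cond)
                summ.insert(0, "line", line)
                deg_rows.append(summ)
                tr, cc = chromosome_tracks(degs, catalog)
                tracks[(line, cond)] = tr
                chrom_counts[(line, cond)] = cc
        deg_summary = pd.concat(deg_rows, ignore_index=True)
        deg_summary.to_csv(
            os.path.join(config.out_dir, "deg_summary.tsv"), sep="\t", index=False
        )
        track_frames = []
        for (line, cond), tr in tracks.items():
            t = tr.copy()
            t.insert(0, "condition", cond)
            t.insert(0, "line", line)
            track_frames.append(t)
        pd.concat(track_frames, ignore_index=True).to_csv(
            os.path.join(config.out_dir, "tracks.tsv"), sep="\t", index=False
        )

    mode_calls: dict[tuple[str, str], pd.DataFrame] = {}
    attribution_frames = []
    with _Stage("modes"):
        for cond in config.conditions:
            mix_samples = design[(design["genotype"] == "Mix") & (design["condition"] == cond)].index.tolist()
            de_parent = copy_contrast(counts, analyzed_pairs, mix_samples, _sf(mix_samples))
            for line in config.lines:
                line_samples = design[
                    (design["genotype"] == line) & (design["condition"] == cond)
                ].index.tolist()
                de_progeny = copy_contrast(
                    counts, analyzed_pairs, line_samples, _sf(line_samples)
                )
                calls = call_modes(de_parent, de_progeny, alpha=config.alpha)
                # copies that failed the gene-level expression screen were not
                # tested vs Mix; they count as "unchanged" in the attribution
                copy_genes = pd.Index(
                    sorted(set(analyzed_pairs["a_gene"]) | set(analyzed_pairs["d_gene"]))
                )
                de_copies = de_tables[(line, cond)].reindex(copy_genes)
                de_copies["log2FoldChange"] = de_copies["log2FoldChange"].fillna(0.0)
                de_copies["padj"] = de_copies["padj"].fillna(1.0)
                per_pair, crosstab = attribute_mode_changes(
                    calls, analyzed_pairs, de_copies, alpha=config.alpha
                )
                mode_calls[(line, cond)] = per_pair
                crosstab.insert(0, "condition", cond)
                crosstab.insert(0, "line", line)
                attribution_frames.append(crosstab)
        mode_summary = summarize_modes(mode_calls)
        mode_summary.to_csv(
            os.path.join(config.out_dir, "mode_summary.tsv"), sep="\t", index=False
        )
        long_calls = []
        for (line, cond), calls in mode_calls.items():
            c = calls.copy()
            c.insert(0, "condition", cond)
            c.insert(0, "line", line)
            long_calls.append(c)
        pd.concat(long_calls).to_csv(
            os.path.join(config.out_dir, "modes.tsv"), sep="\t", index_label="pair_id"
        )
        attribution = pd.concat(attribution_frames, ignore_index=True)
        attribution.to_csv(
            os.path.join(config.out_dir, "mode_attribution.tsv"), sep="\t", index=False
        )

    enrichment_frames = []
    with _Stage("enrichment"):
        if config.run_enrichment and go_map is not None:
            for line in config.lines:
                for cond in config.conditions:
                    degs = call_degs(de_tables[(line, cond)], config.alpha)
                    expressed_sub = catalog.loc[expressed, "subgenome"]
                    deg_sub = catalog.loc[degs.index, "subgenome"]
                    for sub in ("A", "D"):
                        universe = expressed[(expressed_sub == sub).to_numpy()]
                        sub_degs = degs.index[(deg_sub == sub).to_numpy()]
                        res = enrich(
                            set(sub_degs), set(universe), go_map,
                            min_term_size=config.min_term_size, alpha=config.alpha,
                        )
                        res.insert(0, "subgenome", sub)
                        res.insert(0, "condition", cond)
                        res.insert(0, "line", line)
                        enrichment_frames.append(res)
        enrichment = (
            pd.concat(enrichment_frames, ignore_index=True)
            if enrichment_frames
            else pd.DataFrame()
        )
        enrichment.to_csv(
            os.path.join(config.out_dir, "enrichment.tsv"), sep="\t", index=False
        )

    log = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "n_genes": int(len(catalog)),
        "n_expressed": int(len(expressed)),
        "n_pairs_input": int(len(pairs)),
        "n_pairs_analyzed": int(len(analyzed_pairs)),
        "filter_tallies": filter_report.to_dict(orient="records"),
    }
    with open(os.path.join(config.out_dir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2)

    return PipelineResult(
        config=config,
        filter_report=filter_report,
        expressed_genes=expressed,
        analyzed_pairs=analyzed_pairs,
        de_tables=de_tables,
        deg_summary=deg_summary,
        tracks=tracks,
        chrom_counts=chrom_counts,
        mode_calls=mode_calls,
        mode_summary=mode_summary,
        attribution=attribution,
        enrichment=enrichment,
        dataset=dataset,
        log=log,
    )
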