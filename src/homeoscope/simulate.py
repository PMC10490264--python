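"""Synthetic data generator with planted truth.

The generator emulates the design of an RNA-seq study of a synthetic
allotetraploid (genome AADD) and its diploid parents: two diploid parent
genotypes (parentA, parentD), an in-silico equal-mass mixture of the parents
(Mix), a euploid allotetraploid (EUP) and a line carrying homoeologous
exchanges (X190), each sequenced under four conditions (mock-2d, PEG6000-2d,
mock-5d, NaCl-5d) with replication.

World model
-----------
* Two parental gene catalogs with 7 chromosomes each (Chr1A..Chr7A,
  Chr1D..Chr7D), genes evenly spaced, plus a few unplaced scaffold genes.
* 1:1 collinear homoeolog pairs link the i-th A gene to the i-th D gene, so
  pair members sit on homologous chromosomes at matching relative positions.
* Every pair carries, per condition, a planted expression mode (1..9): a true
  parental A-vs-D ratio state, a true progeny state, and a per-copy change
  (up/down/unchanged) realizing the transition, drawn from configured
  mode proportions and attribution probabilities.
* Counts are negative binomial: ``NB(mean = rate x library factor x
  copy-number multiplier, dispersion = alpha)`` with a gamma-Poisson sampler
  (Poisson when alpha = 0).  Rates are expressed on the "Mix scale": a Mix
  sample sees rate r per copy, the corresponding pure parent sees 2r (all its
  reads come from one genome at the same sequencing depth), the tetraploids
  see the planted progeny rate per copy, and X190 additionally multiplies
  genes inside HE intervals by the configured copy-number multiplier
  (2 = duplicated segment, 0 = deleted segment).

Baseline rates are drawn log-uniformly from a moderately-expressed range,
with configured fractions of clearly-low and clearly-high genes so that the
mean-count filter (retain mean in [10, 5000]) has a deterministic expected
outcome per gene.  The default ranges are chosen so that even after the
fold-change structure (per-copy rates span base/fold .. base*fold) and HE
multipliers, every gene's expected mean raw count stays many standard
deviations away from both thresholds: the truth table's expected-mean rule
and the realized-count rule then agree with overwhelming probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as hio
from .exceptions import ConfigurationError, ConsistencyError
from .modes import MODE_STATES, SWAP_MODE

CHROM_LENGTH = 750_000_000
GENE_SPAN = 3_000  # genomic footprint of one gene, bp

#: default planted mode proportions per condition (counts/4420 from the
#: euploid columns of the study-style summary table)
_EUP_MODE_COUNTS = {
    "mock-2d": [360, 357, 2645, 425, 279, 136, 204, 11, 3],
    "PEG6000-2d": [762, 790, 1633, 401, 353, 210, 260, 6, 5],
    "mock-5d": [452, 420, 2648, 305, 232, 162, 197, 3, 1],
    "NaCl-5d": [702, 758, 1679, 436, 403, 210, 220, 7, 5],
}
DEFAULT_MODE_PROPORTIONS = {
    cond: tuple(c / 4420 for c in counts) for cond, counts in _EUP_MODE_COUNTS.items()
}

#: default HE regions of the X190 line: the 2A/3A segments are duplicated
#: (multiplier 2), their 2D/3D counterparts deleted (multiplier 0)
DEFAULT_HE_REGIONS = (
    ("Chr2A", 800_000, 51_800_000, "X190", 2.0),
    ("Chr2D", 400_000, 58_000_000, "X190", 0.0),
    ("Chr3A", 684_600_000, CHROM_LENGTH, "X190", 2.0),
    ("Chr3D", 557_400_000, CHROM_LENGTH, "X190", 0.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic world; ``seed`` is mandatory.

    ``mode_proportions`` maps each condition to nine probabilities
    (modes 1..9); ``attribution_probs`` gives (A-copy-only, D-copy-only,
    both-copies) probabilities for realizing a mode transition.
    """

    seed: int
    n_pairs: int = 3000
    n_singletons_a: int = 150
    n_singletons_d: int = 150
    n_unplaced_a: int = 25
    n_unplaced_d: int = 25
    replicates: int = 3
    dispersion: float = 0.05
    fold: float = 4.0
    libsize_range: tuple[float, float] = (0.7, 1.4)
    length_disparity_fraction: float = 0.2
    rate_range: tuple[float, float] = (60.0, 1000.0)
    low_rate: float = 1.5
    high_rate: float = 60000.0
    frac_low: float = 0.05
    frac_high: float = 0.01
    mode_proportions: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MODE_PROPORTIONS)
    )
    attribution_probs: tuple[float, float, float] = (0.45, 0.45, 0.10)
    he_regions: tuple[tuple[str, int, int, str, float], ...] = DEFAULT_HE_REGIONS
    n_chromosomes: int = 7
    chrom_length: int = CHROM_LENGTH
    conditions: tuple[str, ...] = hio.CONDITIONS
    go_n_terms: int = 40
    go_terms_per_gene: float = 2.0
    go_odds_ratio: float = 8.0

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.n_pairs < 1:
            raise ConfigurationError("n_pairs must be >= 1")
        if min(self.n_singletons_a, self.n_singletons_d, self.n_unplaced_a, self.n_unplaced_d) < 0:
            raise ConfigurationError("gene counts must be non-negative")
        if self.replicates < 2:
            raise ConfigurationError("replicates must be >= 2")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.fold <= 1:
            raise ConfigurationError("fold must be > 1")
        if not 0 <= self.length_disparity_fraction <= 1:
            raise ConfigurationError("length_disparity_fraction must be in [0, 1]")
        per_chrom = -(-(self.n_pairs + max(self.n_singletons_a, self.n_singletons_d)) // self.n_chromosomes)
        if per_chrom * GENE_SPAN > self.chrom_length:
            raise ConfigurationError("more genes than placeable on the chromosomes")
        for cond in self.conditions:
            props = self.mode_proportions.get(cond)
            if props is None or len(props) != 9:
                raise ConfigurationError(f"mode_proportions must give 9 values for {cond!r}")
            if abs(sum(props) - 1.0) > 1e-8 or min(props) < 0:
                raise ConfigurationError(f"mode proportions for {cond!r} must be a distribution")
        if abs(sum(self.attribution_probs) - 1.0) > 1e-8 or min(self.attribution_probs) < 0:
            raise ConfigurationError("attribution_probs must be a distribution")
        for chrom, start, end, _line, mult in self.he_regions:
            if start >= end or mult < 0:
                raise ConfigurationError(f"invalid HE region {chrom}:{start}-{end} x{mult}")


@dataclass
class TruthTable:
    """Planted ground truth of one simulated dataset.

    ``pair_truth`` has one row per pair x condition with the planted parental
    and progeny ratio states, mode, fold magnitude, per-copy change and the
    per-copy Mix-scale and progeny rates.  ``gene_truth`` is per gene:
    baseline Mix-scale rate, HE copy-number multiplier (X190) and, once counts
    are simulated, the expected mean raw count over all samples.
    """

    pair_truth: pd.DataFrame
    gene_truth: pd.DataFrame
    mix_rate: pd.DataFrame  # genes x conditions, Mix-scale per-copy rate
    prog_rate: pd.DataFrame  # genes x conditions, per-copy rate in tetraploids

    def validate(self) -> None:
        pt = self.pair_truth
        if not np.isclose(pt.groupby("condition").size().sum(), len(pt)):
            raise ConsistencyError("pair truth rows do not partition by condition")
        eq = pt["parent_state"] == "A=D"
        if not np.allclose(pt.loc[eq & (pt["progeny_state"] == "A=D"), "fold"], 1.0):
            raise ConsistencyError("fold must be exactly 1 for fully balanced pairs")
        if (self.gene_truth["he_multiplier"] < 0).any():
            raise ConsistencyError("copy-number multipliers must be non-negative")

    def expressed_genes(self) -> pd.Index:
        """Genes whose expected mean raw count over all samples is in [10, 5000]."""
        m = self.gene_truth["expected_mean"]
        return self.gene_truth.index[(m >= 10) & (m <= 5000)]

    def deg_truth(self, line: str, condition: str) -> pd.Series:
        """True changed-vs-Mix status per gene for one tetraploid line."""
        rate_mix = self.mix_rate[condition]
        rate_prog = self.prog_rate[condition].copy()
        if line == "X190":
            rate_prog = rate_prog * self.gene_truth["he_multiplier"]
        return pd.Series(
            ~np.isclose(rate_prog.to_numpy(), rate_mix.to_numpy()),
            index=self.gene_truth.index,
        )


@dataclass
class SimulatedDataset:
    """Bundle of everything one simulation run produces."""

    config: SimulationConfig
    catalog_a: pd.DataFrame
    catalog_d: pd.DataFrame
    pairs: pd.DataFrame
    he_regions: pd.DataFrame
    truth: TruthTable
    counts: pd.DataFrame
    design: pd.DataFrame
    go_map: pd.DataFrame
    go_enriched_term: str

    @property
    def catalog(self) -> pd.DataFrame:
        return hio.merge_catalogs(self.catalog_a, self.catalog_d)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """One master seed, deterministic sub-streams per stage."""
    names = ("catalog", "truth", "counts", "go")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


# ---------------------------------------------------------------------------
# catalog


def generate_catalog(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the two parental gene catalogs, the 1:1 pair table and the HE
    interval table.

    Pair i links ``gA{i}`` and ``gD{i}``; the configured fraction of pairs is
    given a transcript-length disparity exceeding 10% (length ratio drawn in
    [0.70, 0.85]), the rest stay within 10% (ratio in [0.92, 1.0]).
    """
    config.validate()
    rng = _streams(config.seed)["catalog"]
    catalogs = {}
    for sub, n_single, n_unplaced in (
        ("A", config.n_singletons_a, config.n_unplaced_a),
        ("D", config.n_singletons_d, config.n_unplaced_d),
    ):
        n_placed = config.n_pairs + n_single
        chrom_idx = np.arange(n_placed) % config.n_chromosomes
        within = np.arange(n_placed) // config.n_chromosomes
        per_chrom = np.bincount(chrom_idx, minlength=config.n_chromosomes)
        starts = np.array(
            [
                int((within[i] + 0.5) * config.chrom_length / per_chrom[chrom_idx[i]])
                for i in range(n_placed)
            ],
            dtype=np.int64,
        )
        chroms = [f"Chr{c + 1}{sub}" for c in chrom_idx]
        ids = [f"g{sub}{i}" for i in range(n_placed + n_unplaced)]
        catalogs[sub] = pd.DataFrame(
            {
                "subgenome": sub,
                "chromosome": chroms + [hio.UNPLACED] * n_unplaced,
                "start": np.concatenate([starts, np.zeros(n_unplaced, dtype=np.int64)]),
                "end": np.concatenate(
                    [starts + GENE_SPAN, np.zeros(n_unplaced, dtype=np.int64)]
                ),
                "transcript_length": 0,  # filled below
            },
            index=pd.Index(ids, name="gene_id"),
        )

    # transcript lengths: paired genes get correlated lengths with the
    # configured disparity structure; singletons are independent
    n = config.n_pairs
    base_len = np.round(_log_uniform(rng, 600, 6000, n)).astype(np.int64)
    n_violate = int(round(config.length_disparity_fraction * n))
    violate = np.zeros(n, dtype=bool)
    violate[rng.permutation(n)[:n_violate]] = True
    ratio = np.where(
        violate, rng.uniform(0.70, 0.85, n), rng.uniform(0.92, 1.0, n)
    )
    shorter_is_d = rng.random(n) < 0.5
    len_a = np.where(shorter_is_d, base_len, np.round(base_len * ratio)).astype(np.int64)
    len_d = np.where(shorter_is_d, np.round(base_len * ratio), base_len).astype(np.int64)

    for sub, lens in (("A", len_a), ("D", len_d)):
        cat = catalogs[sub]
        extra = len(cat) - n
        tl = np.concatenate(
            [lens, np.round(_log_uniform(rng, 600, 6000, extra)).astype(np.int64)]
        )
        cat["transcript_length"] = tl

    pairs = pd.DataFrame(
        {
            "pair_id": [f"p{i}" for i in range(n)],
            "a_gene": [f"gA{i}" for i in range(n)],
            "d_gene": [f"gD{i}" for i in range(n)],
            # generator-side truth: which pairs were planted to violate the
            # 10% transcript-length rule (not written to pairs.tsv)
            "planted_length_violation": violate,
        }
    )
    he = pd.DataFrame(
        list(config.he_regions),
        columns=["chromosome", "start", "end", "line", "multiplier"],
    )
    return catalogs["A"], catalogs["D"], pairs, he


# ---------------------------------------------------------------------------
# truth


def _progeny_rates(
    parent_a: np.ndarray,
    parent_d: np.ndarray,
    base: np.ndarray,
    mode: np.ndarray,
    attribution: np.ndarray,
    fold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-copy progeny rates realizing each planted mode transition.

    ``attribution`` is 0 = A copy changes, 1 = D copy changes, 2 = both.
    Conserved modes (1-3) leave both copies at their Mix rates; reversed
    modes (8-9) always change both copies.
    """
    sf = np.sqrt(fold)
    rate_a = parent_a.copy()
    rate_d = parent_d.copy()
    for i, (m, att) in enumerate(zip(mode, attribution)):
        b = base[i]
        if m in (1, 2, 3):
            continue
        if m == 4:  # A>D -> A=D
            if att == 0:
                rate_a[i] = parent_d[i]
            elif att == 1:
                rate_d[i] = parent_a[i]
            else:
                rate_a[i] = rate_d[i] = b
        elif m == 5:  # A<D -> A=D
            if att == 0:
                rate_a[i] = parent_d[i]
            elif att == 1:
                rate_d[i] = parent_a[i]
            else:
                rate_a[i] = rate_d[i] = b
        elif m == 6:  # A=D -> A>D
            if att == 0:
                rate_a[i] = b * fold
            elif att == 1:
                rate_d[i] = b / fold
            else:
                rate_a[i], rate_d[i] = b * sf, b / sf
        elif m == 7:  # A=D -> A<D
            if att == 0:
                rate_a[i] = b / fold
            elif att == 1:
                rate_d[i] = b * fold
            else:
                rate_a[i], rate_d[i] = b / sf, b * sf
        elif m == 8:  # A>D -> A<D: both copies must move
            rate_a[i], rate_d[i] = parent_d[i], parent_a[i]
        elif m == 9:  # A<D -> A>D
            rate_a[i], rate_d[i] = parent_d[i], parent_a[i]
    return rate_a, rate_d


def generate_truth(
    config: SimulationConfig,
    catalog_a: pd.DataFrame,
    catalog_d: pd.DataFrame,
    pairs: pd.DataFrame,
    he_regions: pd.DataFrame,
) -> TruthTable:
    """Draw the planted truth: baseline rates, per-condition modes, per-copy
    changes and HE copy-number multipliers."""
    config.validate()
    rng = _streams(config.seed)["truth"]
    catalog = hio.merge_catalogs(catalog_a, catalog_d)
    genes = catalog.index
    n_genes = len(genes)
    n_pairs = len(pairs)

    # baseline Mix-scale rates, with clearly-low / clearly-high fractions so
    # the mean-count filter outcome is deterministic in expectation
    base = _log_uniform(rng, *config.rate_range, n_genes)
    u = rng.random(n_genes)
    base[u < config.frac_low] = config.low_rate
    base[(u >= config.frac_low) & (u < config.frac_low + config.frac_high)] = config.high_rate
    base = pd.Series(base, index=genes, name="base_rate")
    # pair members share one baseline (the A copy's draw)
    base[pairs["d_gene"].to_numpy()] = base[pairs["a_gene"].to_numpy()].to_numpy()

    # HE multipliers (apply to X190 only)
    mult = pd.Series(1.0, index=genes, name="he_multiplier")
    for row in he_regions.itertuples(index=False):
        if row.line != "X190":
            continue
        hit = (
            (catalog["chromosome"] == row.chromosome)
            & (catalog["start"] < row.end)
            & (catalog["end"] > row.start)
        )
        mult[hit.to_numpy()] = row.multiplier

    mix_rate = pd.DataFrame(
        {c: base.to_numpy(copy=True) for c in config.conditions}, index=genes
    )
    prog_rate = mix_rate.copy()

    records = []
    sf = np.sqrt(config.fold)
    for cond in config.conditions:
        props = np.asarray(config.mode_proportions[cond], dtype=float)
        mode = rng.choice(np.arange(1, 10), size=n_pairs, p=props / props.sum())
        attribution = rng.choice(3, size=n_pairs, p=config.attribution_probs)
        b = base[pairs["a_gene"].to_numpy()].to_numpy()
        parent_state = np.array([MODE_STATES[m][0] for m in mode])
        progeny_state = np.array([MODE_STATES[m][1] for m in mode])
        parent_a = np.where(
            parent_state == "A>D", b * sf, np.where(parent_state == "A<D", b / sf, b)
        )
        parent_d = np.where(
            parent_state == "A>D", b / sf, np.where(parent_state == "A<D", b * sf, b)
        )
        rate_a, rate_d = _progeny_rates(
            parent_a, parent_d, b, mode, attribution, config.fold
        )
        mix_rate.loc[pairs["a_gene"].to_numpy(), cond] = parent_a
        mix_rate.loc[pairs["d_gene"].to_numpy(), cond] = parent_d
        prog_rate.loc[pairs["a_gene"].to_numpy(), cond] = rate_a
        prog_rate.loc[pairs["d_gene"].to_numpy(), cond] = rate_d

        def _chg(new: np.ndarray, old: np.ndarray) -> np.ndarray:
            out = np.full(len(new), "unchanged", dtype=object)
            out[new > old * (1 + 1e-9)] = "up"
            out[new < old * (1 - 1e-9)] = "down"
            return out

        fold_col = np.where((parent_state == "A=D") & (progeny_state == "A=D"), 1.0, config.fold)
        records.append(
            pd.DataFrame(
                {
                    "pair_id": pairs["pair_id"],
                    "a_gene": pairs["a_gene"],
                    "d_gene": pairs["d_gene"],
                    "condition": cond,
                    "mode": mode,
                    "parent_state": parent_state,
                    "progeny_state": progeny_state,
                    "fold": fold_col,
                    "a_change": _chg(rate_a, parent_a),
                    "d_change": _chg(rate_d, parent_d),
                    "base_rate": b,
                    "mix_rate_a": parent_a,
                    "mix_rate_d": parent_d,
                    "progeny_rate_a": rate_a,
                    "progeny_rate_d": rate_d,
                }
            )
        )

    gene_truth = pd.DataFrame(
        {"base_rate": base, "he_multiplier": mult, "expected_mean": np.nan}, index=genes
    )
    truth = TruthTable(
        pair_truth=pd.concat(records, ignore_index=True),
        gene_truth=gene_truth,
        mix_rate=mix_rate,
        prog_rate=prog_rate,
    )
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# counts


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    if dispersion == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    config: SimulationConfig,
    truth: TruthTable,
    catalog: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the count matrix and sample design from the planted truth.

    Also fills ``truth.gene_truth['expected_mean']`` with the exact expected
    mean raw count per gene over all samples (library factors included), which
    is the quantity the mean-count filter estimates.
    """
    config.validate()
    rng = _streams(config.seed)["counts"]
    genes = catalog.index
    is_a = (catalog["subgenome"] == "A").to_numpy()

    samples, genotypes, conditions, reps = [], [], [], []
    for genotype in hio.GENOTYPES:
        for cond in config.conditions:
            for r in range(1, config.replicates + 1):
                samples.append(f"{genotype}_{cond}_r{r}")
                genotypes.append(genotype)
                conditions.append(cond)
                reps.append(r)
    design = pd.DataFrame(
        {"genotype": genotypes, "condition": conditions, "replicate": reps},
        index=pd.Index(samples, name="sample"),
    )
    lib = _log_uniform(rng, *config.libsize_range, len(samples))

    he_mult = truth.gene_truth["he_multiplier"].to_numpy()
    mu = np.zeros((len(genes), len(samples)))
    for j, (genotype, cond) in enumerate(zip(genotypes, conditions)):
        mix = truth.mix_rate[cond].to_numpy()
        prog = truth.prog_rate[cond].to_numpy()
        if genotype == "parentA":
            rate = np.where(is_a, 2.0 * mix, 0.0)
        elif genotype == "parentD":
            rate = np.where(is_a, 0.0, 2.0 * mix)
        elif genotype == "Mix":
            rate = mix
        elif genotype == "EUP":
            rate = prog
        else:  # X190
            rate = prog * he_mult
        mu[:, j] = rate * lib[j]

    counts = pd.DataFrame(
        _nb_sample(rng, mu, config.dispersion).astype(np.int64),
        index=genes,
        columns=samples,
    )
    truth.gene_truth["expected_mean"] = mu.mean(axis=1)
    return counts, design


# ---------------------------------------------------------------------------
# GO map


def generate_go_map(
    config: SimulationConfig,
    truth: TruthTable,
    catalog: pd.DataFrame,
    odds_ratio: float | None = None,
) -> tuple[pd.DataFrame, str]:
    """Random flat GO annotation with one planted enriched term.

    Background terms are assigned uniformly; the designated term ``GO:ENR``
    is assigned with probability inflated by ``odds_ratio`` for genes that are
    truly changed (EUP vs Mix, first condition).  Returns (go_map, term id).
    """
    config.validate()
    rng = _streams(config.seed)["go"]
    odds = config.go_odds_ratio if odds_ratio is None else odds_ratio
    genes = catalog.index
    n_genes = len(genes)
    n_terms = config.go_n_terms
    p_term = min(config.go_terms_per_gene / n_terms, 1.0)

    rows: list[tuple[str, str]] = []
    assign = rng.random((n_genes, n_terms)) < p_term
    for gi, gene in enumerate(genes):
        for ti in np.nonzero(assign[gi])[0]:
            rows.append((gene, f"GO:{ti:07d}"))

    changed = truth.deg_truth("EUP", config.conditions[0]).reindex(genes).fillna(False)
    p_base = p_term
    # inflate the odds of carrying the enriched term for changed genes
    base_odds = p_base / (1 - p_base)
    p_changed = (base_odds * odds) / (1 + base_odds * odds)
    p_enr = np.where(changed.to_numpy(), p_changed, p_base)
    hit = rng.random(n_genes) < p_enr
    enriched_term = "GO:ENR"
    for gene in genes[hit]:
        rows.append((gene, enriched_term))
    go_map = pd.DataFrame(rows, columns=["gene_id", "term_id"])
    return go_map, enriched_term


# ---------------------------------------------------------------------------
# one-shot driver


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run every generation stage with deterministic per-stage sub-streams."""
    catalog_a, catalog_d, pairs, he = generate_catalog(config)
    truth = generate_truth(config, catalog_a, catalog_d, pairs, he)
    catalog = hio.merge_catalogs(catalog_a, catalog_d)
    counts, design = simulate_counts(config, truth, catalog)
    go_map, enriched = generate_go_map(config, truth, catalog)
    return SimulatedDataset(
        config=config,
        catalog_a=catalog_a,
        catalog_d=catalog_d,
        pairs=pairs,
        he_regions=he,
        truth=truth,
        counts=counts,
        design=design,
        go_map=go_map,
        go_enriched_term=enriched,
    )


def swap_subgenomes(dataset: SimulatedDataset) -> SimulatedDataset:
    """Relabel A<->D everywhere (a symmetry check helper): pair columns swap,
    and the planted mode of every pair maps through the swap permutation."""
    pairs = dataset.pairs.rename(columns={"a_gene": "d_gene", "d_gene": "a_gene"})
    pair_truth = dataset.truth.pair_truth.copy()
    pair_truth["mode"] = [SWAP_MODE[m] for m in pair_truth["mode"]]
    truth = TruthTable(
        pair_truth=pair_truth,
        gene_truth=dataset.truth.gene_truth,
        mix_rate=dataset.truth.mix_rate,
        prog_rate=dataset.truth.prog_rate,
    )
    return replace(dataset, pairs=pairs, truth=truth)


def write_dataset(dataset: SimulatedDataset, outdir: str) -> None:
    """Write every exchange file of one simulated dataset."""
    import os

    os.makedirs(outdir, exist_ok=True)
    hio.write_counts(dataset.counts, os.path.join(outdir, "counts.tsv"))
    hio.write_design(dataset.design, os.path.join(outdir, "design.tsv"))
    hio.write_genes(dataset.catalog_a, os.path.join(outdir, "genes_A.bed"))
    hio.write_genes(dataset.catalog_d, os.path.join(outdir, "genes_D.bed"))
    hio.write_pairs(dataset.pairs, os.path.join(outdir, "pairs.tsv"))
    hio.write_intervals(dataset.he_regions, os.path.join(outdir, "he_regions.bed"))
    hio.write_go(dataset.go_map, os.path.join(outdir, "go_map.tsv"))
    dataset.truth.pair_truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    dataset.truth.gene_truth.to_csv(
        os.path.join(outdir, "truth_genes.tsv"), sep="\t", index_label="gene_id"
    )
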