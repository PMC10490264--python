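"""Generator contracts: determinism, planted structure, the mixing rule and
the negative-binomial count model."""

import numpy as np
import pandas as pd
import pytest

from homeoscope.enrichment import enrich
from homeoscope.exceptions import ConfigurationError
from homeoscope.filtering import length_disparity
from homeoscope.simulate import (
    DEFAULT_HE_REGIONS,
    SimulationConfig,
    generate_catalog,
    generate_go_map,
    generate_truth,
    simulate_counts,
    simulate_dataset,
    write_dataset,
)


def test_determinism_byte_identical(tmp_path):
    cfg = SimulationConfig(seed=11, n_pairs=80, n_singletons_a=10, n_singletons_d=10)
    for sub in ("a", "b"):
        write_dataset(simulate_dataset(cfg), str(tmp_path / sub))
    for name in ("counts.tsv", "design.tsv", "genes_A.bed", "pairs.tsv", "truth.tsv", "go_map.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_zero_singletons_catalog_sizes_equal_pair_count():
    cfg = SimulationConfig(
        seed=2, n_pairs=50, n_singletons_a=0, n_singletons_d=0,
        n_unplaced_a=0, n_unplaced_d=0,
    )
    cat_a, cat_d, pairs, _ = generate_catalog(cfg)
    assert len(cat_a) == len(cat_d) == len(pairs) == 50


def test_default_he_regions_match_known_breakpoints():
    he = pd.DataFrame(list(DEFAULT_HE_REGIONS),
                      columns=["chromosome", "start", "end", "line", "multiplier"])
    by_chrom = he.set_index("chromosome")
    assert by_chrom.loc["Chr2A", "start"] == 800_000
    assert by_chrom.loc["Chr2A", "end"] == 51_800_000
    assert by_chrom.loc["Chr2D", "start"] == 400_000
    assert by_chrom.loc["Chr2D", "end"] == 58_000_000
    assert by_chrom.loc["Chr3A", "start"] == 684_600_000
    assert by_chrom.loc["Chr3D", "start"] == 557_400_000
    # duplicated A segments, deleted D segments
    assert by_chrom.loc[["Chr2A", "Chr3A"], "multiplier"].eq(2.0).all()
    assert by_chrom.loc[["Chr2D", "Chr3D"], "multiplier"].eq(0.0).all()


def test_length_disparity_fraction_is_exact():
    cfg = SimulationConfig(seed=5, n_pairs=1000, length_disparity_fraction=0.2)
    cat_a, cat_d, pairs, _ = generate_catalog(cfg)
    la = cat_a.loc[pairs["a_gene"], "transcript_length"].to_numpy()
    ld = cat_d.loc[pairs["d_gene"], "transcript_length"].to_numpy()
    violates = length_disparity(la, ld) > 0.10
    assert violates.sum() == 200
    assert (violates == pairs["planted_length_violation"].to_numpy()).all()


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(seed=1, replicates=1).validate()
    with pytest.raises(ConfigurationError):
        SimulationConfig(seed=1, dispersion=-0.1).validate()
    with pytest.raises(ConfigurationError):
        SimulationConfig(seed=1, n_pairs=0).validate()
    with pytest.raises(ConfigurationError):
        SimulationConfig(seed=1, n_pairs=10**7).validate()  # unplaceable
    with pytest.raises(ConfigurationError):
        SimulationConfig(seed=1, mode_proportions={"mock-2d": (1.0,)}).validate()


def test_zero_dispersion_counts_are_poisson():
    """With dispersion 0 the NB degenerates to Poisson: variance ~ mean."""
    cfg = SimulationConfig(
        seed=3, n_pairs=40, n_singletons_a=0, n_singletons_d=0,
        n_unplaced_a=0, n_unplaced_d=0, dispersion=0.0, replicates=60,
        libsize_range=(1.0, 1.0), conditions=("mock-2d",),
        mode_proportions={"mock-2d": (0, 0, 1.0, 0, 0, 0, 0, 0, 0)},
    )
    ds = simulate_dataset(cfg)
    mix = ds.design.index[ds.design["genotype"] == "Mix"]
    k = ds.counts[mix].to_numpy(dtype=float)
    mean = k.mean(axis=1)
    var = k.var(axis=1, ddof=1)
    # Var/mean ratio concentrates near 1 for Poisson (chi2 tail bound ~4 sd)
    ratio = var / mean
    assert abs(ratio.mean() - 1.0) < 0.1
    assert (np.abs(ratio - 1.0) < 1.0).all()


@pytest.fixture(scope="module")
def deep_dataset():
    """Many replicates, one condition: for Monte-Carlo mean checks."""
    cfg = SimulationConfig(
        seed=4, n_pairs=60, n_singletons_a=20, n_singletons_d=20,
        n_unplaced_a=0, n_unplaced_d=0, replicates=400,
        libsize_range=(1.0, 1.0), conditions=("mock-2d",),
        mode_proportions={"mock-2d": (0.5, 0, 0.5, 0, 0, 0, 0, 0, 0)},
    )
    return simulate_dataset(cfg)


def test_planted_progeny_ratio_recovered(deep_dataset):
    """A pair planted A>D with fold 4: the Monte-Carlo mean ratio of progeny
    A-copy to D-copy counts approaches 4."""
    ds = deep_dataset
    truth = ds.truth.pair_truth
    planted = truth[(truth["condition"] == "mock-2d") & (truth["mode"] == 1)]
    eup = ds.design.index[ds.design["genotype"] == "EUP"]
    ka = ds.counts.loc[planted["a_gene"], eup].to_numpy().mean(axis=1)
    kd = ds.counts.loc[planted["d_gene"], eup].to_numpy().mean(axis=1)
    ratios = ka / kd
    assert np.allclose(ratios, 4.0, rtol=0.15)
    assert abs(np.mean(ratios) - 4.0) < 0.2


def test_mixing_contract(deep_dataset):
    """mean(Mix)/mean(parent A) -> 0.5 for A genes (equal-mass mixture at
    fixed depth); CLT tolerance at 400 replicates."""
    ds = deep_dataset
    a_genes = ds.catalog_a.index
    mix = ds.design.index[ds.design["genotype"] == "Mix"]
    pa = ds.design.index[ds.design["genotype"] == "parentA"]
    m_mix = ds.counts.loc[a_genes, mix].to_numpy().mean(axis=1)
    m_par = ds.counts.loc[a_genes, pa].to_numpy().mean(axis=1)
    ratio = m_mix / m_par
    assert abs(ratio.mean() - 0.5) < 0.02
    # parent-exclusive expression: D genes are silent in parent A
    d_genes = ds.catalog_d.index
    assert ds.counts.loc[d_genes, pa].to_numpy().sum() == 0


def test_he_deletion_zeroes_x190(default_dataset):
    """Genes in a deleted HE segment (multiplier 0) yield zero counts in all
    X190 samples."""
    ds = default_dataset
    gt = ds.truth.gene_truth
    deleted = gt.index[gt["he_multiplier"] == 0.0]
    assert len(deleted) > 0
    x190 = ds.design.index[ds.design["genotype"] == "X190"]
    assert ds.counts.loc[deleted, x190].to_numpy().sum() == 0
    # and duplicated segments roughly double vs EUP
    dup = gt.index[gt["he_multiplier"] == 2.0]
    eup = ds.design.index[ds.design["genotype"] == "EUP"]
    r = (
        ds.counts.loc[dup, x190].to_numpy().mean()
        / ds.counts.loc[dup, eup].to_numpy().mean()
    )
    assert 1.6 < r < 2.4


def test_planted_mode_proportions_within_multinomial_error(default_dataset):
    truth = default_dataset.truth.pair_truth
    cfg = default_dataset.config
    for cond in cfg.conditions:
        sub = truth[truth["condition"] == cond]
        n = len(sub)
        observed = sub["mode"].value_counts()
        for m in range(1, 10):
            p = cfg.mode_proportions[cond][m - 1]
            tol = 5 * np.sqrt(n * p * (1 - p)) + 1
            assert abs(observed.get(m, 0) - n * p) < tol, (cond, m)


def test_truth_invariants(default_dataset):
    truth = default_dataset.truth
    truth.validate()
    pt = truth.pair_truth
    balanced = (pt["parent_state"] == "A=D") & (pt["progeny_state"] == "A=D")
    assert (pt.loc[balanced, "fold"] == 1.0).all()
    assert (pt.loc[~balanced, "fold"] > 1.0).all()
    assert (truth.gene_truth["he_multiplier"] >= 0).all()


def test_go_map_enriched_term_wins_across_seeds():
    """With a strong planted odds ratio, the designated term attains the
    smallest adjusted p among all terms in nearly every seed (tested on the
    planted truth DEG set, independent of the DE engine)."""
    wins = 0
    n_seeds = 100
    for seed in range(n_seeds):
        cfg = SimulationConfig(
            seed=seed, n_pairs=150, n_singletons_a=20, n_singletons_d=20,
            n_unplaced_a=0, n_unplaced_d=0, go_odds_ratio=20.0,
        )
        cat_a, cat_d, pairs, he = generate_catalog(cfg)
        import homeoscope.io as hio

        catalog = hio.merge_catalogs(cat_a, cat_d)
        truth = generate_truth(cfg, cat_a, cat_d, pairs, he)
        simulate_counts(cfg, truth, catalog)  # fills expected means
        go_map, term = generate_go_map(cfg, truth, catalog)
        changed = truth.deg_truth("EUP", "mock-2d")
        universe = set(truth.expressed_genes())
        degs = {g for g in changed.index[changed] if g in universe}
        res = enrich(degs, universe, go_map)
        if len(res) and res.iloc[0]["term_id"] == term:
            wins += 1
    assert wins >= 95


def test_go_small_terms_excluded_downstream(small_dataset):
    ds = small_dataset
    universe = set(ds.catalog.index)
    go_map = ds.go_map
    sizes = go_map.groupby("term_id").size()
    small_terms = set(sizes.index[sizes < 5])
    res = enrich(set(), universe, go_map, min_term_size=5)
    assert small_terms.isdisjoint(res["term_id"])
    assert (res["K"] >= 5).all()
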