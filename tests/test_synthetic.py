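"""Generator properties: determinism, divergence, corruption rates,
annotation structure, trait conservation and trial structure."""

import numpy as np
import pandas as pd
import pytest

import panelgs as pg
from panelgs.dosage import HET, MISSING
from tests.conftest import as_final


def test_same_seed_bit_identical():
    cfg = pg.SimulationConfig(seed=7, n_lines_per_panel=20, n_markers=300)
    g1, s1 = pg.simulate_panel_genotypes(cfg)
    g2, s2 = pg.simulate_panel_genotypes(cfg)
    assert np.array_equal(g1.values, g2.values)
    assert g1.markers.equals(g2.markers)
    assert np.array_equal(s1.panel_labels, s2.panel_labels)


def test_config_validation():
    with pytest.raises(ValueError):
        pg.SimulationConfig(fst=1.0)
    with pytest.raises(ValueError):
        pg.SimulationConfig(missing_rate_mean=1.5)
    with pytest.raises(ValueError):
        pg.SimulationConfig(n_markers=50, n_qtl=100)
    with pytest.raises(ValueError):
        pg.SimulationConfig(n_markers=5, n_chrom=10, n_qtl=2)
    with pytest.raises(ValueError):
        pg.SimulationConfig(variance_components=(-1, 0, 0, 0, 1))


@pytest.mark.parametrize("fst,separated", [(0.0, False), (0.3, True)])
def test_divergence_controls_pc1_split(fst, separated):
    """fst=0 gives exchangeable lines; fst=0.3 splits the sub-panels on PC1."""
    cfg = pg.SimulationConfig(seed=3, n_lines_per_panel=40, n_markers=600, fst=fst)
    g, state = pg.simulate_panel_genotypes(cfg)
    res = pg.pca(as_final(g), 2)
    pc1 = res.scores[:, 0]
    r = abs(np.corrcoef(pc1, state.panel_labels)[0, 1])
    if separated:
        assert r >= 0.8
        a, b = pc1[state.panel_labels == 0], pc1[state.panel_labels == 1]
        cross = np.abs(a[:, None] - b[None, :])
        within = np.concatenate([np.abs(np.subtract.outer(a, a))[np.triu_indices(len(a), 1)],
                                 np.abs(np.subtract.outer(b, b))[np.triu_indices(len(b), 1)]])
        assert cross.min() > np.median(within)
    else:
        assert r < 0.5


def test_corrupt_noop_when_rates_zero(small_panel):
    g, _ = small_panel
    cfg = pg.SimulationConfig(seed=1, n_lines_per_panel=40, n_markers=800,
                              missing_rate_mean=0.0, het_artifact_rate=0.0)
    out = pg.corrupt_genotypes(g, cfg)
    assert np.array_equal(out.values, g.values)


def test_corrupt_realized_missing_rate():
    cfg = pg.SimulationConfig(seed=5, n_lines_per_panel=100, n_markers=2000,
                              missing_rate_mean=0.30)
    g, _ = pg.simulate_panel_genotypes(cfg)
    out = pg.corrupt_genotypes(g, cfg)
    frac = float(np.mean(out.values == MISSING))
    assert 0.28 <= frac <= 0.32


def test_corrupt_creates_artifact_loci(small_panel, small_cfg):
    g, _ = small_panel
    out = pg.corrupt_genotypes(g, small_cfg)
    called = out.values != MISSING
    het_frac = (out.values == HET).sum(0) / np.maximum(called.sum(0), 1)
    assert het_frac.max() > 0.5  # at least one duplicated-region-like locus


def test_annotation_structure(small_cfg, annotation):
    genes = annotation.genes
    assert (genes["start"] <= genes["end"]).all()
    # non-overlapping within chromosome
    for _, grp in genes.groupby("chrom"):
        s = grp.sort_values("start")
        assert (s["start"].to_numpy()[1:] > s["end"].to_numpy()[:-1]).all()
    sizes = [len(v) for v in annotation.gene_to_go.values()]
    assert min(sizes) >= 1 and max(sizes) <= 40


def test_annotation_empty_when_gene_fraction_zero(small_panel):
    cfg = pg.SimulationConfig(seed=1, n_lines_per_panel=40, n_markers=800,
                              gene_fraction=0.0)
    ann = pg.simulate_gene_annotation(cfg)
    assert len(ann.genes) == 0
    g, _ = small_panel
    assignments = pg.assign_snps_to_genes(g.markers, ann)
    assert all(len(t) == 0 for t in assignments)


def test_annotation_deterministic_gff_text(tmp_path, small_cfg):
    from panelgs.io import write_gff3

    a1 = pg.simulate_gene_annotation(small_cfg)
    a2 = pg.simulate_gene_annotation(small_cfg)
    p1, p2 = tmp_path / "a1.gff3", tmp_path / "a2.gff3"
    write_gff3(a1, p1)
    write_gff3(a2, p2)
    assert p1.read_text() == p2.read_text()


def test_go_clusters_cover_exactly_genic_snps(small_final, annotation):
    assignments = pg.assign_snps_to_genes(small_final.markers, annotation)
    clusters = pg.build_go_clusters(assignments)
    genic = {i for i, t in enumerate(assignments) if t}
    union = set().union(*clusters.values()) if clusters else set()
    assert union == genic
    assert all(len(v) >= 1 for v in clusters.values())


def test_breeding_values_exact_dosage_product(small_final, annotation, small_cfg):
    state = pg.simulate_qtl_architecture(small_final, annotation, small_cfg)
    expect = small_final.values.astype(float) @ state.true_effects
    assert np.array_equal(state.true_breeding_values, expect)
    assert len(state.true_effects) == small_final.n_markers
    assert np.count_nonzero(state.true_effects) == small_cfg.n_qtl


def test_planted_term_must_exist(small_final, annotation):
    cfg = pg.SimulationConfig(seed=1, n_lines_per_panel=40, n_markers=800,
                              planted_terms=(("GO:9999999", 5.0),))
    with pytest.raises(ValueError, match="absent"):
        pg.simulate_qtl_architecture(small_final, annotation, cfg)


def test_planting_multiplies_effects(small_final, annotation):
    term = pg.pick_plantable_term(small_final, annotation, 10)
    base = pg.SimulationConfig(seed=9, n_lines_per_panel=40, n_markers=800,
                               n_qtl=800)
    planted = pg.SimulationConfig(seed=9, n_lines_per_panel=40, n_markers=800,
                                  n_qtl=800, planted_terms=((term, 5.0),))
    s0 = pg.simulate_qtl_architecture(small_final, annotation, base)
    s1 = pg.simulate_qtl_architecture(small_final, annotation, planted)
    assignments = pg.assign_snps_to_genes(small_final.markers, annotation)
    inside = np.array([term in t for t in assignments])
    assert np.allclose(s1.true_effects[inside], 5.0 * s0.true_effects[inside])
    assert np.array_equal(s1.true_effects[~inside], s0.true_effects[~inside])


def test_trials_noise_free_replicates_identical():
    cfg = pg.SimulationConfig(seed=2, n_lines_per_panel=10, n_markers=100,
                              n_qtl=50, variance_components=(2.0, 0.0, 0.0, 0.0, 0.0),
                              beta_stand=0.0, gamma_flowering=0.0, n_years=2)
    rng = np.random.default_rng(0)
    state = pg.TruePanelState(panel_labels=np.zeros(20, int),
                              true_breeding_values=rng.normal(size=20))
    obs = pg.simulate_trials(state, cfg)
    spread = obs.groupby(["genotype", "year"])["trait"].agg(lambda s: s.max() - s.min())
    assert np.allclose(spread, 0.0)


def test_trials_structure_and_errors():
    cfg = pg.SimulationConfig(seed=2, n_lines_per_panel=10, n_markers=100,
                              n_qtl=50, n_years=1)
    state = pg.TruePanelState(panel_labels=np.zeros(20, int))
    with pytest.raises(ValueError, match="breeding values"):
        pg.simulate_trials(state, cfg)
    state.true_breeding_values = np.arange(20.0)
    obs = pg.simulate_trials(state, cfg)
    assert set(obs.columns) == {"genotype", "year", "rep", "block", "stand",
                                "flowering", "trait"}
    assert obs["year"].nunique() == 1
    assert obs["rep"].nunique() == cfg.n_reps
    assert (obs["stand"] >= 1).all()
    # every genotype appears once per replicate (resolvable design)
    counts = obs.groupby(["genotype", "rep"]).size()
    assert (counts == 1).all()
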