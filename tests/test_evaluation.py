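"""Cross-validation, prediction scenarios and marker-density experiments."""

import numpy as np
import pytest

import panelgs as pg
from panelgs.gs import GsModelSpec
from tests.conftest import as_final

RR = GsModelSpec(model="RRBLUP")


@pytest.fixture(scope="module")
def panel():
    cfg = pg.SimulationConfig(seed=51, n_lines_per_panel=50, n_markers=600,
                              n_qtl=300)
    g, state = pg.simulate_panel_genotypes(cfg)
    final = as_final(g)
    state = pg.simulate_qtl_architecture(final, None, cfg, state)
    return final, state


def test_fold_contract():
    ids = [f"L{i}" for i in range(200)]
    folds = pg.make_folds(ids, 10, seed=3)
    sizes = [len(folds.fold_ids(f)) for f in range(1, 11)]
    assert sizes == [20] * 10
    union = set().union(*(folds.fold_ids(f) for f in range(1, 11)))
    assert union == set(ids)
    assert pg.make_folds(ids, 10, seed=3).assignment == folds.assignment
    assert any(pg.make_folds(ids, 10, seed=s).assignment != folds.assignment
               for s in range(4, 9))
    with pytest.raises(ValueError):
        pg.make_folds(ids, 1)
    with pytest.raises(ValueError):
        pg.make_folds(ids[:5], 10)


def test_unbalanced_fold_sizes():
    folds = pg.make_folds([f"L{i}" for i in range(23)], 5, seed=0)
    sizes = sorted(len(folds.fold_ids(f)) for f in range(1, 6))
    assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 23


def test_cv_noiseless_high_ability():
    """Noiseless fully additive trait (every marker causal) on the full
    200-line panel: RRBLUP CV ability approaches the no-noise ceiling."""
    cfg = pg.SimulationConfig(seed=41, n_lines_per_panel=100, n_markers=500,
                              n_qtl=500)
    g, state = pg.simulate_panel_genotypes(cfg)
    final = as_final(g)
    state = pg.simulate_qtl_architecture(final, None, cfg, state)
    folds = pg.make_folds(final.lines, 10, seed=1)
    cv = pg.cross_validate(final, state.true_breeding_values, RR, folds)
    assert cv.mean_ability >= 0.95
    assert len(cv.predictions) == final.n_lines
    assert abs(cv.mean_ability - cv.pooled_ability) <= 0.05


def test_cv_null_trait_near_zero(panel):
    final, _ = panel
    folds = pg.make_folds(final.lines, 10, seed=1)
    abilities = []
    for seed in range(10):
        y = np.random.default_rng(seed).normal(size=final.n_lines)
        abilities.append(pg.cross_validate(final, y, RR, folds).mean_ability)
    assert abs(np.mean(abilities)) <= 0.2


def test_cv_shift_invariance(panel):
    final, state = panel
    y = state.true_breeding_values
    folds = pg.make_folds(final.lines, 5, seed=2)
    a = pg.cross_validate(final, y, RR, folds).mean_ability
    b = pg.cross_validate(final, y + 100.0, RR, folds).mean_ability
    assert a == pytest.approx(b, abs=1e-9)


def test_cv_no_leakage_canary(panel):
    """Permuting one fold's phenotypes must not change the predictions for
    that fold (its lines are never in the training data)."""
    final, state = panel
    y = state.true_breeding_values.copy()
    folds = pg.make_folds(final.lines, 5, seed=3)
    cv1 = pg.cross_validate(final, y, RR, folds)
    test_ids = folds.fold_ids(2)
    pos = {l: i for i, l in enumerate(final.lines)}
    idx = [pos[l] for l in test_ids]
    y2 = y.copy()
    y2[idx] = np.random.default_rng(0).permutation(y2[idx])
    cv2 = pg.cross_validate(final, y2, RR, folds)
    p1 = cv1.predictions.query("fold == 2").set_index("line")["gebv"]
    p2 = cv2.predictions.query("fold == 2").set_index("line")["gebv"]
    assert np.allclose(p1.sort_index(), p2.sort_index())


def test_across_sets_scenarios(panel):
    final, state = panel
    y = state.true_breeding_values
    half = final.n_lines // 2
    A, B = final.take_lines(np.arange(half)), final.take_lines(np.arange(half, 2 * half))
    ability = pg.predict_across_sets(A, y[:half], B, y[half:], RR)
    assert -1 <= ability <= 1
    with pytest.raises(ValueError, match="overlap"):
        pg.predict_across_sets(A, y[:half], A, y[:half], RR)
    # allow flag: in-sample ability >= CV ability on the same data
    folds = pg.make_folds(A.lines, 5, seed=1)
    rng = np.random.default_rng(0)
    ynoise = y[:half] + rng.normal(0, y.std(), half)
    in_sample = pg.predict_across_sets(A, ynoise, A, ynoise, RR,
                                       allow_overlap=True)
    cv = pg.cross_validate(A, ynoise, RR, folds)
    assert in_sample >= cv.mean_ability
    with pytest.raises(ValueError, match="absent"):
        eff = pg.fit_rrblup(A, y[:half])
        pg.predict_gebv(eff, B.take_markers(np.arange(10)))


def test_across_panel_ability_below_within(panel):
    """Structured panels predict better within than across sub-panels."""
    cfg = pg.SimulationConfig(seed=61, n_lines_per_panel=50, n_markers=600,
                              n_qtl=300, fst=0.4)
    g, state = pg.simulate_panel_genotypes(cfg)
    final = as_final(g)
    state = pg.simulate_qtl_architecture(final, None, cfg, state)
    y = state.true_breeding_values + np.random.default_rng(61).normal(
        0, state.true_breeding_values.std() * 0.4, final.n_lines)
    a_idx = np.where(state.panel_labels == 0)[0]
    b_idx = np.where(state.panel_labels == 1)[0]
    A, B = final.take_lines(a_idx), final.take_lines(b_idx)
    across = pg.predict_across_sets(A, y[a_idx], B, y[b_idx], RR)
    folds = pg.make_folds(A.lines, 5, seed=1)
    within = pg.cross_validate(A, y[a_idx], RR, folds).mean_ability
    assert across < within


def test_halving_schedule():
    assert pg.halving_schedule(1024) == [1024, 512, 256, 128, 64, 32, 16]
    assert pg.halving_schedule(100) == [100, 50, 25]  # ceil(25/2)=13 < 16
    assert pg.halving_schedule(33) == [33, 17]
    with pytest.raises(ValueError):
        pg.halving_schedule(8)


def test_density_full_level_equals_plain_cv(panel):
    final, state = panel
    y = state.true_breeding_values
    folds = pg.make_folds(final.lines, 5, seed=4)
    plain = pg.cross_validate(final, y, RR, folds).mean_ability
    res = pg.density_random_thinning(final, y, folds, n_subsets=2, seed=0)
    full = res.table.query("n_markers == @final.n_markers")
    assert len(full) == 1
    assert full["ability"].iloc[0] == pytest.approx(plain, abs=0)


def test_density_top_effect_nesting_and_first_level(panel):
    final, state = panel
    y = state.true_breeding_values
    folds = pg.make_folds(final.lines, 5, seed=4)
    plain = pg.cross_validate(final, y, RR, folds)
    res = pg.density_top_effect(final, y, folds)
    first = res.table.query("scheme == 'top_effect' and n_markers == @final.n_markers")
    assert np.allclose(sorted(first["ability"]), sorted(plain.per_fold))
    levels = pg.halving_schedule(final.n_markers)
    for f, sets in res.selected_markers.items():
        for a, b in zip(sets, sets[1:]):
            assert set(b) <= set(a)
        assert [len(s) for s in sets] == levels


def test_top_effect_beats_random_on_sparse_architecture():
    """20 large QTL: effect-guided selection at 64 markers outperforms the
    median random subset of 64."""
    cfg = pg.SimulationConfig(seed=71, n_lines_per_panel=50, n_markers=512,
                              n_qtl=20, qtl_effect_scale=1.5)
    g, state = pg.simulate_panel_genotypes(cfg)
    final = as_final(g)
    state = pg.simulate_qtl_architecture(final, None, cfg, state)
    y = state.true_breeding_values
    folds = pg.make_folds(final.lines, 5, seed=1)
    top = pg.density_top_effect(final, y, folds)
    rnd = pg.density_random_thinning(final, y, folds, n_subsets=10, seed=2)
    t64 = top.table.query("scheme == 'top_effect_mean' and n_markers == 64")["ability"].iloc[0]
    r64 = rnd.table.query("n_markers == 64")["ability"].median()
    assert t64 >= r64


def test_ability_increases_with_heritability(panel):
    """CV ability rises with simulated h2 across {0.2, 0.5, 0.8}."""
    final, state = panel
    g = state.true_breeding_values
    folds = pg.make_folds(final.lines, 5, seed=5)
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        abilities = []
        for h2 in (0.2, 0.5, 0.8):
            noise_sd = g.std() * np.sqrt((1 - h2) / h2)
            y = g + rng.normal(0, noise_sd, len(g))
            abilities.append(pg.cross_validate(final, y, RR, folds).mean_ability)
        wins += abilities[0] < abilities[1] < abilities[2]
    assert wins >= 9
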