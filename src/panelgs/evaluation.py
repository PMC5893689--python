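"""Cross-validation, across-set prediction scenarios and the two
marker-density experiments.

Predictive ability is the Pearson correlation between GEBVs and the
phenotype-derived breeding values of held-out lines.  The headline CV number
is the mean of per-fold correlations; the pooled correlation over all
out-of-fold predictions is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .dosage import DosageMatrix
from .gs import GsModelSpec, fit_gs_model, predict_gebv


@dataclass
class FoldAssignment:
    """Mapping line id -> fold index (1..k)."""

    assignment: dict
    k: int
    seed: int

    def fold_ids(self, fold: int):
        return [i for i, f in self.assignment.items() if f == fold]


@dataclass
class CvResult:
    per_fold: np.ndarray          # Pearson r per fold
    mean_ability: float           # mean of per-fold correlations (headline)
    pooled_ability: float         # correlation over all out-of-fold pairs
    predictions: pd.DataFrame     # line, fold, gebv, observed


@dataclass
class DensityResult:
    table: pd.DataFrame  # columns: n_markers, replicate, ability, scheme
    scheme: str
    # top-effect scheme: fold -> list of nested marker-index arrays per level
    selected_markers: Optional[dict] = None


def make_folds(line_ids, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Seeded uniform partition of line ids into k balanced folds
    (sizes differ by at most one)."""
    line_ids = list(line_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(line_ids):
        raise ValueError("k exceeds the number of lines")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(line_ids))
    assignment = {line_ids[idx]: (i % k) + 1 for i, idx in enumerate(order)}
    return FoldAssignment(assignment=assignment, k=k, seed=seed)


def _rows_of(M: DosageMatrix, ids):
    pos = {l: i for i, l in enumerate(M.lines)}
    return np.array([pos[i] for i in ids])


def _pearson(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 3:
        raise ValueError("correlation undefined for fewer than 3 lines")
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def cross_validate(M: DosageMatrix, y, spec: GsModelSpec,
                   folds: FoldAssignment) -> CvResult:
    """K-fold CV: fit on each training complement, predict the held-out fold,
    correlate GEBVs with the observed breeding values."""
    y = np.asarray(y, dtype=float)
    if len(y) != M.n_lines:
        raise ValueError("y must align with the rows of M")
    per_fold, records = [], []
    for f in range(1, folds.k + 1):
        test_ids = folds.fold_ids(f)
        if len(test_ids) < 3:
            raise ValueError(f"fold {f} has <3 lines; correlation undefined")
        train_ids = [l for l in M.lines if folds.assignment[l] != f]
        tr, te = _rows_of(M, train_ids), _rows_of(M, test_ids)
        eff = fit_gs_model(M.take_lines(tr), y[tr], spec)
        gebv = predict_gebv(eff, M.take_lines(te))
        per_fold.append(_pearson(gebv, y[te]))
        for lid, g, o in zip(test_ids, gebv, y[te]):
            records.append((lid, f, g, o))
    pred = pd.DataFrame(records, columns=["line", "fold", "gebv", "observed"])
    pooled = _pearson(pred["gebv"], pred["observed"])
    return CvResult(per_fold=np.array(per_fold),
                    mean_ability=float(np.nanmean(per_fold)),
                    pooled_ability=pooled, predictions=pred)


def predict_across_sets(M_train: DosageMatrix, y_train, M_test: DosageMatrix,
                        y_test, spec: GsModelSpec,
                        allow_overlap: bool = False) -> float:
    """One fit on the training set, one prediction on the test set, one
    correlation.  Overlapping line ids raise (leakage guard) unless the
    across-year same-genotype scenario sets ``allow_overlap``."""
    overlap = set(M_train.lines) & set(M_test.lines)
    if overlap and not allow_overlap:
        raise ValueError(f"train/test lines overlap: {sorted(overlap)[:5]}...")
    eff = fit_gs_model(M_train, np.asarray(y_train, float), spec)
    gebv = predict_gebv(eff, M_test)
    return _pearson(gebv, np.asarray(y_test, float))


def halving_schedule(p0: int, minimum: int = 16):
    """Marker-count schedule p0, ceil(p0/2), ... stopping at the last
    value >= minimum."""
    if p0 < minimum:
        raise ValueError(f"need at least {minimum} markers")
    out = [p0]
    while True:
        nxt = int(np.ceil(out[-1] / 2))
        if nxt < minimum or nxt == out[-1]:
            break
        out.append(nxt)
    return out


def density_random_thinning(M: DosageMatrix, y, folds: FoldAssignment,
                            n_subsets: int = 10, seed: int = 0,
                            spec: Optional[GsModelSpec] = None) -> DensityResult:
    """Random marker thinning: at each halving level draw ``n_subsets``
    uniform marker subsets and run RRBLUP CV on each.  The full-density level
    is a single deterministic draw, so its ability equals plain CV exactly.
    """
    spec = spec or GsModelSpec(model="RRBLUP")
    rng = np.random.default_rng(seed)
    levels = halving_schedule(M.n_markers)
    rows = []
    for level in levels:
        draws = 1 if level == M.n_markers else n_subsets
        for rep in range(1, draws + 1):
            if level == M.n_markers:
                sub = M
            else:
                cols = np.sort(rng.choice(M.n_markers, size=level, replace=False))
                sub = M.take_markers(cols)
            cv = cross_validate(sub, y, spec, folds)
            rows.append((level, rep, cv.mean_ability, "random"))
    return DensityResult(
        table=pd.DataFrame(rows, columns=["n_markers", "replicate", "ability",
                                          "scheme"]),
        scheme="random")


def density_top_effect(M: DosageMatrix, y, folds: FoldAssignment,
                       spec: Optional[GsModelSpec] = None) -> DensityResult:
    """Effect-guided thinning inside CV: within each training fold, fit
    RRBLUP, keep the half of markers with largest |effect| (ties by marker
    order), refit, and evaluate the fold's test lines at every level.
    Selection uses only training data, so there is no leakage; marker sets
    are nested across levels within each fold.
    """
    spec = spec or GsModelSpec(model="RRBLUP")
    y = np.asarray(y, dtype=float)
    levels = halving_schedule(M.n_markers)
    per_level_fold = {lvl: [] for lvl in levels}
    sel_sets = {}
    for f in range(1, folds.k + 1):
        test_ids = folds.fold_ids(f)
        train_ids = [l for l in M.lines if folds.assignment[l] != f]
        tr, te = _rows_of(M, train_ids), _rows_of(M, test_ids)
        current = np.arange(M.n_markers)
        fold_sets = []
        for lvl in levels:
            if len(current) != lvl:
                raise AssertionError("schedule desynchronized")
            sub = M.take_markers(current)
            eff = fit_gs_model(sub.take_lines(tr), y[tr], spec)
            gebv = predict_gebv(eff, sub.take_lines(te))
            per_level_fold[lvl].append(_pearson(gebv, y[te]))
            fold_sets.append(current.copy())
            nxt = int(np.ceil(lvl / 2))
            if nxt >= 16 and nxt != lvl:
                # stable top-half selection: sort by (-|effect|, marker order)
                order = np.lexsort((np.arange(len(current)),
                                    -np.abs(eff.effects)))
                current = np.sort(current[order[:nxt]])
        sel_sets[f] = fold_sets
    rows = [(lvl, f + 1, r, "top_effect")
            for lvl in levels for f, r in enumerate(per_level_fold[lvl])]
    table = pd.DataFrame(rows, columns=["n_markers", "replicate", "ability",
                                        "scheme"])
    agg = table.groupby("n_markers", as_index=False)["ability"].mean()
    agg["replicate"] = 0
    agg["scheme"] = "top_effect_mean"
    return DensityResult(table=pd.concat([table, agg], ignore_index=True),
                         scheme="top_effect", selected_markers=sel_sets)
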