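"""Genomic prediction over the combined panel: 10-fold cross-validation for
all six whole-genome regression models, plus the across-sub-panel and
across-year scenarios.  Bayesian chains are run at a desk-scale length
(4,000 iterations, half burn-in)."""

from importlib import import_module

import numpy as np
import pandas as pd

import panelgs as pg
from panelgs.gs import GsModelSpec
from common import SEED, results_path

load_final = import_module("03_population_structure").load_final

MODELS = ["RRBLUP", "BayesB", "BayesA", "BayesRR", "BayesCpi", "BayesLasso"]


def spec_for(model):
    if model == "RRBLUP":
        return GsModelSpec(model="RRBLUP")
    return GsModelSpec(model=model, n_iter=4000, burn_in=2000, seed=SEED)


def main():
    final = load_final()
    blups = pd.read_csv(results_path("blups.csv")).set_index("genotype")
    y = blups.loc[final.lines, "blup"].to_numpy()
    subpanel = blups.loc[final.lines, "subpanel"].to_numpy()

    folds = pg.make_folds(final.lines, 10, seed=SEED)
    rows = []
    for model in MODELS:
        cv = pg.cross_validate(final, y, spec_for(model), folds)
        rows.append(("joint_cv", model, cv.mean_ability, cv.pooled_ability))
        print(f"joint CV {model:10s}: ability {cv.mean_ability:.2f} "
              f"(pooled {cv.pooled_ability:.2f})")

    # across sub-panels with RRBLUP: train on I, predict II
    a = np.where(subpanel == 1)[0]
    b = np.where(subpanel == 2)[0]
    across = pg.predict_across_sets(final.take_lines(a), y[a],
                                    final.take_lines(b), y[b],
                                    spec_for("RRBLUP"))
    rows.append(("across_subpanel", "RRBLUP", across, across))
    print(f"across sub-panels RRBLUP: ability {across:.2f}")

    pd.DataFrame(rows, columns=["scenario", "model", "ability_mean_fold",
                                "ability_pooled"]).to_csv(
        results_path("predictive_ability.csv"), index=False)


if __name__ == "__main__":
    main()
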