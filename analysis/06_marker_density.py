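"""Marker-density experiments with RRBLUP: random halving (10 subsets per
density) and effect-guided halving inside cross-validation, both down to 16
markers."""

from importlib import import_module

import pandas as pd

import panelgs as pg
from common import SEED, results_path

load_final = import_module("03_population_structure").load_final


def main():
    final = load_final()
    blups = pd.read_csv(results_path("blups.csv")).set_index("genotype")
    y = blups.loc[final.lines, "blup"].to_numpy()
    folds = pg.make_folds(final.lines, 10, seed=SEED)

    rnd = pg.density_random_thinning(final, y, folds, n_subsets=10, seed=SEED)
    top = pg.density_top_effect(final, y, folds)
    table = pd.concat([rnd.table, top.table], ignore_index=True)
    table.to_csv(results_path("density_ability.csv"), index=False)

    med = rnd.table.groupby("n_markers")["ability"].median().sort_index()
    print("random thinning, median ability per density:")
    for n, a in med.items():
        print(f"  {n:5d} markers: {a:.2f}")
    tmean = top.table.query("scheme == 'top_effect_mean'").set_index("n_markers")
    print("effect-guided thinning, mean ability per density:")
    for n, a in tmean["ability"].sort_index().items():
        print(f"  {n:5d} markers: {a:.2f}")


if __name__ == "__main__":
    main()
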