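"""Fit the lattice mixed models per sub-panel, select variance structures by
BIC in two stages (genetic/design terms first, then residual), estimate
heritability and write genotype BLUPs."""

import pandas as pd

import panelgs as pg
from common import results_path


def fit_subpanel(obs, multi_year):
    g_structs = ["CS", "ID", "DIAG"] if multi_year else ["ID"]
    stage1 = [pg.VcovSpec(genotype=s, rep="ID", block="ID", residual="ID")
              for s in g_structs]
    best1, table1 = pg.select_vcov_by_bic(obs, stage1, stage="random_terms")
    stage2 = [pg.VcovSpec(genotype=best1.spec.genotype, rep="ID", block="ID",
                          residual=r)
              for r in (["ID", "DIAG"] if multi_year else ["ID"])]
    best2, table2 = pg.select_vcov_by_bic(obs, stage2, stage="residual")
    return best2, pd.concat([table1, table2], ignore_index=True)


def main():
    obs_a = pd.read_csv(results_path("phenotypes_subpanel1.csv"))
    obs_b = pd.read_csv(results_path("phenotypes_subpanel2.csv"))

    best_a, bic_a = fit_subpanel(obs_a, multi_year=True)
    best_b, bic_b = fit_subpanel(obs_b, multi_year=False)
    pd.concat([bic_a.assign(subpanel=1), bic_b.assign(subpanel=2)],
              ignore_index=True).to_csv(results_path("bic_table.csv"),
                                        index=False)

    if best_a.spec.genotype == "CS":
        sg = best_a.varcomps["genotype"]["variance_main"]
        sga = best_a.varcomps["genotype"]["variance_interaction"]
    else:
        vals = list(best_a.varcomps["genotype"].values())
        sg, sga = sum(vals) / len(vals), 0.0
    se_a = list(best_a.varcomps["residual"].values())[0]
    h2_a = pg.heritability_multi_year(sg, sga, se_a, n_r=3, m=2)

    sg_b = best_b.varcomps["genotype"]["variance"]
    se_b = list(best_b.varcomps["residual"].values())[0]
    h2_b = pg.heritability_single_year(sg_b, se_b, n_r=3)

    blups = pd.concat([
        pg.genotype_blups(best_a).assign(subpanel=1),
        pg.genotype_blups(best_b).assign(subpanel=2),
    ], ignore_index=True)
    blups.to_csv(results_path("blups.csv"), index=False)

    print(f"sub-panel I : best spec {best_a.spec.label()}, "
          f"h2 = {h2_a:.2f} (sg2={sg:.2f}, sga2={sga:.2f}, se2={se_a:.2f})")
    print(f"sub-panel II: best spec {best_b.spec.label()}, h2 = {h2_b:.2f}")
    print(f"wrote {len(blups)} genotype BLUPs")


if __name__ == "__main__":
    main()
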