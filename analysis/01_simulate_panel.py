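"""Simulate the study panel and write its raw artifacts.

Generates the two-sub-panel inbred genotypes, corrupts them with GBS-style
missingness and heterozygous artifacts, lays out the gene/GO annotation,
draws the trait architecture (with one planted GO term for validation) and
simulates the lattice field trials.  Writes VCF, GFF3, gene->GO TSV and
phenotype CSVs under results/.
"""

import numpy as np
import pandas as pd

import panelgs as pg
from panelgs import io
from common import SEED, results_path, study_config


def main():
    cfg = study_config()
    g_clean, state = pg.simulate_panel_genotypes(cfg)
    raw = pg.corrupt_genotypes(g_clean, cfg)
    ann = pg.simulate_gene_annotation(cfg)

    final_clean = pg.recode_final(
        pg.DosageMatrix(g_clean.values.copy(), g_clean.markers.copy(),
                        list(g_clean.lines), coding_state="imputed"))
    term = pg.pick_plantable_term(final_clean, ann, 20)
    cfg_tr = study_config(planted_terms=((term, 5.0),))
    state = pg.simulate_qtl_architecture(final_clean, ann, cfg_tr, state)

    # sub-panel I: two years; sub-panel II: one year.  Breeding values are
    # scaled once on the full panel so between-sub-panel differences stay on
    # a common scale in both trials.
    sg2 = study_config().variance_components[0]
    gall = state.true_breeding_values
    gscaled = (gall - gall.mean()) / gall.std() * np.sqrt(sg2)
    idx_a = np.where(state.panel_labels == 0)[0]
    idx_b = np.where(state.panel_labels == 1)[0]
    sub_a = pg.TruePanelState(state.panel_labels[idx_a],
                              true_breeding_values=gscaled[idx_a])
    sub_b = pg.TruePanelState(state.panel_labels[idx_b],
                              true_breeding_values=gscaled[idx_b])
    obs_a = pg.simulate_trials(sub_a, study_config(n_years=2), scale_g=False,
                               line_ids=[g_clean.lines[i] for i in idx_a])
    obs_b = pg.simulate_trials(sub_b, study_config(seed=SEED + 7, n_years=1),
                               scale_g=False,
                               line_ids=[g_clean.lines[i] for i in idx_b])

    io.write_vcf(raw, results_path("genotypes_raw.vcf"))
    io.write_gff3(ann, results_path("genes.gff3"))
    io.write_go_map(ann, results_path("gene_go_map.tsv"))
    io.write_phenotypes(obs_a, results_path("phenotypes_subpanel1.csv"))
    io.write_phenotypes(obs_b, results_path("phenotypes_subpanel2.csv"))
    pd.DataFrame({"line": g_clean.lines,
                  "subpanel": state.panel_labels + 1,
                  "true_breeding_value": state.true_breeding_values}).to_csv(
        results_path("panel_truth.csv"), index=False)
    with open(results_path("planted_term.txt"), "w") as fh:
        fh.write(term + "\n")

    miss = float(np.mean(raw.values == pg.dosage.MISSING))
    print(f"panel: {raw.n_lines} lines x {raw.n_markers} markers, "
          f"{miss:.1%} missing calls")
    print(f"annotation: {len(ann.genes)} genes, "
          f"{len(ann.all_terms)} GO terms; planted term {term} (x5 effects)")


if __name__ == "__main__":
    main()
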