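"""QC the raw genotypes: statistics, het-artifact removal, imputation,
MAF >= 5% filter and -1/+1 recoding.  Writes the marker statistics, the QC
summary and the final marker matrix."""

import numpy as np
import pandas as pd

import panelgs as pg
from panelgs import io
from common import SEED, results_path


def main():
    raw = io.read_vcf(results_path("genotypes_raw.vcf"))
    stats = pg.compute_marker_stats(raw)
    stats.to_frame(raw.markers).to_csv(results_path("marker_stats.tsv"),
                                       sep="\t", index=False)

    final, summary = pg.run_qc_pipeline(raw, max_het=0.10, min_maf=0.05,
                                        seed=SEED)
    mat = pd.DataFrame(final.values, index=pd.Index(final.lines, name="line"),
                       columns=final.markers["id"])
    mat.to_csv(results_path("genotypes_final.csv"))
    final.markers.to_csv(results_path("marker_map_final.tsv"), sep="\t",
                         index=False)

    print(f"missing calls: mean {100 * summary['mean_missing']:.1f}%, "
          f"het calls: mean {100 * summary['mean_het']:.1f}%")
    print(f"markers: {summary['n_markers_raw']} raw -> "
          f"{summary['n_markers_post_het']} after het filter -> "
          f"{summary['n_markers_post_maf']} after MAF filter "
          f"(imputation window {summary['chosen_window']})")


if __name__ == "__main__":
    main()
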