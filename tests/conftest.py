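import numpy as np
import pytest

import panelgs as pg
from panelgs.dosage import DosageMatrix


@pytest.fixture(scope="session")
def small_cfg():
    return pg.SimulationConfig(seed=42, n_lines_per_panel=40, n_markers=800)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    """Clean simulated genotypes + ground truth for a 80-line panel."""
    g, state = pg.simulate_panel_genotypes(small_cfg)
    return g, state


@pytest.fixture(scope="session")
def small_final(small_panel):
    """Final-coded version of the clean panel (no QC losses)."""
    g, _ = small_panel
    imputed = DosageMatrix(g.values.copy(), g.markers.copy(), list(g.lines),
                           coding_state="imputed")
    return pg.recode_final(imputed)


@pytest.fixture(scope="session")
def annotation(small_cfg):
    return pg.simulate_gene_annotation(small_cfg)


def as_final(g):
    """Treat clean homozygous raw genotypes as imputed and recode."""
    imputed = DosageMatrix(g.values.copy(), g.markers.copy(), list(g.lines),
                           coding_state="imputed")
    return pg.recode_final(imputed)
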