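"""Shared configuration for the numbered analysis scripts.

The study conditions: a 200-line panel in two sub-panels of 100, genotyped at
2,000 desk-scale markers over 10 chromosomes with GBS-style missingness, a
10 x 10 lattice with 3 replicates, two trial years for sub-panel I and one
for sub-panel II.  Scripts communicate through plain-text files under
``results/``.
"""

import os

import panelgs as pg

SEED = 1
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def study_config(**overrides):
    base = dict(seed=SEED, n_lines_per_panel=100, n_markers=2000, n_qtl=400)
    base.update(overrides)
    return pg.SimulationConfig(**base)


def results_path(name):
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)
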