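"""Shared study conditions for the numbered analysis scripts.

The panel emulates the antibody-titration experiment: 10 surface proteins,
4 antibody clones each, four barcoded genotypes per well, stained at
20 / 1 / 0.05 µg/mL.  Scripts regenerate data deterministically from SEED,
so every step can be run independently.
"""

from pathlib import Path

from glycoshield import cytometry, synthetic

SEED = 20_260
RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"

N_EVENTS = 2000
QC = cytometry.QCConfig(min_events=500)


def study_panel():
    return synthetic.example_panel(n_proteins=10, n_antibodies=4)


def study_events():
    """Deterministic regeneration of the panel event tables + truth."""
    return synthetic.simulate_panel(
        study_panel(), n_events_per_genotype=N_EVENTS, seed=SEED
    )
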