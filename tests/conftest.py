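import numpy as np
import pandas as pd
import pytest

from glycoshield import cytometry, synthetic
from glycoshield.cytometry import QCConfig, TitrationCurve
from glycoshield.synthetic import Genotype


@pytest.fixture(scope="session")
def small_qc() -> QCConfig:
    """QC thresholds scaled to the small event counts used in tests."""
    return QCConfig(min_events=100)


def curve_from_dict(antibody: str, mfis: dict[tuple[str, float], float]) -> TitrationCurve:
    """Build a TitrationCurve from {(genotype, concentration): mfi}."""
    rows = [
        {"genotype": g, "concentration_ugml": c, "mfi": m, "n_events": 1000}
        for (g, c), m in mfis.items()
    ]
    return TitrationCurve(antibody, pd.DataFrame(rows))


def noiseless_curve(model: synthetic.BindingModel, concentrations, antibody="ab") -> TitrationCurve:
    """Titration curve at the generator's closed-form population means."""
    rows = []
    for g in Genotype:
        for c in concentrations:
            rows.append(
                {
                    "genotype": g.value,
                    "concentration_ugml": float(c),
                    "mfi": model.expected_stain(g, c),
                    "n_events": 1000,
                }
            )
    return TitrationCurve(antibody, pd.DataFrame(rows))


@pytest.fixture(scope="session")
def shielded_model() -> synthetic.BindingModel:
    return synthetic.BindingModel(
        bmax=1000.0,
        kd_nm=5.0,
        background=0.0,
        shield_beta={Genotype.SPPL3KO: 1.5, Genotype.DKO: 0.0},
    )


@pytest.fixture(scope="session")
def small_panel_run(small_qc):
    """One simulated 4-protein panel, demultiplexed into titration curves."""
    panel = synthetic.example_panel(4, 2)
    events, truth = synthetic.simulate_panel(
        panel, n_events_per_genotype=1500, seed=11
    )
    curves = cytometry.titration_curves(events, config=small_qc)
    return panel, events, truth, curves
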