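"""Affinity dependence of shielding on the 13-clone single-target panel.

Finding: with uniform shielding (beta = 1.5) across clones, the shielding
ratio at a fixed sub-saturating concentration correlates strongly and
negatively with log10 Kd — lower-affinity antibodies are more shielded —
while the epitope-position categories show no systematic effect, exactly the
emergent behavior of the Langmuir model with multiplicative Kd inflation.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common

from glycoshield import affinity, cytometry, synthetic


def main() -> None:
    common.RESULTS.mkdir(parents=True, exist_ok=True)
    meta = affinity.load_cd147_panel()
    panel = [
        synthetic.PanelAntibody(
            str(r.antibody), "CD147", float(r.kd_nm),
            beta_sppl3=1.5, beta_dko=0.0,
            epitope_position=str(r.epitope_position),
        )
        for r in meta.itertuples()
    ]
    events, _ = synthetic.simulate_panel(
        panel, n_events_per_genotype=common.N_EVENTS, seed=common.SEED + 6
    )
    curves = cytometry.titration_curves(events, config=common.QC)
    sens = affinity.sensitivity_panel(curves, common.QC, concentration=1.0)
    sens.to_csv(common.RESULTS / "sensitivity.tsv", sep="\t", index=False)

    meta = meta.assign(antibody=meta["antibody"].astype(str))
    rows = []
    for method in ("pearson", "spearman"):
        res = affinity.correlate_affinity(sens, meta, method=method)
        rows.append({"method": method, "r": res.r, "p": res.p, "n": res.n})
        print(f"{method}: r = {res.r:.3f}, p = {res.p:.2g} (n = {res.n})")
    pd.DataFrame(rows).to_csv(
        common.RESULTS / "affinity_correlation.tsv", sep="\t", index=False
    )

    cat = affinity.position_category_analysis(sens, meta)
    cat.summary.assign(anova_f=cat.f, anova_p=cat.p).to_csv(
        common.RESULTS / "position_categories.tsv", sep="\t", index=False
    )
    print("per-category mean shielding ratios:")
    print(cat.summary.to_string(index=False))
    print(f"position-category ANOVA: F = {cat.f:.2f}, p = {cat.p:.2f}")
    print(f"wrote sensitivity.tsv, affinity_correlation.tsv, position_categories.tsv")


if __name__ == "__main__":
    main()
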