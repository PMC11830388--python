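"""Per-antibody shielding sensitivity and its relation to affinity and epitope position.

For a panel of antibodies against one target (the 13-clone CD147-style
panel), the shielding ratio is the SPPL3-knockout/WT MFI at the chosen
sub-saturating concentration and the rescue ratio the double-knockout/WT MFI.
Under Langmuir binding with multiplicative Kd shielding the expected ratio

    r(c) = (c + Kd) / (c + Kd (1 + beta))

is strictly decreasing in Kd at fixed concentration and beta, so
lower-affinity antibodies are more shielded; the correlation of the ratio
with log10 Kd quantifies that dependence.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cytometry import QCConfig, TitrationCurve, detect_saturating
from .classify import accessibility_ratio
from .synthetic import Genotype

__all__ = [
    "CorrelationResult",
    "CategoryAnalysis",
    "sensitivity_panel",
    "correlate_affinity",
    "position_category_analysis",
    "load_cd147_panel",
]

EPITOPE_POSITIONS = ("proximal", "intermediate", "distal")


def sensitivity_panel(
    curves: Mapping[str, TitrationCurve],
    qc_config: QCConfig = QCConfig(),
    concentration: float | None = None,
) -> pd.DataFrame:
    """Shielding and rescue ratios per antibody at its analysis concentration.

    By default the analysis concentration is chosen per antibody (highest
    non-saturating); passing ``concentration`` forces a common fixed staining
    concentration across the panel, which isolates the affinity dependence of
    the shielding ratio from concentration choice.  One row per antibody with
    columns ``antibody, analysis_concentration, shielding_ratio,
    rescue_ratio, excluded, reason``; antibodies whose concentrations are all
    saturating are excluded with a reason.
    """
    rows = []
    for antibody, curve in sorted(curves.items()):
        if concentration is not None:
            sat = None
            chosen = concentration
        else:
            sat = detect_saturating(curve, config=qc_config)
            chosen = sat.analysis_concentration
        if chosen is None:
            rows.append(
                {
                    "antibody": antibody, "analysis_concentration": np.nan,
                    "shielding_ratio": np.nan, "rescue_ratio": np.nan,
                    "excluded": True, "reason": sat.status,
                }
            )
            continue
        c = chosen
        wt = curve.mfi(Genotype.WT, c)
        row = {
            "antibody": antibody, "analysis_concentration": c,
            "shielding_ratio": accessibility_ratio(curve.mfi(Genotype.SPPL3KO, c), wt),
            "excluded": False, "reason": "",
        }
        try:
            row["rescue_ratio"] = accessibility_ratio(curve.mfi(Genotype.DKO, c), wt)
        except KeyError:
            row["rescue_ratio"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str
    transform: str


def correlate_affinity(
    sensitivities: pd.DataFrame,
    affinities: pd.DataFrame,
    transform: str = "log10",
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate shielding ratios with antibody affinity.

    ``sensitivities`` must carry ``antibody, shielding_ratio`` and
    ``affinities`` ``antibody, kd_nm``.  Affinities spanning orders of
    magnitude are log10-transformed by default; Pearson is the default
    method, Spearman available.  Requires at least 3 paired records and
    non-zero variance in both variables.
    """
    merged = sensitivities.merge(affinities, on="antibody")
    merged = merged[~merged.get("excluded", pd.Series(False, index=merged.index))]
    if len(merged) < 3:
        raise ValueError("need at least 3 paired antibody records")
    x = merged["kd_nm"].to_numpy(dtype=float)
    if transform == "log10":
        if np.any(x <= 0):
            raise ValueError("affinities must be positive for log transform")
        x = np.log10(x)
    elif transform != "linear":
        raise ValueError(f"unknown transform {transform!r}")
    y = merged["shielding_ratio"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in affinity or shielding ratio")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(float(r), float(p), len(merged), method, transform)


@dataclass(frozen=True)
class CategoryAnalysis:
    summary: pd.DataFrame  # per-category n, mean, sd, tested flag
    f: float
    p: float
    tested_categories: tuple[str, ...]


def position_category_analysis(
    sensitivities: pd.DataFrame,
    affinities: pd.DataFrame,
) -> CategoryAnalysis:
    """Shielding ratios by epitope-position category with a one-way ANOVA.

    ``affinities`` must carry ``antibody, epitope_position``.  Categories with
    fewer than 2 members are summarised descriptively but excluded from the
    omnibus test; fewer than 2 testable categories is an error.
    """
    merged = sensitivities.merge(affinities, on="antibody")
    merged = merged[~merged.get("excluded", pd.Series(False, index=merged.index))]
    rows, tested = [], {}
    for cat, sub in merged.groupby("epitope_position"):
        vals = sub["shielding_ratio"].to_numpy(dtype=float)
        rows.append(
            {
                "epitope_position": cat, "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "tested": len(vals) >= 2,
            }
        )
        if len(vals) >= 2:
            tested[cat] = vals
    if len(tested) < 2:
        raise ValueError("need >= 2 categories with >= 2 members for the omnibus test")
    f, p = stats.f_oneway(*tested.values())
    return CategoryAnalysis(
        pd.DataFrame(rows), float(f), float(p), tuple(sorted(tested))
    )


def load_cd147_panel() -> pd.DataFrame:
    """Packaged synthetic 13-antibody panel metadata (affinity, epitope position).

    A synthetic stand-in for a published single-target antibody panel: the
    epitope-position categories follow the published scheme (clones 6, 7, 12
    membrane-proximal; 1, 2, 11 membrane-distal; the rest in between), while
    the Kd values are generator choices spanning 0.1-100 nM, since the real
    affinities are not reprinted here.
    """
    ref = importlib.resources.files("glycoshield.data") / "cd147_panel_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
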