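"""Effector-assay readouts: specific target-cell death, trogocytosis, statistics.

Specific death subtracts the background death observed in no-effector control
wells from the death in effector wells.  Trogocytosis is the percentage of
effector-gated cells that acquired target-membrane dye above a threshold set
from the effector-only control.  Group statistics follow the conventions of
plate-based coculture experiments: Student's t (paired or unpaired) or
one-way ANOVA with Tukey's multiple-comparison test, significance at
p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpecificDeath",
    "TrogGates",
    "specific_death",
    "specific_death_table",
    "trogocytosis_fraction",
    "run_stats",
    "ALPHA",
]

#: Significance level for all assay statistics.
ALPHA = 0.05


@dataclass(frozen=True)
class SpecificDeath:
    value: float  # percentage points
    negative_effect: bool

    def __float__(self) -> float:
        return self.value


def specific_death(pct_with: float, pct_without: float) -> SpecificDeath:
    """Percentage of target death attributable to effectors.

    ``pct_with - pct_without``; negative values are reported, not clipped,
    and flagged so replicate means stay unbiased.
    """
    for v in (pct_with, pct_without):
        if not 0 <= v <= 100:
            raise ValueError("percentages must be in [0, 100]")
    value = pct_with - pct_without
    return SpecificDeath(value, value < 0)


def specific_death_table(wells: pd.DataFrame) -> pd.DataFrame:
    """Apply the no-effector subtraction across a plate table.

    Expects columns ``target, et_ratio, replicate, pct_dead``; the mean of
    each target's E:T = 0 control wells is subtracted from its effector
    wells.  Targets without a control raise.
    """
    controls = (
        wells[wells["et_ratio"] == 0].groupby("target")["pct_dead"].mean()
    )
    effector = wells[wells["et_ratio"] > 0].copy()
    missing = set(effector["target"]) - set(controls.index)
    if missing:
        raise ValueError(f"no E:T=0 control wells for targets: {sorted(missing)}")
    effector["specific_death"] = (
        effector["pct_dead"] - effector["target"].map(controls)
    )
    effector["negative_effect"] = effector["specific_death"] < 0
    return effector


@dataclass(frozen=True)
class TrogGates:
    """Gating configuration for dye-transfer quantification."""

    effector_channel: str = "vpd450"
    dio_channel: str = "dio"
    effector_threshold: float | None = None  # None = all events are effectors
    control_percentile: float = 99.5


def trogocytosis_fraction(
    effector_events: pd.DataFrame,
    control_events: pd.DataFrame,
    gates: TrogGates = TrogGates(),
) -> float:
    """Percentage of effector-gated cells positive for target-membrane dye.

    The DiO positivity threshold is the ``control_percentile`` quantile of
    the no-target control's DiO channel, so the control scores at most
    ``100 - control_percentile`` percent against itself by construction.
    """
    for df, label in ((effector_events, "effector"), (control_events, "control")):
        if gates.dio_channel not in df.columns:
            raise ValueError(f"{label} events lack DiO channel {gates.dio_channel!r}")
    ev = effector_events
    if gates.effector_threshold is not None:
        ev = ev[ev[gates.effector_channel] >= gates.effector_threshold]
    if len(ev) == 0:
        raise ValueError("no effector-gated events")
    threshold = np.percentile(
        control_events[gates.dio_channel], gates.control_percentile
    )
    return float(100.0 * (ev[gates.dio_channel] > threshold).mean())


def run_stats(
    groups: Mapping[str, Sequence[float]],
    design: str = "student_t",
) -> pd.DataFrame:
    """Group comparison statistics table.

    ``design`` is one of:

    * ``student_t`` — two groups, pooled-variance two-sided t test;
    * ``paired_t`` — two equal-length groups, paired t test (a zero-variance
      difference is flagged rather than producing an infinite statistic);
    * ``anova_tukey`` — one-way ANOVA across all groups followed by Tukey's
      HSD for every pairwise contrast.

    Returns one row per test/contrast with columns
    ``contrast, statistic, p, significant, flag``.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs at least 2 values")

    if design in ("student_t", "paired_t"):
        if len(arrays) != 2:
            raise ValueError(f"{design} requires exactly 2 groups")
        (ka, a), (kb, b) = arrays.items()
        if design == "student_t":
            t, p = stats.ttest_ind(a, b, equal_var=True)
            flag = ""
        else:
            if len(a) != len(b):
                raise ValueError("paired design requires equal group lengths")
            diff = a - b
            if np.allclose(diff, diff[0]):
                # constant difference: paired t is degenerate
                return pd.DataFrame(
                    [{
                        "contrast": f"{ka} vs {kb}", "statistic": np.nan,
                        "p": np.nan, "significant": False,
                        "flag": "zero_variance_difference",
                    }]
                )
            t, p = stats.ttest_rel(a, b)
            flag = ""
        return pd.DataFrame(
            [{
                "contrast": f"{ka} vs {kb}", "statistic": float(t),
                "p": float(p), "significant": bool(p <= ALPHA), "flag": flag,
            }]
        )

    if design == "anova_tukey":
        if len(arrays) < 2:
            raise ValueError("ANOVA requires at least 2 groups")
        f, p = stats.f_oneway(*arrays.values())
        rows = [
            {
                "contrast": "omnibus", "statistic": float(f), "p": float(p),
                "significant": bool(p <= ALPHA), "flag": "",
            }
        ]
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(list(arrays.values()))
        labels = np.concatenate(
            [np.repeat(k, len(v)) for k, v in arrays.items()]
        )
        tukey = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
        summary = tukey.summary().data[1:]  # drop header
        for g1, g2, meandiff, p_adj, lower, upper, reject in summary:
            rows.append(
                {
                    "contrast": f"{g1} vs {g2}", "statistic": float(meandiff),
                    "p": float(p_adj), "significant": bool(reject), "flag": "tukey",
                }
            )
        return pd.DataFrame(rows)

    raise ValueError(f"unknown design {design!r}")
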