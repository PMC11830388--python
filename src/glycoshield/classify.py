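"""Ratio-threshold classification of epitope accessibility.

An epitope is called *affected* when the SPPL3-knockout/WT MFI ratio at the
sub-saturating analysis concentration leaves the similarity band (strictly
below the lower bound or strictly above the upper bound).  Glycosphingolipid
(nsGSL) dependence of a decreased epitope is called from restoration of
binding in the SPPL3/B3GNT5 double knockout.  Proteins are grouped from their
antibody-level calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .cytometry import QCConfig, TitrationCurve, detect_saturating, qc_equal_expression
from .synthetic import Genotype

__all__ = [
    "ClassificationConfig",
    "AccessibilityCall",
    "ProteinGroupCall",
    "accessibility_ratio",
    "classify_epitope",
    "classify_nsgsl_dependence",
    "make_call",
    "group_protein",
    "classify_panel",
]


@dataclass(frozen=True)
class ClassificationConfig:
    """Similarity band for KO/WT ratios; inequalities are strict on both sides.

    The default upper bound is 1.2; 1.25 is an accepted alternate convention
    and can be configured.  Both bounds are echoed in the QC log so the
    convention in force is auditable.
    """

    lower: float = 0.8
    upper: float = 1.2

    def __post_init__(self) -> None:
        if not 0 < self.lower < 1 < self.upper:
            raise ValueError("band must satisfy 0 < lower < 1 < upper")


def accessibility_ratio(mfi_ko: float, mfi_wt: float) -> float:
    """KO/WT MFI ratio; the WT denominator must be positive."""
    if mfi_wt <= 0:
        raise ValueError("WT MFI must be positive")
    if mfi_ko < 0:
        raise ValueError("KO MFI must be non-negative")
    return mfi_ko / mfi_wt


def classify_epitope(r_sppl3: float, config: ClassificationConfig = ClassificationConfig()) -> str:
    """Label one epitope from its SPPL3-KO/WT ratio.

    ``affected_decreased`` strictly below the band, ``affected_increased``
    strictly above, otherwise ``unaffected`` (band-inclusive).
    """
    if r_sppl3 < config.lower:
        return "affected_decreased"
    if r_sppl3 > config.upper:
        return "affected_increased"
    return "unaffected"


@dataclass(frozen=True)
class AccessibilityCall:
    """Per-antibody accessibility outcome with the ratios that justify it."""

    antibody: str
    r_sppl3: float
    r_b3gnt5: float | None = None
    r_dko: float | None = None
    epitope_label: str = "unaffected"
    nsgsl_label: str = "not_applicable"
    analysis_concentration: float | None = None


def classify_nsgsl_dependence(
    call: AccessibilityCall, config: ClassificationConfig = ClassificationConfig()
) -> str:
    """Call nsGSL dependence of a decreased epitope from double-KO restoration.

    Only epitopes labelled ``affected_decreased`` get a call: binding restored
    in the double knockout (DKO/WT ratio above the lower band bound) means the
    loss was glycosphingolipid-driven.  The single-B3GNT5-knockout ratio is
    carried on the call for the log but does not decide the label.
    """
    if call.epitope_label != "affected_decreased":
        return "not_applicable"
    if call.r_dko is None:
        return "not_applicable"
    return "nsGSL_dependent" if call.r_dko > config.lower else "nsGSL_independent"


def make_call(
    antibody: str,
    r_sppl3: float,
    r_b3gnt5: float | None = None,
    r_dko: float | None = None,
    config: ClassificationConfig = ClassificationConfig(),
    analysis_concentration: float | None = None,
) -> AccessibilityCall:
    """Build a fully-labelled accessibility call from the three ratios."""
    call = AccessibilityCall(
        antibody=antibody,
        r_sppl3=r_sppl3,
        r_b3gnt5=r_b3gnt5,
        r_dko=r_dko,
        epitope_label=classify_epitope(r_sppl3, config),
        analysis_concentration=analysis_concentration,
    )
    return AccessibilityCall(
        **{**call.__dict__, "nsgsl_label": classify_nsgsl_dependence(call, config)}
    )


@dataclass(frozen=True)
class ProteinGroupCall:
    protein: str
    category: str  # fully_affected | partially_affected | unaffected | increased | b3gnt5_specific
    calls: tuple[AccessibilityCall, ...]


def group_protein(
    protein: str,
    calls: Sequence[AccessibilityCall],
    config: ClassificationConfig = ClassificationConfig(),
) -> ProteinGroupCall:
    """Group a protein from its QC-passing antibody calls.

    Precedence: any increased epitope -> ``increased``; all B3GNT5-KO ratios
    out of band while all SPPL3-KO ratios in band -> ``b3gnt5_specific``; all
    epitopes decreased -> ``fully_affected``; some decreased ->
    ``partially_affected``; otherwise ``unaffected``.
    """
    if len(calls) == 0:
        raise ValueError(f"protein {protein}: no QC-passing antibody calls")
    labels = [c.epitope_label for c in calls]
    in_band = lambda r: r is not None and config.lower <= r <= config.upper
    out_band = lambda r: r is not None and not config.lower <= r <= config.upper
    if any(l == "affected_increased" for l in labels):
        category = "increased"
    elif all(out_band(c.r_b3gnt5) for c in calls) and all(
        in_band(c.r_sppl3) for c in calls
    ):
        category = "b3gnt5_specific"
    elif all(l == "affected_decreased" for l in labels):
        category = "fully_affected"
    elif any(l == "affected_decreased" for l in labels):
        category = "partially_affected"
    else:
        category = "unaffected"
    return ProteinGroupCall(protein, category, tuple(calls))


def classify_panel(
    curves: Mapping[str, TitrationCurve],
    antibody_to_protein: Mapping[str, str],
    config: ClassificationConfig = ClassificationConfig(),
    qc_config: QCConfig = QCConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run saturation detection, expression QC and classification on a panel.

    Returns ``(calls, groups)`` tables.  Per antibody, ratios are computed at
    the single chosen sub-saturating analysis concentration.  Proteins whose
    clones fail the equal-expression QC are excluded with a reason.
    """
    by_protein: dict[str, list[str]] = {}
    for ab, protein in antibody_to_protein.items():
        by_protein.setdefault(protein, []).append(ab)

    call_rows, group_rows = [], []
    for protein, abs_ in sorted(by_protein.items()):
        clone_curves = [curves[a] for a in abs_ if a in curves]
        if not clone_curves:
            group_rows.append(
                {"protein": protein, "category": "excluded", "reason": "no_curves"}
            )
            continue
        expr_qc = qc_equal_expression(clone_curves, qc_config)
        if not expr_qc.passed:
            group_rows.append(
                {"protein": protein, "category": "excluded", "reason": expr_qc.reason}
            )
            continue
        calls = []
        for ab in abs_:
            if ab not in curves:
                continue
            curve = curves[ab]
            sat = detect_saturating(curve, config=qc_config)
            if sat.analysis_concentration is None:
                call_rows.append(
                    {
                        "antibody": ab, "protein": protein,
                        "r_sppl3": float("nan"), "r_b3gnt5": float("nan"),
                        "r_dko": float("nan"), "epitope_label": "excluded",
                        "nsgsl_label": "not_applicable",
                        "analysis_concentration": float("nan"),
                        "reason": sat.status,
                    }
                )
                continue
            c = sat.analysis_concentration
            wt = curve.mfi(Genotype.WT, c)
            ratios = {}
            for g in (Genotype.SPPL3KO, Genotype.B3GNT5KO, Genotype.DKO):
                try:
                    ratios[g] = accessibility_ratio(curve.mfi(g, c), wt)
                except KeyError:
                    ratios[g] = None
            if ratios[Genotype.SPPL3KO] is None:
                continue
            call = make_call(
                ab,
                ratios[Genotype.SPPL3KO],
                r_b3gnt5=ratios[Genotype.B3GNT5KO],
                r_dko=ratios[Genotype.DKO],
                config=config,
                analysis_concentration=c,
            )
            calls.append(call)
            call_rows.append(
                {
                    "antibody": ab, "protein": protein,
                    "r_sppl3": call.r_sppl3, "r_b3gnt5": call.r_b3gnt5,
                    "r_dko": call.r_dko, "epitope_label": call.epitope_label,
                    "nsgsl_label": call.nsgsl_label,
                    "analysis_concentration": c, "reason": "",
                }
            )
        if calls:
            group = group_protein(protein, calls, config)
            group_rows.append(
                {"protein": protein, "category": group.category, "reason": ""}
            )
        else:
            group_rows.append(
                {"protein": protein, "category": "excluded", "reason": "no_usable_calls"}
            )
    return pd.DataFrame(call_rows), pd.DataFrame(group_rows)
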