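"""Event-table ingest, demultiplexing, MFI computation and quality control.

The analysis contract for event tables is a plain :class:`pandas.DataFrame`
with one row per cell and the columns

    ``genotype`` (optional ground truth), ``antibody``,
    ``concentration_ugml``, ``well``, ``stain``, ``viability``,
    plus the two barcode-dye channels named by the :class:`BarcodeScheme`.

Quality control mirrors standard titration practice: antibodies must stain
positively over the secondary-only control, surface expression must be equal
across genotypes at a saturating concentration, and accessibility ratios are
read at the highest sub-saturating concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synthetic import BarcodeScheme, Genotype, ugml_to_nm

__all__ = [
    "QCConfig",
    "TitrationCurve",
    "SaturationResult",
    "QCResult",
    "BindingFit",
    "read_events_csv",
    "write_events_csv",
    "viability_gate",
    "demultiplex",
    "compute_mfi",
    "titration_curves",
    "detect_saturating",
    "qc_positivity",
    "qc_equal_expression",
    "fit_binding_curve",
]


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for titration quality control.

    positivity_factor
        Minimum fold over the secondary-only control for an antibody to count
        as staining positively (kappa, > 1).
    saturation_tolerance
        Plateau tolerance tau: a concentration is saturating when the WT MFI
        is within ``tau`` of the curve maximum.
    similarity_low / similarity_high
        The KO/WT ratio band considered "similar to WT".
    min_events
        Reliability floor: MFIs from fewer events are not reported.
    """

    positivity_factor: float = 2.0
    saturation_tolerance: float = 0.10
    similarity_low: float = 0.8
    similarity_high: float = 1.2
    min_events: int = 500

    def __post_init__(self) -> None:
        if self.positivity_factor <= 1:
            raise ValueError("positivity_factor must be > 1")
        if not 0 < self.saturation_tolerance < 1:
            raise ValueError("saturation_tolerance must be in (0, 1)")
        if not 0 < self.similarity_low < 1 < self.similarity_high:
            raise ValueError("similarity band must straddle 1")


def read_events_csv(path) -> pd.DataFrame:
    """Read an event table from CSV, checking the column contract."""
    events = pd.read_csv(path)
    required = {"antibody", "concentration_ugml", "well", "stain", "viability"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table {path} missing columns: {sorted(missing)}")
    return events


def write_events_csv(events: pd.DataFrame, path, blind: bool = False) -> None:
    """Write an event table; ``blind=True`` drops the genotype truth column."""
    out = events.drop(columns=["genotype"]) if blind and "genotype" in events else events
    out.to_csv(path, index=False)


def _two_means_split(log_values: np.ndarray) -> tuple[float, float]:
    """Deterministic 1D two-means partition of log intensities.

    Returns the (low, high) cluster means in log10 space, found by scanning
    every sorted split point and minimising the within-class sum of squares.
    """
    x = np.sort(log_values)
    n = len(x)
    if n < 2:
        return float(x[0]), float(x[0])
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csum2 = np.concatenate([[0.0], np.cumsum(x * x)])
    k = np.arange(1, n)  # split after k elements
    left = csum2[k] - csum[k] ** 2 / k
    right = (csum2[n] - csum2[k]) - (csum[n] - csum[k]) ** 2 / (n - k)
    best = int(np.argmin(left + right)) + 1
    return float(csum[best] / best), float((csum[n] - csum[best]) / (n - best))


# log10 fold difference between modes below which a channel is treated as
# unimodal (no genuine high population)
_MIN_BIMODAL_GAP = np.log10(1.5)


def _channel_threshold(values: np.ndarray) -> float | None:
    """Gate threshold at the geometric midpoint between the two fitted modes.

    Returns ``None`` when the channel looks unimodal (mode gap below 1.5x).
    """
    logs = np.log10(np.clip(values, 1e-12, None))
    lo, hi = _two_means_split(logs)
    if hi - lo < _MIN_BIMODAL_GAP:
        return None
    return 10 ** ((lo + hi) / 2.0)


def viability_gate(events: pd.DataFrame, threshold: float | None = None) -> pd.DataFrame:
    """Remove dead cells (viability-dye high) before any statistic.

    The default threshold is the geometric midpoint between the live and dead
    modes of the viability channel; if the channel is unimodal all events are
    kept (no detectable dead population).
    """
    if len(events) == 0:
        return events
    if threshold is None:
        threshold = _channel_threshold(events["viability"].to_numpy())
        if threshold is None:
            return events
    return events[events["viability"] < threshold]


def demultiplex(
    events: pd.DataFrame,
    scheme: BarcodeScheme = BarcodeScheme(),
    gate_viability: bool = True,
) -> dict[Genotype, pd.DataFrame]:
    """Assign barcoded events to genotypes by per-channel high/low gating.

    Each barcode channel is split at the geometric midpoint between its two
    fitted modes; the high/low combination maps to a genotype through the
    :class:`BarcodeScheme`.  A channel that looks unimodal where a bimodal
    signal is expected triggers a warning and is called all-low.  Every viable
    event is assigned to exactly one genotype.
    """
    for ch in (scheme.dye1, scheme.dye2):
        if ch not in events.columns:
            raise ValueError(f"barcode channel {ch!r} missing from event table")
    if len(events) == 0:
        return {g: events.copy() for g in Genotype}
    viable = viability_gate(events) if gate_viability else events

    calls = {}
    for ch in (scheme.dye1, scheme.dye2):
        values = viable[ch].to_numpy()
        thr = _channel_threshold(values)
        if thr is None:
            warnings.warn(
                f"barcode channel {ch!r} looks unimodal where bimodal was "
                "expected; calling all events low"
            )
            calls[ch] = np.zeros(len(viable), dtype=bool)
        else:
            calls[ch] = values >= thr

    assigned = np.full(len(viable), "unassigned", dtype=object)
    for g in Genotype:
        h1, h2 = scheme.combination(g)
        mask = (calls[scheme.dye1] == h1) & (calls[scheme.dye2] == h2)
        assigned[mask] = g.value
    return {g: viable[assigned == g.value].copy() for g in Genotype}


def compute_mfi(values: Iterable[float], method: str = "mean") -> float:
    """Summary fluorescence intensity of a population.

    ``method`` is one of ``mean`` (default), ``geomean`` or ``median``; the
    geometric mean requires strictly positive values.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute MFI of an empty population")
    if method == "mean":
        return float(arr.mean())
    if method == "geomean":
        if np.any(arr <= 0):
            raise ValueError("geometric mean requires positive values")
        return float(np.exp(np.mean(np.log(arr))))
    if method == "median":
        return float(np.median(arr))
    raise ValueError(f"unknown MFI method {method!r}")


@dataclass
class TitrationCurve:
    """MFI per (genotype, concentration) for one antibody."""

    antibody: str
    table: pd.DataFrame  # columns: genotype, concentration_ugml, mfi, n_events
    method: str = "mean"

    def __post_init__(self) -> None:
        if len(self.table) == 0:
            raise ValueError("titration curve has no data")

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.table["concentration_ugml"].unique())

    def mfi(self, genotype: Genotype, concentration: float) -> float:
        sel = self.table[
            (self.table["genotype"] == Genotype(genotype).value)
            & np.isclose(self.table["concentration_ugml"], concentration)
        ]
        if len(sel) == 0:
            raise KeyError((genotype, concentration))
        return float(sel["mfi"].iloc[0])

    def genotype_series(self, genotype: Genotype) -> pd.Series:
        sub = self.table[self.table["genotype"] == Genotype(genotype).value]
        return sub.set_index("concentration_ugml")["mfi"].sort_index()


def titration_curves(
    events: pd.DataFrame,
    scheme: BarcodeScheme = BarcodeScheme(),
    config: QCConfig = QCConfig(),
    method: str = "mean",
) -> dict[str, TitrationCurve]:
    """Demultiplex a panel event table and compute MFIs per antibody.

    Wells with fewer than ``config.min_events`` cells for a genotype are
    dropped from the curve (reliability floor).
    """
    curves: dict[str, TitrationCurve] = {}
    for antibody, ab_events in events.groupby("antibody"):
        rows = []
        for conc, well_events in ab_events.groupby("concentration_ugml"):
            split = demultiplex(well_events, scheme)
            for genotype, gv in split.items():
                if len(gv) < config.min_events:
                    continue
                rows.append(
                    {
                        "genotype": genotype.value,
                        "concentration_ugml": float(conc),
                        "mfi": compute_mfi(gv["stain"], method),
                        "n_events": len(gv),
                    }
                )
        if rows:
            curves[str(antibody)] = TitrationCurve(str(antibody), pd.DataFrame(rows), method)
    return curves


@dataclass(frozen=True)
class SaturationResult:
    """Per-concentration saturation flags and the chosen analysis concentration."""

    flags: Mapping[float, bool]
    analysis_concentration: float | None
    status: str  # ok | all_saturating | undetermined

    @property
    def saturating(self) -> list[float]:
        return sorted(c for c, f in self.flags.items() if f)


def detect_saturating(curve: TitrationCurve, tolerance: float | None = None,
                      config: QCConfig = QCConfig()) -> SaturationResult:
    """Flag saturating concentrations on the WT curve.

    A concentration is saturating when the WT MFI is within the plateau
    tolerance of the curve maximum; the analysis concentration is the highest
    non-saturating one.  A single-concentration curve is passed through as
    ``undetermined`` with a warning; a flat curve has no analysis
    concentration.
    """
    tol = config.saturation_tolerance if tolerance is None else tolerance
    wt = curve.genotype_series(Genotype.WT)
    if len(wt) < 2:
        warnings.warn(
            f"antibody {curve.antibody}: single concentration, saturation undetermined"
        )
        return SaturationResult(
            {float(c): False for c in wt.index}, None, "undetermined"
        )
    cutoff = (1.0 - tol) * wt.max()
    flags = {float(c): bool(m >= cutoff) for c, m in wt.items()}
    non_sat = [c for c, f in flags.items() if not f]
    if not non_sat:
        return SaturationResult(flags, None, "all_saturating")
    return SaturationResult(flags, max(non_sat), "ok")


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: str = ""


def qc_positivity(curve: TitrationCurve, control_mfi: float,
                  config: QCConfig = QCConfig()) -> QCResult:
    """Positive-stain check against the secondary-antibody-only control.

    Passes when the WT MFI at the top concentration is at least
    ``positivity_factor`` times the control MFI (inclusive).
    """
    if control_mfi <= 0:
        raise ValueError("control MFI must be positive")
    try:
        wt = curve.genotype_series(Genotype.WT)
    except KeyError:
        wt = pd.Series(dtype=float)
    if len(wt) == 0:
        return QCResult(False, "no_wt_curve")
    top = wt.loc[wt.index.max()]
    if top >= config.positivity_factor * control_mfi:
        return QCResult(True)
    return QCResult(False, "no_positive_stain")


def qc_equal_expression(
    curves: TitrationCurve | Sequence[TitrationCurve],
    config: QCConfig = QCConfig(),
) -> QCResult:
    """Equal-surface-expression check at a saturating concentration.

    A protein passes when, for at least one of its antibody clones, every
    KO/WT MFI ratio at a saturating concentration falls inside the similarity
    band.  With no saturating concentration available for any clone the
    protein is ``undetermined`` and excluded.
    """
    if isinstance(curves, TitrationCurve):
        curves = [curves]
    any_saturating = False
    for curve in curves:
        sat = detect_saturating(curve, config=config)
        if not sat.saturating:
            continue
        any_saturating = True
        # check at the top saturating concentration
        c = max(sat.saturating)
        try:
            wt = curve.mfi(Genotype.WT, c)
        except KeyError:
            continue
        ratios = []
        for g in (Genotype.SPPL3KO, Genotype.B3GNT5KO, Genotype.DKO):
            try:
                ratios.append(curve.mfi(g, c) / wt)
            except KeyError:
                continue
        if ratios and all(
            config.similarity_low <= r <= config.similarity_high for r in ratios
        ):
            return QCResult(True)
    if not any_saturating:
        return QCResult(False, "undetermined_no_saturating_concentration")
    return QCResult(False, "differential_expression_at_saturation")


class FitError(RuntimeError):
    """Binding-curve fit failed or parameters are unidentifiable."""


@dataclass(frozen=True)
class BindingFit:
    bmax: float
    kd_eff_nm: float
    background: float
    residual_norm: float


def fit_binding_curve(
    curve: TitrationCurve,
    genotype: Genotype,
    mw_kda: float = 150.0,
) -> BindingFit:
    """Least-squares Langmuir fit MFI(c) = background + Bmax*c/(c + Kd_eff).

    Concentrations are converted from µg/mL to nM assuming IgG molar mass
    unless overridden.  Requires at least three concentrations; a flat curve
    (dynamic range below 5% of the maximum) is rejected as unidentifiable.
    """
    series = curve.genotype_series(genotype)
    if len(series) < 3:
        raise FitError("need at least 3 concentrations to fit a binding curve")
    c_nm = np.asarray(ugml_to_nm(series.index.to_numpy(), mw_kda), dtype=float)
    mfi = series.to_numpy(dtype=float)
    if mfi.max() <= 0 or (mfi.max() - mfi.min()) < 0.05 * mfi.max():
        raise FitError("flat titration curve: Kd unidentifiable")

    def langmuir(c, bmax, kd, bg):
        return bg + bmax * c / (c + kd)

    p0 = (mfi.max() - mfi.min(), np.median(c_nm), max(mfi.min(), 1e-6))
    try:
        popt, _ = curve_fit(
            langmuir, c_nm, mfi, p0=p0,
            bounds=([0, 1e-9, 0], [np.inf, np.inf, np.inf]), maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy non-convergence
        raise FitError(f"binding-curve fit did not converge: {exc}") from exc
    residual = float(np.linalg.norm(langmuir(c_nm, *popt) - mfi))
    return BindingFit(float(popt[0]), float(popt[1]), float(popt[2]), residual)
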