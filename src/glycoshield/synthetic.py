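"""Synthetic data generation with known ground truth.

This module emulates the statistical structure of the experiments the rest of
the package analyses:

* barcoded four-genotype mixtures (WT, SPPL3 knockout, B3GNT5 knockout and the
  double knockout) stained with titrated antibodies, where glycosphingolipid
  shielding is modelled as a multiplicative inflation of the apparent
  dissociation constant;
* toy protein structures (lines, helices, point clouds) written as PDB/mmCIF
  files for exercising the protrusion geometry;
* cytotoxicity plates with binomial per-well death counts.

The shielding model is a Langmuir isotherm with genotype-dependent effective
Kd:

    stain(c) = [background + Bmax * c / (c + Kd * (1 + beta_g))] * L * M

with L and M independent log-normal factors of unit mean representing
cell-to-cell and measurement variation.  Because shielding only inflates Kd,
saturating concentrations stain all genotypes equally (the expression-QC
premise), while sub-saturating concentrations reveal the shielding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Genotype",
    "BindingModel",
    "BarcodeScheme",
    "ToyStructureSpec",
    "PanelAntibody",
    "ugml_to_nm",
    "simulate_titration",
    "attach_barcodes",
    "write_toy_structure",
    "toy_structure_coordinates",
    "simulate_killing_plate",
    "simulate_panel",
    "DEFAULT_CONCENTRATIONS",
]

#: Antibody staining series (µg/mL) used throughout the titration analyses.
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (20.0, 1.0, 0.05)

#: Molar mass assumed for IgG when converting µg/mL to nM.
IGG_MW_KDA = 150.0


class Genotype(str, Enum):
    """The four barcoded target-cell lines."""

    WT = "WT"
    SPPL3KO = "SPPL3KO"
    B3GNT5KO = "B3GNT5KO"
    DKO = "DKO"  # SPPL3-/- B3GNT5-/- double knockout


def ugml_to_nm(c_ugml: float | np.ndarray, mw_kda: float = IGG_MW_KDA):
    """Convert an antibody concentration from µg/mL to nM.

    c [µg/mL] = c [mg/L]; dividing by the molar mass in kDa (kg/mol) gives
    µmol/m^3 = nmol/L, i.e. ``c_nM = 1000 * c_ugml / mw_kda``.
    """
    if mw_kda <= 0:
        raise ValueError("molar mass must be positive")
    return 1000.0 * np.asarray(c_ugml, dtype=float) / mw_kda


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean log-normal multiplicative noise with fractional CV ``cv``."""
    if cv < 0:
        raise ValueError("CV must be non-negative")
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


@dataclass
class BindingModel:
    """Ground truth for one antibody's binding to the four cell lines.

    Parameters
    ----------
    bmax : float
        Saturating stain intensity (arbitrary fluorescence units, > 0).
    kd_nm : float
        Intrinsic dissociation constant in nM (> 0).
    background : float
        Stain at zero concentration (a.u., >= 0).
    shield_beta : mapping Genotype -> float
        Dimensionless multiplicative Kd inflation per genotype
        (``Kd_eff = Kd * (1 + beta)``).  WT is fixed at 0.
    height_factor : float
        Optional scaling of beta in (0, 1] representing how far the epitope
        protrudes above the glycocalyx (1 = fully exposed to shielding).
    mw_kda : float
        Antibody molar mass for the µg/mL -> nM conversion.
    cv_cell, cv_meas : float
        Fractional CVs of the cell-to-cell and measurement log-normal factors.
    """

    bmax: float
    kd_nm: float
    background: float = 0.0
    shield_beta: Mapping[Genotype, float] = field(default_factory=dict)
    height_factor: float = 1.0
    mw_kda: float = IGG_MW_KDA
    cv_cell: float = 0.3
    cv_meas: float = 0.05

    def __post_init__(self) -> None:
        if self.bmax <= 0:
            raise ValueError("bmax must be positive")
        if self.kd_nm <= 0:
            raise ValueError("kd must be positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        if not (0 < self.height_factor <= 1):
            raise ValueError("height_factor must be in (0, 1]")
        if self.cv_cell < 0 or self.cv_meas < 0:
            raise ValueError("CVs must be non-negative")
        beta = {Genotype(g): float(b) for g, b in dict(self.shield_beta).items()}
        for g in Genotype:
            beta.setdefault(g, 0.0)
        if beta[Genotype.WT] != 0.0:
            raise ValueError("shield_beta[WT] must be 0")
        if any(b < 0 for b in beta.values()):
            raise ValueError("shielding factors must be non-negative")
        self.shield_beta = beta

    def effective_kd(self, genotype: Genotype) -> float:
        beta = self.shield_beta[Genotype(genotype)] * self.height_factor
        return self.kd_nm * (1.0 + beta)

    def expected_stain(self, genotype: Genotype, c_ugml: float) -> float:
        """Noise-free population mean stain at concentration ``c_ugml``."""
        c_nm = float(ugml_to_nm(c_ugml, self.mw_kda))
        kd_eff = self.effective_kd(genotype)
        return self.background + self.bmax * c_nm / (c_nm + kd_eff)

    def expected_ratio(self, genotype: Genotype, c_ugml: float) -> float:
        """Closed-form KO/WT mean-stain ratio at ``c_ugml``."""
        return self.expected_stain(genotype, c_ugml) / self.expected_stain(
            Genotype.WT, c_ugml
        )


def simulate_titration(
    model: BindingModel,
    genotype: Genotype,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    n_events: int = 10_000,
    seed: int = 0,
    pct_dead: float = 2.0,
    antibody: str = "ab",
) -> pd.DataFrame:
    """Simulate per-cell stain values for one genotype across a dilution series.

    Returns an event table with one row per cell and columns
    ``genotype, antibody, concentration_ugml, well, stain, viability``.
    The viability channel is low for live cells and high for the ``pct_dead``
    fraction of dead cells (default 2% background death).
    """
    genotype = Genotype(genotype)
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if len(concentrations) == 0:
        raise ValueError("at least one concentration required")
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be positive")
    if not 0 <= pct_dead <= 100:
        raise ValueError("pct_dead must be in [0, 100]")

    rng = np.random.default_rng(seed)
    frames = []
    for c in concentrations:
        mean = model.expected_stain(genotype, c)
        cell = _lognormal_factor(rng, model.cv_cell, n_events)
        meas = _lognormal_factor(rng, model.cv_meas, n_events)
        stain = mean * cell * meas
        dead = rng.random(n_events) < pct_dead / 100.0
        # live cells sit around 100 a.u. on the viability dye, dead around 1e4
        viability = np.where(dead, 1.0e4, 100.0) * _lognormal_factor(rng, 0.2, n_events)
        frames.append(
            pd.DataFrame(
                {
                    "genotype": genotype.value,
                    "antibody": antibody,
                    "concentration_ugml": float(c),
                    "well": f"{antibody}_c{c:g}",
                    "stain": stain,
                    "viability": viability,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class BarcodeScheme:
    """Two-dye barcoding of the four genotypes.

    Each genotype maps to one of the four high/low combinations on the two
    barcode channels: WT is high on dye 1 only, the SPPL3 knockout high on
    dye 2 only, the double knockout high on both, and the B3GNT5 knockout
    carries neither dye.
    """

    dye1: str = "dye1"
    dye2: str = "dye2"
    base_intensity: float = 100.0

    #: genotype -> (high on dye1, high on dye2)
    COMBINATIONS: Mapping[Genotype, tuple[bool, bool]] = field(
        default_factory=lambda: {
            Genotype.WT: (True, False),
            Genotype.SPPL3KO: (False, True),
            Genotype.DKO: (True, True),
            Genotype.B3GNT5KO: (False, False),
        }
    )

    def combination(self, genotype: Genotype) -> tuple[bool, bool]:
        return self.COMBINATIONS[Genotype(genotype)]

    def genotype_for(self, hi1: bool, hi2: bool) -> Genotype:
        for g, combo in self.COMBINATIONS.items():
            if combo == (hi1, hi2):
                return g
        raise KeyError((hi1, hi2))


def attach_barcodes(
    events: pd.DataFrame,
    scheme: BarcodeScheme = BarcodeScheme(),
    separation: float = 100.0,
    cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Add the two barcode-dye channels according to each event's genotype.

    ``separation`` is the fold difference between the high and low dye modes
    (must exceed 1).  The genotype ground-truth column is retained so that
    demultiplexing accuracy can be scored downstream.
    """
    if separation <= 1:
        raise ValueError("separation must be > 1")
    unknown = set(events["genotype"]) - {g.value for g in Genotype}
    if unknown:
        raise ValueError(f"unknown genotypes in event table: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    out = events.copy()
    n = len(out)
    hi1 = np.empty(n, dtype=bool)
    hi2 = np.empty(n, dtype=bool)
    for g in Genotype:
        mask = (out["genotype"] == g.value).to_numpy()
        h1, h2 = scheme.combination(g)
        hi1[mask] = h1
        hi2[mask] = h2
    lo, hi = scheme.base_intensity, scheme.base_intensity * separation
    out[scheme.dye1] = np.where(hi1, hi, lo) * _lognormal_factor(rng, cv, n)
    out[scheme.dye2] = np.where(hi2, hi, lo) * _lognormal_factor(rng, cv, n)
    return out


@dataclass(frozen=True)
class ToyStructureSpec:
    """Specification of a synthetic Cα-only structure fixture."""

    n_residues: int
    geometry: str = "line"  # line | helix | cloud
    spacing: float = 3.8  # Å between consecutive Cα (line); cloud scale
    helix_radius: float = 2.3
    helix_rise: float = 1.5
    helix_turn_deg: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.geometry not in ("line", "helix", "cloud"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def toy_structure_coordinates(spec: ToyStructureSpec) -> np.ndarray:
    """Cα coordinates (n, 3) for a toy structure specification."""
    n = spec.n_residues
    if spec.geometry == "line":
        coords = np.zeros((n, 3))
        coords[:, 2] = np.arange(n) * spec.spacing
    elif spec.geometry == "helix":
        t = np.arange(n)
        theta = np.deg2rad(spec.helix_turn_deg) * t
        coords = np.column_stack(
            [
                spec.helix_radius * np.cos(theta),
                spec.helix_radius * np.sin(theta),
                spec.helix_rise * t,
            ]
        )
    else:  # cloud
        rng = np.random.default_rng(spec.seed)
        coords = rng.normal(scale=3.0 * spec.spacing, size=(n, 3))
    return coords


def write_toy_structure(spec: ToyStructureSpec, path) -> None:
    """Write the toy structure as a Cα-only single-chain PDB or mmCIF file.

    The format follows the file suffix (``.pdb`` vs ``.cif``); residues are
    numbered sequentially from 1 on chain A.
    """
    import gemmi

    coords = toy_structure_coordinates(spec)
    structure = gemmi.Structure()
    structure.name = "toy"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (x, y, z) in enumerate(coords, start=1):
        res = gemmi.Residue()
        res.name = "GLY"
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    path = str(path)
    if path.endswith(".cif"):
        structure.make_mmcif_document().write_file(path)
    else:
        structure.write_pdb(path)


def simulate_killing_plate(
    base_death: float,
    effect: Mapping[tuple[str, float], float],
    n_cells_per_well: int = 10_000,
    seed: int = 0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulate a cytotoxicity plate with binomial per-well death counts.

    ``effect`` maps ``(genotype, E:T ratio)`` to the added percentage of dead
    target cells over ``base_death``.  For every genotype appearing in
    ``effect`` a matching no-effector control well (E:T = 0, effect 0) is
    included.  Means pushed outside [0, 100] are clamped with a warning.
    """
    if not 0 <= base_death <= 100:
        raise ValueError("base_death must be in [0, 100]")
    if n_cells_per_well < 1:
        raise ValueError("n_cells_per_well must be >= 1")

    rng = np.random.default_rng(seed)
    rows = []
    genotypes = sorted({g for g, _ in effect})
    conditions = list(effect.items()) + [((g, 0.0), 0.0) for g in genotypes]
    for (genotype, et_ratio), added in conditions:
        mean = base_death + added
        if mean < 0 or mean > 100:
            warnings.warn(
                f"death probability for ({genotype}, E:T {et_ratio}) clamped "
                f"from {mean:.1f}% into [0, 100]"
            )
            mean = min(max(mean, 0.0), 100.0)
        for rep in range(n_replicates):
            dead = rng.binomial(n_cells_per_well, mean / 100.0)
            rows.append(
                {
                    "target": genotype,
                    "et_ratio": float(et_ratio),
                    "replicate": rep + 1,
                    "n_cells": n_cells_per_well,
                    "pct_dead": 100.0 * dead / n_cells_per_well,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PanelAntibody:
    """Ground-truth record for one simulated panel antibody."""

    antibody: str
    protein: str
    kd_nm: float
    beta_sppl3: float = 0.0
    beta_b3gnt5: float = 0.0
    beta_dko: float = 0.0
    epitope_position: str = "intermediate"  # proximal | intermediate | distal

    def binding_model(self, bmax=1000.0, background=0.0, cv_cell=0.3, cv_meas=0.05) -> BindingModel:
        return BindingModel(
            bmax=bmax,
            kd_nm=self.kd_nm,
            background=background,
            shield_beta={
                Genotype.SPPL3KO: self.beta_sppl3,
                Genotype.B3GNT5KO: self.beta_b3gnt5,
                Genotype.DKO: self.beta_dko,
            },
            cv_cell=cv_cell,
            cv_meas=cv_meas,
        )

    @property
    def true_epitope_label(self) -> str:
        return "affected_decreased" if self.beta_sppl3 > 0 else "unaffected"

    @property
    def true_nsgsl_label(self) -> str:
        if self.beta_sppl3 <= 0:
            return "not_applicable"
        # DKO restoration (no shielding left in the double knockout) defines
        # glycosphingolipid dependence
        return "nsGSL_dependent" if self.beta_dko < self.beta_sppl3 / 2 else "nsGSL_independent"


def example_panel(
    n_proteins: int = 10,
    n_antibodies: int = 4,
    beta_shielded: float = 1.5,
    kd_range_nm: tuple[float, float] = (2.0, 20.0),
) -> list[PanelAntibody]:
    """Deterministic study-condition panel: proteins x antibody clones.

    The first 40% of proteins are fully shielded (every clone carries
    ``beta_shielded``), the next 30% partially shielded (half the clones),
    and the rest unshielded.  Shielding is relieved in the double knockout.
    Kd values cycle deterministically over a log-spaced grid inside
    ``kd_range_nm`` so clones differ in affinity; the default 2-20 nM grid
    keeps the sub-saturating analysis concentration (1 µg/mL of IgG, about
    6.7 nM) near or below every Kd, so that the closed-form shielding ratio
    (c + Kd)/(c + Kd (1 + beta)) leaves the similarity band for every
    shielded clone while saturating stains remain genotype-equal.
    """
    kds = np.logspace(*np.log10(kd_range_nm), num=n_antibodies)
    n_full = max(1, round(0.4 * n_proteins))
    n_partial = max(1, round(0.3 * n_proteins))
    panel = []
    for p in range(n_proteins):
        protein = f"P{p + 1:02d}"
        for a in range(n_antibodies):
            if p < n_full:
                beta = beta_shielded
            elif p < n_full + n_partial:
                beta = beta_shielded if a < n_antibodies // 2 else 0.0
            else:
                beta = 0.0
            panel.append(
                PanelAntibody(
                    antibody=f"{protein}_ab{a + 1}",
                    protein=protein,
                    kd_nm=float(kds[a]),
                    beta_sppl3=beta,
                    beta_dko=0.0,
                )
            )
    return panel


def panel_truth(panel: Sequence[PanelAntibody]) -> pd.DataFrame:
    """Per-antibody and per-protein ground-truth labels for a simulated panel."""
    rows = []
    for ab in panel:
        rows.append(
            {
                "antibody": ab.antibody,
                "protein": ab.protein,
                "kd_nm": ab.kd_nm,
                "beta_sppl3": ab.beta_sppl3,
                "beta_dko": ab.beta_dko,
                "epitope_position": ab.epitope_position,
                "epitope_label": ab.true_epitope_label,
                "nsgsl_label": ab.true_nsgsl_label,
            }
        )
    truth = pd.DataFrame(rows)
    group = {}
    for protein, sub in truth.groupby("protein"):
        n_aff = (sub["epitope_label"] == "affected_decreased").sum()
        if n_aff == len(sub):
            group[protein] = "fully_affected"
        elif n_aff > 0:
            group[protein] = "partially_affected"
        else:
            group[protein] = "unaffected"
    truth["protein_group"] = truth["protein"].map(group)
    return truth


def simulate_panel(
    panel: Sequence[PanelAntibody],
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    n_events_per_genotype: int = 10_000,
    seed: int = 0,
    bmax: float = 1000.0,
    background: float = 0.0,
    cv_cell: float = 0.3,
    cv_meas: float = 0.05,
    scheme: BarcodeScheme = BarcodeScheme(),
    separation: float = 100.0,
    barcode_cv: float = 0.05,
    pct_dead: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full barcoded antibody panel.

    Each antibody/concentration well contains a 1:1:1:1 mixture of the four
    genotypes with barcode dyes attached.  Returns ``(events, truth)`` where
    ``events`` has one row per cell (genotype truth retained) and ``truth``
    is the :func:`panel_truth` table.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(panel) * len(Genotype) + 1)
    frames = []
    k = 0
    for ab in panel:
        model = ab.binding_model(bmax=bmax, background=background, cv_cell=cv_cell, cv_meas=cv_meas)
        for genotype in Genotype:
            ev = simulate_titration(
                model,
                genotype,
                concentrations=concentrations,
                n_events=n_events_per_genotype,
                seed=int(seeds[k] % (2**31)),
                pct_dead=pct_dead,
                antibody=ab.antibody,
            )
            ev = attach_barcodes(
                ev, scheme, separation=separation, cv=barcode_cv,
                seed=int(seeds[k + 1] % (2**31)),
            )
            frames.append(ev)
            k += 2
    events = pd.concat(frames, ignore_index=True)
    return events, panel_truth(panel)
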