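"""Config-driven orchestration: simulate -> mfi -> classify -> protrude -> assay -> affinity.

Stages run in dependency order, share in-memory intermediates within one run,
and each writes its TSV outputs under the configured output directory.  The
consolidated ``report.tsv`` only re-reads stage outputs, so every reported
number is traceable to a file on disk.  Fixed seeds make reruns byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import affinity as aff
from . import assays, classify, cytometry, protrusion, synthetic

logger = logging.getLogger("glycoshield")

ALL_STEPS = ("simulate", "mfi", "classify", "protrude", "assay", "affinity", "report")


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-loadable)."""

    outdir: str = "results/pipeline"
    seed: int = 0
    steps: tuple[str, ...] = ALL_STEPS
    # synthetic panel (study conditions)
    n_proteins: int = 10
    n_antibodies: int = 4
    beta_shielded: float = 1.5
    n_events_per_genotype: int = 2000
    concentrations: tuple[float, ...] = synthetic.DEFAULT_CONCENTRATIONS
    bmax: float = 1000.0
    background: float = 0.0
    cv_cell: float = 0.3
    cv_meas: float = 0.05
    write_events: bool = False
    # QC and classification thresholds
    positivity_factor: float = 2.0
    saturation_tolerance: float = 0.10
    band_lower: float = 0.8
    band_upper: float = 1.2
    min_events: int = 200
    control_mfi: float = 50.0
    # effector assay
    base_death: float = 10.0
    killing_effects: dict = field(
        default_factory=lambda: {
            ("WT", 10.0): 40.0, ("WT", 5.0): 30.0, ("WT", 1.0): 10.0,
            ("SPPL3KO", 10.0): 20.0, ("SPPL3KO", 5.0): 15.0, ("SPPL3KO", 1.0): 5.0,
            ("DKO", 10.0): 38.0, ("DKO", 5.0): 28.0, ("DKO", 1.0): 9.0,
        }
    )
    n_cells_per_well: int = 10_000
    # affinity panel
    affinity_beta: float = 1.5
    # structure inputs: list of {protein, path, chain, tm_spans, n_term}
    structures: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        effects = raw.pop("killing_effects", None)
        cfg = cls(**raw)
        if effects is not None:
            cfg.killing_effects = {
                (str(e["target"]), float(e["et_ratio"])): float(e["added_death"])
                for e in effects
            }
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.steps) - set(ALL_STEPS)
        if unknown:
            raise ValueError(f"unknown pipeline steps: {sorted(unknown)}")
        for entry in self.structures:
            p = Path(entry["path"])
            if not p.exists():
                raise FileNotFoundError(f"structure file not found: {p}")

    @property
    def qc_config(self) -> cytometry.QCConfig:
        return cytometry.QCConfig(
            positivity_factor=self.positivity_factor,
            saturation_tolerance=self.saturation_tolerance,
            similarity_low=self.band_lower,
            similarity_high=self.band_upper,
            min_events=self.min_events,
        )

    @property
    def class_config(self) -> classify.ClassificationConfig:
        return classify.ClassificationConfig(self.band_lower, self.band_upper)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages; returns the output directory.

    Stage failures propagate after partial outputs are preserved on disk.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    state: dict = {}

    steps = [s for s in ALL_STEPS if s in config.steps]
    for step in steps:
        logger.info("running stage %s", step)
        try:
            _STAGES[step](config, outdir, seeds, state)
        except Exception:
            logger.exception("stage %s failed; partial outputs kept in %s", step, outdir)
            raise
    return outdir


def _stage_simulate(config: RunConfig, outdir: Path, seeds, state) -> None:
    panel = synthetic.example_panel(
        config.n_proteins, config.n_antibodies, config.beta_shielded
    )
    events, truth = synthetic.simulate_panel(
        panel,
        concentrations=config.concentrations,
        n_events_per_genotype=config.n_events_per_genotype,
        seed=int(seeds[0]),
        bmax=config.bmax,
        background=config.background,
        cv_cell=config.cv_cell,
        cv_meas=config.cv_meas,
    )
    state["events"], state["truth"], state["panel"] = events, truth, panel
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if config.write_events:
        cytometry.write_events_csv(events, outdir / "events.csv")


def _stage_mfi(config: RunConfig, outdir: Path, seeds, state) -> None:
    if "events" not in state:
        raise RuntimeError("mfi stage requires the simulate stage (or loaded events)")
    curves = cytometry.titration_curves(
        state["events"], config=config.qc_config
    )
    state["curves"] = curves
    tables = []
    qc_rows = []
    for ab, curve in sorted(curves.items()):
        t = curve.table.copy()
        t.insert(0, "antibody", ab)
        tables.append(t)
        pos = cytometry.qc_positivity(curve, config.control_mfi, config.qc_config)
        sat = cytometry.detect_saturating(curve, config=config.qc_config)
        qc_rows.append(
            {
                "antibody": ab,
                "positivity_pass": pos.passed,
                "positivity_reason": pos.reason,
                "saturation_status": sat.status,
                "analysis_concentration": sat.analysis_concentration,
            }
        )
    pd.concat(tables, ignore_index=True).to_csv(
        outdir / "titration_mfi.tsv", sep="\t", index=False
    )
    qc = pd.DataFrame(qc_rows)
    # surface the thresholds in force for auditability
    qc.attrs["thresholds"] = asdict(config.qc_config) if hasattr(config.qc_config, "__dict__") else {}
    qc.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    state["qc"] = qc


def _stage_classify(config: RunConfig, outdir: Path, seeds, state) -> None:
    if "curves" not in state:
        raise RuntimeError("classify stage requires the mfi stage")
    mapping = {ab.antibody: ab.protein for ab in state["panel"]}
    calls, groups = classify.classify_panel(
        state["curves"], mapping, config.class_config, config.qc_config
    )
    calls.to_csv(outdir / "epitope_calls.tsv", sep="\t", index=False)
    groups.to_csv(outdir / "protein_groups.tsv", sep="\t", index=False)
    state["calls"], state["groups"] = calls, groups


def _stage_protrude(config: RunConfig, outdir: Path, seeds, state) -> None:
    rows = []
    for entry in config.structures:
        trace = protrusion.load_ca_trace(entry["path"], entry.get("chain"))
        topo = protrusion.TopologyAnnotation(
            chain=trace.chain,
            tm_spans=tuple(tuple(s) for s in entry.get("tm_spans", ())),
            n_term=entry.get("n_term", "out"),
        )
        result = protrusion.protrusion_result(entry["protein"], trace, topo)
        for seg in result.segments:
            rows.append(
                {
                    "protein": entry["protein"],
                    "segment_start": seg.segment.start,
                    "segment_end": seg.segment.end,
                    "anchor": seg.segment.anchor,
                    "protrusion_angstrom": round(seg.distance, 1),
                    "reported": result.reported,
                }
            )
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "protrusion.tsv", sep="\t", index=False)
    # group statistics from the packaged reference ECD sizes
    table1 = protrusion.load_table1()
    affected = table1.loc[table1["group"] == "affected", "ecd_size_angstrom"]
    non_affected = table1.loc[table1["group"] == "non_affected", "ecd_size_angstrom"]
    stats_rows = []
    for label, non_aff in (
        ("with_HLA-I", non_affected),
        ("without_HLA-I", non_affected[table1["protein"] != "HLA-I"]),
    ):
        cmp = protrusion.compare_groups(affected, non_aff)
        stats_rows.append(
            {
                "non_affected_variant": label,
                "affected_mean": cmp.mean_a, "affected_sd": cmp.sd_a,
                "non_affected_mean": cmp.mean_b, "non_affected_sd": cmp.sd_b,
                "t": cmp.t, "p": cmp.p,
            }
        )
    pd.DataFrame(stats_rows).to_csv(outdir / "group_stats.tsv", sep="\t", index=False)


def _stage_assay(config: RunConfig, outdir: Path, seeds, state) -> None:
    wells = synthetic.simulate_killing_plate(
        config.base_death,
        config.killing_effects,
        n_cells_per_well=config.n_cells_per_well,
        seed=int(seeds[1]),
    )
    results = assays.specific_death_table(wells)
    results.to_csv(outdir / "assay_results.tsv", sep="\t", index=False)
    stats_frames = []
    for et, sub in results.groupby("et_ratio"):
        groups = {
            t: g["specific_death"].to_numpy() for t, g in sub.groupby("target")
        }
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            continue
        design = "anova_tukey" if len(groups) > 2 else "student_t"
        table = assays.run_stats(groups, design)
        table.insert(0, "et_ratio", et)
        stats_frames.append(table)
    if stats_frames:
        pd.concat(stats_frames, ignore_index=True).to_csv(
            outdir / "assay_stats.tsv", sep="\t", index=False
        )
    state["assay_results"] = results


def _stage_affinity(config: RunConfig, outdir: Path, seeds, state) -> None:
    meta = aff.load_cd147_panel()
    panel = [
        synthetic.PanelAntibody(
            antibody=str(r.antibody), protein="CD147", kd_nm=float(r.kd_nm),
            beta_sppl3=config.affinity_beta, beta_dko=0.0,
            epitope_position=str(r.epitope_position),
        )
        for r in meta.itertuples()
    ]
    events, _ = synthetic.simulate_panel(
        panel,
        concentrations=config.concentrations,
        n_events_per_genotype=config.n_events_per_genotype,
        seed=int(seeds[2]),
        bmax=config.bmax,
        background=config.background,
        cv_cell=config.cv_cell,
        cv_meas=config.cv_meas,
    )
    curves = cytometry.titration_curves(events, config=config.qc_config)
    sens = aff.sensitivity_panel(curves, config.qc_config)
    sens.to_csv(outdir / "sensitivity.tsv", sep="\t", index=False)
    meta2 = meta.copy()
    meta2["antibody"] = meta2["antibody"].astype(str)
    rows = []
    for method in ("pearson", "spearman"):
        res = aff.correlate_affinity(sens, meta2, method=method)
        rows.append(
            {"method": method, "transform": res.transform, "r": res.r,
             "p": res.p, "n": res.n}
        )
    pd.DataFrame(rows).to_csv(outdir / "affinity_correlation.tsv", sep="\t", index=False)
    cat = aff.position_category_analysis(sens, meta2)
    cat.summary.assign(anova_f=cat.f, anova_p=cat.p).to_csv(
        outdir / "position_categories.tsv", sep="\t", index=False
    )
    state["sensitivity"], state["correlation"] = sens, rows


def _stage_report(config: RunConfig, outdir: Path, seeds, state) -> None:
    """Consolidated summary, assembled purely from stage output files."""
    rows = [
        {"item": "seed", "value": config.seed},
        {"item": "band_lower", "value": config.band_lower},
        {"item": "band_upper", "value": config.band_upper},
        {"item": "saturation_tolerance", "value": config.saturation_tolerance},
        {"item": "positivity_factor", "value": config.positivity_factor},
    ]
    qc_path = outdir / "qc_report.tsv"
    if qc_path.exists():
        qc = pd.read_csv(qc_path, sep="\t")
        rows.append({"item": "antibodies_positive", "value": int(qc["positivity_pass"].sum())})
    groups_path = outdir / "protein_groups.tsv"
    if groups_path.exists():
        groups = pd.read_csv(groups_path, sep="\t")
        for cat, n in groups["category"].value_counts().items():
            rows.append({"item": f"proteins_{cat}", "value": int(n)})
    gs_path = outdir / "group_stats.tsv"
    if gs_path.exists():
        gs = pd.read_csv(gs_path, sep="\t")
        rows.append({"item": "affected_ecd_mean", "value": float(gs["affected_mean"].iloc[0])})
        rows.append({"item": "affected_ecd_sd", "value": float(gs["affected_sd"].iloc[0])})
    corr_path = outdir / "affinity_correlation.tsv"
    if corr_path.exists():
        corr = pd.read_csv(corr_path, sep="\t")
        pearson = corr[corr["method"] == "pearson"].iloc[0]
        rows.append({"item": "affinity_pearson_r", "value": float(pearson["r"])})
    pd.DataFrame(rows).to_csv(outdir / "report.tsv", sep="\t", index=False)


_STAGES = {
    "simulate": _stage_simulate,
    "mfi": _stage_mfi,
    "classify": _stage_classify,
    "protrude": _stage_protrude,
    "assay": _stage_assay,
    "affinity": _stage_affinity,
    "report": _stage_report,
}
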