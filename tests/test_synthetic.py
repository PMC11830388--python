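"""Generator correctness: closed-form expectations, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest

from glycoshield import cytometry, synthetic
from glycoshield.synthetic import (
    BarcodeScheme,
    BindingModel,
    Genotype,
    ToyStructureSpec,
    attach_barcodes,
    simulate_killing_plate,
    simulate_titration,
    toy_structure_coordinates,
    ugml_to_nm,
    write_toy_structure,
)


def c_ugml(c_nm: float, mw_kda: float = 150.0) -> float:
    return c_nm * mw_kda / 1000.0


class TestSimulateTitration:
    def test_half_saturation_identity(self):
        """At c = Kd with no background the population mean is Bmax/2."""
        model = BindingModel(bmax=1000.0, kd_nm=5.0, background=0.0)
        ev = simulate_titration(model, Genotype.WT, [c_ugml(5.0)], n_events=100_000, seed=1)
        mean = ev["stain"].mean()
        se = ev["stain"].std() / np.sqrt(len(ev))
        assert abs(mean - 500.0) < 3 * se

    def test_saturation_limit_ratio_is_one(self):
        """At 1e4-fold excess over Kd_eff the KO/WT mean ratio is 1 within 1%."""
        beta = 2.0
        model = BindingModel(
            bmax=1000.0, kd_nm=5.0, background=0.0,
            shield_beta={Genotype.SPPL3KO: beta},
        )
        c = c_ugml(1e4 * 5.0 * (1 + beta))
        wt = simulate_titration(model, Genotype.WT, [c], n_events=50_000, seed=2)
        ko = simulate_titration(model, Genotype.SPPL3KO, [c], n_events=50_000, seed=3)
        ratio = ko["stain"].mean() / wt["stain"].mean()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_closed_form_shielding_ratio(self):
        """beta=1.5 at c = Kd gives KO/WT = 2/3.5, checked at 1e5 draws."""
        model = BindingModel(
            bmax=1000.0, kd_nm=5.0, background=0.0,
            shield_beta={Genotype.SPPL3KO: 1.5},
        )
        c = c_ugml(5.0)
        n = 100_000
        wt = simulate_titration(model, Genotype.WT, [c], n_events=n, seed=4)
        ko = simulate_titration(model, Genotype.SPPL3KO, [c], n_events=n, seed=5)
        ratio = ko["stain"].mean() / wt["stain"].mean()
        expected = 2.0 / 3.5
        # delta-method SE of the ratio of two independent means
        se = expected * np.sqrt(
            (wt["stain"].std() / wt["stain"].mean()) ** 2
            + (ko["stain"].std() / ko["stain"].mean()) ** 2
        ) / np.sqrt(n)
        assert abs(ratio - expected) < 3 * se
        assert model.expected_ratio(Genotype.SPPL3KO, c) == pytest.approx(expected)

    def test_seed_determinism(self):
        model = BindingModel(bmax=500.0, kd_nm=2.0)
        a = simulate_titration(model, Genotype.WT, [1.0, 0.1], n_events=500, seed=9)
        b = simulate_titration(model, Genotype.WT, [1.0, 0.1], n_events=500, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_event_count_exact_and_rejects_bad_input(self):
        model = BindingModel(bmax=500.0, kd_nm=2.0)
        ev = simulate_titration(model, Genotype.WT, [1.0], n_events=123, seed=0)
        assert len(ev) == 123
        with pytest.raises(ValueError):
            simulate_titration(model, Genotype.WT, [-1.0], n_events=10, seed=0)
        with pytest.raises(ValueError):
            BindingModel(bmax=500.0, kd_nm=0.0)
        with pytest.raises(ValueError):
            BindingModel(bmax=500.0, kd_nm=1.0, shield_beta={Genotype.WT: 1.0})

    @pytest.mark.parametrize("beta", [0.5, 1.5, 4.0])
    def test_saturation_invariance_property(self, beta):
        """KO/WT expected ratio at c >= 1e3*Kd_eff stays within [0.99, 1.01]."""
        model = BindingModel(
            bmax=1000.0, kd_nm=5.0, background=0.0,
            shield_beta={Genotype.SPPL3KO: beta},
        )
        c = c_ugml(1e3 * 5.0 * (1 + beta))
        assert 0.99 <= model.expected_ratio(Genotype.SPPL3KO, c) <= 1.01

    def test_shielding_ratio_decreases_with_kd(self):
        """At fixed beta and concentration, higher Kd means more shielding."""
        c = 1.0
        ratios = []
        for kd in [0.5, 2.0, 8.0, 32.0]:
            m = BindingModel(
                bmax=1000.0, kd_nm=kd, background=0.0,
                shield_beta={Genotype.SPPL3KO: 1.5},
            )
            ratios.append(m.expected_ratio(Genotype.SPPL3KO, c))
        assert all(a > b for a, b in zip(ratios, ratios[1:]))


class TestBarcodes:
    def test_demultiplex_recovers_labels(self):
        model = BindingModel(bmax=1000.0, kd_nm=5.0)
        frames = [
            simulate_titration(model, g, [1.0], n_events=3000, seed=i, pct_dead=0.0)
            for i, g in enumerate(Genotype)
        ]
        events = attach_barcodes(pd.concat(frames, ignore_index=True), separation=100, cv=0.05, seed=42)
        split = cytometry.demultiplex(events, gate_viability=False)
        total = sum(len(v) for v in split.values())
        correct = sum((v["genotype"] == g.value).sum() for g, v in split.items())
        assert total == len(events)
        assert correct / total >= 0.999

    def test_near_degenerate_separation_gives_chance(self):
        """With vanishing dye separation everything is called all-low (25%)."""
        model = BindingModel(bmax=1000.0, kd_nm=5.0)
        frames = [
            simulate_titration(model, g, [1.0], n_events=1000, seed=i, pct_dead=0.0)
            for i, g in enumerate(Genotype)
        ]
        events = attach_barcodes(
            pd.concat(frames, ignore_index=True), separation=1.0001, cv=0.05, seed=7
        )
        with pytest.warns(UserWarning, match="unimodal"):
            split = cytometry.demultiplex(events, gate_viability=False)
        correct = sum((v["genotype"] == g.value).sum() for g, v in split.items())
        assert correct / len(events) == pytest.approx(0.25, abs=0.02)

    def test_determinism_and_unknown_genotype(self):
        model = BindingModel(bmax=1000.0, kd_nm=5.0)
        ev = simulate_titration(model, Genotype.WT, [1.0], n_events=200, seed=3)
        a = attach_barcodes(ev, separation=50, cv=0.05, seed=5)
        b = attach_barcodes(ev, separation=50, cv=0.05, seed=5)
        pd.testing.assert_frame_equal(a, b)
        bad = ev.assign(genotype="MUTANT")
        with pytest.raises(ValueError, match="unknown genotype"):
            attach_barcodes(bad, separation=50, cv=0.05, seed=5)
        with pytest.raises(ValueError):
            attach_barcodes(ev, separation=1.0, cv=0.05, seed=5)


def brute_force_protrusion(coords: np.ndarray, anchor_index: int) -> float:
    return max(
        float(np.linalg.norm(coords[anchor_index] - coords[j]))
        for j in range(len(coords))
    )


class TestToyStructures:
    def test_line_protrusion_from_end(self, tmp_path):
        spec = ToyStructureSpec(n_residues=11, geometry="line", spacing=3.8)
        path = tmp_path / "line.pdb"
        write_toy_structure(spec, path)
        from glycoshield.protrusion import (
            Segment, load_ca_trace, max_protrusion,
        )
        trace = load_ca_trace(path)
        assert len(trace) == 11
        result = max_protrusion(trace, Segment(1, 11, 1))
        assert result.distance == pytest.approx(38.0, abs=1e-6)
        oracle = brute_force_protrusion(toy_structure_coordinates(spec), 0)
        assert result.distance == pytest.approx(oracle, abs=1e-6)

    def test_single_residue_zero(self, tmp_path):
        path = tmp_path / "one.pdb"
        write_toy_structure(ToyStructureSpec(n_residues=1), path)
        from glycoshield.protrusion import Segment, load_ca_trace, max_protrusion
        trace = load_ca_trace(path)
        assert max_protrusion(trace, Segment(1, 1, 1)).distance == 0.0

    def test_cloud_matches_brute_force(self, tmp_path):
        spec = ToyStructureSpec(n_residues=50, geometry="cloud", seed=13)
        path = tmp_path / "cloud.pdb"
        write_toy_structure(spec, path)
        from glycoshield.protrusion import Segment, load_ca_trace, max_protrusion
        trace = load_ca_trace(path)
        got = max_protrusion(trace, Segment(1, 50, 1)).distance
        # coordinates round-trip through fixed-precision PDB fields
        oracle = brute_force_protrusion(toy_structure_coordinates(spec), 0)
        assert got == pytest.approx(oracle, abs=2e-3)


class TestKillingPlate:
    def test_null_plate(self):
        wells = simulate_killing_plate(
            10.0, {("WT", 5.0): 0.0}, n_cells_per_well=10_000, seed=0, n_replicates=6
        )
        from glycoshield.assays import specific_death_table
        sd = specific_death_table(wells)["specific_death"]
        se = 100 * np.sqrt(0.1 * 0.9 / 10_000)
        assert abs(sd.mean()) < 3 * se

    def test_effect_recovery_within_binomial_se(self):
        wells = simulate_killing_plate(
            10.0, {("WT", 5.0): 30.0}, n_cells_per_well=10_000, seed=1, n_replicates=6
        )
        from glycoshield.assays import specific_death_table
        sd = specific_death_table(wells)
        got = sd[sd["et_ratio"] == 5.0]["specific_death"].mean()
        se = 100 * np.sqrt(0.4 * 0.6 / 10_000)
        assert abs(got - 30.0) < 3 * se

    def test_monotone_effect_recovered(self):
        effects = {("WT", et): 5.0 * et for et in (0.5, 1.0, 2.5, 5.0, 10.0)}
        wells = simulate_killing_plate(
            5.0, effects, n_cells_per_well=100_000, seed=2, n_replicates=3
        )
        from glycoshield.assays import specific_death_table
        sd = (
            specific_death_table(wells)
            .groupby("et_ratio")["specific_death"].mean().sort_index()
        )
        assert sd.is_monotonic_increasing

    def test_clamping_warns(self):
        with pytest.warns(UserWarning, match="clamped"):
            simulate_killing_plate(90.0, {("WT", 5.0): 30.0}, seed=0)
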