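import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmaqc import simulate as sim


class TestPlasmaProteome:
    def test_top20_mass_fraction_hits_target(self):
        plasma = sim.generate_plasma_proteome(1000, 0.99, seed=1)
        assert 0.985 <= plasma.top20_mass_fraction() <= 0.995
        assert plasma.abundance.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(plasma.abundance) <= 0)  # descending

    def test_low_target_small_n_normalises(self):
        # a 50% top-20 target at n=30 cannot stay globally descending
        # (pigeonhole on block means); the mass split is still exact
        with pytest.warns(UserWarning, match="descending"):
            plasma = sim.generate_plasma_proteome(30, 0.5, seed=7)
        assert plasma.abundance.sum() == pytest.approx(1.0, abs=1e-9)
        assert plasma.abundance[:20].sum() == pytest.approx(0.5, abs=1e-9)

    def test_fixed_seed_determinism(self):
        a = sim.generate_plasma_proteome(1000, 0.99, seed=1)
        b = sim.generate_plasma_proteome(1000, 0.99, seed=1)
        assert np.array_equal(a.abundance, b.abundance)

    def test_too_few_proteins_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_plasma_proteome(29, 0.99, seed=0)
        with pytest.raises(ValueError):
            sim.generate_plasma_proteome(100, 1.5, seed=0)


class TestCellProteome:
    def test_erythrocyte_hemoglobin_dominance(self):
        cell = sim.generate_cell_proteome("erythrocyte", 3000, 50, seed=2)
        assert cell.abundance[:5].sum() >= 0.75
        assert cell.abundance.sum() == pytest.approx(1.0, abs=1e-9)

    def test_determinism(self):
        a = sim.generate_cell_proteome("platelet", 6000, 50, seed=3)
        b = sim.generate_cell_proteome("platelet", 6000, 50, seed=3)
        assert np.array_equal(a.abundance, b.abundance)
        assert np.array_equal(a.protein_ids, b.protein_ids)

    def test_markers_disjoint_from_plasma_namespace(self):
        cell = sim.generate_cell_proteome("pbmc", 8000, 50, seed=1)
        assert len(cell.marker_ids) == 50
        assert not any(m.startswith("P0") for m in cell.marker_ids)
        assert all(s.startswith("P") for s in cell.shared_ids)

    def test_unknown_cell_type_rejected(self):
        with pytest.raises(ValueError, match="cell_type"):
            sim.generate_cell_proteome("neuron", 100, 10, seed=0)

    def test_per_cell_mass_tracks_cell_volume(self):
        plt = sim.generate_cell_proteome("platelet", 100, 10, seed=0)
        ery = sim.generate_cell_proteome("erythrocyte", 100, 10, seed=0)
        pbmc = sim.generate_cell_proteome("pbmc", 100, 10, seed=0)
        assert pbmc.per_cell_protein_mass > ery.per_cell_protein_mass > plt.per_cell_protein_mass


class TestSpikeInMixture:
    @pytest.fixture()
    def models(self):
        plasma = sim.generate_plasma_proteome(100, 0.99, seed=1)
        cells = [
            sim.generate_cell_proteome(ct, 60, 10, seed=i, plasma_namespace_size=100)
            for i, ct in enumerate(["platelet", "erythrocyte", "pbmc"])
        ]
        return plasma, cells

    def test_zero_spike_equals_pure_plasma(self, models):
        plasma, cells = models
        truth = sim.simulate_spikein_series(plasma, cells, [{c.cell_type: 0.0 for c in cells}])
        mix = truth.mixture()
        expected = plasma.mass_series().reindex(mix.index, fill_value=0.0)
        assert np.allclose(mix.iloc[:, 0].to_numpy(), expected.to_numpy(), rtol=1e-12)

    def test_doubling_count_doubles_contribution(self, models):
        plasma, cells = models
        t1 = sim.simulate_spikein_series(plasma, cells[:1], [{"platelet": 1e4}])
        t2 = sim.simulate_spikein_series(plasma, cells[:1], [{"platelet": 2e4}])
        c1 = t1.contaminant_mass(0)
        c2 = t2.contaminant_mass(0)
        assert np.allclose(c2.to_numpy(), 2.0 * c1.to_numpy(), rtol=1e-12)

    def test_combined_contamination_is_sum_of_single_types(self, models):
        plasma, cells = models
        counts = {"erythrocyte": 5e5, "platelet": 5e4, "pbmc": 500.0}
        combined = sim.simulate_spikein_series(plasma, cells, [counts])
        total = combined.contaminant_mass(0)
        # oracle: independent per-type summation
        expected = pd.Series(0.0, index=total.index)
        for cell in cells:
            expected = expected.add(
                cell.mass_series(counts[cell.cell_type]), fill_value=0.0
            )
        assert np.allclose(
            total.to_numpy(), expected.reindex(total.index, fill_value=0.0).to_numpy(),
            rtol=1e-12,
        )

    def test_mass_conservation(self, models):
        plasma, cells = models
        counts = {"erythrocyte": 1e5, "platelet": 1e4, "pbmc": 100.0}
        truth = sim.simulate_spikein_series(plasma, cells, [counts])
        total = truth.mixture().iloc[:, 0].sum()
        expected = truth.plasma_mass().sum() + sum(
            counts[c.cell_type] * c.per_cell_protein_mass for c in cells
        )
        assert total == pytest.approx(expected, rel=1e-9)

    def test_negative_count_rejected(self, models):
        plasma, cells = models
        with pytest.raises(ValueError, match="negative"):
            sim.simulate_spikein_series(plasma, cells[:1], [{"platelet": -1.0}])


class TestWorkflow:
    def test_identity_workflow_is_neat_baseline(self):
        wf = sim.WorkflowModel("neat", 1.0, math.inf)
        table = pd.DataFrame({"s": [10.0, 5.0, 0.0]}, index=["a", "b", "c"])
        captured = sim.apply_workflow(table, wf)
        assert np.array_equal(captured.to_numpy(), table.to_numpy())

    def test_saturation_caps_total_at_capacity(self):
        wf = sim.WorkflowModel("bead", 1.0, 100.0)
        table = pd.DataFrame({"s": [1e6, 2e6]}, index=["a", "b"])
        captured = sim.apply_workflow(table, wf)
        assert captured["s"].sum() == pytest.approx(100.0, rel=1e-12)
        # relative composition preserved under proportional rescaling
        assert captured.loc["b", "s"] / captured.loc["a", "s"] == pytest.approx(2.0)

    def test_half_exponent_halves_log_dynamic_range(self):
        wf = sim.WorkflowModel("bead", 0.5, math.inf)
        table = pd.DataFrame({"s": [1e8, 1e2]}, index=["a", "b"])
        captured = sim.apply_workflow(table, wf)
        dr_in = np.log10(table["s"].max() / table["s"].min())
        dr_out = np.log10(captured["s"].max() / captured["s"].min())
        assert dr_out == pytest.approx(0.5 * dr_in, rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        exponent=st.floats(0.2, 1.0),
        capacity=st.floats(10.0, 1e6),
        values=st.lists(st.floats(0.0, 1e8), min_size=3, max_size=12),
    )
    def test_capture_monotone_and_capped(self, exponent, capacity, values):
        wf = sim.WorkflowModel("w", exponent, capacity)
        table = pd.DataFrame({"s": values}, index=[f"p{i}" for i in range(len(values))])
        captured = sim.apply_workflow(table, wf)
        assert captured["s"].sum() <= capacity * (1 + 1e-9)
        order_in = np.argsort(table["s"].to_numpy())
        out_sorted = captured["s"].to_numpy()[order_in]
        assert np.all(np.diff(out_sorted) >= -1e-12)


class TestMeasurement:
    def test_noiseless_replicates_identical_to_input(self):
        wf = sim.WorkflowModel("neat", cv=0.0, lod=0.0)
        table = pd.DataFrame({"s": [10.0, 5.0]}, index=["a", "b"])
        matrix, meta = sim.corrupt_measurements(table, wf, 3, seed=1)
        assert matrix.shape == (2, 3)
        assert np.allclose(matrix.intensities.to_numpy(), [[10, 10, 10], [5, 5, 5]])
        assert list(meta["replicate"]) == [1, 2, 3]

    def test_target_cv_recovered_from_emitted_matrix(self):
        wf = dataclasses.replace(sim.WORKFLOW_PRESETS["neat"], cv=0.2, lod=0.0)
        plasma = sim.generate_plasma_proteome(2000, seed=11)
        captured = sim.apply_workflow(plasma.mass_series().to_frame("s"), wf)
        matrix, _ = sim.corrupt_measurements(captured, wf, 4, seed=11)
        sub = matrix.intensities
        cv = (sub.std(axis=1, ddof=0) / sub.mean(axis=1)).median()
        assert cv == pytest.approx(0.2, abs=0.03)

    def test_lod_above_everything_warns_fully_missing(self):
        wf = sim.WorkflowModel("neat", cv=0.0, lod=1e9)
        table = pd.DataFrame({"s": [10.0, 5.0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="fully missing"):
            matrix, _ = sim.corrupt_measurements(table, wf, 2, seed=0)
        assert matrix.detected().to_numpy().sum() == 0

    def test_precursor_counts_monotone_in_abundance(self):
        wf = sim.WorkflowModel("neat", cv=0.1, lod=10.0)
        table = pd.DataFrame({"s": [1e8, 1e4, 20.0]}, index=["a", "b", "c"])
        matrix, _ = sim.corrupt_measurements(table, wf, 2, seed=0)
        pc = matrix.precursor_counts
        assert pc["a"] > pc["b"] > pc["c"] >= 1

    def test_seed_determinism_bit_identical(self):
        wf = dataclasses.replace(sim.WORKFLOW_PRESETS["sax"])
        plasma = sim.generate_plasma_proteome(200, seed=5)
        captured = sim.apply_workflow(plasma.mass_series().to_frame("s"), wf)
        a, _ = sim.corrupt_measurements(captured, wf, 4, seed=9)
        b, _ = sim.corrupt_measurements(captured, wf, 4, seed=9)
        va, vb = a.intensities.to_numpy(), b.intensities.to_numpy()
        assert np.array_equal(va, vb, equal_nan=True)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError, match="cv"):
            sim.WorkflowModel("neat", cv=-0.1)


class TestRescue:
    def test_no_removal_reproduces_unrescued_exactly(self):
        before, after, _, _ = sim.scenario_rescue(removal_fraction=0.0, seed=2)
        assert before.equals(after)

    def test_full_removal_recovers_pure_plasma_index(self):
        from plasmaqc.markers import MarkerPanel
        from plasmaqc.metrics import contamination_index

        before, after, _, truth = sim.scenario_rescue(
            removal_fraction=1.0, cv=0.0, lod=0.0, seed=2, n_replicates=1
        )
        panel = MarkerPanel.from_protein_ids("platelet", truth.true_markers["platelet"])
        ci = contamination_index(after, panel)
        assert ci.loc["contaminated.r1", "ci"] == ci.loc["pure.r1", "ci"] == 0.0

    def test_ninety_percent_removal_tenfold_marker_reduction(self):
        before, after, _, truth = sim.scenario_rescue(
            removal_fraction=0.9, cv=0.0, lod=0.0, seed=4, n_replicates=1
        )
        markers = truth.true_markers["platelet"]
        b = before.intensities.loc[markers, "contaminated.r1"].sum()
        a = after.intensities.loc[markers, "contaminated.r1"].sum()
        assert a / b == pytest.approx(0.1, abs=1e-9)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError, match="removal_fraction"):
            sim.scenario_rescue(removal_fraction=1.5, seed=0)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), count=st.floats(0.0, 1e6))
def test_mixture_mass_conservation_property(seed, count):
    plasma = sim.generate_plasma_proteome(60, seed=seed % 50)
    cell = sim.generate_cell_proteome("platelet", 40, 10, seed=seed % 50,
                                      plasma_namespace_size=60)
    truth = sim.simulate_spikein_series(plasma, [cell], [{"platelet": count}])
    total = truth.mixture().iloc[:, 0].sum()
    expected = sim.PLASMA_MASS_PER_UL + count * cell.per_cell_protein_mass
    assert total == pytest.approx(expected, rel=1e-9)
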