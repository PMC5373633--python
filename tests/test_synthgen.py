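"""Ground-truth generator: population structure, rendering, events, washing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skimage.measure import label as cc_label

from brduquant import synthgen
from brduquant.kinetics import AntibodyKinetics


class TestGeneratePopulation:
    def test_zero_replicating_fraction_yields_no_s_cells(self):
        pop = synthgen.PopulationParams(n_cells=1000, frac_replicating=0.0, seed=3)
        cyc = synthgen.CellCycleParams(frac_g1=0.8, frac_s=0.0, frac_g2m=0.2)
        truth = synthgen.generate_population(pop, cyc)
        assert len(truth) == 1000
        assert (truth["phase"] == "S").sum() == 0

    def test_s_count_within_binomial_99_interval(self):
        pop = synthgen.PopulationParams(n_cells=10_000, frac_replicating=0.44, seed=5)
        truth = synthgen.generate_population(pop, synthgen.CellCycleParams())
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.44)
        assert lo <= (truth["phase"] == "S").sum() <= hi

    def test_default_replicating_fraction_near_044(self, default_population):
        _, _, truth = default_population
        # "ca 44 +/- 6%": the generator should land within sampling error of 0.44
        f = (truth["phase"] == "S").mean()
        assert abs(f - 0.44) < 3 * np.sqrt(0.44 * 0.56 / 10_000)

    def test_fraction_mismatch_error_names_both_values(self):
        pop = synthgen.PopulationParams(n_cells=10, frac_replicating=0.3)
        cyc = synthgen.CellCycleParams()  # frac_s = 0.44
        with pytest.raises(ValueError, match=r"0\.44.*0\.3|0\.3.*0\.44"):
            synthgen.generate_population(pop, cyc)

    def test_phase_counts_conserved_and_dna_ranges(self, default_population):
        _, cyc, truth = default_population
        counts = truth["phase"].value_counts()
        assert counts.sum() == len(truth)
        # base S-phase DNA lies between 2N and 4N; allow the dna_cv perturbation
        s_dna = truth.loc[truth["phase"] == "S", "dna_content"]
        assert s_dna.between(cyc.dna_g1 * 0.8, cyc.dna_g2m * 1.2).all()
        g1 = truth.loc[truth["phase"] == "G1", "dna_content"].mean()
        g2m = truth.loc[truth["phase"] == "G2M", "dna_content"].mean()
        assert g2m / g1 == pytest.approx(2.0, rel=0.02)

    def test_identical_seed_identical_output(self):
        pop = synthgen.PopulationParams(n_cells=500, seed=9)
        cyc = synthgen.CellCycleParams()
        a = synthgen.generate_population(pop, cyc)
        b = synthgen.generate_population(pop, cyc)
        pd.testing.assert_frame_equal(a, b)

    def test_component_mean_recovery_at_n_10000(self, default_population):
        pop, _, truth = default_population
        r = truth.loc[truth["phase"] == "S", "true_signal"]
        se = pop.mu_signal_R * pop.cv_R / np.sqrt(len(r))
        assert abs(r.mean() - pop.mu_signal_R) < 3 * se

    @pytest.mark.parametrize(
        "bad",
        [
            dict(frac_replicating=1.0),
            dict(frac_replicating=-0.1),
            dict(mu_signal_R=10.0, mu_signal_nonR=50.0),
            dict(cv_R=-0.2),
        ],
    )
    def test_invalid_population_params_rejected(self, bad):
        with pytest.raises(ValueError):
            synthgen.PopulationParams(**bad).validate()


class TestRendering:
    def test_empty_truth_renders_blank(self):
        img = synthgen.ImagingParams(
            image_width=64, image_height=64, gaussian_noise_sd=0.0, poisson_noise=False
        )
        truth = synthgen.generate_population(
            synthgen.PopulationParams(n_cells=0), synthgen.CellCycleParams()
        )
        dapi, signal, labels = synthgen.render_images(truth, img)
        assert labels.max() == 0
        assert signal.sum() == 0
        assert dapi.sum() == 0

    def test_50_cells_noise_off_give_50_components(self):
        pop = synthgen.PopulationParams(n_cells=50, seed=13)
        truth = synthgen.generate_population(pop, synthgen.CellCycleParams())
        img = synthgen.ImagingParams(
            image_width=512, image_height=512, gaussian_noise_sd=0.0,
            poisson_noise=False, seed=14,
        )
        placed = synthgen.place_nuclei(truth, img)
        dapi, signal, labels = synthgen.render_images(placed, img)
        assert len(np.unique(labels)) - 1 == 50  # conservation of objects
        assert cc_label(labels > 0, connectivity=2).max() == 50

    def test_single_cell_mean_signal_equals_truth(self):
        truth = pd.DataFrame(
            {
                "cell_id": [1], "phase": ["S"], "dna_content": [150.0],
                "true_signal": [1000.0], "center_row": [32.0],
                "center_col": [32.0], "radius": [10.0],
            }
        )
        img = synthgen.ImagingParams(
            image_width=64, image_height=64, gaussian_noise_sd=0.0, poisson_noise=False
        )
        _, signal, labels = synthgen.render_images(truth, img)
        assert signal[labels == 1].mean() == pytest.approx(1000.0, abs=0.5)

    def test_unplaced_truth_rejected(self):
        truth = synthgen.generate_population(
            synthgen.PopulationParams(n_cells=5), synthgen.CellCycleParams()
        )
        with pytest.raises(ValueError, match="place_nuclei"):
            synthgen.render_images(truth, synthgen.ImagingParams())

    def test_placement_failure_reports_placed_count(self):
        truth = synthgen.generate_population(
            synthgen.PopulationParams(n_cells=100), synthgen.CellCycleParams()
        )
        img = synthgen.ImagingParams(image_width=64, image_height=64)
        with pytest.raises(RuntimeError, match="placed"):
            synthgen.place_nuclei(truth, img)

    def test_rendering_is_deterministic(self, rendered_scene):
        placed, img, dapi, signal, labels = rendered_scene
        dapi2, signal2, labels2 = synthgen.render_images(placed, img)
        assert np.array_equal(dapi, dapi2)
        assert np.array_equal(signal, signal2)
        assert np.array_equal(labels, labels2)


class TestFlowEvents:
    def test_zero_noise_reproduces_truth_columns(self, default_population):
        _, _, truth = default_population
        ev = synthgen.generate_flow_events(truth, noise_cv=0.0, seed=1)
        assert len(ev) == len(truth)
        assert np.allclose(np.sort(ev["signal"]), np.sort(truth["true_signal"]))
        assert np.allclose(np.sort(ev["dna_content"]), np.sort(truth["dna_content"]))

    def test_g1_dna_cv_matches_configured_noise(self):
        # dna_cv = 0 and no S phase, so the G1 event spread is purely the
        # flow measurement noise; G1 and G2M separate cleanly at 2x
        pop = synthgen.PopulationParams(n_cells=10_000, frac_replicating=0.0, seed=4)
        cyc = synthgen.CellCycleParams(frac_g1=0.8, frac_s=0.0, frac_g2m=0.2, dna_cv=0.0)
        truth = synthgen.generate_population(pop, cyc)
        ev = synthgen.generate_flow_events(truth, noise_cv=0.1, seed=2)
        g1 = ev.loc[ev["dna_content"] < cyc.dna_g1 * np.sqrt(2.0), "dna_content"]
        cv = g1.std() / g1.mean()
        assert 0.08 < cv < 0.12  # within 20% of the configured 0.1

    def test_negative_noise_rejected(self, default_population):
        _, _, truth = default_population
        with pytest.raises(ValueError):
            synthgen.generate_flow_events(truth, noise_cv=-0.1)


class TestWashDissociation:
    def test_zero_wash_unstabilised_is_identity(self, default_population):
        _, _, truth = default_population
        washed = synthgen.apply_wash_dissociation(truth, AntibodyKinetics(), 0.0)
        pd.testing.assert_frame_equal(washed, truth)

    def test_five_minute_wash_leaves_20_percent_specific(self, default_population):
        _, _, truth = default_population
        kin = AntibodyKinetics()  # k_off = ln(5)/5
        washed = synthgen.apply_wash_dissociation(truth, kin, 5.0)
        is_s = truth["phase"] == "S"
        bg = truth.loc[~is_s, "true_signal"].mean()
        before = truth.loc[is_s, "true_signal"].to_numpy() - bg
        after = washed.loc[is_s, "true_signal"].to_numpy() - bg
        assert np.allclose(after, 0.2 * before)

    def test_thirty_minute_wash_below_01_percent(self, default_population):
        # exp(-ln(5)/5 * 30) = 5**-6 = 6.4e-5, "nearly zero"
        _, _, truth = default_population
        washed = synthgen.apply_wash_dissociation(truth, AntibodyKinetics(), 30.0)
        is_s = truth["phase"] == "S"
        bg = truth.loc[~is_s, "true_signal"].mean()
        ratio = (washed.loc[is_s, "true_signal"] - bg) / (
            truth.loc[is_s, "true_signal"] - bg
        )
        assert (ratio.abs() < 1e-3).all()

    def test_background_and_non_s_cells_untouched(self, default_population):
        _, _, truth = default_population
        washed = synthgen.apply_wash_dissociation(truth, AntibodyKinetics(), 10.0)
        is_s = truth["phase"] == "S"
        assert np.array_equal(
            washed.loc[~is_s, "true_signal"], truth.loc[~is_s, "true_signal"]
        )

    def test_longer_wash_never_increases_signal(self, default_population):
        _, _, truth = default_population
        kin = AntibodyKinetics()
        prev = synthgen.apply_wash_dissociation(truth, kin, 0.0)["true_signal"]
        for t in (1.0, 5.0, 15.0, 30.0):
            cur = synthgen.apply_wash_dissociation(truth, kin, t)["true_signal"]
            assert (cur <= prev + 1e-12).all()
            prev = cur

    def test_stabilised_signal_does_not_decay(self, default_population):
        _, _, truth = default_population
        kin = AntibodyKinetics()
        a = synthgen.apply_wash_dissociation(
            truth, kin, 5.0, stabilised=True, formaldehyde_conc=0.2
        )
        b = synthgen.apply_wash_dissociation(
            truth, kin, 30.0, stabilised=True, formaldehyde_conc=0.2
        )
        pd.testing.assert_frame_equal(a, b)

    def test_negative_time_or_concentration_rejected(self, default_population):
        _, _, truth = default_population
        with pytest.raises(ValueError):
            synthgen.apply_wash_dissociation(truth, AntibodyKinetics(), -1.0)
        with pytest.raises(ValueError):
            synthgen.apply_wash_dissociation(
                truth, AntibodyKinetics(), 1.0, stabilised=True, formaldehyde_conc=-0.5
            )
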