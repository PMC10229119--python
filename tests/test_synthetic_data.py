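"""Population sampling, neuron rules, voxel pooling, and recovery plumbing."""

import numpy as np
import pandas as pd
import pytest

from voxnorm import SimConfig, build_voxels, fit_voxel, sample_population, simulate_dataset
from voxnorm.conditions import CANONICAL_CONDITIONS, RAW_CONDITIONS, canonicalize
from voxnorm.synthetic_data import (
    model_recovery_experiment,
    neuron_response,
    population_responses,
)


@pytest.fixture(scope="module")
def small_config():
    return SimConfig(
        n_neurons=200,
        neurons_per_voxel=20,
        n_voxels_per_roi=2,
        roi_body_ratio={"LO": 0.5, "EBA": 0.9},
        seed=5,
    )


class TestSamplePopulation:
    def test_size_and_category_split(self, small_config):
        pop = sample_population("normalizing", small_config)
        assert len(pop) == 200
        assert (pop["preferred_category"] == "body").sum() == 100

    def test_null_drive_weaker_than_preferred(self, small_config):
        pop = sample_population("summing", small_config)
        assert (pop["l_null"] < pop["l_pref"]).all()
        assert (pop["l_pref"] > 0).all() and (pop["beta"] > 1).all()

    def test_deterministic_given_seed(self, small_config):
        a = sample_population("averaging", small_config, seed=3)
        b = sample_population("averaging", small_config, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_kind_rejected(self, small_config):
        with pytest.raises(ValueError, match="kind"):
            sample_population("multiplying", small_config)


class TestNeuronResponse:
    def test_summing_neuron_adds_isolated_responses(self, small_config):
        neuron = sample_population("summing", small_config).iloc[0]
        assert neuron_response(neuron, "PN") == pytest.approx(
            neuron_response(neuron, "P") + neuron_response(neuron, "N")
        )

    def test_averaging_neuron_averages(self, small_config):
        neuron = sample_population("averaging", small_config).iloc[0]
        assert neuron_response(neuron, "PN") == pytest.approx(
            (neuron_response(neuron, "P") + neuron_response(neuron, "N")) / 2
        )

    def test_normalizing_neuron_approaches_average_at_small_sigma_unit_gain(self, small_config):
        neuron = sample_population("normalizing", small_config).iloc[0].copy()
        neuron["sigma"] = 1e-9
        neuron["beta"] = 1.0
        assert neuron_response(neuron, "PN") == pytest.approx(
            (neuron["l_pref"] + neuron["l_null"]) / 2, rel=1e-6
        )

    @pytest.mark.parametrize("kind", ["summing", "averaging", "normalizing"])
    def test_vectorized_population_matrix_matches_per_neuron_rule(self, kind, small_config):
        pop = sample_population(kind, small_config).head(10)
        matrix = population_responses(pop)
        for i in range(len(pop)):
            for j, cond in enumerate(CANONICAL_CONDITIONS):
                assert matrix[i, j] == pytest.approx(neuron_response(pop.iloc[i], cond))


class TestBuildVoxels:
    def test_schema_and_completeness(self, small_config):
        data = build_voxels(sample_population("normalizing", small_config), small_config)
        assert list(data.columns) == ["subject", "roi", "voxel", "half", "condition", "value"]
        counts = data.groupby(["subject", "roi", "voxel", "half"])["condition"].count()
        assert (counts == 7).all()
        assert set(data["roi"]) == {"LO", "EBA"}
        assert data.groupby(["subject", "roi"])["voxel"].nunique().eq(2).all()

    def test_zero_noise_makes_halves_identical(self, small_config):
        cfg = SimConfig(**{**small_config.to_dict(), "noise_sd_frac": 0.0})
        data = build_voxels(sample_population("summing", cfg), cfg)
        wide = data.pivot_table(
            index=["subject", "roi", "voxel", "condition"], columns="half", values="value"
        )
        np.testing.assert_allclose(wide["odd"], wide["even"], atol=1e-12)

    def test_pure_body_roi_prefers_the_body_conditions(self):
        cfg = SimConfig(
            n_neurons=100,
            neurons_per_voxel=10,
            n_voxels_per_roi=3,
            roi_body_ratio={"pure": 1.0},
            noise_sd_frac=0.0,
            seed=2,
        )
        data = build_voxels(sample_population("normalizing", cfg), cfg)
        wide = data.pivot_table(index=["voxel", "half"], columns="condition", values="value")
        # every voxel pools only body-preferring neurons: isolated body beats house
        assert (wide["B"] > wide["H"]).all()

    def test_half_means_converge_to_noiseless_voxel(self):
        base = dict(
            n_neurons=100,
            neurons_per_voxel=10,
            n_voxels_per_roi=2,
            roi_body_ratio={"LO": 0.5},
            seed=7,
        )
        noisy_cfg = SimConfig(**base, n_runs=400, noise_sd_frac=0.2)
        clean_cfg = SimConfig(**base, n_runs=400, noise_sd_frac=0.0)
        # identical rng streams: the noise draws are scaled by sd, so voxel
        # membership and noise realizations align between the two datasets
        noisy = build_voxels(sample_population("summing", noisy_cfg), noisy_cfg)
        clean = build_voxels(sample_population("summing", clean_cfg), clean_cfg)
        merged = noisy.merge(
            clean, on=["subject", "roi", "voxel", "half", "condition"], suffixes=("", "_clean")
        )
        sd = 0.2 * merged["value_clean"].abs().mean()
        tol = 3 * sd / np.sqrt(200)  # each half averages 200 runs
        assert (merged["value"] - merged["value_clean"]).abs().max() < 3 * tol

    def test_oversized_voxels_rejected(self, small_config):
        pop = sample_population("summing", small_config)
        bad = SimConfig(**{**small_config.to_dict(), "neurons_per_voxel": 150})
        with pytest.raises(ValueError, match="sample"):
            build_voxels(pop, bad)


def test_single_neuron_voxel_parameter_recovery():
    """The pipeline-level identity check: a noiseless voxel built from one
    normalizing neuron refits to that neuron's own parameters within 1%."""
    cfg = SimConfig(
        n_neurons=2,
        neurons_per_voxel=1,
        n_voxels_per_roi=1,
        roi_body_ratio={"solo": 1.0},
        noise_sd_frac=0.0,
        response_scale=1.0,
        l_pref_range=(4.0, 8.0),
        l_null_frac_range=(0.3, 0.7),
        beta_range=(1.5, 3.0),
        sigma_range=(0.5, 3.0),
        seed=13,
    )
    pop = sample_population("normalizing", cfg)
    data = build_voxels(pop, cfg)
    raw = data[data["half"] == "odd"].set_index("condition")["value"].to_dict()
    profile = canonicalize(raw, "body")
    fit = fit_voxel("normalization", profile)
    neuron = pop[pop["preferred_category"] == "body"].iloc[0]
    truth = {"l_p": neuron["l_pref"], "l_n": neuron["l_null"],
             "sigma": neuron["sigma"], "beta": neuron["beta"]}
    for name, true_val in truth.items():
        assert fit.param_dict[name] == pytest.approx(true_val, rel=0.01)


def test_model_recovery_report_shape_and_determinism():
    cfg = SimConfig(
        n_neurons=200,
        neurons_per_voxel=20,
        n_voxels_per_roi=2,
        roi_body_ratio={"LO": 0.5},
        seed=1,
    )
    rep1 = model_recovery_experiment(
        cfg, seed=1, kinds=("summing",), models=("weighted_sum", "wa_ew")
    )
    rep2 = model_recovery_experiment(
        cfg, seed=1, kinds=("summing",), models=("weighted_sum", "wa_ew")
    )
    pd.testing.assert_frame_equal(rep1, rep2)
    assert set(rep1.columns) == {"kind", "model", "mean_gof", "n_voxels"}
    assert set(rep1["model"]) == {"weighted_sum", "wa_ew"}


def test_simulate_dataset_rescales_to_unit_grand_mean():
    cfg = SimConfig(
        n_neurons=200, neurons_per_voxel=20, n_voxels_per_roi=3,
        roi_body_ratio={"LO": 0.5}, noise_sd_frac=0.0, seed=4,
    )
    data = simulate_dataset("summing", cfg)
    assert data["value"].abs().mean() == pytest.approx(1.0, rel=0.02)
    raw_cfg = SimConfig(**{**cfg.to_dict(), "response_scale": 1.0})
    raw_units = simulate_dataset("summing", raw_cfg)
    assert raw_units["value"].abs().mean() > 5  # spike-rate scale before rescaling
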