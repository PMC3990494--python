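"""Per-subject estimation: recovery, evidence ordering, matrix contracts."""

import numpy as np
import pytest

from costevidence import fitting as ft
from costevidence import synthetic_data as sd
from costevidence.model_space import ModelSpace, ModulationConfig, winning_config

NULL_CONFIG = ModulationConfig("linear", frozenset())
FULL_LINEAR = ModulationConfig(
    "linear",
    frozenset(
        (p, f) for p in ("A", "Se", "Sr") for f in ("incentive", "actual")
    ),
)


class TestFitSubject:
    def test_noiseless_data_recovers_generating_weights(self, noiseless_subject):
        fit = ft.fit_subject(noiseless_subject, winning_config("implicit"), n_starts=4, seed=1)
        truth = noiseless_subject.truth
        scale = truth.A.mean  # fitted parameters are relative to A_mean = 1
        assert fit.params["w_A_incentive"] == pytest.approx(
            truth.A.incentive / scale, rel=1e-3
        )
        assert fit.params["w_Se_actual"] == pytest.approx(
            truth.Se.actual / scale, rel=1e-3
        )
        assert fit.params["w_Sr_incentive"] == pytest.approx(
            truth.Sr.incentive / scale, rel=1e-3
        )
        assert np.exp(fit.params["log_mean_Se"]) == pytest.approx(
            truth.Se.mean / scale, rel=1e-3
        )
        assert fit.residual_sd["effort"] < 1e-3

    def test_cell_mean_mode_matches_epoch_mode_on_noiseless_data(
        self, noiseless_subject
    ):
        # without epoch noise the cell means are the epochs, so the two
        # observation modes share the same posterior mode
        config = winning_config("implicit")
        fit_epoch = ft.fit_subject(noiseless_subject, config, n_starts=3, seed=4)
        fit_cell = ft.fit_subject(
            noiseless_subject, config, n_starts=3, seed=4, mode="cell_mean"
        )
        # cell-mean mode carries less likelihood weight, so the prior
        # shrinks its mode slightly more; structure and scale agree
        for name, value in fit_epoch.params.items():
            assert fit_cell.params[name] == pytest.approx(value, rel=0.05, abs=0.02)

    def test_null_data_prefers_null_over_full_model(self, implicit_truth):
        # data generated with no modulation at all: the complexity penalty
        # must favour the means-only model
        from costevidence.core_model import ModelCoefficients, ParamCoefficients

        null_truth = ModelCoefficients(
            "linear",
            A=ParamCoefficients(6.0),
            Se=ParamCoefficients(1.0),
            Sr=ParamCoefficients(1.3),
        )
        data = sd.generate_effort_allocation(
            sd.implicit_design(), null_truth, sd.NoiseSpec(seed=21), 1
        )[0]
        fit_null = ft.fit_subject(data, NULL_CONFIG, n_starts=4, seed=2)
        fit_full = ft.fit_subject(data, FULL_LINEAR, n_starts=4, seed=2)
        assert fit_null.log_evidence > fit_full.log_evidence

    def test_missing_incentive_pathway_fits_worse(self, implicit_cohort):
        data = implicit_cohort[0]
        no_incentive = ModulationConfig("linear", frozenset({("Se", "actual")}))
        fit_win = ft.fit_subject(data, winning_config("implicit"), n_starts=4, seed=3)
        fit_poor = ft.fit_subject(data, no_incentive, n_starts=4, seed=3)
        assert fit_poor.residual_sd["effort"] >= fit_win.residual_sd["effort"]
        assert fit_poor.log_evidence < fit_win.log_evidence

    def test_last_rest_epochs_are_excluded_from_summaries(self, noiseless_subject):
        summary = ft.condition_summaries(noiseless_subject, drop_last_rest=True)
        kept = ft.condition_summaries(noiseless_subject, drop_last_rest=False)
        n_rest = summary[summary["kind"] == "rest"]["n"].sum()
        n_rest_all = kept[kept["kind"] == "rest"]["n"].sum()
        assert n_rest < n_rest_all

    def test_recovery_error_shrinks_as_noise_vanishes(self, implicit_truth):
        # median absolute weight error decreases monotonically toward 0 noise
        design = sd.implicit_design()
        config = winning_config("implicit")
        scale = implicit_truth.A.mean
        true_w = np.array(
            [
                implicit_truth.A.incentive,
                implicit_truth.Se.actual,
                implicit_truth.Sr.incentive,
            ]
        ) / scale
        errors = []
        for noise_sd in (2.0, 0.5, 0.0):
            noise = sd.NoiseSpec(duration_sd=noise_sd, between_subject_sd=0.0, seed=31)
            cohort = sd.generate_effort_allocation(design, implicit_truth, noise, 3)
            errs = []
            for data in cohort:
                fit = ft.fit_subject(data, config, n_starts=3, seed=5)
                rec = np.array(
                    [
                        fit.params["w_A_incentive"],
                        fit.params["w_Se_actual"],
                        fit.params["w_Sr_incentive"],
                    ]
                )
                errs.append(np.abs(rec - true_w))
            errors.append(np.median(errs))
        assert errors[0] > errors[1] > errors[2]


class TestEvidenceMatrix:
    def test_single_model_space_gives_one_column(self, implicit_cohort):
        space = ModelSpace((winning_config("implicit"),))
        matrix = ft.build_evidence_matrix(
            implicit_cohort[:2], space, n_starts=2, seed=1
        )
        assert matrix.log_evidence.shape == (2, 1)
        assert np.all(np.isfinite(matrix.log_evidence))

    def test_duplicate_models_give_identical_columns(self, implicit_cohort):
        # same flag set listed twice: identical fits up to optimizer seed
        config = winning_config("implicit")
        evidence = []
        for j in range(2):
            fit = ft.fit_subject(implicit_cohort[0], config, n_starts=3, seed=17)
            evidence.append(fit.log_evidence)
        assert evidence[0] == pytest.approx(evidence[1], abs=1e-9)

    def test_matrix_is_deterministic_given_seed(self, implicit_cohort):
        space = ModelSpace((NULL_CONFIG, winning_config("implicit")))
        m1 = ft.build_evidence_matrix(implicit_cohort[:2], space, n_starts=2, seed=7)
        m2 = ft.build_evidence_matrix(implicit_cohort[:2], space, n_starts=2, seed=7)
        np.testing.assert_array_equal(m1.log_evidence, m2.log_evidence)

    def test_generating_config_beats_reduced_nested_configs(self, implicit_truth):
        # on near-noiseless data (epoch noise far below every modulation
        # effect) the generating configuration's evidence must be at least
        # that of any config missing one of its active pathways
        design = sd.implicit_design()
        config = winning_config("implicit")
        for seed in range(4):
            noise = sd.NoiseSpec(duration_sd=0.02, between_subject_sd=0.1, seed=seed)
            data = sd.generate_effort_allocation(design, implicit_truth, noise, 1)[0]
            fit_gen = ft.fit_subject(data, config, n_starts=4, seed=seed)
            for dropped in config.flags:
                reduced = ModulationConfig("linear", config.flags - {dropped})
                fit_red = ft.fit_subject(data, reduced, n_starts=4, seed=seed)
                assert fit_gen.log_evidence >= fit_red.log_evidence - 1e-6

    def test_frame_export_has_model_labels(self, implicit_cohort):
        space = ModelSpace((NULL_CONFIG, winning_config("implicit")))
        matrix = ft.build_evidence_matrix(implicit_cohort[:2], space, n_starts=2, seed=3)
        frame = matrix.to_frame()
        assert list(frame.columns[:1]) == ["subject"]
        assert len(frame.columns) == 3
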