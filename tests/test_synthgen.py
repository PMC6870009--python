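"""Synthetic cohort generator: determinism, forward model, covariates."""

import numpy as np
import pytest

from gatenet.erp import average_erp, preprocess
from gatenet.synthgen import (
    GROUPS,
    SynthConfig,
    burst_template,
    generate_atlas,
    generate_cohort,
    generate_feature_covariates,
    generate_lead_field,
)

SMALL = dict(n_per_group={"FESZ": 2, "UHR": 2, "HC": 2}, n_trials=6, n_sensors=16)


class TestConfig:
    def test_invalid_planted_edge_rejected(self):
        cfg = SynthConfig(planted_edges=[(0, 99, {"FESZ": 0.5})], **SMALL)
        with pytest.raises(ValueError, match="planted edge"):
            cfg.validate()

    def test_coupling_outside_unit_interval_rejected(self):
        cfg = SynthConfig(planted_edges=[(0, 1, {"FESZ": 1.5})], **SMALL)
        with pytest.raises(ValueError, match="coupling"):
            cfg.validate()

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_per_group={"FESZ": 0, "UHR": 1, "HC": 1}).validate()


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = generate_cohort(SynthConfig(seed=7, **SMALL))
        b = generate_cohort(SynthConfig(seed=7, **SMALL))
        for ea, eb in zip(a.epochs, b.epochs):
            assert np.array_equal(ea.data, eb.data)
        assert np.array_equal(a.lead_field.gain, b.lead_field.gain)
        assert a.covariates.equals(b.covariates)

    def test_different_seed_differs(self):
        a = generate_cohort(SynthConfig(seed=7, **SMALL))
        b = generate_cohort(SynthConfig(seed=8, **SMALL))
        assert not np.array_equal(a.epochs[0].data, b.epochs[0].data)


class TestForwardModel:
    @staticmethod
    def noiseless_config(**kw):
        return SynthConfig(
            noise_sd=0.0,
            trial_noise_sd=0.0,
            sensor_noise_sd=0.0,
            planted_edges=[],
            seed=5,
            **{**SMALL, **kw},
        )

    def test_noiseless_single_source_matches_gain_column(self):
        cfg = self.noiseless_config(auditory_rois=(3,))
        cohort = generate_cohort(cfg)
        ep = cohort.epochs[0]
        g = cohort.lead_field.gain[:, 3]
        t_ms = ep.times_ms
        a1 = cohort.truth["s1_amp_true"][0]
        a2 = cohort.truth["s2_amp_true"][0]
        wave = cohort.truth["amp_scale"] * (
            a1 * burst_template(t_ms, 50.0, cfg.burst_sigma_ms)
            + a2 * burst_template(t_ms, 550.0, cfg.burst_sigma_ms)
        )
        expected = g[:, None] * wave[None, :]
        assert np.allclose(ep.data[0], expected, atol=1e-5)

    def test_linearity_doubling_amplitudes_doubles_sensors(self):
        cfg1 = self.noiseless_config()
        cfg2 = self.noiseless_config()
        cfg2.s1_amp_mean_sd = {g: (2 * m, 0.0) for g, (m, _) in cfg1.s1_amp_mean_sd.items()}
        cfg2.s2_amp_mean_sd = {g: (2 * m, 0.0) for g, (m, _) in cfg1.s2_amp_mean_sd.items()}
        cfg1.s1_amp_mean_sd = {g: (m, 0.0) for g, (m, _) in cfg1.s1_amp_mean_sd.items()}
        cfg1.s2_amp_mean_sd = {g: (m, 0.0) for g, (m, _) in cfg1.s2_amp_mean_sd.items()}
        a = generate_cohort(cfg1)
        b = generate_cohort(cfg2)
        assert np.allclose(b.epochs[0].data, 2 * a.epochs[0].data, atol=1e-5)

    def test_lead_field_well_conditioned_and_reported(self):
        cohort = generate_cohort(SynthConfig(seed=2, **SMALL))
        assert np.isfinite(cohort.truth["lead_field_condition"])
        assert cohort.truth["lead_field_condition"] < 1e6

    def test_artifact_trials_are_rejected_downstream(self):
        cfg = SynthConfig(artifact_fraction=0.25, seed=3, **SMALL)
        cohort = generate_cohort(cfg)
        ep = cohort.epochs[0]
        clean = preprocess(ep, reject_threshold_uv=100.0)
        assert clean.n_trials == ep.n_trials - round(0.25 * ep.n_trials)


class TestAtlas:
    def test_80_regions_40_per_hemisphere(self):
        atlas = generate_atlas(80)
        assert len(atlas) == 80
        assert (atlas.hemisphere == "Left").sum() == 40
        assert (atlas.hemisphere == "Right").sum() == 40

    def test_epoch_window_and_s2_timing(self):
        cohort = generate_cohort(SynthConfig(seed=4, **SMALL))
        ep = cohort.epochs[0]
        assert ep.times_ms[0] == pytest.approx(-200.0)
        assert ep.times_ms[-1] == pytest.approx(1000.0)
        assert ep.times_ms[ep.t0_idx] == 0.0
        assert ep.s2_offset_ms == 500.0


class TestCovariates:
    def test_default_sizes_give_67_rows(self):
        table = generate_feature_covariates(SynthConfig(seed=0))
        assert len(table) == 67
        assert (table.group.value_counts()[list(GROUPS)] == [25, 23, 19]).all()

    def test_zero_sd_gives_exact_group_means(self):
        cfg = SynthConfig(seed=0, **SMALL)
        cfg.covariate_params = {
            k: {g: (m, 0.0) for g, (m, _) in v.items()}
            for k, v in cfg.covariate_params.items()
        }
        table = generate_feature_covariates(cfg)
        for g in GROUPS:
            sub = table[table.group == g]
            assert np.allclose(sub["AVV"], cfg.covariate_params["AVV"][g][0])

    def test_hc_attention_mean_recovers_parameter(self):
        """HC attention/vigilance sample mean near 47.79 averaged over seeds."""
        means = [
            generate_feature_covariates(SynthConfig(seed=s))
            .query("group == 'HC'")["AVV"]
            .mean()
            for s in range(10)
        ]
        sem2 = 2 * 8.80 / np.sqrt(19)
        assert abs(np.mean(means) - 47.79) < sem2

    def test_scores_nonnegative(self):
        cfg = SynthConfig(seed=1)
        table = generate_feature_covariates(cfg)
        score_cols = [c for c in table.columns if c not in ("subject", "group", "gender")]
        assert (table[score_cols].to_numpy() >= 0).all()


class TestPlantedEffects:
    def test_coupling_monotone_in_downstream_nmi(self):
        """Stronger planted coupling raises that edge's average NMI."""
        from gatenet import connectivity as cn
        from gatenet.erp import extract_segments
        from gatenet.inverse import ELoreta, extract_roi

        edge = (10, 50)
        mean_nmi = []
        for c in (0.1, 0.5, 0.9):
            vals = []
            for seed in range(20):
                cfg = SynthConfig(
                    n_per_group={"FESZ": 1, "UHR": 1, "HC": 1},
                    n_trials=4,
                    n_sensors=20,
                    lead_field_kind="gaussian",
                    planted_edges=[(edge[0], edge[1], {"FESZ": c})],
                    seed=100 + seed,
                )
                cohort = generate_cohort(cfg)
                ep = cohort.epochs[0]  # the FESZ subject
                clean = preprocess(ep, reject_threshold_uv=1e9)
                segs = extract_segments(average_erp(clean), ep.fs, ep.t0_idx)
                inv = ELoreta().fit(cohort.lead_field)
                rois = extract_roi(inv.apply(segs.gating_seg), cohort.atlas)
                vals.append(cn.nmi(rois.values[edge[0]], rois.values[edge[1]]))
            mean_nmi.append(np.mean(vals))
        assert mean_nmi[0] < mean_nmi[1] < mean_nmi[2]
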