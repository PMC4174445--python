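"""Weighted curve fitting and bootstrap confidence intervals."""

import dataclasses

import numpy as np
import pytest

from rateseq import (
    RunConfig,
    bootstrap_ci,
    fit_all,
    fit_transcript,
    make_observations,
    make_truth,
    normalize,
    simulate,
)
from rateseq.fitting import FitObservations
from rateseq.kinetics import model_y

from _oracles import grid_fit

REP1_TIMES = np.array([3.0, 5.0, 7.0, 11.0, 13.0, 25.0])


def obs_from_arrays(t, y, cfg, tid="x"):
    w = 1.0 / np.maximum(y, cfg.weight_floor)
    return FitObservations(tid, np.asarray(t, float), np.asarray(y, float), w)


class TestFitTranscript:
    def test_noise_free_recovery(self, cfg):
        y = model_y(REP1_TIMES, 0.05, 400.0, cfg.t_d)
        est = fit_transcript(obs_from_arrays(REP1_TIMES, y, cfg), cfg)
        assert est.converged
        assert est.alpha_total == pytest.approx(0.05, abs=1e-6)
        assert est.y_eq == pytest.approx(400.0, rel=1e-6)
        assert est.alpha_rna == pytest.approx(0.05 - cfg.alpha_growth)

    def test_agrees_with_grid_oracle(self, cfg):
        rng = np.random.default_rng(17)
        t = np.repeat(REP1_TIMES, 2)
        y = model_y(t, 0.08, 400.0, cfg.t_d) * rng.gamma(10, 0.1, t.size)
        obs = obs_from_arrays(t, y, cfg)
        est = fit_transcript(obs, cfg)
        a_grid, yeq_grid, sse_grid = grid_fit(
            obs.t, obs.y, obs.w, cfg.t_d, np.arange(1e-4, 1.0, 1e-4)
        )
        assert abs(est.alpha_total - a_grid) <= 1e-4
        assert est.y_eq == pytest.approx(yeq_grid, rel=max(5e-3, 2e-4 / a_grid))
        sse_fit = float(np.sum(obs.w * (obs.y - model_y(obs.t, est.alpha_total, est.y_eq, cfg.t_d)) ** 2))
        assert sse_fit <= sse_grid * (1 + 1e-9)

    def test_too_few_points_is_unfittable(self, cfg):
        est = fit_transcript(obs_from_arrays([3, 5], [1.0, 2.0], cfg), cfg)
        assert not est.converged and np.isnan(est.alpha_total)

    def test_all_zero_signal_is_unfittable(self, cfg):
        est = fit_transcript(obs_from_arrays(REP1_TIMES, np.zeros(6), cfg), cfg)
        assert not est.converged

    def test_scale_equivariance(self, cfg):
        """Scaling y by c leaves alpha unchanged and scales Y_eq by c."""
        rng = np.random.default_rng(3)
        y = model_y(REP1_TIMES, 0.06, 300.0, cfg.t_d) * rng.gamma(20, 0.05, 6)
        e1 = fit_transcript(obs_from_arrays(REP1_TIMES, y, cfg), cfg)
        e2 = fit_transcript(obs_from_arrays(REP1_TIMES, 50 * y, cfg), cfg)
        assert e2.alpha_total == pytest.approx(e1.alpha_total, rel=1e-4)
        assert e2.y_eq == pytest.approx(50 * e1.y_eq, rel=1e-4)

    def test_weighting_lowers_alpha_rmse_on_heteroscedastic_data(self):
        """1/Y weights beat unit weights when noise grows with the mean."""
        cfg = RunConfig()
        rng = np.random.default_rng(8)
        t = np.concatenate([REP1_TIMES, [5, 7, 9, 13, 20, 25, 30, 100.0]])
        errs_w, errs_u = [], []
        for _ in range(150):
            a = np.log(2) / np.exp(rng.uniform(np.log(2), np.log(60))) + cfg.alpha_growth
            m = model_y(t, a, 500.0, cfg.t_d)
            y = m * rng.gamma(10, 0.1, t.size)
            ow = obs_from_arrays(t, y, cfg)
            ou = FitObservations("x", ow.t, ow.y, np.ones_like(ow.y))
            ew, eu = fit_transcript(ow, cfg), fit_transcript(ou, cfg)
            if ew.converged and eu.converged:
                errs_w.append((ew.alpha_total - a) / a)
                errs_u.append((eu.alpha_total - a) / a)
        rmse = lambda e: float(np.sqrt(np.mean(np.square(e))))
        assert rmse(errs_w) < rmse(errs_u)


class TestBootstrap:
    def test_noise_free_ci_collapses_onto_estimate(self, cfg):
        y = model_y(np.repeat(REP1_TIMES, 2), 0.05, 400.0, cfg.t_d)
        obs = obs_from_arrays(np.repeat(REP1_TIMES, 2), y, cfg)
        est = fit_transcript(obs, cfg)
        lo, hi, n_fail, unreliable = bootstrap_ci(obs, est, cfg)
        assert hi - lo < 1e-6
        assert lo <= est.alpha_total <= hi or abs(lo - est.alpha_total) < 1e-6
        assert not unreliable

    def test_degenerate_resamples_counted_as_failures(self, cfg):
        # two distinct times only: resamples drawing a single time must fail
        t = np.array([3.0, 3.0, 25.0, 25.0])
        y = model_y(t, 0.1, 200.0, cfg.t_d)
        obs = obs_from_arrays(t, y, cfg)
        est = fit_transcript(obs, cfg)
        cfg2 = dataclasses.replace(cfg, n_bootstrap=400)
        lo, hi, n_fail, _ = bootstrap_ci(obs, est, cfg2)
        # P(resample has a single distinct time) = 2 * (1/2)^4 = 1/8
        assert n_fail > 0
        assert np.isfinite(lo) and np.isfinite(hi)

    def test_nonconverged_fit_rejected(self, cfg):
        obs = obs_from_arrays([3, 5], [1.0, 2.0], cfg)
        est = fit_transcript(obs, cfg)
        with pytest.raises(ValueError):
            bootstrap_ci(obs, est, cfg)

    def test_ci_width_shrinks_with_noise(self):
        """Bootstrap interval width is monotone in simulated dispersion."""
        widths = []
        for size in (5.0, 50.0, 5000.0):
            truth = make_truth(30, seed=4, dispersion=size)
            cfg = RunConfig(n_bootstrap=120, rng_seed=2)
            series, _ = normalize(simulate(truth).counts, cfg)
            ests = fit_all(series, cfg)
            rel = [
                (e.ci_high - e.ci_low) / e.alpha_total for e in ests if e.converged
            ]
            widths.append(float(np.median(rel)))
        assert widths[0] > widths[1] > widths[2]


class TestFitAll:
    def test_unfittable_transcripts_flagged_not_dropped(self, cfg):
        truth = make_truth(12, seed=5)
        ds = simulate(truth)
        cm = ds.counts
        cm.counts.loc["gene0003"] = 0  # kill one transcript's signal
        series, _ = normalize(cm, cfg)
        ests = fit_all(series, cfg, with_ci=False)
        assert len(ests) == 12
        by_id = {e.transcript_id: e for e in ests}
        assert not by_id["gene0003"].converged
        assert sum(e.converged for e in ests) == 11

    def test_results_independent_of_transcript_order(self, cfg):
        truth = make_truth(15, seed=6)
        series, _ = normalize(simulate(truth).counts, cfg)
        fwd = fit_all(series, cfg)
        rev = fit_all(series[::-1], cfg)
        by_id = {e.transcript_id: e for e in rev}
        for e in fwd:
            o = by_id[e.transcript_id]
            assert (e.alpha_total, e.ci_low, e.ci_high) == (o.alpha_total, o.ci_low, o.ci_high)
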