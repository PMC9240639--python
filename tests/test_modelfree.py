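"""Model-free inference: tau_c estimation, per-residue fits, selection, errors."""

import numpy as np
import pandas as pd
import pytest

from dynsuite.modelfree import (
    ModelFreeAnalysis,
    TumblingTimeEstimator,
    classify_exchange,
    estimate_tauc,
    fit_residue,
    monte_carlo_errors,
    rigid_r2_over_r1,
    select_model,
)
from dynsuite.simulate import make_scenario, simulate_relaxation


def rigid_table(n, tau_c, relax_record, rng=None, sig_frac=0.02):
    rows = [
        relax_record(s2=1.0, tau_c=tau_c, res_num=i + 1, rng=rng, sig_frac=sig_frac)
        for i in range(n)
    ]
    return pd.concat(rows, ignore_index=True)


class TestTaucEstimation:
    def test_single_noiseless_rigid_residue_recovers_tauc(self, relax_record):
        est = estimate_tauc(rigid_table(1, 10.4e-9, relax_record))
        assert est.tau_c == pytest.approx(10.4e-9, rel=1e-3)

    def test_hundred_noisy_residues_within_two_percent(self, relax_record):
        rng = np.random.default_rng(11)
        est = estimate_tauc(rigid_table(100, 12.5e-9, relax_record, rng=rng))
        assert est.tau_c == pytest.approx(12.5e-9, rel=0.02)
        assert est.tau_c_err > 0
        assert est.n_residues_used >= 80

    def test_all_mobile_residues_rejected(self, relax_record):
        df = rigid_table(5, 10e-9, relax_record)
        df["NOE"] = 0.2
        with pytest.raises(ValueError, match="no rigid residues"):
            estimate_tauc(df)

    def test_invariant_to_duplicating_every_record(self, relax_record):
        rng = np.random.default_rng(5)
        df = rigid_table(30, 11e-9, relax_record, rng=rng)
        a = estimate_tauc(df)
        b = estimate_tauc(pd.concat([df, df], ignore_index=True))
        assert b.tau_c == pytest.approx(a.tau_c, rel=1e-12)

    def test_exclusions_carry_reasons(self, relax_record):
        df = rigid_table(20, 10e-9, relax_record, rng=np.random.default_rng(2))
        df.loc[0, "NOE"] = 0.1  # mobile
        df.loc[1, "R2"] = df.loc[1, "R2"] * 3  # ratio far off
        est = TumblingTimeEstimator().fit(df).estimate_
        reasons = dict(zip(est.excluded_residues.res_num, est.excluded_residues.reason))
        assert reasons[1] == "NOE below cutoff"
        assert 2 in reasons

    def test_rigid_ratio_monotone_in_tauc(self, constants):
        taus = np.linspace(1e-9, 40e-9, 15)
        ratios = [rigid_r2_over_r1(t, constants) for t in taus]
        assert np.all(np.diff(ratios) > 0)


GRID = [
    ("M1", dict(s2=0.95)),
    ("M1", dict(s2=0.5)),
    ("M2", dict(s2=0.85, tau_e=50e-12)),
    ("M2", dict(s2=0.6, tau_e=300e-12)),
    ("M3", dict(s2=0.9, rex=4.0)),
    ("M3", dict(s2=0.7, rex=1.5)),
    ("M4", dict(s2=0.8, tau_e=100e-12, rex=3.0)),
    ("M4", dict(s2=0.45, tau_e=800e-12, rex=6.0)),
]


class TestResidueFits:
    @pytest.mark.parametrize("model_id, truth", GRID)
    def test_noiseless_round_trip(self, relax_record, model_id, truth):
        tau_c = 10.4e-9
        rec = relax_record(tau_c=tau_c, **truth)
        fit = fit_residue(rec, tau_c, model_id)
        assert fit.success
        for name, want in truth.items():
            got = getattr(fit.params, name)
            assert got == pytest.approx(want, rel=1e-3), name

    def test_noiseless_rigid_data_fits_m1_exactly(self, relax_record):
        fit = fit_residue(relax_record(s2=1.0), 10.4e-9, "M1")
        assert fit.params.s2 == pytest.approx(1.0, abs=1e-6)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_inflated_r2_read_as_exchange_by_m3(self, relax_record):
        rec = relax_record(s2=0.85, tau_e=50e-12)
        rec["R2"] += 4.0
        fit = fit_residue(rec, 10.4e-9, "M3")
        assert fit.params.rex == pytest.approx(4.0, abs=1.0)
        assert fit.params.rex > 2.0

    def test_extended_model_round_trip(self, relax_record):
        rec = relax_record(s2=0.63, sf2=0.9, tau_s=1.2e-9)
        fit = fit_residue(rec, 10.4e-9, "M5")
        assert fit.params.s2 == pytest.approx(0.63, rel=5e-3)
        assert "saturated" in fit.flags

    def test_unknown_model_rejected(self, relax_record):
        with pytest.raises(ValueError, match="unknown model"):
            fit_residue(relax_record(s2=0.9), 1e-8, "M9")


class TestModelSelection:
    def candidates(self, rec, tau_c=10.4e-9):
        return {m: fit_residue(rec, tau_c, m) for m in ("M1", "M2", "M3", "M4", "M5")}

    def test_noiseless_m1_data_selects_m1(self, relax_record):
        assert select_model(self.candidates(relax_record(s2=0.9))) == "M1"

    def test_m1_majority_under_noise(self, relax_record):
        rng = np.random.default_rng(7)
        picks = []
        for i in range(500):
            rec = relax_record(s2=0.88, res_num=i, rng=rng)
            picks.append(select_model(self.candidates(rec)))
        frac_m1 = np.mean([p == "M1" for p in picks])
        assert frac_m1 > 0.5

    def test_exchange_data_selects_exchange_model(self, relax_record):
        rng = np.random.default_rng(3)
        rec = relax_record(s2=0.85, rex=6.0, rng=rng)
        fits = self.candidates(rec)
        best = select_model(fits)
        assert best in ("M3", "M4")
        assert fits[best].params.rex > 2.0

    def test_needs_at_least_two_candidates(self, relax_record):
        fits = {"M1": fit_residue(relax_record(s2=0.9), 1e-8, "M1")}
        with pytest.raises(ValueError, match="at least two"):
            select_model(fits)


class TestMonteCarloErrors:
    def test_vanishing_observation_noise_gives_vanishing_spread(self, relax_record):
        rec = relax_record(s2=0.85, tau_e=50e-12, sig_frac=1e-8, sig_noe=1e-8)
        fit = fit_residue(rec, 10.4e-9, "M2")
        errs = monte_carlo_errors(rec, fit, n_draws=100, seed=0)
        assert errs["s2_err"] < 1e-6

    def test_same_seed_reproduces_identical_errors(self, relax_record):
        rec = relax_record(s2=0.85, tau_e=50e-12)
        fit = fit_residue(rec, 10.4e-9, "M2")
        a = monte_carlo_errors(rec, fit, n_draws=120, seed=42)
        b = monte_carlo_errors(rec, fit, n_draws=120, seed=42)
        assert a == b

    def test_spread_consistent_with_repeated_regeneration(self, relax_record):
        """MC posterior spread should match the frequentist spread across
        independently regenerated noisy datasets within a factor 1.5."""
        tau_c = 10.4e-9
        rec = relax_record(s2=0.85, tau_e=50e-12, tau_c=tau_c)
        fit = fit_residue(rec, tau_c, "M2")
        errs = monte_carlo_errors(rec, fit, n_draws=500, seed=1)
        rng = np.random.default_rng(99)
        s2_hats = []
        for _ in range(50):
            noisy = relax_record(s2=0.85, tau_e=50e-12, tau_c=tau_c, rng=rng)
            s2_hats.append(fit_residue(noisy, tau_c, "M2").params.s2)
        observed_sd = np.std(s2_hats, ddof=1)
        assert errs["s2_err"] == pytest.approx(observed_sd, rel=0.5)

    def test_too_few_draws_rejected(self, relax_record):
        rec = relax_record(s2=0.9)
        fit = fit_residue(rec, 1e-8, "M1")
        with pytest.raises(ValueError, match="at least 100"):
            monte_carlo_errors(rec, fit, n_draws=10)


class TestExchangeClassification:
    @pytest.mark.parametrize(
        "rex, expected",
        [(2.5, True), (0.0, False), (2.0, False), (2.0000001, True)],
    )
    def test_strict_threshold(self, rex, expected):
        assert classify_exchange(rex) is expected

    def test_array_input(self):
        out = classify_exchange(np.array([0.0, 2.0, 3.0]), threshold=2.0)
        assert out.tolist() == [False, False, True]


class TestS2RecoveryUnderNoise:
    def test_core_residue_s2_median_error_below_five_hundredths(self, relax_record):
        rng = np.random.default_rng(17)
        errors = []
        for i in range(60):
            s2_true = float(np.random.default_rng(1000 + i).uniform(0.7, 0.98))
            rec = relax_record(s2=s2_true, tau_e=40e-12, res_num=i, rng=rng)
            fits = {m: fit_residue(rec, 10.4e-9, m) for m in ("M1", "M2", "M3")}
            best = select_model(fits)
            errors.append(abs(fits[best].params.s2 - s2_true))
        assert np.median(errors) < 0.05


class TestFullAnalysis:
    def test_pipeline_recovers_scenario_signature(self):
        scn = make_scenario("apo", seed=8)
        table, truth = simulate_relaxation(scn)
        mfa = ModelFreeAnalysis().fit(table)
        res = mfa.results_.merge(
            truth[["res_num", "segment", "s2"]], on="res_num", suffixes=("", "_true")
        )
        tail = res[res.segment == "tail"]["s2"].mean()
        core = res[res.segment.str.startswith("core")]["s2"].mean()
        assert tail < core - 0.2
        assert mfa.tauc_.tau_c == pytest.approx(12.5e-9, rel=0.03)

    def test_estimator_api_round_trip(self):
        est = ModelFreeAnalysis(tau_c=9e-9, models=("M1", "M2"))
        params = est.get_params()
        assert params["tau_c"] == 9e-9
        est.set_params(rex_threshold=3.0)
        assert est.rex_threshold == 3.0
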