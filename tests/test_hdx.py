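"""H/D exchange: intrinsic rates, decay fitting, protection factors."""

import csv
import math
from importlib import resources

import numpy as np
import pandas as pd
import pytest

from dynsuite.hdx import (
    ExchangeRateFit,
    HDXSeries,
    ProtectionFactorAnalysis,
    compare_states,
    fit_exchange_rate,
    intrinsic_rate,
    intrinsic_rates,
    protection_factor,
)


def spreadsheet_intrinsic_rate(sequence, position, pD, T):
    """Independent spreadsheet-style evaluation reading the bundled factor
    table with the stdlib csv module and applying the rate law step by step."""
    with resources.files("dynsuite.data").joinpath("exchange_factors.tsv").open() as fh:
        rows = [r for r in csv.DictReader(
            (l for l in fh if not l.startswith("#")), delimiter="\t")]
    tab = {r["res"]: {k: float(v) for k, v in r.items() if k != "res"} for r in rows}
    res, left = sequence[position - 1], sequence[position - 2]
    acid = tab[res]["acid_lambda"] + tab[left]["acid_rho"]
    base = tab[res]["base_lambda"] + tab[left]["base_rho"]
    if position == 2:
        acid += tab["NT"]["acid_rho"]
        base += tab["NT"]["base_rho"]
    if position == len(sequence):
        acid += tab["CT"]["acid_lambda"]
        base += tab["CT"]["base_lambda"]
    R = 1.987204e-3
    arr = lambda ea: math.exp(ea / R * (1 / 293.0 - 1 / T))
    ka = 10 ** (1.62 + acid - pD) * arr(14.0)
    kb = 10 ** (10.05 + base + pD - 15.05) * arr(17.0)
    kw = 10 ** (-1.50 + base) * arr(19.0)
    return (ka + kb + kw) / 60.0


class TestIntrinsicRate:
    @pytest.mark.parametrize(
        "seq, pos, ph, t",
        [
            ("AAA", 2, 7.0, 308.0),
            ("AAAA", 3, 7.0, 308.0),
            ("GLYK", 3, 6.5, 298.0),
            ("WTSERV", 6, 7.4, 310.0),  # C-terminal position
        ],
    )
    def test_matches_spreadsheet_oracle(self, seq, pos, ph, t):
        got = intrinsic_rate(seq, pos, ph, t)
        want = spreadsheet_intrinsic_rate(seq, pos, ph, t)
        assert got == pytest.approx(want, rel=1e-12)

    def test_base_catalysis_first_order_in_hydroxide(self):
        ratio = intrinsic_rate("AAAA", 3, 8.0, 308.0) / intrinsic_rate("AAAA", 3, 7.0, 308.0)
        assert ratio == pytest.approx(10.0, rel=0.02)

    def test_pure_function(self):
        a = intrinsic_rate("KLMNQ", 3, 7.0, 308.0)
        b = intrinsic_rate("KLMNQ", 3, 7.0, 308.0)
        assert a == b

    def test_monotone_in_temperature_and_ph(self):
        temps = [288.0, 298.0, 308.0, 318.0]
        rates = [intrinsic_rate("AAAA", 3, 7.0, t) for t in temps]
        assert np.all(np.diff(rates) > 0)
        phs = [5.5, 6.0, 6.5, 7.0, 8.0]
        rates = [intrinsic_rate("AAAA", 3, p, 308.0) for p in phs]
        assert np.all(np.diff(rates) > 0)

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="'X'"):
            intrinsic_rate("AXA", 2, 7.0, 308.0)

    def test_proline_and_first_position_rejected(self):
        with pytest.raises(ValueError, match="proline"):
            intrinsic_rate("APA", 2, 7.0, 308.0)
        with pytest.raises(ValueError, match="no backbone amide"):
            intrinsic_rate("AAA", 1, 7.0, 308.0)

    def test_vectorized_rates_skip_prolines(self):
        ks = intrinsic_rates("APAGA", 7.0, 308.0)
        assert 2 not in ks.index
        assert set(ks.index) == {3, 4, 5}


class TestExchangeRateFit:
    def test_exact_exponential_recovered(self):
        t = np.linspace(1, 400, 10)
        k, k_err, censored = fit_exchange_rate(HDXSeries(1, t, 100 * np.exp(-0.01 * t)))
        assert k == pytest.approx(0.01, rel=1e-8)
        assert not censored

    def test_flat_noisy_series_is_censored(self):
        rng = np.random.default_rng(4)
        t = np.linspace(60, 86400, 10)
        y = 100 + rng.normal(0, 1.0, 10)
        k, _, censored = fit_exchange_rate(HDXSeries(1, t, np.clip(y, 0, None),
                                                     intensity_err=np.full(10, 1.0)))
        assert censored
        assert k == pytest.approx(math.log(1 / 0.95) / 86400, rel=1e-9)

    def test_noisy_decay_within_fifteen_percent(self):
        rng = np.random.default_rng(10)
        t = np.geomspace(30, 4000, 12)
        y = 100 * np.exp(-1e-3 * t) * (1 + rng.normal(0, 0.05, 12))
        k, _, censored = fit_exchange_rate(HDXSeries(1, t, np.clip(y, 0, None)))
        assert not censored
        assert k == pytest.approx(1e-3, rel=0.15)

    def test_series_validation(self):
        with pytest.raises(ValueError, match=">=3 time points"):
            HDXSeries(1, [1, 2], [5, 4])
        with pytest.raises(ValueError, match="strictly increasing"):
            HDXSeries(1, [1, 3, 2], [5, 4, 3])
        with pytest.raises(ValueError, match="negative"):
            HDXSeries(1, [1, 2, 3], [5, -1, 3])

    def test_all_zero_series_fails(self):
        with pytest.raises(ValueError, match="no positive intensities"):
            fit_exchange_rate(HDXSeries(1, [1, 2, 3, 4], np.zeros(4)))

    def test_estimator_attributes(self):
        t = np.linspace(1, 400, 8)
        est = ExchangeRateFit().fit(t, 50 * np.exp(-0.02 * t))
        assert est.i0_ == pytest.approx(50, rel=1e-6)
        assert est.k_reported_ == est.k_


class TestProtectionFactor:
    def test_unprotected_limit(self):
        r = protection_factor(0.5, 0.5)
        assert r.pf == pytest.approx(1.0)
        assert r.log10_pf == pytest.approx(0.0)

    def test_four_orders_of_protection(self):
        r = protection_factor(10.0, 1e-3)
        assert r.pf == pytest.approx(1e4)

    def test_scale_invariance_through_the_fit(self):
        t = np.linspace(1, 300, 9)
        y = 20 * np.exp(-0.02 * t)
        k1, _, _ = fit_exchange_rate(HDXSeries(1, t, y))
        k2, _, _ = fit_exchange_rate(HDXSeries(1, t, 7.3 * y))
        assert k1 == pytest.approx(k2, rel=1e-9)

    def test_unphysically_fast_observed_rate_flagged(self):
        r = protection_factor(0.1, 5.0)
        assert "unphysical" in r.flags

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError, match="k_int"):
            protection_factor(0.0, 1.0)
        with pytest.raises(ValueError, match="k_obs"):
            protection_factor(1.0, 0.0)


class TestCompareStates:
    def frame(self, pfs, censored=False):
        return pd.DataFrame(
            {
                "res_num": np.arange(1, len(pfs) + 1),
                "PF": pfs,
                "log10_PF": np.log10(pfs),
                "censored": censored,
            }
        )

    def test_identical_states_give_zero_deltas(self):
        a = self.frame([10.0, 100.0, 1000.0])
        table, summary = compare_states(a, a.copy())
        assert np.allclose(table["delta_log10_PF"], 0.0)
        assert summary["n_increased"] == 0

    def test_tenfold_increase_gives_unit_median_delta(self):
        a = self.frame([10.0, 20.0, 50.0, 100.0])
        b = self.frame([100.0, 200.0, 500.0, 1000.0])
        _, summary = compare_states(a, b)
        assert summary["median_delta_log10_PF"] == pytest.approx(1.0)

    def test_censored_pairs_marked_bounded(self):
        a = self.frame([10.0, 10.0, 10.0])
        b = self.frame([100.0, 100.0, 100.0], censored=True)
        table, summary = compare_states(a, b)
        assert table["bounded"].all()
        assert summary["n_bounded"] == 3

    def test_disjoint_residue_sets_fail(self):
        a = self.frame([10.0])
        b = self.frame([10.0])
        b["res_num"] = [99]
        with pytest.raises(ValueError, match="no residues"):
            compare_states(a, b)


class TestPipeline:
    def make_table(self, kints, pfs, times, i0=100.0):
        rows = []
        for res, (k, pf) in enumerate(zip(kints, pfs), start=2):
            y = i0 * np.exp(-(k / pf) * times)
            for t, v in zip(times, y):
                rows.append({"res_num": res, "time_s": t, "intensity": v,
                             "intensity_err": 0.5})
        return pd.DataFrame(rows)

    def test_time_unit_invariance(self):
        seq = "AAAAAA"
        kints = intrinsic_rates(seq, 7.0, 308.0)
        times = np.geomspace(300, 86400, 8)
        pf_true = [1e5, 1e4, 3e3, 5e3, 2e3]
        tab_s = self.make_table([kints[r] for r in range(2, 7)], pf_true, times)
        tab_h = tab_s.copy()
        tab_h["time_s"] = tab_h["time_s"] / 3600.0
        res_s = ProtectionFactorAnalysis(sequence=seq).fit(tab_s).results_
        res_h = ProtectionFactorAnalysis(sequence=seq, time_unit="h").fit(tab_h).results_
        np.testing.assert_allclose(res_s["PF"], res_h["PF"], rtol=1e-6)

    def test_recovers_constructed_protection_factors(self):
        seq = "AAAAAA"
        kints = intrinsic_rates(seq, 7.0, 308.0)
        times = np.geomspace(300, 86400, 10)
        pf_true = [1e5, 1e4, 3e3, 5e3, 2e3]
        tab = self.make_table([kints[r] for r in range(2, 7)], pf_true, times)
        res = ProtectionFactorAnalysis(sequence=seq).fit(tab).results_
        np.testing.assert_allclose(res["PF"], pf_true, rtol=1e-6)
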