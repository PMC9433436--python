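import numpy as np
import pandas as pd
import pytest

from htskin import kinfit, simulate
from htskin.kinfit import (
    fit_binding,
    fit_dissociation,
    fit_initial_rate,
    fit_mm,
    fold_changes,
)

NM = 1e-9

# multiple-turnover parameters of the characterized constructs:
# (kcat s^-1, kcat/Km M^-1 s^-1)
CONSTRUCTS = {
    "AU": (0.12, 7e6),
    "AU_T5": (0.0250, 1.3e6),
    "AU_D3": (0.261, 26e6),
    "AU_T5D3": (0.060, 3.1e6),
    "GG": (0.07, 0.5e6),
    "GG_D3": (0.048, 4.2e6),
}

S_GRID = np.geomspace(10 * NM, 1000 * NM, 10)  # 10 nM - 1 uM
E0 = 1 * NM


def noiseless_mm_fit(kcat, kcat_over_Km, S_grid=S_GRID, E0=E0):
    Km = kcat / kcat_over_Km
    data = simulate.simulate_initial_rates(kcat, Km, E0, S_grid, replicates=3)
    return fit_mm(data, E0=E0)


class TestInitialRate:
    def test_linear_progress_curve(self):
        t = np.arange(0, 100, 10.0)
        frac = 0.001 * t
        v, se, n_excl = fit_initial_rate(t, frac, S0=100.0)
        assert v == pytest.approx(0.1, rel=1e-12)
        assert n_excl == 0

    def test_points_beyond_ten_percent_excluded(self):
        t = np.arange(0, 300, 20.0)
        frac = 0.001 * t  # crosses 0.1 at t=100
        v, _, n_excl = fit_initial_rate(t, frac, S0=50.0)
        assert n_excl == (frac > 0.1).sum()
        assert v == pytest.approx(0.05, rel=1e-12)

    def test_exponential_truncation_small_bias(self):
        # first-order progress truncated at 10% approximates the true k*S;
        # early-weighted sampling as in a real quench time course
        k = 1e-3
        t = np.array([0.0, 5, 10, 15, 20, 30, 45, 60, 90, 120])
        frac = 1 - np.exp(-k * t)
        v, _, _ = fit_initial_rate(t, frac, S0=1.0)
        assert v == pytest.approx(k, rel=0.05)

    def test_too_few_linear_points_error(self):
        with pytest.raises(ValueError):
            fit_initial_rate([0, 10, 20], [0.2, 0.4, 0.6], S0=1.0)


class TestMichaelisMenten:
    @pytest.mark.parametrize("name", list(CONSTRUCTS))
    def test_noiseless_exact_recovery(self, name):
        kcat, ratio = CONSTRUCTS[name]
        fit = noiseless_mm_fit(kcat, ratio)
        assert fit.kcat == pytest.approx(kcat, rel=1e-6)
        assert fit.kcat_over_Km == pytest.approx(ratio, rel=1e-6)
        assert fit.Km_identifiable

    def test_unit_rescaling_invariance(self):
        # same curve expressed in nM instead of M: kcat and fold ratios unchanged
        fit_m = noiseless_mm_fit(0.12, 7e6)
        data_nm = simulate.simulate_initial_rates(
            0.12, (0.12 / 7e6) / NM, 1.0, S_GRID / NM, replicates=3)
        fit_nm = fit_mm(data_nm, E0=1.0)
        assert fit_nm.kcat == pytest.approx(fit_m.kcat, rel=1e-6)
        assert fit_nm.Km == pytest.approx(fit_m.Km / NM, rel=1e-6)

    def test_weighted_and_unweighted_agree_homoscedastic(self):
        data = simulate.simulate_initial_rates(0.12, 17 * NM, E0, S_GRID,
                                               noise_sd=2e-13, seed=4,
                                               replicates=3)
        fw = fit_mm(data, E0=E0, weighted=True)
        fu = fit_mm(data, E0=E0, weighted=False)
        assert fw.kcat == pytest.approx(fu.kcat, rel=0.05)
        assert fw.Km == pytest.approx(fu.Km, rel=0.15)

    def test_noisy_recovery_unbiased(self):
        """5% noise, 3 replicates: RMSE under 10% across seeds."""
        kcats, kms = [], []
        vmax = 0.12 * E0
        for seed in range(50):
            data = simulate.simulate_initial_rates(
                0.12, 17 * NM, E0, S_GRID, noise_sd=0.05 * vmax,
                seed=seed, replicates=3)
            fit = fit_mm(data, E0=E0)
            kcats.append(fit.kcat)
            kms.append(fit.Km)
        kcats, kms = np.array(kcats), np.array(kms)
        assert abs(kcats.mean() / 0.12 - 1) < 0.05
        assert np.sqrt(np.mean((kcats / 0.12 - 1) ** 2)) < 0.10
        assert np.sqrt(np.mean((kms / (17 * NM) - 1) ** 2)) < 0.25

    def test_sub_Km_range_flags_Km(self):
        # S everywhere far below Km: only the ratio is identifiable
        S = np.geomspace(0.1 * NM, 1 * NM, 6)
        data = simulate.simulate_initial_rates(0.12, 1000 * NM, E0, S,
                                               replicates=1)
        fit = fit_mm(data, E0=E0)
        assert not fit.Km_identifiable
        assert fit.kcat_over_Km == pytest.approx(0.12 / (1000 * NM), rel=0.05)


class TestBinding:
    E_GRID = np.geomspace(2.5 * NM, 200 * NM, 8)

    @pytest.mark.parametrize("Kd_nm", [35.0, 63.0])
    def test_noiseless_exact_recovery(self, Kd_nm):
        data = simulate.simulate_binding(Kd_nm * NM, 0.9, self.E_GRID,
                                         replicates=3)
        fit = fit_binding(data)
        assert fit.Kd == pytest.approx(Kd_nm * NM, rel=1e-6)
        assert fit.Bmax == pytest.approx(0.9, rel=1e-6)
        assert fit.in_range

    def test_out_of_range_Kd_flagged(self):
        data = simulate.simulate_binding(50000 * NM, 0.9, self.E_GRID,
                                         replicates=1)
        fit = fit_binding(data)
        assert not fit.in_range


class TestDissociation:
    T_GRID = np.linspace(0, 600, 25)

    def test_single_exponential_selects_one_phase(self):
        data = simulate.simulate_dissociation(0.0, 1.0, 0.005, self.T_GRID)
        fit = fit_dissociation(data)
        assert fit.n_phases == 1
        assert fit.amp_fast == 0.0
        assert fit.k_slow == pytest.approx(0.005, rel=1e-4)

    def test_gg_like_half_fast(self):
        """Half the complexes dissociate rapidly: ES fraction about 0.5."""
        data = simulate.simulate_dissociation(0.5, 0.05, 1e-5, self.T_GRID,
                                              noise_sd=0.005, seed=1)
        fit = fit_dissociation(data)
        assert fit.n_phases == 2
        assert fit.es_fraction == pytest.approx(0.5, abs=0.05)
        assert fit.es_star_fraction == pytest.approx(0.5, abs=0.05)
        assert fit.k_fast > fit.k_slow

    def test_au_like_mostly_stable(self):
        data = simulate.simulate_dissociation(0.1, 0.05, 1e-5, self.T_GRID,
                                              noise_sd=0.005, seed=2)
        fit = fit_dissociation(data)
        assert fit.es_star_fraction == pytest.approx(0.9, abs=0.05)

    def test_amplitudes_bounded_on_normalized_data(self):
        data = simulate.simulate_dissociation(0.3, 0.1, 1e-4, self.T_GRID,
                                              noise_sd=0.005, seed=3)
        fit = fit_dissociation(data)
        assert fit.amp_fast + fit.amp_slow <= 1.02

    def test_requires_time_zero(self):
        data = pd.DataFrame({"x": [10.0, 20, 30, 40], "y": [0.9, 0.8, 0.7, 0.6],
                             "replicate": 1})
        with pytest.raises(ValueError):
            fit_dissociation(data)


class TestFoldChanges:
    def test_identical_fits_unity(self):
        fit = noiseless_mm_fit(0.12, 7e6)
        table = fold_changes({"a": fit, "b": fit})
        assert np.allclose(table["fold"], 1.0)

    def test_construct_panel_ratios(self):
        """Ratios between the recovered construct parameters: the optimal
        leader beats the 2-pair leader ~14-fold in kcat/Km, and deleting the
        3' tail raises the optimal construct's kcat/Km ~3.7-fold."""
        fits = {name: noiseless_mm_fit(*params)
                for name, params in CONSTRUCTS.items()}
        table = fold_changes(fits).set_index(["numerator", "denominator",
                                              "parameter"])
        au_gg = table.loc[("AU", "GG", "kcat_over_Km"), "fold"]
        assert au_gg == pytest.approx(14.0, rel=1e-3)
        d3 = table.loc[("AU_D3", "AU", "kcat_over_Km"), "fold"]
        assert d3 == pytest.approx(26 / 7, rel=1e-3)
        t5 = table.loc[("AU", "AU_T5", "kcat"), "fold"]
        assert t5 == pytest.approx(0.12 / 0.025, rel=1e-3)

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError):
            fold_changes({"a": noiseless_mm_fit(0.12, 7e6)})

    def test_binding_folds_use_Kd(self):
        d1 = simulate.simulate_binding(35 * NM, 0.9, TestBinding.E_GRID)
        d2 = simulate.simulate_binding(63 * NM, 0.9, TestBinding.E_GRID)
        table = fold_changes({"AU": fit_binding(d1), "GG": fit_binding(d2)})
        row = table.set_index(["numerator", "denominator", "parameter"])
        assert row.loc[("GG", "AU", "Kd"), "fold"] == pytest.approx(63 / 35, rel=1e-4)
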