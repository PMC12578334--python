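import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cphmdkit import (
    Censor,
    DataError,
    TitrationModel,
    build_curve,
    classify_residue,
    fit_hh,
    fit_hill,
    hh_theta,
    interpolate_pka,
    theta_true,
)

GRID = np.arange(1.0, 9.0)


def _curve(theta, pH=GRID, residue_id="X", replicas=1):
    return build_curve(
        pd.DataFrame(
            [
                (0, r, p, t)
                for r in range(replicas)
                for p, t in zip(pH, theta)
            ],
            columns=["monomer", "replica", "pH", "fraction"],
        ),
        residue_id=residue_id,
    )


class TestHHTheta:
    @pytest.mark.parametrize("n", [0.3, 1.0, 2.5])
    def test_midpoint_half_for_any_n(self, n):
        assert hh_theta(4.0, 4.0, n) == pytest.approx(0.5)

    def test_closed_form_values(self):
        assert hh_theta(5.0, 4.0) == pytest.approx(1 / 11)
        assert hh_theta(3.0, 4.0) == pytest.approx(10 / 11)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0, 10), st.floats(1, 9), st.floats(0.1, 4))
    def test_normalization(self, pH, pKa, n):
        th = hh_theta(pH, pKa, n)
        assert 0 <= th <= 1
        # the deprotonated fraction is the mirrored sigmoid
        assert th + 1 / (1 + 10 ** (n * (pKa - pH))) == pytest.approx(1.0)

    def test_symmetry_about_midpoint(self):
        assert hh_theta(3.0, 4.0) == pytest.approx(1 - hh_theta(5.0, 4.0))


class TestInterpolatePka:
    def test_symmetric_crossing(self):
        est = interpolate_pka(([3.0, 4.0], [0.909, 0.091]))
        assert est.value == pytest.approx(3.5)

    def test_exact_hh_sampled_on_grid(self):
        # HH with pKa 2.7 on the unit grid: crossing of the chord between
        # theta(2)=0.8337 and theta(3)=0.3339 sits at 2.668
        est = interpolate_pka((GRID, hh_theta(GRID, 2.7)))
        assert est.value == pytest.approx(2.668, abs=5e-4)

    def test_always_protonated_censored_above(self):
        est = interpolate_pka((GRID, np.full(8, 0.62)))
        assert est.censor == Censor("above", 8.0)

    def test_always_deprotonated_censored_below(self):
        est = interpolate_pka((GRID, np.full(8, 0.11)))
        assert est.censor == Censor("below", 1.0)

    def test_exact_half_resolves_to_grid_ph(self):
        est = interpolate_pka(([3.0, 4.0, 5.0], [0.9, 0.5, 0.1]))
        assert est.value == 4.0

    def test_noise_regularized_before_crossing(self):
        # a non-monotone wiggle around the crossing still yields one pKa
        theta = np.array([0.95, 0.9, 0.55, 0.6, 0.2, 0.1, 0.05, 0.02])
        est = interpolate_pka((GRID, theta))
        assert 3.0 < est.value < 5.0


class TestFits:
    def test_hh_exact_recovery(self):
        est = fit_hh((GRID, hh_theta(GRID, 3.3)))
        assert est.value == pytest.approx(3.3, abs=1e-6)
        assert est.rss == pytest.approx(0.0, abs=1e-12)

    def test_hill_exact_recovery(self):
        hill = fit_hill((GRID, hh_theta(GRID, 4.0)))
        assert hill.pKa == pytest.approx(4.0, abs=1e-4)
        assert hill.n == pytest.approx(1.0, abs=1e-4)

    def test_hill_on_symmetric_mixture(self, mixture_model):
        # two conformers one pKa unit either side of 3.5: the apparent
        # least-squares Hill exponent on the 1-8 window is ~0.54
        hill = fit_hill((GRID, theta_true(GRID, mixture_model)))
        assert hill.pKa == pytest.approx(3.5, abs=1e-3)
        assert hill.n == pytest.approx(0.541, abs=0.01)
        assert hill.n < 1.0

    def test_degenerate_mixture_recovers_n_of_one(self):
        m = TitrationModel(conformers=((0.5, 4.0), (0.5, 4.0)))
        hill = fit_hill((GRID, theta_true(GRID, m)))
        assert hill.n == pytest.approx(1.0, abs=1e-4)

    def test_censored_curve_requires_force(self):
        with pytest.raises(DataError):
            fit_hh((GRID, np.full(8, 0.9)))

    def test_generator_recovery_at_study_scale(self, single_site_model):
        from cphmdkit import fraction_lambda_mean, simulate_lambda

        model = TitrationModel(conformers=((1.0, 3.3),))
        rows = []
        for m in range(3):
            for r in range(3):
                for pH in GRID:
                    traj = simulate_lambda(
                        model, float(pH), 200.0, seed=7_000_000 + 10000 * m + 100 * r + int(pH)
                    )
                    rows.append((m, r, float(pH), fraction_lambda_mean(traj).fraction))
        curve = build_curve(
            pd.DataFrame(rows, columns=["monomer", "replica", "pH", "fraction"])
        )
        est = fit_hh(curve)
        assert abs(est.value - 3.3) < 0.15

    def test_interp_and_fits_agree_on_hh_data(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            pka = rng.uniform(2.0, 7.0)
            theta = np.clip(hh_theta(GRID, pka) + rng.normal(0, 0.01, 8), 0, 1)
            pi = interpolate_pka((GRID, theta)).value
            ph = fit_hh((GRID, theta)).value
            pl = fit_hill((GRID, theta)).pKa
            assert max(abs(pi - ph), abs(pi - pl), abs(ph - pl)) < 0.05

    def test_hill_n_decreases_with_conformer_separation(self):
        ns = []
        for delta in (0.0, 1.0, 2.0, 3.0):
            m = TitrationModel(conformers=((0.5, 4.5 - delta / 2), (0.5, 4.5 + delta / 2)))
            ns.append(fit_hill((GRID, theta_true(GRID, m))).n)
        assert all(a > b for a, b in zip(ns, ns[1:]))
        assert ns[0] == pytest.approx(1.0, abs=1e-4)


class TestClassifyResidue:
    def test_always_deprotonated_call(self):
        curve = _curve(np.full(8, 0.3))
        call = classify_residue(curve)
        assert call.label == "always_deprotonated"
        assert call.pka_interp.censor == Censor("below", 1.0)
        assert call.pka_hh is None

    def test_titrating_call_with_fits(self):
        curve = _curve(hh_theta(GRID, 3.0), replicas=3)
        call = classify_residue(curve)
        assert call.label == "titrating"
        assert call.pka_interp.value == pytest.approx(3.0, abs=0.02)
        assert call.pka_hh.value == pytest.approx(3.0, abs=1e-4)
        assert call.hill.n == pytest.approx(1.0, abs=1e-3)
        assert call.pka_interp.sd == pytest.approx(0.0, abs=1e-12)

    def test_boundary_crossing_is_titrating(self):
        theta = np.array([0.51, 0.4, 0.3, 0.2, 0.1, 0.05, 0.02, 0.01])
        call = classify_residue(_curve(theta))
        assert call.label == "titrating"
        assert 1.0 < call.pka_interp.value < 2.0

    def test_always_protonated_call(self):
        call = classify_residue(_curve(np.full(8, 0.95)))
        assert call.label == "always_protonated"
        assert call.pka_interp.censor == Censor("above", 8.0)
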