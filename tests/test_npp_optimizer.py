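"""NPP functional, numeric ET optimization and its closed forms."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from percbudyko import (
    NPPModelParams,
    SoilSystem,
    et_fraction_closed_form,
    et_first_order,
    et_partition_selfconsistent,
    et_second_order,
    et_with_interception,
    npp_value,
    optimize_et_numeric,
)

CONST_D_SOIL = SoilSystem(x0=1.0, porosity=0.4, D=1.0)


class TestNPPValue:
    def test_zero_at_both_ends(self):
        params = NPPModelParams.humid()
        assert npp_value(0.0, 1.0, params, CONST_D_SOIL) == 0.0
        assert npp_value(1.0, 1.0, params, CONST_D_SOIL) == pytest.approx(0.0)

    def test_interior_unimodality_grid_scan(self):
        # brute-force oracle: a dense scan must rise then fall exactly once
        params = NPPModelParams.humid()
        ets = np.linspace(0.0, 1.0, 100_001)
        vals = np.array([npp_value(e, 1.0, params, CONST_D_SOIL) for e in ets])
        sign_changes = np.sum(np.diff(np.sign(np.diff(vals))) != 0)
        assert sign_changes == 1
        assert 0 < ets[np.argmax(vals)] < 1

    def test_outside_feasible_interval_rejected(self):
        params = NPPModelParams.humid()
        with pytest.raises(ValueError, match="feasible"):
            npp_value(0.9, 1.0, params, CONST_D_SOIL, qsurf=0.2)


class TestClosedForm:
    @pytest.mark.parametrize(
        "df,beta,expected",
        [
            (1.9, 1.15, 0.6229508196721312),  # humid base → prints as 0.623
            (1.0, 1.0, 0.5),
            (2.5, 0.575, 0.8130081300813008),  # arid branch → prints as 0.813
        ],
    )
    def test_known_fractions(self, df, beta, expected):
        assert et_fraction_closed_form(df, beta) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            et_fraction_closed_form(0.0, 1.0)
        with pytest.raises(ValueError):
            et_fraction_closed_form(1.9, -1.0)

    @given(
        df=st.floats(1.2, 2.9),
        beta=st.floats(0.3, 1.5),
        shift=st.floats(0.05, 0.5),
    )
    def test_monotone_in_df_and_beta(self, df, beta, shift):
        f = et_fraction_closed_form(df, beta)
        assert et_fraction_closed_form(min(df + shift, 3.0), beta) > f
        assert et_fraction_closed_form(df, beta + shift) < f


class TestNumericOptimizer:
    @pytest.mark.parametrize(
        "params,expected",
        [
            (NPPModelParams.humid(), 1.9 / (1.9 + 1.15)),
            (NPPModelParams(df=2.0, depth_power=1.0), 2.0 / 3.0),
            (NPPModelParams.arid(), 2.5 / (2.5 + 0.575)),
        ],
    )
    def test_matches_closed_form_anchors(self, params, expected):
        res = optimize_et_numeric(1.0, params, CONST_D_SOIL)
        assert res.ET == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("df", [1.2, 1.7, 2.2, 2.9])
    @pytest.mark.parametrize("beta", [0.3, 0.7, 1.15, 1.5])
    def test_matches_closed_form_grid(self, df, beta):
        params = NPPModelParams(df=df, depth_power=beta, depth_factor_power=1.0)
        res = optimize_et_numeric(1.0, params, CONST_D_SOIL)
        assert res.ET == pytest.approx(
            et_fraction_closed_form(df, beta), rel=1e-6
        )

    def test_interception_and_runoff_shift_optimum(self):
        # numeric optimum with constant D equals the exact interception form
        res = optimize_et_numeric(
            1.0, NPPModelParams.humid(), CONST_D_SOIL, qsurf=0.1, interception=0.2
        )
        expected = et_with_interception(1.0, 0.2, 0.1, mode="exact")
        assert res.ET == pytest.approx(expected.ET, rel=1e-6)

    def test_degenerate_interval_returns_all_runoff(self):
        with pytest.warns(RuntimeWarning, match="all-run-off"):
            res = optimize_et_numeric(
                1.0, NPPModelParams.humid(), CONST_D_SOIL, qsurf=0.9, interception=0.2
            )
        assert "degenerate-interval" in res.flags
        assert res.ET == pytest.approx(0.2)  # interception only

    def test_stationarity_of_numeric_maximum(self):
        # symbolic derivative of the functional vanishes at the numeric optimum
        sympy = pytest.importorskip("sympy")
        et = sympy.symbols("et", positive=True)
        df, dp, phi = sympy.Rational(19, 10), sympy.Rational(23, 20), sympy.Rational(2, 5)
        a, b, qs = sympy.Rational(1, 100), sympy.Integer(1), sympy.Rational(1, 5)
        qsub = 1 - et - qs
        npp = (qsub / (sympy.Rational(187, 100) * phi * (a * qsub + b * qs))) ** dp * et**df
        dn = sympy.lambdify(et, sympy.diff(npp, et), "numpy")
        soil = SoilSystem(x0=1.0, porosity=0.4, a=0.01, b=1.0)
        res = optimize_et_numeric(1.0, NPPModelParams.humid(), soil, qsurf=0.2)
        scale = float(npp_value(0.5, 1.0, NPPModelParams.humid(), soil, qsurf=0.2))
        assert abs(float(dn(res.ET))) < 1e-8 * scale / 0.01  # derivative scale ~ npp/ET


class TestExpansions:
    def test_first_order_anchors(self):
        assert et_first_order(1.0, 0.0) == pytest.approx(0.623)
        assert et_first_order(1.0, 1.0) == 0.0
        # Qsurf = 0.24·P: surface run-off fixture (35% run-off − 11% deep)
        assert et_first_order(1.0, 0.24) == pytest.approx(0.623 * 0.76, rel=1e-12)
        with pytest.raises(ValueError):
            et_first_order(1.0, 1.1)

    def test_second_order_reduces_to_two_thirds(self):
        assert et_second_order(1.0, 0.3, a=0.0, b=1.0) == pytest.approx(
            (2 / 3) * 0.7, rel=1e-12
        )

    def test_second_order_singular_at_zero_qsurf(self):
        with pytest.warns(RuntimeWarning, match="singular"):
            val = et_second_order(1.0, 0.0, a=0.01, b=1.0)
        assert val == pytest.approx(2 / 3)

    @pytest.mark.parametrize("eps", [0.1, 0.01])
    def test_second_order_accuracy(self, eps):
        # error against the numeric optimum must be O((a/b)²)
        params = NPPModelParams(df=2.0, depth_power=1.0)
        soil = SoilSystem(x0=1.0, porosity=0.4, a=eps, b=1.0)
        res = optimize_et_numeric(1.0, params, soil, qsurf=0.2)
        approx = et_second_order(1.0, 0.2, a=eps, b=1.0)
        assert abs(res.ET - approx) < 2.0 * eps**2

    def test_second_order_convergence_rate(self):
        params = NPPModelParams(df=2.0, depth_power=1.0)
        errs = []
        for eps in (0.1, 0.01):
            soil = SoilSystem(x0=1.0, porosity=0.4, a=eps, b=1.0)
            res = optimize_et_numeric(1.0, params, soil, qsurf=0.2)
            errs.append(abs(res.ET - et_second_order(1.0, 0.2, a=eps, b=1.0)))
        ratio = errs[0] / errs[1]
        assert 50 < ratio < 200  # quadratic: x100 when a/b shrinks x10


class TestInterceptionPartition:
    def test_reduces_to_first_order_without_interception(self):
        res = et_with_interception(1.0, 0.0, 0.2)
        assert res.ET == pytest.approx(et_first_order(1.0, 0.2), rel=1e-12)

    @pytest.mark.parametrize(
        "interception,expected",
        [(0.214, 0.610), (0.30, 0.642)],
    )
    def test_published_partition_values(self, interception, expected):
        res = et_with_interception(1.0, interception, 0.4 * 0.377)
        assert res.et_over_p == pytest.approx(expected, abs=5e-4)

    def test_infeasible_inputs_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            et_with_interception(1.0, 0.7, 0.4)

    @given(
        interception=st.floats(0.0, 0.4),
        qsurf=st.floats(0.0, 0.4),
        p=st.floats(0.5, 2000.0),
    )
    def test_closure_property(self, interception, qsurf, p):
        res = et_with_interception(p, interception * p, qsurf * p)
        assert abs(res.P - (res.ET + res.Qsurf + res.Qsub)) <= 1e-12 * res.P

    def test_selfconsistent_fixed_point(self):
        res = et_partition_selfconsistent(1.0, 0.214, 0.6)
        # the returned Qsurf must satisfy Qsurf = (1−f_sub)(P−ET)
        assert res.Qsurf == pytest.approx(0.4 * (1.0 - res.ET), rel=1e-12)
        assert abs(res.P - (res.ET + res.Qsurf + res.Qsub)) <= 1e-12
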