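"""Tests for effect computation, isoeffect inversion, curves, and reports."""

import math

import numpy as np
import pytest

from lqiso.fitting import FitResult
from lqiso.isoeffect import (
    Schedule,
    anchored_lq_isoeffect_dose,
    effect,
    elq_effect,
    elq_isoeffect_dose,
    fraction_ratio,
    isoeffect_curve,
    isoeffect_uncertainty_band,
    lq_approximation_report,
    lq_effect,
    lq_isoeffect_dose,
    parse_schedule,
)
from lqiso.models import GAMMA_UNBOUNDED, ELQParameters, LQParameters
from lqiso.reference import (
    ISOEFFECT_TABLE_40X2,
    ISOEFFECT_TABLE_COLUMNS,
    KNOWN_DISCREPANT_CELLS,
    LITERATURE_FITS,
    SURVIVAL_TABLE_2GY,
)

REF_40X2 = Schedule(40, 2.0)
REF_3X15 = Schedule(3, 15.0)


def bisect_isoeffect_oracle(params, E, n, lo=1e-9, hi=1e4, iters=200):
    """Independent plain-bisection inverse of the effect map, for cross-checks."""
    f = lambda D: effect(params, Schedule(n, D / n)) - E
    assert f(lo) < 0 < f(hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestSchedule:
    def test_parse(self):
        s = parse_schedule("40x2")
        assert (s.n, s.dose_per_fraction, s.total_dose) == (40, 2.0, 80.0)
        assert parse_schedule("3x15").total_dose == 45.0

    @pytest.mark.parametrize("bad", ["40", "x2", "0x2", "4x0", "axb"])
    def test_parse_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            parse_schedule(bad)


class TestEffect:
    def test_lq_effect_cho_40x2(self):
        assert lq_effect(LITERATURE_FITS["CHO"].lq, REF_40X2) == pytest.approx(
            27.138, abs=1e-3
        )

    def test_elq_effect_ncih841_40x2(self):
        assert elq_effect(LITERATURE_FITS["NCIH841"].elq, REF_40X2) == pytest.approx(
            11.09, abs=0.01
        )

    def test_single_fraction_identity(self, all_parameter_sets):
        from lqiso.models import elq_log_survival, lq_log_survival

        for p in all_parameter_sets.values():
            s = Schedule(1, 7.5)
            if isinstance(p, ELQParameters):
                assert effect(p, s) == pytest.approx(-elq_log_survival(p, 7.5), rel=1e-12)
            else:
                assert effect(p, s) == pytest.approx(-lq_log_survival(p, 7.5), rel=1e-12)

    def test_unbounded_gamma_effect_equals_lq(self):
        p = ELQParameters(0.2, 0.04, GAMMA_UNBOUNDED)
        assert elq_effect(p, REF_40X2) == lq_effect(p.as_lq(), REF_40X2)


class TestLQInversion:
    def test_cho_single_fraction(self):
        E = lq_effect(LITERATURE_FITS["CHO"].lq, REF_40X2)
        assert lq_isoeffect_dose(LITERATURE_FITS["CHO"].lq, E, 1) == pytest.approx(
            24.3, abs=0.05
        )

    def test_ncih841_24_fractions(self):
        p = LITERATURE_FITS["NCIH841"].lq
        assert lq_isoeffect_dose(p, lq_effect(p, REF_40X2), 24) == pytest.approx(
            68.3, abs=0.05
        )

    def test_self_consistency_at_reference(self, all_parameter_sets):
        for p in all_parameter_sets.values():
            E = effect(p, REF_40X2)
            assert isoeffect_curve(p, REF_40X2, [40]).total_dose[0] == pytest.approx(
                80.0, abs=1e-9
            )

    def test_alpha_zero_pure_quadratic_branch(self):
        p = LQParameters(0.0, 0.05)
        E = 5.0
        for n in (1, 10):
            D = lq_isoeffect_dose(p, E, n)
            assert D == pytest.approx(math.sqrt(n * E / 0.05), rel=1e-12)

    def test_closed_form_matches_numeric_root(self, all_parameter_sets):
        from scipy.optimize import brentq

        for p in all_parameter_sets.values():
            if isinstance(p, ELQParameters):
                continue
            E = lq_effect(p, REF_40X2)
            for n in (1, 7, 33):
                D_closed = lq_isoeffect_dose(p, E, n)
                D_num = brentq(
                    lambda D: lq_effect(p, Schedule(n, D / n)) - E, 1e-6, 1e4,
                    xtol=1e-12, rtol=1e-15,
                )
                assert D_closed == pytest.approx(D_num, abs=1e-9)


class TestELQInversion:
    @pytest.mark.parametrize(
        "n,expected",
        [(1, 15.9), (24, 62.7)],
    )
    def test_ncih841_40x2_equivalents(self, n, expected):
        p = LITERATURE_FITS["NCIH841"].elq
        E = elq_effect(p, REF_40X2)
        assert elq_isoeffect_dose(p, E, n) == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize("n,expected", [(10, 72.8), (20, 98.9)])
    def test_ncih841_3x15_equivalents(self, n, expected):
        p = LITERATURE_FITS["NCIH841"].elq
        E = elq_effect(p, REF_3X15)
        assert elq_isoeffect_dose(p, E, n) == pytest.approx(expected, abs=0.05)

    def test_round_trip_inversion(self, all_parameter_sets):
        for p in all_parameter_sets.values():
            for n in (1.0, 3.0, 12.5, 50.0):
                for E in (0.5, 5.0, 30.0):
                    D = (
                        elq_isoeffect_dose(p, E, n)
                        if isinstance(p, ELQParameters)
                        else lq_isoeffect_dose(p, E, n)
                    )
                    assert effect(p, Schedule(n, D / n)) == pytest.approx(E, abs=1e-8)

    def test_agrees_with_bisection_oracle(self, all_parameter_sets):
        for name, p in all_parameter_sets.items():
            if not isinstance(p, ELQParameters):
                continue
            E = elq_effect(p, REF_40X2)
            for n in (1, 2, 4, 8, 16, 24, 30, 40, 50):
                D = elq_isoeffect_dose(p, E, n)
                assert D == pytest.approx(
                    bisect_isoeffect_oracle(p, E, n), abs=1e-6
                ), f"{name} n={n}"

    def test_unbounded_gamma_uses_closed_form(self):
        p = ELQParameters(0.2697, 0.03476, GAMMA_UNBOUNDED)
        E = elq_effect(p, REF_40X2)
        assert elq_isoeffect_dose(p, E, 1) == pytest.approx(
            lq_isoeffect_dose(p.as_lq(), E, 1), rel=1e-12
        )


class TestPublishedTables:
    def test_isoeffect_table_40x2_reproduces(self):
        """Every printed cell of the 40x2 Gy isoeffect table reproduces to
        0.1 Gy from the published parameters; no cell is known-discrepant."""
        assert not KNOWN_DISCREPANT_CELLS
        for n, row in ISOEFFECT_TABLE_40X2.items():
            for col, printed in zip(ISOEFFECT_TABLE_COLUMNS, row):
                if col.startswith("AB"):
                    ab = float(col[2:].split("_")[0])
                    value = anchored_lq_isoeffect_dose(ab, REF_40X2, n)
                else:
                    cell, kind = col.rsplit("_", 1)
                    params = (
                        LITERATURE_FITS[cell].lq if kind == "LQ" else LITERATURE_FITS[cell].elq
                    )
                    value = isoeffect_curve(params, REF_40X2, [n]).total_dose[0]
                assert value == pytest.approx(printed, abs=0.1), f"{col} n={n}"

    def test_survival_and_ratio_table(self):
        from lqiso.models import elq_log_survival, lq_log_survival

        for cell, (s_lq, s_elq, ratio) in SURVIVAL_TABLE_2GY.items():
            f = LITERATURE_FITS[cell]
            assert math.exp(lq_log_survival(f.lq, 2.0)) == pytest.approx(s_lq, abs=0.005)
            assert math.exp(elq_log_survival(f.elq, 2.0)) == pytest.approx(s_elq, abs=0.005)
            assert fraction_ratio(f.lq, f.elq, 2.0) == pytest.approx(ratio, abs=0.01)

    def test_fraction_ratio_identical_models_is_one(self):
        lq = LQParameters(0.2, 0.04)
        assert fraction_ratio(lq, ELQParameters(0.2, 0.04, GAMMA_UNBOUNDED), 2.0) == 1.0


class TestCurvesAndBands:
    def test_all_curves_pass_through_reference(self, all_parameter_sets):
        for p in all_parameter_sets.values():
            curve = isoeffect_curve(p, REF_40X2)
            assert curve.dose_at(40) == pytest.approx(80.0, abs=1e-9)

    def test_zero_uncertainty_band_has_zero_width(self):
        fit = FitResult(
            model_kind="LQ",
            parameters=LITERATURE_FITS["CHO"].lq,
            wssr=0.0,
            pct_uncertainty={"alpha": 0.0, "beta": 0.0},
            n_points=12,
            free_names=("alpha", "beta"),
        )
        n, lo, hi, clipped = isoeffect_uncertainty_band(fit, REF_40X2)
        assert np.allclose(lo, hi)
        assert not clipped

    def _published_fit(self, cell, kind):
        f = LITERATURE_FITS[cell]
        if kind == "LQ":
            return FitResult(
                model_kind="LQ", parameters=f.lq, wssr=f.lq_wssr,
                pct_uncertainty=dict(f.lq_pct), n_points=12,
                free_names=tuple(f.lq_pct),
            )
        return FitResult(
            model_kind="ELQ", parameters=f.elq, wssr=f.elq_wssr,
            pct_uncertainty=dict(f.elq_pct), n_points=12,
            alpha_fixed_to_zero=f.elq_alpha_fixed,
            gamma_unbounded=f.elq.gamma_unbounded,
            free_names=tuple(f.elq_pct),
        )

    def test_band_contains_nominal_curve(self):
        for cell in LITERATURE_FITS:
            for kind in ("LQ", "ELQ"):
                fit = self._published_fit(cell, kind)
                n, lo, hi, _ = isoeffect_uncertainty_band(fit, REF_40X2)
                nominal = isoeffect_curve(fit.parameters, REF_40X2, n).total_dose
                assert np.all(lo <= nominal + 1e-9)
                assert np.all(nominal <= hi + 1e-9)

    def test_lq_band_wider_than_elq_band_for_lung_line(self):
        """The published lung-line LQ parameters are far less certain than the
        ELQ ones; the single-fraction isoeffect band must reflect that."""
        lq_fit = self._published_fit("NCIH841", "LQ")
        elq_fit = self._published_fit("NCIH841", "ELQ")
        _, lo_lq, hi_lq, _ = isoeffect_uncertainty_band(lq_fit, REF_40X2, [1])
        _, lo_elq, hi_elq, _ = isoeffect_uncertainty_band(elq_fit, REF_40X2, [1])
        assert hi_lq[0] - lo_lq[0] > hi_elq[0] - lo_elq[0]


class TestApproximationReport:
    def test_cp3_small_alpha_beta_agrees_at_moderate_fractions(self):
        """alpha/beta = 0.5 tracks the prostate-line ELQ curve within 1 Gy
        except at small fraction numbers, where it dips below."""
        elq = LITERATURE_FITS["CP3"].elq
        (res,) = lq_approximation_report(elq, [0.5], REF_40X2, tolerance_gy=1.0)
        assert res.n_start is not None
        assert res.n_start > 1  # disagreement at small n
        assert res.n_end == 50
        assert res.n_end - res.n_start >= 30  # agrees over most of the range
        # the disagreement at small n is a dip below the ELQ curve
        assert res.diffs[0] < -1.0

    def test_self_candidate_agrees_everywhere(self):
        elq = ELQParameters(0.2, 0.04, GAMMA_UNBOUNDED)
        (res,) = lq_approximation_report(elq, [0.2 / 0.04], REF_40X2, tolerance_gy=1e-6)
        assert (res.n_start, res.n_end) == (1, 50)
        assert res.max_abs_diff_gy < 1e-9

    def test_small_alpha_beta_fails_for_large_dose_per_fraction(self):
        """With a 3x15 Gy reference the alpha/beta = 0.5 shortcut overshoots
        the lung-line ELQ by far more than 1 Gy (113 vs ~99 Gy at n=20)."""
        elq = LITERATURE_FITS["NCIH841"].elq
        E = elq_effect(elq, REF_3X15)
        d_elq = elq_isoeffect_dose(elq, E, 20)
        d_lq = anchored_lq_isoeffect_dose(0.5, REF_3X15, 20)
        assert d_lq - d_elq > 1.0
        assert d_lq == pytest.approx(113, abs=0.5)
        assert d_elq == pytest.approx(98.9, abs=0.05)

    def test_wildly_wrong_candidate_agrees_only_at_the_anchor(self):
        # every anchored curve passes through the reference point, so with the
        # reference n in range the agreement interval degenerates to it
        elq = LITERATURE_FITS["NCIH841"].elq
        (res,) = lq_approximation_report(elq, [50.0], REF_40X2, tolerance_gy=0.01)
        assert (res.n_start, res.n_end) == (40, 40)

    def test_empty_agreement_interval_is_not_an_error(self):
        elq = LITERATURE_FITS["NCIH841"].elq
        (res,) = lq_approximation_report(
            elq, [50.0], REF_40X2, n_range=np.arange(1, 21), tolerance_gy=0.01
        )
        assert res.n_start is None and res.n_end is None
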