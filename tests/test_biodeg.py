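"""Rayleigh model, extent inversion and biodegradation diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mudgas.biodeg import (
    RayleighParams,
    codegradation_slope,
    extent_from_offset,
    extents_for_records,
    isotope_cotrend,
    rayleigh_forward,
    rayleigh_invert,
    secondary_methane_indicator,
)
from mudgas.records import BDL, GasComposition, IsotopeValue, SampleRecord


class TestForwardModel:
    def test_no_reaction_returns_initial(self):
        assert rayleigh_forward(1.0, 33.0, -25.0) == pytest.approx(-25.0, abs=1e-12)

    def test_half_consumed_closed_form(self):
        # (975) * 0.5**(-0.033) - 1000
        expected = 975.0 * 0.5 ** (-0.033) - 1000.0
        assert rayleigh_forward(0.5, 33.0, -25.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-2.44, abs=0.005)

    def test_zero_eps_is_conservative(self):
        for f in (0.1, 0.5, 0.9):
            assert rayleigh_forward(f, 0.0, -25.0) == -25.0

    def test_strictly_decreasing_in_f(self):
        fs = np.linspace(0.05, 1.0, 40)
        deltas = [rayleigh_forward(f, 33.0, 0.0) for f in fs]
        assert all(a > b for a, b in zip(deltas, deltas[1:]))

    def test_invalid_fraction_rejected(self):
        for f in (0.0, -0.1, 1.2):
            with pytest.raises(ValueError):
                rayleigh_forward(f, 33.0, 0.0)


@given(f=st.floats(0.05, 0.95), eps=st.floats(1.0, 60.0), d0=st.floats(-30.0, 5.0))
def test_forward_inverse_round_trip(f, eps, d0):
    delta = rayleigh_forward(f, eps, d0)
    assert rayleigh_invert(delta, eps, d0) == pytest.approx(f, rel=1e-9)


class TestExtentInversion:
    def test_zero_offset_zero_extent(self):
        est = extent_from_offset(0.0, RayleighParams())
        assert est.extent_percent == pytest.approx(0.0, abs=1e-12)

    def test_largest_offset_near_upper_printed_extent(self):
        est = extent_from_offset(40.5, RayleighParams())
        assert est.extent_percent == pytest.approx(70.0, abs=1.5)

    def test_below_initial_offset_rejected(self):
        with pytest.raises(ValueError, match="negative extent"):
            extent_from_offset(-1.0, RayleighParams())

    def test_bdl_offset_unavailable(self):
        assert extent_from_offset(BDL, RayleighParams()) is None
        assert extent_from_offset(None, RayleighParams()) is None

    def test_monotone_in_offset(self):
        offsets = np.linspace(0.0, 45.0, 30)
        exts = [extent_from_offset(o, RayleighParams()).extent_percent for o in offsets]
        assert all(b > a for a, b in zip(exts, exts[1:]))

    def test_table_extents_within_coarse_envelope(self, tokamachi):
        """All field extents in [50, 75]% with >= 10 pp spread; M-3 skipped via bdl."""
        ests = extents_for_records(tokamachi)
        assert len(ests) == 6
        assert all("M-3" != e.sample_id for e in ests)
        exts = [e.extent_percent for e in ests]
        assert min(exts) >= 50.0 and max(exts) <= 75.0
        assert max(exts) - min(exts) >= 10.0

    def test_linear_limit_agreement(self):
        """For small offsets, 1 - exp(-D/eps) matches the exact inversion."""
        for off in np.linspace(0.5, 8.0, 10):
            exact = extent_from_offset(off, RayleighParams()).extent_percent
            approx = 100.0 * (1.0 - math.exp(-off / 33.0))
            assert abs(exact - approx) <= 0.5


def _rec(sid, **kw):
    comp = GasComposition(
        **{k: kw.pop(k) for k in ("ch4", "co2", "c2h6", "c3h8") if k in kw}
    )
    iso = {k: (v if not isinstance(v, float) else IsotopeValue(v)) for k, v in kw.items()}
    return SampleRecord(id=sid, site="Murono", composition=comp, isotopes=iso)


class TestCodegradationSlope:
    def test_murono_field_slope_is_0p4(self, murono):
        fit = codegradation_slope(murono)
        assert round(fit.slope, 1) == 0.4
        assert fit.n == 5

    def test_exact_two_point_slope_rejected_insufficient(self):
        with pytest.raises(ValueError, match=">= 3"):
            codegradation_slope(
                [_rec("a", c2h6=0.0, c3h8=0.0), _rec("b", c2h6=1.0, c3h8=0.4)]
            )

    def test_exact_line_and_order_invariance(self):
        recs = [
            _rec("a", c2h6=0.0, c3h8=0.0),
            _rec("b", c2h6=1.0, c3h8=0.4),
            _rec("c", c2h6=2.0, c3h8=0.8),
        ]
        fit = codegradation_slope(recs)
        assert fit.slope == pytest.approx(0.4, abs=1e-12)
        fit2 = codegradation_slope(list(reversed(recs)))
        assert fit2.slope == fit.slope and fit2.intercept == fit.intercept

    def test_zero_variance_predictor_rejected(self):
        recs = [_rec(s, c2h6=0.5, c3h8=v) for s, v in zip("abc", (0.1, 0.2, 0.3))]
        with pytest.raises(ValueError, match="variance"):
            codegradation_slope(recs)


class TestIsotopeCotrend:
    def test_methane_delta_anticorrelates_with_offset(self, murono):
        fit = isotope_cotrend(murono, "delta13c_central", "d13c_ch4")
        assert fit.r < 0
        assert fit.n == 4  # M-3 dropped via bdl offset

    def test_methane_fraction_correlates_with_offset(self, murono):
        fit = isotope_cotrend(murono, "delta13c_central", "pct:ch4")
        assert fit.r > 0

    def test_identity_series(self):
        recs = [_rec(s, d13c_ch4=v, d13c_co2=v) for s, v in zip("abc", (-40.0, -35.0, -30.0))]
        fit = isotope_cotrend(recs, "d13c_ch4", "d13c_co2")
        assert fit.slope == pytest.approx(1.0) and fit.r == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        recs = [_rec("a", d13c_ch4=-40.0, d13c_co2=20.0)]
        with pytest.raises(ValueError):
            isotope_cotrend(recs, "d13c_ch4", "d13c_co2")


class TestSecondaryMethaneIndicator:
    def test_field_samples_verdict_consistent(self, murono):
        rep = secondary_methane_indicator(murono, co2_threshold=15.0)
        assert rep.verdict == "consistent with secondary methanogenesis"
        assert rep.co2_all_above_threshold is True
        assert rep.r_offset_vs_d13c_ch4 < 0 and rep.r_offset_vs_pct_ch4 > 0

    def test_flat_synthetic_deltas_not_consistent(self):
        recs = [
            _rec(s, ch4=90.0, d13c_ch4=-40.0, d13c_co2=0.0, delta13c_central=0.0)
            for s in "abc"
        ]
        rep = secondary_methane_indicator(recs)
        assert rep.verdict in ("indeterminate", "not consistent")

    def test_missing_series_gives_indeterminate(self):
        recs = [_rec(s, ch4=90.0) for s in "abc"]
        rep = secondary_methane_indicator(recs)
        assert rep.verdict == "indeterminate"
        assert rep.notes


class TestParams:
    def test_negative_eps_rejected(self):
        with pytest.raises(ValueError):
            RayleighParams(eps_central=-1.0)

    def test_defaults_are_pure_culture_factors(self):
        p = RayleighParams()
        assert (p.eps_central, p.eps_terminal, p.delta0_offset) == (33.0, 3.0, 0.0)
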