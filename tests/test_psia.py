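"""Position-specific reconstruction from pyrolysis fragments."""

import math

import pytest
from hypothesis import given, strategies as st

from mudgas.psia import (
    FragmentMeasurement,
    bulk_from_positions,
    central_delta,
    central_offset,
    linear_sigma_offset,
    positions_from_fragments,
    propagate_uncertainty,
    read_fragment_table,
    terminal_delta,
)
from mudgas.records import BDL, Bdl


def frag(d_ch4=-20.0, a_ch4=1.0, d_c2h4=-20.0, a_c2h4=1.0, d_c2h6=-20.0,
         a_c2h6=0.3, sigma=0.0):
    return FragmentMeasurement(
        "s", a_ch4, d_ch4, a_c2h4, d_c2h4, a_c2h6, d_c2h6,
        sigma_ch4=sigma, sigma_c2h4=sigma, sigma_c2h6=sigma,
    )


class TestTerminalDelta:
    def test_equal_deltas_collapse(self):
        assert terminal_delta(frag(d_ch4=-20.0, a_ch4=1.0, d_c2h6=-20.0, a_c2h6=0.5)) == -20.0

    def test_area_weighted_mean(self):
        f = frag(d_ch4=-22.0, a_ch4=2.0, d_c2h6=-18.0, a_c2h6=1.0)
        assert terminal_delta(f) == pytest.approx((-22.0 * 2 - 18.0 * 1) / 3, abs=1e-12)

    def test_single_fragment_limit(self):
        f = frag(d_ch4=-17.3, a_ch4=1.0, d_c2h6=99.0, a_c2h6=1e-300)
        assert terminal_delta(f) == pytest.approx(-17.3, abs=1e-9)

    def test_zero_areas_rejected_at_construction(self):
        with pytest.raises(ValueError):
            frag(a_ch4=0.0)


class TestCentralDelta:
    @pytest.mark.parametrize(
        "d_c2h4, d_term, expected",
        [
            (-20.0, -20.0, -20.0),  # homogeneous molecule
            (-4.55, -20.3, 11.2),   # algebraic inversion of the G-1 positions
            (0.0, -10.0, 10.0),
        ],
    )
    def test_examples(self, d_c2h4, d_term, expected):
        assert central_delta(d_c2h4, d_term) == pytest.approx(expected, abs=1e-9)


class TestCentralOffset:
    @pytest.mark.parametrize(
        "central, terminal, expected",
        [(11.2, -20.3, 31.5), (18.2, -22.3, 40.5), (-5.0, -5.0, 0.0)],
    )
    def test_examples(self, central, terminal, expected):
        assert central_offset(central, terminal) == pytest.approx(expected, abs=1e-12)

    def test_bdl_propagates(self):
        assert isinstance(central_offset(BDL, -20.0), Bdl)
        assert central_offset(None, -20.0) is None


class TestBulkFromPositions:
    @pytest.mark.parametrize(
        "terminal, central, expected",
        [(-20.3, 11.2, -9.8), (-22.8, 14.4, -10.4), (-7.0, -7.0, -7.0)],
    )
    def test_examples(self, terminal, central, expected):
        assert bulk_from_positions(terminal, central) == pytest.approx(expected, abs=0.05)

    def test_table_consistency_sweep(self, tokamachi):
        """2:1 position mass balance closes on every sample with positions."""
        checked = 0
        for r in tokamachi:
            t = r.isotope_value("d13c_terminal")
            c = r.isotope_value("d13c_central")
            bulk = r.isotope_value("d13c_c3h8")
            if isinstance(t, float) and isinstance(c, float):
                assert abs(bulk_from_positions(t, c) - bulk) <= 0.1
                checked += 1
        assert checked == 6


@given(
    d=st.floats(-60, 60, allow_nan=False),
    t=st.floats(-60, 60, allow_nan=False),
)
def test_offset_identity(d, t):
    """central_offset(central_delta(d, t), t) == 2(d - t) algebraically."""
    assert central_offset(central_delta(d, t), t) == pytest.approx(2 * (d - t), abs=1e-9)


class TestUncertainty:
    def test_zero_sigma_gives_zero_spread(self):
        pos = propagate_uncertainty([frag()], n_draws=500, seed=0)
        assert pos.sigma_offset == 0.0 and pos.sigma_terminal == 0.0
        assert pos.delta_central_offset == 0.0

    def test_monte_carlo_matches_linear_propagation(self):
        f = frag(d_ch4=-20.0, d_c2h4=-5.0, d_c2h6=-20.0, sigma=0.3)
        pos = propagate_uncertainty([f], n_draws=20000, seed=42)
        analytic = linear_sigma_offset(f)
        assert 0.5 <= pos.sigma_offset <= 1.5
        assert pos.sigma_offset == pytest.approx(analytic, rel=0.05)

    def test_identical_replicates_same_mean_as_one(self):
        one = propagate_uncertainty([frag(d_c2h4=-5.0)], n_draws=200, seed=1)
        two = propagate_uncertainty([frag(d_c2h4=-5.0)] * 2, n_draws=200, seed=1)
        assert one.delta_central == pytest.approx(two.delta_central, abs=1e-12)

    def test_deterministic_for_fixed_seed(self):
        f = frag(sigma=0.4, d_c2h4=-10.0)
        a = propagate_uncertainty([f], n_draws=500, seed=9)
        b = propagate_uncertainty([f], n_draws=500, seed=9)
        assert a == b

    def test_seed_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            propagate_uncertainty([frag()], n_draws=500, seed=None)


class TestFragmentTable:
    def test_round_trip_via_csv(self, tmp_path):
        p = tmp_path / "frags.csv"
        p.write_text(
            "sample_id,replicate,area_ch4,d13c_ch4,area_c2h4,d13c_c2h4,"
            "area_c2h6,d13c_c2h6\n"
            "G-1,1,1.0,-20.3,1.0,-4.55,0.3,-20.3\n"
            "G-1,2,1.0,-20.3,1.0,-4.55,0.3,-20.3\n"
        )
        frags = read_fragment_table(p)
        assert set(frags) == {"G-1"} and len(frags["G-1"]) == 2
        pos = positions_from_fragments(frags["G-1"][0])
        assert pos.delta_central_offset == pytest.approx(31.5, abs=1e-9)

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "frags.csv"
        p.write_text("sample_id,area_ch4\nG-1,1.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_fragment_table(p)
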