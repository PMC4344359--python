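import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stillmerge.geometry import Beam, MosaicModel, crystal_from_cell, ewald_offset, reciprocal_vector
from stillmerge.partiality import (
    correct_to_full,
    intersection_radius,
    partiality_mono,
    partiality_poly,
    partiality_record,
    resample_spectrum,
    rlp_radius,
)


class TestRlpRadius:
    def test_zero_spread_is_resolution_independent(self):
        mos = MosaicModel(4000.0, 0.0)
        radii = [rlp_radius(mos, d) for d in (1.5, 3.0, 50.0, 400.0)]
        assert all(r == pytest.approx(1 / 4000.0) for r in radii)

    def test_f000_radius_ignores_angular_term(self):
        mos = MosaicModel(4000.0, math.radians(0.5))
        assert rlp_radius(mos, math.inf) == pytest.approx(1 / 4000.0)

    def test_scalar_oracle(self):
        """Independent one-line re-derivation: size and angular term summed,
        with the fitted thermolysin-like magnitudes (block 4220 Å, 0.168°
        half-width spread) at 2.2 Å."""
        d_eff, eta_half_deg, d = 4220.0, 0.168, 2.2
        eta_full = math.radians(2 * eta_half_deg)
        expected = 1.0 / d_eff + (eta_full / 2.0) / d
        mos = MosaicModel.from_degrees(d_eff, eta_half_deg, half_width=True)
        assert rlp_radius(mos, d) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_resolution(self):
        with pytest.raises(ValueError):
            rlp_radius(MosaicModel(4000.0, 0.0), -1.0)


class TestIntersectionRadius:
    @pytest.mark.parametrize(
        "r_q,dr,expected",
        [
            (5e-4, 0.0, 5e-4),  # great-circle slice
            (5e-4, 5e-4, 0.0),  # tangency
            (5e-4, 3e-4, 4e-4),  # 3-4-5 right triangle
            (5e-4, 7e-4, 0.0),  # beyond the ball
        ],
    )
    def test_right_triangle(self, r_q, dr, expected):
        assert intersection_radius(r_q, dr) == pytest.approx(expected, abs=1e-18)


class TestPartialityMono:
    def test_zero_at_ball_edge(self):
        mos = MosaicModel(4000.0, math.radians(0.2))
        rq = rlp_radius(mos, 2.5)
        assert partiality_mono(mos, 2.5, rq) == 0.0
        assert partiality_mono(mos, 2.5, -rq) == 0.0

    def test_unity_in_zero_spread_limit(self):
        mos = MosaicModel(4000.0, 0.0)
        assert partiality_mono(mos, 2.0, 0.0) == pytest.approx(1.0, rel=1e-14)

    def test_peak_below_one_with_spread(self):
        mos = MosaicModel(4000.0, math.radians(0.2))
        p = partiality_mono(mos, 2.5, 0.0)
        assert 0.0 < p < 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        d=st.floats(1.5, 500.0),
        d_eff=st.floats(500.0, 1e5),
        eta_deg=st.floats(0.0, 1.0),
        frac=st.floats(0.0, 2.0),
    )
    def test_bounded_over_fuzzed_grid(self, d, d_eff, eta_deg, frac):
        mos = MosaicModel(d_eff, math.radians(eta_deg))
        rq = rlp_radius(mos, d)
        p = partiality_mono(mos, d, frac * rq)
        assert 0.0 <= p <= 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        d=st.floats(1.5, 500.0),
        d_eff=st.floats(500.0, 1e5),
        eta_deg=st.floats(0.0, 1.0),
        f1=st.floats(0.0, 1.0),
        f2=st.floats(0.0, 1.0),
    )
    def test_non_increasing_in_offset(self, d, d_eff, eta_deg, f1, f2):
        mos = MosaicModel(d_eff, math.radians(eta_deg))
        rq = rlp_radius(mos, d)
        lo, hi = sorted((f1, f2))
        assert partiality_mono(mos, d, lo * rq) >= partiality_mono(mos, d, hi * rq)

    def test_peak_non_increasing_with_resolution(self):
        mos = MosaicModel(4000.0, math.radians(0.3))
        ds = [50.0, 10.0, 5.0, 2.5, 1.8]
        peaks = [partiality_mono(mos, d, 0.0) for d in ds]
        assert all(a >= b for a, b in zip(peaks, peaks[1:]))
        # and constant when the angular spread vanishes
        mos0 = MosaicModel(4000.0, 0.0)
        peaks0 = [partiality_mono(mos0, d, 0.0) for d in ds]
        assert np.allclose(peaks0, 1.0)

    def test_rejects_infinite_block_size(self):
        with pytest.raises(ValueError):
            partiality_mono(MosaicModel(math.inf, 0.001), 2.5, 0.0)


class TestCapAreaOracle:
    def test_circle_approximates_spherical_cap(self):
        """The flat-circle area pi*r_f^2 must match the exact area of the
        Ewald-sphere cap inside the rlp ball to <= 1% relative, for
        r_q <= 1e-3 1/A at lambda ~ 1.3 A.

        Exact cap: spheres of radius R (Ewald) and r_q with centre
        separation D = R + dr; the portion of the R-sphere inside the ball
        is a cap of height h = R - (D^2 + R^2 - r_q^2)/(2D), area 2*pi*R*h.
        """
        lam = 1.3
        R = 1.0 / lam
        rng = np.random.default_rng(42)
        for _ in range(300):
            r_q = 10 ** rng.uniform(-5, -3)
            dr = rng.uniform(-r_q, r_q) * 0.999
            D = R + dr
            h = R - (D**2 + R**2 - r_q**2) / (2 * D)
            exact = 2 * math.pi * R * h
            approx = math.pi * intersection_radius(r_q, dr) ** 2
            assert approx == pytest.approx(exact, rel=0.01)


@pytest.fixture(scope="module")
def setup():
    mos = MosaicModel(4000.0, math.radians(0.2))
    crystal = crystal_from_cell((55, 60, 70, 90, 90, 90), "P 21 21 21", mos)
    return mos, crystal


class TestPartialityPoly:
    def test_single_line_equals_mono(self, setup):
        mos, crystal = setup
        lam = 1.269
        beam = Beam(lam, spectrum=[(lam, 1.0)])
        hkl = (3, 5, 7)
        q = reciprocal_vector(crystal, hkl)
        dr = ewald_offset(q, beam)
        d = 1.0 / np.linalg.norm(q)
        mono = partiality_mono(mos, d, dr)
        assert partiality_poly(mos, crystal, hkl, beam) == pytest.approx(mono, rel=1e-12)

    def test_two_equal_lines_average(self, setup):
        mos, crystal = setup
        lams = (1.25, 1.29)
        beam = Beam(1.27, spectrum=[(lams[0], 1.0), (lams[1], 1.0)])
        hkl = (3, 5, 7)
        q = reciprocal_vector(crystal, hkl)
        d = 1.0 / np.linalg.norm(q)
        monos = [
            partiality_mono(mos, d, ewald_offset(q, beam, wavelength_override=lam))
            for lam in lams
        ]
        assert partiality_poly(mos, crystal, hkl, beam) == pytest.approx(
            np.mean(monos), rel=1e-12
        )

    def test_weight_normalisation_invariance(self, setup):
        mos, crystal = setup
        spec = [(1.25, 0.2), (1.27, 0.5), (1.29, 0.3)]
        beam1 = Beam(1.27, spectrum=spec)
        beam7 = Beam(1.27, spectrum=[(l, 7 * w) for l, w in spec])
        hkl = (2, -4, 6)
        assert partiality_poly(mos, crystal, hkl, beam1) == pytest.approx(
            partiality_poly(mos, crystal, hkl, beam7), rel=1e-14
        )

    def test_requires_spectrum(self, setup):
        mos, crystal = setup
        with pytest.raises(ValueError, match="spectrum"):
            partiality_poly(mos, crystal, (1, 0, 0), Beam(1.27))

    def test_all_zero_weights_rejected_at_construction(self):
        with pytest.raises(ValueError):
            Beam(1.27, spectrum=[(1.25, 0.0), (1.29, 0.0)])

    def test_resample_conserves_weight(self):
        rng = np.random.default_rng(3)
        lam = np.linspace(1.25, 1.29, 2000)
        w = rng.random(2000)
        out = resample_spectrum(np.column_stack([lam, w]), max_points=100)
        assert len(out) <= 100
        assert out[:, 1].sum() == pytest.approx(w.sum(), rel=1e-12)


class TestCorrectToFull:
    def test_half_partiality_doubles(self):
        i_full, s_full, ok = correct_to_full(100.0, 10.0, 0.5)
        assert ok and i_full == pytest.approx(200.0) and s_full == pytest.approx(20.0)

    def test_unit_partiality_identity(self):
        i_full, s_full, ok = correct_to_full(100.0, 10.0, 1.0)
        assert ok and i_full == 100.0 and s_full == 10.0

    def test_geometric_rejection(self):
        i_full, s_full, ok = correct_to_full(100.0, 10.0, 0.4, accepted=False)
        assert not ok and math.isnan(i_full)

    def test_partiality_floor(self):
        _, _, ok = correct_to_full(100.0, 10.0, 0.05, p_min=0.1)
        assert not ok

    def test_record_acceptance_matches_offset(self):
        mos = MosaicModel(4000.0, math.radians(0.2))
        crystal = crystal_from_cell((55, 60, 70, 90, 90, 90), "P 21 21 21", mos)
        beam = Beam(1.269)
        rec = partiality_record(crystal, beam, (1, 2, 10))
        assert rec.accepted == (abs(rec.delta_r) <= rec.r_q)
        assert rec.r_f == pytest.approx(
            math.sqrt(max(0.0, rec.r_q**2 - rec.delta_r**2))
        )
        assert rec.r_q >= rec.r_zero > 0
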