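"""Unit and property tests for the analytical diffusion evaluators."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import erfc

from embryodose.diffusion import (
    conc_box,
    conc_point_1d,
    conc_profile,
    conc_strip,
    uncertainty_band,
)
from embryodose.medium import (
    Calibration,
    ExposurePoint,
    MediumProperties,
    SourceSpec,
    agar_block,
    make_effective_medium,
    source_concentration,
)


class TestSourceConcentration:
    @pytest.mark.parametrize(
        "vol_ul, molarity, dims_mm, expected",
        [
            (3.0, 1e-3, (2, 2, 3), 2.5e-4),
            (2.0, 0.1, (2, 2, 3), 1.6667e-2),
            (0.0, 0.5, (2, 2, 3), 0.0),
        ],
    )
    def test_volumetric_rule(self, vol_ul, molarity, dims_mm, expected):
        """c0 is injected moles over block volume (average volumetric conc)."""
        src = agar_block(dims_mm, vol_ul, molarity)
        assert src.c0 == pytest.approx(expected, rel=1e-4)

    def test_calibration_conventions(self):
        vol = agar_block((2, 2, 3), 3.0, 1e-3, Calibration.VOLUMETRIC)
        dil = agar_block((2, 2, 3), 3.0, 1e-3, Calibration.DILUTED)
        soak = agar_block((2, 2, 3), 3.0, 1e-3, Calibration.SOAK)
        assert vol.c0 == pytest.approx(2.5e-4)
        assert dil.c0 == pytest.approx(2.0e-4)  # moles / (12 + 3) uL
        assert soak.c0 == pytest.approx(1e-3)

    def test_zero_block_volume_rejected(self):
        with pytest.raises(ValueError):
            source_concentration(3e-3, 1e-3, (0.0, 0.2, 0.3))


class TestEffectiveMedium:
    def test_identity_at_r1(self):
        m = MediumProperties.isotropic(6e-6, lam=0.0, R=1.0)
        assert make_effective_medium(m) is m

    def test_division_by_r(self):
        m = MediumProperties.isotropic(6e-6, lam=2e-5, R=2.0)
        eff = make_effective_medium(m)
        assert eff.Dx == pytest.approx(3e-6)
        assert eff.lam == pytest.approx(1e-5)
        assert eff.R == 1.0

    def test_retardation_fold_equivalence_is_exact(self, at_source):
        """Strip solutions for (D, lam, R) and (D/R, lam/R, 1) are identical."""
        retarded = MediumProperties.isotropic(6e-6, lam=1e-5, R=2.5)
        effective = MediumProperties.isotropic(6e-6 / 2.5, lam=1e-5 / 2.5, R=1.0)
        rng = np.random.default_rng(42)
        for _ in range(10):
            pt = ExposurePoint(
                x=rng.uniform(0.01, 0.8),
                y=rng.uniform(-0.5, 0.5),
                t=rng.uniform(60, 3600 * 10),
            )
            a = conc_strip(pt, retarded, at_source)
            b = conc_strip(pt, effective, at_source)
            assert a == b


class TestPoint1D:
    def test_boundary_value(self, medium):
        assert conc_point_1d(0.0, 3600.0, medium, 2.5e-4) == pytest.approx(2.5e-4)

    def test_initially_zero_away_from_source(self, medium):
        assert conc_point_1d(0.2, 0.0, medium, 2.5e-4) == 0.0
        assert conc_point_1d(0.2, 1e-6, medium, 2.5e-4) < 1e-30

    def test_reference_value_2mm_2h(self, medium):
        """erfc(x / 2 sqrt(D t)) evaluated independently at 2 mm, 2 h."""
        expected = 2.5e-4 * erfc(0.2 / (2.0 * math.sqrt(6e-6 * 7200.0)))
        assert expected == pytest.approx(1.2406e-4, rel=1e-3)  # frozen
        assert conc_point_1d(0.2, 7200.0, medium, 2.5e-4) == pytest.approx(expected)

    def test_negative_arguments_rejected(self, medium):
        with pytest.raises(ValueError):
            conc_point_1d(-0.1, 100.0, medium, 1e-4)
        with pytest.raises(ValueError):
            conc_point_1d(0.1, -100.0, medium, 1e-4)

    def test_decay_closed_form_matches_kernel_quadrature(self):
        """The two-term erfc decay form equals the decay-weighted Duhamel
        integral (evaluated via the wide-strip quadrature) to 1e-6."""
        lam_medium = MediumProperties.isotropic(6e-6, lam=5e-5)
        wide = agar_block((2, 2000.0, 3), 3.0, 1e-3)
        for x, t in [(0.05, 1800.0), (0.2, 7200.0), (0.4, 36000.0)]:
            closed = conc_point_1d(x, t, lam_medium, wide.c0)
            quadrature = conc_strip(ExposurePoint(x=x, t=t), lam_medium, wide)
            assert quadrature == pytest.approx(closed, rel=1e-6)


class TestStrip:
    @given(
        x=st.floats(0.01, 0.8),
        y=st.floats(0.0, 0.6),
        t=st.floats(100.0, 1e5),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_y_symmetry(self, x, y, t):
        """The kernel is even in y about the source centreline."""
        medium = MediumProperties.isotropic(6e-6)
        src = agar_block()
        up = conc_strip(ExposurePoint(x=x, y=y, t=t), medium, src)
        down = conc_strip(ExposurePoint(x=x, y=-y, t=t), medium, src)
        assert up == down

    def test_wide_strip_reduces_to_1d(self, medium):
        """Ly >= 20 sqrt(D t): strip equals the erfc closed form to 1e-6."""
        t = 7200.0
        Ly = 20.0 * math.sqrt(6e-6 * t)
        src = SourceSpec(Ly=Ly, c0=2.5e-4)
        for x in (0.05, 0.2, 0.5):
            strip = conc_strip(ExposurePoint(x=x, t=t), medium, src)
            oned = conc_point_1d(x, t, medium, src.c0)
            assert strip == pytest.approx(oned, rel=1e-6)

    def test_zero_at_t0_and_boundary_value(self, medium, at_source):
        assert conc_strip(ExposurePoint(x=0.3, t=0.0), medium, at_source) == 0.0
        on_face = conc_strip(ExposurePoint(x=0.0, y=0.05, t=100.0), medium, at_source)
        assert on_face == at_source.c0

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_homogeneity_in_c0(self, scale):
        """Concentration is linear in the boundary value to 1e-12 relative."""
        medium = MediumProperties.isotropic(6e-6)
        base = agar_block()
        scaled = replace(base, c0=base.c0 * scale)
        pt = ExposurePoint(x=0.15, y=0.03, t=5000.0)
        a = conc_strip(pt, medium, base)
        b = conc_strip(pt, medium, scaled)
        assert b == pytest.approx(scale * a, rel=1e-12)

    def test_maximum_principle_random_points(self, medium, at_source):
        """0 <= c <= c0 over 1000 random space-time points."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            pt = ExposurePoint(
                x=rng.uniform(0.0, 1.0),
                y=rng.uniform(-1.0, 1.0),
                t=rng.uniform(0.0, 3600.0 * 30),
            )
            c = conc_strip(pt, medium, at_source)
            assert 0.0 <= c <= at_source.c0 * (1 + 1e-12)

    def test_monotone_in_time_and_distance(self, medium, at_source):
        """No decay, constant source: c grows in t and falls along the axis."""
        times = [600.0 * k for k in range(1, 20)]
        on_axis = [
            conc_strip(ExposurePoint(x=0.2, t=t), medium, at_source) for t in times
        ]
        assert all(b >= a for a, b in zip(on_axis, on_axis[1:]))
        xs = np.linspace(0.05, 1.0, 15)
        along = [
            conc_strip(ExposurePoint(x=float(x), t=7200.0), medium, at_source)
            for x in xs
        ]
        assert all(b <= a for a, b in zip(along, along[1:]))


class TestBox:
    BOX = SourceSpec(x0=0.2, y1=-0.1, y2=0.1, z1=-0.05, z2=0.05, c0=0.0)

    def test_zero_at_t0(self, medium):
        assert conc_box(ExposurePoint(x=0.1, t=0.0), medium, self.BOX, r0=1e-7) == 0.0

    def test_reflection_symmetry(self, medium):
        """Reflecting the probe and the box together through an axis leaves c unchanged."""
        r0 = 1e-7
        asym = SourceSpec(x0=0.2, y1=0.02, y2=0.1, z1=-0.05, z2=0.05, c0=0.0)
        mirrored = SourceSpec(x0=0.2, y1=-0.1, y2=-0.02, z1=-0.05, z2=0.05, c0=0.0)
        pt = ExposurePoint(x=0.3, y=0.12, z=0.02, t=1800.0)
        flipped = ExposurePoint(x=pt.x, y=-pt.y, z=pt.z, t=pt.t)
        assert conc_box(pt, medium, asym, r0=r0) == conc_box(
            flipped, medium, mirrored, r0=r0
        )
        # the y-symmetric default box is even in y at the probe
        sym_pt = ExposurePoint(x=pt.x, y=-pt.y, z=pt.z, t=pt.t)
        assert conc_box(pt, medium, self.BOX, r0=r0) == conc_box(
            sym_pt, medium, self.BOX, r0=r0
        )

    def test_nonnegative(self, medium):
        rng = np.random.default_rng(3)
        for _ in range(50):
            pt = ExposurePoint(
                x=rng.uniform(-0.4, 0.6),
                y=rng.uniform(-0.4, 0.4),
                z=rng.uniform(-0.2, 0.2),
                t=rng.uniform(0.0, 7200.0),
            )
            assert conc_box(pt, medium, self.BOX, r0=1e-7) >= 0.0


class TestUncertaintyBand:
    def test_degenerate_without_uncertainty(self, medium, at_source):
        pt = ExposurePoint(x=0.2, t=7200.0)
        lo, mid, hi = uncertainty_band(
            lambda m: conc_strip(pt, m, at_source), medium
        )
        assert lo == mid == hi

    def test_band_contains_mid(self, medium_band, at_source):
        rng = np.random.default_rng(11)
        for _ in range(20):
            pt = ExposurePoint(x=rng.uniform(0.05, 0.8), t=rng.uniform(600, 1e5))
            lo, mid, hi = uncertainty_band(
                lambda m, _p=pt: conc_strip(_p, m, at_source), medium_band
            )
            assert lo <= mid <= hi

    def test_sigma_larger_than_d_rejected(self, at_source):
        bad = MediumProperties.isotropic(6e-6, sigma_D=5.9e-6)
        over = replace(bad, sigma_D=6e-6)
        pt = ExposurePoint(x=0.2, t=7200.0)
        uncertainty_band(lambda m: conc_strip(pt, m, at_source), bad)  # ok
        with pytest.raises(ValueError):
            uncertainty_band(lambda m: conc_strip(pt, m, at_source), over)

    def test_halfband_order_of_magnitude_at_head(self, at_source_calibrated):
        """At 2 mm / 2 h the D band half-width is of order 1e-5 M."""
        medium = MediumProperties.isotropic(6e-6, sigma_D=3e-6)
        pt = ExposurePoint(x=0.2, t=7200.0)
        lo, mid, hi = uncertainty_band(
            lambda m: conc_point_1d(pt.x, pt.t, m, at_source_calibrated.c0), medium
        )
        half = 0.5 * (hi - lo)
        assert 1e-6 < half < 1e-4


class TestProfile:
    def test_single_point_single_time(self, medium, at_source):
        table = conc_profile([(2.0, 0.0)], [2.0], medium, at_source)
        assert len(table) == 1
        row = table.iloc[0]
        direct = conc_strip(ExposurePoint(x=0.2, t=7200.0), medium, at_source)
        assert row.conc_M == pytest.approx(direct)
        assert row.conc_lo_M == row.conc_M == row.conc_hi_M

    def test_profile_shape_and_monotonicity(self, medium_band, at_source):
        table = conc_profile(
            [(2.0, 0.0), (5.0, 0.0)], [1.0, 2.0, 4.0, 8.0], medium_band, at_source
        )
        assert len(table) == 8
        assert (table.conc_lo_M <= table.conc_M).all()
        assert (table.conc_M <= table.conc_hi_M).all()
        near = table[table.x_mm == 2.0].sort_values("time_h").conc_M.to_numpy()
        far = table[table.x_mm == 5.0].sort_values("time_h").conc_M.to_numpy()
        assert (np.diff(near) >= 0).all()  # grows in time at fixed point
        assert (far <= near).all()  # decays with distance at fixed time

    def test_empty_inputs_rejected(self, medium, at_source):
        with pytest.raises(ValueError):
            conc_profile([], [1.0], medium, at_source)
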