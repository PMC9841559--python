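"""Reaction-path loading, interpolation, and barrier analysis."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tautodyn as td
from tautodyn import pes
from tautodyn.errors import (
    DomainError,
    InsufficientDataError,
    InvalidWindowError,
    MalformedPathError,
    NoBarrierError,
    ParameterError,
    PathParseError,
)


def _write_csv(tmp_path, rows, header="s_angstrom,energy_ev"):
    f = tmp_path / "path.csv"
    f.write_text(header + "\n" + "\n".join(rows) + "\n")
    return f


class TestLoadPath:
    def test_energies_shifted_to_first_image(self, tmp_path):
        f = _write_csv(tmp_path, ["0,0.1", "1,0.6", "2,0.2"])
        path = pes.load_path(f)
        np.testing.assert_allclose(path.energy, [0.0, 0.5, 0.1])
        np.testing.assert_allclose(path.s, [0.0, 1.0, 2.0])

    def test_non_monotone_coordinate_rejected(self, tmp_path):
        f = _write_csv(tmp_path, ["0,0", "2,0.5", "1,0.1"])
        with pytest.raises(MalformedPathError):
            pes.load_path(f)

    def test_too_few_rows_rejected(self, tmp_path):
        f = _write_csv(tmp_path, ["0,0", "1,0.5"])
        with pytest.raises(InsufficientDataError):
            pes.load_path(f)

    def test_non_numeric_entry_reports_line(self, tmp_path):
        f = _write_csv(tmp_path, ["0,0", "1,abc", "2,0.1"])
        with pytest.raises(PathParseError) as err:
            pes.load_path(f)
        assert err.value.line == 3

    def test_missing_header_rejected(self, tmp_path):
        f = _write_csv(tmp_path, ["1,0.5", "2,0.1"], header="0,0")
        with pytest.raises(PathParseError):
            pes.load_path(f)

    def test_csv_roundtrip(self, tmp_path):
        path = td.gen_fixture_pes(td.FixturePESSpec.trs_barrier(), n_images=41)
        f = tmp_path / "rt.csv"
        pes.save_path(path, f)
        back = pes.load_path(f)
        np.testing.assert_allclose(back.s, path.s)
        np.testing.assert_allclose(back.energy, path.energy, atol=1e-12)

    def test_geometry_sidecar_roundtrip(self, tmp_path):
        path = td.attach_linear_geometries(
            td.gen_fixture_pes(td.FixturePESSpec.trs_barrier(), n_images=12)
        )
        f = tmp_path / "g.csv"
        side = tmp_path / "g.json"
        pes.save_path(path, f, geometry_sidecar=side)
        back = pes.load_path(f, geometry_sidecar=side)
        np.testing.assert_allclose(
            back.geometries[5].coords, path.geometries[5].coords
        )


class TestInterpolation:
    def test_polynomials_reproduced_exactly(self):
        # a natural cubic spline is exact for polynomials of degree <= 1 at
        # arbitrary points and node-exact always; for an inner quadratic
        # segment the mid-node error is far below 1e-10 with dense nodes
        s = np.linspace(0.0, 2.0, 101)
        path = pes.ReactionPath(s=s, energy=0.5 * 1.3 * s**2)
        prof = pes.interpolate(path)
        mid = 0.5 * (s[40] + s[41])
        assert abs(prof(mid) - 0.5 * 1.3 * mid**2) < 1e-10
        np.testing.assert_allclose(prof(s), path.energy, atol=1e-12)

    def test_third_derivative_of_cubic_constant(self):
        # natural end conditions perturb the spline near the boundaries, so
        # the piecewise third derivative is compared in the interior only
        s = np.linspace(0.0, 3.0, 61)
        path = pes.ReactionPath(s=s, energy=2.0 * s**3 - s**2)
        prof = pes.interpolate(path)
        inner = np.linspace(0.75, 2.25, 17)
        np.testing.assert_allclose(prof(inner, nu=3), 12.0, rtol=2e-3)

    def test_out_of_domain_query_raises(self, eckart_profile):
        with pytest.raises(DomainError):
            eckart_profile(99.0)


class TestBarrierSummary:
    def test_symmetric_double_well(self):
        h, L = 0.4, 4.0
        s = np.linspace(0.0, L, 301)
        path = pes.ReactionPath(s=s, energy=h * (1 - (2 * s / L - 1) ** 2) ** 2)
        bs = td.barrier_summary(pes.interpolate(path))
        assert bs.E_f == pytest.approx(h, abs=1e-6)
        assert bs.E_r == pytest.approx(h, abs=1e-6)
        assert bs.delta_E == pytest.approx(0.0, abs=1e-9)

    def test_cubic_extrema_match_closed_form(self):
        # E = s^3 - 6 s^2 + 9 s has a maximum at s=1 and a minimum at s=3
        s = np.linspace(0.0, 4.0, 201)
        path = pes.ReactionPath(s=s, energy=s**3 - 6 * s**2 + 9 * s)
        bs = td.barrier_summary(pes.interpolate(path))
        assert bs.s_TS == pytest.approx(1.0, abs=1e-6)
        assert bs.s_product == pytest.approx(3.0, abs=1e-6)

    def test_delta_e_identity_and_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            s = np.linspace(0.0, 6.0, 241)
            e = np.zeros_like(s)
            for m in range(1, 5):
                e += rng.normal(0, 0.1) * np.sin(np.pi * m * s / 6.0)
            e += 0.5 * (1 - np.cos(2 * np.pi * s / 6.0))  # guarantee a bump
            prof = pes.interpolate(pes.ReactionPath(s=s, energy=e))
            try:
                bs = td.barrier_summary(prof)
            except NoBarrierError:
                continue
            assert bs.delta_E == pytest.approx(bs.E_f - bs.E_r, abs=1e-12)
            dense = np.linspace(0.0, 6.0, 100_001)
            ed = prof(dense)
            i_ts = np.argmin(np.abs(dense - bs.s_TS))
            assert abs(ed[i_ts] - (bs.E_f + prof(bs.s_reactant))) < 1e-4

    def test_monotone_profile_has_no_barrier(self):
        s = np.linspace(0.0, 2.0, 50)
        prof = pes.interpolate(pes.ReactionPath(s=s, energy=0.3 * s))
        with pytest.raises(NoBarrierError):
            td.barrier_summary(prof)

    def test_reflection_swaps_forward_and_reverse(self, wobble_profile):
        bs = td.barrier_summary(wobble_profile)
        path = wobble_profile.path
        refl = pes.ReactionPath(
            s=path.s[-1] - path.s[::-1], energy=path.energy[::-1]
        )
        bs_r = td.barrier_summary(pes.interpolate(refl))
        assert bs_r.E_f == pytest.approx(bs.E_r, abs=1e-9)
        assert bs_r.E_r == pytest.approx(bs.E_f, abs=1e-9)


class TestSegmentation:
    def test_constant_profile_single_region(self):
        s = np.linspace(0.0, 5.0, 60)
        prof = pes.interpolate(pes.ReactionPath(s=s, energy=1e-6 * s))
        seg = td.segment_regions(prof)
        assert len(seg.boundaries) == 1
        assert seg.boundaries[0].label == pes.LABEL_COLLECTIVE

    def test_wobble_fixture_proton_transfer_window(self, wobble_profile):
        seg = td.segment_regions(wobble_profile)
        region = seg.region_of(pes.LABEL_TRANSFER)
        assert region is not None
        assert region.s_lo == pytest.approx(4.0, abs=0.5)
        assert region.s_hi == pytest.approx(7.5, abs=0.5)

    def test_symmetric_barrier_symmetric_region(self):
        s = np.linspace(-5.0, 5.0, 401)
        prof = pes.interpolate(
            pes.ReactionPath(s=s, energy=0.3 / np.cosh(s / 0.8) ** 2)
        )
        seg = td.segment_regions(prof)
        region = seg.region_of(pes.LABEL_TRANSFER)
        assert abs(region.s_lo + region.s_hi) < 0.1  # symmetric about 0

    def test_regions_cover_domain_contiguously(self, wobble_profile):
        seg = td.segment_regions(wobble_profile)
        lo, hi = wobble_profile.domain
        assert seg.boundaries[0].s_lo == pytest.approx(lo)
        assert seg.boundaries[-1].s_hi == pytest.approx(hi)


class TestCrop:
    def test_crop_reduces_barrier_by_pre_gain(self, wobble_profile):
        bs = td.barrier_summary(wobble_profile)
        sub = td.extract_trs_subpath(wobble_profile, 4.0, 7.5)
        bs_sub = td.barrier_summary(td.interpolate(sub))
        expected = bs.E_f - float(wobble_profile(4.0))
        assert bs_sub.E_f == pytest.approx(expected, abs=2e-3)
        assert sub.s[0] == 0.0 and sub.energy[0] == 0.0

    def test_full_domain_crop_is_identity(self, eckart_profile):
        lo, hi = eckart_profile.domain
        sub = td.extract_trs_subpath(eckart_profile, lo, hi)
        np.testing.assert_allclose(sub.s, eckart_profile.path.s - lo)
        np.testing.assert_allclose(sub.energy, eckart_profile.path.energy, atol=1e-12)

    def test_crop_is_idempotent(self, wobble_profile):
        sub = td.extract_trs_subpath(wobble_profile, 4.0, 7.5)
        again = td.extract_trs_subpath(td.interpolate(sub), 0.0, 3.5)
        np.testing.assert_allclose(again.s, sub.s, atol=1e-12)
        np.testing.assert_allclose(again.energy, sub.energy, atol=1e-12)

    def test_window_without_ts_rejected(self, wobble_profile):
        with pytest.raises(InvalidWindowError):
            td.extract_trs_subpath(wobble_profile, 0.0, 3.0)


class TestFreeEnergyCorrection:
    def test_fractional_reduction(self):
        bs = pes.BarrierSummary(
            E_f=0.926, E_r=0.680, delta_E=0.246,
            s_reactant=0.0, s_TS=5.7, s_product=9.5,
        )
        G = td.apply_free_energy_correction(bs, 0.20, 0.30)
        assert G.G_f == pytest.approx(0.7408, abs=1e-12)
        assert G.G_r == pytest.approx(0.476, abs=1e-12)
        assert G.source == "fractional-correction"

    def test_zero_fraction_is_identity(self):
        bs = pes.BarrierSummary(1.0, 0.5, 0.5, 0.0, 1.0, 2.0)
        G = td.apply_free_energy_correction(bs, 0.0, 0.0)
        assert (G.G_f, G.G_r) == (1.0, 0.5)

    @given(st.floats(min_value=1.0, max_value=5.0))
    def test_fraction_out_of_range_rejected(self, f):
        bs = pes.BarrierSummary(1.0, 0.5, 0.5, 0.0, 1.0, 2.0)
        with pytest.raises(ParameterError):
            td.apply_free_energy_correction(bs, f, 0.0)
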