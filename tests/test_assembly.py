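"""Self-consistency engine: missing-angle correction, inelastic residual,
resonance extraction and the vibrational/electronic partition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eltrack import assembly, fixtures, xs
from eltrack.errors import ConfigError, DomainError, InsufficientDataError


class TestMissingAngleCorrection:
    def test_isotropic_half_sphere_gives_half_sigma(self):
        sigma = 7.3
        geom = assembly.AcceptanceGeometry(theta_acc_deg=89.9999999)
        got = assembly.missing_angle_correction(
            lambda th: sigma / (4 * np.pi), geom)
        assert got == pytest.approx(sigma / 2, rel=1e-6)

    def test_zero_acceptance_angle_gives_zero(self):
        geom = assembly.AcceptanceGeometry(theta_acc_deg=0.0)
        assert assembly.missing_angle_correction(lambda th: 1.0, geom) == 0.0

    def test_cos_squared_closed_form(self):
        # 2 pi c int_0^{60 deg} cos^2 sin dtheta = 2 pi c (1 - cos^3 60)/3
        c = 2.5
        geom = assembly.AcceptanceGeometry(theta_acc_deg=60.0)
        got = assembly.missing_angle_correction(
            lambda th: c * np.cos(np.radians(th)) ** 2, geom)
        assert got == pytest.approx(2 * np.pi * c * (7 / 24), rel=1e-6)

    def test_backward_cone_adds_symmetric_contribution(self):
        geom = assembly.AcceptanceGeometry(theta_acc_deg=30.0,
                                           theta_back_deg=150.0)
        iso = lambda th: 1.0 / (4 * np.pi)  # noqa: E731
        got = assembly.missing_angle_correction(iso, geom)
        forward_only = assembly.missing_angle_correction(
            iso, assembly.AcceptanceGeometry(theta_acc_deg=30.0))
        assert got == pytest.approx(2 * forward_only, rel=1e-9)

    def test_negative_dcs_rejected(self):
        geom = assembly.AcceptanceGeometry(theta_acc_deg=30.0)
        with pytest.raises(DomainError):
            assembly.missing_angle_correction(lambda th: -1.0, geom)


class TestTotalInelastic:
    def test_reference_minus_elastic_at_20_ev(self, tcs_set, recommended_set):
        out = assembly.derive_total_inelastic(
            tcs_set[xs.Channel.TCS_REFERENCE],
            recommended_set[xs.Channel.ELASTIC])
        i = int(np.flatnonzero(out.energies == 20.0)[0])
        assert out.values[i] == pytest.approx(73.18 - 54.9, abs=1e-9)

    def test_identical_tables_give_zero(self, recommended_set):
        elastic = recommended_set[xs.Channel.ELASTIC]
        ref = xs.ChannelTable(channel=xs.Channel.TCS_REFERENCE,
                              energies=elastic.energies,
                              values=elastic.values)
        out = assembly.derive_total_inelastic(ref, elastic)
        assert np.all(out.values == 0.0)

    def test_negative_differences_clamped(self, caplog):
        e = np.array([1.0, 2.0, 4.0])
        ref = xs.ChannelTable(channel=xs.Channel.TCS_REFERENCE, energies=e,
                              values=np.array([10.0, 10.0, 10.0]))
        ela = xs.ChannelTable(channel=xs.Channel.ELASTIC, energies=e,
                              values=np.array([8.0, 11.0, 9.0]))
        with caplog.at_level("WARNING"):
            out = assembly.derive_total_inelastic(ref, ela)
        assert out.values[1] == 0.0
        assert out.values[0] == pytest.approx(2.0)
        assert any("clamping" in r.message for r in caplog.records)


class TestResonanceExtraction:
    GRID = np.geomspace(0.5, 15.0, 60)

    def test_recovers_center_and_area_of_synthetic_resonance(self):
        curve, truth = fixtures.make_resonance_curve(
            self.GRID, (40.0, 50.0), [(2.0, 0.2, 30.0)])
        dec = assembly.extract_resonances(curve)
        real = [p for p in dec.peaks if not p[2]]
        assert len(real) == 1
        center = real[0][0]
        spacing = self.GRID[np.searchsorted(self.GRID, 2.0)] \
            - self.GRID[np.searchsorted(self.GRID, 2.0) - 1]
        assert abs(center - 2.0) <= spacing
        recovered = np.trapezoid(dec.attachment.values, self.GRID)
        expected = np.trapezoid(truth.peaks_total, self.GRID)
        assert recovered == pytest.approx(expected, rel=0.05)

    def test_two_overlapping_resonances_resolved(self):
        curve, truth = fixtures.make_resonance_curve(
            self.GRID, (40.0, 50.0),
            [(2.0, 0.2, 30.0), (6.0, 0.5, 15.0)], shape="gaussian")
        dec = assembly.extract_resonances(curve)
        centers = sorted(p[0] for p in dec.peaks if not p[2])
        assert len(centers) == 2
        assert abs(centers[0] - 2.0) < 0.2 and abs(centers[1] - 6.0) < 0.5
        # overlapping structures share background support, so the area
        # check is looser than the isolated-peak case
        recovered = np.trapezoid(dec.attachment.values, self.GRID)
        expected = np.trapezoid(truth.peaks_total, self.GRID)
        assert recovered == pytest.approx(expected, rel=0.10)

    def test_smooth_curve_yields_zero_attachment(self):
        curve, _ = fixtures.make_resonance_curve(self.GRID, (40.0, 50.0), [])
        dec = assembly.extract_resonances(curve)
        assert dec.peaks == ()
        assert np.all(dec.attachment.values == 0.0)

    def test_idempotent_on_own_background(self):
        curve, _ = fixtures.make_resonance_curve(
            self.GRID, (40.0, 50.0), [(2.0, 0.2, 30.0)])
        dec = assembly.extract_resonances(curve)
        again = assembly.extract_resonances(dec.background)
        assert np.all(again.attachment.values == 0.0)

    def test_peak_above_cutoff_flagged_pseudo_and_zeroed(self):
        curve, _ = fixtures.make_resonance_curve(
            self.GRID, (40.0, 50.0), [(12.0, 0.5, 20.0)])
        dec = assembly.extract_resonances(curve, pseudo_cutoff=10.0)
        assert len(dec.peaks) == 1
        center, _height, flagged = dec.peaks[0]
        assert flagged and center > 10.0
        assert np.all(dec.attachment.values[self.GRID > 10.0] == 0.0)

    def test_background_plus_attachment_reproduces_curve(self):
        curve, _ = fixtures.make_resonance_curve(
            self.GRID, (40.0, 50.0), [(2.0, 0.2, 30.0)])
        dec = assembly.extract_resonances(curve)
        rebuilt = dec.background.values + dec.attachment.values
        # exact wherever the curve exceeds the background and the excess is
        # kept (below the pseudo-resonance cutoff, where it is not zeroed)
        above = (curve.values >= dec.background.values) & (self.GRID <= 10.0)
        assert np.allclose(rebuilt[above], curve.values[above], rtol=1e-12)
        # elsewhere the mismatch is bounded by the fit scatter
        assert np.all(np.abs(rebuilt - curve.values)
                      <= 0.05 * curve.values + 1e-9)

    def test_too_few_points_rejected(self):
        curve, _ = fixtures.make_resonance_curve(
            np.array([1.0, 2.0, 3.0, 4.0, 5.0]), (40.0, 50.0), [])
        with pytest.raises(InsufficientDataError):
            assembly.extract_resonances(curve)


class TestPartition:
    def test_calibrated_weights_reproduce_published_columns(
            self, recommended_set):
        vib = recommended_set[xs.Channel.VIBRATIONAL]
        ele = recommended_set[xs.Channel.ELECTRONIC]
        spec = assembly.calibrate_partition(vib, ele)
        # vibrational-only energy: 2 eV row
        residual_2 = xs.ChannelTable(channel=xs.Channel.TOTAL_INELASTIC,
                                     energies=np.array([2.0]),
                                     values=np.array([20.3]))
        v, e = assembly.partition_inelastic(residual_2, spec)
        assert v.values[0] == pytest.approx(20.3)
        assert e.values[0] == 0.0
        # electronic-only energy: 20 eV row
        residual_20 = xs.ChannelTable(channel=xs.Channel.TOTAL_INELASTIC,
                                      energies=np.array([20.0]),
                                      values=np.array([15.2]))
        v, e = assembly.partition_inelastic(residual_20, spec)
        assert e.values[0] == pytest.approx(15.2)
        assert v.values[0] == 0.0

    def test_zero_residual_gives_zero_channels(self):
        spec = assembly.PartitionSpec()
        residual = xs.ChannelTable(channel=xs.Channel.TOTAL_INELASTIC,
                                   energies=np.array([1.0, 5.0, 20.0]),
                                   values=np.zeros(3))
        v, e = assembly.partition_inelastic(residual, spec)
        assert np.all(v.values == 0.0) and np.all(e.values == 0.0)

    def test_weight_outside_unit_interval_rejected(self):
        with pytest.raises(ConfigError):
            assembly.PartitionSpec(anchor_energies=np.array([5.0]),
                                   anchor_weights=np.array([1.2]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 100.0), min_size=3, max_size=8),
           st.floats(0.0, 1.0))
    def test_partition_conserves_residual_exactly(self, values, weight):
        energies = np.geomspace(5.0, 100.0, len(values))
        residual = xs.ChannelTable(channel=xs.Channel.TOTAL_INELASTIC,
                                   energies=energies,
                                   values=np.array(values))
        spec = assembly.PartitionSpec(anchor_energies=np.array([5.0, 100.0]),
                                      anchor_weights=np.array([weight, weight]))
        v, e = assembly.partition_inelastic(residual, spec)
        # vibrational is defined as residual minus electronic, so the sum
        # reconstructs the residual to within one rounding unit
        np.testing.assert_allclose(v.values + e.values, residual.values,
                                   rtol=4e-16, atol=0.0)
        assert np.array_equal(v.values, residual.values - e.values)
        assert np.all(v.values >= 0.0) and np.all(e.values >= 0.0)


def test_end_to_end_reconstruction_of_published_partition(
        tcs_set, recommended_set):
    """Reference TCS+MA minus elastic, ionization and attachment, split with
    the calibrated weights, reproduces the published vibrational and
    electronic columns within 0.15e-20 m^2 on the energies where the
    reference table has exact rows (up to 150 eV; beyond that the printed
    reference and the recommended sums disagree at the 0.2-0.4 level, and
    the 70 eV row is the known anomaly)."""
    ref = tcs_set[xs.Channel.TCS_REFERENCE]
    spec = assembly.calibrate_partition(
        recommended_set[xs.Channel.VIBRATIONAL],
        recommended_set[xs.Channel.ELECTRONIC])
    for e in [1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 7.0, 10.0, 20.0, 30.0,
              40.0, 50.0, 100.0, 150.0]:
        residual = (xs.interpolate(ref, e)
                    - xs.interpolate(recommended_set[xs.Channel.ELASTIC], e)
                    - xs.interpolate(recommended_set[xs.Channel.IONIZATION], e)
                    - xs.interpolate(recommended_set[xs.Channel.ATTACHMENT], e))
        residual = max(residual, 0.0)
        w = spec.electronic_weight(e)
        assert w * residual == pytest.approx(
            xs.interpolate(recommended_set[xs.Channel.ELECTRONIC], e), abs=0.15)
        assert (1 - w) * residual == pytest.approx(
            xs.interpolate(recommended_set[xs.Channel.VIBRATIONAL], e), abs=0.15)
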