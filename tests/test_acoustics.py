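"""Ring geometry, pulses, Born synthesis and the FDTD cross-check."""

import numpy as np
import pytest

from ringtomo.phantoms import AcousticMap, ScattererCloud
from ringtomo.acoustics import (
    EchoDataset,
    ScanSeries,
    make_pulse,
    make_ring,
    scan_3d,
    simulate_echoes_born,
    simulate_echoes_fdtd,
)
from ringtomo.phantoms import make_breast_phantom_3d


def born_reference(cloud, array, pulse, c_ref, record_time, eps_mm):
    """Dense NumPy re-statement of the Born model (oracle for the kernel)."""
    fs = pulse.sampling_rate
    nt = int(np.ceil(record_time * fs)) + 1
    n = array.n_elements
    t = np.arange(nt) / fs
    rf = np.zeros((n, n, nt))
    pos = array.element_positions
    for s in range(len(cloud)):
        d = np.hypot(pos[:, 0] - cloud.positions[s, 0],
                     pos[:, 1] - cloud.positions[s, 1])
        for tx in range(n):
            for rx in range(n):
                tau = (d[tx] + d[rx]) * 1e-3 / c_ref
                amp = cloud.reflectivities[s] / (np.sqrt(d[tx] * d[rx])
                                                 + eps_mm)
                rf[tx, rx] += amp * np.interp(t - tau,
                                              np.arange(pulse.samples.size)
                                              / fs, pulse.samples,
                                              left=0.0, right=0.0)
    return rf


class TestRingGeometry:
    def test_four_element_symmetry(self):
        ring = make_ring(4, 20.0)
        np.testing.assert_allclose(
            ring.element_positions,
            [[10, 0], [0, 10], [-10, 0], [0, -10]], atol=1e-12)

    def test_256_element_pitch_on_200mm_ring(self):
        ring = make_ring(256, 200.0)
        assert ring.element_pitch == pytest.approx(2.454, abs=5e-4)

    def test_all_elements_on_circle(self):
        ring = make_ring(17, 200.0)
        r = np.hypot(*ring.element_positions.T)
        np.testing.assert_allclose(r, 100.0, rtol=1e-12)

    def test_too_few_elements(self):
        with pytest.raises(ValueError):
            make_ring(2, 200.0)


class TestPulse:
    def test_duration_5_cycles_3mhz(self):
        p = make_pulse(3e6, 5, 24e6)
        assert p.duration == pytest.approx(5.0 / 3.0e6)  # ~1.667 us

    def test_sample_count_at_hardware_rate(self):
        # floor(duration*fs)+1 oracle: 5 cycles of 3 MHz at 11.9 MHz
        with pytest.warns(UserWarning):
            p = make_pulse(3e6, 5, 11.9e6)
        assert p.samples.size == int(np.floor(5 / 3e6 * 11.9e6)) + 1 == 20

    def test_single_cycle_rect_window(self):
        p = make_pulse(1e6, 1, 32e6, window="rect")
        assert p.samples[0] == 0.0
        t = np.arange(p.samples.size) / 32e6
        np.testing.assert_allclose(p.samples, np.sin(2 * np.pi * 1e6 * t))

    def test_whole_cycles_near_zero_mean(self):
        p = make_pulse(1e6, 3, 64e6)
        assert abs(p.samples[:-1].mean()) < 1e-12

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            make_pulse(-1e6, 5, 24e6)
        with pytest.raises(ValueError):
            make_pulse(3e6, 5, 5e6)  # below Nyquist


class TestBorn:
    def test_empty_cloud_all_zero(self, ring8, pulse3mhz):
        cloud = ScattererCloud(np.zeros((0, 2)), np.zeros(0))
        ds = simulate_echoes_born(cloud, ring8, pulse3mhz,
                                  include_direct=False)
        assert not np.any(ds.data)

    def test_center_scatterer_arrival_time(self, ring8, pulse3mhz):
        # two-way path 200 mm at 1500 m/s -> 133.3 us
        cloud = ScattererCloud([[0.0, 0.0]], [1.0])
        ds = simulate_echoes_born(cloud, ring8, pulse3mhz, 1500.0,
                                  include_direct=False)
        tr = np.abs(ds.data[0, 0])
        onset = ds.times[np.argmax(tr > 0.5 * tr.max())]
        assert onset == pytest.approx(0.2 / 1500.0, abs=2 / 24e6)

    def test_center_scatterer_same_arrival_any_pair(self, ring8, pulse3mhz):
        cloud = ScattererCloud([[0.0, 0.0]], [1.0])
        ds = simulate_echoes_born(cloud, ring8, pulse3mhz,
                                  include_direct=False)
        np.testing.assert_allclose(ds.data[0, 0], ds.data[2, 5], atol=1e-6)

    def test_kernel_matches_numpy_reference(self, ring8, pulse3mhz, rng):
        pts = rng.uniform(-20, 20, (4, 2))
        refl = rng.uniform(-1, 1, 4)
        cloud = ScattererCloud(pts, refl)
        rec = 2.2e-4
        ds = simulate_echoes_born(cloud, ring8, pulse3mhz, 1500.0,
                                  record_time=rec, include_direct=False,
                                  eps_mm=0.3)
        ref = born_reference(cloud, ring8, pulse3mhz, 1500.0, rec, 0.3)
        np.testing.assert_allclose(ds.data, ref, atol=2e-4 * np.abs(ref).max())

    def test_reciprocity(self, ring8, pulse3mhz, rng):
        cloud = ScattererCloud(rng.uniform(-30, 30, (5, 2)),
                               rng.uniform(-1, 1, 5))
        ds = simulate_echoes_born(cloud, ring8, pulse3mhz,
                                  include_direct=False)
        np.testing.assert_allclose(ds.data, np.swapaxes(ds.data, 0, 1),
                                   atol=1e-7)

    def test_linearity_over_cloud_union(self, ring8, pulse3mhz, rng):
        a = ScattererCloud(rng.uniform(-20, 20, (3, 2)), rng.uniform(0, 1, 3))
        b = ScattererCloud(rng.uniform(-20, 20, (2, 2)), rng.uniform(0, 1, 2))
        kw = dict(include_direct=False)
        ds_a = simulate_echoes_born(a, ring8, pulse3mhz, **kw)
        ds_b = simulate_echoes_born(b, ring8, pulse3mhz, **kw)
        ds_ab = simulate_echoes_born(a + b, ring8, pulse3mhz, **kw)
        np.testing.assert_allclose(ds_ab.data, ds_a.data + ds_b.data,
                                   atol=1e-6)

    def test_translation_invariance(self, pulse3mhz, rng):
        pts = rng.uniform(-20, 20, (3, 2))
        refl = rng.uniform(0, 1, 3)
        shift = np.array([7.0, -11.0])
        ring_a = make_ring(8, 200.0)
        ring_b = make_ring(8, 200.0, center=tuple(shift))
        ds_a = simulate_echoes_born(ScattererCloud(pts, refl), ring_a,
                                    pulse3mhz, include_direct=False)
        ds_b = simulate_echoes_born(ScattererCloud(pts + shift, refl), ring_b,
                                    pulse3mhz, include_direct=False)
        np.testing.assert_allclose(ds_a.data, ds_b.data, atol=1e-7)

    def test_record_time_too_short(self, ring8, pulse3mhz):
        cloud = ScattererCloud([[0.0, 0.0]], [1.0])
        with pytest.raises(ValueError, match="record_time too short"):
            simulate_echoes_born(cloud, ring8, pulse3mhz,
                                 record_time=5e-5)

    def test_direct_arrival_flagged(self, ring8, pulse3mhz):
        cloud = ScattererCloud(np.zeros((0, 2)), np.zeros(0))
        ds = simulate_echoes_born(cloud, ring8, pulse3mhz,
                                  include_direct=True)
        assert ds.meta["direct_included"]
        assert np.any(ds.data)


class TestFdtd:
    def _setup(self):
        n = 121
        h = 0.5
        c = np.full((n, n), 1500.0)
        rho = np.full((n, n), 1000.0)
        origin = (-30.0, -30.0)
        amap = AcousticMap(c, rho, (h, h), origin)
        ring = make_ring(8, 40.0, 0.5e6)
        pulse = make_pulse(0.5e6, 2, 5.0e6)
        return amap, ring, pulse

    def test_homogeneous_map_direct_only(self):
        amap, ring, pulse = self._setup()
        ds = simulate_echoes_fdtd(amap, ring, pulse, dt=2e-7,
                                  record_time=1.2e-4, tx_elements=[0])
        tr = np.abs(ds.data[0, 4])  # opposite element, distance 40 mm
        direct_t = 0.04 / 1500.0
        peak = tr.max()
        T = pulse.duration
        t = ds.times
        # the only feature is the direct arrival: its 2D cylindrical-wave
        # afterglow decays monotonically (no echo bump) and the late
        # residue (sponge reflections) stays below 10% of the arrival
        early_tail = tr[(t > direct_t + 4 * T) & (t < direct_t + 6 * T)]
        late = tr[t > direct_t + 8 * T]
        assert late.max() < early_tail.max()
        assert late.max() < 0.10 * peak

    def test_inclusion_arrival_matches_born(self):
        amap, ring, pulse = self._setup()
        iy = ix = 60  # center cell
        amap.sound_speed[iy - 1: iy + 2, ix - 1: ix + 2] = 1600.0
        ds = simulate_echoes_fdtd(amap, ring, pulse, dt=2e-7,
                                  record_time=8e-5, tx_elements=[0])
        cloud = ScattererCloud([[0.0, 0.0]], [1.0])
        born = simulate_echoes_born(cloud, ring, pulse, 1500.0,
                                    record_time=8e-5, include_direct=False)
        # compare echo onset at a receiver far from the direct path
        rx = 2  # 90 degrees away: direct is early, echo well separated
        direct_t = (np.hypot(*(ring.element_positions[0]
                               - ring.element_positions[rx])) * 1e-3 / 1500.0)
        t_min = direct_t + 2.5 * pulse.duration
        tr_f = np.where(ds.times > t_min, np.abs(ds.data[0, rx]), 0.0)
        tr_b = np.where(born.times > t_min, np.abs(born.data[0, rx]), 0.0)
        on_f = np.argmax(tr_f > 0.3 * tr_f.max())
        on_b = np.argmax(tr_b > 0.3 * tr_b.max())
        assert abs(int(on_f) - int(on_b)) <= 2

    def test_cfl_violation(self):
        amap, ring, pulse = self._setup()
        with pytest.raises(ValueError, match="CFL"):
            simulate_echoes_fdtd(amap, ring, pulse, dt=5e-7)

    def test_grid_size_limit(self):
        c = np.full((400, 400), 1500.0)
        amap = AcousticMap(c, np.full((400, 400), 1000.0), (0.5, 0.5),
                           (-100.0, -100.0))
        ring = make_ring(8, 40.0)
        pulse = make_pulse(0.5e6, 2, 5e6)
        with pytest.raises(ValueError, match="300"):
            simulate_echoes_fdtd(amap, ring, pulse, dt=1e-7)


class TestScan3D:
    def test_layer_span_and_count(self):
        spec = make_breast_phantom_3d("model2")
        ring = make_ring(8, 200.0)
        pulse = make_pulse(3e6, 5, 12.1e6)
        series = scan_3d(spec, ring, n_layers=4, pitch=1.5, z0=18.0,
                         pulse=pulse, raster_spacing=0.3,
                         raster_extent=((2, 8), (-3, 3)))
        assert len(series) == 4
        zs = [ds.layer_z for ds in series]
        assert zs == [18.0, 19.5, 21.0, 22.5]
        # full 32-layer protocol spans (32-1)*1.5 = 46.5 mm
        assert (32 - 1) * 1.5 == pytest.approx(46.5)

    def test_no_layer_intersects(self):
        spec = make_breast_phantom_3d("model1")
        ring = make_ring(8, 200.0)
        with pytest.raises(ValueError, match="no scan layer"):
            scan_3d(spec, ring, n_layers=3, pitch=1.5, z0=200.0)

    def test_series_monotonic_z_enforced(self, ring8, pulse3mhz):
        cloud = ScattererCloud(np.zeros((0, 2)), np.zeros(0))
        d1 = simulate_echoes_born(cloud, ring8, pulse3mhz,
                                  include_direct=False)
        d2 = simulate_echoes_born(cloud, ring8, pulse3mhz,
                                  include_direct=False)
        d1.layer_z, d2.layer_z = 3.0, 1.5
        with pytest.raises(ValueError):
            ScanSeries([d1, d2], 1.5)

    def test_dataset_shape_validation(self, ring8):
        with pytest.raises(ValueError):
            EchoDataset(np.zeros((4, 4, 10)), 24e6, 0.0, 1500.0, ring8)
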