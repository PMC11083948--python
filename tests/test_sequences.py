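"""Tests for ISIS, PRESS and the PSYCHE-ISIS pseudo-2D experiment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import psychemrs as pm
from psychemrs.phantom import Compartment, MetaboliteFixture, Phantom, Voxel
from psychemrs.sequences import (
    _increment_delays,
    isis_scheme,
    isis_weights,
    psyche_element,
)
from psychemrs.spin_core import (
    apply_hard_pulse,
    build_hamiltonian,
    equilibrium_state,
    spin_operators,
)

from conftest import make_ax_system, run_psyche_spectrum, single_met_phantom


# ---------------------------------------------------------------------------
# ISIS


class TestIsisScheme:
    def test_eight_distinct_patterns_with_signs(self):
        scheme = isis_scheme()
        assert len(set(scheme.patterns)) == 8
        for p, s in zip(scheme.patterns, scheme.signs):
            assert s == (-1) ** sum(p)

    def test_single_axis_reduction(self):
        """Toggling one axis over its 2 patterns gives weight 2 in-slice,
        0 outside: (+1) - (-1) vs (+1) - (+1)."""
        inside, outside = True, False
        for pos, expect in ((inside, 2), (outside, 0)):
            total = 0
            for active_sign in (+1, -1):  # pattern off (+) / on (-)
                pol = -1 if (active_sign < 0 and pos) else 1
                total += (1 if active_sign > 0 else -1) * pol
            assert total == expect

    def test_brute_force_3x3x3_grid(self, voxel5):
        """Combined weight over all 8 patterns: 8 at the central cell,
        exactly 0 at the 26 others."""
        g = np.array([-2.0, 0.0, 2.0])
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        pos = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        vox = Voxel((0, 0, 0), (1.5, 1.5, 1.5))
        w = isis_weights(pos, vox)
        center = np.all(pos == 0, axis=1)
        assert np.all(w[center] == 8.0)
        assert np.all(w[~center] == 0.0)

    def test_invalid_scheme_rejected(self):
        scheme = isis_scheme()
        with pytest.raises(ValueError, match="sign"):
            pm.IsisScheme(patterns=scheme.patterns, signs=tuple(-s for s in scheme.signs))


class TestIsisAcquire:
    def test_out_of_voxel_cancellation(self, ctx, library):
        phantom = single_met_phantom("AX")
        vox_outside = Voxel((20.0, 0.0, 0.0), (5.0, 5.0, 5.0))
        acq = pm.AcqParams(n_points=64)
        with pytest.warns(UserWarning, match="outside"):
            fid = pm.run_isis_acquire(phantom, vox_outside, ctx, acq, library=library)
        vox_in = Voxel((0, 0, 0), (5, 5, 5))
        ref = pm.run_isis_acquire(phantom, vox_in, ctx, acq, library=library)
        assert np.max(np.abs(fid)) < 1e-10 * np.max(np.abs(ref))

    def test_single_cell_gives_eight_times_pulse_acquire(self, ctx, library):
        """One grid cell inside the voxel: the 8-transient combination is
        exactly 8x the plain pulse-acquire FID of that cell."""
        from psychemrs.sequences import _pulse_acquire_fid

        phantom = Phantom([Compartment([[-0.5, 0.5]] * 3, {"AX": 1.0})], grid_step_mm=1.0)
        vox = Voxel((0, 0, 0), (2, 2, 2))
        acq = pm.AcqParams(n_points=64)
        fid = pm.run_isis_acquire(phantom, vox, ctx, acq, library=library)
        subsys = library["AX"].spin_subsystems[0]
        unit = _pulse_acquire_fid(subsys, ctx, acq)
        scale = 10.0 * subsys.weight / subsys.dim  # concentration x 1/2^n
        np.testing.assert_allclose(fid, 8.0 * scale * unit, rtol=1e-10)

    def test_coupled_doublets_in_phase(self, ctx, library, voxel5):
        """Localization precedes excitation, so no J-modulation phase: the
        four fitted line amplitudes agree in phase to 1 degree."""
        from conftest import transition_lines

        phantom = single_met_phantom("AX")
        acq = pm.AcqParams(n_points=4096)
        fid = pm.run_isis_acquire(phantom, voxel5, ctx, acq, library=library)
        freqs, _ = transition_lines(library["AX"].spin_subsystems[0], ctx)
        t = np.arange(acq.n_points) * acq.dwell_s
        basis = np.exp((2j * np.pi * freqs[None, :]) * t[:, None] - (t / acq.t2_s)[:, None])
        coeffs, *_ = np.linalg.lstsq(basis, fid, rcond=None)
        phases = np.rad2deg(np.angle(coeffs))
        spread = np.angle(np.exp(1j * np.deg2rad(phases - phases[0])))
        assert np.max(np.abs(np.rad2deg(spread))) < 1.0

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        s1=st.floats(0.5, 4.0),
        s2=st.floats(0.5, 4.0),
        j=st.floats(-15.0, 15.0),
    )
    def test_cancellation_exact_for_random_two_spin_systems(self, s1, s2, j, ctx):
        """ISIS cancellation is exact for arbitrary in-cell spin systems,
        not just singlets: brute force over the 8 patterns."""
        fx = MetaboliteFixture(
            name="R",
            spin_subsystems=(pm.SpinSystem(["a", "b"], [s1, s2], [[0, j], [j, 0]]),),
            concentration_mm=10.0,
        )
        phantom = Phantom([Compartment([[-4, 4]] * 3, {"R": 1.0})], grid_step_mm=2.0)
        vox_out = Voxel((0.0, 0.0, 20.0), (2.0, 2.0, 2.0))
        acq = pm.AcqParams(n_points=16)
        with pytest.warns(UserWarning, match="outside"):
            fid = pm.run_isis_acquire(phantom, vox_out, ctx, acq, library={"R": fx})
        assert np.max(np.abs(fid)) < 1e-12


# ---------------------------------------------------------------------------
# PRESS


class TestPress:
    def test_t2_weighting_uncoupled(self, ctx, library, voxel5):
        """Uncoupled spin, TE = 100 ms, T2 = 200 ms: PRESS amplitude is
        exp(-1/2) of the ISIS pulse-acquire amplitude."""
        phantom = single_met_phantom("SINGLET")
        press = pm.PressParams(te1_s=0.05, te2_s=0.05)
        acq = pm.AcqParams(n_points=32, t2_s=0.2)
        fid_press = pm.run_press(phantom, voxel5, ctx, press, acq, library=library)
        fid_ref = pm.run_isis_acquire(phantom, voxel5, ctx, acq, library=library) / 8.0
        ratio = np.abs(fid_press[0]) / np.abs(fid_ref[0])
        assert ratio == pytest.approx(np.exp(-0.5), rel=1e-6)

    def test_antiphase_at_te_half_over_j(self, ctx, voxel5):
        """Weak AX at TE = 1/(2J): the in-phase component vanishes and the
        spectrum is purely antiphase."""
        j = 7.0
        fx = MetaboliteFixture(
            name="WAX",
            spin_subsystems=(
                pm.SpinSystem(["a", "x"], [4.7, 4.7 + 600 / 298.0425], [[0, j], [j, 0]]),
            ),
            concentration_mm=10.0,
        )
        lib = {"WAX": fx}
        phantom = Phantom([Compartment([[-5, 5]] * 3, {"WAX": 1.0})], grid_step_mm=1.0)
        te = 1.0 / (2 * j)
        press = pm.PressParams(te1_s=te / 2, te2_s=te / 2)
        acq = pm.AcqParams(n_points=4096, t2_s=10.0)
        fid = pm.run_press(phantom, voxel5, ctx, press, acq, library=lib)
        spec = pm.process_fid(fid, acq.dwell_s, ctx, phase=None, first_point_scale=1.0)
        real = np.real(spec.intensities)
        # antiphase doublets: equal positive and negative lobes
        assert real.max() > 0 and real.min() < 0
        assert abs(real.max() + real.min()) < 0.05 * real.max()
        assert abs(np.sum(real)) < 0.02 * np.sum(np.abs(real))

    def test_j_modulation_follows_cosine(self, ctx, voxel5):
        """In-phase AX amplitude vs TE matches cos(pi J TE) within 2%
        (relaxation effectively off)."""
        j = 7.0
        fx = MetaboliteFixture(
            name="WAX",
            spin_subsystems=(
                pm.SpinSystem(["a", "x"], [4.7, 4.7 + 600 / 298.0425], [[0, j], [j, 0]]),
            ),
            concentration_mm=10.0,
        )
        lib = {"WAX": fx}
        phantom = Phantom([Compartment([[-5, 5]] * 3, {"WAX": 1.0})], grid_step_mm=1.0)
        ops = spin_operators(2)
        acq = pm.AcqParams(n_points=1, t2_s=1e9)
        norm = None
        for te in np.linspace(0.02, 0.2, 7):
            press = pm.PressParams(te1_s=te / 2, te2_s=te / 2)
            fid = pm.run_press(phantom, voxel5, ctx, press, acq, library=lib)
            # first FID point of the echo: in-phase sum signal
            if norm is None:
                norm = np.real(fid[0]) / np.cos(np.pi * j * 0.02)
            assert np.real(fid[0]) / norm == pytest.approx(np.cos(np.pi * j * te), abs=0.02)

    def test_mixed_phase_for_straddling_voxel(self, ctx, library, two_compartment_phantom):
        """Voxel spanning both bottles: J-modulation during TE leaves
        multiplet components with phases differing by > 10 deg."""
        from scipy.signal import find_peaks

        vox = Voxel((0.0, 2.5, 0.0), (5.0, 10.0, 5.0))
        press = pm.PressParams(te1_s=0.02, te2_s=0.02)
        acq = pm.AcqParams(n_points=4096)
        fid = pm.run_press(two_compartment_phantom, vox, ctx, press, acq, library=library)
        spec = pm.process_fid(fid, acq.dwell_s, ctx, phase=None)
        mag = np.abs(spec.intensities)
        idx, _ = find_peaks(mag, height=0.15 * mag.max())
        phases = np.rad2deg(np.angle(spec.intensities[idx]))
        spread = np.max(np.abs(np.diff(np.sort(phases))))
        assert spread > 10.0

    def test_shaped_profile_mode_reduces_weight(self, ctx, library, voxel5):
        phantom = single_met_phantom("SINGLET")
        acq = pm.AcqParams(n_points=8)
        ideal = pm.run_press(
            phantom, voxel5, ctx, pm.PressParams(), acq, library=library
        )
        shaped = pm.run_press(
            phantom, voxel5, ctx, pm.PressParams(slice_profile="shaped"), acq, library=library
        )
        assert 0.2 < np.abs(shaped[0]) / np.abs(ideal[0]) < 1.0


# ---------------------------------------------------------------------------
# PSYCHE element and pseudo-2D


class TestPsycheElement:
    def test_j_zero_phase_tracks_pure_shift(self, ctx):
        """Uncoupled spin: after the element the detected phase equals the
        shift evolution over t1 plus the documented chirp-exposure offset
        (one chirp duration), for every t1."""
        nu = -400.0
        sys1 = pm.SpinSystem(["s"], [ctx.carrier_ppm + nu / ctx.larmor_hz * 1e6], [[0.0]])
        params = pm.PsycheParams()
        z = np.linspace(-2.5, 2.5, 16, endpoint=False) + 2.5 / 16
        ops = spin_operators(1)
        rho0 = apply_hard_pulse(equilibrium_state(sys1), 90.0, np.pi / 2)
        for t1 in (0.0, 0.02, 0.08):
            states = psyche_element([rho0] * len(z), z, sys1, params, ctx, t1)
            sig = np.mean([np.trace(s.matrix @ ops.fplus) for s in states])
            expected = np.exp(2j * np.pi * nu * (t1 + params.chirp_duration_s))
            delta = np.angle(sig / expected)
            assert abs(delta) < 0.02 * 2 * np.pi

    def test_ensemble_guard(self, ctx):
        sys1 = pm.SpinSystem(["s"], [2.0], [[0.0]])
        rho0 = apply_hard_pulse(equilibrium_state(sys1), 90.0, np.pi / 2)
        with pytest.raises(ValueError, match="16 z positions"):
            psyche_element([rho0] * 4, np.linspace(-2, 2, 4), sys1, pm.PsycheParams(), ctx, 0.01)

    def test_selection_modes_agree_on_peak_positions(self, ctx, library, voxel5, ax_psyche):
        _, _, spec_ens = ax_psyche
        _, _, spec_ideal = run_psyche_spectrum(
            single_met_phantom("AX"), voxel5, ctx, library,
            params=pm.PsycheParams(selection="ideal"),
        )
        p_ens = sorted(p.ppm for p in pm.pick_peaks(spec_ens, 0.3))
        p_ideal = sorted(p.ppm for p in pm.pick_peaks(spec_ideal, 0.3))
        assert len(p_ens) == len(p_ideal) == 2
        bin_ppm = spec_ens.digital_res_hz / ctx.larmor_hz * 1e6
        np.testing.assert_allclose(p_ens, p_ideal, atol=bin_ppm)


class TestPsycheIsis:
    def test_out_of_voxel_metabolite_cancels(self, ctx, library):
        phantom = Phantom(
            [Compartment([[10, 20], [-5, 5], [-5, 5]], {"SINGLET": 1.0})], grid_step_mm=1.0
        )
        vox = Voxel((0, 0, 0), (5, 5, 5))
        params = pm.PsycheParams(n_increments=2)
        with pytest.warns(UserWarning, match="outside"):
            p2d = pm.run_psyche_isis(phantom, vox, ctx, params, pm.AcqParams(), library=library)
        in_phantom = Phantom(
            [Compartment([[-5, 5]] * 3, {"SINGLET": 1.0})], grid_step_mm=1.0
        )
        ref = pm.run_psyche_isis(in_phantom, vox, ctx, params, pm.AcqParams(), library=library)
        assert np.max(np.abs(p2d.data)) < 1e-8 * np.max(np.abs(ref.data))

    def test_ax_collapses_to_two_singlets(self, ctx, ax_psyche):
        """End-to-end: weak AX (J = 7 Hz) at 1.0 / 3.0 ppm reconstructs to
        exactly two peaks above 10%, at the shifts, with no 7 Hz split."""
        _, _, spec = ax_psyche
        peaks = pm.pick_peaks(spec, 0.1)
        assert len(peaks) == 2
        bin_ppm = spec.digital_res_hz / ctx.larmor_hz * 1e6
        got = sorted(p.ppm for p in peaks)
        np.testing.assert_allclose(got, [1.0, 3.0], atol=2 * bin_ppm)

    def test_transient_count_bookkeeping(self, ctx, ax_psyche):
        p2d, _, _ = ax_psyche
        assert p2d.meta["n_transients"] == 8 * p2d.n_increments

    def test_single_increment_degenerates_to_one_chunk(self, ctx, library, voxel5):
        params = pm.PsycheParams(n_increments=1)
        p2d = pm.run_psyche_isis(
            single_met_phantom("SINGLET"), voxel5, ctx, params, pm.AcqParams(), library=library
        )
        assert p2d.n_increments == 1
        fid = pm.chunk_concatenate(p2d)
        assert fid.size == 40  # half chunk: tau / dwell

    def test_acquisition_shorter_than_chunk_refused(self, ctx, library, voxel5):
        with pytest.raises(ValueError, match="chunk"):
            pm.run_psyche_isis(
                single_met_phantom("SINGLET"),
                voxel5,
                ctx,
                pm.PsycheParams(tau_s=0.02),
                pm.AcqParams(n_points=80),
                library=library,
            )

    def test_half_first_delay_schedule(self):
        params = pm.PsycheParams()
        assert _increment_delays(params, 0) == (0.0, 0.0)
        a, b = _increment_delays(params, 3)
        assert a == pytest.approx(0.03)
        assert b == pytest.approx(0.02)  # t1/2 - tau: J echo at chunk centre

    def test_beta_near_90_degrades_decoupling(self, ctx, library, voxel5, ax_psyche):
        """Large-flip regression: the small-flip statistical argument
        breaks down and extra structure appears above 10%."""
        _, _, spec15 = ax_psyche
        _, _, spec85 = run_psyche_spectrum(
            single_met_phantom("AX"), voxel5, ctx, library,
            params=pm.PsycheParams(beta_deg=85.0),
        )
        assert len(pm.pick_peaks(spec85, 0.1)) > len(pm.pick_peaks(spec15, 0.1))

    def test_noise_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            pm.AcqParams(noise_sigma=0.1)

    def test_pseudo2d_roundtrip(self, tmp_path, ax_psyche):
        p2d, _, _ = ax_psyche
        path = tmp_path / "p2d.h5"
        p2d.save(path)
        again = pm.Pseudo2D.load(path)
        np.testing.assert_array_equal(again.data, p2d.data)
        assert again.meta == p2d.meta
        assert again.dwell_s == p2d.dwell_s
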