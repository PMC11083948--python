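"""Shared fixtures and independent oracles for the test suite.

Heavy pseudo-2D simulations (GABA, brain phantom, two-compartment
phantom) are session-scoped so the acceptance checks and the unit tests
share one run each.
"""

import warnings

import numpy as np
import pytest
from scipy.linalg import eigh

import psychemrs as pm
from psychemrs.phantom import Compartment, MetaboliteFixture, Phantom, Voxel
from psychemrs.spin_core import build_hamiltonian, spin_operators

warnings.filterwarnings("ignore", message="voxel lies outside")


# ---------------------------------------------------------------------------
# independent oracles (kept free of the code paths they check)


def transition_lines(system, ctx, extra_offset_hz=None):
    """Enumerate allowed single-quantum transitions by diagonalizing H.

    Returns (freq_hz, amplitude) arrays using the package's detection
    sign convention (a line of an uncoupled spin at offset +nu appears at
    +nu).  Independent of detect_fid: pure eigenbasis enumeration.
    """
    h = build_hamiltonian(system, ctx, extra_offset_hz)
    e, v = eigh(h)
    fp = v.conj().T @ spin_operators(system.n_spins).fplus @ v
    freqs, amps = [], []
    for a in range(len(e)):
        for b in range(len(e)):
            if np.abs(fp[a, b]) > 1e-9:
                freqs.append((e[a] - e[b]) / (2 * np.pi))
                amps.append(np.abs(fp[a, b]) ** 2)
    return np.array(freqs), np.array(amps)


def lorentzian_fwhm_hz(t2_s):
    return 1.0 / (np.pi * t2_s)


# ---------------------------------------------------------------------------
# shared systems / phantoms


AX_J_HZ = 7.0


def make_ax_system(j_hz=AX_J_HZ, ppm_a=3.0, ppm_x=1.0):
    return pm.SpinSystem(["A", "X"], [ppm_a, ppm_x], [[0.0, j_hz], [j_hz, 0.0]])


@pytest.fixture(scope="session")
def ctx():
    return pm.FieldContext()


@pytest.fixture(scope="session")
def library():
    lib = dict(pm.default_library())
    lib["AX"] = MetaboliteFixture(
        name="AX",
        spin_subsystems=(make_ax_system(),),
        reference_peaks_ppm=(("A", 3.0), ("X", 1.0)),
        concentration_mm=10.0,
    )
    lib["SINGLET"] = MetaboliteFixture(
        name="SINGLET",
        spin_subsystems=(pm.SpinSystem(["s"], [2.0], [[0.0]]),),
        reference_peaks_ppm=(("s", 2.0),),
        concentration_mm=10.0,
    )
    return lib


def single_met_phantom(name, half_mm=5.0):
    return Phantom(
        [Compartment([[-half_mm, half_mm]] * 3, {name: 1.0})], grid_step_mm=1.0
    )


@pytest.fixture(scope="session")
def voxel5():
    return Voxel((0.0, 0.0, 0.0), (5.0, 5.0, 5.0))


def run_psyche_spectrum(phantom, voxel, ctx, library, params=None, acq=None, lb_hz=1.0):
    """Simulate, chunk-concatenate and process one PSYCHE-ISIS spectrum."""
    params = params or pm.PsycheParams()
    acq = acq or pm.AcqParams()
    p2d = pm.run_psyche_isis(phantom, voxel, ctx, params, acq, library=library)
    fid = pm.chunk_concatenate(p2d)
    spec = pm.process_fid(
        fid,
        acq.dwell_s,
        ctx,
        apodization_hz=lb_hz,
        time_origin_s=p2d.meta["time_origin_s"],
    )
    return p2d, fid, spec


@pytest.fixture(scope="session")
def ax_psyche(ctx, library, voxel5):
    return run_psyche_spectrum(single_met_phantom("AX"), voxel5, ctx, library)


@pytest.fixture(scope="session")
def gaba_psyche(ctx, library, voxel5):
    return run_psyche_spectrum(single_met_phantom("GABA"), voxel5, ctx, library)


@pytest.fixture(scope="session")
def gaba_press_spec(ctx, library, voxel5):
    acq = pm.AcqParams(n_points=2048)
    fid = pm.run_press(
        single_met_phantom("GABA"), voxel5, ctx, pm.PressParams(), acq, library=library
    )
    return pm.process_fid(fid, acq.dwell_s, ctx, apodization_hz=1.0)


@pytest.fixture(scope="session")
def brain_phantom():
    mixture = {"NAA": 1.0, "Cr": 1.0, "Cho": 1.0, "mI": 1.0, "Tau": 1.0, "Asp": 1.0, "GABA": 1.0}
    return Phantom([Compartment([[-10, 10]] * 3, mixture)], grid_step_mm=1.0)


@pytest.fixture(scope="session")
def brain_psyche(ctx, library, brain_phantom, voxel5):
    return run_psyche_spectrum(brain_phantom, voxel5, ctx, library)


@pytest.fixture(scope="session")
def two_compartment_phantom():
    return Phantom(
        [
            Compartment([[-15, 15]] * 3, {"GABA": 100.0}),
            Compartment([[-5, 5]] * 3, {"Prop": 100.0}),
        ],
        grid_step_mm=1.0,
    )


@pytest.fixture(scope="session")
def two_compartment_psyche(ctx, library, two_compartment_phantom):
    vox = Voxel((0.0, 2.5, 0.0), (5.0, 10.0, 5.0))
    return run_psyche_spectrum(two_compartment_phantom, vox, ctx, library)


@pytest.fixture(scope="session")
def singlet_sensitivity(ctx, library, voxel5):
    """(psyche fid, isis fid) of the uncoupled-singlet phantom."""
    phantom = single_met_phantom("SINGLET")
    _, fid, _ = run_psyche_spectrum(phantom, voxel5, ctx, library)
    acq = pm.AcqParams(n_points=fid.size)
    fid_isis = pm.run_isis_acquire(phantom, voxel5, ctx, acq, library=library)
    return fid, fid_isis
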