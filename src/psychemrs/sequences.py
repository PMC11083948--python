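"""Pulse-sequence engines: ISIS localization, PRESS, and PSYCHE-ISIS.

ISIS localizes the voxel *before* excitation: eight transient experiments
toggle slice-selective inversions on each axis (2^3 on/off patterns) and
are combined with signs (-1)^(number of active axes), so longitudinal
magnetization sums to 8x inside the triple-slice intersection and cancels
exactly everywhere else.  Because the inversions precede excitation, the
combination is a scalar weight on each cell's subsequent signal — the
explicit eight-pattern bookkeeping is still performed.

PRESS is the double-spin-echo baseline (90-180-180 with slice-selective
refocusing); J-coupling evolves throughout TE, which is what produces the
phase-twisted multiplets the pure-shift experiment avoids.

The PSYCHE element sandwiches a hard 180 between two small-flip saltire
chirps swept under a weak z gradient G3, centred in symmetric t1/2
pure-shift evolution delays.  Coherence selection is performed by explicit
integration over a z ensemble of gradient-induced phases.  Writing the
coherence order during the first t1/2 as p0 and between the chirps as pa,
a pathway accumulates total gradient phase ``u z (p0 - 3 pa + 1)`` from
dephasers of area ratio 1 : 3 : -1 placed after the first t1/2, after the
180 and after the second chirp; the only single-quantum solution of
``p0 - 3 pa + 1 = 0`` is the wanted pure-shift pathway (p0, pa) = (-1, 0):
order -1 through both t1/2 delays, with the active spin stored
longitudinally between the chirps (a first-order sin(beta) transfer at
each saltire crossing, hence the familiar sin^2(beta) sensitivity) while
the hard 180 inverts its coupling partners.  Chemical shift then evolves
for the full t1 while J coupling is refocused — the interferogram
ingredient of pure-shift NMR.  An ideal CTP projection filter is
available as a fast mode and agrees with the ensemble on peak positions.

Two deterministic by-products of the storage pathway are handled
explicitly: (a) the G3 exposure of the transverse intervals does not
cancel for the stored pathway, so a balancing gradient of area
``-2 pi G3 Tp`` (Tp = chirp duration) is applied with the final dephaser
— without it the z ensemble dephases the wanted signal almost completely;
(b) the pathway spends a fixed extra transverse time Tp in the chirps, a
constant time-origin shift recorded as ``time_origin_s`` in the Pseudo2D
metadata and removed as an exact first-order phase during processing.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import eigh

from .phantom import DiscretizedPhantom, Phantom, Voxel, default_library, discretize, voxel_mask
from .spin_core import (
    DensityState,
    FieldContext,
    SpinSystem,
    _hard_pulse_propagator,
    build_hamiltonian,
    coherence_filter,
    make_saltire,
    shaped_pulse_propagator,
    spin_operators,
)

__all__ = [
    "AcqParams",
    "IsisScheme",
    "PsycheParams",
    "PressParams",
    "Pseudo2D",
    "isis_scheme",
    "isis_weights",
    "run_isis_acquire",
    "run_press",
    "psyche_element",
    "run_psyche_isis",
]

#: excitation pulse phase (y), so equilibrium Iz is excited to +Ix and the
#: detected signal starts real and positive
_EXC_PHASE = np.pi / 2.0


@dataclass(frozen=True)
class AcqParams:
    """Direct-acquisition settings shared by all sequences.

    ``t2_s`` is the fallback transverse decay constant used when a spin
    system does not carry its own; ``noise_sigma`` adds seeded complex
    Gaussian noise at detection (per point, absolute units).
    """

    n_points: int = 80
    dwell_s: float = 0.25e-3
    t2_s: float = 0.3
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_points < 1 or self.dwell_s <= 0:
            raise ValueError("n_points >= 1 and dwell_s > 0 required")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_sigma > 0 and self.seed is None:
            raise ValueError("a seed is mandatory when noise_sigma > 0")


@dataclass(frozen=True)
class IsisScheme:
    """The eight on/off inversion patterns and their combination signs."""

    patterns: tuple
    signs: tuple

    def __post_init__(self):
        pats = [tuple(p) for p in self.patterns]
        if len(pats) != 8 or len(set(pats)) != 8:
            raise ValueError("ISIS scheme needs exactly 8 distinct patterns")
        for p, s in zip(pats, self.signs):
            if s != (-1) ** sum(p):
                raise ValueError("ISIS sign must be (-1)^(bx+by+bz)")


def isis_scheme() -> IsisScheme:
    """Minimal complete ISIS scheme: 2^3 = 8 transients."""
    pats = tuple(itertools.product((0, 1), repeat=3))
    signs = tuple((-1) ** sum(p) for p in pats)
    return IsisScheme(patterns=pats, signs=signs)


def _slice_masks(positions_mm: np.ndarray, voxel: Voxel) -> np.ndarray:
    """(N, 3) boolean: position inside the half-open slice on each axis."""
    p = np.atleast_2d(np.asarray(positions_mm, dtype=float))
    lo, hi = voxel.bounds()
    return (p >= lo) & (p < hi)


def isis_weights(
    positions_mm: np.ndarray,
    voxel: Voxel,
    scheme: IsisScheme | None = None,
) -> np.ndarray:
    """Combined longitudinal weight per position after the 8-scan scheme.

    Runs the explicit pattern loop: each active axis inverts the polarity
    of in-slice positions; the signed sum is 8 inside the triple-slice
    intersection and exactly 0 elsewhere.
    """
    scheme = scheme or isis_scheme()
    inside = _slice_masks(positions_mm, voxel)
    w = np.zeros(inside.shape[0])
    for pattern, sign in zip(scheme.patterns, scheme.signs):
        pol = np.ones(inside.shape[0])
        for ax, active in enumerate(pattern):
            if active:
                pol = np.where(inside[:, ax], -pol, pol)
        w += sign * pol
    return w


# ---------------------------------------------------------------------------
# shared helpers


def _iter_metabolites(mixture, library) -> list:
    """Yield (subsystem, amplitude) pairs for a mixture.

    ``amplitude`` folds relative concentration, the fixture's nominal
    concentration, the subsystem population weight, and the 1/2^n
    high-temperature normalization of the deviation density operator, so
    equimolar metabolites give equal per-proton signal regardless of
    subsystem size.
    """
    out = []
    for name, conc in mixture:
        if name not in library:
            raise KeyError(f"metabolite {name!r} not found in fixture library")
        fx = library[name]
        for subsys in fx.spin_subsystems:
            out.append((subsys, conc * fx.concentration_mm * subsys.weight / subsys.dim))
    return out


def _group_cells(cells: DiscretizedPhantom):
    """Yield (mixture, positions) per compartment-mixture group."""
    for idx in np.unique(cells.mixture_index):
        yield cells.mixtures[idx], cells.positions_mm[cells.mixture_index == idx]


def _pulse_acquire_fid(subsys, ctx, acq, extra_offset_hz=0.0) -> np.ndarray:
    """Equilibrium -> 90(y) -> detect; the per-cell unit signal."""
    from .spin_core import apply_hard_pulse, detect_fid, equilibrium_state

    h = build_hamiltonian(subsys, ctx, extra_offset_hz)
    rho = apply_hard_pulse(equilibrium_state(subsys), 90.0, _EXC_PHASE)
    return detect_fid(rho, h, acq.n_points, acq.dwell_s, t2_s=subsys.t2_s or acq.t2_s)


def _maybe_add_noise(fid: np.ndarray, acq: AcqParams) -> np.ndarray:
    if acq.noise_sigma > 0:
        rng = np.random.default_rng(acq.seed)
        fid = fid + acq.noise_sigma * (
            rng.standard_normal(fid.shape) + 1j * rng.standard_normal(fid.shape)
        )
    return fid


def _check_voxel_in_phantom(cells, voxel) -> np.ndarray:
    mask = voxel_mask(cells.positions_mm, voxel)
    if not np.any(mask):
        warnings.warn("voxel lies outside the phantom: expect near-zero signal", stacklevel=3)
    return mask


# ---------------------------------------------------------------------------
# ISIS pulse-acquire


def run_isis_acquire(
    phantom: Phantom,
    voxel: Voxel,
    ctx: FieldContext,
    acq: AcqParams,
    library: Mapping | None = None,
    scheme: IsisScheme | None = None,
) -> np.ndarray:
    """Eight-transient ISIS-localized pulse-acquire experiment.

    For each pattern the in-slice longitudinal magnetization is inverted
    (ideal 180s), a non-selective 90 excites, and the FID is detected; the
    signed sum cancels everything outside the voxel.  A fresh equilibrium
    is assumed for each transient (T1 reset between scans).
    """
    library = library or default_library()
    scheme = scheme or isis_scheme()
    cells = discretize(phantom)
    _check_voxel_in_phantom(cells, voxel)
    total = np.zeros(acq.n_points, dtype=complex)
    for mixture, positions in _group_cells(cells):
        inside = _slice_masks(positions, voxel)
        # explicit eight-pattern accumulation of the per-cell polarity
        weight = 0.0
        for pattern, sign in zip(scheme.patterns, scheme.signs):
            pol = np.ones(positions.shape[0])
            for ax, active in enumerate(pattern):
                if active:
                    pol = np.where(inside[:, ax], -pol, pol)
            weight += sign * np.sum(pol)
        if weight == 0.0:
            continue
        for subsys, amp in _iter_metabolites(mixture, library):
            total += weight * amp * _pulse_acquire_fid(subsys, ctx, acq)
    return _maybe_add_noise(total, acq)


# ---------------------------------------------------------------------------
# PRESS


@dataclass(frozen=True)
class PressParams:
    """Double-spin-echo timing: TE = te1_s + te2_s."""

    te1_s: float = 0.02
    te2_s: float = 0.02
    slice_profile: str = "ideal"

    def __post_init__(self):
        if self.te1_s <= 0 or self.te2_s <= 0:
            raise ValueError("te1_s and te2_s must be > 0")
        if self.slice_profile not in ("ideal", "shaped"):
            raise ValueError("slice_profile must be 'ideal' or 'shaped'")

    @property
    def te_s(self) -> float:
        return self.te1_s + self.te2_s


_PROFILE_CACHE: tuple | None = None


def _sinc_inversion_profile(u: np.ndarray) -> np.ndarray:
    """Inversion efficiency of a 3-lobe sinc 180 vs normalized offset.

    ``u`` is position over half the slice width (|u| = 1 at the slice
    edge).  Computed once by Bloch simulation of a single spin, cached.
    Used only by the 'shaped' PRESS profile mode for realism studies.
    """
    global _PROFILE_CACHE
    if _PROFILE_CACHE is None:
        from .spin_core import PulseShape

        n, lobes, dur = 256, 3, 2.0e-3
        t = (np.arange(n) + 0.5) / n
        wave = np.sinc(2 * lobes * (t - 0.5))
        bw = 2 * lobes / dur  # main-lobe bandwidth ~ slice bandwidth
        area = 2 * np.pi * np.sum(wave) * (dur / n)
        wave = (np.pi / area) * wave  # calibrate to a 180 on resonance
        shape = PulseShape(
            np.abs(wave), np.where(wave >= 0, 0.0, np.pi), dur / n, 180.0, kind="sinc"
        )
        ops = spin_operators(1)
        grid = np.linspace(-2.5, 2.5, 101)
        prof = np.empty_like(grid)
        sys1 = SpinSystem(["a"], [4.7], [[0.0]])
        ctx0 = FieldContext()
        for i, g in enumerate(grid):
            h = build_hamiltonian(sys1, ctx0, extra_offset_hz=[g * bw / 2.0])
            u1 = shaped_pulse_propagator(shape, h, method="split")
            mzrot = u1 @ ops.fz @ u1.conj().T
            prof[i] = -np.real(np.trace(mzrot @ ops.fz)) / 0.5  # +1 = full inversion
        _PROFILE_CACHE = (grid, prof)
    grid, prof = _PROFILE_CACHE
    return np.interp(u, grid, prof, left=-1.0, right=-1.0)


def run_press(
    phantom: Phantom,
    voxel: Voxel,
    ctx: FieldContext,
    press: PressParams,
    acq: AcqParams,
    library: Mapping | None = None,
) -> np.ndarray:
    """PRESS: 90 - te1/2 - 180 - (te1+te2)/2 - 180 - te2/2 - acquire.

    In the default ideal profile mode the slice-selective pulses act only
    on in-slice cells and crusher pairs purge transverse coherence of every
    cell failing a slice test, so only the triple intersection contributes;
    J-coupling evolves throughout TE (shift is refocused at the echo).
    """
    from .spin_core import apply_hard_pulse, detect_fid, equilibrium_state, free_evolve

    library = library or default_library()
    cells = discretize(phantom)
    _check_voxel_in_phantom(cells, voxel)
    total = np.zeros(acq.n_points, dtype=complex)
    for mixture, positions in _group_cells(cells):
        inside = _slice_masks(positions, voxel)
        in_voxel = np.all(inside, axis=1)
        if press.slice_profile == "ideal":
            weight = float(np.sum(in_voxel))
        else:
            lo, hi = voxel.bounds()
            half = (hi - lo) / 2.0
            centre = (hi + lo) / 2.0
            u = (positions - centre) / half
            # excitation slice on x (boxcar), shaped inversion profiles on y/z;
            # regions with negative inversion efficiency are crushed, not refocused
            wx = inside[:, 0].astype(float)
            wy = np.clip(_sinc_inversion_profile(u[:, 1]), 0.0, 1.0)
            wz = np.clip(_sinc_inversion_profile(u[:, 2]), 0.0, 1.0)
            weight = float(np.sum(wx * wy * wz))
        if weight == 0.0:
            continue
        for subsys, amp in _iter_metabolites(mixture, library):
            h = build_hamiltonian(subsys, ctx)
            rho = apply_hard_pulse(equilibrium_state(subsys), 90.0, _EXC_PHASE)
            rho = free_evolve(rho, h, press.te1_s / 2.0)
            rho = apply_hard_pulse(rho, 180.0, 0.0)
            rho = free_evolve(rho, h, (press.te1_s + press.te2_s) / 2.0)
            rho = apply_hard_pulse(rho, 180.0, 0.0)
            rho = free_evolve(rho, h, press.te2_s / 2.0)
            fid = detect_fid(
                rho,
                h,
                acq.n_points,
                acq.dwell_s,
                t2_s=subsys.t2_s or acq.t2_s,
                t0_s=press.te_s,
            )
            total += weight * amp * fid
    return _maybe_add_noise(total, acq)


# ---------------------------------------------------------------------------
# PSYCHE


@dataclass(frozen=True)
class PsycheParams:
    """PSYCHE pure-shift element and pseudo-2D loop parameters.

    The t1 increment is locked to the chunk time, ``delta_t1_s = 2 tau_s``.
    ``g3_hz_per_mm``/``g1_area_rad_per_mm`` default to automatic matching:
    G3 spreads the full sweep width across the voxel z extent and the
    coherence-selection base area G1 is sized so unwanted-pathway phases
    cancel exactly over the n_z-point ensemble (dephaser areas in ratio
    1:3:2, see module docstring).  ``selection`` chooses explicit
    gradient-ensemble integration ("ensemble") or an ideal CTP projection
    filter ("ideal"); the two agree on peak positions.
    """

    beta_deg: float = 15.0
    sweep_hz: float = 10_000.0
    chirp_duration_s: float = 0.015
    tau_s: float = 0.010
    n_increments: int = 32
    g3_hz_per_mm: float | None = None
    g1_area_rad_per_mm: float | None = None
    n_z: int = 16
    sweep_margin_hz: float = 2000.0
    saltire_phase_cycle: int = 2
    chunk_mode: str = "half_first"
    selection: str = "ensemble"
    chirp_dt_s: float | None = None

    def __post_init__(self):
        if not 0 < self.beta_deg < 90:
            raise ValueError("beta_deg must be in (0, 90)")
        if self.n_increments < 1:
            raise ValueError("n_increments must be >= 1")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be > 0")
        if self.chunk_mode not in ("half_first", "full"):
            raise ValueError("chunk_mode must be 'half_first' or 'full'")
        if self.selection not in ("ensemble", "ideal"):
            raise ValueError("selection must be 'ensemble' or 'ideal'")
        if self.selection == "ensemble" and self.n_z < 16:
            raise ValueError("ensemble selection needs n_z >= 16 z positions")
        if self.saltire_phase_cycle not in (1, 2):
            raise ValueError("saltire_phase_cycle must be 1 or 2")
        if not 0 <= 2 * self.sweep_margin_hz < self.sweep_hz:
            raise ValueError("sweep_margin_hz must satisfy 0 <= 2*margin < sweep")

    @property
    def delta_t1_s(self) -> float:
        return 2.0 * self.tau_s


@dataclass
class Pseudo2D:
    """t1-incremented interferogram block: (n_increments, n_points)."""

    data: np.ndarray
    dwell_s: float
    tau_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=complex))
        if self.data.shape[1] * self.dwell_s < 2 * self.tau_s - 1e-12:
            raise ValueError(
                "each increment must record at least one full chunk (n_points*dwell >= 2 tau)"
            )

    @property
    def n_increments(self) -> int:
        return self.data.shape[0]

    @property
    def n_points(self) -> int:
        return self.data.shape[1]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("dwell_s", data=self.dwell_s)
            f.create_dataset("tau_s", data=self.tau_s)
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def load(cls, path) -> "Pseudo2D":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                dwell_s=float(f["dwell_s"][()]),
                tau_s=float(f["tau_s"][()]),
                meta=json.loads(f.attrs.get("meta", "{}")),
            )


def _auto_g3(params: PsycheParams, z_span_mm: float) -> float:
    if params.g3_hz_per_mm is not None:
        return params.g3_hz_per_mm
    # leave a margin so every chemical shift is swept well inside the band
    return (params.sweep_hz - 2.0 * params.sweep_margin_hz) / z_span_mm


#: dephaser area multipliers (after first t1/2, after the 180, after the
#: second chirp); pathway survival requires p0 - 3 pa + 1 = 0
_G_MULTS = (1.0, 3.0, -1.0)


def _auto_g1(params: PsycheParams, z_span_mm: float) -> float:
    if params.g1_area_rad_per_mm is not None:
        return params.g1_area_rad_per_mm
    # with z_j uniform over the span, c*g1*dz*n_z = 2 pi c: every pathway
    # with phase coefficient c != 0 (mod n_z) sums to zero exactly
    return 2.0 * np.pi / z_span_mm


def _ensemble_z(voxel: Voxel, n_z: int) -> np.ndarray:
    zc = voxel.center_mm[2]
    dz = voxel.size_mm[2]
    return zc - dz / 2.0 + (np.arange(n_z) + 0.5) * dz / n_z


def psyche_element(
    states: Sequence[DensityState],
    z_positions_mm: Sequence[float],
    system: SpinSystem,
    params: PsycheParams,
    ctx: FieldContext,
    t1_s: float,
    pre_delay_s: float | None = None,
    post_delay_s: float | None = None,
) -> list:
    """Apply the PSYCHE element to a z ensemble of states.

    Per member: free(t1/2) -> dephase(1u) -> saltire(beta) under G3 ->
    hard 180 -> dephase(3u) -> saltire(beta) under G3 -> dephase(-1u) ->
    free(t1/2), with u = G1 area x z.  ``pre/post_delay_s`` override the
    symmetric t1/2 delays (used by the pseudo-2D loop to centre the J
    echo in each chunk).
    """
    from .spin_core import apply_hard_pulse, apply_shaped_pulse, free_evolve, rotate_about_z

    z = np.asarray(z_positions_mm, dtype=float)
    if params.selection == "ensemble" and z.size < 16:
        raise ValueError("ensemble coherence selection needs >= 16 z positions")
    if len(states) != z.size:
        raise ValueError("need one state per z position")
    span = (z.max() - z.min()) + (z[1] - z[0] if z.size > 1 else 1.0)
    g3 = _auto_g3(params, span)
    g1 = _auto_g1(params, span)
    h0 = build_hamiltonian(system, ctx)
    a = t1_s / 2.0 if pre_delay_s is None else pre_delay_s
    b = t1_s / 2.0 if post_delay_s is None else post_delay_s
    ideal = params.selection == "ideal"
    comp = -2.0 * np.pi * g3 * params.chirp_duration_s  # storage-pathway balance
    shapes = [
        make_saltire(
            params.beta_deg,
            params.sweep_hz,
            params.chirp_duration_s,
            params.chirp_dt_s,
            phase0_rad=k * np.pi / 2.0,
        )
        for k in range(params.saltire_phase_cycle)
    ]
    out = []
    for rho0, zj in zip(states, z):
        hz = build_hamiltonian(system, ctx, extra_offset_hz=g3 * zj)
        acc = None
        for shape in shapes:
            rho = free_evolve(rho0, h0, a)
            if ideal:
                rho = coherence_filter(rho, [-1])
            else:
                rho = rotate_about_z(rho, _G_MULTS[0] * g1 * zj)
            rho = apply_shaped_pulse(rho, shape, hz, method="split")
            if ideal:
                rho = coherence_filter(rho, [0])
            rho = apply_hard_pulse(rho, 180.0, 0.0)
            if not ideal:
                rho = rotate_about_z(rho, _G_MULTS[1] * g1 * zj)
            rho = apply_shaped_pulse(rho, shape, hz, method="split")
            if ideal:
                rho = coherence_filter(rho, [-1])
                rho = rotate_about_z(rho, comp * zj)
            else:
                rho = rotate_about_z(rho, _G_MULTS[2] * g1 * zj + comp * zj)
            rho = free_evolve(rho, h0, b)
            acc = rho.matrix if acc is None else acc + rho.matrix
        out.append(DensityState(acc / len(shapes)))
    return out


def _increment_delays(params: PsycheParams, k: int) -> tuple:
    """Pre/post element delays for increment k (t1 = 2 tau k).

    half_first mode shifts the post-delay by -tau for k >= 1 so the J echo
    falls at the chunk centre (t2 = tau) while the chemical-shift phase at
    each acquired point still equals the reconstructed time exactly.
    """
    t1 = params.delta_t1_s * k
    if params.chunk_mode == "half_first" and k >= 1:
        return t1 / 2.0, t1 / 2.0 - params.tau_s
    return t1 / 2.0, t1 / 2.0


class _SubsystemEngine:
    """Cached propagators for one spin subsystem in one field context."""

    def __init__(self, subsys, ctx, params, z_mm, dwell_s, n_points):
        self.subsys = subsys
        self.ops = spin_operators(subsys.n_spins)
        self.h0 = build_hamiltonian(subsys, ctx)
        self.energies, self.v = eigh(self.h0)
        self.z = z_mm
        span = (z_mm.max() - z_mm.min()) + (z_mm[1] - z_mm[0] if z_mm.size > 1 else 1.0)
        self.g3 = _auto_g3(params, span)
        self.g1 = _auto_g1(params, span)
        self.params = params
        # balancing gradient for the storage pathway's G3 exposure (rad/mm)
        self.comp = -2.0 * np.pi * self.g3 * params.chirp_duration_s
        # one saltire propagator set per phase-cycle step and z position
        phases0 = [k * np.pi / 2.0 for k in range(params.saltire_phase_cycle)]
        h_z = [build_hamiltonian(subsys, ctx, extra_offset_hz=self.g3 * zj) for zj in z_mm]
        self.u_chirp_cycle = [
            [
                shaped_pulse_propagator(
                    make_saltire(
                        params.beta_deg,
                        params.sweep_hz,
                        params.chirp_duration_s,
                        params.chirp_dt_s,
                        phase0_rad=p0,
                    ),
                    h,
                    method="split",
                )
                for h in h_z
            ]
            for p0 in phases0
        ]
        u90 = _hard_pulse_propagator(subsys.n_spins, np.pi / 2.0, _EXC_PHASE)
        self.rho90 = u90 @ self.ops.fz.astype(complex) @ u90.conj().T
        self.u180 = _hard_pulse_propagator(subsys.n_spins, np.pi, 0.0)
        self.mz = np.real(np.diag(self.ops.fz))
        order = np.rint(self.ops.order).astype(int)
        self.keep = order == -1
        self.keep_zero = order == 0
        # detection in the eigenbasis of h0
        self.det_e = self.v.conj().T @ self.ops.fplus @ self.v
        self.t_acq = np.arange(n_points) * dwell_s
        w = (self.energies[:, None] - self.energies[None, :]).ravel()
        self.det_kernel = np.exp(-1j * np.outer(self.t_acq, w))

    def _free(self, t_s: float) -> np.ndarray:
        ph = np.exp(-1j * self.energies * t_s)
        return (self.v * ph) @ self.v.conj().T

    def increment_fid(self, k: int, t2_s: float) -> np.ndarray:
        """z-ensemble-averaged FID of increment k (unit concentration)."""
        p = self.params
        a, b = _increment_delays(p, k)
        ua = self._free(a)
        rho_a = ua @ self.rho90 @ ua.conj().T
        rho_sum = np.zeros_like(rho_a)
        ideal = p.selection == "ideal"

        def _zrot(rho, phi):
            ph = np.exp(-1j * phi * self.mz)
            return (ph[:, None] * rho) * ph.conj()[None, :]

        for u_chirp in self.u_chirp_cycle:
            for uj, zj in zip(u_chirp, self.z):
                rho = rho_a if ideal else _zrot(rho_a, _G_MULTS[0] * self.g1 * zj)
                if ideal:
                    rho = np.where(self.keep, rho, 0.0)
                rho = uj @ rho @ uj.conj().T
                if ideal:
                    rho = np.where(self.keep_zero, rho, 0.0)
                rho = self.u180 @ rho @ self.u180.conj().T
                if not ideal:
                    rho = _zrot(rho, _G_MULTS[1] * self.g1 * zj)
                rho = uj @ rho @ uj.conj().T
                if ideal:
                    rho = np.where(self.keep, rho, 0.0)
                    rho = _zrot(rho, self.comp * zj)
                else:
                    rho = _zrot(rho, _G_MULTS[2] * self.g1 * zj + self.comp * zj)
                rho_sum += rho
        rho_sum /= len(self.z) * len(self.u_chirp_cycle)
        ub = self._free(b)
        rho_b = ub @ rho_sum @ ub.conj().T
        rho_e = self.v.conj().T @ rho_b @ self.v
        amp = (rho_e * self.det_e.T).ravel()
        sig = self.det_kernel @ amp
        return sig * np.exp(-(a + b + self.t_acq) / t2_s)


def run_psyche_isis(
    phantom: Phantom,
    voxel: Voxel,
    ctx: FieldContext,
    params: PsycheParams,
    acq: AcqParams,
    library: Mapping | None = None,
    scheme: IsisScheme | None = None,
) -> Pseudo2D:
    """Full PSYCHE-ISIS pseudo-2D experiment.

    Per t1 increment (t1 = 2 tau k) the 8-pattern ISIS block localizes the
    voxel before a non-selective 90, the PSYCHE element runs over the
    sub-voxel z ensemble, and ``n_points`` are acquired; increments stack
    into a :class:`Pseudo2D`.  The minimal transient count is
    8 x n_increments (the ISIS weight enters each increment as the signed
    8-scan sum).
    """
    if acq.n_points * acq.dwell_s < 2 * params.tau_s - 1e-12:
        raise ValueError(
            "acquisition shorter than one pure-shift chunk (need n_points*dwell >= 2 tau)"
        )
    library = library or default_library()
    scheme = scheme or isis_scheme()
    cells = discretize(phantom)
    _check_voxel_in_phantom(cells, voxel)
    z_ens = _ensemble_z(voxel, params.n_z)
    data = np.zeros((params.n_increments, acq.n_points), dtype=complex)
    for mixture, positions in _group_cells(cells):
        weight = float(np.sum(isis_weights(positions, voxel, scheme)))
        if weight == 0.0:
            continue
        for subsys, amp in _iter_metabolites(mixture, library):
            eng = _SubsystemEngine(subsys, ctx, params, z_ens, acq.dwell_s, acq.n_points)
            t2 = subsys.t2_s or acq.t2_s
            for k in range(params.n_increments):
                data[k] += weight * amp * eng.increment_fid(k, t2)
    if acq.noise_sigma > 0:
        rng = np.random.default_rng(acq.seed)
        data = data + acq.noise_sigma * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    meta = {
        "sequence": "psyche-isis",
        "carrier_ppm": ctx.carrier_ppm,
        "larmor_hz": ctx.larmor_hz,
        "b0_t": ctx.b0_t,
        "chunk_mode": params.chunk_mode,
        "selection": params.selection,
        "beta_deg": params.beta_deg,
        "sweep_hz": params.sweep_hz,
        "chirp_duration_s": params.chirp_duration_s,
        "tau_s": params.tau_s,
        "n_increments": params.n_increments,
        "n_z": params.n_z,
        "time_origin_s": params.chirp_duration_s,
        "n_transients": 8 * params.n_increments,
    }
    return Pseudo2D(data=data, dwell_s=acq.dwell_s, tau_s=params.tau_s, meta=meta)
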