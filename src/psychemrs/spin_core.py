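"""Dense density-matrix engine for small networks of J-coupled protons.

All spin dynamics in the package run through this module: Hamiltonian
construction, equilibrium states, hard and shaped pulse propagation, free
evolution, gradient z-rotations, coherence-order filtering and quadrature
detection.  Hilbert space is capped at 8 spins (dimension 256), which is
enough for every bundled metabolite once magnetically equivalent uncoupled
groups are folded into a population ``weight``.

Conventions (fixed once, relied on everywhere else)
---------------------------------------------------
* Rotating frame at the transmitter carrier ``FieldContext.carrier_ppm``.
  Per-spin offset ``nu_i = (shift_ppm_i - carrier_ppm) * larmor_hz * 1e-6``.
* ``H = sum_i 2 pi nu_i I_iz + sum_{i<j} 2 pi J_ij (I_i . I_j)`` in rad/s,
  always the full (strong-coupling) scalar product.
* Propagation ``rho -> exp(-i H t) rho exp(+i H t)``.
* Hard pulse of flip ``theta`` and phase ``phi`` rotates about the axis
  ``(cos phi, sin phi, 0)``: ``U = exp(-i theta (Fx cos phi + Fy sin phi))``.
  A 90deg pulse of phase x sends ``Iz`` to ``-Iy``.
* Detection ``s(t) = Tr(rho(t) F+)`` with ``F+ = Fx + i Fy`` picks the
  coherence-order -1 part of ``rho``; an uncoupled spin at offset ``+nu``
  yields ``s(t) ~ exp(+2 i pi nu t)`` and appears at ``+nu`` Hz, i.e. the
  ppm axis is ``carrier_ppm + f / larmor_hz * 1e6`` (downfield = positive).
* Relaxation is phenomenological: a mono-exponential T2 envelope applied at
  detection only; all pulse/evolution operations are exactly unitary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from types import SimpleNamespace
from typing import Sequence

import numpy as np
from scipy.linalg import eigh

__all__ = [
    "GAMMA_1H_HZ_PER_T",
    "MAX_SPINS",
    "FieldContext",
    "SpinSystem",
    "DensityState",
    "PulseShape",
    "spin_operators",
    "build_hamiltonian",
    "equilibrium_state",
    "apply_hard_pulse",
    "apply_shaped_pulse",
    "free_evolve",
    "rotate_about_z",
    "coherence_filter",
    "detect_fid",
    "make_saltire",
]

#: proton gyromagnetic ratio, gamma / 2 pi  (Hz per tesla)
GAMMA_1H_HZ_PER_T = 42.5775e6

#: Hilbert-space guard: at most 8 coupled spins per subsystem (dim 256)
MAX_SPINS = 8

_HERM_TOL = 1e-10


@dataclass(frozen=True)
class FieldContext:
    """Static-field / transmitter context of an experiment.

    Defaults describe the 7.0 T small-animal scanner geometry with the
    transmitter on water (4.7 ppm), giving 1 ppm ~= 298.04 Hz.
    """

    b0_t: float = 7.0
    carrier_ppm: float = 4.7
    gamma_hz_per_t: float = GAMMA_1H_HZ_PER_T

    @property
    def larmor_hz(self) -> float:
        return self.gamma_hz_per_t * self.b0_t

    def offset_hz(self, shift_ppm) -> np.ndarray | float:
        """Rotating-frame offset of a chemical shift, in Hz."""
        return (np.asarray(shift_ppm, dtype=float) - self.carrier_ppm) * self.larmor_hz * 1e-6

    def hz_to_ppm(self, f_hz) -> np.ndarray | float:
        return self.carrier_ppm + np.asarray(f_hz, dtype=float) / self.larmor_hz * 1e6


@dataclass(frozen=True)
class SpinSystem:
    """A proton network: chemical shifts (ppm) and scalar couplings (Hz).

    ``weight`` is a population multiplier used when subsystem signals are
    summed (e.g. a nine-proton N(CH3)3 group simulated as one spin with
    weight 9 — exact for magnetically equivalent uncoupled protons).
    """

    labels: tuple
    shifts_ppm: tuple
    j_hz: tuple
    t2_s: float | None = None
    t1_s: float | None = None
    weight: float = 1.0

    def __init__(self, labels, shifts_ppm, j_hz, t2_s=None, t1_s=None, weight=1.0):
        labels = tuple(str(l) for l in labels)
        shifts = np.asarray(shifts_ppm, dtype=float)
        j = np.atleast_2d(np.asarray(j_hz, dtype=float))
        n = len(labels)
        if not 1 <= n <= MAX_SPINS:
            raise ValueError(f"need 1..{MAX_SPINS} spins, got {n}")
        if shifts.shape != (n,):
            raise ValueError("shifts_ppm length does not match labels")
        if not np.all(np.isfinite(shifts)):
            raise ValueError("chemical shifts must be finite")
        if j.shape != (n, n):
            raise ValueError(f"J matrix must be {n}x{n}, got {j.shape}")
        if not np.allclose(j, j.T, atol=1e-12):
            raise ValueError("J matrix must be symmetric")
        if np.any(np.abs(np.diag(j)) > 1e-12):
            raise ValueError("J matrix must have zero diagonal")
        for name, val in (("t2_s", t2_s), ("t1_s", t1_s)):
            if val is not None and not val > 0:
                raise ValueError(f"{name} must be > 0 when present")
        if not weight > 0:
            raise ValueError("weight must be > 0")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "shifts_ppm", tuple(float(s) for s in shifts))
        object.__setattr__(self, "j_hz", tuple(tuple(float(x) for x in row) for row in j))
        object.__setattr__(self, "t2_s", None if t2_s is None else float(t2_s))
        object.__setattr__(self, "t1_s", None if t1_s is None else float(t1_s))
        object.__setattr__(self, "weight", float(weight))

    @property
    def n_spins(self) -> int:
        return len(self.labels)

    @property
    def dim(self) -> int:
        return 2 ** self.n_spins

    def shifts(self) -> np.ndarray:
        return np.asarray(self.shifts_ppm, dtype=float)

    def couplings(self) -> np.ndarray:
        return np.asarray(self.j_hz, dtype=float)


@dataclass
class DensityState:
    """Deviation density operator in the Zeeman product basis."""

    matrix: np.ndarray
    basis: str = "zeeman"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=complex)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("density matrix must be square")
        n = int(np.log2(m.shape[0]))
        if 2**n != m.shape[0]:
            raise ValueError("dimension must be a power of two")
        if np.max(np.abs(m - m.conj().T)) > 1e-8 * max(1.0, np.max(np.abs(m))):
            raise ValueError("density matrix is not Hermitian")
        self.matrix = m

    @property
    def n_spins(self) -> int:
        return int(np.log2(self.matrix.shape[0]))

    def copy(self) -> "DensityState":
        return DensityState(self.matrix.copy(), self.basis)


# ---------------------------------------------------------------------------
# spin operators


@lru_cache(maxsize=None)
def spin_operators(n_spins: int) -> SimpleNamespace:
    """Cartesian single-spin and total operators for ``n_spins`` spins-1/2.

    Returns a namespace with tuples ``x, y, z`` of per-spin operators and
    totals ``fx, fy, fz, fplus, fminus`` plus ``order`` (the coherence-order
    matrix ``m_row - m_col``).
    """
    if not 1 <= n_spins <= MAX_SPINS:
        raise ValueError(f"need 1..{MAX_SPINS} spins")
    sx = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
    sy = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
    sz = np.array([[0.5, 0], [0, -0.5]], dtype=complex)
    eye = np.eye(2, dtype=complex)

    def embed(op, k):
        mats = [eye] * n_spins
        mats[k] = op
        out = mats[0]
        for m in mats[1:]:
            out = np.kron(out, m)
        return out

    xs = tuple(embed(sx, k) for k in range(n_spins))
    ys = tuple(embed(sy, k) for k in range(n_spins))
    zs = tuple(embed(sz, k) for k in range(n_spins))
    fx = sum(xs)
    fy = sum(ys)
    fz = sum(zs)
    mz = np.real(np.diag(fz))
    order = mz[:, None] - mz[None, :]
    return SimpleNamespace(
        n=n_spins,
        dim=2**n_spins,
        x=xs,
        y=ys,
        z=zs,
        fx=fx,
        fy=fy,
        fz=fz,
        fplus=fx + 1j * fy,
        fminus=fx - 1j * fy,
        order=order,
    )


# ---------------------------------------------------------------------------
# Hamiltonian and states


def build_hamiltonian(
    system: SpinSystem,
    ctx: FieldContext,
    extra_offset_hz: Sequence[float] | float | None = None,
) -> np.ndarray:
    """Rotating-frame Hamiltonian (rad/s) with full strong-coupling J terms.

    ``extra_offset_hz`` adds a per-spin frequency offset (scalar = same for
    all spins), used for gradient-induced position-dependent offsets.
    """
    n = system.n_spins
    ops = spin_operators(n)
    if extra_offset_hz is None:
        extra = np.zeros(n)
    else:
        arr = np.asarray(extra_offset_hz, dtype=float)
        if arr.ndim == 0:
            extra = np.full(n, float(arr))
        elif arr.shape == (n,):
            extra = arr
        else:
            raise ValueError("extra_offset_hz length must equal n_spins")
    nu = ctx.offset_hz(system.shifts()) + extra
    h = np.zeros((ops.dim, ops.dim), dtype=complex)
    for i in range(n):
        h += 2 * np.pi * nu[i] * ops.z[i]
    j = system.couplings()
    for i in range(n):
        for k in range(i + 1, n):
            if j[i, k] != 0.0:
                h += (
                    2
                    * np.pi
                    * j[i, k]
                    * (ops.x[i] @ ops.x[k] + ops.y[i] @ ops.y[k] + ops.z[i] @ ops.z[k])
                )
    return h


def equilibrium_state(system: SpinSystem) -> DensityState:
    """High-temperature deviation density matrix ``rho_eq = sum_i I_iz``."""
    ops = spin_operators(system.n_spins)
    return DensityState(ops.fz.astype(complex).copy())


# ---------------------------------------------------------------------------
# propagation


def _hard_pulse_propagator(n_spins: int, flip_rad: float, phase_rad: float) -> np.ndarray:
    c, s = np.cos(flip_rad / 2.0), np.sin(flip_rad / 2.0)
    u2 = np.array(
        [
            [c, -1j * np.exp(-1j * phase_rad) * s],
            [-1j * np.exp(1j * phase_rad) * s, c],
        ],
        dtype=complex,
    )
    u = u2
    for _ in range(n_spins - 1):
        u = np.kron(u, u2)
    return u


def apply_hard_pulse(state: DensityState, flip_deg: float, phase_rad: float = 0.0) -> DensityState:
    """Ideal non-selective pulse on all spins."""
    u = _hard_pulse_propagator(state.n_spins, np.deg2rad(flip_deg), phase_rad)
    return DensityState(u @ state.matrix @ u.conj().T, state.basis)


def free_evolve(state: DensityState, h: np.ndarray, t_s: float) -> DensityState:
    """Evolve ``rho -> exp(-iHt) rho exp(+iHt)`` for ``t_s >= 0`` seconds."""
    if t_s < 0:
        raise ValueError("t_s must be >= 0")
    if t_s == 0:
        return state.copy()
    energies, v = eigh(h)
    phases = np.exp(-1j * energies * t_s)
    rho_e = v.conj().T @ state.matrix @ v
    rho_e *= phases[:, None] * phases.conj()[None, :]
    return DensityState(v @ rho_e @ v.conj().T, state.basis)


def rotate_about_z(state: DensityState, phi_rad: float) -> DensityState:
    """Rotation ``exp(-i phi Fz)`` — a gradient-induced phase for each
    coherence order (order p acquires ``exp(-i p phi)``)."""
    ops = spin_operators(state.n_spins)
    ph = np.exp(-1j * phi_rad * np.real(np.diag(ops.fz)))
    return DensityState(ph[:, None] * state.matrix * ph.conj()[None, :], state.basis)


def coherence_filter(state: DensityState, keep_orders: Sequence[int]) -> DensityState:
    """Project onto the given total coherence orders (ideal CTP filter /
    crusher emulation: ``keep_orders=[0]`` purges all transverse terms)."""
    ops = spin_operators(state.n_spins)
    mask = np.isin(np.rint(ops.order).astype(int), list(keep_orders))
    return DensityState(np.where(mask, state.matrix, 0.0), state.basis)


# ---------------------------------------------------------------------------
# shaped pulses


@dataclass(frozen=True)
class PulseShape:
    """Time-discretized RF envelope at uniform step ``dt_s``.

    ``amplitude_hz`` is the nutation-rate envelope (gamma B1 / 2 pi, >= 0);
    ``phase_rad`` the RF phase per sample.  Saltire waveforms are real:
    phases are restricted to {0, pi}.
    """

    amplitude_hz: tuple
    phase_rad: tuple
    dt_s: float
    flip_deg: float
    kind: str = "hard"
    sweep_hz: float | None = None

    def __init__(self, amplitude_hz, phase_rad, dt_s, flip_deg, kind="hard", sweep_hz=None):
        amp = np.asarray(amplitude_hz, dtype=float)
        ph = np.asarray(phase_rad, dtype=float)
        if amp.shape != ph.shape or amp.ndim != 1 or amp.size == 0:
            raise ValueError("amplitude and phase must be equal-length 1-D arrays")
        if np.any(amp < 0):
            raise ValueError("amplitudes must be >= 0")
        if dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        if kind == "saltire":
            ok = np.isclose(ph, 0) | np.isclose(ph, np.pi)
            if not np.all(ok):
                raise ValueError("saltire waveform must be real (phase in {0, pi})")
        object.__setattr__(self, "amplitude_hz", tuple(amp))
        object.__setattr__(self, "phase_rad", tuple(ph))
        object.__setattr__(self, "dt_s", float(dt_s))
        object.__setattr__(self, "flip_deg", float(flip_deg))
        object.__setattr__(self, "kind", str(kind))
        object.__setattr__(self, "sweep_hz", None if sweep_hz is None else float(sweep_hz))

    @property
    def n_samples(self) -> int:
        return len(self.amplitude_hz)

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.dt_s

    @property
    def samples(self) -> np.ndarray:
        """(n, 2) array of (amplitude_hz, phase_rad)."""
        return np.column_stack([self.amplitude_hz, self.phase_rad])

    def signed_amplitude_hz(self) -> np.ndarray:
        """Real waveform ``amp * cos(phase)`` — exact for phases {0, pi}."""
        return np.asarray(self.amplitude_hz) * np.cos(self.phase_rad)


_STEP_GUARD_RAD = 0.2


def apply_shaped_pulse(
    state: DensityState,
    shape: PulseShape,
    h_free: np.ndarray,
    method: str = "exact",
) -> DensityState:
    """Piecewise-constant propagation through a shaped pulse.

    ``method="exact"`` diagonalizes ``H_free + H_rf`` per sample;
    ``method="split"`` uses a symmetric split-step
    ``exp(-iH0 dt/2) exp(-iHrf dt) exp(-iH0 dt/2)`` with cached
    eigendecompositions (error O(dt^3) per step), used by the sequence
    engine where thousands of samples are propagated.
    """
    u = shaped_pulse_propagator(shape, h_free, method=method)
    return DensityState(u @ state.matrix @ u.conj().T, state.basis)


def shaped_pulse_propagator(shape: PulseShape, h_free: np.ndarray, method: str = "exact") -> np.ndarray:
    amp = np.asarray(shape.amplitude_hz)
    max_step = 2 * np.pi * np.max(amp) * shape.dt_s
    if max_step >= _STEP_GUARD_RAD:
        raise ValueError(
            f"per-sample RF rotation {max_step:.3f} rad exceeds the {_STEP_GUARD_RAD} rad "
            "guard; use a finer dt_s"
        )
    n = int(np.log2(h_free.shape[0]))
    ops = spin_operators(n)
    dt = shape.dt_s
    phases = np.asarray(shape.phase_rad)
    if method == "exact":
        u = np.eye(ops.dim, dtype=complex)
        for a, ph in zip(amp, phases):
            h_rf = 2 * np.pi * a * (np.cos(ph) * ops.fx + np.sin(ph) * ops.fy)
            energies, v = eigh(h_free + h_rf)
            u = (v * np.exp(-1j * energies * dt)) @ v.conj().T @ u
        return u
    if method != "split":
        raise ValueError("method must be 'exact' or 'split'")
    # symmetric split-step; fold phase into a signed x amplitude when the
    # waveform is real (saltire), else conjugate the x rotation by Rz(phase)
    e0, v0 = eigh(h_free)
    d_half = np.exp(-1j * e0 * dt / 2.0)
    ex, vx = eigh(ops.fx)
    mz = np.real(np.diag(ops.fz))
    real_waveform = np.all(np.isclose(phases, 0) | np.isclose(phases, np.pi))
    u = np.eye(ops.dim, dtype=complex)
    signed = amp * np.cos(phases)
    for k in range(shape.n_samples):
        if real_waveform:
            theta = 2 * np.pi * signed[k] * dt
            u_rf = (vx * np.exp(-1j * ex * theta)) @ vx.conj().T
        else:
            theta = 2 * np.pi * amp[k] * dt
            rz = np.exp(-1j * phases[k] * mz)
            u_rf = (rz[:, None] * ((vx * np.exp(-1j * ex * theta)) @ vx.conj().T)) * rz.conj()[None, :]
        step = (v0 * d_half) @ (v0.conj().T @ u_rf @ v0) @ ((v0.conj().T) * d_half[:, None])
        u = step @ u
    return u


# ---------------------------------------------------------------------------
# detection


def detect_fid(
    state: DensityState,
    h: np.ndarray,
    n_points: int,
    dwell_s: float,
    t2_s: float | None = None,
    t0_s: float = 0.0,
) -> np.ndarray:
    """Quadrature FID ``s[k] = Tr(rho(k dwell) F+) * exp(-(t0 + k dwell)/T2)``.

    ``t0_s`` is transverse time already elapsed before acquisition; it only
    scales the phenomenological T2 envelope (the state itself must already
    carry any coherent pre-evolution).
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if dwell_s <= 0:
        raise ValueError("dwell_s must be > 0")
    ops = spin_operators(state.n_spins)
    energies, v = eigh(h)
    rho_e = v.conj().T @ state.matrix @ v
    det_e = v.conj().T @ ops.fplus @ v
    # s(t) = sum_ab rho_ab exp(-i (Ea - Eb) t) det_ba
    amp = rho_e * det_e.T
    freqs = energies[:, None] - energies[None, :]
    mask = np.abs(amp) > 1e-14 * max(1.0, np.max(np.abs(amp)))
    a = amp[mask]
    w = freqs[mask]
    t = np.arange(n_points) * dwell_s
    sig = np.exp(-1j * np.outer(t, w)) @ a
    if t2_s is not None:
        if t2_s <= 0:
            raise ValueError("t2_s must be > 0")
        sig = sig * np.exp(-(t0_s + t) / t2_s)
    return sig


# ---------------------------------------------------------------------------
# saltire chirps


@lru_cache(maxsize=64)
def make_saltire(
    flip_deg: float,
    sweep_hz: float,
    duration_s: float,
    dt_s: float | None = None,
    phase0_rad: float = 0.0,
) -> PulseShape:
    """Real (cosine-modulated) saltire chirp, amplitude-calibrated.

    The saltire is the equal-amplitude sum of a low-to-high and a
    high-to-low linear sweep over ``[-sweep/2, +sweep/2]``; with the phase
    referenced to the sweep centre the waveform is
    ``A cos(pi F (t - T/2)^2 / T + phase0)``.  On resonance all RF samples
    share the x axis and commute, so for ``phase0 = 0`` the net flip is
    exactly ``2 pi A dt sum_k cos(Phi_k)`` and the calibration ``A`` for a
    requested flip is closed-form; the propagation oracle in the tests
    checks it.  ``phase0_rad`` offsets the internal chirp phase at fixed
    amplitude (the B1 calibration is always done at phase0 = 0); cycling
    it suppresses mismatched sweep pairings in the pure-shift element.
    """
    if sweep_hz <= 0 or duration_s <= 0:
        raise ValueError("sweep_hz and duration_s must be > 0")
    tb = sweep_hz * duration_s
    if tb < 10:
        warnings.warn(f"time-bandwidth product {tb:.1f} < 10: poor chirp behaviour", stacklevel=2)
    if dt_s is None:
        # resolve the fastest modulation (sweep/2 Hz) with >= 8 samples/cycle
        n = int(max(1000, np.ceil(4 * tb)))
        dt_s = duration_s / n
    n = int(round(duration_s / dt_s))
    if not np.isclose(n * dt_s, duration_s, rtol=1e-9):
        n = int(np.ceil(duration_s / dt_s))
        dt_s = duration_s / n
    t = (np.arange(n) + 0.5) * dt_s
    phi = np.pi * sweep_hz / duration_s * (t - duration_s / 2.0) ** 2
    c = np.cos(phi)
    integral = 2 * np.pi * dt_s * np.sum(c)  # net on-resonance rotation per unit amplitude
    a0 = np.deg2rad(flip_deg) / integral
    if a0 < 0:
        raise RuntimeError("saltire calibration produced negative amplitude")
    wave = a0 * np.cos(phi + phase0_rad)
    return PulseShape(
        amplitude_hz=np.abs(wave),
        phase_rad=np.where(wave >= 0, 0.0, np.pi),
        dt_s=dt_s,
        flip_deg=flip_deg,
        kind="saltire",
        sweep_hz=sweep_hz,
    )
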