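"""Spatial phantom model and the bundled metabolite fixture library.

Phantoms are stacks of axis-aligned box compartments filled with metabolite
mixtures; later compartments override earlier ones where they overlap
(nested-bottle precedence).  Metabolite fixtures are JSON files carrying
proton spin subsystems (shifts in ppm, J matrices in Hz), reference peak
assignments and a nominal concentration.  Chemical shifts printed in the
source experiments (e.g. NAA acetyl 1.98 ppm, Cr methyl 3.00 ppm, the most
upfield propionate multiplet at 0.98 ppm) are pinned in the fixtures; the
remaining shifts and all couplings use standard solution-NMR literature
values, noted per fixture in ``source_note``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .spin_core import SpinSystem

__all__ = [
    "MetaboliteFixture",
    "Compartment",
    "Phantom",
    "Voxel",
    "DiscretizedPhantom",
    "load_metabolite_library",
    "load_fixture",
    "save_fixture",
    "default_library",
    "discretize",
    "voxel_mask",
]


@dataclass(frozen=True)
class MetaboliteFixture:
    """A metabolite: one or more independent proton spin subsystems."""

    name: str
    spin_subsystems: tuple
    reference_peaks_ppm: tuple = ()
    concentration_mm: float = 10.0
    source_note: str = ""

    def __post_init__(self):
        if not self.spin_subsystems:
            raise ValueError(f"fixture {self.name!r}: subsystem list must be non-empty")
        for _, ppm in self.reference_peaks_ppm:
            if not 0.0 <= ppm <= 10.0:
                raise ValueError(
                    f"fixture {self.name!r}: reference peak {ppm} ppm outside [0, 10]"
                )
        if not self.concentration_mm > 0:
            raise ValueError(f"fixture {self.name!r}: concentration must be > 0")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "concentration_mm": self.concentration_mm,
            "source_note": self.source_note,
            "reference_peaks": [[lab, ppm] for lab, ppm in self.reference_peaks_ppm],
            "subsystems": [
                {
                    "labels": list(s.labels),
                    "shifts_ppm": list(s.shifts_ppm),
                    "j_hz": [list(r) for r in s.j_hz],
                    **({"t2_s": s.t2_s} if s.t2_s is not None else {}),
                    **({"t1_s": s.t1_s} if s.t1_s is not None else {}),
                    **({"weight": s.weight} if s.weight != 1.0 else {}),
                }
                for s in self.spin_subsystems
            ],
        }


def _fixture_from_dict(d: Mapping) -> MetaboliteFixture:
    for key in ("name", "subsystems"):
        if key not in d:
            raise ValueError(f"metabolite fixture missing required field {key!r}")
    subs = []
    for i, s in enumerate(d["subsystems"]):
        for key in ("labels", "shifts_ppm", "j_hz"):
            if key not in s:
                raise ValueError(
                    f"fixture {d['name']!r} subsystem {i}: missing field {key!r}"
                )
        try:
            subs.append(
                SpinSystem(
                    labels=s["labels"],
                    shifts_ppm=s["shifts_ppm"],
                    j_hz=s["j_hz"],
                    t2_s=s.get("t2_s"),
                    t1_s=s.get("t1_s"),
                    weight=s.get("weight", 1.0),
                )
            )
        except ValueError as exc:
            raise ValueError(f"fixture {d['name']!r} subsystem {i}: {exc}") from exc
    return MetaboliteFixture(
        name=str(d["name"]),
        spin_subsystems=tuple(subs),
        reference_peaks_ppm=tuple((str(l), float(p)) for l, p in d.get("reference_peaks", [])),
        concentration_mm=float(d.get("concentration_mm", 10.0)),
        source_note=str(d.get("source_note", "")),
    )


def load_fixture(path) -> MetaboliteFixture:
    with open(path) as fh:
        return _fixture_from_dict(json.load(fh))


def save_fixture(fixture: MetaboliteFixture, path) -> None:
    with open(path, "w") as fh:
        json.dump(fixture.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_metabolite_library(path=None) -> dict:
    """Load all ``*.json`` metabolite fixtures from a directory.

    With ``path=None`` the library bundled with the package is returned
    (Prop, GABA, NAA, Cr, Cho, mI, Tau, Asp and a stress-test water
    fixture).  Keys are fixture names.
    """
    if path is None:
        root = resources.files("psychemrs").joinpath("data/metabolites")
        files = sorted(p for p in root.iterdir() if p.name.endswith(".json"))
    else:
        root = Path(path)
        if not root.exists():
            raise FileNotFoundError(f"no such metabolite library: {root}")
        files = sorted(root.glob("*.json"))
    lib = {}
    for f in files:
        fx = _fixture_from_dict(json.loads(f.read_text()))
        lib[fx.name] = fx
    if not lib:
        raise ValueError(f"no metabolite fixtures found under {path!r}")
    return lib


def default_library() -> dict:
    return load_metabolite_library(None)


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class Compartment:
    """Axis-aligned box filled with a metabolite mixture.

    ``bounds_mm``: ((xmin, xmax), (ymin, ymax), (zmin, zmax));
    ``mixture``: mapping metabolite name -> relative concentration (> 0).
    """

    bounds_mm: tuple
    mixture: tuple

    def __init__(self, bounds_mm, mixture):
        b = tuple((float(lo), float(hi)) for lo, hi in bounds_mm)
        if len(b) != 3:
            raise ValueError("bounds_mm must give (min, max) for x, y, z")
        for lo, hi in b:
            if not lo < hi:
                raise ValueError(f"compartment bounds need min < max, got ({lo}, {hi})")
        if isinstance(mixture, Mapping):
            mix = tuple((str(k), float(v)) for k, v in mixture.items())
        else:
            mix = tuple((str(k), float(v)) for k, v in mixture)
        if not mix:
            raise ValueError("compartment mixture must be non-empty")
        for name, conc in mix:
            if not conc > 0:
                raise ValueError(f"mixture concentration for {name!r} must be > 0")
        object.__setattr__(self, "bounds_mm", b)
        object.__setattr__(self, "mixture", mix)

    def contains(self, positions_mm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(positions_mm)
        ok = np.ones(p.shape[0], dtype=bool)
        for ax, (lo, hi) in enumerate(self.bounds_mm):
            ok &= (p[:, ax] >= lo) & (p[:, ax] < hi)
        return ok


@dataclass(frozen=True)
class Phantom:
    """Ordered compartments (later entries override earlier at overlaps)
    plus an isotropic discretization step."""

    compartments: tuple
    grid_step_mm: float = 1.0

    def __init__(self, compartments, grid_step_mm=1.0):
        comps = tuple(compartments)
        if not comps:
            raise ValueError("phantom needs at least one compartment")
        if not grid_step_mm > 0:
            raise ValueError("grid_step_mm must be > 0")
        object.__setattr__(self, "compartments", comps)
        object.__setattr__(self, "grid_step_mm", float(grid_step_mm))

    def bounding_box(self) -> np.ndarray:
        lo = np.min([[b[0] for b in c.bounds_mm] for c in self.compartments], axis=0)
        hi = np.max([[b[1] for b in c.bounds_mm] for c in self.compartments], axis=0)
        return np.array([lo, hi])


@dataclass(frozen=True)
class Voxel:
    """The selected cuboid volume: centre and edge lengths in mm."""

    center_mm: tuple
    size_mm: tuple

    def __init__(self, center_mm, size_mm):
        c = tuple(float(x) for x in center_mm)
        s = tuple(float(x) for x in size_mm)
        if len(c) != 3 or len(s) != 3:
            raise ValueError("voxel needs 3-D centre and size")
        if not all(x > 0 for x in s):
            raise ValueError("voxel sizes must be > 0")
        object.__setattr__(self, "center_mm", c)
        object.__setattr__(self, "size_mm", s)

    def bounds(self) -> np.ndarray:
        c, s = np.array(self.center_mm), np.array(self.size_mm)
        return np.array([c - s / 2.0, c + s / 2.0])


@dataclass(frozen=True)
class DiscretizedPhantom:
    """Grid-cell centres with the mixture of the containing compartment.

    Iterating yields ``(position_mm, mixture)`` tuples; vectorized access
    via ``positions_mm`` (N, 3) and ``mixture_index`` into ``mixtures``.
    """

    positions_mm: np.ndarray
    mixture_index: np.ndarray
    mixtures: tuple

    def __len__(self) -> int:
        return self.positions_mm.shape[0]

    def __iter__(self) -> Iterator:
        for pos, idx in zip(self.positions_mm, self.mixture_index):
            yield tuple(pos), self.mixtures[idx]


def discretize(phantom: Phantom) -> DiscretizedPhantom:
    """Deterministic enumeration of grid-cell centres inside compartments.

    Cells are centred at ``lo + (i + 1/2) step`` on each axis of the
    phantom bounding box, in C order (x outer, z inner).  A cell belongs to
    the *last* compartment containing it; cells outside all compartments
    are excluded.
    """
    import warnings as _warnings

    step = phantom.grid_step_mm
    lo, hi = phantom.bounding_box()
    smallest = min(
        min(b[1] - b[0] for b in c.bounds_mm) for c in phantom.compartments
    )
    if smallest / step < 2:
        _warnings.warn(
            f"grid step {step} mm gives < 2 cells across the smallest compartment "
            f"dimension ({smallest} mm)",
            stacklevel=2,
        )
    axes = [lo[ax] + (np.arange(max(1, int(round((hi[ax] - lo[ax]) / step)))) + 0.5) * step for ax in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pos = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    owner = np.full(pos.shape[0], -1, dtype=int)
    for i, comp in enumerate(phantom.compartments):
        owner[comp.contains(pos)] = i
    keep = owner >= 0
    return DiscretizedPhantom(
        positions_mm=pos[keep],
        mixture_index=owner[keep],
        mixtures=tuple(c.mixture for c in phantom.compartments),
    )


def voxel_mask(positions_mm: np.ndarray, voxel: Voxel) -> np.ndarray:
    """Half-open box membership test ``[centre - size/2, centre + size/2)``
    per axis (a position exactly on the +face is outside)."""
    p = np.atleast_2d(np.asarray(positions_mm, dtype=float))
    lo, hi = voxel.bounds()
    return np.all((p >= lo) & (p < hi), axis=1)
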