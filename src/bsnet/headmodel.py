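"""Analytic EEG forward model for concentric-sphere volume conductors.

The head is modeled as five nested spherical shells (white matter, grey
matter, CSF, skull, scalp), each with a homogeneous isotropic conductivity.
The potential generated on the scalp by a current dipole inside the
innermost sphere is the classical Legendre-series solution: per spherical
harmonic degree ``n`` the radial profile in every shell is a combination of
``r^n`` and ``r^-(n+1)``, matched across shell boundaries by continuity of
potential and of radial current density, with zero radial current through
the scalp surface.  The series is evaluated with stable three-term
recurrences for ``P_n`` and ``P_n'`` and truncated adaptively.

Conventions: origin at the sphere center, +x right, +y anterior,
+z superior; distances in mm, conductivities in S/m, dipole moments in
nA*m, potentials in microvolts, average-referenced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ElectrodeMontage",
    "SphereModel",
    "SourceGrid",
    "LeadField",
    "standard_montage_1020",
    "build_sphere_model",
    "build_source_grid",
    "dipole_potential",
    "compute_leadfield",
    "apply_average_reference",
    "save_leadfield",
    "load_leadfield",
]

#: Default infant-scaled shell radii in mm (innermost -> outermost):
#: white matter, grey matter, CSF, skull, scalp.
DEFAULT_RADII_MM = (58.0, 60.0, 62.0, 65.0, 70.0)
#: Default shell conductivities in S/m, same order.  The neonatal skull is
#: substantially more conductive than the adult one.
DEFAULT_CONDUCTIVITIES = (0.33, 0.33, 1.79, 0.04, 0.33)

_SERIES_RTOL = 1e-8
_SERIES_MAX_TERMS = 200


@dataclass(frozen=True)
class SphereModel:
    """Concentric-spheres volume conductor (5 shells, innermost first)."""

    radii: tuple[float, ...]
    conductivities: tuple[float, ...]

    @property
    def scalp_radius(self) -> float:
        return self.radii[-1]

    @property
    def inner_radius(self) -> float:
        return self.radii[0]


@dataclass(frozen=True)
class ElectrodeMontage:
    """Scalp electrode set: unique labels and positions on the outer shell."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), mm

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.positions, columns=["x", "y", "z"])
        df.insert(0, "label", list(self.labels))
        df.to_csv(path, sep="\t", index=False)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(",".join(self.labels).encode())
        h.update(np.ascontiguousarray(np.round(self.positions, 9)).tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class SourceGrid:
    """Regular cubic lattice of candidate source points inside the brain."""

    points: np.ndarray  # (n_points, 3), mm
    spacing: float

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class LeadField:
    """Gain tensor: scalp potential (uV) per unit dipole moment (nA*m).

    ``gain[e, g, o]`` is the average-referenced potential at electrode ``e``
    for a unit dipole at grid point ``g`` oriented along axis ``o``.
    """

    gain: np.ndarray  # (n_channels, n_points, 3)
    montage: ElectrodeMontage
    grid: SourceGrid
    model: SphereModel = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

def _ring(alpha_deg: float, side: int, incl_deg: float = 72.0) -> np.ndarray:
    """Unit vector on the circumferential 10% ring.

    ``alpha_deg`` is the angle along the ring from the anterior midline;
    ``side`` is -1 for left (x<0), +1 for right.
    """
    th = np.deg2rad(incl_deg)
    al = np.deg2rad(alpha_deg)
    return np.array([side * np.sin(th) * np.sin(al), np.sin(th) * np.cos(al), np.cos(th)])


def _sagittal(incl_deg: float) -> np.ndarray:
    """Unit vector on the nasion-inion midline arc; positive = anterior."""
    th = np.deg2rad(incl_deg)
    return np.array([0.0, np.sin(th), np.cos(th)])


def _coronal(incl_deg: float, side: int) -> np.ndarray:
    th = np.deg2rad(incl_deg)
    return np.array([side * np.sin(th), 0.0, np.cos(th)])


def _midarc(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    w = u + v
    return w / np.linalg.norm(w)


def standard_montage_1020(n_channels: int = 19) -> ElectrodeMontage:
    """Canonical 10-20 electrode positions on the scalp sphere.

    The idealized geometric construction of the 10-20 system is used: the
    nasion-inion and ear-to-ear arcs are divided in 10/20% steps, the
    circumferential "10% ring" sits at 72 deg inclination, and F3/F4/P3/P4
    lie on the great-circle midpoints between the midline and ring
    electrodes of their row.  Supported sets: 19 channels (Fp1..O2) or 21
    (adds Fpz and Oz).
    """
    if n_channels not in (19, 21):
        raise ValueError(f"unsupported 10-20 channel count: {n_channels} (use 19 or 21)")

    units: dict[str, np.ndarray] = {
        "Cz": np.array([0.0, 0.0, 1.0]),
        "Fz": _sagittal(36.0),
        "Pz": _sagittal(-36.0),
        "C3": _coronal(36.0, -1),
        "C4": _coronal(36.0, +1),
        "T7": _coronal(72.0, -1),
        "T8": _coronal(72.0, +1),
        "Fp1": _ring(18.0, -1),
        "Fp2": _ring(18.0, +1),
        "F7": _ring(54.0, -1),
        "F8": _ring(54.0, +1),
        "P7": _ring(126.0, -1),
        "P8": _ring(126.0, +1),
        "O1": _ring(162.0, -1),
        "O2": _ring(162.0, +1),
    }
    units["F3"] = _midarc(units["Fz"], units["F7"])
    units["F4"] = _midarc(units["Fz"], units["F8"])
    units["P3"] = _midarc(units["Pz"], units["P7"])
    units["P4"] = _midarc(units["Pz"], units["P8"])

    labels = [
        "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
        "T7", "C3", "Cz", "C4", "T8",
        "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
    ]
    if n_channels == 21:
        units["Fpz"] = _sagittal(72.0)
        units["Oz"] = _sagittal(-72.0)
        labels = labels[:2] + ["Fpz"] + labels[2:17] + ["Oz"] + labels[17:]

    scalp_r = DEFAULT_RADII_MM[-1]
    pos = np.stack([units[lab] for lab in labels]) * scalp_r
    return ElectrodeMontage(labels=tuple(labels), positions=pos)


# ---------------------------------------------------------------------------
# volume conductor
# ---------------------------------------------------------------------------

def build_sphere_model(
    radii: tuple[float, ...] = DEFAULT_RADII_MM,
    conductivities: tuple[float, ...] = DEFAULT_CONDUCTIVITIES,
) -> SphereModel:
    """Validate and build a five-shell concentric-spheres model."""
    radii = tuple(float(r) for r in radii)
    conductivities = tuple(float(c) for c in conductivities)
    if len(radii) != 5 or len(conductivities) != 5:
        raise ValueError("exactly 5 shells are required")
    if not all(b > a for a, b in zip(radii, radii[1:])):
        raise ValueError(f"shell radii must be strictly increasing, got {radii}")
    if not all(c > 0 for c in conductivities):
        raise ValueError(f"shell conductivities must be positive, got {conductivities}")
    return SphereModel(radii=radii, conductivities=conductivities)


def build_source_grid(model: SphereModel, spacing: float = 8.0) -> SourceGrid:
    """Cubic lattice (multiples of ``spacing``) clipped to the brain interior.

    Points satisfy ``|r| < r_inner - spacing/2`` so every source keeps a
    safety margin to the innermost boundary.
    """
    if not 0 < spacing < model.inner_radius:
        raise ValueError(f"spacing must be in (0, {model.inner_radius}), got {spacing}")
    rmax = model.inner_radius - spacing / 2.0
    kmax = int(np.floor(rmax / spacing))
    ax = np.arange(-kmax, kmax + 1) * spacing
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) < rmax]
    if pts.shape[0] == 0:
        raise ValueError(f"spacing {spacing} mm leaves no grid point inside the brain")
    # lexicographic order for a deterministic, index-stable grid
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    return SourceGrid(points=pts[order], spacing=float(spacing))


@lru_cache(maxsize=16)
def _radial_transfer(model: SphereModel, n_max: int) -> np.ndarray:
    """Per-degree surface transfer coefficients of the layered sphere.

    For each harmonic degree ``n`` solves the radial boundary-value problem
    with a unit primary coefficient on ``(rho/h1)^-(n+1)`` in the innermost
    shell (``rho`` = radius / scalp radius, ``h1`` = normalized inner
    radius) and returns the potential at the scalp surface.  In the
    homogeneous limit this reduces to ``h1^(n+1) * (2n+1)/n``.
    """
    radii = np.asarray(model.radii) / model.radii[-1]
    sig = np.asarray(model.conductivities)
    m = len(radii)
    t = np.empty(n_max, dtype=float)
    for n in range(1, n_max + 1):
        # unknowns: A1, (A2,B2), ..., (Am,Bm)
        n_unk = 2 * m - 1
        M = np.zeros((n_unk, n_unk))
        rhs = np.zeros(n_unk)

        def idx(j: int) -> int:  # index of A_j (B_j = idx+1, j >= 2)
            return 0 if j == 1 else 1 + 2 * (j - 2)

        row = 0
        for j in range(1, m):  # interface between shell j and j+1 at radii[j-1]
            kap = radii[j - 1] / radii[j]
            kn = kap**n
            km = kap ** (-(n + 1))
            # potential continuity
            M[row, idx(j)] += 1.0
            if j >= 2:
                M[row, idx(j) + 1] += 1.0
            M[row, idx(j + 1)] -= kn
            M[row, idx(j + 1) + 1] -= km
            if j == 1:
                rhs[row] = -1.0  # primary term value at the boundary
            row += 1
            # radial current continuity (rho * dG/drho form)
            M[row, idx(j)] += sig[j - 1] * n
            if j >= 2:
                M[row, idx(j) + 1] += -sig[j - 1] * (n + 1)
            M[row, idx(j + 1)] -= sig[j] * n * kn
            M[row, idx(j + 1) + 1] -= -sig[j] * (n + 1) * km
            if j == 1:
                rhs[row] = sig[0] * (n + 1)  # move primary derivative to rhs
            row += 1
        # no radial current through the scalp surface
        M[row, idx(m)] = n
        M[row, idx(m) + 1] = -(n + 1)
        sol = np.linalg.solve(M, rhs)
        t[n - 1] = sol[idx(m)] + sol[idx(m) + 1]
    return t


def _potentials(
    model: SphereModel,
    montage: ElectrodeMontage,
    locations: np.ndarray,
    moments: np.ndarray,
    n_terms: int = _SERIES_MAX_TERMS,
    rtol: float = _SERIES_RTOL,
) -> np.ndarray:
    """Series evaluation for a batch of dipoles.

    locations: (G, 3) mm, moments: (G, 3) nA*m -> potentials (G, E) uV,
    average-referenced.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    moments = np.atleast_2d(np.asarray(moments, dtype=float))
    a = np.linalg.norm(locations, axis=1)  # (G,)
    if np.any(a >= model.inner_radius):
        bad = locations[a >= model.inner_radius][0]
        raise ValueError(f"dipole location {bad} outside the innermost shell")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")

    tcoef = _radial_transfer(model, max(n_terms, 1))
    r_scalp_m = model.scalp_radius * 1e-3
    h1 = model.inner_radius / model.scalp_radius
    # SI prefactor: unit-nA*m dipole, potentials in uV
    pref = 1e-9 / (4.0 * np.pi * model.conductivities[0] * (r_scalp_m * h1) ** 2) * 1e6

    e_hat = montage.positions / np.linalg.norm(montage.positions, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        a_hat = np.where(a[:, None] > 0, locations / np.where(a > 0, a, 1.0)[:, None], 0.0)
    a_hat[a == 0] = np.array([0.0, 0.0, 1.0])  # direction is immaterial at the center

    u = a_hat @ e_hat.T  # (G, E) cos(angle dipole-electrode)
    q_r = np.einsum("gi,gi->g", moments, a_hat)  # radial moment component
    # w = q . (e_hat - u * a_hat): tangential moment projected toward the electrode
    w = moments @ e_hat.T - q_r[:, None] * u

    x = (a / model.inner_radius)[:, None]  # (G, 1), < 1
    xp = np.ones_like(x)  # x^(n-1)

    p_prev = np.ones_like(u)  # P_0
    p_cur = u.copy()  # P_1
    dp_prev = np.zeros_like(u)  # P'_0
    dp_cur = np.ones_like(u)  # P'_1

    out = np.zeros_like(u)
    scale = np.zeros(u.shape[0])
    for n in range(1, n_terms + 1):
        term = tcoef[n - 1] * xp * (n * q_r[:, None] * p_cur + w * dp_cur)
        out += term
        scale = np.maximum(scale, np.max(np.abs(out), axis=1))
        tmax = np.max(np.abs(term), axis=1)
        if n >= 8 and np.all(tmax <= rtol * np.maximum(scale, 1e-300)):
            break
        p_next = ((2 * n + 1) * u * p_cur - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
        xp = xp * x
    out *= pref
    return apply_average_reference(out.T).T


def dipole_potential(
    model: SphereModel,
    montage: ElectrodeMontage,
    location: np.ndarray,
    moment: np.ndarray,
    n_terms: int = _SERIES_MAX_TERMS,
) -> np.ndarray:
    """Average-referenced scalp potentials (uV) of one dipole (nA*m)."""
    return _potentials(model, montage, np.asarray(location), np.asarray(moment), n_terms)[0]


def compute_leadfield(
    model: SphereModel,
    montage: ElectrodeMontage,
    grid: SourceGrid,
    n_terms: int = _SERIES_MAX_TERMS,
) -> LeadField:
    """Gain tensor for unit dipoles along x, y, z at every grid point."""
    gains = []
    eye = np.eye(3)
    for o in range(3):
        mom = np.tile(eye[o], (grid.n_points, 1))
        gains.append(_potentials(model, montage, grid.points, mom, n_terms).T)
    gain = np.stack(gains, axis=2)  # (E, G, 3)
    if not np.all(np.isfinite(gain)):
        raise FloatingPointError("non-finite lead field entries")
    return LeadField(gain=gain, montage=montage, grid=grid, model=model)


def apply_average_reference(signals: np.ndarray) -> np.ndarray:
    """Re-reference channels x time (or channels x anything) to the mean."""
    signals = np.asarray(signals, dtype=float)
    if signals.ndim == 1 or signals.shape[0] < 2:
        raise ValueError("average reference requires at least 2 channels")
    return signals - signals.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# lead field cache
# ---------------------------------------------------------------------------

def save_leadfield(lf: LeadField, path: str | Path) -> None:
    """Cache a lead field as .npy plus a JSON sidecar with provenance."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), lf.gain)
    meta = {
        "radii_mm": list(lf.model.radii),
        "conductivities_s_per_m": list(lf.model.conductivities),
        "spacing_mm": lf.grid.spacing,
        "montage_hash": lf.montage.content_hash(),
        "labels": list(lf.montage.labels),
        "n_points": lf.grid.n_points,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_leadfield(path: str | Path, montage: ElectrodeMontage, grid: SourceGrid,
                   model: SphereModel) -> LeadField:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta["montage_hash"] != montage.content_hash():
        raise ValueError("cached lead field was computed for a different montage")
    if meta["spacing_mm"] != grid.spacing or meta["n_points"] != grid.n_points:
        raise ValueError("cached lead field was computed for a different grid")
    gain = np.load(path.with_suffix(".npy"))
    return LeadField(gain=gain, montage=montage, grid=grid, model=model)
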