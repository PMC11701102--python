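"""Helical lattice geometry of ring-shaped assemblies.

Given one anchor point per spoke (for the gamma-tubulin ring, the Cα of
Gln12 of each gamma-tubulin; for the microtubule reference, Gln15 of each
alpha-tubulin), these routines fit the helical axis and summarise the
lattice as radius, twist per spoke and rise per spoke, mean ± SD — the
quantities that decide whether a ring presents a microtubule-compatible
nucleation template.

Axis fitting is two-stage: an initial direction from the smallest-variance
principal component of the centred anchors (the normal of the best-fit
circle plane), then nonlinear least-squares refinement of four parameters
(two direction angles, two in-plane origin offsets) minimising the spread of
the radial distances.  The axis direction is signed so that the mean rise
along it is non-negative.

Statistics convention: radius over all N anchors; twist and rise over the
N−1 successive steps (14 spokes define 13 steps); SD is the population
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .structure_io import Selection, StructureModel, select_atoms

__all__ = [
    "AnchorSet",
    "HelixAxis",
    "HelicalParams",
    "LatticeComparison",
    "AxisFitError",
    "extract_anchors",
    "fit_axis",
    "helical_parameters",
    "compare_lattices",
]


class AxisFitError(ValueError):
    """Degenerate anchor geometry: axis fitting is not possible."""


@dataclass
class AnchorSet:
    """Ordered per-spoke anchor points.

    ``labels`` carries (spoke_index, chain_id) per point with spoke_index
    strictly increasing; ``source`` records the anchor rule (residue + atom).
    """

    points: np.ndarray  # (N, 3), Angstrom
    labels: list[tuple[int, str]] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not self.labels:
            self.labels = [(i + 1, "") for i in range(len(self.points))]
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points length mismatch")
        idx = [i for i, _ in self.labels]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("spoke_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class HelixAxis:
    """A line in space: point ``origin`` plus unit ``direction``."""

    origin: tuple[float, float, float]
    direction: tuple[float, float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("axis direction must be a unit vector")

    @property
    def o(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    @property
    def d(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)


@dataclass(frozen=True)
class HelicalParams:
    """Radius / twist / rise summary of a helical lattice (mean ± SD)."""

    n_points: int
    radius_mean: float  # Angstrom
    radius_sd: float
    twist_mean: float  # degrees per step, in (0, 360)
    twist_sd: float
    rise_mean: float  # Angstrom per step
    rise_sd: float
    handedness: str = "right"  # {right, left}

    def __post_init__(self) -> None:
        if self.radius_mean <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 < self.twist_mean < 360.0:
            raise ValueError("twist must lie in (0, 360) degrees")
        if min(self.radius_sd, self.twist_sd, self.rise_sd) < 0:
            raise ValueError("SDs must be non-negative")
        if self.handedness not in ("right", "left"):
            raise ValueError("handedness must be 'right' or 'left'")

    @property
    def n_steps(self) -> int:
        return self.n_points - 1


@dataclass(frozen=True)
class LatticeComparison:
    """Per-parameter |Δ| between two lattices and a compatibility verdict.

    ``compatible`` is true iff every absolute difference is within the sum
    of the two SDs — the descriptive sense in which two lattices are
    indistinguishable at their stated spread.
    """

    query: HelicalParams
    reference: HelicalParams
    radius_diff: float
    twist_diff: float
    rise_diff: float
    radius_compatible: bool
    twist_compatible: bool
    rise_compatible: bool

    @property
    def compatible(self) -> bool:
        return self.radius_compatible and self.twist_compatible and self.rise_compatible


def extract_anchors(
    model: StructureModel,
    ordered_chains: Sequence[str],
    residue_number: int,
    atom_name: str = "CA",
) -> AnchorSet:
    """One anchor per chain, in the given (ring) order.

    The chain order is the spoke order around the ring; it is an explicit
    input because deposited chain naming need not follow the ring.
    """
    points = []
    labels = []
    for i, chain in enumerate(ordered_chains, start=1):
        sel = Selection.of(chains=chain, residues=residue_number, atoms=atom_name)
        hits = [a for a in select_atoms(model, sel) if not a.is_hydrogen]
        if not hits:
            raise ValueError(
                f"anchor atom {atom_name} not found in chain {chain!r} "
                f"residue {residue_number} of {model.identifier!r}"
            )
        points.append(hits[0].xyz)
        labels.append((i, chain))
    return AnchorSet(
        points=np.array(points),
        labels=labels,
        source=f"residue {residue_number}, atom {atom_name}",
    )


def _frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """A deterministic right-handed in-plane frame (e1, e2) for axis d."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ d) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ d) * d
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(d, e1)


def _radial_residuals(params: np.ndarray, pts: np.ndarray, centroid: np.ndarray,
                      d0: np.ndarray, e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    # direction as a tilt of the initial guess (nonsingular near d0),
    # origin as in-plane offsets from the centroid
    a, b, u, v = params
    d = d0 + a * e1 + b * e2
    d = d / np.linalg.norm(d)
    origin = centroid + u * e1 + v * e2
    rel = pts - origin
    radial = rel - np.outer(rel @ d, d)
    r = np.linalg.norm(radial, axis=1)
    return r - r.mean()


def _helix_residuals(params: np.ndarray, pts: np.ndarray, centroid: np.ndarray,
                     d0: np.ndarray, e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    # ideal-helix model: point k at origin + r·(cos φ_k ê1 + sin φ_k ê2)
    # + (z0 + k·h)·d with φ_k = φ0 + k·τ; residuals are the 3N coordinate
    # differences, so the axis is constrained by the full lattice, not just
    # the radial spread
    a, b, u, v, radius, tau, rise, phi0, z0 = params
    d = d0 + a * e1 + b * e2
    d = d / np.linalg.norm(d)
    f1, f2 = _frame(d)
    origin = centroid + u * e1 + v * e2
    k = np.arange(len(pts))
    phi = phi0 + k * tau
    model = (
        origin
        + radius * (np.cos(phi)[:, None] * f1 + np.sin(phi)[:, None] * f2)
        + (z0 + k * rise)[:, None] * d
    )
    return (pts - model).ravel()


def fit_axis(anchors: AnchorSet) -> HelixAxis:
    """Fit the helical axis to ≥4 anchor points.

    Minimises the variance of point-axis radial distances; deterministic for
    fixed input.  Raises :class:`AxisFitError` for collinear or coincident
    points.
    """
    pts = anchors.points
    n = len(pts)
    if n < 4:
        raise AxisFitError(f"need at least 4 anchors to fit an axis, got {n}")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    cov = centred.T @ centred
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-12 * max(evals[2], 1.0):
        raise AxisFitError("anchors are collinear or coincident")
    # initial direction: successive chords of a helix traversed in ring
    # order have cross products all pointing along the axis, whatever the
    # pitch; fall back to the smallest-variance principal component for
    # unordered/degenerate clouds
    chords = np.diff(pts, axis=0)
    crosses = np.cross(chords[:-1], chords[1:])
    mean_cross = crosses.mean(axis=0)
    if np.linalg.norm(mean_cross) > 1e-8 * np.abs(crosses).max():
        d0 = mean_cross / np.linalg.norm(mean_cross)
    else:
        d0 = evecs[:, 0]
    e1, e2 = _frame(d0)

    # origin initialiser: algebraic (Kasa) circle fit of the anchors
    # projected on the initial plane — the centroid of a partial arc can sit
    # far from the true centre
    x = centred @ e1
    y = centred @ e2
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    sol, *_ = np.linalg.lstsq(A, x**2 + y**2, rcond=None)
    u0, v0 = float(sol[0]), float(sol[1])

    # stage 1: minimise the spread of radial distances (direction tilt +
    # in-plane origin)
    stage1 = least_squares(
        _radial_residuals,
        x0=np.array([0.0, 0.0, u0, v0]),
        args=(pts, centroid, d0, e1, e2),
        method="lm",
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    a, b, u, v = stage1.x

    # stage 2: refine against the full ideal-helix model; the radial spread
    # alone under-constrains the tilt of a ~single-turn ring
    d1 = d0 + a * e1 + b * e2
    d1 /= np.linalg.norm(d1)
    origin1 = centroid + u * e1 + v * e2
    r_i, theta_i, z_i = _cylindrical(pts, HelixAxis(tuple(origin1), tuple(d1)))
    dtheta = np.diff(theta_i)
    dtheta = (dtheta + np.pi) % (2 * np.pi) - np.pi
    x0 = np.array([a, b, u, v, r_i.mean(), dtheta.mean(), np.diff(z_i).mean(),
                   theta_i[0], z_i[0]])
    # stage-2 frame must match the one _helix_residuals derives from d
    f1, f2 = _frame(d1)
    phi0 = float(np.arctan2((pts[0] - origin1 - z_i[0] * d1) @ f2,
                            (pts[0] - origin1 - z_i[0] * d1) @ f1))
    x0[7] = phi0
    stage2 = least_squares(
        _helix_residuals,
        x0=x0,
        args=(pts, centroid, d0, e1, e2),
        method="lm",
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if stage2.success and np.all(np.isfinite(stage2.x)):
        a, b, u, v = stage2.x[:4]
    d = d0 + a * e1 + b * e2
    d = d / np.linalg.norm(d)
    origin = centroid + u * e1 + v * e2
    # sign: mean rise along the axis is non-negative; tie-break on +z then +x
    z = (pts - origin) @ d
    mean_step = np.diff(z).mean() if n > 1 else 0.0
    if abs(mean_step) < 1e-9:
        if d[2] < 0 or (abs(d[2]) < 1e-12 and (d[0] < 0 or (abs(d[0]) < 1e-12 and d[1] < 0))):
            d = -d
    elif mean_step < 0:
        d = -d
    d = d / np.linalg.norm(d)
    # place the origin at the foot of the centroid's perpendicular for a
    # reproducible representative point
    origin = origin + ((centroid - origin) @ d) * d
    return HelixAxis(origin=tuple(origin), direction=tuple(d))


def _cylindrical(pts: np.ndarray, axis: HelixAxis) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Radius, azimuth (rad) and height of each point about the axis."""
    d = axis.d
    rel = pts - axis.o
    z = rel @ d
    radial = rel - np.outer(z, d)
    r = np.linalg.norm(radial, axis=1)
    e1, e2 = _frame(d)
    theta = np.arctan2(radial @ e2, radial @ e1)
    return r, theta, z


def helical_parameters(anchors: AnchorSet, axis: HelixAxis) -> HelicalParams:
    """Radius / twist / rise statistics of the anchors about the axis.

    Twist angles are the per-step azimuth increments, unwrapped into
    (0°, 360°) in the rotational sense of the lattice; handedness is the
    sign of that sense relative to the rise direction.  Consecutive anchors
    must advance monotonically in one rotational sense (supply spokes in
    ring order).
    """
    n = len(anchors)
    if n < 3:
        raise ValueError(f"need at least 3 anchors (2 steps), got {n}")
    r, theta, z = _cylindrical(anchors.points, axis)
    # signed step angles in (-180, 180]; a ring lattice advances < 180°/step
    dtheta = np.degrees(np.diff(theta))
    dtheta = (dtheta + 180.0) % 360.0 - 180.0
    dz = np.diff(z)
    sense = np.sign(dtheta.mean()) or 1.0
    handedness = "right" if sense > 0 else "left"
    twist = (dtheta * sense) % 360.0
    return HelicalParams(
        n_points=n,
        radius_mean=float(r.mean()),
        radius_sd=float(r.std(ddof=0)),
        twist_mean=float(twist.mean()),
        twist_sd=float(twist.std(ddof=0)),
        rise_mean=float(dz.mean()),
        rise_sd=float(dz.std(ddof=0)),
        handedness=handedness,
    )


def compare_lattices(query: HelicalParams, reference: HelicalParams) -> LatticeComparison:
    """Absolute per-parameter differences and the SD-sum compatibility flag."""
    rd = abs(query.radius_mean - reference.radius_mean)
    td = abs(query.twist_mean - reference.twist_mean)
    zd = abs(query.rise_mean - reference.rise_mean)
    return LatticeComparison(
        query=query,
        reference=reference,
        radius_diff=rd,
        twist_diff=td,
        rise_diff=zd,
        radius_compatible=rd <= query.radius_sd + reference.radius_sd,
        twist_compatible=td <= query.twist_sd + reference.twist_sd,
        rise_compatible=zd <= query.rise_sd + reference.rise_sd,
    )
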