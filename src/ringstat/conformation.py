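"""Rigid-body superposition and domain-motion measurements.

The oligomerisation hinge of GCP-family proteins is quantified the classic
way: pair Cα atoms between two models of the same protein, superpose on a
selection with the least-squares optimal rotation (Kabsch), and report the
RMSD over that selection.  Element displacements (e.g. CM1-helix shifts
between receptor systems) are measured as the distance between selection
centroids after aligning both models on a shared frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Selection, StructureModel, select_atoms

__all__ = [
    "SuperpositionResult",
    "DisplacementResult",
    "PairingError",
    "kabsch_superpose",
    "paired_ca",
    "domain_rmsd",
    "displacement_after_alignment",
]


class PairingError(ValueError):
    """Coordinate lists cannot be paired for superposition."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mobile→target and the resulting RMSD.

    ``rotation`` is a proper orthonormal 3×3 matrix; the transform maps a
    mobile point x to ``rotation @ x + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    n_dropped: int = 0
    mobile_selection: Selection | None = None
    target_selection: Selection | None = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class DisplacementResult:
    """Distance between element centroids after alignment on a shared frame."""

    displacement: float  # Angstrom
    alignment: SuperpositionResult
    align_selection: Selection
    measure_selection_a: Selection
    measure_selection_b: Selection


def kabsch_superpose(mobile, target) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation (Kabsch, SVD).

    ``mobile`` and ``target`` are paired equal-length lists of 3-vectors,
    n ≥ 3 and not all collinear.
    """
    P = np.asarray(mobile, dtype=float).reshape(-1, 3)
    Q = np.asarray(target, dtype=float).reshape(-1, 3)
    if len(P) != len(Q):
        raise PairingError(f"coordinate lists differ in length: {len(P)} vs {len(Q)}")
    if len(P) < 3:
        raise PairingError(f"superposition is underdetermined with {len(P)} pairs")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    # enforce a proper rotation (det +1)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=len(P))


def paired_ca(
    model_a: StructureModel,
    model_b: StructureModel,
    sel: Selection,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Cα coordinates of both models paired by (chain, residue, icode).

    Residues present in only one model are dropped; the count of dropped
    residues is returned alongside the two (n, 3) arrays.
    """
    ca_sel = Selection(chain_ids=sel.chain_ids, residue_range=sel.residue_range,
                       atom_names=frozenset({"CA"}))
    a_atoms = {a.key[:3]: a for a in select_atoms(model_a, ca_sel) if not a.hetero}
    b_atoms = {a.key[:3]: a for a in select_atoms(model_b, ca_sel) if not a.hetero}
    common = [k for k in a_atoms if k in b_atoms]
    if not common:
        raise PairingError(
            f"no common Cα between {model_a.identifier!r} and {model_b.identifier!r} "
            f"for selection {sel}"
        )
    dropped = (len(a_atoms) - len(common)) + (len(b_atoms) - len(common))
    coords_a = np.array([a_atoms[k].position for k in common])
    coords_b = np.array([b_atoms[k].position for k in common])
    return coords_a, coords_b, dropped


def domain_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    sel: Selection,
    align_sel: Selection | None = None,
) -> SuperpositionResult:
    """Cα RMSD of ``sel`` after superposing the two models.

    By default the superposition frame IS ``sel`` (align and measure on the
    same residues); pass ``align_sel`` to align on a different region and
    measure the RMSD that the relative motion produces over ``sel``.
    """
    frame = align_sel if align_sel is not None else sel
    fa, fb, n_dropped_frame = paired_ca(model_a, model_b, frame)
    sup = kabsch_superpose(fb, fa)  # map B onto A
    ma, mb, n_dropped = paired_ca(model_a, model_b, sel)
    diff = sup.apply(mb) - ma
    rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
    return SuperpositionResult(
        rotation=sup.rotation,
        translation=sup.translation,
        rmsd=rmsd,
        n_atoms=len(ma),
        n_dropped=n_dropped,
        mobile_selection=sel,
        target_selection=frame,
    )


def displacement_after_alignment(
    model_a: StructureModel,
    model_b: StructureModel,
    align_sel: Selection,
    measure_sel_a: Selection,
    measure_sel_b: Selection,
) -> DisplacementResult:
    """Centroid shift of an element after aligning both models.

    B is superposed onto A via the paired Cα of ``align_sel``; the
    displacement is the distance between the Cα centroid of
    ``measure_sel_a`` in A and of ``measure_sel_b`` in transformed B.  The
    two measured selections need not pair residue-by-residue, which makes
    the metric usable across systems with different modelled lengths.
    """
    fa, fb, _ = paired_ca(model_a, model_b, align_sel)
    sup = kabsch_superpose(fb, fa)

    def _centroid(model: StructureModel, sel: Selection) -> np.ndarray:
        ca = Selection(chain_ids=sel.chain_ids, residue_range=sel.residue_range,
                       atom_names=frozenset({"CA"}))
        atoms = [a for a in select_atoms(model, ca) if not a.hetero]
        if not atoms:
            raise ValueError(f"empty measure selection {sel} in {model.identifier!r}")
        return np.array([a.position for a in atoms]).mean(axis=0)

    ca_a = _centroid(model_a, measure_sel_a)
    ca_b = sup.apply(_centroid(model_b, measure_sel_b))
    return DisplacementResult(
        displacement=float(np.linalg.norm(ca_a - ca_b)),
        alignment=sup,
        align_selection=align_sel,
        measure_selection_a=measure_sel_a,
        measure_selection_b=measure_sel_b,
    )
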