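"""Synthetic fixtures with retrievable ground truth.

Every generator maps (spec, seed) deterministically to its output and
stores the exact noise-free truth, so each analysis stage can be tested by
recovery: run the stage on generated data and compare to the stored truth.

Four generators cover the pipeline:

* :func:`make_ring` — N-spoke helical rings (one Cα anchor per spoke) with
  prescribed radius / twist / rise, optional rigid pose and coordinate noise;
  the default parameter sets mirror a 14-spoke nucleation-template ring
  (102.5 Å / 27.6° / 9.2 Å) and a 13-protofilament microtubule lattice
  (101.8 Å / 27.6° / 9.6 Å).
* :func:`make_hinge_pair` — two copies of one chain related by a rigid hinge
  rotation of the C-terminal block, with the exact mobile-block RMSD stored.
* :func:`make_hx_tables` — baseline and ligand peptide centroid-mass tables
  realising prescribed per-residue baseline-exchange and protection
  profiles.
* :func:`make_gel` — band intensities drawn from a prescribed molar
  stoichiometry and molecular weights with lognormal multiplicative noise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.transform import Rotation

from .hxms import PeptideExchange, BASELINE_SHOWN_THRESHOLD
from .ring_geometry import HelicalParams
from .stoichiometry import BandMeasurement
from .structure_io import AtomRecord, StructureModel

__all__ = [
    "RingSpec",
    "RingTruth",
    "HingeSpec",
    "HingeTruth",
    "HxSpec",
    "HxTruth",
    "make_ring",
    "make_hinge_pair",
    "make_hx_tables",
    "make_gel",
    "GAMMA_RING_SPEC",
    "MT13_REFERENCE_SPEC",
    "COMPLEX_STOICHIOMETRY",
    "CONSTRUCT_MW_KDA",
]

_CHAIN_POOL = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-component stream derived from one global seed."""
    digest = hashlib.sha256(stream.encode()).digest()
    key = int.from_bytes(digest[:4], "little") & 0x7FFFFFFF
    child = np.random.SeedSequence(seed, spawn_key=(key,))
    return np.random.default_rng(child)


# ---------------------------------------------------------------------------
# helical rings


@dataclass(frozen=True)
class RingSpec:
    """Helical lattice to generate: radius (Å), twist (°/step), rise (Å/step)."""

    n_spokes: int = 14
    radius: float = 102.5
    twist: float = 27.6
    rise: float = 9.2
    noise_sd: float = 0.0
    seed: int = 0
    pose: tuple | None = None  # (3x3 rotation, 3-vector translation)
    decorate: bool = False  # add a short dummy helix per spoke for selection tests

    def __post_init__(self) -> None:
        if self.n_spokes < 4:
            raise ValueError("need at least 4 spokes")
        if self.n_spokes > len(_CHAIN_POOL):
            raise ValueError(f"at most {len(_CHAIN_POOL)} spokes supported")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 < self.twist < 360.0:
            raise ValueError("twist must lie in (0, 360) degrees")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class RingTruth:
    """Exact noise-free geometry of a generated ring."""

    anchors: np.ndarray  # (N, 3) noise-free, posed anchor coordinates
    axis_origin: np.ndarray
    axis_direction: np.ndarray
    params: HelicalParams
    chain_ids: list[str] = field(default_factory=list)
    anchor_residue: int = 12
    anchor_atom: str = "CA"


#: the study's ring conditions: 14-spoke nucleation template and MT reference
GAMMA_RING_SPEC = RingSpec(n_spokes=14, radius=102.5, twist=27.6, rise=9.2)
MT13_REFERENCE_SPEC = RingSpec(n_spokes=14, radius=101.8, twist=27.6, rise=9.6)


def _apply_pose(points: np.ndarray, pose: tuple | None) -> np.ndarray:
    if pose is None:
        return points
    R = np.asarray(pose[0], dtype=float)
    t = np.asarray(pose[1], dtype=float)
    return points @ R.T + t


def make_ring(spec: RingSpec) -> tuple[StructureModel, RingTruth]:
    """Generate a CA-only ring: one single-residue chain per spoke.

    Spoke k sits at (r·cos kτ, r·sin kτ, k·rise) about the z axis (τ = twist)
    before the optional rigid pose; isotropic Gaussian noise of sd
    ``noise_sd`` is then added per coordinate.  Deterministic under seed.
    """
    k = np.arange(spec.n_spokes)
    tau = np.radians(spec.twist)
    lattice = np.column_stack(
        [spec.radius * np.cos(k * tau), spec.radius * np.sin(k * tau), k * spec.rise]
    )
    posed = _apply_pose(lattice, spec.pose)
    rng = _rng(spec.seed, "ring")
    noisy = posed + rng.normal(0.0, spec.noise_sd, size=posed.shape) if spec.noise_sd else posed

    chains = [_CHAIN_POOL[i] for i in range(spec.n_spokes)]
    atoms: list[AtomRecord] = []
    for i, chain in enumerate(chains):
        atoms.append(
            AtomRecord(
                chain_id=chain,
                residue_number=12,
                residue_name="GLN",
                atom_name="CA",
                element="C",
                position=tuple(noisy[i]),
            )
        )
        if spec.decorate:
            # short dummy helix rising radially outward from the anchor
            direction = noisy[i] / max(np.linalg.norm(noisy[i]), 1.0)
            for j in range(1, 7):
                atoms.append(
                    AtomRecord(
                        chain_id=chain,
                        residue_number=12 + j,
                        residue_name="ALA",
                        atom_name="CA",
                        element="C",
                        position=tuple(noisy[i] + direction * 1.5 * j),
                    )
                )
    model_atoms = sorted(atoms, key=lambda a: (chains.index(a.chain_id), a.residue_number))
    model = StructureModel(
        identifier=f"synthetic-ring-n{spec.n_spokes}-seed{spec.seed}",
        atoms=model_atoms,
        provenance="synthetic ring generator",
    )
    axis_dir = _apply_pose(np.array([[0.0, 0.0, 1.0]]), (spec.pose[0], (0, 0, 0)))[0] \
        if spec.pose is not None else np.array([0.0, 0.0, 1.0])
    axis_origin = _apply_pose(np.zeros((1, 3)), spec.pose)[0] if spec.pose is not None \
        else np.zeros(3)
    truth = RingTruth(
        anchors=posed,
        axis_origin=axis_origin,
        axis_direction=axis_dir,
        params=HelicalParams(
            n_points=spec.n_spokes,
            radius_mean=spec.radius,
            radius_sd=0.0,
            twist_mean=spec.twist,
            twist_sd=0.0,
            rise_mean=spec.rise,
            rise_sd=0.0,
            handedness="right",
        ),
        chain_ids=chains,
    )
    return model, truth


# ---------------------------------------------------------------------------
# hinge pairs


@dataclass(frozen=True)
class HingeSpec:
    """Two-domain chain with a rigid hinge rotation of the mobile block."""

    n_residues_static: int = 100
    n_residues_mobile: int = 160
    hinge_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    hinge_angle: float = 12.0  # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues_static < 4 or self.n_residues_mobile < 4:
            raise ValueError("each domain needs at least 4 residues")
        if np.linalg.norm(self.hinge_axis) == 0:
            raise ValueError("hinge axis must be non-zero")


@dataclass
class HingeTruth:
    """Closed-form consequences of the generated hinge motion."""

    pivot: np.ndarray
    rotation: np.ndarray  # 3x3 applied to the mobile block about the pivot
    mobile_rmsd: float  # exact Cα RMSD of the mobile block between the models
    static_range: tuple[int, int]
    mobile_range: tuple[int, int]
    coords_a: np.ndarray  # (n, 3) noise-free model-A Cα coordinates


def _coil_coords(n: int, rng: np.random.Generator) -> np.ndarray:
    """A smooth, non-collinear Cα trace: a coarse helix plus jitter."""
    t = np.arange(n)
    base = np.column_stack(
        [2.3 * np.cos(t * 1.75), 2.3 * np.sin(t * 1.75), 1.5 * t]
    )
    return base + rng.normal(0.0, 0.3, size=base.shape)


def make_hinge_pair(spec: HingeSpec) -> tuple[StructureModel, StructureModel, HingeTruth]:
    """Model B = model A with the mobile residue block rigidly rotated.

    Residues 1..n_static form the static domain; the following
    n_residues_mobile residues are rotated by ``hinge_angle`` about
    ``hinge_axis`` through the last static Cα (the pivot).  The exact
    mobile-block RMSD implied by that rotation is stored in the truth.
    """
    rng = _rng(spec.seed, "hinge")
    n = spec.n_residues_static + spec.n_residues_mobile
    coords = _coil_coords(n, rng)
    pivot = coords[spec.n_residues_static - 1].copy()
    axis = np.asarray(spec.hinge_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.radians(spec.hinge_angle) * axis).as_matrix()

    coords_b = coords.copy()
    mobile = slice(spec.n_residues_static, n)
    coords_b[mobile] = (coords[mobile] - pivot) @ R.T + pivot

    def _model(tag: str, xyz: np.ndarray) -> StructureModel:
        atoms = [
            AtomRecord(
                chain_id="A",
                residue_number=i + 1,
                residue_name="ALA",
                atom_name="CA",
                element="C",
                position=tuple(xyz[i]),
            )
            for i in range(n)
        ]
        return StructureModel(
            identifier=f"synthetic-hinge-{tag}-seed{spec.seed}",
            atoms=atoms,
            provenance="synthetic hinge generator",
        )

    diff = coords_b[mobile] - coords[mobile]
    mobile_rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
    truth = HingeTruth(
        pivot=pivot,
        rotation=R,
        mobile_rmsd=mobile_rmsd,
        static_range=(1, spec.n_residues_static),
        mobile_range=(spec.n_residues_static + 1, n),
        coords_a=coords,
    )
    return _model("a", coords), _model("b", coords_b), truth


# ---------------------------------------------------------------------------
# HX-MS tables


@dataclass(frozen=True)
class HxSpec:
    """Peptide coverage plus per-residue baseline and protection profiles.

    ``baseline_profile`` and ``protection_profile`` map a residue number
    (1-based) to percent baseline exchange and percent relative protection;
    by default the baseline sweeps 5–85 % (so some peptides fall below the
    10 % display threshold) and a contiguous block of residues carries 80 %
    protection, emulating a single ligand-binding site.
    """

    protein_length: int = 160
    peptide_length: int = 10
    peptide_step: int = 4
    noise_sd: float = 0.0  # Da, on labelled centroid masses
    seed: int = 0
    baseline_profile: Callable[[int], float] | None = None
    protection_profile: Callable[[int], float] | None = None

    def __post_init__(self) -> None:
        if self.protein_length < self.peptide_length:
            raise ValueError("protein shorter than one peptide")
        if self.peptide_step < 1 or self.peptide_length < 2:
            raise ValueError("invalid coverage plan")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def baseline_at(self, residue: int) -> float:
        if self.baseline_profile is not None:
            return float(self.baseline_profile(residue))
        # smooth sweep between 5 % and 85 % across the chain
        return 45.0 + 40.0 * np.sin(2.0 * np.pi * residue / self.protein_length)

    def protection_at(self, residue: int) -> float:
        if self.protection_profile is not None:
            return float(self.protection_profile(residue))
        lo = int(0.4 * self.protein_length)
        hi = int(0.65 * self.protein_length)
        return 80.0 if lo <= residue <= hi else 0.0


@dataclass
class HxTruth:
    """Per-peptide and per-residue ground truth of a generated HX dataset."""

    peptides: list[dict]  # id, start, end, baseline %, protection %, shown
    residue_relative_exchange: np.ndarray  # consolidated truth, NaN = no coverage


def make_hx_tables(
    spec: HxSpec,
) -> tuple[list[PeptideExchange], list[PeptideExchange], HxTruth]:
    """Baseline and ligand centroid-mass tables realising the profiles.

    Peptide-level truth is the mean of the residue profiles over the
    peptide.  Masses: m0 grows with peptide length, m100 − m0 equals the
    number of exchanging amides (length − 1), and the labelled centroid
    interpolates by the true uptake fraction, plus Gaussian noise.
    """
    rng = _rng(spec.seed, "hx")
    starts = list(range(1, spec.protein_length - spec.peptide_length + 2, spec.peptide_step))
    baseline_rows: list[PeptideExchange] = []
    ligand_rows: list[PeptideExchange] = []
    peptide_truth: list[dict] = []
    for idx, start in enumerate(starts, start=1):
        end = start + spec.peptide_length - 1
        residues = range(start, end + 1)
        base_pct = float(np.mean([spec.baseline_at(r) for r in residues]))
        prot_pct = float(np.mean([spec.protection_at(r) for r in residues]))
        lig_pct = base_pct * (1.0 - prot_pct / 100.0)
        pid = f"pep{idx:03d}"
        m0 = 500.0 + 110.0 * spec.peptide_length + 7.0 * idx
        m100 = m0 + (spec.peptide_length - 1)  # one exchanging amide per peptide bond
        for condition, pct, rows in (
            ("baseline", base_pct, baseline_rows),
            ("ligand", lig_pct, ligand_rows),
        ):
            m_t = m0 + (pct / 100.0) * (m100 - m0)
            if spec.noise_sd:
                m_t += rng.normal(0.0, spec.noise_sd)
            rows.append(
                PeptideExchange(
                    peptide_id=pid,
                    start=start,
                    end=end,
                    condition=condition,
                    m0=m0,
                    m_t=m_t,
                    m100=m100,
                )
            )
        peptide_truth.append(
            {
                "peptide_id": pid,
                "start": start,
                "end": end,
                "baseline_exchange": base_pct,
                "relative_protection": prot_pct,
                "relative_exchange": 100.0 - prot_pct,
                "shown": base_pct >= BASELINE_SHOWN_THRESHOLD,
            }
        )
    # consolidated per-residue truth over shown peptides (independent of the
    # analysis path: direct overlap bookkeeping)
    total = np.zeros(spec.protein_length)
    count = np.zeros(spec.protein_length)
    for p in peptide_truth:
        if not p["shown"]:
            continue
        total[p["start"] - 1 : p["end"]] += p["relative_exchange"]
        count[p["start"] - 1 : p["end"]] += 1
    with np.errstate(invalid="ignore"):
        residue_truth = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return baseline_rows, ligand_rows, HxTruth(peptide_truth, residue_truth)


# ---------------------------------------------------------------------------
# gel densitometry


#: molar stoichiometry of the purified oligomeric complex (reference Spc97)
COMPLEX_STOICHIOMETRY = {"Spc97": 1.0, "Spc98": 1.0, "gamma-tubulin": 2.0, "Spc72": 2.0}

#: approximate tagged-construct masses (kDa) used by the gel generator
CONSTRUCT_MW_KDA = {
    "Spc97": 97.0,
    "Spc98": 98.0,
    "gamma-tubulin": 52.5,
    "Spc72": 68.0,
    "Stu2": 102.0,
}


def make_gel(
    true_ratios: dict[str, float] = COMPLEX_STOICHIOMETRY,
    mws: dict[str, float] = CONSTRUCT_MW_KDA,
    cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[BandMeasurement]:
    """Band intensities from a true molar stoichiometry.

    intensity = scale_rep · ratio · MW · ε, with ε lognormal of mean 1 and
    coefficient of variation ``cv`` (ε ≡ 1 when cv = 0) and scale_rep a
    random per-replicate loading factor that cancels in ratio analysis.
    """
    if cv < 0 or n_replicates < 1:
        raise ValueError("cv must be >= 0 and n_replicates >= 1")
    missing = [p for p in true_ratios if p not in mws]
    if missing:
        raise ValueError(f"no molecular weight for: {missing}")
    if any(r <= 0 for r in true_ratios.values()) or any(mws[p] <= 0 for p in true_ratios):
        raise ValueError("ratios and molecular weights must be positive")
    rng = _rng(seed, "gel")
    sigma = float(np.sqrt(np.log1p(cv**2)))
    bands: list[BandMeasurement] = []
    for rep in range(1, n_replicates + 1):
        scale = rng.uniform(0.5, 2.0)
        for protein in sorted(true_ratios):
            eps = rng.lognormal(-0.5 * sigma**2, sigma) if cv > 0 else 1.0
            bands.append(
                BandMeasurement(
                    protein=protein,
                    intensity=scale * true_ratios[protein] * mws[protein] * eps,
                    molecular_weight=mws[protein],
                    replicate=rep,
                )
            )
    return bands
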