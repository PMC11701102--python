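"""Inter-chain contact detection and classification.

Contacts are classified purely by distance and atom chemistry — deposited
models carry no hydrogens, so a hydrogen bond is scored as any
donor/acceptor-capable N/O pair within the cutoff, without an angle term.
Classification precedence is salt_bridge > hbond > hydrophobic so that each
atom pair receives exactly one label.

Default cutoffs: 3.5 A (H-bond), 4.0 A (salt bridge), 4.5 A (hydrophobic
carbon-carbon).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, StructureModel

__all__ = [
    "Contact",
    "ContactCriteria",
    "find_contacts",
    "pocket_contacts",
    "contacts_by_residue_pair",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: apolar residues whose side-chain carbons count for hydrophobic contacts
APOLAR_RESIDUES = frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"})

#: side-chain nitrogens of basic residues (histidine switchable)
_BASIC_SIDECHAIN_N = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}
#: side-chain carboxylate oxygens of acidic residues
_ACIDIC_SIDECHAIN_O = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


@dataclass(frozen=True, order=True)
class AtomRef:
    """Identity of one contact partner."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str


@dataclass(frozen=True)
class Contact:
    kind: str  # hbond_backbone_backbone | hbond_sidechain | salt_bridge | hydrophobic
    atom1: AtomRef
    atom2: AtomRef
    distance: float  # Angstrom


@dataclass(frozen=True)
class ContactCriteria:
    hbond_max: float = 3.5
    salt_bridge_max: float = 4.0
    hydrophobic_max: float = 4.5
    histidine_salt_bridge: bool = True

    def __post_init__(self) -> None:
        if min(self.hbond_max, self.salt_bridge_max, self.hydrophobic_max) <= 0:
            raise ValueError("contact cutoffs must be positive")

    @property
    def max_cutoff(self) -> float:
        return max(self.hbond_max, self.salt_bridge_max, self.hydrophobic_max)


def _is_salt_bridge_n(a: AtomRecord, criteria: ContactCriteria) -> bool:
    if a.residue_name == "HIS" and not criteria.histidine_salt_bridge:
        return False
    return a.atom_name in _BASIC_SIDECHAIN_N.get(a.residue_name, ())


def _is_salt_bridge_o(a: AtomRecord) -> bool:
    return a.atom_name in _ACIDIC_SIDECHAIN_O.get(a.residue_name, ())


def _is_polar_no(a: AtomRecord) -> bool:
    return a.element.upper() in ("N", "O")


def _is_apolar_sidechain_c(a: AtomRecord) -> bool:
    return (
        a.element.upper() == "C"
        and a.atom_name not in BACKBONE_ATOMS
        and a.residue_name in APOLAR_RESIDUES
    )


def _classify(a: AtomRecord, b: AtomRecord, dist: float,
              criteria: ContactCriteria) -> str | None:
    # precedence: salt bridge > hydrogen bond > hydrophobic
    if dist <= criteria.salt_bridge_max:
        if (_is_salt_bridge_n(a, criteria) and _is_salt_bridge_o(b)) or (
            _is_salt_bridge_n(b, criteria) and _is_salt_bridge_o(a)
        ):
            return "salt_bridge"
    if dist <= criteria.hbond_max and _is_polar_no(a) and _is_polar_no(b):
        both_backbone = a.atom_name in BACKBONE_ATOMS and b.atom_name in BACKBONE_ATOMS
        return "hbond_backbone_backbone" if both_backbone else "hbond_sidechain"
    if dist <= criteria.hydrophobic_max:
        if _is_apolar_sidechain_c(a) and _is_apolar_sidechain_c(b):
            return "hydrophobic"
    return None


def _heavy_protein_atoms(model: StructureModel, chain: str) -> list[AtomRecord]:
    atoms = [
        a
        for a in model.atoms
        if a.chain_id == chain and not (a.is_hydrogen or a.is_water or a.hetero)
    ]
    return atoms


def _contact_ref(a: AtomRecord) -> AtomRef:
    return AtomRef(a.chain_id, a.residue_number, a.residue_name, a.atom_name)


def find_contacts(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    criteria: ContactCriteria = ContactCriteria(),
) -> list[Contact]:
    """All classified inter-chain atom contacts between two chains.

    Heavy protein atoms only.  Output is ordered by (residue of chain_a,
    residue of chain_b, distance) and is symmetric in the chain arguments
    up to the atom1/atom2 roles.
    """
    atoms_a = _heavy_protein_atoms(model, chain_a)
    atoms_b = _heavy_protein_atoms(model, chain_b)
    if not atoms_a:
        raise ValueError(f"chain {chain_a!r} absent or without heavy atoms")
    if not atoms_b:
        raise ValueError(f"chain {chain_b!r} absent or without heavy atoms")
    xa = np.array([a.position for a in atoms_a])
    xb = np.array([b.position for b in atoms_b])
    pairs = cKDTree(xa).query_ball_tree(cKDTree(xb), r=criteria.max_cutoff)
    contacts: list[Contact] = []
    for i, hits in enumerate(pairs):
        for j in hits:
            dist = float(np.linalg.norm(xa[i] - xb[j]))
            kind = _classify(atoms_a[i], atoms_b[j], dist, criteria)
            if kind is not None:
                contacts.append(
                    Contact(kind=kind, atom1=_contact_ref(atoms_a[i]),
                            atom2=_contact_ref(atoms_b[j]), distance=dist)
                )
    contacts.sort(key=lambda c: (c.atom1.residue_number, c.atom2.residue_number,
                                 c.distance, c.atom1.atom_name, c.atom2.atom_name))
    return contacts


def pocket_contacts(
    model: StructureModel,
    probe: tuple[str, int],
    partner_chain: str,
    criteria: ContactCriteria = ContactCriteria(),
) -> list[Contact]:
    """Hydrophobic contacts from one probe residue's side chain to a chain.

    Used to characterise pocket docking (e.g. a phenylalanine buried in a
    neighbouring subunit): returns carbon-carbon contacts from the probe's
    side-chain carbons to apolar side chains of ``partner_chain``.  The set
    of partner residues across the returned contacts is "the pocket".
    """
    chain, resnum = probe
    probe_atoms = [
        a
        for a in _heavy_protein_atoms(model, chain)
        if a.residue_number == resnum and a.atom_name not in BACKBONE_ATOMS
        and a.element.upper() == "C"
    ]
    if not probe_atoms:
        raise ValueError(f"probe residue {chain}:{resnum} missing or without side-chain carbons")
    partner_atoms = [
        b for b in _heavy_protein_atoms(model, partner_chain) if _is_apolar_sidechain_c(b)
    ]
    contacts: list[Contact] = []
    for a in probe_atoms:
        for b in partner_atoms:
            dist = float(np.linalg.norm(a.xyz - b.xyz))
            if dist <= criteria.hydrophobic_max:
                contacts.append(
                    Contact(kind="hydrophobic", atom1=_contact_ref(a),
                            atom2=_contact_ref(b), distance=dist)
                )
    contacts.sort(key=lambda c: (c.atom2.residue_number, c.distance, c.atom1.atom_name))
    return contacts


def contacts_by_residue_pair(contacts: list[Contact]) -> dict[tuple, list[Contact]]:
    """Aggregate atom-pair contacts per residue pair for reporting."""
    grouped: dict[tuple, list[Contact]] = defaultdict(list)
    for c in contacts:
        key = (
            (c.atom1.chain_id, c.atom1.residue_number, c.atom1.residue_name),
            (c.atom2.chain_id, c.atom2.residue_number, c.atom2.residue_name),
        )
        grouped[key].append(c)
    return dict(grouped)
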