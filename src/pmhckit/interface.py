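"""Geometric engagement metrics for designed pMHC-I binders.

A binder suitable for peptide-specific recognition must contact the
presented peptide extensively while touching the conserved MHC surface as
little as possible.  This module provides the geometry primitives behind
that selection: heavy-atom contact maps, geometric hydrogen-bond
detection with heavy-atom donor proxies, Shrake-Rupley solvent-accessible
surface area, and per-design engagement summaries with configurable
triage thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import (
    AtomRecord,
    BACKBONE_ATOMS,
    ChainRole,
    PMHCComplex,
    PositionClass,
    StructureError,
)

__all__ = [
    "ContactTable",
    "HBond",
    "EngagementMetrics",
    "TriageThresholds",
    "ATOMIC_RADII",
    "contact_pairs",
    "detect_hbonds",
    "shrake_rupley_sasa",
    "engagement_metrics",
    "triage_designs",
]

#: van der Waals radii (Angstrom) used for SASA; config-exposed.
ATOMIC_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}

#: Heavy-atom H-bond donors: (residue or "*" for backbone, atom) -> antecedent
#: atom defining the donor direction.  Proline backbone N has no amide H.
_DONORS: dict[tuple[str, str], str] = {
    ("*", "N"): "CA",
    ("SER", "OG"): "CB",
    ("THR", "OG1"): "CB",
    ("TYR", "OH"): "CZ",
    ("ASN", "ND2"): "CG",
    ("GLN", "NE2"): "CD",
    ("LYS", "NZ"): "CE",
    ("ARG", "NE"): "CD",
    ("ARG", "NH1"): "CZ",
    ("ARG", "NH2"): "CZ",
    ("HIS", "ND1"): "CG",
    ("HIS", "NE2"): "CD2",
    ("TRP", "NE1"): "CD1",
}

#: Heavy-atom H-bond acceptors: (residue or "*" for backbone, atom).
_ACCEPTORS: set[tuple[str, str]] = {
    ("*", "O"),
    ("*", "OXT"),
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"),
    ("GLN", "OE1"),
    ("SER", "OG"),
    ("THR", "OG1"),
    ("TYR", "OH"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}


@dataclass
class ContactTable:
    """Unordered heavy-atom contact pairs between two chain-role groups."""

    pairs: list[tuple[tuple[str, int, str], tuple[str, int, str], float]]
    cutoff: float
    group_a: tuple[ChainRole, ...]
    group_b: tuple[ChainRole, ...]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class HBond:
    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    distance: float
    angle: float  # antecedent-donor-acceptor, degrees


@dataclass
class EngagementMetrics:
    design_id: str
    per_position_contacts: dict[int, int]
    n_peptide_contacts: int
    n_mhc_contacts: int
    peptide_contact_fraction: float | None  # None when the binder makes no contacts
    n_hbonds_to_peptide: int
    outward_coverage: float


@dataclass
class TriageThresholds:
    """Minima a design must meet to pass the engagement triage."""

    min_peptide_contacts: int = 10
    min_peptide_contact_fraction: float = 0.25
    min_outward_coverage: float = 0.5
    min_hbonds_to_peptide: int = 1


def _as_roles(group) -> tuple[ChainRole, ...]:
    if isinstance(group, ChainRole):
        return (group,)
    return tuple(ChainRole(g) if not isinstance(g, ChainRole) else g for g in group)


def _group_atoms(cpx: PMHCComplex, roles: tuple[ChainRole, ...]) -> list[AtomRecord]:
    out: list[AtomRecord] = []
    for r in roles:
        out.extend(cpx.atoms_of_role(r))
    return out


def contact_pairs(
    cpx: PMHCComplex,
    group_a,
    group_b,
    cutoff: float = 4.5,
) -> ContactTable:
    """All heavy-atom pairs across two role groups within ``cutoff`` Angstrom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    roles_a, roles_b = _as_roles(group_a), _as_roles(group_b)
    chains_a = {c for r in roles_a for c in cpx.chains_with_role(r)}
    chains_b = {c for r in roles_b for c in cpx.chains_with_role(r)}
    if chains_a & chains_b:
        raise ValueError(f"overlapping groups share chains {sorted(chains_a & chains_b)}")
    atoms_a = _group_atoms(cpx, roles_a)
    atoms_b = _group_atoms(cpx, roles_b)
    if not atoms_a or not atoms_b:
        raise ValueError("contact groups must be non-empty")

    xyz_a, xyz_b = cpx.coords_of(atoms_a), cpx.coords_of(atoms_b)
    tree_b = cKDTree(xyz_b)
    pairs = []
    for i, hits in enumerate(cKDTree(xyz_a).query_ball_tree(tree_b, cutoff)):
        for j in sorted(hits):
            d = float(np.linalg.norm(xyz_a[i] - xyz_b[j]))
            pairs.append((atoms_a[i].key(), atoms_b[j].key(), d))
    return ContactTable(pairs=pairs, cutoff=cutoff, group_a=roles_a, group_b=roles_b)


def _donor_antecedent(atom: AtomRecord) -> str | None:
    if atom.atom_name == "N":
        return None if atom.residue_name == "PRO" else "CA"
    return _DONORS.get((atom.residue_name, atom.atom_name))


def _is_acceptor(atom: AtomRecord) -> bool:
    if ("*", atom.atom_name) in _ACCEPTORS:
        return True
    return (atom.residue_name, atom.atom_name) in _ACCEPTORS


def detect_hbonds(
    cpx: PMHCComplex,
    donor_group,
    acceptor_group,
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> list[HBond]:
    """Geometric hydrogen bonds between donor and acceptor role groups.

    Hydrogens are never present, so the donor direction is proxied by the
    donor's bonded antecedent heavy atom: a bond requires donor-acceptor
    distance <= ``d_max`` and antecedent-donor-acceptor angle >=
    ``angle_min`` degrees.  Pairs within one residue, or between residues
    fewer than two apart on the same chain, are excluded (covalent
    neighbours).  Donor and acceptor groups may coincide (intra-chain
    bonds, e.g. helical backbone i -> i-4).
    """
    roles_d, roles_a = _as_roles(donor_group), _as_roles(acceptor_group)
    donors = [a for a in _group_atoms(cpx, roles_d) if _donor_antecedent(a)]
    acceptors = [a for a in _group_atoms(cpx, roles_a) if _is_acceptor(a)]
    if not _group_atoms(cpx, roles_d) or not _group_atoms(cpx, roles_a):
        raise ValueError("donor/acceptor groups must be non-empty")

    # antecedent lookup within the donor's residue
    by_res: dict[tuple[str, int], dict[str, AtomRecord]] = {}
    for a in cpx.atoms:
        by_res.setdefault((a.chain_id, a.residue_index), {})[a.atom_name] = a

    if not donors or not acceptors:
        return []
    acc_xyz = cpx.coords_of(acceptors)
    tree = cKDTree(acc_xyz)
    bonds: list[HBond] = []
    for don in donors:
        ante_name = _donor_antecedent(don)
        ante = by_res.get((don.chain_id, don.residue_index), {}).get(ante_name)
        if ante is None:
            continue
        for j in sorted(tree.query_ball_point(don.coords, d_max)):
            acc = acceptors[j]
            if acc.chain_id == don.chain_id and abs(acc.residue_index - don.residue_index) < 2:
                continue
            v1 = ante.coords - don.coords
            v2 = acc.coords - don.coords
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom == 0:
                continue
            cosang = float(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0))
            angle = math.degrees(math.acos(cosang))
            if angle >= angle_min:
                bonds.append(
                    HBond(
                        donor=don.key(),
                        acceptor=acc.key(),
                        distance=float(np.linalg.norm(don.coords - acc.coords)),
                        angle=angle,
                    )
                )
    return bonds


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA


def _sphere_lattice(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of ``n`` points on the unit sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    atoms: Sequence[AtomRecord] | PMHCComplex,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii: Mapping[str, float] = ATOMIC_RADII,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Angstrom^2).

    Rolls a probe of ``probe_radius`` over the heavy atoms using the
    Shrake-Rupley point lattice (a fixed golden-spiral lattice, so results
    are deterministic for a given ``n_sphere_points``).
    """
    if isinstance(atoms, PMHCComplex):
        atoms = atoms.atoms
    if n_sphere_points < 60:
        raise ValueError("n_sphere_points must be >= 60")
    n = len(atoms)
    if n == 0:
        return np.zeros(0)
    try:
        rads = np.array([radii[a.element.upper()] for a in atoms], dtype=float)
    except KeyError as exc:
        raise KeyError(f"no atomic radius for element {exc}") from exc
    ext = rads + probe_radius
    xyz = np.array([a.coords for a in atoms], dtype=float)
    lattice = _sphere_lattice(n_sphere_points)

    tree = cKDTree(xyz)
    max_reach = 2.0 * float(np.max(ext))
    sasa = np.zeros(n)
    for i in range(n):
        pts = xyz[i] + ext[i] * lattice
        neighbors = [j for j in tree.query_ball_point(xyz[i], max_reach) if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
        sasa[i] = accessible.mean() * 4.0 * math.pi * ext[i] ** 2
    return sasa


# ---------------------------------------------------------------------------
# engagement + triage


def engagement_metrics(
    cpx: PMHCComplex,
    position_classes: Sequence[PositionClass],
    design_id: str = "design",
    contact_cutoff: float = 4.5,
    hbond_d_max: float = 3.5,
    hbond_angle_min: float = 120.0,
    min_contacts_per_outward: int = 1,
) -> EngagementMetrics:
    """Summarise how a binder engages the peptide versus the MHC.

    ``outward_coverage`` is the fraction of OUTWARD peptide positions the
    binder touches with at least ``min_contacts_per_outward`` heavy-atom
    contacts (vacuously 1.0 when no position is OUTWARD).  When the binder
    makes no contacts at all, ``peptide_contact_fraction`` is ``None``
    rather than a misleading ratio.
    """
    if not cpx.chains_with_role(ChainRole.BINDER):
        raise StructureError("engagement metrics require a BINDER chain")

    posmap = cpx.peptide_position_map()
    pep_contacts = contact_pairs(cpx, ChainRole.BINDER, ChainRole.PEPTIDE, contact_cutoff)
    per_position = {p: 0 for p in posmap.values()}
    for _, key_b, _d in pep_contacts.pairs:
        per_position[posmap[key_b[1]]] += 1

    n_pep = len(pep_contacts)
    if cpx.chains_with_role(ChainRole.MHC_HEAVY):
        n_mhc = len(contact_pairs(cpx, ChainRole.BINDER, ChainRole.MHC_HEAVY, contact_cutoff))
    else:
        n_mhc = 0
    total = n_pep + n_mhc
    fraction = n_pep / total if total > 0 else None

    hb_fwd = detect_hbonds(cpx, ChainRole.BINDER, ChainRole.PEPTIDE, hbond_d_max, hbond_angle_min)
    hb_rev = detect_hbonds(cpx, ChainRole.PEPTIDE, ChainRole.BINDER, hbond_d_max, hbond_angle_min)
    n_hb = len(hb_fwd) + len(hb_rev)

    outward = [pc.position for pc in position_classes if pc.cls == "OUTWARD"]
    if outward:
        covered = sum(
            1 for p in outward if per_position.get(p, 0) >= min_contacts_per_outward
        )
        coverage = covered / len(outward)
    else:
        coverage = 1.0

    return EngagementMetrics(
        design_id=design_id,
        per_position_contacts=per_position,
        n_peptide_contacts=n_pep,
        n_mhc_contacts=n_mhc,
        peptide_contact_fraction=fraction,
        n_hbonds_to_peptide=n_hb,
        outward_coverage=coverage,
    )


def triage_designs(
    metrics: Iterable[EngagementMetrics],
    thresholds: TriageThresholds | None = None,
) -> list[tuple[str, bool, list[str]]]:
    """Pass/fail each design against the engagement minima, with reasons."""
    th = thresholds or TriageThresholds()
    out: list[tuple[str, bool, list[str]]] = []
    for m in metrics:
        reasons: list[str] = []
        if m.n_peptide_contacts < th.min_peptide_contacts:
            reasons.append(
                f"n_peptide_contacts {m.n_peptide_contacts} < {th.min_peptide_contacts}"
            )
        if m.peptide_contact_fraction is None:
            reasons.append("peptide_contact_fraction undefined (no contacts)")
        elif m.peptide_contact_fraction < th.min_peptide_contact_fraction:
            reasons.append(
                f"peptide_contact_fraction {m.peptide_contact_fraction:.3f} < "
                f"{th.min_peptide_contact_fraction}"
            )
        if m.outward_coverage < th.min_outward_coverage:
            reasons.append(
                f"outward_coverage {m.outward_coverage:.3f} < {th.min_outward_coverage}"
            )
        if m.n_hbonds_to_peptide < th.min_hbonds_to_peptide:
            reasons.append(
                f"n_hbonds_to_peptide {m.n_hbonds_to_peptide} < {th.min_hbonds_to_peptide}"
            )
        out.append((m.design_id, not reasons, reasons))
    return out
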