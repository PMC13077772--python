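"""Atom-level representation of binder/pMHC-I complexes.

A peptide-MHC class I (pMHC-I) complex consists of the MHC heavy chain
(whose alpha-1/alpha-2 helices form the peptide-binding groove),
beta-2-microglobulin, a short presented peptide (8-11 residues), and —
for design models — a binder domain arcing above the groove.  This module
parses such complexes from PDB/mmCIF, validates them, and classifies
peptide positions as groove-buried anchors versus outward-facing
(recognition-available) positions.

Conventions used throughout the package:

* hydrogens are discarded at load time (models and crystal structures
  place them differently, so all geometry is heavy-atom only);
* author residue numbering is preserved, but peptide positions are always
  reported 1-based from the N-terminus;
* alternate locations are resolved to the highest-occupancy conformer
  (ties broken by file order).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ChainRole",
    "PMHCComplex",
    "PositionClass",
    "StructureError",
    "load_structure",
    "write_pdb",
    "validate_complex",
    "classify_peptide_positions",
]


class StructureError(ValueError):
    """Raised for unusable input structures or inconsistent role maps."""


class ChainRole(enum.Enum):
    MHC_HEAVY = "MHC_HEAVY"
    B2M = "B2M"
    PEPTIDE = "PEPTIDE"
    BINDER = "BINDER"
    OTHER = "OTHER"


#: Backbone heavy-atom names; everything else on a residue is side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Known modified residues mapped to their parent standard residue.
MODIFIED_PARENT = {
    "MSE": "MET", "SEC": "CYS", "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "CSO": "CYS", "HYP": "PRO", "MLY": "LYS", "M3L": "LYS", "PYL": "LYS",
    "CME": "CYS", "KCX": "LYS", "LLP": "LYS", "PCA": "GLU",
}


@dataclass
class AtomRecord:
    """One heavy atom with its chain/residue/atom identity and position."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    coords: np.ndarray
    is_heavy: bool = True

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_index, self.atom_name)

    def copy(self) -> "AtomRecord":
        return replace(self, coords=np.array(self.coords, dtype=float))


@dataclass
class PMHCComplex:
    """A parsed binder/pMHC-I complex.

    ``atoms`` hold all heavy atoms in file order; ``roles`` tags each chain
    with its biological role.  The peptide sequence is derived from the
    PEPTIDE chain's residues in residue-index order.
    """

    atoms: list[AtomRecord]
    roles: dict[str, ChainRole]
    allele: str | None = None

    # -- selectors ---------------------------------------------------------

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def chains_with_role(self, role: ChainRole) -> list[str]:
        return [cid for cid, r in self.roles.items() if r is role]

    def atoms_of_chain(self, chain_id: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def atoms_of_role(self, role: ChainRole) -> list[AtomRecord]:
        cids = set(self.chains_with_role(role))
        return [a for a in self.atoms if a.chain_id in cids]

    def coords_of(self, atoms: Sequence[AtomRecord]) -> np.ndarray:
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in atoms], dtype=float)

    def without_role(self, role: ChainRole) -> "PMHCComplex":
        cids = set(self.chains_with_role(role))
        return PMHCComplex(
            atoms=[a.copy() for a in self.atoms if a.chain_id not in cids],
            roles={c: r for c, r in self.roles.items() if c not in cids},
            allele=self.allele,
        )

    def copy(self) -> "PMHCComplex":
        return PMHCComplex(
            atoms=[a.copy() for a in self.atoms],
            roles=dict(self.roles),
            allele=self.allele,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PMHCComplex":
        """Apply a rigid transform x -> R x + t to every atom."""
        out = self.copy()
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for a in out.atoms:
            a.coords = R @ a.coords + t
        return out

    # -- peptide helpers ---------------------------------------------------

    def peptide_chain_id(self) -> str:
        cids = self.chains_with_role(ChainRole.PEPTIDE)
        if len(cids) != 1:
            raise StructureError(
                f"expected exactly one PEPTIDE chain, found {len(cids)}"
            )
        return cids[0]

    def peptide_residue_indices(self) -> list[int]:
        cid = self.peptide_chain_id()
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.chain_id == cid:
                seen.setdefault(a.residue_index, None)
        return sorted(seen)

    @property
    def peptide_sequence(self) -> str:
        cid = self.peptide_chain_id()
        by_index: dict[int, str] = {}
        for a in self.atoms:
            if a.chain_id == cid:
                by_index.setdefault(a.residue_index, a.residue_name)
        letters = []
        for idx in sorted(by_index):
            name = by_index[idx]
            letters.append(THREE_TO_ONE.get(name, "X"))
        return "".join(letters)

    def peptide_position_map(self) -> dict[int, int]:
        """Map author residue_index -> 1-based peptide position."""
        return {ri: i + 1 for i, ri in enumerate(self.peptide_residue_indices())}

    def residues_of_chain(self, chain_id: str) -> dict[int, list[AtomRecord]]:
        out: dict[int, list[AtomRecord]] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                out.setdefault(a.residue_index, []).append(a)
        return out


@dataclass
class PositionClass:
    """Anchor/outward classification of one peptide position."""

    position: int
    cls: str  # "ANCHOR" | "OUTWARD" | "INTERMEDIATE"
    sidechain_mhc_contact_fraction: float
    relative_sidechain_sasa: float


# ---------------------------------------------------------------------------
# loading


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by file order."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order of the winning atoms
    chosen = set(id(a) for a in best.values())
    return [a for a in residue if id(a) in chosen]


def load_structure(
    path: str | Path,
    role_map: Mapping[str, ChainRole | str],
    model_index: int = 0,
) -> PMHCComplex:
    """Load a binder/pMHC-I complex from a PDB or mmCIF file.

    Only chains named in ``role_map`` are retained; waters, ligands and
    hydrogens are dropped; alternate locations resolve to the
    highest-occupancy conformer.  Known modified residues (e.g. MSE) are
    mapped to their parent standard residue; unknown nonstandard polymer
    residues cause a :class:`StructureError`.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such structure file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on parse failures
        raise StructureError(f"could not parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path} contains no models")
    if model_index >= len(st):
        raise StructureError(
            f"model_index {model_index} out of range ({len(st)} models)"
        )
    st.setup_entities()
    model = st[model_index]

    roles: dict[str, ChainRole] = {
        cid: (r if isinstance(r, ChainRole) else ChainRole(str(r)))
        for cid, r in role_map.items()
    }
    present = {chain.name for chain in model}
    missing = sorted(set(roles) - present)
    if missing:
        raise StructureError(f"role_map references absent chain(s): {missing}")

    atoms: list[AtomRecord] = []
    for chain in model:
        if chain.name not in roles:
            continue
        for residue in chain:
            info = gemmi.find_tabulated_residue(residue.name)
            if info is not None and info.is_water():
                continue
            name = residue.name
            if name not in THREE_TO_ONE:
                if name in MODIFIED_PARENT:
                    name = MODIFIED_PARENT[name]
                elif info is not None and not info.is_amino_acid():
                    continue  # ligand / non-polymer heteroatom group
                else:
                    raise StructureError(
                        f"unknown nonstandard residue {residue.name} in chain "
                        f"{chain.name} {residue.seqid.num}"
                    )
            for atom in _resolve_altlocs(residue):
                if atom.element.is_hydrogen:
                    continue
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_index=residue.seqid.num,
                        residue_name=name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        coords=np.array(
                            [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                        ),
                    )
                )

    cpx = PMHCComplex(atoms=atoms, roles=roles)
    if not cpx.chains_with_role(ChainRole.PEPTIDE):
        raise StructureError("no PEPTIDE chain after filtering")
    if not any(a.chain_id in cpx.chains_with_role(ChainRole.PEPTIDE) for a in atoms):
        raise StructureError("PEPTIDE chain has no atoms after filtering")
    return cpx


def write_pdb(cpx: PMHCComplex, path: str | Path) -> None:
    """Write the complex as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = "pmhckit"
    model = gemmi.Model("1")
    for cid in cpx.chain_ids():
        chain = gemmi.Chain(cid)
        for ridx, ratoms in cpx.residues_of_chain(cid).items():
            res = gemmi.Residue()
            res.name = ratoms[0].residue_name
            res.seqid = gemmi.SeqId(ridx, " ")
            for a in ratoms:
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*[float(x) for x in a.coords])
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# validation


def validate_complex(cpx: PMHCComplex) -> list[str]:
    """Return a list of invariant violations (empty iff the complex is valid)."""
    violations: list[str] = []

    role_chains = set(cpx.roles)
    for a in cpx.atoms:
        if a.chain_id not in role_chains:
            violations.append(
                f"chain-role coverage: atom {a.key()} has chain_id "
                f"{a.chain_id!r} absent from roles"
            )
            break

    peptide_chains = cpx.chains_with_role(ChainRole.PEPTIDE)
    if len(peptide_chains) != 1:
        violations.append(
            f"peptide-chain count: expected exactly 1 PEPTIDE chain, found "
            f"{len(peptide_chains)}"
        )
    binder_chains = cpx.chains_with_role(ChainRole.BINDER)
    if len(binder_chains) > 1:
        violations.append(
            f"binder-chain count: at most 1 BINDER chain allowed, found "
            f"{len(binder_chains)}"
        )

    seen: set[tuple[str, int, str]] = set()
    for a in cpx.atoms:
        k = a.key()
        if k in seen:
            violations.append(f"atom-key uniqueness: duplicate atom {k}")
        seen.add(k)
        if not np.all(np.isfinite(a.coords)):
            violations.append(f"finite coordinates: atom {k} has non-finite coords")
        if a.element and a.atom_name:
            lead = a.atom_name.lstrip("0123456789")[: len(a.element)]
            if lead.upper() != a.element.upper():
                violations.append(
                    f"element consistency: atom {k} name {a.atom_name!r} does "
                    f"not lead with element {a.element!r}"
                )

    if len(peptide_chains) == 1:
        n = len(cpx.peptide_residue_indices())
        if not 8 <= n <= 11:
            violations.append(
                f"peptide-length bound: peptide has {n} residues, expected 8-11"
            )
    return violations


# ---------------------------------------------------------------------------
# anchor/outward classification


def _sidechain_atoms(ratoms: Sequence[AtomRecord]) -> list[AtomRecord]:
    return [a for a in ratoms if a.atom_name not in BACKBONE_ATOMS]


def classify_peptide_positions(
    cpx: PMHCComplex,
    contact_cutoff: float = 4.5,
    anchor_min_fraction: float = 0.5,
    outward_max_fraction: float = 0.2,
    outward_min_rel_sasa: float = 0.2,
    probe_radius: float = 1.4,
    n_sphere_points: int = 240,
) -> list[PositionClass]:
    """Classify each peptide position as ANCHOR, OUTWARD or INTERMEDIATE.

    The contact fraction is the share of a position's side-chain heavy
    atoms lying within ``contact_cutoff`` of any MHC heavy-chain atom
    (glycine, having no side chain, is assigned fraction 1.0 by convention:
    it cannot present a recognizable side chain either way).  Relative
    side-chain SASA is computed with the binder removed, normalised by the
    same side chain's SASA in isolation, so it is representation-agnostic.
    Classification: ANCHOR if fraction >= ``anchor_min_fraction``; OUTWARD
    if fraction <= ``outward_max_fraction`` and relative SASA >=
    ``outward_min_rel_sasa``; otherwise INTERMEDIATE.
    """
    from .interface import shrake_rupley_sasa  # local import, no cycle at load

    if not cpx.chains_with_role(ChainRole.MHC_HEAVY):
        raise StructureError("classification requires an MHC_HEAVY chain")

    noB = cpx.without_role(ChainRole.BINDER)
    pep_cid = noB.peptide_chain_id()
    pep_residues = noB.residues_of_chain(pep_cid)
    posmap = noB.peptide_position_map()

    mhc_atoms = noB.atoms_of_role(ChainRole.MHC_HEAVY)
    mhc_xyz = noB.coords_of(mhc_atoms)

    from scipy.spatial import cKDTree

    tree = cKDTree(mhc_xyz) if len(mhc_xyz) else None

    sasa_all = shrake_rupley_sasa(
        noB.atoms, probe_radius=probe_radius, n_sphere_points=n_sphere_points
    )
    atom_index = {id(a): i for i, a in enumerate(noB.atoms)}

    out: list[PositionClass] = []
    for ridx in sorted(pep_residues):
        ratoms = pep_residues[ridx]
        pos = posmap[ridx]
        side = _sidechain_atoms(ratoms)
        if not side:  # glycine
            fraction = 1.0
            ref_atoms = [a for a in ratoms if a.atom_name == "CA"] or ratoms
        else:
            if tree is None:
                n_close = 0
            else:
                d, _ = tree.query(noB.coords_of(side), k=1)
                n_close = int(np.sum(d <= contact_cutoff))
            fraction = n_close / len(side)
            ref_atoms = side

        complex_sasa = float(
            sum(sasa_all[atom_index[id(a)]] for a in ref_atoms)
        )
        iso = shrake_rupley_sasa(
            ref_atoms, probe_radius=probe_radius, n_sphere_points=n_sphere_points
        )
        iso_sasa = float(np.sum(iso))
        rel = complex_sasa / iso_sasa if iso_sasa > 0 else 0.0

        if fraction >= anchor_min_fraction:
            cls = "ANCHOR"
        elif fraction <= outward_max_fraction and rel >= outward_min_rel_sasa:
            cls = "OUTWARD"
        else:
            cls = "INTERMEDIATE"
        out.append(
            PositionClass(
                position=pos,
                cls=cls,
                sidechain_mhc_contact_fraction=float(fraction),
                relative_sidechain_sasa=float(rel),
            )
        )
    return out
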