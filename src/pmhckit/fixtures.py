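"""Deterministic toy pMHC-I fixtures and synthetic proteomes.

Real pMHC-I complexes are a peptide lying extended in a groove formed by
two long alpha helices, with (for design models) a binder domain arcing
above.  ``make_toy_pmhc`` emulates exactly that topology at toy scale:

* an extended peptide along x (3.5 Angstrom rise per residue) whose side
  chains are reduced to Cbeta plus one distal pseudo-atom, oriented down
  into the groove at designated anchor positions and up (outward)
  elsewhere;
* an MHC heavy chain consisting of two flanking ideal-helix atom clouds
  plus a beta-sheet-like groove floor beneath the anchors;
* an optional binder: two helices above the peptide with serine "stems"
  reaching down to touch exactly the designated contact positions.

The construction is engineered so that contact/classification outcomes
are knowable by design (anchors contact the floor with fraction 1.0;
outward side chains contact nothing), making every geometric operation
testable against brute-force oracles without any structure downloads.
All generators are pure functions of (spec, seed).

``ideal_alpha_helix`` builds a chemically sensible poly-Ala helix from
standard internal coordinates (phi = -57, psi = -47), suitable for
checking backbone i -> i-4 hydrogen-bond detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure import (
    AtomRecord,
    ChainRole,
    ONE_TO_THREE,
    PMHCComplex,
    StructureError,
)

__all__ = [
    "FixtureSpec",
    "make_toy_pmhc",
    "make_random_spec",
    "perturb_coords",
    "make_synthetic_proteome",
    "write_fasta",
    "ideal_alpha_helix",
]

#: Distal side-chain pseudo-atom name/element per residue letter.  The name
#: is chosen so H-bond donor/acceptor tables behave sensibly (e.g. Ser OG).
_DISTAL = {
    "S": ("OG", "O"), "T": ("OG1", "O"), "Y": ("OH", "O"), "C": ("SG", "S"),
    "D": ("OD1", "O"), "E": ("OE1", "O"), "N": ("OD1", "O"), "Q": ("OE1", "O"),
    "V": ("CG1", "C"), "I": ("CG1", "C"),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one toy pMHC-I fixture (same spec + seed => same atoms)."""

    peptide: str = "EVDPIGHLY"
    anchor_positions: tuple[int, ...] = (2, 9)
    contact_positions: tuple[int, ...] = (5, 7, 8)
    helix_separation: float = 17.0  # Angstrom between the two groove helix axes
    peptide_rise: float = 3.5  # Angstrom per residue, extended conformation
    binder_height: float = 10.0  # binder helix axis height above the peptide plane
    include_binder: bool = True
    seed: int = 0


def _atom(cid, ridx, rname, aname, elem, x, y, z) -> AtomRecord:
    return AtomRecord(
        chain_id=cid,
        residue_index=ridx,
        residue_name=rname,
        atom_name=aname,
        element=elem,
        coords=np.array([x, y, z], dtype=float),
    )


def _helix_cloud(cid: str, first_index: int, n_res: int, x0: float,
                 y0: float, z0: float) -> list[AtomRecord]:
    """Poly-Ala helix-shaped atom cloud with axis along x at (y0, z0)."""
    atoms = []
    for i in range(n_res):
        theta = math.radians(100.0 * i)
        x = x0 + 1.5 * i
        y = y0 + 2.3 * math.cos(theta)
        z = z0 + 2.3 * math.sin(theta)
        ridx = first_index + i
        atoms.append(_atom(cid, ridx, "ALA", "N", "N", x - 0.5, y, z))
        atoms.append(_atom(cid, ridx, "ALA", "CA", "C", x, y, z))
        atoms.append(_atom(cid, ridx, "ALA", "C", "C", x + 0.5, y, z))
        atoms.append(_atom(cid, ridx, "ALA", "O", "O", x + 0.5, y, z + 0.8))
    return atoms


def make_toy_pmhc(spec: FixtureSpec) -> PMHCComplex:
    """Build a toy binder/pMHC-I complex from a fixture spec.

    Contact positions must be outward-facing (not anchors) and carry a
    side chain long enough to be reached (not Gly/Ala).  Raises
    :class:`StructureError` on geometrically impossible specs.
    """
    k = len(spec.peptide)
    if not 8 <= k <= 11:
        raise StructureError(f"peptide length {k} outside 8-11")
    for aa in spec.peptide:
        if aa not in ONE_TO_THREE:
            raise StructureError(f"unknown peptide letter {aa!r}")
    anchors = set(spec.anchor_positions)
    if not all(1 <= p <= k for p in anchors):
        raise StructureError(f"anchor positions {sorted(anchors)} out of range 1..{k}")
    contacts = set(spec.contact_positions)
    if not all(1 <= p <= k for p in contacts):
        raise StructureError(f"contact positions {sorted(contacts)} out of range 1..{k}")
    if contacts & anchors:
        raise StructureError("binder contact positions must be outward, not anchors")
    for p in contacts:
        if spec.peptide[p - 1] in "GA":
            raise StructureError(
                f"contact position {p} is {spec.peptide[p-1]}: side chain too short"
            )
    half_sep = spec.helix_separation / 2.0
    if half_sep - 2.3 - 0.5 < 2.0:
        raise StructureError("helix_separation too small: helices overlap the peptide")

    rise = spec.peptide_rise
    atoms: list[AtomRecord] = []

    # --- peptide (chain C), extended along x in the z = 0 plane
    for i, aa in enumerate(spec.peptide):
        pos = i + 1
        x = i * rise
        rname = ONE_TO_THREE[aa]
        atoms.append(_atom("C", pos, rname, "N", "N", x - 1.2, 0.5, 0.0))
        atoms.append(_atom("C", pos, rname, "CA", "C", x, 0.0, 0.0))
        atoms.append(_atom("C", pos, rname, "C", "C", x + 1.2, 0.5, 0.0))
        atoms.append(_atom("C", pos, rname, "O", "O", x + 1.2, 1.7, 0.0))
        if aa == "G":
            continue
        zdir = -1.0 if pos in anchors else 1.0
        atoms.append(_atom("C", pos, rname, "CB", "C", x, 0.0, 1.53 * zdir))
        if aa != "A":
            name, elem = _DISTAL.get(aa, ("CG", "C"))
            atoms.append(_atom("C", pos, rname, name, elem, x, 0.0, 3.0 * zdir))

    # --- MHC heavy chain (chain A): two flanking helices + groove floor
    span = (k - 1) * rise
    n_helix = int(math.ceil((span + 8.0) / 1.5))
    atoms += _helix_cloud("A", 1, n_helix, -4.0, +half_sep, 0.0)
    atoms += _helix_cloud("A", 1 + n_helix, n_helix, -4.0, -half_sep, 0.0)
    ridx = 1 + 2 * n_helix
    xgrid = np.arange(-1.75, span + 1.75 + 1e-9, 1.75)
    for y in (-2.5, 0.0, 2.5):
        for x in xgrid:
            atoms.append(_atom("A", ridx, "GLY", "CA", "C", float(x), y, -5.0))
            ridx += 1

    # --- beta-2-microglobulin (chain B): small cloud below the floor
    for i in range(4):
        atoms.append(_atom("B", i + 1, "GLY", "CA", "C", span / 2 + 2.0 * i, 0.0, -9.0))

    roles = {
        "A": ChainRole.MHC_HEAVY,
        "B": ChainRole.B2M,
        "C": ChainRole.PEPTIDE,
    }

    # --- binder (chain D): two helices above + serine stems at contacts
    if spec.include_binder:
        h = spec.binder_height
        atoms += _helix_cloud("D", 1, n_helix, -4.0, +3.0, h)
        atoms += _helix_cloud("D", 1 + n_helix, n_helix, -4.0, -3.0, h)
        ridx = 1 + 2 * n_helix
        for p in sorted(contacts):
            x = (p - 1) * rise
            atoms.append(_atom("D", ridx, "SER", "CA", "C", x, 0.0, h - 0.8))
            atoms.append(_atom("D", ridx, "SER", "CB", "C", x, 0.0, h - 2.3))
            atoms.append(_atom("D", ridx, "SER", "OG", "O", x, 0.0, h - 3.8))
            ridx += 1
        roles["D"] = ChainRole.BINDER

    return PMHCComplex(atoms=atoms, roles=roles)


def make_random_spec(seed: int) -> FixtureSpec:
    """A randomized but always-valid fixture spec (pure function of seed)."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(8, 12))
    letters = np.array(list("CDEFHIKLMNPQRSTVWY"))  # no G/A: every side chain reachable
    peptide = "".join(rng.choice(letters, size=k))
    anchors = (2, k)
    candidates = [p for p in range(1, k + 1) if p not in anchors]
    n_contacts = int(rng.integers(2, min(5, len(candidates)) + 1))
    contacts = tuple(sorted(rng.choice(candidates, size=n_contacts, replace=False).tolist()))
    return FixtureSpec(
        peptide=peptide,
        anchor_positions=anchors,
        contact_positions=contacts,
        seed=seed,
    )


def perturb_coords(cpx: PMHCComplex, sigma: float, seed: int) -> PMHCComplex:
    """Add i.i.d. zero-mean Gaussian noise (scale ``sigma``) to every coordinate."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = cpx.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(len(out.atoms), 3))
    for a, dx in zip(out.atoms, noise):
        a.coords = a.coords + dx
    return out


# ---------------------------------------------------------------------------
# synthetic proteomes


def make_synthetic_proteome(
    n_proteins: int,
    length: int,
    seed: int,
    planted: Sequence[tuple[str, int, int]] = (),
) -> list[tuple[str, str]]:
    """Random proteome records with planted substrings at known loci.

    ``planted`` entries are (sequence, protein index 1-based, offset
    1-based); the planted peptide overwrites the random background at
    exactly that locus.  Overlapping or out-of-range plants are errors.
    Residue frequencies are uniform over the 20 standard letters.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seqs = ["".join(rng.choice(letters, size=length)) for _ in range(n_proteins)]

    occupied: dict[int, list[tuple[int, int]]] = {}
    for pep, prot, off in planted:
        if not 1 <= prot <= n_proteins:
            raise ValueError(f"planted protein index {prot} out of range")
        if not 1 <= off <= length - len(pep) + 1:
            raise ValueError(
                f"planted offset {off} out of range for length-{len(pep)} peptide"
            )
        span = (off, off + len(pep) - 1)
        for s, e in occupied.get(prot, []):
            if span[0] <= e and s <= span[1]:
                raise ValueError(f"overlapping planted loci in protein {prot}")
        occupied.setdefault(prot, []).append(span)
        s = seqs[prot - 1]
        seqs[prot - 1] = s[: off - 1] + pep + s[off - 1 + len(pep) :]
    return [(f"prot{i+1:04d}", s) for i, s in enumerate(seqs)]


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# ideal alpha-helix via internal coordinates (NeRF construction)


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Position a new atom given three predecessors and internal coordinates."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def ideal_alpha_helix(
    n_res: int,
    chain_id: str = "H",
    role: ChainRole = ChainRole.OTHER,
    phi: float = -57.0,
    psi: float = -47.0,
) -> PMHCComplex:
    """Poly-Ala alpha helix with standard backbone internal coordinates.

    Bond lengths/angles follow standard peptide geometry; at the default
    (phi, psi) the N(i)...O(i-4) backbone distances fall near 3 Angstrom,
    producing the canonical helical hydrogen-bond ladder.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([1.458, 0.0, 0.0])
    C = CA + 1.525 * np.array([math.cos(math.radians(180 - 111.2)),
                               math.sin(math.radians(180 - 111.2)), 0.0])
    coords = [{"N": N, "CA": CA, "C": C}]
    for i in range(1, n_res):
        prev = coords[-1]
        Ni = _place_atom(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, psi)
        CAi = _place_atom(prev["CA"], prev["C"], Ni, 1.458, 121.7, 180.0)  # omega trans
        Ci = _place_atom(prev["C"], Ni, CAi, 1.525, 111.2, phi)
        coords.append({"N": Ni, "CA": CAi, "C": Ci})
    # carbonyl O: trans to the next N (torsion psi + 180); CB: standard branch
    for i, res in enumerate(coords):
        res["O"] = _place_atom(res["N"], res["CA"], res["C"], 1.231, 120.8, psi + 180.0)
        res["CB"] = _place_atom(res["C"], res["N"], res["CA"], 1.53, 110.6, 122.7)

    atoms = []
    for i, res in enumerate(coords):
        for name in ("N", "CA", "C", "O", "CB"):
            elem = name[0]
            xyz = res[name]
            atoms.append(_atom(chain_id, i + 1, "ALA", name, elem, *xyz))
    return PMHCComplex(atoms=atoms, roles={chain_id: role})
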