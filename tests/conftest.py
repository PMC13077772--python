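"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive every quantity with naive double loops
(no KD-trees, no shared code paths with the package) so they can stand as
independent references for the geometric operations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from pmhckit import ChainRole, FixtureSpec, make_toy_pmhc
from pmhckit.structure import BACKBONE_ATOMS


@pytest.fixture(scope="session")
def toy_spec() -> FixtureSpec:
    return FixtureSpec()  # EVDPIGHLY, anchors (2, 9), binder contacts (5, 7, 8)


@pytest.fixture(scope="session")
def toy_complex(toy_spec):
    return make_toy_pmhc(toy_spec)


def group_atoms(cpx, role: ChainRole):
    return cpx.atoms_of_role(role)


def brute_contact_pairs(cpx, role_a, role_b, cutoff):
    """All-pairs double-loop contact oracle."""
    out = []
    for a in cpx.atoms_of_role(role_a):
        for b in cpx.atoms_of_role(role_b):
            d = math.dist(a.coords, b.coords)
            if d <= cutoff:
                out.append((a.key(), b.key(), d))
    return out


# Independent donor/acceptor definitions for the H-bond oracle (kept small:
# the fixtures only ever contain these heavy-atom types).
_ORACLE_DONORS = {
    ("N", None): "CA",  # backbone amide (not PRO)
    ("OG", "SER"): "CB",
    ("OG1", "THR"): "CB",
}
_ORACLE_ACCEPTORS = {"O", "OXT", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH",
                     "ND1", "NE2"}


def brute_hbonds(cpx, donor_role, acceptor_role, d_max=3.5, angle_min=120.0):
    """Double-loop H-bond oracle with its own donor/acceptor rules."""
    atoms_by_key = {a.key(): a for a in cpx.atoms}
    bonds = []
    for don in cpx.atoms_of_role(donor_role):
        if don.atom_name == "N":
            if don.residue_name == "PRO":
                continue
            ante_name = "CA"
        elif (don.atom_name, don.residue_name) in _ORACLE_DONORS:
            ante_name = _ORACLE_DONORS[(don.atom_name, don.residue_name)]
        else:
            continue
        ante = atoms_by_key.get((don.chain_id, don.residue_index, ante_name))
        if ante is None:
            continue
        for acc in cpx.atoms_of_role(acceptor_role):
            is_acc = acc.atom_name in {"O", "OXT"} or (
                acc.atom_name in _ORACLE_ACCEPTORS
                and acc.atom_name not in {"O", "OXT"}
                and acc.residue_name in {"ASP", "GLU", "ASN", "GLN", "SER", "THR",
                                         "TYR", "HIS"}
            )
            if not is_acc:
                continue
            if (acc.chain_id == don.chain_id
                    and abs(acc.residue_index - don.residue_index) < 2):
                continue
            d = math.dist(don.coords, acc.coords)
            if d > d_max:
                continue
            v1 = ante.coords - don.coords
            v2 = acc.coords - don.coords
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if angle >= angle_min:
                bonds.append((don.key(), acc.key()))
    return bonds


def brute_interface_residues(cpx, cutoff):
    out = set()
    targets = cpx.atoms_of_role(ChainRole.PEPTIDE) + cpx.atoms_of_role(ChainRole.MHC_HEAVY)
    for a in cpx.atoms_of_role(ChainRole.BINDER):
        for t in targets:
            if math.dist(a.coords, t.coords) <= cutoff:
                out.add((a.chain_id, a.residue_index))
                break
    return out


def brute_sidechain_contact_fraction(cpx, cutoff=4.5):
    """Per peptide position, fraction of side-chain atoms near any MHC atom."""
    pep_cid = cpx.peptide_chain_id()
    posmap = cpx.peptide_position_map()
    mhc = cpx.atoms_of_role(ChainRole.MHC_HEAVY)
    fractions = {}
    for ridx, ratoms in cpx.residues_of_chain(pep_cid).items():
        side = [a for a in ratoms if a.atom_name not in BACKBONE_ATOMS]
        if not side:
            fractions[posmap[ridx]] = 1.0
            continue
        n = sum(
            1 for a in side
            if any(math.dist(a.coords, m.coords) <= cutoff for m in mhc)
        )
        fractions[posmap[ridx]] = n / len(side)
    return fractions


def random_rigid_transform(seed: int):
    """A uniformly random rotation (via QR) and a random translation."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=20.0, size=3)
    return q, t
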