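"""On/off-target specificity scoring for designed pMHC-I binders.

The design funnel keeps only binders that recognise the target peptide
more confidently than closely related off-target peptides.  Scoring is a
pluggable contract — any callable ``scorer(complex, peptide_seq) ->
float`` with the fixed orientation *higher = more favorable* (energy-like
scorers must negate before reporting).  For desk-scale, fully
deterministic testing this module ships a coarse-grained contact-potential
proxy: peptide sequences are threaded onto the fixed peptide backbone and
scored by summing residue-residue contact energies over peptide/binder
residue pairs whose Cbeta atoms (Calpha for glycine) lie within a cutoff.
The proxy is a transparent test harness, not a reimplementation of the
neural sequence/structure predictors used in real campaigns; externally
computed predictor scores can be loaded from TSV and ranked with the same
downstream logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .structure import ChainRole, PMHCComplex, StructureError

__all__ = [
    "AMINO_ACIDS",
    "ContactPotential",
    "SpecificityRecord",
    "default_contact_potential",
    "proxy_peptide_score",
    "peptide_identity_margin",
    "specificity_margin",
    "rank_designs",
    "read_score_table",
    "write_score_table",
    "records_from_score_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Kyte-Doolittle hydropathy, used to build the default contact potential.
_KD = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}


@dataclass
class ContactPotential:
    """Symmetric 20x20 residue-contact potential (contact energies, kT-like).

    More negative entries are more favorable contacts; the proxy score
    negates the summed energy so that the package-wide convention
    (higher score = more favorable) holds.
    """

    matrix: np.ndarray
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (20, 20):
            raise ValueError(f"potential must be 20x20, got {m.shape}")
        if not np.allclose(m, m.T):
            raise ValueError("contact potential must be symmetric")
        self.matrix = m

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        try:
            return float(self.matrix[_AA_INDEX[a], _AA_INDEX[b]])
        except KeyError as exc:
            raise KeyError(f"unknown residue letter {exc}") from exc


def default_contact_potential(scale: float = 0.65) -> ContactPotential:
    """Hydrophobicity-additive contact potential.

    Pairwise residue contact energies of the Miyazawa-Jernigan type are
    well approximated by an additive function of the partners'
    hydrophobicities; this builds e(a,b) = -scale * (h'(a) + h'(b)) with
    h' the Kyte-Doolittle hydropathy shifted to [0, 9], giving energies in
    roughly [-6, 0] kT with hydrophobic pairs most favorable.
    """
    h = np.array([_KD[aa] + 4.5 for aa in AMINO_ACIDS])  # 0 .. 9
    e = -scale * (h[:, None] + h[None, :]) / 2.0
    return ContactPotential(matrix=e)


@dataclass
class SpecificityRecord:
    design_id: str
    on_target_peptide: str
    on_score: float
    off_scores: dict[str, float]
    margin: float
    aggregation: str  # "worst_case_max" | "mean"
    target_rank: int


# ---------------------------------------------------------------------------
# proxy scorer


def _cb_atoms(cpx: PMHCComplex, role: ChainRole) -> dict[int, np.ndarray]:
    """Per residue: Cbeta coordinate, falling back to Calpha (glycine)."""
    out: dict[int, np.ndarray] = {}
    for cid in cpx.chains_with_role(role):
        for ridx, ratoms in cpx.residues_of_chain(cid).items():
            names = {a.atom_name: a for a in ratoms}
            atom = names.get("CB") or names.get("CA")
            if atom is not None:
                out[ridx] = atom.coords
    return out


def proxy_peptide_score(
    cpx: PMHCComplex,
    peptide_seq: str,
    potential: ContactPotential | None = None,
    cb_cutoff: float = 8.0,
) -> float:
    """Thread ``peptide_seq`` onto the peptide backbone and score its contacts.

    score = -sum over (peptide position i, binder residue j) pairs with
    Cbeta-Cbeta distance <= ``cb_cutoff`` of potential[seq[i], binder_aa_j].
    Threading is sequence-only: the backbone geometry is untouched, so the
    contact set is identical for every candidate sequence and only the
    residue identities change.  Deterministic; higher = more favorable.
    """
    from .structure import THREE_TO_ONE

    pot = potential or default_contact_potential()
    posmap = cpx.peptide_position_map()
    if len(peptide_seq) != len(posmap):
        raise ValueError(
            f"peptide_seq length {len(peptide_seq)} != peptide chain length {len(posmap)}"
        )
    for aa in peptide_seq:
        if aa not in _AA_INDEX:
            raise KeyError(f"unknown residue letter {aa!r}")

    pep_cb = _cb_atoms(cpx, ChainRole.PEPTIDE)
    binder_cb = _cb_atoms(cpx, ChainRole.BINDER)

    binder_aa: dict[int, str] = {}
    for cid in cpx.chains_with_role(ChainRole.BINDER):
        for ridx, ratoms in cpx.residues_of_chain(cid).items():
            binder_aa[ridx] = THREE_TO_ONE.get(ratoms[0].residue_name, "X")

    energy = 0.0
    for ridx, xyz in pep_cb.items():
        aa_i = peptide_seq[posmap[ridx] - 1]
        for bidx, bxyz in binder_cb.items():
            if np.linalg.norm(xyz - bxyz) <= cb_cutoff:
                aa_j = binder_aa[bidx]
                if aa_j not in _AA_INDEX:
                    raise KeyError(f"unknown binder residue letter {aa_j!r}")
                energy += pot[aa_i, aa_j]
    return -energy


# ---------------------------------------------------------------------------
# margins and ranking


def specificity_margin(
    on_score: float,
    off_scores: Mapping[str, float],
    aggregation: str = "worst_case_max",
) -> tuple[float, int]:
    """Margin of the on-target score over the off-target aggregate, plus rank.

    ``worst_case_max`` aggregates off-targets by their maximum (the hardest
    competitor); ``mean`` by their average.  The target rank is 1 plus the
    number of off-targets scoring strictly higher (ties share the better
    rank).
    """
    if not off_scores:
        raise ValueError("off_scores must be non-empty")
    vals = list(off_scores.values())
    if aggregation == "worst_case_max":
        agg = max(vals)
    elif aggregation == "mean":
        agg = float(np.mean(vals))
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    margin = on_score - agg
    rank = 1 + sum(1 for v in vals if v > on_score)
    return margin, rank


def peptide_identity_margin(
    cpx: PMHCComplex,
    target_seq: str,
    decoy_seqs: Sequence[str],
    scorer: Callable[[PMHCComplex, str], float] | None = None,
    design_id: str = "design",
    aggregation: str = "worst_case_max",
) -> SpecificityRecord:
    """Score the target sequence against decoys on the same structure."""
    if not decoy_seqs:
        raise ValueError("decoy_seqs must be non-empty")
    score = scorer or proxy_peptide_score
    try:
        on = score(cpx, target_seq)
    except Exception as exc:
        raise type(exc)(f"scoring target {target_seq!r}: {exc}") from exc
    offs: dict[str, float] = {}
    for seq in decoy_seqs:
        try:
            offs[seq] = score(cpx, seq)
        except Exception as exc:
            raise type(exc)(f"scoring decoy {seq!r}: {exc}") from exc
    margin, rank = specificity_margin(on, offs, aggregation)
    return SpecificityRecord(
        design_id=design_id,
        on_target_peptide=target_seq,
        on_score=on,
        off_scores=offs,
        margin=margin,
        aggregation=aggregation,
        target_rank=rank,
    )


def rank_designs(
    records: Iterable[SpecificityRecord],
    min_margin: float = 0.0,
) -> list[SpecificityRecord]:
    """Designs with margin >= ``min_margin``, best margin first.

    Ties are broken by design_id lexicographically.
    """
    passing = [r for r in records if r.margin >= min_margin]
    return sorted(passing, key=lambda r: (-r.margin, r.design_id))


# ---------------------------------------------------------------------------
# external score tables (design_id, peptide, score)

SCORE_COLUMNS = ["design_id", "peptide", "score"]


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"score table missing columns {missing}")
    return df[SCORE_COLUMNS]


def write_score_table(df: pd.DataFrame, path: str | Path) -> None:
    df[SCORE_COLUMNS].to_csv(path, sep="\t", index=False)


def records_from_score_table(
    df: pd.DataFrame,
    target_peptides: Mapping[str, str],
    aggregation: str = "worst_case_max",
) -> list[SpecificityRecord]:
    """Build one SpecificityRecord per design from a long score table.

    ``target_peptides`` maps design_id -> its on-target peptide; every
    other peptide scored for that design is treated as an off-target.
    """
    records = []
    for design_id, sub in df.groupby("design_id", sort=True):
        target = target_peptides.get(str(design_id))
        if target is None:
            raise ValueError(f"no target peptide given for design {design_id!r}")
        scores = dict(zip(sub["peptide"], sub["score"].astype(float)))
        if target not in scores:
            raise ValueError(f"design {design_id!r} has no score for its target {target!r}")
        offs = {p: s for p, s in scores.items() if p != target}
        if not offs:
            raise ValueError(f"design {design_id!r} has no off-target scores")
        margin, rank = specificity_margin(scores[target], offs, aggregation)
        records.append(
            SpecificityRecord(
                design_id=str(design_id),
                on_target_peptide=target,
                on_score=scores[target],
                off_scores=offs,
                margin=margin,
                aggregation=aggregation,
                target_rank=rank,
            )
        )
    return records
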