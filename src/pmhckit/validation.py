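"""Structural and functional validation analytics.

Structural side: Kabsch least-squares superposition, interface residue
sets, and model-vs-crystal comparison reporting binder Calpha RMSD and
all-atom RMSD over the interface residues.  Functional side: CD69
activation (MFI) summaries with fold-over-control, and yeast-display sort
enrichment from pre/post NGS counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structure import ChainRole, PMHCComplex, StructureError

__all__ = [
    "SuperpositionResult",
    "CompareParams",
    "EnrichmentRecord",
    "kabsch_superpose",
    "interface_residue_set",
    "compare_model_to_crystal",
    "activation_summary",
    "sort_enrichment",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_atoms: int
    degenerate: bool = False  # collinear/rank-deficient point set: rotation not unique

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``reference``.

    Correspondence is by row order; reflections are excluded (the rotation
    determinant is forced to +1).  Point sets whose spread is essentially
    one-dimensional are flagged ``degenerate`` — the RMSD is still optimal
    but the rotation about the line is arbitrary.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"coordinate sets must both be (n, 3); got {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 corresponding atoms")

    cP, cQ = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cP, Q - cQ
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - R @ cP

    moved = P0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q0) ** 2, axis=1))))
    # rank of the spread: collinear sets have at most one significant axis
    spread = min(np.linalg.svd(P0, compute_uv=False)[1] if n > 1 else 0.0,
                 np.linalg.svd(Q0, compute_uv=False)[1])
    degenerate = bool(spread < 1e-8 * max(1.0, float(np.max(np.abs(P0)) or 1.0)))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=n,
                               degenerate=degenerate)


def interface_residue_set(cpx: PMHCComplex, cutoff: float = 4.5) -> set[tuple[str, int]]:
    """Binder residues with any heavy atom within ``cutoff`` of peptide or MHC."""
    binder_atoms = cpx.atoms_of_role(ChainRole.BINDER)
    if not binder_atoms:
        raise StructureError("interface_residue_set requires a BINDER chain")
    if cutoff <= 0:
        return set()
    target_atoms = cpx.atoms_of_role(ChainRole.PEPTIDE) + cpx.atoms_of_role(
        ChainRole.MHC_HEAVY
    )
    if not target_atoms:
        return set()
    from scipy.spatial import cKDTree

    tree = cKDTree(cpx.coords_of(target_atoms))
    out: set[tuple[str, int]] = set()
    d, _ = tree.query(cpx.coords_of(binder_atoms), k=1)
    for atom, dist in zip(binder_atoms, d):
        if dist <= cutoff:
            out.add((atom.chain_id, atom.residue_index))
    return out


@dataclass
class CompareParams:
    interface_cutoff: float = 4.5
    report_cutoffs: tuple[float, ...] = (3.5, 4.0, 4.5, 5.0)
    superpose_on: str = "binder"  # "binder" | "mhc"


def _pair_chains(model: PMHCComplex, crystal: PMHCComplex) -> list[tuple[str, str, ChainRole]]:
    pairs = []
    for role in (ChainRole.MHC_HEAVY, ChainRole.B2M, ChainRole.PEPTIDE, ChainRole.BINDER):
        mc = model.chains_with_role(role)
        cc = crystal.chains_with_role(role)
        for m, c in zip(sorted(mc), sorted(cc)):
            pairs.append((m, c, role))
    return pairs


def _residue_correspondence(
    model: PMHCComplex, mcid: str, crystal: PMHCComplex, ccid: str
) -> list[tuple[int, int]]:
    """Pair residues by index, or by global sequence alignment if numbering differs."""
    mres = model.residues_of_chain(mcid)
    cres = crystal.residues_of_chain(ccid)
    common = sorted(set(mres) & set(cres))
    if len(common) >= 0.5 * min(len(mres), len(cres)) and common:
        same = [
            (i, i) for i in common
            if mres[i][0].residue_name == cres[i][0].residue_name
        ]
        if len(same) >= 0.5 * len(common):
            return same
    # numbering differs: align the one-letter sequences
    from Bio import Align

    from .structure import THREE_TO_ONE

    m_idx = sorted(mres)
    c_idx = sorted(cres)
    m_seq = "".join(THREE_TO_ONE.get(mres[i][0].residue_name, "X") for i in m_idx)
    c_seq = "".join(THREE_TO_ONE.get(cres[i][0].residue_name, "X") for i in c_idx)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aln = aligner.align(m_seq, c_seq)[0]
    pairs: list[tuple[int, int]] = []
    for (ms, me), (cs, ce) in zip(aln.aligned[0], aln.aligned[1]):
        for off in range(me - ms):
            if m_seq[ms + off] == c_seq[cs + off]:
                pairs.append((m_idx[ms + off], c_idx[cs + off]))
    return pairs


def compare_model_to_crystal(
    model: PMHCComplex,
    crystal: PMHCComplex,
    params: CompareParams | None = None,
) -> dict:
    """Compare a design model against a crystal structure of the same complex.

    Reports the binder Calpha RMSD (after Kabsch on the binder Calpha
    set by default, or on MHC Calpha with ``superpose_on="mhc"``), the
    all-atom RMSD over the model-defined interface residues (after Kabsch
    on that shared heavy-atom set), the interface residue count at the
    main cutoff, and the count at each cutoff in ``report_cutoffs``.
    Unpairable residues are reported and excluded.
    """
    p = params or CompareParams()
    chain_pairs = _pair_chains(model, crystal)
    if not chain_pairs:
        raise StructureError("no role-matched chain pairs between model and crystal")

    corr: dict[ChainRole, list[tuple[str, str, int, int]]] = {}
    unpaired: list[str] = []
    for mcid, ccid, role in chain_pairs:
        rp = _residue_correspondence(model, mcid, crystal, ccid)
        corr.setdefault(role, []).extend((mcid, ccid, mi, ci) for mi, ci in rp)
        mres = set(model.residues_of_chain(mcid))
        paired_m = {mi for mi, _ in rp}
        for i in sorted(mres - paired_m):
            unpaired.append(f"model {mcid}:{i}")
    if not any(corr.values()):
        raise StructureError("no pairable residues between model and crystal")

    def _atom_lookup(cpx: PMHCComplex) -> dict[tuple[str, int, str], np.ndarray]:
        return {a.key(): a.coords for a in cpx.atoms}

    m_atoms = _atom_lookup(model)
    c_atoms = _atom_lookup(crystal)

    def _matched_coords(role_pairs, atom_names=None):
        mc, cc = [], []
        m_names = {}
        for a in model.atoms:
            m_names.setdefault((a.chain_id, a.residue_index), []).append(a.atom_name)
        for mcid, ccid, mi, ci in role_pairs:
            names = m_names.get((mcid, mi), [])
            for name in names:
                if atom_names is not None and name not in atom_names:
                    continue
                mk, ck = (mcid, mi, name), (ccid, ci, name)
                if mk in m_atoms and ck in c_atoms:
                    mc.append(m_atoms[mk])
                    cc.append(c_atoms[ck])
        return np.array(mc), np.array(cc)

    # --- binder Calpha RMSD
    binder_pairs = corr.get(ChainRole.BINDER, [])
    if not binder_pairs:
        raise StructureError("no pairable BINDER residues")
    if p.superpose_on == "mhc":
        frame_pairs = corr.get(ChainRole.MHC_HEAVY, [])
        if not frame_pairs:
            raise StructureError("superpose_on='mhc' but no pairable MHC residues")
    else:
        frame_pairs = binder_pairs
    fm, fc = _matched_coords(frame_pairs, atom_names={"CA"})
    sup = kabsch_superpose(fm, fc)
    bm, bc = _matched_coords(binder_pairs, atom_names={"CA"})
    moved = sup.apply(bm)
    ca_rmsd = float(np.sqrt(np.mean(np.sum((moved - bc) ** 2, axis=1))))

    # --- interface all-atom RMSD (interface defined on the model)
    iface = interface_residue_set(model, p.interface_cutoff)
    iface_pairs = [
        (mcid, ccid, mi, ci)
        for mcid, ccid, mi, ci in binder_pairs
        if (mcid, mi) in iface
    ]
    if not iface_pairs:
        raise StructureError(f"empty interface at cutoff {p.interface_cutoff}")
    im, ic = _matched_coords(iface_pairs)
    isup = kabsch_superpose(im, ic)
    iface_rmsd = isup.rmsd

    by_cutoff = {
        f"{c:.1f}": len(interface_residue_set(model, c)) for c in p.report_cutoffs
    }
    return {
        "ca_rmsd_binder": ca_rmsd,
        "interface_allatom_rmsd": iface_rmsd,
        "n_interface_residues": len(iface),
        "n_interface_atoms": int(isup.n_atoms),
        "n_binder_ca": int(len(bm)),
        "n_interface_by_cutoff": by_cutoff,
        "unpaired_residues": unpaired,
    }


# ---------------------------------------------------------------------------
# functional readouts


def activation_summary(
    table: pd.DataFrame, control_label: str = "DMSO"
) -> pd.DataFrame:
    """Per-condition mean MFI, sample SD and fold-over-control.

    ``table`` needs columns (condition, replicate, mfi).  SD uses n-1
    degrees of freedom and is reported as 0 for single replicates; fold
    change is mean MFI / mean control MFI.
    """
    for col in ("condition", "mfi"):
        if col not in table.columns:
            raise ValueError(f"activation table missing column {col!r}")
    if control_label not in set(table["condition"]):
        raise ValueError(f"control condition {control_label!r} not in table")
    if not np.all(np.isfinite(table["mfi"].astype(float))):
        raise ValueError("MFI values must be finite")

    g = table.groupby("condition")["mfi"]
    mean = g.mean()
    sd = g.std(ddof=1).fillna(0.0)
    control_mean = float(mean[control_label])
    if control_mean == 0:
        raise ValueError("control mean MFI is zero; fold change undefined")
    out = pd.DataFrame(
        {
            "mean_mfi": mean,
            "sd_mfi": sd,
            "n": g.count(),
            "fold_over_control": mean / control_mean,
        }
    )
    return out.reset_index().sort_values("condition").reset_index(drop=True)


@dataclass
class EnrichmentRecord:
    design_id: str
    count_pre: int
    count_post: int
    log2_enrichment: float


def sort_enrichment(
    counts_pre: Mapping[str, int],
    counts_post: Mapping[str, int],
    pseudocount: float | None = None,
) -> list[EnrichmentRecord]:
    """log2 frequency enrichment of each design across a FACS sort.

    log2e = log2((f_post + p) / (f_pre + p)) with f = count / pool total.
    Designs absent from one pool get count 0.  The default pseudocount is
    Jeffreys-style, p = 0.5 / mean(total_pre, total_post); pass an
    explicit ``pseudocount`` for depth-independent behaviour.
    """
    designs = sorted(set(counts_pre) | set(counts_post))
    pre = {d: int(counts_pre.get(d, 0)) for d in designs}
    post = {d: int(counts_post.get(d, 0)) for d in designs}
    if any(v < 0 for v in pre.values()) or any(v < 0 for v in post.values()):
        raise ValueError("counts must be non-negative")
    total_pre, total_post = sum(pre.values()), sum(post.values())
    if total_pre == 0 and total_post == 0:
        raise ValueError("both pools have zero total counts")
    if pseudocount is None:
        pseudocount = 0.5 / ((total_pre + total_post) / 2.0)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")

    out = []
    for d in designs:
        f_pre = pre[d] / total_pre if total_pre else 0.0
        f_post = post[d] / total_post if total_post else 0.0
        log2e = math.log2((f_post + pseudocount) / (f_pre + pseudocount))
        out.append(
            EnrichmentRecord(
                design_id=d, count_pre=pre[d], count_post=post[d], log2_enrichment=log2e
            )
        )
    return out
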