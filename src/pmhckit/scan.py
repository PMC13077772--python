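"""Proteome-wide cross-reactivity scanning for pMHC-I binders.

A binder that reads out only a few outward-facing peptide positions can
be activated by any proteome peptide that (a) is presentable on the same
HLA allele — i.e. carries compatible anchor residues — and (b) matches
the target at the positions the binder actually contacts.  This module
enumerates every length-k window of a proteome, filters by HLA
anchor-motif membership, and ranks candidates by a transparent
position-weighted substitution-matrix similarity in which, by default,
outward-facing positions carry weight 1 and anchor positions weight 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MotifTable",
    "PeptideHit",
    "DEFAULT_MOTIFS",
    "identity_matrix",
    "blosum62",
    "enumerate_windows",
    "anchor_filter",
    "positional_similarity",
    "scan_proteome",
    "read_fasta",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class MotifTable:
    """Allowed anchor residues per position for one HLA allele.

    Positions are 1-based; the key ``"C"`` denotes the C-terminal position
    whatever the peptide length.  These packaged tables are editable
    defaults capturing textbook anchor preferences, not fitted motifs.
    """

    allele: str
    allowed: dict[str, set[str]]

    def resolved(self, k: int) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for pos, residues in self.allowed.items():
            p = k if pos == "C" else int(pos)
            if not 1 <= p <= k:
                raise ValueError(f"motif position {pos} invalid for length {k}")
            if not residues:
                raise ValueError(f"motif position {pos} has an empty residue set")
            out[p] = set(residues)
        return out

    def anchor_positions(self, k: int) -> set[int]:
        return set(self.resolved(k))


DEFAULT_MOTIFS: dict[str, MotifTable] = {
    "A*01:01": MotifTable("A*01:01", {"3": set("DE"), "C": set("Y")}),
    "A*02:01": MotifTable("A*02:01", {"2": set("LMIV"), "C": set("VLI")}),
    "A*03:01": MotifTable("A*03:01", {"2": set("LMIVAT"), "C": set("KR")}),
    "C*07:02": MotifTable("C*07:02", {"2": set("YF"), "C": set("FYL")}),
}


@dataclass
class PeptideHit:
    """One proteome window with provenance and (optionally) its score."""

    sequence: str
    protein_id: str
    start: int  # 1-based offset within the protein
    anchors_pass: bool | None = None
    similarity: float | None = None


# ---------------------------------------------------------------------------
# substitution matrices


class _IdentityMatrix:
    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return 1.0 if a == b else 0.0


def identity_matrix():
    """Match = 1, mismatch = 0; similarity is then a weighted identity count."""
    return _IdentityMatrix()


def blosum62():
    """BLOSUM62 substitution matrix (Biopython's packaged copy)."""
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# enumeration, filtering, scoring


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(record id, uppercase sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _as_records(proteome) -> list[tuple[str, str]]:
    if isinstance(proteome, (str, Path)):
        return read_fasta(proteome)
    return [(str(pid), str(seq).upper()) for pid, seq in proteome]


def enumerate_windows(proteome, k: int) -> Iterator[PeptideHit]:
    """Every length-``k`` window of every protein, with provenance.

    Records containing non-standard letters (B, J, O, U, X, Z, ...) are
    skipped with a logged warning rather than silently scored.
    """
    if not 8 <= k <= 11:
        raise ValueError(f"window length k={k} outside the pMHC-I range 8-11")
    records = _as_records(proteome)
    if not records:
        raise ValueError("empty proteome")
    for pid, seq in records:
        bad = set(seq) - STANDARD_AA
        if bad:
            logger.warning(
                "skipping record %s: non-standard letters %s", pid, sorted(bad)
            )
            continue
        for start in range(len(seq) - k + 1):
            yield PeptideHit(sequence=seq[start : start + k], protein_id=pid, start=start + 1)


def anchor_filter(
    hits: Iterable[PeptideHit], motif: MotifTable | None
) -> Iterator[PeptideHit]:
    """Keep hits whose residues satisfy the motif at every anchor position.

    An absent or empty motif passes everything; ``anchors_pass`` is set on
    every emitted hit.
    """
    resolved_cache: dict[int, dict[int, set[str]]] = {}
    for hit in hits:
        if motif is None or not motif.allowed:
            hit.anchors_pass = True
            yield hit
            continue
        k = len(hit.sequence)
        if k not in resolved_cache:
            resolved_cache[k] = motif.resolved(k)
        ok = all(hit.sequence[p - 1] in allowed for p, allowed in resolved_cache[k].items())
        hit.anchors_pass = ok
        if ok:
            yield hit


def positional_similarity(
    query: str,
    candidate: str,
    weights: Sequence[float] | None = None,
    matrix=None,
) -> float:
    """sum_i weights[i] * matrix[query[i], candidate[i]].

    With the identity matrix and unit weights this is the number of
    matching positions (k minus the Hamming distance).
    """
    if len(query) != len(candidate):
        raise ValueError(
            f"length mismatch: query {len(query)} vs candidate {len(candidate)}"
        )
    k = len(query)
    w = [1.0] * k if weights is None else list(weights)
    if len(w) != k:
        raise ValueError(f"weights length {len(w)} != peptide length {k}")
    if any(x < 0 for x in w):
        raise ValueError("weights must be non-negative")
    m = matrix if matrix is not None else identity_matrix()
    return float(sum(w[i] * m[query[i], candidate[i]] for i in range(k)))


def outward_weights(k: int, anchor_positions: Iterable[int]) -> list[float]:
    """Weight 1 everywhere except 0 at anchor positions (1-based)."""
    anchors = set(anchor_positions)
    return [0.0 if i + 1 in anchors else 1.0 for i in range(k)]


def scan_proteome(
    proteome,
    query: str,
    motif: MotifTable | None = None,
    weights: Sequence[float] | None = None,
    matrix=None,
    top_n: int = 50,
) -> list[PeptideHit]:
    """Rank proteome windows by similarity to the query peptide.

    Pipeline: enumerate all length-k windows, keep those passing the HLA
    anchor motif, score each with :func:`positional_similarity`, and
    return the ``top_n`` by similarity descending (ties broken by
    (protein_id, start), so results do not depend on FASTA record order).
    Default weights are 1 at non-anchor (outward) positions and 0 at the
    motif's anchor positions; with no motif, all positions weigh 1.
    """
    k = len(query)
    if weights is None:
        if motif is not None and motif.allowed:
            weights = outward_weights(k, motif.anchor_positions(k))
        else:
            weights = [1.0] * k
    mat = matrix if matrix is not None else blosum62()

    scored: list[PeptideHit] = []
    for hit in anchor_filter(enumerate_windows(proteome, k), motif):
        hit.similarity = positional_similarity(query, hit.sequence, weights, mat)
        scored.append(hit)
    scored.sort(key=lambda h: (-h.similarity, h.protein_id, h.start))
    return scored[: max(0, top_n)]
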