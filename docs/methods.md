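# Methods

## Problem setting

A peptide–MHC-I (pMHC-I) complex displays a short peptide (8–11 residues)
in a groove formed by the α1/α2 helices of the MHC heavy chain, with
β2-microglobulin underneath. A designed binder intended to substitute for
a T cell receptor must derive its specificity from the peptide — in
practice from the few **outward-facing** side chains not buried as anchors
in the groove — while minimising contact with the allele-invariant MHC
surface. `pmhckit` implements the analytics of that selection funnel:
engagement triage, on/off-target specificity margins, proteome
cross-reactivity scanning, and structural/functional validation summaries.
It deliberately contains no structure prediction, relaxation or energetics;
all geometry is heavy-atom and distance-based.

## Structure model and conventions

Structures load from PDB or mmCIF via gemmi. Conventions applied at load
time and throughout:

- **hydrogens are discarded** (design models and crystal structures place
  them differently; every criterion below is defined on heavy atoms);
- **alternate locations** resolve to the highest-occupancy conformer, ties
  broken by file order;
- waters and non-polymer heteroatom groups are dropped; known modified
  residues (MSE, SEP, PTR, …) map to their parent standard residue, and
  unknown nonstandard polymer residues are an error rather than a silent
  skip;
- author residue numbering is preserved, but peptide positions are always
  reported 1-based from the N-terminus;
- each chain is tagged with a role (MHC_HEAVY, B2M, PEPTIDE, BINDER,
  OTHER) supplied by the caller; a valid complex has exactly one peptide
  chain (8–11 residues) and at most one binder chain.

## Anchor / outward classification

For each peptide position two quantities are computed with the binder
chain removed:

- **side-chain MHC contact fraction** — the share of the position's
  side-chain heavy atoms within the contact cutoff (default 4.5 Å) of any
  MHC heavy-chain atom. Glycine, which has no side chain to present, is
  assigned fraction 1.0 by convention and therefore never counts as
  recognisable surface.
- **relative side-chain SASA** — side-chain SASA in the binder-free
  complex divided by the same side chain's SASA computed in isolation.
  Normalising by the in-conformation isolated value (rather than a
  tabulated per-residue maximum) keeps the measure meaningful for the
  reduced side-chain representation used in fixtures as well as for
  full-atom structures.

Classification: ANCHOR if fraction ≥ 0.5; OUTWARD if fraction ≤ 0.2 and
relative SASA ≥ 0.2; otherwise INTERMEDIATE. The thresholds are exposed as
parameters. How "outward-facing" was operationalised in the original
design campaigns is not public; this contact/SASA rule is a transparent
stand-in and is documented as such.

## Interface metrics

- **Contacts**: all heavy-atom pairs across two role groups within a
  cutoff (default 4.5 Å, the common interface convention), computed with a
  KD-tree and verified in the test suite against all-pairs double loops.
- **Hydrogen bonds**: with no hydrogens present, a donor is represented by
  its heavy atom and its bonded antecedent (e.g. backbone N with CA,
  Ser OG with CB); a bond requires donor–acceptor distance ≤ 3.5 Å and
  antecedent–donor–acceptor angle ≥ 120°. Donor/acceptor capability comes
  from a packaged per-residue atom table; proline's backbone N is not a
  donor; pairs closer than two residues apart on one chain are excluded as
  covalent neighbours. On an ideal poly-Ala α-helix (φ = −57°, ψ = −47°)
  these criteria yield exactly the i → i−4 backbone ladder.
- **SASA**: Shrake–Rupley with a deterministic golden-spiral lattice
  (default 960 points, probe 1.4 Å; radii C 1.7, N 1.55, O 1.52, S 1.8 Å).
  Deterministic for fixed point count; isolated-atom values agree with
  4π(r+probe)² to well under 1%.
- **Engagement metrics** per design: peptide contact count, MHC contact
  count, peptide contact fraction (reported as undefined — not 0/0 — when
  the binder makes no contacts at all), hydrogen bonds to the peptide, and
  **outward coverage**: the fraction of OUTWARD positions receiving at
  least m contacts (default m = 1; vacuously 1.0 if no position is
  OUTWARD). Default triage minima (≥ 10 peptide contacts, fraction ≥ 0.25,
  coverage ≥ 0.5, ≥ 1 H-bond) are heuristics for full-atom models and are
  fully configurable — the reduced-detail toy fixtures make fewer contacts
  by construction, so tests and examples set explicit thresholds.

## Specificity scoring

All scorers follow one orientation contract: **higher = more favorable**
(energy-like scorers negate before reporting). The margin of a design is
on-score minus an aggregate of its off-target scores; the default
aggregate is the worst case (maximum off-target), with the mean available
as an alternative. The target rank counts strictly-better off-targets, so
ties share the better rank. No minimum margin is baked in: strict
superiority (margin ≥ 0) is the default filter and anything else must be
requested explicitly.

The packaged **proxy scorer** threads a candidate sequence onto the fixed
peptide backbone and sums residue-contact energies over peptide/binder
residue pairs whose Cβ atoms (Cα for glycine) lie within 8 Å, the common
coarse-grained contact convention. The potential is hydrophobicity-
additive: e(a,b) = −s·(h′(a)+h′(b))/2 with h′ the Kyte–Doolittle
hydropathy shifted to [0, 9] and s = 0.65, giving contact energies in
roughly [−6, 0] kT with hydrophobic pairs most favorable — the additive
structure that dominates empirical residue-contact potentials of the
Miyazawa–Jernigan type. The proxy exists so the funnel's logic is fully
exercisable and deterministic at desk scale; it is *not* a reimplementation
of the neural sequence-recovery or structure-prediction scorers used in
real campaigns, whose outputs can instead be imported from TSV
(design_id, peptide, score) and ranked with identical downstream logic.

## Proteome cross-reactivity scan

Every length-k window of the proteome is enumerated with provenance
(records containing non-standard letters are skipped with a warning, never
silently scored). Windows pass an **HLA anchor-motif filter** — packaged
editable defaults: A\*01:01 {P3: DE, C-term: Y}, A\*02:01 {P2: LMIV,
C-term: VLI}, A\*03:01 {P2: LMIVAT, C-term: KR}, C\*07:02 {P2: YF, C-term:
FYL} — and are scored by Σᵢ wᵢ·M[qᵢ, cᵢ]. Default weights are 1 at
non-anchor (outward) positions and 0 at anchor positions, mirroring the
biology: anchors fix presentability, outward residues drive
cross-activation. Default matrix BLOSUM62 (Biopython's copy); the identity
matrix turns the score into a weighted identity count (k minus Hamming
distance at unit weights). Ranking ties break by (protein_id, start), so
results are independent of FASTA record order. Offsets are 1-based, windows
closed intervals. This scan is a transparent reference method; it is not
expected to reproduce any particular published candidate list, and it does
no binding-affinity prediction.

## Structural validation

Kabsch superposition (SVD with reflection exclusion) returns the optimal
rotation/translation and RMSD; near-collinear point sets are flagged as
degenerate rather than rejected. Model-vs-crystal comparison pairs
residues within role-matched chains by residue index, falling back to
global sequence alignment when the numbering disagrees; unpairable
residues are reported and excluded. Reported quantities:

- **binder CαRMSD** after superposing on the binder Cα set (the alignment
  frame is configurable to the MHC instead, since published values rarely
  state the frame);
- **interface all-atom RMSD** over all shared heavy atoms of the
  model-defined interface residues (binder residues with any heavy atom
  within the cutoff of peptide or MHC), after Kabsch on that atom set;
- the interface residue count at the main cutoff (default 4.5 Å) and at
  each of {3.5, 4.0, 4.5, 5.0} Å, because published interface-residue
  counts rarely state their cutoff either.

## Functional readouts

Activation tables (condition, replicate, MFI) summarise to mean, sample SD
(n−1; 0 for single replicates) and fold-over-control (mean MFI / mean
control MFI, control typically the DMSO condition). Sort enrichment from
pre/post NGS counts is log₂((f_post+p)/(f_pre+p)) on frequencies, with a
Jeffreys-style default pseudocount p = 0.5 / mean(pool totals); pass an
explicit pseudocount for strictly depth-independent values.

## Synthetic fixtures: what they emulate, and what they don't

`make_toy_pmhc` reproduces the *topology* of a pMHC-I design model — two
flanking helices, a groove floor, an extended peptide (3.5 Å/residue) with
anchors pointing into the groove and other side chains outward, and a
binder arcing above that touches exactly the designated outward positions
— with side chains reduced to Cβ plus one distal pseudo-atom (named so the
H-bond tables behave: Ser → OG, Asp → OD1, …). Ideal-helix parameters are
textbook (1.5 Å rise, 100°/residue); `ideal_alpha_helix` builds a real
poly-Ala helix from standard internal coordinates for H-bond tests.
Synthetic proteomes draw residues uniformly over the 20 letters and
overwrite planted peptides at stated loci. All generators are pure
functions of (spec, seed).

These fixtures make geometric outcomes *knowable by construction*, which
is what the oracle tests need. They are not physically realistic: no
packing, no rotamers, no real MHC fold, uniform (not proteome) residue
frequencies. Passing tests therefore demonstrate correctness of the
*computations* — contact counting, classification logic, margins, ranking,
RMSDs — not the biological adequacy of any threshold on real structures.

## Problem sizes and numerical choices

The test suite and acceptance script run on toy complexes of ~600–900
atoms, 20 seeded fixtures for the geometry oracle suite, 1000 randomized
score tables, a 100-protein × 500-aa proteome (49,200 windows), and
10-seed perturbation series at σ ∈ {0.1, 0.3, 1.0} Å — sizes chosen so a
full from-scratch rerun completes in seconds while every code path is
exercised. Classification SASA defaults to a 240-point lattice (closed-form
agreement tests use 960). Distance criteria use closed comparisons (≤);
ranking ties break lexicographically; all RNG is NumPy `default_rng`
seeded explicitly.

## Known limitations

- Geometry only: no electrostatics, van der Waals or solvation energies.
- The proxy potential ignores position-specific and orientation effects;
  its margins are illustrative, not predictive.
- Anchor motifs are presence/absence filters, not affinity models; a
  peptide passing the motif need not be presented in vivo.
- The anchor/outward rule is a stand-in for an unpublished operational
  definition; on real structures the INTERMEDIATE class can be large.
- Model-vs-crystal pairing assumes role-matched chains are the same
  molecule; domain swaps or large rearrangements are out of scope.
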