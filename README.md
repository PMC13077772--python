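# pmhckit

Analysis toolkit for **designed peptide–MHC-I (pMHC-I) binders** — the
computational funnel used to select, score and validate small proteins that
recognise a specific peptide presented in the MHC class I groove while
avoiding the conserved MHC surface.

## Who this is for

Protein designers and structural immunologists triaging candidate pMHC-I
binders (e.g. for CAR recognition domains or bispecific engagers). A safe
binder must read out the **outward-facing residues** of the presented
peptide — the positions a T cell receptor would see — and not the
ubiquitous MHC scaffold, otherwise it will cross-react with the thousands
of self-peptides displayed on the same HLA allele.

## What it computes

- **structure**: PDB/mmCIF parsing with chain roles (MHC heavy, β2m,
  peptide, binder), validation, and classification of peptide positions as
  groove-buried *anchors* vs *outward-facing*, from side-chain/MHC contact
  fraction and relative side-chain SASA.
- **interface**: heavy-atom contact maps, geometric hydrogen-bond
  detection (heavy-atom donor proxies), deterministic Shrake–Rupley SASA,
  and per-design engagement metrics — peptide contact count, peptide-vs-MHC
  contact fraction, outward-position coverage — with configurable triage
  thresholds.
- **specificity**: the on/off-target filter as a model-agnostic contract.
  For a design with on-target score *s*₀ and off-target scores {*s*ᵢ}, the
  specificity margin is *m* = *s*₀ − max ᵢ *s*ᵢ (or the mean aggregate);
  designs are kept when *m* ≥ a chosen minimum. A deterministic
  contact-potential proxy scorer (Cβ–Cβ contacts, hydrophobicity-additive
  potential) makes the whole funnel runnable without neural-network
  weights; externally computed predictor scores load from TSV.
- **scan**: proteome-wide cross-reactivity scanning — every length-k
  window, HLA anchor-motif filtering, and a position-weighted
  substitution-matrix similarity Σᵢ wᵢ·M[qᵢ, cᵢ] with weight on
  outward-facing positions (BLOSUM62 or identity).
- **validation**: Kabsch superposition, model-vs-crystal comparison
  (binder CαRMSD, all-atom RMSD over interface residues), CD69 activation
  (MFI) summaries, and NGS sort-enrichment log₂ ratios.
- **fixtures**: deterministic toy pMHC-I-like structures (two groove
  helices, extended peptide, binder arcing above with designed contact
  positions) and synthetic proteomes with planted peptides, so everything
  is testable offline.

## Worked example

Generate a toy design model presenting the MAGE-A3 peptide EVDPIGHLY on
HLA-A\*01:01, triage it, score it against the Titin off-target ESDPIVAQY,
and scan a synthetic proteome containing planted cross-reactivity
candidates:

```bash
pmhckit fixtures --out-dir fx --seed 0 --n-designs 1 --peptide EVDPIGHLY \
    --proteome-proteins 100 --proteome-length 500 \
    --plant EVDPIGHLY:10:200 --plant EVDPIGHVY:20:200 --plant VTDFISHLF:30:200

pmhckit triage --in-dir fx --out-dir tri --min-peptide-contacts 3 --min-hbonds 0
# design_id    n_peptide_contacts  n_mhc_contacts  peptide_contact_fraction ... pass
# design_000   3                   0               1                        ... True

pmhckit specificity --structure fx/design_000.pdb \
    --target EVDPIGHLY --decoys ESDPIVAQY --out-dir spec
# design_id   target     on_score  margin  target_rank
# design_000  EVDPIGHLY  83.72     7.735   1

pmhckit scan --proteome fx/proteome.fasta --peptide EVDPIGHLY \
    --allele "A*01:01" --top-n 5 --out-dir scan
# rank  protein_id  start  sequence   anchors_pass  similarity
# 1     prot0010    200    EVDPIGHLY  True          38
# 2     prot0020    200    EVDPIGHVY  True          35
# 3     prot0090    271    EIEICCHNY  True          6
```

Reading the output: the toy binder touches only the peptide
(`peptide_contact_fraction = 1`, `n_mhc_contacts = 0`) at its designated
outward positions; the on-target peptide outscores the Titin decoy by a
margin of 7.7 (rank 1); and the proteome scan recovers the planted query
at rank 1 with the single-substitution cross-activator EVDPIGHVY
immediately behind it, while VTDFISHLF is removed by the A\*01:01 anchor
filter (its C-terminal F violates the motif). Random proteome windows trail
far behind (similarity 6 vs 38).

The same logic is importable:

```python
from pmhckit import make_toy_pmhc, FixtureSpec, classify_peptide_positions, engagement_metrics

cpx = make_toy_pmhc(FixtureSpec(peptide="EVDPIGHLY"))
metrics = engagement_metrics(cpx, classify_peptide_positions(cpx))
```

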