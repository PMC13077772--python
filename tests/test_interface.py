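"""Contact maps, hydrogen bonds, SASA and engagement triage."""

import math

import numpy as np
import pytest

from pmhckit import (
    AtomRecord,
    ChainRole,
    EngagementMetrics,
    PMHCComplex,
    StructureError,
    TriageThresholds,
    contact_pairs,
    detect_hbonds,
    engagement_metrics,
    classify_peptide_positions,
    ideal_alpha_helix,
    make_random_spec,
    make_toy_pmhc,
    shrake_rupley_sasa,
    triage_designs,
)
from conftest import brute_contact_pairs, brute_hbonds, random_rigid_transform


def _single_atom_complex(d: float) -> PMHCComplex:
    """Two single-atom chains separated by d Angstrom."""
    atoms = [
        AtomRecord("X", 1, "GLY", "CA", "C", np.array([0.0, 0.0, 0.0])),
        AtomRecord("Y", 1, "GLY", "CA", "C", np.array([d, 0.0, 0.0])),
    ]
    return PMHCComplex(atoms=atoms, roles={"X": ChainRole.BINDER,
                                           "Y": ChainRole.PEPTIDE})


class TestContactPairs:
    def test_far_apart_atoms_no_contact(self):
        cpx = _single_atom_complex(10.0)
        table = contact_pairs(cpx, ChainRole.BINDER, ChainRole.PEPTIDE, 4.5)
        assert len(table) == 0

    def test_close_atoms_one_contact(self):
        cpx = _single_atom_complex(3.0)
        table = contact_pairs(cpx, ChainRole.BINDER, ChainRole.PEPTIDE, 4.5)
        assert len(table) == 1
        assert table.pairs[0][2] == pytest.approx(3.0)

    def test_matches_brute_force_on_toy_fixture(self, toy_complex):
        for pair in ((ChainRole.BINDER, ChainRole.PEPTIDE),
                     (ChainRole.BINDER, ChainRole.MHC_HEAVY),
                     (ChainRole.PEPTIDE, ChainRole.MHC_HEAVY)):
            got = contact_pairs(toy_complex, *pair, 4.5)
            expected = brute_contact_pairs(toy_complex, *pair, 4.5)
            assert sorted((a, b) for a, b, _ in got.pairs) == \
                   sorted((a, b) for a, b, _ in expected)

    def test_symmetric_in_group_order(self, toy_complex):
        ab = contact_pairs(toy_complex, ChainRole.BINDER, ChainRole.PEPTIDE, 4.5)
        ba = contact_pairs(toy_complex, ChainRole.PEPTIDE, ChainRole.BINDER, 4.5)
        assert sorted(frozenset((a, b)) for a, b, _ in ab.pairs) == \
               sorted(frozenset((a, b)) for a, b, _ in ba.pairs)

    def test_monotone_in_cutoff(self, toy_complex):
        counts = [len(contact_pairs(toy_complex, ChainRole.BINDER,
                                    ChainRole.PEPTIDE, c))
                  for c in (3.0, 4.0, 4.5, 6.0, 8.0)]
        assert counts == sorted(counts)

    def test_overlapping_groups_error(self, toy_complex):
        with pytest.raises(ValueError, match="overlap"):
            contact_pairs(toy_complex, ChainRole.BINDER, ChainRole.BINDER, 4.5)

    def test_empty_group_error(self, toy_complex):
        no_binder = toy_complex.without_role(ChainRole.BINDER)
        with pytest.raises(ValueError, match="non-empty"):
            contact_pairs(no_binder, ChainRole.BINDER, ChainRole.PEPTIDE, 4.5)


class TestHBonds:
    def test_linear_backbone_pair_detected(self):
        atoms = [
            AtomRecord("X", 1, "ALA", "CA", "C", np.array([0.0, 0.0, 1.5])),
            AtomRecord("X", 1, "ALA", "N", "N", np.array([0.0, 0.0, 0.0])),
            AtomRecord("Y", 5, "ALA", "O", "O", np.array([0.0, 0.0, -2.9])),
        ]
        cpx = PMHCComplex(atoms=atoms, roles={"X": ChainRole.BINDER,
                                              "Y": ChainRole.PEPTIDE})
        bonds = detect_hbonds(cpx, ChainRole.BINDER, ChainRole.PEPTIDE)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9)
        assert bonds[0].angle == pytest.approx(180.0)

    def test_distance_cutoff_excludes(self):
        atoms = [
            AtomRecord("X", 1, "ALA", "CA", "C", np.array([0.0, 0.0, 1.5])),
            AtomRecord("X", 1, "ALA", "N", "N", np.array([0.0, 0.0, 0.0])),
            AtomRecord("Y", 5, "ALA", "O", "O", np.array([0.0, 0.0, -5.0])),
        ]
        cpx = PMHCComplex(atoms=atoms, roles={"X": ChainRole.BINDER,
                                              "Y": ChainRole.PEPTIDE})
        assert detect_hbonds(cpx, ChainRole.BINDER, ChainRole.PEPTIDE) == []

    def test_ideal_helix_ladder_is_i_to_i_minus_4(self):
        n = 15
        helix = ideal_alpha_helix(n)
        bonds = detect_hbonds(helix, ChainRole.OTHER, ChainRole.OTHER)
        pairs = sorted((b.donor[1], b.acceptor[1]) for b in bonds)
        assert pairs == [(i, i - 4) for i in range(5, n + 1)]

    def test_matches_brute_force_oracle_on_fixtures(self):
        for seed in range(5):
            cpx = make_toy_pmhc(make_random_spec(seed))
            got = detect_hbonds(cpx, ChainRole.BINDER, ChainRole.PEPTIDE)
            expected = brute_hbonds(cpx, ChainRole.BINDER, ChainRole.PEPTIDE)
            assert sorted((b.donor, b.acceptor) for b in got) == sorted(expected)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        atom = AtomRecord("X", 1, "CYS", "SG", "S", np.zeros(3))
        sasa = shrake_rupley_sasa([atom], probe_radius=1.4, n_sphere_points=960)
        expected = 4.0 * math.pi * (1.8 + 1.4) ** 2
        assert sasa[0] == pytest.approx(expected, rel=0.02)

    def test_two_distant_atoms_each_fully_exposed(self):
        a = AtomRecord("X", 1, "GLY", "CA", "C", np.zeros(3))
        b = AtomRecord("X", 2, "GLY", "CA", "C", np.array([100.0, 0.0, 0.0]))
        sasa = shrake_rupley_sasa([a, b])
        free = 4.0 * math.pi * (1.7 + 1.4) ** 2
        assert sasa[0] == pytest.approx(free, rel=0.02)
        assert sasa[1] == pytest.approx(free, rel=0.02)

    def test_caged_atom_nearly_buried(self):
        # dense icosphere-like shell of atoms around a central atom
        from pmhckit.interface import _sphere_lattice

        shell = 3.4 * _sphere_lattice(80)
        atoms = [AtomRecord("X", 1, "GLY", "CA", "C", np.zeros(3))]
        atoms += [AtomRecord("X", i + 2, "GLY", "CA", "C", p)
                  for i, p in enumerate(shell)]
        sasa = shrake_rupley_sasa(atoms)
        free = 4.0 * math.pi * (1.7 + 1.4) ** 2
        assert sasa[0] < 0.01 * free

    def test_never_exceeds_isolated_closed_form(self, toy_complex):
        sasa = shrake_rupley_sasa(toy_complex.atoms, n_sphere_points=240)
        from pmhckit.interface import ATOMIC_RADII

        for atom, s in zip(toy_complex.atoms, sasa):
            free = 4.0 * math.pi * (ATOMIC_RADII[atom.element] + 1.4) ** 2
            assert s <= free + 1e-9

    def test_unknown_element_errors(self):
        atom = AtomRecord("X", 1, "GLY", "FE", "FE", np.zeros(3))
        with pytest.raises(KeyError):
            shrake_rupley_sasa([atom])

    def test_too_few_lattice_points_rejected(self):
        atom = AtomRecord("X", 1, "GLY", "CA", "C", np.zeros(3))
        with pytest.raises(ValueError):
            shrake_rupley_sasa([atom], n_sphere_points=10)


class TestEngagement:
    def test_binder_contacting_only_peptide_fraction_one(self, toy_complex):
        pcs = classify_peptide_positions(toy_complex)
        m = engagement_metrics(toy_complex, pcs)
        assert m.peptide_contact_fraction == 1.0
        assert m.n_mhc_contacts == 0
        assert sum(m.per_position_contacts.values()) == m.n_peptide_contacts

    def test_displaced_binder_gives_undefined_fraction(self, toy_complex):
        moved = toy_complex.copy()
        for a in moved.atoms:
            if a.chain_id == "D":
                a.coords = a.coords + np.array([0.0, 0.0, 50.0])
        pcs = classify_peptide_positions(moved)
        m = engagement_metrics(moved, pcs)
        assert m.n_peptide_contacts == 0
        assert m.peptide_contact_fraction is None

    def test_fields_match_brute_force_recomputation(self):
        for seed in range(5):
            spec = make_random_spec(seed)
            cpx = make_toy_pmhc(spec)
            pcs = classify_peptide_positions(cpx)
            m = engagement_metrics(cpx, pcs)
            pep = brute_contact_pairs(cpx, ChainRole.BINDER, ChainRole.PEPTIDE, 4.5)
            mhc = brute_contact_pairs(cpx, ChainRole.BINDER, ChainRole.MHC_HEAVY, 4.5)
            assert m.n_peptide_contacts == len(pep)
            assert m.n_mhc_contacts == len(mhc)
            posmap = cpx.peptide_position_map()
            per_pos = {p: 0 for p in posmap.values()}
            for _, bkey, _d in pep:
                per_pos[posmap[bkey[1]]] += 1
            assert m.per_position_contacts == per_pos
            hb = brute_hbonds(cpx, ChainRole.BINDER, ChainRole.PEPTIDE) + \
                brute_hbonds(cpx, ChainRole.PEPTIDE, ChainRole.BINDER)
            assert m.n_hbonds_to_peptide == len(hb)
            outward = [p.position for p in pcs if p.cls == "OUTWARD"]
            covered = sum(1 for p in outward if per_pos[p] >= 1)
            assert m.outward_coverage == pytest.approx(covered / len(outward))

    def test_rigid_transform_invariance(self, toy_complex):
        R, t = random_rigid_transform(11)
        moved = toy_complex.transformed(R, t)
        a = engagement_metrics(toy_complex, classify_peptide_positions(toy_complex))
        b = engagement_metrics(moved, classify_peptide_positions(moved))
        assert a.per_position_contacts == b.per_position_contacts
        assert a.n_hbonds_to_peptide == b.n_hbonds_to_peptide
        assert a.outward_coverage == b.outward_coverage

    def test_missing_binder_errors(self, toy_complex):
        noB = toy_complex.without_role(ChainRole.BINDER)
        with pytest.raises(StructureError, match="BINDER"):
            engagement_metrics(noB, classify_peptide_positions(noB))


def _metric(design_id="d", n_pep=12, n_mhc=4, hb=2, cov=0.8):
    frac = n_pep / (n_pep + n_mhc) if n_pep + n_mhc else None
    return EngagementMetrics(
        design_id=design_id,
        per_position_contacts={1: n_pep},
        n_peptide_contacts=n_pep,
        n_mhc_contacts=n_mhc,
        peptide_contact_fraction=frac,
        n_hbonds_to_peptide=hb,
        outward_coverage=cov,
    )


class TestTriage:
    def test_all_minima_met_passes(self):
        (_, passed, reasons), = triage_designs([_metric()])
        assert passed and reasons == []

    def test_single_failure_lists_one_reason(self):
        (_, passed, reasons), = triage_designs([_metric(cov=0.2)])
        assert not passed
        assert len(reasons) == 1
        assert "outward_coverage" in reasons[0]

    def test_pass_set_matches_direct_predicate(self):
        rng = np.random.default_rng(0)
        th = TriageThresholds()
        metrics = [
            _metric(f"d{i:03d}",
                    n_pep=int(rng.integers(0, 30)),
                    n_mhc=int(rng.integers(0, 30)),
                    hb=int(rng.integers(0, 5)),
                    cov=float(rng.random()))
            for i in range(100)
        ]
        verdicts = triage_designs(metrics, th)
        for m, (did, passed, _r) in zip(metrics, verdicts):
            expected = (
                m.n_peptide_contacts >= th.min_peptide_contacts
                and m.peptide_contact_fraction is not None
                and m.peptide_contact_fraction >= th.min_peptide_contact_fraction
                and m.outward_coverage >= th.min_outward_coverage
                and m.n_hbonds_to_peptide >= th.min_hbonds_to_peptide
            )
            assert did == m.design_id and passed == expected

    def test_raising_thresholds_shrinks_pass_set(self):
        rng = np.random.default_rng(1)
        metrics = [
            _metric(f"d{i}", n_pep=int(rng.integers(0, 30)),
                    hb=int(rng.integers(0, 5)), cov=float(rng.random()))
            for i in range(50)
        ]
        loose = {d for d, p, _ in triage_designs(metrics, TriageThresholds())
                 if p}
        strict = {d for d, p, _ in triage_designs(
            metrics, TriageThresholds(min_peptide_contacts=20,
                                      min_outward_coverage=0.9)) if p}
        assert strict <= loose
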