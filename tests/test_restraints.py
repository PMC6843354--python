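"""Distance restraints: generation, measurement, comparison, round-trip."""

import numpy as np
import pytest

from msbridge.chem_masses import DSG, DSS, TRANSPLATIN, OligoSpecies, PeptideSpecies
from msbridge.restraints import (
    DistanceRestraint,
    RestraintEnd,
    RestraintGroup,
    apply_numbering_offset,
    compare_distance_sets,
    export_restraints,
    measure,
    measure_group,
    parse_restraints_tsv,
    xl_to_restraints,
)
from msbridge.synthetic_data import fold_to_structure, gen_duplex_coords
from msbridge.xl_search import CandidateConjugate, Identification


def ident_for(cand):
    return Identification(cand.mass, 100.0, (cand,), (0.0,))


def inter_candidate(linker, seq_a="AKG", start_a=1, seq_b="GLK", start_b=10):
    from msbridge.chem_masses import conjugate_mass
    from msbridge.xl_search import peptide_reactive_sites

    pa = PeptideSpecies(seq_a, start_a)
    pb = PeptideSpecies(seq_b, start_b)
    sites = (peptide_reactive_sites(pa, linker, protein_start=-999),
             peptide_reactive_sites(pb, linker, protein_start=-999))
    return CandidateConjugate("inter", (pa, pb), linker.name, "light",
                              conjugate_mass((pa, pb), linker, "light"), sites)


def line_structure(distances, chain="A"):
    """Alanine chain whose residue i sits at x = distances[i]."""
    coords = np.zeros((len(distances), 3))
    coords[:, 0] = distances
    return fold_to_structure(coords, "A" * len(distances), 1, chain)


class TestGeneration:
    @pytest.mark.parametrize("linker,span", [(DSG, 20.5), (DSS, 24.2)])
    def test_span_and_tolerance_from_linker(self, linker, span):
        [group] = xl_to_restraints([ident_for(inter_candidate(linker))], {linker.name: linker})
        for m in group.members:
            assert m.span == span and m.tolerance == 3.0
            assert m.upper_bound == pytest.approx(span + 3.0)

    def test_mono_links_carry_no_restraint(self):
        pep = PeptideSpecies("AKG", 1)
        cand = CandidateConjugate("mono", (pep,), "DSG", "mono-light", 500.0, ((2,),))
        assert xl_to_restraints([ident_for(cand)], {"DSG": DSG}) == []

    def test_ambiguous_sites_expand_to_group(self):
        cand = inter_candidate(DSG, seq_a="AKSG")     # K and S on one side
        [group] = xl_to_restraints([ident_for(cand)], {"DSG": DSG})
        assert len(group.members) == 2
        assert {m.end_a.residue for m in group.members} == {2, 3}

    def test_peptide_dna_targets_guanine_n7(self):
        from msbridge.xl_search import oligo_reactive_sites

        pep = PeptideSpecies("MTK", 1)
        oligo = OligoSpecies("AGGT", strand="reverse")
        sites = ((1, 2), oligo_reactive_sites(oligo, TRANSPLATIN))
        cand = CandidateConjugate("peptide-DNA", (pep, oligo), TRANSPLATIN.name,
                                  "bifunctional", 2000.0, sites)
        [group] = xl_to_restraints([ident_for(cand)], {}, TRANSPLATIN)
        assert {m.end_b.chain for m in group.members} == {"C"}     # reverse strand
        assert {m.end_b.residue for m in group.members} == {2, 3}  # the two G bases
        assert all(m.span == 5.0 and m.tolerance == 2.0 for m in group.members)

    def test_numbering_offset(self):
        g = RestraintGroup((DistanceRestraint(
            RestraintEnd("A", 10), RestraintEnd("A", 20), 20.5, 3.0),))
        [shifted] = apply_numbering_offset([g], {"A": -73})
        assert (shifted.members[0].end_a.residue, shifted.members[0].end_b.residue) == (-63, -53)

    def test_invalid_restraint_rejected(self):
        with pytest.raises(ValueError):
            DistanceRestraint(RestraintEnd("A", 1), RestraintEnd("A", 2), 0.0, 3.0)
        with pytest.raises(ValueError):
            RestraintGroup(())


class TestMeasurement:
    def test_satisfied_at_ten_angstrom(self):
        st = line_structure([0.0, 10.0])
        r = DistanceRestraint(RestraintEnd("A", 1), RestraintEnd("A", 2), 20.5, 3.0, "DSG")
        rep = measure(st, r)
        assert rep.measured == pytest.approx(10.0)
        assert rep.satisfied and rep.violation == 0.0

    def test_dss_violated_at_thirty_angstrom(self):
        st = line_structure([0.0, 30.0])
        r = DistanceRestraint(RestraintEnd("A", 1), RestraintEnd("A", 2), 24.2, 3.0, "DSS")
        rep = measure(st, r)
        assert not rep.satisfied
        assert rep.violation == pytest.approx(30.0 - 27.2)

    def test_missing_residue_is_not_evaluable(self):
        st = line_structure([0.0, 10.0])
        r = DistanceRestraint(RestraintEnd("A", 1), RestraintEnd("A", 99), 20.5, 3.0)
        rep = measure(st, r)
        assert rep.measured is None and rep.satisfied is None

    def test_group_satisfied_if_any_member_is(self):
        st = line_structure([0.0, 10.0, 40.0])
        far = DistanceRestraint(RestraintEnd("A", 1), RestraintEnd("A", 3), 20.5, 3.0)
        near = DistanceRestraint(RestraintEnd("A", 1), RestraintEnd("A", 2), 20.5, 3.0)
        gs = measure_group(st, RestraintGroup((far, near)))
        assert gs.satisfied and gs.min_distance == pytest.approx(10.0)
        gs_bad = measure_group(st, RestraintGroup((far,)))
        assert not gs_bad.satisfied

    def test_matches_brute_force_distance_oracle(self, rng):
        coords = rng.uniform(-30, 30, size=(20, 3))
        st = fold_to_structure(coords, "A" * 20, 1)
        for _ in range(50):
            i, j = rng.choice(20, size=2, replace=False)
            r = DistanceRestraint(RestraintEnd("A", int(i) + 1),
                                  RestraintEnd("A", int(j) + 1), 20.5, 3.0)
            rep = measure(st, r)
            d = float(np.linalg.norm(coords[i] - coords[j]))
            assert rep.measured == pytest.approx(d, abs=1e-4)
            assert rep.satisfied == (d <= 23.5)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.uniform(-20, 20, size=(15, 3))
        # random rotation via QR; enforce a proper rotation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = coords @ q.T + np.array([100.0, -50.0, 25.0])
        st1 = fold_to_structure(coords, "A" * 15, 1)
        st2 = fold_to_structure(moved, "A" * 15, 1)
        pairs = [(RestraintEnd("A", a), RestraintEnd("A", b))
                 for a in range(1, 16) for b in range(a + 1, 16)]
        table, rmsd = compare_distance_sets(st1, st2, pairs)
        assert table["evaluable"].all()
        assert rmsd <= 1e-6
        assert np.abs(table["delta"]).max() <= 1e-6


class TestCompareDistanceSets:
    def test_rmsd_closed_form(self):
        # distances differ by 0, 3 and 4 A -> RMSD sqrt((9+16)/3) = 2.887
        st_a = line_structure([0.0, 10.0, 30.0, 60.0])
        st_b = line_structure([0.0, 10.0, 33.0, 64.0])
        pairs = [(RestraintEnd("A", 1), RestraintEnd("A", k)) for k in (2, 3, 4)]
        table, rmsd = compare_distance_sets(st_a, st_b, pairs)
        assert sorted(np.abs(table["delta"])) == pytest.approx([0.0, 3.0, 4.0])
        assert rmsd == pytest.approx(np.sqrt(25.0 / 3.0), abs=1e-3)
        assert rmsd == pytest.approx(2.887, abs=1e-3)

    def test_identical_structures_rmsd_zero(self):
        st = line_structure([0.0, 7.0, 19.0])
        pairs = [(RestraintEnd("A", 1), RestraintEnd("A", 3))]
        _, rmsd = compare_distance_sets(st, st, pairs)
        assert rmsd == 0.0

    def test_unresolvable_pair_flagged_not_counted(self):
        st = line_structure([0.0, 7.0])
        pairs = [(RestraintEnd("A", 1), RestraintEnd("A", 2)),
                 (RestraintEnd("A", 1), RestraintEnd("A", 9))]
        table, rmsd = compare_distance_sets(st, st, pairs)
        assert list(table["evaluable"]) == [True, False]
        assert rmsd == 0.0


class TestExportRoundTrip:
    def _groups(self):
        cand = inter_candidate(DSG, seq_a="AKSG")
        pep = PeptideSpecies("MTK", 1)
        oligo = OligoSpecies("AGGT", strand="reverse")
        pt = CandidateConjugate("peptide-DNA", (pep, oligo), TRANSPLATIN.name,
                                "bifunctional", 2000.0, ((1, 2), (2, 3)))
        return xl_to_restraints([ident_for(cand), ident_for(pt)], {"DSG": DSG}, TRANSPLATIN)

    def test_tsv_roundtrip_is_byte_identical(self):
        groups = self._groups()
        text = export_restraints(groups, "tsv")
        assert export_restraints(parse_restraints_tsv(text), "tsv") == text

    def test_parse_recovers_values(self):
        groups = self._groups()
        parsed = parse_restraints_tsv(export_restraints(groups, "tsv"))
        assert len(parsed) == len(groups)
        assert parsed[0].members[0].span == 20.5
        assert parsed[1].members[0].span == 5.0

    def test_cns_and_haddock_render(self):
        groups = self._groups()
        cns = export_restraints(groups, "cns")
        n_assign = sum(ln.startswith("assign") for ln in cns.splitlines())
        assert n_assign == sum(len(g.members) for g in groups)
        hdk = export_restraints(groups, "haddock")
        assert sum(ln.startswith("assign") for ln in hdk.splitlines()) == len(groups)
        assert any(ln.strip().startswith("or") for ln in hdk.splitlines())

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError, match="unsupported format"):
            export_restraints(self._groups(), "xplor")


class TestPlantedSatisfaction:
    def test_all_planted_restraints_hold_on_generating_fold(self, noiseless_scenario):
        truth = noiseless_scenario["truth"]
        st = fold_to_structure(truth.coords, truth.sequence, truth.protein_start)
        groups = xl_to_restraints(
            [ident_for(c) for c in truth.conjugates], {"DSG": DSG, "DSS": DSS})
        assert groups
        for g in groups:
            gs = measure_group(st, g)
            assert gs.satisfied is True

    def test_dna_restraints_evaluable_on_synthetic_duplex(self, noiseless_scenario):
        truth = noiseless_scenario["truth"]
        cfg = noiseless_scenario["config"]
        st = fold_to_structure(
            truth.coords, truth.sequence, truth.protein_start,
            duplex=noiseless_scenario["duplex"],
            forward=cfg.forward_strand, reverse=cfg.reverse_strand)
        r = DistanceRestraint(RestraintEnd("B", 3), RestraintEnd("C", 1), 5.0, 2.0)
        rep = measure(st, r)
        assert rep.measured is not None
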