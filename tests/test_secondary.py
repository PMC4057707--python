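"""Secondary-structure assignment: H-bond energies, turn patterns, π
preference, bulge detection, and concordance with a reference DSSP."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from seventm.secondary import (
    AtomClash,
    HBOND_ENERGY_CUTOFF,
    IncompleteBackbone,
    NoDonorHydrogen,
    assign_secondary_structure,
    bulge_census,
    find_alpha_bulges,
    hbond_energy,
    place_amide_hydrogen,
)
from seventm.structures import Atom, Residue, SegmentTable, Structure
from seventm.synthetic import BundleSpec, HelixSpec, build_bundle, build_ideal_helix, bundle_segments

from conftest import add_noise, make_structure


def _res(**atoms):
    return Residue(1, atoms={k: Atom(k, np.asarray(v, float)) for k, v in atoms.items()})


class TestAmideHydrogen:
    def test_placement_along_o_to_c(self):
        prev = _res(C=(0, 0, 0), O=(0, 0, -1.23))
        cur = _res(N=(1.33, 0, 0))
        h = place_amide_hydrogen(prev, cur)
        assert np.allclose(h, [1.33, 0, 1.0])

    def test_proline_has_no_donor(self):
        prev = _res(C=(0, 0, 0), O=(0, 0, -1.23))
        pro = Residue(2, amino_acid="P", atoms={"N": Atom("N", np.zeros(3) + 1)})
        with pytest.raises(NoDonorHydrogen):
            place_amide_hydrogen(prev, pro)

    def test_missing_atoms(self):
        with pytest.raises(IncompleteBackbone):
            place_amide_hydrogen(_res(C=(0, 0, 0)), _res(N=(1, 0, 0)))

    def test_unit_distance_property(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            c, n = rng.normal(size=3), rng.normal(size=3)
            o = c + rng.normal(size=3)
            h = place_amide_hydrogen(_res(C=c, O=o), _res(N=n))
            assert np.linalg.norm(h - n) == pytest.approx(1.0, abs=1e-12)


class TestHBondEnergy:
    def _ideal_pair(self):
        """N/H and C/O atoms of an i->i+4 pair from the ideal helix."""
        helix = build_ideal_helix(HelixSpec(n_residues=10))
        donor, acceptor = helix.residues[6], helix.residues[2]
        h = place_amide_hydrogen(helix.residues[5], donor)
        return donor.coords("N"), h, acceptor.coords("C"), acceptor.coords("O")

    def test_distant_acceptor_energy_vanishes(self):
        n, h, c, o = self._ideal_pair()
        shift = np.array([50.0, 0, 0])
        assert abs(hbond_energy(n, h, c + shift, o + shift)) < 0.05

    def test_helical_pair_bonds_below_cutoff(self):
        n, h, c, o = self._ideal_pair()
        # independent direct evaluation of the electrostatic formula
        expected = 27.888 * (
            1 / np.linalg.norm(o - n)
            + 1 / np.linalg.norm(c - h)
            - 1 / np.linalg.norm(o - h)
            - 1 / np.linalg.norm(c - n)
        )
        assert hbond_energy(n, h, c, o) == pytest.approx(expected, abs=1e-9)
        assert expected < HBOND_ENERGY_CUTOFF

    def test_energy_is_asymmetric_under_role_swap(self):
        helix = build_ideal_helix(HelixSpec(n_residues=10))
        a, b = helix.residues[2], helix.residues[6]
        h_b = place_amide_hydrogen(helix.residues[5], b)
        h_a = place_amide_hydrogen(helix.residues[1], a)
        forward = hbond_energy(b.coords("N"), h_b, a.coords("C"), a.coords("O"))
        backward = hbond_energy(a.coords("N"), h_a, b.coords("C"), b.coords("O"))
        assert forward != pytest.approx(backward, abs=1e-3)

    def test_clash_guard(self):
        with pytest.raises(AtomClash):
            hbond_energy(
                np.zeros(3), np.array([1.0, 0, 0]), np.array([0.1, 0, 0]), np.array([2.0, 0, 0])
            )


class TestAssignment:
    def test_ideal_alpha_helix_is_contiguous_h(self, alpha_helix):
        codes = assign_secondary_structure(alpha_helix).code_string()
        assert "HHHHHHHHHHHHHHHH" in codes
        assert "I" not in codes and "G" not in codes

    def test_planted_pi_window_yields_single_i_stretch(self, bulge_helix):
        codes = assign_secondary_structure(bulge_helix).code_string()
        assert codes.count("I") >= 5
        runs = [r for r in codes.split("H") if "I" in r]
        assert len([r for r in runs if r]) == 1

    def test_extended_chain_has_no_helix_codes(self):
        chain = build_ideal_helix(HelixSpec(n_residues=12, phi=180.0, psi=180.0))
        codes = assign_secondary_structure(chain).code_string()
        assert not set(codes) & {"H", "G", "I"}

    def test_too_short_structure_rejected(self):
        st = build_ideal_helix(HelixSpec(n_residues=4))
        st.residues = st.residues[:2]
        with pytest.raises(ValueError):
            assign_secondary_structure(st)

    def test_every_stored_bond_is_below_cutoff_and_donors_capped(self, bulge_helix):
        assignment = assign_secondary_structure(bulge_helix)
        donors = {}
        for hb in assignment.hbonds:
            assert hb.energy < HBOND_ENERGY_CUTOFF
            assert abs(hb.donor_index - hb.acceptor_index) >= 2
            donors[hb.donor_index] = donors.get(hb.donor_index, 0) + 1
        assert max(donors.values()) <= 2

    @pytest.mark.parametrize("code,n", [("H", 4), ("G", 3), ("I", 5)])
    def test_helix_codes_are_pattern_sound(self, code, n, bulge_helix, alpha_helix):
        """Brute-force check: every coded residue lies in a span i..i+n-1
        with n-turn starts at both i-1 and i."""
        for st in (bulge_helix, alpha_helix, build_ideal_helix(HelixSpec(n_residues=24, three_ten_positions=(11,)))):
            a = assign_secondary_structure(st)
            starts = a.turn_starts[n]
            supported = set()
            for i in range(1, len(a.codes) - n):
                if starts[i] and starts[i - 1]:
                    supported.update(range(i, i + n))
            for idx, c in enumerate(a.codes):
                if c == code:
                    assert idx in supported

    def test_assignment_invariant_under_rigid_motion(self, bulge_helix):
        codes = assign_secondary_structure(bulge_helix).code_string()
        rot = Rotation.from_rotvec([0.3, -1.2, 0.7]).as_matrix()
        moved = bulge_helix.copy()
        for res in moved.residues:
            for atom in res.atoms.values():
                atom.coords = rot @ atom.coords + np.array([13.0, -4.0, 101.0])
        assert assign_secondary_structure(moved).code_string() == codes

    def test_chain_break_splits_patterns(self):
        st = build_ideal_helix(HelixSpec(n_residues=16))
        for res in st.residues[8:]:
            for atom in res.atoms.values():
                atom.coords = atom.coords + np.array([40.0, 0, 0])
        codes = assign_secondary_structure(st).code_string()
        # each 8-residue fragment can support at most a short helix; no code
        # may span the break
        assert codes[7] == " " or codes[8] == " "

    def test_pi_priority_flag_only_changes_five_turn_neighbourhoods(self, bulge_helix):
        with_pi = assign_secondary_structure(bulge_helix, pi_priority=True)
        without = assign_secondary_structure(bulge_helix, pi_priority=False)
        changed = {
            i for i, (a, b) in enumerate(zip(with_pi.codes, without.codes)) if a != b
        }
        near_five_turns = set()
        for i in np.flatnonzero(with_pi.turn_starts[5]):
            near_five_turns.update(range(i - 1, i + 6))
        assert changed <= near_five_turns


class TestBulges:
    def test_all_h_assignment_gives_empty_list(self, alpha_helix):
        a = assign_secondary_structure(alpha_helix)
        table = SegmentTable({"TM5": (501, 534)})
        assert find_alpha_bulges(a, alpha_helix, table) == []

    def test_single_bulge_located_in_tm5(self, bulge_helix):
        a = assign_secondary_structure(bulge_helix)
        table = SegmentTable({"TM5": (501, 534)})
        records = find_alpha_bulges(a, bulge_helix, table)
        assert len(records) == 1
        rec = records[0]
        assert rec.helix == "TM5"
        assert rec.start_generic <= 512 <= rec.end_generic
        assert rec.length == rec.end_generic - rec.start_generic + 1

    def test_two_bulges_in_one_helix_yield_two_records(self):
        st = build_ideal_helix(HelixSpec(n_residues=29, bulge_positions=(8, 20)), start_generic=501)
        a = assign_secondary_structure(st)
        records = find_alpha_bulges(a, st, SegmentTable({"TM5": (501, 534)}))
        assert len(records) == 2
        assert all(r.helix == "TM5" for r in records)
        assert records[0].end_generic < records[1].start_generic

    def test_census_recovers_planted_pattern(self, bundle_pair):
        plain, bulged, segments = bundle_pair
        table = bulge_census([plain, bulged], segments)
        assert table.loc["plain"].tolist() == [0, 0, 0, 0, 0, 0, 0]
        assert table.loc["bulged"].tolist() == [0, 1, 0, 0, 1, 0, 0]

    def test_census_without_five_turns_is_zero(self):
        spec = BundleSpec(tuple(HelixSpec(n_residues=15) for _ in range(7)))
        st = build_bundle(spec, "clean")
        assignment = assign_secondary_structure(st)
        assert not assignment.turn_starts[5].any()
        table = bulge_census([st], bundle_segments(spec))
        assert table.loc["clean"].sum() == 0

    def test_census_skips_failing_structures(self, bundle_pair):
        plain, _, segments = bundle_pair
        broken = Structure("broken", [])
        table = bulge_census([plain, broken], segments)
        assert list(table.index) == ["plain"]


class TestReferenceConcordance:
    def test_codes_match_reference_dssp_on_generated_fixtures(self, tmp_path):
        """Per-residue agreement with an independent DSSP implementation
        on a battery of clean and noisy fixtures."""
        mdtraj = pytest.importorskip("mdtraj")
        from seventm.structures import write_pdb

        fixtures = [
            build_ideal_helix(HelixSpec(n_residues=20)),
            build_ideal_helix(HelixSpec(n_residues=24, bulge_positions=(11,))),
            build_ideal_helix(HelixSpec(n_residues=24, three_ten_positions=(11,))),
            build_ideal_helix(HelixSpec(n_residues=29, bulge_positions=(8, 20))),
            build_ideal_helix(HelixSpec(n_residues=12, phi=180.0, psi=180.0)),
        ]
        rng = np.random.default_rng(7)
        for seed in range(5):
            fixtures.append(
                add_noise(build_ideal_helix(HelixSpec(n_residues=24, bulge_positions=(11,))), 0.1, rng)
            )
        agree = total = 0
        for k, st in enumerate(fixtures):
            mine = assign_secondary_structure(st).code_string()
            path = tmp_path / f"fix{k}.pdb"
            write_pdb(st, path)
            ref = mdtraj.compute_dssp(mdtraj.load(str(path)), simplified=False)[0]
            ref = "".join(c if c != "C" else " " for c in ref)
            agree += sum(m == r for m, r in zip(mine, ref))
            total += len(mine)
        assert agree / total > 0.999
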