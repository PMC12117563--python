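"""Descriptor suite: SASA, depth, protrusion, HSE, torsions, secondary
structure, hydrophobicity, CSV emission."""

import math

import numpy as np
import pandas as pd
import pytest

from fvkit.descriptors import (CSV_COLUMNS, DescriptorConfig, KYTE_DOOLITTLE,
                               MAX_ASA_TIEN, VDW_RADII, compute_descriptors,
                               dihedrals, half_sphere_exposure, hydrophobicity,
                               protrusion_index, relative_sasa, residue_depth,
                               sasa, secondary_structure, write_descriptor_table)
from fvkit.fixtures import (FixtureSpec, line_chain, make_ideal_secondary,
                            make_strand_pair)
from fvkit.model import Atom, Chain, Residue, StructureModel
from fvkit.structure_io import write_structure


def _single_atom_model(element="C"):
    res = Residue("ALA", 1, "", [Atom("CA", element, (0.0, 0.0, 0.0))])
    return StructureModel("1ABC", [Chain("A", [res])])


def _shell_model(radius=3.2, n_shell=80):
    """One central atom tightly enclosed by a shell of dummy atoms."""
    atoms = [Atom("CA", "C", (0.0, 0.0, 0.0))]
    residues = [Residue("ALA", 1, "", atoms)]
    golden = math.pi * (3 - math.sqrt(5))
    for k in range(n_shell):
        z = 1 - 2 * (k + 0.5) / n_shell
        r = math.sqrt(1 - z * z)
        pos = radius * np.array([r * math.cos(golden * k),
                                 r * math.sin(golden * k), z])
        residues.append(Residue("GLY", k + 2, "", [Atom("CA", "C", pos)]))
    return StructureModel("1ABC", [Chain("A", residues)])


class TestSasa:
    def test_single_sphere_closed_form(self):
        """Isolated carbon sphere: area is exactly 4 pi (r_vdw + probe)^2."""
        r = sasa(_single_atom_model(), probe_radius=1.4, n_sphere_points=960)
        exact = 4 * math.pi * (1.70 + 1.4) ** 2
        assert r.atom_areas[0] == pytest.approx(exact, rel=5e-3)

    def test_two_far_atoms_additive(self):
        residues = [Residue("GLY", 1, "", [Atom("CA", "C", (0, 0, 0))]),
                    Residue("GLY", 2, "", [Atom("CA", "C", (100, 0, 0))])]
        model = StructureModel("1ABC", [Chain("A", residues)])
        r = sasa(model)
        single = 4 * math.pi * (1.70 + 1.4) ** 2
        assert r.atom_areas.sum() == pytest.approx(2 * single, rel=5e-3)

    def test_enclosed_atom_near_zero(self):
        r = sasa(_shell_model(), n_sphere_points=960)
        assert r.atom_areas[0] == pytest.approx(0.0, abs=1.0)

    def test_matches_naive_dot_counting_oracle(self, helix12):
        """Independent brute-force oracle: for every atom, count golden-
        spiral dots outside all other expanded spheres, no neighbor
        culling tricks."""
        model = StructureModel("1ABC", [helix12])
        n_pts = 240
        r = sasa(model, 1.4, n_pts)
        coords, radii = [], []
        for c in model.chains:
            for res in c:
                for a in res.atoms:
                    coords.append(a.coord)
                    radii.append(VDW_RADII.get(a.element, 1.70))
        coords = np.array(coords)
        radii = np.array(radii) + 1.4
        i_pts = np.arange(n_pts) + 0.5
        phi = math.pi * (3 - math.sqrt(5)) * i_pts
        z = 1 - 2 * i_pts / n_pts
        rr = np.sqrt(np.clip(1 - z * z, 0, 1))
        unit = np.column_stack([rr * np.cos(phi), rr * np.sin(phi), z])
        for i in range(len(coords)):
            pts = coords[i] + radii[i] * unit
            free = np.ones(n_pts, bool)
            for j in range(len(coords)):
                if j == i:
                    continue
                free &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
            oracle = free.mean() * 4 * math.pi * radii[i] ** 2
            assert r.atom_areas[i] == pytest.approx(oracle, abs=1e-9)

    def test_agrees_with_biopython(self, standardized_ref, tmp_path):
        """Cross-check per-residue areas against the independent
        Shrake-Rupley implementation in Bio.PDB."""
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley
        antigen = standardized_ref.subset(["D"])
        path = tmp_path / "ag.pdb"
        write_structure(antigen, path)
        bio = PDBParser(QUIET=True).get_structure("x", str(path))
        ShrakeRupley(probe_radius=1.4, n_points=960).compute(bio[0], level="R")
        ours = sasa(antigen, 1.4, 960)
        for res in bio[0]["D"]:
            key = ("D", (res.id[1], res.id[2].strip()))
            assert ours.residue_areas[key] == pytest.approx(res.sasa, rel=0.05,
                                                            abs=2.0)

    def test_residue_sums_equal_atom_sums(self, standardized_ref):
        r = sasa(standardized_ref.subset(["D"]), n_sphere_points=240)
        assert sum(r.residue_areas.values()) == pytest.approx(
            r.atom_areas.sum(), abs=1e-6)


class TestRelativeSasa:
    def test_zero_and_max(self):
        assert relative_sasa(0.0, "ALA") == 0.0
        assert relative_sasa(MAX_ASA_TIEN["TRP"], "TRP") == pytest.approx(1.0)

    def test_unknown_residue_none(self):
        assert relative_sasa(50.0, "XYZ") is None

    def test_complexed_not_more_exposed_than_isolated(self, standardized_ref):
        """Relative SASA in the complex never exceeds the isolated value."""
        iso = sasa(standardized_ref.subset(["D"]), n_sphere_points=240)
        com = sasa(standardized_ref, n_sphere_points=240)
        for key, area in iso.residue_areas.items():
            if key[0] != "D":
                continue
            assert com.residue_areas[key] <= area + 1e-6


class TestDepth:
    def test_lone_residue_shallow(self):
        model = _single_atom_model()
        depth = residue_depth(model)
        assert list(depth.values()) == [0.0]  # single-atom convention

    def test_exposed_residue_within_vdw_scale(self, helix12):
        model = StructureModel("1ABC", [helix12])
        depth = residue_depth(model, n_sphere_points=240)
        assert all(0 < d <= 2.0 for d in depth.values())

    def test_core_deeper_than_surface(self):
        model = _shell_model()
        depth = residue_depth(model, n_sphere_points=240)
        core = depth[("A", (1, ""))]
        surface = [v for k, v in depth.items() if k != ("A", (1, ""))]
        assert core > max(surface)

    def test_remote_atoms_do_not_change_depth(self, helix12):
        model = StructureModel("1ABC", [helix12])
        depth1 = residue_depth(model, n_sphere_points=240)
        far = Chain("Z", [Residue("GLY", 1, "",
                                  [Atom("CA", "C", (500.0, 0, 0))])])
        model2 = StructureModel("1ABC", [helix12.copy(), far])
        depth2 = residue_depth(model2, n_sphere_points=240)
        for key, v in depth1.items():
            assert depth2[key] == pytest.approx(v, abs=1e-9)


class TestProtrusion:
    def test_isolated_atom_reported_at_cap(self):
        cx = protrusion_index(_single_atom_model(), 10.0, 20.1, cap=15.0)
        assert list(cx.values()) == [15.0]

    def test_isolated_atom_uncapped_value(self):
        cx = protrusion_index(_single_atom_model(), 10.0, 20.1, cap=1e9)
        expected = (4.0 / 3.0 * math.pi * 1000.0 - 20.1) / 20.1
        assert list(cx.values())[0] == pytest.approx(expected, rel=1e-6)

    def test_center_of_filled_sphere_near_zero(self):
        rng = np.random.default_rng(0)
        residues = [Residue("ALA", 1, "", [Atom("CA", "C", (0, 0, 0))])]
        pts = rng.normal(size=(420, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= rng.uniform(0, 1, size=(420, 1)) ** (1 / 3) * 10.0
        for i, p in enumerate(pts):
            residues.append(Residue("GLY", i + 2, "", [Atom("CA", "C", p)]))
        model = StructureModel("1ABC", [Chain("A", residues)])
        cx = protrusion_index(model, 10.0, 20.1)
        assert cx[("A", (1, ""))] < 1.0

    def test_rod_tip_more_protruding_than_middle(self):
        residues = [Residue("GLY", i + 1, "",
                            [Atom("CA", "C", (i * 2.0, 0, 0))])
                    for i in range(20)]
        model = StructureModel("1ABC", [Chain("A", residues)])
        cx = protrusion_index(model, 10.0, 20.1, cap=1e9)
        assert cx[("A", (1, ""))] > cx[("A", (10, ""))]


class TestHse:
    def test_partition_identity(self, helix12):
        """up + down equals the total Calpha neighbor count."""
        hse = half_sphere_exposure(helix12, 13.0)
        cas = {r.rid: r.ca.coord for r in helix12}
        for res in helix12:
            total = sum(1 for rid, c in cas.items()
                        if rid != res.rid
                        and np.linalg.norm(c - cas[res.rid]) <= 13.0)
            up, down = hse[res.rid]
            assert up + down == total

    def test_two_far_residues_zero(self):
        residues = [Residue("GLY", 1, "", [Atom("CA", "C", (0, 0, 0))]),
                    Residue("GLY", 2, "", [Atom("CA", "C", (50, 0, 0))])]
        chain = Chain("A", residues)
        hse = half_sphere_exposure(chain, 13.0)
        assert hse[(1, "")] == (0, 0) and hse[(2, "")] == (0, 0)

    def test_matches_halfspace_oracle(self, helix12):
        """Central residue counts agree with a direct half-space
        classification using the explicit CB direction."""
        hse = half_sphere_exposure(helix12, 13.0)
        res = helix12.residues[6]
        ca = res.ca.coord
        cb = res.atom("CB").coord
        d = cb - ca
        up = down = 0
        for other in helix12:
            if other.rid == res.rid:
                continue
            v = other.ca.coord - ca
            if np.linalg.norm(v) > 13.0:
                continue
            if np.dot(d, v) > 0:
                up += 1
            else:
                down += 1
        assert hse[res.rid] == (up, down)


class TestDihedrals:
    def test_ideal_helix_angles(self, helix12):
        tors = dihedrals(helix12)
        for res in helix12.residues[1:-1]:
            phi, psi = tors[res.rid]
            assert phi == pytest.approx(-57.0, abs=2.0)
            assert psi == pytest.approx(-47.0, abs=2.0)

    def test_terminal_angles_absent(self, helix12):
        tors = dihedrals(helix12)
        first = helix12.residues[0].rid
        last = helix12.residues[-1].rid
        assert tors[first][0] is None
        assert tors[last][1] is None

    def test_mirror_negates_angles(self, helix12):
        mirrored = helix12.copy()
        for res in mirrored:
            for atom in res.atoms:
                atom.coord = atom.coord * np.array([1.0, 1.0, -1.0])
        t0 = dihedrals(helix12)
        t1 = dihedrals(mirrored)
        for rid in t0:
            for a, b in zip(t0[rid], t1[rid]):
                if a is not None:
                    assert b == pytest.approx(-a, abs=1e-6)

    def test_chain_break_suppresses_angles(self):
        pair = make_strand_pair(8)
        tors = dihedrals(pair)
        # residue 8 (end of strand one) and 101 (start of strand two)
        assert tors[(8, "")][1] is None
        assert tors[(101, "")][0] is None


class TestSecondaryStructure:
    def test_helix_interior_is_h(self, helix12):
        ss = secondary_structure(helix12)
        interior = [ss[r.rid] for r in helix12.residues[2:-2]]
        assert interior == ["H"] * len(interior)

    def test_lone_extended_strand_is_coil(self):
        s = make_ideal_secondary("strand", 8)
        ss = secondary_structure(s)
        assert set(ss.values()) == {"C"}

    def test_paired_strands_assigned_e(self):
        pair = make_strand_pair(8)
        ss = secondary_structure(pair)
        values = [ss[r.rid] for r in pair]
        assert values.count("E") >= 8
        assert "H" not in values

    def test_missing_oxygen_gives_coil(self, helix12):
        stripped = helix12.copy()
        for res in stripped:
            res.atoms = [a for a in res.atoms if a.name != "O"]
        ss = secondary_structure(stripped)
        assert set(ss.values()) == {"C"}


class TestHydrophobicity:
    @pytest.mark.parametrize("res,val", [("ILE", 4.5), ("ARG", -4.5),
                                         ("GLY", -0.4)])
    def test_kyte_doolittle_values(self, res, val):
        assert hydrophobicity(res) == val

    def test_scale_override(self):
        assert hydrophobicity("ILE", {"ILE": 0.0}) == 0.0

    def test_unknown_residue_none(self):
        assert hydrophobicity("XYZ") is None


@pytest.fixture(scope="module")
def rows(standardized_ref):
    cfg = DescriptorConfig(n_sphere_points=240)
    return compute_descriptors(standardized_ref, cfg)


class TestDescriptorTable:

    def test_one_row_per_residue(self, rows, standardized_ref):
        assert len(rows) == standardized_ref.n_residues()

    def test_csv_round_trip(self, rows, tmp_path):
        path = tmp_path / "d.csv"
        write_descriptor_table(rows, path)
        df = pd.read_csv(path)
        assert list(df.columns) == CSV_COLUMNS
        assert len(df) == len(rows)
        assert df["rel_sasa"].iloc[0] == pytest.approx(rows[0].rel_sasa,
                                                       abs=1e-4)

    def test_header_stable_across_structures(self, rows, helix12, tmp_path):
        write_descriptor_table(rows, tmp_path / "a.csv")
        other = compute_descriptors(StructureModel("1ABC", [helix12]),
                                    DescriptorConfig(n_sphere_points=240))
        write_descriptor_table(other, tmp_path / "b.csv")
        head_a = (tmp_path / "a.csv").read_text().splitlines()[0]
        head_b = (tmp_path / "b.csv").read_text().splitlines()[0]
        assert head_a == head_b

    def test_deterministic(self, standardized_ref):
        cfg = DescriptorConfig(n_sphere_points=240)
        a = compute_descriptors(standardized_ref, cfg)
        b = compute_descriptors(standardized_ref, cfg)
        assert [(r.rel_sasa, r.depth, r.protrusion) for r in a] == \
               [(r.rel_sasa, r.depth, r.protrusion) for r in b]

    def test_invariants_hold(self, rows):
        for r in rows:
            assert r.rel_sasa is None or r.rel_sasa >= 0
            assert r.depth is None or r.depth >= 0
            assert r.protrusion is None or r.protrusion >= 0
            assert r.hse_up is None or r.hse_up >= 0
            assert r.sec_struct in ("H", "E", "C")
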