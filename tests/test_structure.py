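"""Structure parsing, ASA, contact areas and interface labelling."""

import math

import numpy as np
import pytest

from triface.scales import PKA_TABLE
from triface.structure import (
    build_pair_table,
    build_residue_descriptors,
    compute_rasa,
    contact_areas,
    electric_features,
    geometric_features,
    parse_trimer,
    read_pka_tsv,
    shrake_rupley,
)
from triface.synthetic import generate_toy_trimer

PLANTED = {
    ("A", "B"): [(1, 2), (3, 6), (7, 8)],
    ("A", "C"): [(2, 3)],
    ("B", "C"): [(4, 5), (8, 8)],
}


@pytest.fixture(scope="module")
def toy_trimer():
    pdb, truth = generate_toy_trimer(chain_lengths=(8, 8, 8), planted_pairs=PLANTED)
    return parse_trimer(pdb, enforce_lengths=False), truth


class TestParse:
    def test_roundtrip_counts(self, toy_trimer):
        trimer, _ = toy_trimer
        assert {c: len(r) for c, r in trimer.chains.items()} == {
            "A": 8, "B": 8, "C": 8,
        }
        assert trimer.sequence("A") == "A" * 8

    def test_two_chains_rejected(self):
        pdb, _ = generate_toy_trimer()
        # drop chain C records
        two = "\n".join(ln for ln in pdb.splitlines() if len(ln) < 22 or ln[21] != "C")
        with pytest.raises(ValueError, match="3 nonempty"):
            parse_trimer(two, enforce_lengths=False)

    def test_chain_length_rule_enforced(self):
        pdb, _ = generate_toy_trimer()  # 8-residue chains
        with pytest.raises(ValueError, match="20-500"):
            parse_trimer(pdb)

    def test_insertion_codes_preserved(self):
        pdb, _ = generate_toy_trimer(chain_lengths=(4, 4, 4))
        # give chain A residue 2 an insertion-coded sibling 2A
        lines = pdb.splitlines()
        extra = None
        for ln in lines:
            if ln.startswith("ATOM") and ln[21] == "A" and int(ln[22:26]) == 2:
                extra = ln[:26] + "A" + ln[27:]
                extra = extra[:38] + f"{99.0:8.3f}" + extra[46:]
        lines.insert(lines.index(ln) + 1, extra)
        trimer = parse_trimer("\n".join(lines), enforce_lengths=False)
        keys = [(r.number, r.icode) for r in trimer.chains["A"]]
        assert len(trimer.chains["A"]) == 5
        assert (2, "A") in keys and (2, "") in keys


class TestShrakeRupley:
    def test_isolated_sphere_closed_form(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([1.7]), probe=1.4)
        assert area[0] == pytest.approx(4 * math.pi * 3.1**2, rel=1e-6)

    def test_distant_atoms_unoccluded(self):
        coords = np.array([[0.0, 0, 0], [20.0, 0, 0]])
        radii = np.array([1.5, 2.0])
        areas = shrake_rupley(coords, radii, probe=1.4)
        for a, r in zip(areas, radii):
            assert a == pytest.approx(4 * math.pi * (r + 1.4) ** 2, rel=1e-6)

    def test_two_overlapping_unit_spheres_closed_form(self):
        # centres 1.0 apart, probe 0: each loses a cap of height 1 - d/2
        areas = shrake_rupley(
            np.array([[0.0, 0, 0], [1.0, 0, 0]]), np.ones(2), probe=0.0,
            n_points=9600,
        )
        exposed = 4 * math.pi - 2 * math.pi * 0.5
        assert np.allclose(areas, exposed, rtol=0.01)

    def test_matches_brute_force_point_oracle(self):
        # independent oracle: random directions at 10x density
        coords = np.array([[0.0, 0, 0], [1.0, 0.4, -0.2]])
        radii = np.array([1.0, 1.3])
        probe = 0.5
        rng = np.random.default_rng(42)
        expected = []
        for i in range(2):
            ri = radii[i] + probe
            pts = rng.normal(size=(96000, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            pts = coords[i] + ri * pts
            j = 1 - i
            rj = radii[j] + probe
            frac = (np.linalg.norm(pts - coords[j], axis=1) > rj).mean()
            expected.append(4 * math.pi * ri**2 * frac)
        areas = shrake_rupley(coords, radii, probe=probe, n_points=9600)
        assert np.allclose(areas, expected, rtol=0.01)

    def test_matches_independent_library_oracle(self):
        struc = pytest.importorskip("biotite.structure")
        n = 15
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 8, size=(n, 3))
        radii = np.full(n, 1.7)
        arr = struc.AtomArray(n)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * n)
        arr.atom_name = np.array(["CA"] * n)
        arr.res_name = np.array(["ALA"] * n)
        arr.res_id = np.arange(1, n + 1)
        arr.chain_id = np.array(["A"] * n)
        oracle = struc.sasa(arr, probe_radius=1.4, point_number=2000, vdw_radii=radii)
        mine = shrake_rupley(coords, radii, probe=1.4, n_points=2000)
        assert abs(mine.sum() - oracle.sum()) / oracle.sum() < 0.01

    def test_occlusion_monotonicity(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 6, size=(8, 3))
        radii = np.full(8, 1.6)
        base = shrake_rupley(coords, radii)
        grown = shrake_rupley(
            np.vstack([coords, [[3.0, 3.0, 3.0]]]), np.append(radii, 1.6)
        )
        assert np.all(grown[:8] <= base + 1e-9)

    def test_point_count_convergence(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 10, size=(20, 3))
        radii = rng.uniform(1.4, 1.9, size=20)
        coarse = shrake_rupley(coords, radii, n_points=960)
        fine = shrake_rupley(coords, radii, n_points=9600)
        assert abs(coarse.sum() - fine.sum()) / fine.sum() < 0.02

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            shrake_rupley(np.zeros((2, 3)), np.ones(2))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n_points"):
            shrake_rupley(np.zeros((1, 3)), np.ones(1), n_points=50)


class TestRasa:
    def test_direct_ratio(self):
        assert compute_rasa(50.0, 100.0) == 0.5
        assert compute_rasa(73.2, 73.2) == 1.0
        assert compute_rasa(0.0, 80.0) == 0.0

    def test_fully_buried_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="buried"):
            assert compute_rasa(0.0, 0.0) == 0.0


class TestContacts:
    def test_planted_pairs_recovered_exactly(self, toy_trimer):
        trimer, truth = toy_trimer
        labels, eca, ica = contact_areas(trimer)
        found = sorted(
            ((l.res_a[0], l.res_a[1]), (l.res_b[0], l.res_b[1]))
            for l in labels
            if l.is_interface
        )
        assert found == sorted(truth)

    def test_disjoint_chains_have_no_interface(self):
        pdb, _ = generate_toy_trimer(chain_lengths=(6, 6, 6))
        trimer = parse_trimer(pdb, enforce_lengths=False)
        labels, eca, ica = contact_areas(trimer)
        assert labels == []
        assert all(v == 0 for v in eca.values())

    def test_eca_positive_iff_in_interface_pair(self, toy_trimer):
        trimer, _ = toy_trimer
        labels, eca, _ = contact_areas(trimer)
        participating = {l.res_a for l in labels} | {l.res_b for l in labels}
        for key, v in eca.items():
            assert (v > 0) == (key in participating)

    def test_interface_definition_is_positive_area(self, toy_trimer):
        trimer, _ = toy_trimer
        labels, _, _ = contact_areas(trimer)
        for lbl in labels:
            assert lbl.is_interface == (lbl.contact_area > 0)
            assert lbl.contact_area >= 0


class TestGeometricFeatures:
    def test_bound_never_exceeds_unbound(self, toy_trimer):
        trimer, _ = toy_trimer
        geo = geometric_features(trimer, n_points=480)
        assert np.all(geo["asa_bound"] <= geo["asa_unbound"] + 1e-6)
        assert np.all(geo[["asa_bound", "asa_unbound", "eca", "ica", "eva"]] >= 0)
        assert np.all((geo["rasa"] >= 0) & (geo["rasa"] <= 1 + 1e-9))

    def test_descriptor_table_width(self, toy_trimer):
        trimer, _ = toy_trimer
        desc = build_residue_descriptors(trimer, n_points=240)
        assert desc.shape == (24, 64)

    def test_pair_table_dimensions_and_labels(self, toy_trimer):
        trimer, truth = toy_trimer
        labels, _, _ = contact_areas(trimer)
        desc = build_residue_descriptors(
            trimer, n_points=240, precomputed_contacts=(labels, {}, {})
        )
        pairs = build_pair_table(trimer, desc, labels)
        assert len(pairs) == 3 * 8 * 8
        assert int(pairs["is_interface"].sum()) == len(truth)
        feat_cols = [c for c in pairs.columns if c.startswith(("a_", "b_"))]
        assert len(feat_cols) == 128


class TestElectric:
    def test_default_lookup_deterministic(self):
        out = electric_features(["A", "A", "W"])
        assert out[0] == out[1] == PKA_TABLE["A"]
        assert out[2] == PKA_TABLE["W"]

    def test_import_table_passthrough_and_fallback(self, toy_trimer):
        trimer, _ = toy_trimer
        residues = trimer.chains["A"][:2]
        table = {residues[0].key: (2.0, 9.0)}
        with pytest.warns(UserWarning, match="missing"):
            out = electric_features(residues, import_table=table)
        assert out[0] == (2.0, 9.0)
        assert out[1] == PKA_TABLE[residues[1].one_letter]

    def test_malformed_import_names_line(self, tmp_path):
        path = tmp_path / "pka.tsv"
        path.write_text("chain\tresnum\tpk1\tpk2\nA\t1\t2.0\t9.0\nA\toops\t1\t2\n")
        with pytest.raises(ValueError, match=":3"):
            read_pka_tsv(path)

    def test_import_roundtrip(self, tmp_path):
        path = tmp_path / "pka.tsv"
        path.write_text("chain\tresnum\tpk1\tpk2\nB\t4\t3.25\t8.5\n")
        assert read_pka_tsv(path) == {("B", 4, ""): (3.25, 8.5)}
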