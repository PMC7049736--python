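"""Structure loading, superposition, distances, shells and attribute export."""

import gemmi
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from ptcmap.structure import (
    assign_shells,
    export_attribute_map,
    geometric_center,
    load_structure,
    load_structure_from_gemmi,
    nucleotide_distances,
    reference_point,
    superpose,
)
from ptcmap.synth import synth_structure


def build_structure(residues):
    """Assemble a gemmi structure from {chain: {num: [(name, element, xyz, occ, altloc)]}}."""
    st = gemmi.Structure()
    model = gemmi.Model("1")
    for chain_name, res_map in residues.items():
        chain = gemmi.Chain(chain_name)
        for num, atoms in res_map.items():
            res = gemmi.Residue()
            res.name = "N"
            res.seqid = gemmi.SeqId(num, " ")
            for name, element, xyz, occ, altloc in atoms:
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(element)
                atom.pos = gemmi.Position(*xyz)
                atom.occ = occ
                atom.altloc = altloc
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    return st


# --- loading ---------------------------------------------------------------


def test_minimal_file_roundtrip(tmp_path):
    st = build_structure({"B": {1: [("C1", "C", (0, 0, 0), 1.0, "\0"),
                                    ("N1", "N", (1, 0, 0), 1.0, "\0"),
                                    ("O1", "O", (0, 1, 0), 1.0, "\0")]}})
    path = tmp_path / "toy.pdb"
    st.write_pdb(str(path))
    residues = load_structure(path)
    assert len(residues) == 1 and len(residues[0].atoms) == 3


def test_altloc_keeps_highest_occupancy():
    st = build_structure({"B": {1: [("C1", "C", (0, 0, 0), 0.7, "A"),
                                    ("C1", "C", (9, 9, 9), 0.3, "B")]}})
    residues = load_structure_from_gemmi(st)
    assert len(residues[0].atoms) == 1
    assert residues[0].atoms[0].pos == (0.0, 0.0, 0.0)


def test_hydrogen_only_residue_rejected():
    st = build_structure({"B": {1: [("H1", "H", (0, 0, 0), 1.0, "\0")]}})
    with pytest.raises(ValueError, match="heavy"):
        load_structure_from_gemmi(st)


def test_hydrogens_excluded_from_centers():
    st = build_structure({"B": {1: [("C1", "C", (0, 0, 0), 1.0, "\0"),
                                    ("H1", "H", (50, 0, 0), 1.0, "\0")]}})
    residues = load_structure_from_gemmi(st)
    np.testing.assert_allclose(geometric_center(residues[0]), [0, 0, 0])


# --- geometric centers -----------------------------------------------------


def test_single_atom_center():
    st = build_structure({"B": {1: [("C1", "C", (1, 2, 3), 1.0, "\0")]}})
    np.testing.assert_allclose(geometric_center(load_structure_from_gemmi(st)), [1, 2, 3])


def test_two_atom_midpoint():
    st = build_structure({"B": {1: [("C1", "C", (0, 0, 0), 1.0, "\0"),
                                    ("C2", "C", (2, 0, 0), 1.0, "\0")]}})
    np.testing.assert_allclose(geometric_center(load_structure_from_gemmi(st)), [1, 0, 0])


def test_center_matches_brute_force_mean():
    rng = np.random.default_rng(4)
    coords = rng.uniform(-10, 10, (10, 3))
    atoms = [(f"C{i}", "C", tuple(c), 1.0, "\0") for i, c in enumerate(coords)]
    st = build_structure({"B": {1: atoms}})
    # oracle: explicit per-axis summation
    oracle = [sum(c[k] for c in coords) / len(coords) for k in range(3)]
    np.testing.assert_allclose(geometric_center(load_structure_from_gemmi(st)), oracle, atol=1e-9)


# --- superposition ---------------------------------------------------------


def grid_residues(offset=np.zeros(3), rotation=np.eye(3)):
    rng = np.random.default_rng(8)
    pts = rng.uniform(-5, 5, (6, 3))
    res = {}
    for i, p in enumerate(pts):
        q = rotation @ p + offset
        res[i + 1] = [("P", "P", tuple(q), 1.0, "\0")]
    return {"B": res}


def test_identity_superposition():
    fixed = load_structure_from_gemmi(build_structure(grid_residues()))
    tf = superpose(fixed, fixed)
    assert tf.rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(tf.translation, 0.0, atol=1e-9)


def test_translation_recovered():
    fixed = load_structure_from_gemmi(build_structure(grid_residues()))
    mobile = load_structure_from_gemmi(build_structure(grid_residues(offset=np.array([1.0, 2.0, 3.0]))))
    tf = superpose(mobile, fixed)
    assert tf.rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(tf.translation, [-1, -2, -3], atol=1e-9)


def test_random_rotation_recovered_to_numerical_zero():
    R = Rotation.random(rng=np.random.default_rng(12)).as_matrix()
    fixed = load_structure_from_gemmi(build_structure(grid_residues()))
    mobile = load_structure_from_gemmi(
        build_structure(grid_residues(rotation=R, offset=np.array([4.0, -1.0, 2.0])))
    )
    tf = superpose(mobile, fixed)
    assert tf.rmsd < 1e-6
    # transform composed with the applied motion is the identity
    pts = np.vstack([r.coords() for r in mobile])
    np.testing.assert_allclose(tf.apply(pts), np.vstack([r.coords() for r in fixed]), atol=1e-8)


def test_too_few_or_collinear_points_rejected():
    two = {"B": {1: [("P", "P", (0, 0, 0), 1.0, "\0")],
                 2: [("P", "P", (1, 0, 0), 1.0, "\0")]}}
    res2 = load_structure_from_gemmi(build_structure(two))
    with pytest.raises(ValueError, match="3 shared"):
        superpose(res2, res2)
    line = {"B": {i: [("P", "P", (float(i), 0, 0), 1.0, "\0")] for i in range(1, 5)}}
    resl = load_structure_from_gemmi(build_structure(line))
    with pytest.raises(ValueError, match="collinear"):
        superpose(resl, resl)


# --- distances -------------------------------------------------------------


def test_three_four_five_distance():
    st = build_structure({
        "A": {76: [("C1", "C", (0, 0, 0), 1.0, "\0")]},
        "P": {76: [("C1", "C", (10, 0, 0), 1.0, "\0")]},
        "B": {2451: [("C1", "C", (3, 4, 0), 1.0, "\0")]},
    })
    residues = load_structure_from_gemmi(st)
    ref_a = reference_point("A-site", [r for r in residues if r.chain == "A"])
    ref_p = reference_point("P-site", [r for r in residues if r.chain == "P"])
    nucs = {r.number: r for r in residues if r.chain == "B"}
    df, missing = nucleotide_distances(nucs, ref_a, ref_p)
    assert missing == []
    assert df.loc[0, "distance_to_A_site"] == pytest.approx(5.0)


def test_missing_positions_reported_not_fatal():
    st = build_structure({
        "A": {76: [("C1", "C", (0, 0, 0), 1.0, "\0")]},
        "P": {76: [("C1", "C", (10, 0, 0), 1.0, "\0")]},
        "B": {1: [("C1", "C", (1, 1, 1), 1.0, "\0")]},
    })
    residues = load_structure_from_gemmi(st)
    ref_a = reference_point("A-site", [r for r in residues if r.chain == "A"])
    ref_p = reference_point("P-site", [r for r in residues if r.chain == "P"])
    nucs = {r.number: r for r in residues if r.chain == "B"}
    df, missing = nucleotide_distances(nucs, ref_a, ref_p, positions=[1, 2])
    assert missing == [2] and len(df) == 1


def test_synthetic_radii_recovered_exactly():
    radii = {2451: (30.0, 4.0), 2585: (30.0, 12.0), 2253: (36.0, 36.0)}
    st, truth = synth_structure(radii, seed=5)
    residues = load_structure_from_gemmi(st)
    ref_a = reference_point("A-site", [r for r in residues if r.chain == "A"])
    ref_p = reference_point("P-site", [r for r in residues if r.chain == "P"])
    nucs = {r.number: r for r in residues if r.chain == "B"}
    df, _ = nucleotide_distances(nucs, ref_a, ref_p)
    merged = df.merge(truth, on="position")
    np.testing.assert_allclose(merged["distance_to_A_site"], merged["true_distance_A_site"], atol=1e-9)
    np.testing.assert_allclose(merged["distance_to_P_site"], merged["true_distance_P_site"], atol=1e-9)


def test_distances_invariant_under_joint_rigid_motion():
    radii = {1: (30.0, 8.0), 2: (31.0, 20.0), 3: (32.0, 33.0)}
    st, _ = synth_structure(radii, seed=6)
    residues = load_structure_from_gemmi(st)

    def dists(res_list):
        ref_a = reference_point("A-site", [r for r in res_list if r.chain == "A"])
        ref_p = reference_point("P-site", [r for r in res_list if r.chain == "P"])
        nucs = {r.number: r for r in res_list if r.chain == "B"}
        df, _m = nucleotide_distances(nucs, ref_a, ref_p)
        return df

    from ptcmap.structure import RigidTransform

    R = Rotation.random(rng=np.random.default_rng(3)).as_matrix()
    tf = RigidTransform(rotation=R, translation=np.array([10.0, -5.0, 2.0]), rmsd=0.0)
    moved = tf.apply_residues(residues)
    pd.testing.assert_frame_equal(dists(residues), dists(moved), atol=1e-9)


# --- shells ----------------------------------------------------------------


def test_quartet_scores_one_per_shell():
    out = assign_shells({1: 0.0, 2: 1.0, 3: 2.0, 4: 3.0})
    assert list(out["shell"]) == [1, 2, 3, 4]
    assert list(out["label"]) == ["lowest", "medium/low", "medium/high", "highest"]


def test_equal_scores_all_fall_to_lowest_shell():
    out = assign_shells({i: 1.5 for i in range(6)})
    assert (out["shell"] == 1).all()


def test_eight_even_scores_two_per_shell():
    out = assign_shells({i: float(i) for i in range(8)})
    assert list(out["shell"]) == [1, 1, 2, 2, 3, 3, 4, 4]


def test_shell_assignment_monotone_in_score():
    rng = np.random.default_rng(9)
    scores = {i: float(s) for i, s in enumerate(rng.uniform(0, 3, 30))}
    out = assign_shells(scores).set_index("position")
    items = sorted(scores.items(), key=lambda kv: kv[1])
    shells = [out.loc[pos, "shell"] for pos, _ in items]
    assert shells == sorted(shells)


def test_explicit_thresholds_accepted():
    out = assign_shells({1: 0.2, 2: 0.9, 3: 1.7, 4: 2.9}, thresholds=[0.5, 1.5, 2.5])
    assert list(out["shell"]) == [1, 2, 3, 4]


def test_fewer_positions_than_shells_rejected():
    with pytest.raises(ValueError):
        assign_shells({1: 0.5, 2: 1.0}, n_shells=4)


# --- attribute export ------------------------------------------------------


def test_bfactor_export_roundtrip(tmp_path):
    radii = {2451: (30.0, 4.0), 2585: (30.0, 12.0)}
    st, _ = synth_structure(radii, seed=2)
    src = tmp_path / "toy.pdb"
    out = tmp_path / "mapped.pdb"
    st.write_pdb(str(src))
    export_attribute_map(src, {("B", 2451): 2.5, ("B", 2585): 0.75}, out)
    reloaded = gemmi.read_structure(str(out))
    seen = {}
    for chain in reloaded[0]:
        for res in chain:
            bs = {round(a.b_iso, 2) for a in res}
            assert len(bs) == 1  # every atom of a residue carries one score
            seen[(chain.name, res.seqid.num)] = bs.pop()
    assert seen[("B", 2451)] == pytest.approx(2.5)
    assert seen[("B", 2585)] == pytest.approx(0.75)
    assert seen[("A", 76)] == pytest.approx(-1.0)  # unmapped sentinel


def test_unresolvable_position_rejected(tmp_path):
    st, _ = synth_structure({1: (30.0, 10.0)}, seed=2)
    src = tmp_path / "toy.pdb"
    st.write_pdb(str(src))
    with pytest.raises(KeyError):
        export_attribute_map(src, {("Z", 999): 1.0}, tmp_path / "out.pdb")
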