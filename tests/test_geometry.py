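import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import monte_carlo_sasa, rigid_copy
from pdnet import fixtures as fx
from pdnet.geometry_features import (
    ChainContext,
    GeometryError,
    assign_secondary_structure,
    backbone_dihedrals,
    backbone_hbond_map,
    backbone_sasa,
    canonical_frame,
    chain_breaks,
    count_backbone_hbonds,
    dihedral,
)
from pdnet.structure_io import AtomRecord, ResidueRecord

finite = st.floats(-50, 50, allow_nan=False)
point = st.tuples(finite, finite, finite).map(np.array)


# ---------------------------------------------------------------------------
# Dihedral


def test_dihedral_planar_cis_and_trans():
    p = [np.array([1.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0]),
         np.array([2.0, 0.0, 0.0])]
    assert dihedral(*p, np.array([2.0, 1.0, 0.0])) == pytest.approx(0.0, abs=1e-12)
    assert dihedral(*p, np.array([2.0, -1.0, 0.0])) == pytest.approx(180.0, abs=1e-12)


def test_dihedral_collinear_raises():
    a, b, c = (np.array([float(i), 0, 0]) for i in range(3))
    with pytest.raises(GeometryError):
        dihedral(a, b, c, np.array([3.0, 1.0, 0.0]))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(point, point, point, point)
def test_dihedral_invariant_under_reversal_and_flipped_by_mirror(p1, p2, p3, p4):
    # Under the IUPAC convention the torsion does not depend on the
    # traversal direction; a mirror image negates it.
    try:
        fwd = dihedral(p1, p2, p3, p4)
    except GeometryError:
        return
    rev = dihedral(p4, p3, p2, p1)
    assert min(abs(fwd - rev), abs(abs(fwd) - 180) + abs(abs(rev) - 180)) < 1e-6
    m = np.array([1.0, 1.0, -1.0])
    mir = dihedral(p1 * m, p2 * m, p3 * m, p4 * m)
    assert min(abs(fwd + mir), abs(abs(fwd) - 180) + abs(abs(mir) - 180)) < 1e-6


def test_backbone_dihedrals_recover_builder_torsions():
    chain = fx.build_ideal_backbone(fx.BackboneSpec([(-57.0, -47.0, 180.0)] * 8))
    br = chain_breaks(chain)
    for i in range(1, 7):
        d = backbone_dihedrals(chain, i, br)
        assert d.phi == pytest.approx(-57.0, abs=1e-6)
        assert d.psi == pytest.approx(-47.0, abs=1e-6)
        assert abs(d.omega) == pytest.approx(180.0, abs=1e-6)


def test_terminal_dihedrals_undefined_with_sentinel_encoding(helix12):
    first = backbone_dihedrals(helix12, 0)
    assert first.phi is None and first.omega is None and first.psi is not None
    enc = first.cos_sin
    assert np.allclose(enc[0:2], 0) and np.allclose(enc[4:6], 0)
    assert enc[2] ** 2 + enc[3] ** 2 == pytest.approx(1.0, abs=1e-9)
    last = backbone_dihedrals(helix12, 11)
    assert last.psi is None
    with pytest.raises(IndexError):
        backbone_dihedrals(helix12, 12)


def test_defined_angles_lie_on_unit_circle(helix12):
    for i in range(12):
        enc = backbone_dihedrals(helix12, i).cos_sin
        for k in range(3):
            c, s = enc[2 * k], enc[2 * k + 1]
            assert c == s == 0 or c ** 2 + s ** 2 == pytest.approx(1.0, abs=1e-9)


def test_chain_break_suppresses_dihedrals():
    a = fx.make_ideal_helix(4)
    b = rigid_copy(fx.make_ideal_helix(4, start_index=5), np.eye(3),
                   np.array([50.0, 0, 0]))
    chain = a + b
    br = chain_breaks(chain)
    assert br[3] and not br[0]
    d = backbone_dihedrals(chain, 4, br)
    assert d.phi is None and d.omega is None


# ---------------------------------------------------------------------------
# Secondary structure


def test_ideal_helix_interior_is_helix(helix12):
    labels = assign_secondary_structure(helix12)
    assert all(l == "helix" for l in labels[1:11])


def test_paired_strands_contain_sheet_residues(sheet_pair):
    labels = assign_secondary_structure(sheet_pair)
    n = len(sheet_pair) // 2
    assert labels.count("sheet") >= 4
    assert any(l == "sheet" for l in labels[:n])
    assert any(l == "sheet" for l in labels[n:])
    assert "helix" not in labels


def test_sheet_labels_follow_hbond_participation(sheet_pair):
    # The label rule: extended dihedrals + >=1 inter-strand backbone H-bond.
    hbonds = backbone_hbond_map(sheet_pair)
    partners = {i for pair in hbonds for i in pair}
    labels = assign_secondary_structure(sheet_pair)
    for i, lab in enumerate(labels):
        if lab == "sheet":
            assert i in partners


def test_lone_left_handed_residue_is_loop():
    chain = fx.build_ideal_backbone(fx.BackboneSpec([(60.0, 60.0, 180.0)] * 3))
    assert assign_secondary_structure(chain) == ["loop"] * 3


# ---------------------------------------------------------------------------
# Hydrogen bonds


def test_helix_i_to_i_plus_4_hbond(helix12):
    hbonds = backbone_hbond_map(helix12)
    assert count_backbone_hbonds(hbonds, 0, 4) == 1
    assert count_backbone_hbonds(hbonds, 3, 7) == 1


def test_sequential_pair_never_bonds(helix12):
    hbonds = backbone_hbond_map(helix12)
    for i in range(11):
        assert count_backbone_hbonds(hbonds, i, i + 1) == 0


def test_distant_residues_never_bond():
    a = fx.make_ideal_helix(4)
    b = rigid_copy(fx.make_ideal_helix(4, chain_id="B"), np.eye(3),
                   np.array([60.0, 0, 0]))
    hbonds = backbone_hbond_map(a + b)
    for i in range(4):
        for j in range(4, 8):
            assert count_backbone_hbonds(hbonds, i, j) == 0


def test_proline_never_donates():
    helix = fx.make_ideal_helix(12, sequence="A" * 4 + "P" + "A" * 7)
    hbonds = backbone_hbond_map(helix)
    assert (4, 0) not in hbonds  # N-H of the proline at index 4 cannot donate
    assert (5, 1) in hbonds


# ---------------------------------------------------------------------------
# SASA


def test_isolated_atom_sasa_matches_sphere_area():
    res = ResidueRecord("A", 1, "", "G", [
        AtomRecord(n, e, np.array(c)) for n, e, c in [
            ("N", "N", (0.0, 0, 0)), ("CA", "C", (100.0, 0, 0)),
            ("C", "C", (200.0, 0, 0)), ("O", "O", (300.0, 0, 0))]])
    sasa = backbone_sasa([res])
    expected = sum(4 * np.pi * (r + 1.4) ** 2 for r in (1.65, 1.76, 1.76, 1.40))
    assert sasa[0] == pytest.approx(expected, rel=0.01)


def test_two_sphere_sasa_matches_spherical_cap_formula():
    # N and O of widely separated residues, with one N-O pair overlapping.
    r1, r2, sep = 1.65 + 1.4, 1.40 + 1.4, 2.8
    res1 = ResidueRecord("A", 1, "", "G", [
        AtomRecord("N", "N", np.array([0.0, 0, 0])),
        AtomRecord("CA", "C", np.array([100.0, 0, 0])),
        AtomRecord("C", "C", np.array([200.0, 0, 0])),
        AtomRecord("O", "O", np.array([sep, 0, 0]))])
    sasa = backbone_sasa([res1])
    h1 = r1 - (sep ** 2 + r1 ** 2 - r2 ** 2) / (2 * sep)
    h2 = r2 - (sep ** 2 + r2 ** 2 - r1 ** 2) / (2 * sep)
    expected_pair = (4 * np.pi * r1 ** 2 - 2 * np.pi * r1 * h1) + \
        (4 * np.pi * r2 ** 2 - 2 * np.pi * r2 * h2)
    expected = expected_pair + 2 * 4 * np.pi * (1.76 + 1.4) ** 2
    assert sasa[0] == pytest.approx(expected, rel=0.02)


def test_enclosed_atom_has_zero_sasa():
    # Bury residue 1's four atoms inside a dense shell of backbone atoms.
    core = ResidueRecord("A", 1, "", "G", [
        AtomRecord(n, n[0], np.array([0.1 * k, 0, 0]))
        for k, n in enumerate(("N", "CA", "C", "O"))])
    shell_atoms = []
    golden = np.pi * (3 - np.sqrt(5))
    for k in range(400):
        z = 1 - 2 * (k + 0.5) / 400
        r = np.sqrt(1 - z * z)
        th = golden * k
        shell_atoms.append(4.0 * np.array([r * np.cos(th), r * np.sin(th), z]))
    shell = [ResidueRecord("B", i + 1, "", "G", [
        AtomRecord(n, n[0], shell_atoms[4 * i + j] + np.array([0.15, 0, 0]))
        for j, n in enumerate(("N", "CA", "C", "O"))]) for i in range(100)]
    sasa = backbone_sasa([core] + shell)
    assert sasa[0] == pytest.approx(0.0, abs=1e-9)


def test_sasa_matches_monte_carlo_oracle_on_random_toys():
    rng = np.random.default_rng(11)
    radii_by = {"N": 1.65, "CA": 1.76, "C": 1.76, "O": 1.40}
    for trial in range(5):
        coords = rng.uniform(0, 5.0, size=(8, 3))
        names = ["N", "CA", "C", "O"] * 2
        res = [ResidueRecord("A", i + 1, "", "G",
                             [AtomRecord(n, n[0], coords[4 * i + j])
                              for j, n in enumerate(names[4 * i:4 * i + 4])])
               for i in range(2)]
        mine = backbone_sasa(res)
        oracle = monte_carlo_sasa(coords, [radii_by[n] for n in names],
                                  seed=trial)
        per_res_oracle = np.array([oracle[:4].sum(), oracle[4:].sum()])
        np.testing.assert_allclose(mine, per_res_oracle, rtol=0.02, atol=0.5)


def test_sasa_missing_backbone_atom_errors_and_skip():
    res = ResidueRecord("A", 7, "", "G", [AtomRecord("CA", "C", np.zeros(3))])
    ok = fx.make_ideal_helix(3)
    with pytest.raises(GeometryError, match="A:7"):
        backbone_sasa(ok + [res])
    sasa = backbone_sasa(ok + [res], skip_incomplete=True)
    assert np.isnan(sasa[-1]) and np.isfinite(sasa[:3]).all()


# ---------------------------------------------------------------------------
# Canonical frame


def test_canonical_frame_contract(helix12):
    for res in helix12:
        f = canonical_frame(res)
        ca = f.apply(res.coord("CA"))
        n = f.apply(res.coord("N"))
        c = f.apply(res.coord("C"))
        assert np.abs(ca).max() < 1e-9
        assert n[0] < 0 and abs(n[1]) < 1e-9 and abs(n[2]) < 1e-9
        assert abs(c[2]) < 1e-9 and c[1] > 0
        r = f.rotation
        assert np.abs(r @ r.T - np.eye(3)).max() < 1e-9
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)


def test_canonical_frame_matches_gram_schmidt_oracle():
    n = np.array([1.46, 0.0, 0.0])
    ca = np.zeros(3)
    c = np.array([-0.55, 1.42, 0.0])
    res = ResidueRecord("A", 1, "", "G", [
        AtomRecord("N", "N", n), AtomRecord("CA", "C", ca),
        AtomRecord("C", "C", c), AtomRecord("O", "O", np.array([-1.0, 2.0, 0.0]))])
    f = canonical_frame(res)
    # independent Gram-Schmidt construction
    x = (ca - n) / np.linalg.norm(ca - n)
    y = c - ca - np.dot(c - ca, x) * x
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    np.testing.assert_allclose(f.rotation, np.stack([x, y, z]), atol=1e-12)
    tc = f.apply(c)
    assert tc[1] > 0 and abs(tc[2]) < 1e-12
    np.testing.assert_allclose(tc, [np.dot(c - ca, x), np.linalg.norm(y * 0 + (c - ca) - np.dot(c - ca, x) * x), 0.0], atol=1e-12)


def test_collinear_backbone_frame_errors():
    res = ResidueRecord("A", 1, "", "G", [
        AtomRecord("N", "N", np.array([1.0, 0, 0])),
        AtomRecord("CA", "C", np.zeros(3)),
        AtomRecord("C", "C", np.array([-1.0, 0, 0]))])
    with pytest.raises(GeometryError):
        canonical_frame(res)


# ---------------------------------------------------------------------------
# Pair features


def test_pair_features_shape_and_unit_norms(helix12):
    ctx = ChainContext(helix12)
    feat = ctx.pair_features(5, 8)
    assert feat.shape == (31,)
    for sl in (slice(21, 24), slice(24, 27), slice(27, 30)):
        assert np.linalg.norm(feat[sl]) == pytest.approx(1.0, abs=1e-6)
    assert feat[20] > 0
    assert feat[7:10].sum() == pytest.approx(1.0) and feat[17:20].sum() == pytest.approx(1.0)


def test_pair_features_hand_computed_toy():
    # Target frame is the identity by construction: Ca at origin, N on -x,
    # C in z=0 with positive y.
    target = ResidueRecord("A", 1, "", "G", [
        AtomRecord("N", "N", np.array([-1.458, 0.0, 0.0])),
        AtomRecord("CA", "C", np.zeros(3)),
        AtomRecord("C", "C", np.array([-0.551, 1.422, 0.0])),
        AtomRecord("O", "O", np.array([-1.2, 2.3, 0.0]))])
    nb_n = np.array([6.5, 0.5, 0.1])
    nb_c = np.array([5.6, -1.2, 0.4])
    neighbor = ResidueRecord("B", 1, "", "G", [
        AtomRecord("N", "N", nb_n),
        AtomRecord("CA", "C", np.array([6.0, 0.0, 0.0])),
        AtomRecord("C", "C", nb_c),
        AtomRecord("O", "O", np.array([5.0, -2.0, 0.5]))])
    ctx = ChainContext([target, neighbor])
    feat = ctx.pair_features(0, 1)
    assert feat[20] == pytest.approx(6.0, abs=1e-9)
    np.testing.assert_allclose(feat[21:24], [1.0, 0.0, 0.0], atol=1e-9)
    v = nb_n - np.array([6.0, 0, 0])
    np.testing.assert_allclose(feat[24:27], v / np.linalg.norm(v), atol=1e-9)
    w = nb_c - np.array([6.0, 0, 0])
    np.testing.assert_allclose(feat[27:30], w / np.linalg.norm(w), atol=1e-9)
    assert feat[30] == 0.0
    # sentinel dihedrals for single-residue chains
    assert np.allclose(feat[0:6], 0.0) and np.allclose(feat[10:16], 0.0)


def test_mirror_image_flips_dihedral_signs_keeps_distances(helix12):
    mirrored = [
        ResidueRecord(r.chain_id, r.seq_index, r.insertion_code, r.aa_type,
                      [AtomRecord(a.name, a.element, a.coord * np.array([1, 1, -1]),
                                  a.occupancy, a.altloc) for a in r.atoms])
        for r in helix12
    ]
    d0 = backbone_dihedrals(helix12, 5)
    d1 = backbone_dihedrals(mirrored, 5)
    assert d1.phi == pytest.approx(-d0.phi, abs=1e-9)
    assert d1.psi == pytest.approx(-d0.psi, abs=1e-9)
    ca0 = np.linalg.norm(helix12[2].coord("CA") - helix12[9].coord("CA"))
    ca1 = np.linalg.norm(mirrored[2].coord("CA") - mirrored[9].coord("CA"))
    assert ca1 == pytest.approx(ca0, abs=1e-12)
    s0 = backbone_sasa(helix12)
    s1 = backbone_sasa(mirrored)
    # Reflection is an improper motion: the fixed sphere-point set samples the
    # mirrored surface differently, so only sampling-level agreement holds.
    np.testing.assert_allclose(s0, s1, rtol=0.02, atol=1.2)
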