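"""Chemical data model, conformer I/O, connectivity perception, curation."""

import math

import numpy as np
import pytest
from rdkit import Chem
from scipy.spatial.transform import Rotation

from solvaprop.molecular_data import (Conformer, CurationRules, Dataset,
                                      LabeledPair, StructureParseError,
                                      TopologyError, check_topology_consistency,
                                      curate, load_labels, parse_structure,
                                      perceive_connectivity, read_conformers,
                                      write_conformers)


# -- parsing ----------------------------------------------------------------

def test_parse_basic_counts():
    m = parse_structure("CCO")
    assert m.n_atoms == 3
    assert len(m.bonds) == 2


def test_canonical_key_is_spelling_independent():
    assert (parse_structure("c1ccccc1").canonical_key
            == parse_structure("C1=CC=CC=C1").canonical_key)


@pytest.mark.parametrize("bad", ["C(C)(C)(C)(C)C", "C1CC", "", "xyz("])
def test_parse_rejects_invalid(bad):
    with pytest.raises(StructureParseError):
        parse_structure(bad)


def test_canonical_key_under_atom_permutation(rng):
    """Random atom renumberings of one structure share a canonical key."""
    base = Chem.MolFromSmiles("CC(=O)Nc1ccc(O)cc1")
    ref_key = parse_structure(Chem.MolToSmiles(base)).canonical_key
    n = base.GetNumAtoms()
    for _ in range(10):
        perm = [int(x) for x in rng.permutation(n)]
        smi = Chem.MolToSmiles(Chem.RenumberAtoms(base, perm), canonical=False)
        assert parse_structure(smi).canonical_key == ref_key


# -- conformer I/O ----------------------------------------------------------

def _toy_conformers():
    rng = np.random.default_rng(0)
    return [
        Conformer(rng.normal(size=(4, 3)), ["C", "C", "O", "H"], "XTB",
                  source_id="CCO"),
        Conformer(rng.normal(size=(2, 3)), ["N", "N"], "DFT_IMP",
                  source_id="N#N"),
    ]


@pytest.mark.parametrize("fmt", ["xyz", "sdf"])
def test_conformer_roundtrip(fmt, tmp_path):
    confs = _toy_conformers()
    path = tmp_path / f"confs.{fmt}"
    write_conformers(confs, path)
    back = read_conformers(path)
    assert len(back) == 2
    for a, b in zip(confs, back):
        assert a.elements == b.elements
        assert a.fidelity_tag == b.fidelity_tag
        assert a.source_id == b.source_id
        assert np.allclose(a.coordinates, b.coordinates, atol=1e-4)


def test_xyz_malformed_block(tmp_path):
    p = tmp_path / "bad.xyz"
    p.write_text("3\nkey=x fidelity=XTB\nC 0 0 0\nC 1 0 0\n")
    with pytest.raises(ValueError, match="block 1"):
        read_conformers(p)


def test_unknown_fidelity_token_lists_levels(tmp_path):
    p = tmp_path / "bad.xyz"
    p.write_text("1\nkey=x fidelity=BOGUS\nC 0 0 0\n")
    with pytest.raises(ValueError, match="registered"):
        read_conformers(p)


def test_conformer_row_count_mismatch():
    with pytest.raises(ValueError):
        Conformer(np.zeros((3, 3)), ["C", "C"], "XTB")


# -- connectivity perception -------------------------------------------------

def test_two_carbons_bonded_at_bond_length():
    c = Conformer(np.array([[0., 0, 0], [1.54, 0, 0]]), ["C", "C"], "XTB")
    assert len(perceive_connectivity(c, 0.4).bonds) == 1
    far = Conformer(np.array([[0., 0, 0], [3.0, 0, 0]]), ["C", "C"], "XTB")
    assert len(perceive_connectivity(far, 0.4).bonds) == 0


def test_unknown_element_radius_named():
    c = Conformer(np.zeros((1, 3)), ["Xx"], "XTB")
    with pytest.raises(ValueError, match="Xx"):
        perceive_connectivity(c)


def _ethanol_geometry():
    # heavy atoms at standard bond lengths/angles: C-C 1.54, C-O 1.43, 109.5°
    ang = math.radians(180 - 109.5)
    c1 = np.array([0.0, 0.0, 0.0])
    c2 = np.array([1.54, 0.0, 0.0])
    o = c2 + 1.43 * np.array([math.cos(ang), math.sin(ang), 0.0])
    return Conformer(np.array([c1, c2, o]), ["C", "C", "O"], "DFT_IMP")


def _brute_force_bonds(conf, tol=0.4):
    from solvaprop.molecular_data import COVALENT_RADII
    out = set()
    for i in range(conf.n_atoms):
        for j in range(i + 1, conf.n_atoms):
            d = float(np.linalg.norm(conf.coordinates[i] - conf.coordinates[j]))
            if d <= COVALENT_RADII[conf.elements[i]] + \
                    COVALENT_RADII[conf.elements[j]] + tol:
                out.add((i, j))
    return out


def test_ethanol_geometry_matches_parsed_graph():
    conf = _ethanol_geometry()
    mol = perceive_connectivity(conf)
    got = {(i, j) for i, j, *_ in mol.bonds}
    assert got == _brute_force_bonds(conf) == {(0, 1), (1, 2)}
    ok, _ = check_topology_consistency(parse_structure("CCO"), conf)
    assert ok


def test_perception_invariant_to_rigid_motion(rng):
    conf = _ethanol_geometry()
    ref = {(i, j) for i, j, *_ in perceive_connectivity(conf).bonds}
    for k in range(5):
        R = Rotation.random(random_state=k).as_matrix()
        moved = Conformer(conf.coordinates @ R.T + rng.normal(size=3),
                          conf.elements, conf.fidelity_tag)
        assert {(i, j) for i, j, *_ in perceive_connectivity(moved).bonds} == ref


def test_cyclohexane_chair_topology():
    # ideal chair: alternating ring puckering, C-C 1.54
    theta = math.radians(110.9)
    coords = []
    r = 1.54 / (2 * math.sin(math.pi / 6)) * math.sin(theta / 2) * 0.85
    for k in range(6):
        a = math.pi * k / 3
        coords.append([1.46 * math.cos(a), 1.46 * math.sin(a),
                       0.25 if k % 2 else -0.25])
    conf = Conformer(np.array(coords), ["C"] * 6, "DFT_IMP")
    ok, report = check_topology_consistency(parse_structure("C1CCCCC1"), conf)
    assert ok, report


def test_broken_bond_reported():
    conf = _ethanol_geometry()
    moved = conf.coordinates.copy()
    moved[2] += np.array([10.0, 0, 0])
    broken = Conformer(moved, conf.elements, conf.fidelity_tag)
    ok, report = check_topology_consistency(parse_structure("CCO"), broken)
    assert not ok
    assert report["missing_edges"] == [(1, 2)]


def test_element_multiset_mismatch_raises():
    conf = Conformer(np.zeros((2, 3)), ["C", "N"], "XTB")
    with pytest.raises(TopologyError):
        check_topology_consistency(parse_structure("CC"), conf)


# -- labels + curation -------------------------------------------------------

def _record(chrom="c1ccccc1", solv="CCO", abs_nm=400.0, ems=np.nan, plqy=np.nan):
    mask = np.array([not np.isnan(abs_nm), not np.isnan(ems),
                     not np.isnan(plqy)])
    return LabeledPair(parse_structure(chrom), parse_structure(solv),
                       np.array([abs_nm, ems, plqy]), mask)


def test_load_labels_missing_and_rejects(tmp_path):
    p = tmp_path / "labels.csv"
    p.write_text(
        "chromophore_smiles,solvent_smiles,lambda_abs_nm,lambda_ems_nm,plqy\n"
        "c1ccccc1,CCO,400,,0.5\n"
        "c1ccccc1,CC#N,410,450,\n"
        "notasmiles(,CCO,400,,\n"
        "c1ccccc1,CCCCCC,390,,1.5\n")
    ds, issues = load_labels(p)
    assert len(ds) == 2
    assert len(issues) == 2
    assert np.isclose(ds.records[0].targets[2], np.log10(0.5))
    assert not ds.records[1].mask[2]


def test_curate_collapses_exact_duplicates():
    ds = Dataset([_record(), _record()])
    out, report = curate(ds, CurationRules(check_topology=False))
    assert len(out) == 1
    assert report.removed == 1
    assert report.per_rule["duplicate"] == 1


def test_curate_flags_conflicting_labels():
    ds = Dataset([_record(abs_nm=450.0), _record(abs_nm=520.0)])
    out, report = curate(ds, CurationRules(check_topology=False))
    assert len(out) == 2          # flagged, not dropped
    assert report.per_rule["conflicting_labels"] == 2


def test_curate_flags_protonation_variants():
    ds = Dataset([_record(chrom="Oc1ccccc1", solv="CCO"),
                  _record(chrom="[O-]c1ccccc1", solv="CC#N")])
    out, report = curate(ds, CurationRules(check_topology=False))
    assert report.per_rule["protonation_variant"] == 2


def test_curate_clean_dataset_unchanged_and_idempotent(small_fixture):
    _, dataset, _ = small_fixture
    ds = Dataset(list(dataset.records))
    once, rep1 = curate(ds)
    assert rep1.removed == 0 and rep1.total_flags == 0
    twice, rep2 = curate(once)
    assert rep2.removed == 0 and rep2.total_flags == 0
    assert len(twice) == len(once)
    rep1.validate(), rep2.validate()
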