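"""Static contact detectors: H-bonds, water bridges, hydrophobics, shell census."""

import itertools

import numpy as np
import pytest

import fpchrom as fp
from fpchrom.contacts import (
    ContactKind,
    find_hbonds,
    is_apolar_carbon,
    polar_capability,
)
from .conftest import make_structure


def all_indices(s):
    return list(range(len(s.atoms)))


def test_single_polar_pair_at_280(two_ser_pair):
    records = find_hbonds(two_ser_pair, [0, 1], [2, 3], cutoff=3.3)
    assert len(records) == 1
    assert records[0].metric == pytest.approx(2.80, abs=1e-9)
    assert {records[0].donor.name, records[0].acceptor.name} == {"OG"}


def test_out_of_range_pair_is_empty():
    s = make_structure([
        ("N", "ALA", "A", 1, (0, 0, 0)), ("O", "ALA", "A", 1, (1.2, 0.5, 0)),
        ("N", "ALA", "A", 9, (10.0, 0, 0)), ("O", "ALA", "A", 9, (11.2, 0.5, 0)),
    ])
    assert find_hbonds(s, [0, 1], [2, 3], cutoff=3.3) == []


def test_sequence_adjacent_backbone_pair_excluded():
    # carbonyl O(i) sits ~2.25 A from amide N(i+1); that is a covalent
    # neighbourhood, not a hydrogen bond
    s = make_structure([
        ("O", "ALA", "A", 1, (0, 0, 0)),
        ("N", "ALA", "A", 2, (2.25, 0, 0)),
        ("OG", "SER", "A", 2, (3.0, 0.5, 0)),
    ])
    records = find_hbonds(s, [0], [1, 2], cutoff=3.3)
    assert len(records) == 1   # only the O...OG pair; O(i)...N(i+1) excluded
    assert {records[0].donor.name, records[0].acceptor.name} == {"O", "OG"}


def test_hbond_selection_symmetry(toy, toy_chrom):
    structure, _ = toy
    chrom_sel = toy_chrom.heavy_atom_indices()
    other = [i for i in all_indices(structure) if i not in set(chrom_sel)
             and not structure.atoms[i].is_water]
    ab = find_hbonds(structure, chrom_sel, other)
    ba = find_hbonds(structure, other, chrom_sel)
    pairs = lambda recs: {frozenset((r.donor, r.acceptor)) for r in recs}
    assert pairs(ab) == pairs(ba)


def test_hbonds_match_exhaustive_enumeration(toy, toy_chrom):
    """Oracle equivalence: brute-force O(n^2) over all polar pairs."""
    structure, _ = toy
    chrom_sel = toy_chrom.heavy_atom_indices()
    other = [i for i in all_indices(structure)
             if i not in set(chrom_sel) and not structure.atoms[i].is_water
             and not structure.atoms[i].is_hydrogen]
    got = find_hbonds(structure, chrom_sel, other, cutoff=3.3)
    expected = set()
    for i, j in itertools.product(chrom_sel, other):
        a, b = structure.atoms[i], structure.atoms[j]
        ci, cj = polar_capability(a), polar_capability(b)
        if not ci or not cj:
            continue
        if not ((ci in ("donor", "both") and cj in ("acceptor", "both"))
                or (cj in ("donor", "both") and ci in ("acceptor", "both"))):
            continue
        if a.chain_id == b.chain_id and abs(a.res_seq - b.res_seq) <= 1:
            continue  # toy entities are not sequence neighbours of the chromophore
        if np.linalg.norm(a.xyz - b.xyz) <= 3.3:
            expected.add(frozenset((a.ref(), b.ref())))
    assert {frozenset((r.donor, r.acceptor)) for r in got} == expected
    # every reported metric re-measures from raw coordinates
    for r in got:
        i = structure.find_atom(r.donor.chain_id, r.donor.res_seq, r.donor.name)
        j = structure.find_atom(r.acceptor.chain_id, r.acceptor.res_seq, r.acceptor.name)
        d = np.linalg.norm(structure.atoms[i].xyz - structure.atoms[j].xyz)
        assert r.metric == pytest.approx(d, abs=0.01)
        assert r.metric <= 3.3


def test_water_bridge_single_triple():
    s = make_structure([
        ("OH", "CRO", "A", 66, (0, 0, 0), True),
        ("O", "HOH", "A", 201, (2.8, 0, 0), True),
        ("OG", "SER", "A", 101, (2.8 + 2.9, 0, 0)),
    ])
    chrom = _stub_chrom(s)
    records = fp.find_water_mediated(s, chrom, cutoff=3.3)
    assert len(records) == 1
    rec = records[0]
    assert rec.kind == ContactKind.WATER_MEDIATED
    assert rec.via_water.res_seq == 201
    assert rec.metric == pytest.approx(2.9, abs=1e-9)


def test_water_bridge_empty_without_waters(toy, toy_chrom):
    structure, _ = toy
    dry = structure.subset([i for i, a in enumerate(structure.atoms) if not a.is_water])
    chrom = fp.identify_chromophore(dry, "A")
    assert fp.find_water_mediated(dry, chrom) == []


def test_toy_bridging_water_and_partner_counts(toy, toy_chrom):
    structure, manifest = toy
    records = fp.find_water_mediated(structure, toy_chrom, cutoff=3.3)
    waters = {r.via_water for r in records}
    partners = {r.partners[1] for r in records}
    assert len(waters) == manifest.expected_counts["n_waters"] == 2
    assert len(partners) == manifest.expected_counts["water_mediated"] == 6


def test_hydrophobic_leu_sidechain(toy, toy_chrom):
    structure, manifest = toy
    records = fp.find_hydrophobic(structure, toy_chrom, cutoff=4.0)
    residues = {r.partners[1].res_seq for r in records}
    expected = {e["res_seq"] for e in manifest.entities
                if e["kind"] == "hydrophobic" and e["target_min_distance"] <= 4.0}
    assert residues == expected
    for r in records:
        assert 0 < r.metric <= 4.0


def test_polar_only_residue_gives_no_hydrophobic_contact():
    s = make_structure([
        ("CB2", "CRO", "A", 66, (0, 0, 0), True),
        ("OG", "SER", "A", 101, (3.0, 0, 0)),
        ("CB", "SER", "A", 101, (3.8, 0.6, 0)),
    ])
    assert fp.find_hydrophobic(s, _stub_chrom_named(s, {"CB2": 0}), cutoff=4.0) == []


def test_shell_census_brute_force_minimum_distance():
    """Three neighbours at 2.8 / 3.9 / 4.5 A minimum distance: census at 4.0 = 2."""
    spec = fp.GeneratorSpec(
        seed=5,
        shell=[
            fp.ShellResidueSpec("a", "polar", 2.8, "OH"),
            fp.ShellResidueSpec("b", "hydrophobic", 3.9, "CD1"),
            fp.ShellResidueSpec("c", "inert", 4.5, "CA1"),
        ],
        water_bridges=[],
    )
    structure, manifest = fp.make_toy_structure(spec)
    chrom = fp.identify_chromophore(structure, "A")
    report = fp.shell_census(structure, chrom, radius=4.0)
    assert len(report.shell_residues) == 2
    # brute-force oracle over raw coordinates
    chrom_xyz = np.array([structure.atoms[i].xyz for i in chrom.heavy_atom_indices()])
    for rref, indices in structure.residues(exclude_water=True):
        if rref.res_seq == 66:
            continue
        xyz = np.array([structure.atoms[i].xyz for i in indices
                        if not structure.atoms[i].is_hydrogen])
        dmin = np.linalg.norm(xyz[:, None] - chrom_xyz[None], axis=-1).min()
        assert (rref in report.shell_residues) == (dmin <= 4.0)


def test_shell_census_default_world(toy, toy_chrom):
    structure, manifest = toy
    report = fp.shell_census(structure, toy_chrom, radius=4.0)
    counts = manifest.expected_counts
    assert len(report.shell_residues) == counts["shell"] == 19
    assert len(report.direct_hbond_residues) == counts["direct_hbond"] == 5
    assert len(report.water_mediated_residues) == counts["water_mediated"] == 6
    assert len(report.hydrophobic_residues) == counts["hydrophobic"] == 7
    assert len(report.unclassified) == counts["unclassified"] == 1
    for subset in (report.direct_hbond_residues, report.water_mediated_residues,
                   report.hydrophobic_residues):
        assert set(subset) <= set(report.shell_residues)


def test_tiny_radius_empty_shell(toy, toy_chrom):
    structure, _ = toy
    report = fp.shell_census(structure, toy_chrom, radius=0.1)
    assert report.shell_residues == []


@pytest.mark.parametrize("radii", [(3.5, 4.0), (4.0, 4.5), (3.3, 3.7)])
def test_shell_monotone_in_radius(toy, toy_chrom, radii):
    structure, _ = toy
    small, large = radii
    a = fp.shell_census(structure, toy_chrom, radius=small)
    b = fp.shell_census(structure, toy_chrom, radius=large)
    assert set(a.shell_residues) <= set(b.shell_residues)


def test_hbonds_monotone_in_cutoff(toy, toy_chrom):
    structure, _ = toy
    sel = toy_chrom.heavy_atom_indices()
    other = [i for i, a in enumerate(structure.atoms)
             if i not in set(sel) and not a.is_water]
    pairs = lambda recs: {frozenset((r.donor, r.acceptor)) for r in recs}
    previous = set()
    for cutoff in (2.5, 3.0, 3.3, 3.7):
        current = pairs(find_hbonds(structure, sel, other, cutoff=cutoff))
        assert previous <= current
        previous = current


def test_apolar_carbon_table_spot_checks():
    mk = lambda name, res: make_structure([(name, res, "A", 1, (0, 0, 0))]).atoms[0]
    assert is_apolar_carbon(mk("CD1", "LEU"))
    assert not is_apolar_carbon(mk("CB", "SER"))     # bonded to OG
    assert not is_apolar_carbon(mk("CZ", "TYR"))     # bonded to OH
    assert not is_apolar_carbon(mk("CA", "GLY"))     # bonded to N
    assert is_apolar_carbon(mk("CB2", "CRO"))


def _stub_chrom(s):
    return fp.ChromophoreModel(s, s.atoms[0].residue_ref(), {"OH": 0})


def _stub_chrom_named(s, index):
    return fp.ChromophoreModel(s, s.atoms[0].residue_ref(), index)
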