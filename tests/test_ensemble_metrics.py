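"""Ensemble observables: RMSF, occupancy/lifetimes, stacking, dipole states."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import chisquare

import fpchrom as fp
from fpchrom import ensemble_metrics as em
from fpchrom.structure_io import Atom, Structure
from fpchrom.synthetic_data import builtin_charge_table
from .conftest import hexagon, make_structure


@pytest.fixture(scope="module")
def gaussian_ens():
    spec = fp.GeneratorSpec(seed=4, n_frames=1500, sigma=0.30, contacts=[], dipole=None)
    structure, manifest = fp.make_toy_structure(spec)
    ens, manifest = fp.make_ensemble(structure, spec, manifest)
    return structure, ens, manifest


def test_static_ensemble_rmsf_zero(toy):
    structure, _ = toy
    frames = np.repeat(structure.coords[None], 4, axis=0)
    prof = em.rmsf(fp.Ensemble(structure, frames), equil_fraction=0.0)
    assert np.allclose(prof.per_atom, 0.0, atol=1e-12)
    assert all(v == 0.0 for _, _, _, v in prof.entries)


def test_rmsf_requires_two_frames(toy):
    structure, _ = toy
    ens = fp.Ensemble(structure, structure.coords[None])
    with pytest.raises(ValueError):
        em.rmsf(ens, equil_fraction=0.0)


def test_rmsf_invariant_under_rigid_motion(gaussian_ens):
    structure, ens, _ = gaussian_ens
    base = em.rmsf(ens, fit_selection="heavy", atom_scope="heavy", equil_fraction=0.0)
    rot = Rotation.from_euler("xyz", [15, 70, -30], degrees=True).as_matrix()
    moved = fp.Ensemble(structure, ens.frames @ rot.T + np.array([5.0, -3.0, 8.0]), dt=ens.dt)
    again = em.rmsf(moved, fit_selection="heavy", atom_scope="heavy", equil_fraction=0.0)
    assert np.allclose(again.per_atom, base.per_atom, atol=1e-6)


def test_rmsf_equilibration_trimming(gaussian_ens):
    """Trimming must drop the leading fraction: an ensemble whose first half
    is frozen shows zero RMSF only when that half is discarded."""
    structure, _, _ = gaussian_ens
    still = np.repeat(structure.coords[None], 50, axis=0)
    rng = np.random.default_rng(9)
    noisy = structure.coords[None] + rng.normal(scale=0.5, size=(50, len(structure.atoms), 3))
    ens = fp.Ensemble(structure, np.concatenate([noisy, still]), dt=100.0)
    tail_only = em.rmsf(ens, fit_selection="heavy", atom_scope="heavy", equil_fraction=0.5)
    assert np.allclose(tail_only.per_atom, 0.0, atol=1e-9)
    with_head = em.rmsf(ens, fit_selection="heavy", atom_scope="heavy", equil_fraction=0.0)
    assert with_head.per_atom.mean() > 0.1


def test_contact_present_every_frame(toy):
    structure, _ = toy
    frames = np.repeat(structure.coords[None], 20, axis=0)
    ens = fp.Ensemble(structure, frames, dt=100.0)
    chrom = fp.identify_chromophore(structure, "A")
    # the don1 entity sits at 2.7 A from the hydroxyl in every frame
    crit = em.HBondCriterion("always", chrom.index("OH"), structure.find_atom("A", 101, "OG"))
    series = em.contact_occupancy(ens, [crit])[0]
    assert series.pr_oc == 1.0
    assert series.n_events == 1
    assert series.mean_lifetime == pytest.approx(20 * 100.0)


def test_occupancy_matches_generated_markov_series(toy):
    structure, manifest = toy
    spec = fp.GeneratorSpec(
        seed=12, n_frames=3000,
        contacts=[fp.ContactSpec("don2", occupancy=0.4, mean_dwell_frames=8)])
    ens, manifest = fp.make_ensemble(structure, spec, manifest)
    truth = manifest.ensemble["contacts"]["don2"]
    ent = manifest.entity("don2")
    chrom = fp.identify_chromophore(structure, "A")
    crit = em.HBondCriterion("don2", chrom.index(ent["chrom_atom"]),
                             structure.find_atom("A", ent["res_seq"], "OG"))
    series = em.contact_occupancy(ens, [crit])[0]
    # frame-exact agreement with the generator's Markov draw
    assert np.array_equal(series.present, truth["series"])
    assert series.pr_oc == truth["realized_pr_oc"]
    assert series.n_events == truth["n_events"]
    assert series.mean_lifetime == pytest.approx(truth["realized_mean_dwell_frames"] * ens.dt)


def test_lifetime_bookkeeping_conserves_mass():
    rng = np.random.default_rng(2)
    present = rng.random(5000) < 0.37
    series = em.OccupancySeries("x", present, dt=100.0)
    assert series.event_lengths.sum() == present.sum()
    assert series.pr_oc == present.mean()
    if series.n_events:
        assert series.mean_lifetime >= 100.0


def test_hbond_criterion_with_hydrogen_angle():
    # donor at origin, H on the +x axis; acceptor within 3.5 A passes only
    # when the H-donor-acceptor angle is <= 30 deg
    atoms = [("N", "UNK", "A", 1, (0, 0, 0)), ("H", "UNK", "A", 1, (1.0, 0, 0)),
             ("O", "UNK", "A", 2, (3.0, 0, 0))]
    s = make_structure(atoms)
    aligned = s.coords[None]
    tilted = aligned.copy()
    tilted[0, 2] = [3.0 * np.cos(np.radians(60)), 3.0 * np.sin(np.radians(60)), 0.0]
    frames = np.concatenate([aligned, tilted])
    ens = fp.Ensemble(s, frames, dt=1.0)
    crit = em.HBondCriterion("hb", donor=0, acceptor=2, hydrogen=1)
    assert crit.d_max == 3.5
    assert list(crit.evaluate(ens.frames)) == [True, False]


def test_grouped_occupancy_mean_count():
    s = make_structure([("OG", "SER", "A", 1, (0, 0, 0)), ("OG", "SER", "A", 2, (3.0, 0, 0)),
                        ("OG", "SER", "A", 3, (0, 3.0, 0))])
    frames = np.repeat(s.coords[None], 4, axis=0)
    frames[2:, 1] += 10.0       # second contact breaks for half the frames
    ens = fp.Ensemble(s, frames, dt=1.0)
    crits = [em.HBondCriterion("a", 0, 1, d_max=3.3), em.HBondCriterion("b", 0, 2, d_max=3.3)]
    series = em.contact_occupancy(ens, crits, group_label="all")
    group = series[-1]
    assert group.label == "all"
    assert group.mean_count_per_frame == pytest.approx(1.5)
    assert group.pr_oc == 1.0


def test_pipi_stacked_hexagons_always_present():
    ring_a = hexagon(z=0.0)
    ring_b = hexagon(z=3.8)
    atoms = [(f"C{k}", "PHE", "A", 1, tuple(p)) for k, p in enumerate(ring_a)]
    atoms += [(f"C{k}", "PHE", "A", 2, tuple(p)) for k, p in enumerate(ring_b)]
    s = make_structure(atoms)
    ens = fp.Ensemble(s, np.repeat(s.coords[None], 5, axis=0), dt=100.0)
    series = em.pipi_occupancy(ens, range(6), range(6, 12), d_max=5.5, angle_max=30.0)
    assert series.pr_oc == 1.0


def test_pipi_oscillating_separation_counting_oracle():
    ring_a = hexagon(z=0.0)
    ring_b = hexagon(z=3.8)
    atoms = [(f"C{k}", "PHE", "A", 1, tuple(p)) for k, p in enumerate(ring_a)]
    atoms += [(f"C{k}", "PHE", "A", 2, tuple(p)) for k, p in enumerate(ring_b)]
    s = make_structure(atoms)
    rng = np.random.default_rng(7)
    stacked = rng.random(2000) < 0.40
    frames = np.repeat(s.coords[None], 2000, axis=0)
    frames[~stacked, 6:, 2] += 4.0      # move ring B out to 7.8 A
    ens = fp.Ensemble(s, frames, dt=100.0)
    series = em.pipi_occupancy(ens, range(6), range(6, 12))
    assert np.array_equal(series.present, stacked)
    assert series.pr_oc == pytest.approx(0.40, abs=0.02)


def test_dipole_two_point_charges():
    s = Structure(atoms=[
        Atom(1, "CG2", "", "CRO", "A", 66, "", np.zeros(3), hetero=True),
        Atom(2, "CZ", "", "CRO", "A", 66, "", np.array([1.0, 0.0, 0.0]), hetero=True),
    ])
    chrom = fp.ChromophoreModel(s, s.atoms[0].residue_ref(), {"CG2": 0, "CZ": 1},
                                charges={"CG2": -1.0, "CZ": 1.0})
    ens = fp.Ensemble(s, s.coords[None], dt=1.0)
    series = em.dipole_series(ens, chrom)
    assert series.dm_modulus[0] == pytest.approx(4.8032, abs=1e-9)
    assert np.allclose(series.dm_vector[0] / series.dm_modulus[0], [1, 0, 0])
    assert series.axis_angle[0] == pytest.approx(0.0, abs=1e-6)
    assert series.net_charge == 0.0


def test_dipole_zero_charges(toy, toy_chrom):
    structure, manifest = toy
    spec = fp.GeneratorSpec(seed=8, n_frames=5)
    ens, _ = fp.make_ensemble(structure, spec, manifest)
    chrom = fp.identify_chromophore(structure, "A",
                                    charges={n: 0.0 for n in toy_chrom.atom_index} | {"HO": 0.0})
    series = em.dipole_series(ens, chrom)
    assert np.allclose(series.dm_modulus, 0.0, atol=1e-12)


def test_dipole_missing_charge_lists_atoms(toy):
    structure, manifest = toy
    spec = fp.GeneratorSpec(seed=8, n_frames=3)
    ens, _ = fp.make_ensemble(structure, spec, manifest)
    table = dict(builtin_charge_table("neutral"))
    table.pop("CZ")
    chrom = fp.identify_chromophore(structure, "A", charges=table)
    with pytest.raises(ValueError, match="CZ"):
        em.dipole_series(ens, chrom)


def test_neutral_fragment_dipole_origin_independent(toy):
    """For a net-neutral charge set the moment must not depend on the
    reference point: compare against plain charge-weighted positions."""
    structure, manifest = toy
    spec = fp.GeneratorSpec(seed=8, n_frames=50)
    ens, _ = fp.make_ensemble(structure, spec, manifest)
    chrom = fp.identify_chromophore(structure, "A", charges=builtin_charge_table("neutral"))
    series = em.dipole_series(ens, chrom)
    idx = chrom.fragment_indices() + [chrom.hydroxyl_h_index]
    q = np.array([chrom.charges[ens.topology.atoms[i].name] for i in idx])
    raw = np.einsum("m,nmk->nk", q, ens.frames[:, idx]) * em.E_ANGSTROM_TO_DEBYE
    assert np.allclose(series.dm_vector, raw, atol=1e-9)


def test_charged_fragment_reports_reference_and_net_charge(toy):
    structure, manifest = toy
    spec = fp.GeneratorSpec(seed=8, n_frames=5)
    ens, _ = fp.make_ensemble(structure, spec, manifest)
    chrom = fp.identify_chromophore(structure, "A", charges=builtin_charge_table("anion"))
    series = em.dipole_series(ens, chrom, include_hydroxyl_h=False)
    assert series.net_charge == pytest.approx(-1.0, abs=1e-9)
    assert "centroid" in series.reference_point


def test_all_trans_ensemble_classifies_major_one(toy):
    structure, manifest = toy
    spec = fp.GeneratorSpec(seed=8, n_frames=40, dipole=fp.DipoleSpec(trans_fraction=1.0))
    ens, manifest = fp.make_ensemble(structure, spec, manifest)
    chrom = fp.identify_chromophore(structure, "A", charges=builtin_charge_table("neutral"))
    series = em.dipole_series(ens, chrom)
    series, summary = em.classify_states(series, ens, chrom)
    assert summary[em.STATE_MAJOR_TRANS]["population"] == 1.0
    assert summary[em.STATE_MINOR_CIS]["population"] == 0.0


def test_classification_requires_hydroxyl_proton(toy):
    structure, manifest = toy
    heavy = structure.subset([i for i, a in enumerate(structure.atoms) if not a.is_hydrogen])
    chrom = fp.identify_chromophore(heavy, "A", charges=builtin_charge_table("anion"))
    ens = fp.Ensemble(heavy, heavy.coords[None], dt=1.0)
    series = em.dipole_series(ens, chrom, include_hydroxyl_h=False)
    with pytest.raises(ValueError, match="hydroxyl"):
        em.classify_states(series, ens, chrom)


def test_density2d_single_bin_and_refinement():
    vec = np.tile([[3.0, 0.0, 0.0]], (10, 1))
    series = em.DipoleSeries(vec, np.full(10, 42.0), "test", 0.0)
    dens = em.density2d(series, bins=5)
    assert dens.integral() == pytest.approx(1.0, abs=1e-9)
    assert (dens.density > 0).sum() == 1
    finer = em.density2d(series, bins=20)
    assert finer.integral() == pytest.approx(1.0, abs=1e-9)


def test_density2d_uniform_rectangle_is_flat():
    rng = np.random.default_rng(5)
    n = 40000
    vec = np.zeros((n, 3))
    vec[:, 0] = rng.uniform(2.0, 6.0, n)       # modulus uniform on [2, 6]
    angles = rng.uniform(10.0, 80.0, n)
    series = em.DipoleSeries(vec, angles, "test", 0.0)
    dens = em.density2d(series, bins=(4, 4))
    counts = dens.density * np.outer(np.diff(dens.mod_edges), np.diff(dens.angle_edges)) * n
    _, p = chisquare(counts.ravel())
    assert dens.integral() == pytest.approx(1.0, abs=1e-9)
    assert p > 0.01
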