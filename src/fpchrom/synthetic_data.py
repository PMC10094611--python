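"""Synthetic structures and ensembles with exactly known ground truth.

The generator builds a toy mini-protein around a matured GYG-type
chromophore (CRO-style atom names): shell residues are placed so that their
minimum distance to the chromophore equals a prescribed target, waters can
be planted as H-bond bridges, and ensembles add Gaussian positional noise,
two-state Markov switching of individual contacts, and an i.i.d. two-state
(trans/cis hydroxyl) dipole mixture.  Every stochastic element is recorded
in a manifest sufficient to predict the analysis output without rerunning
the generator.

The default ``GeneratorSpec`` states a microenvironment with the census of
a GFP-type chromophore pocket: 19 shell residues at 4 Å — 5 direct H-bond
donors, 6 residues bridged by 2 waters, 7 hydrophobic contacts and one
unclassified neighbour — and an ensemble of 750 frames at dt = 100 ps
(75 ns of analysed trajectory).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .structure_io import (
    Atom,
    ChromophoreModel,
    Ensemble,
    Structure,
    identify_chromophore,
)

GOLDEN_ANGLE = np.pi * (3.0 - 5 ** 0.5)


class InfeasiblePlacementError(ValueError):
    """Requested shell geometry cannot be realized without side effects."""


def builtin_charge_table(name: str = "neutral") -> dict[str, float]:
    """Shipped synthetic charge tables: 'neutral' (Σq = 0) or 'anion' (Σq = −1)."""
    from importlib.resources import files
    from .structure_io import load_charge_table
    fname = {"neutral": "charges_neutral_synthetic.txt",
             "anion": "charges_anion_synthetic.txt"}[name]
    return load_charge_table(files("fpchrom.data").joinpath(fname).read_text())


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class ShellResidueSpec:
    """One neighbour residue: its interaction kind and target minimum
    distance (Å) from the chromophore, anchored at a named chromophore atom."""

    label: str
    kind: str                 # 'polar' | 'hydrophobic' | 'inert'
    min_distance: float
    chrom_atom: str = "OH"
    slot: int = 0             # 0 = radial placement; >0 tilted alternatives


@dataclass
class WaterBridgeSpec:
    """A water planted as an H-bond bridge chromophore···W···partners."""

    label: str
    chrom_atom: str = "OH"
    leg1: float = 2.8         # chromophore polar atom – water O, Å
    leg2: float = 2.9         # water O – partner polar atom, Å
    partner_chrom_distance: float = 3.9   # partner's min distance to chromophore
    n_partners: int = 3
    slot: int = 1


@dataclass
class ContactSpec:
    """Two-state Markov switching of one polar contact.

    The acceptor atom of the named polar shell residue is moved along the
    donor→acceptor axis between ``on_distance`` and ``off_distance`` so the
    heavy-atom H-bond criterion toggles with prescribed stationary occupancy
    and mean on-state dwell (frames)."""

    label: str                # must name a 'polar' ShellResidueSpec
    occupancy: float
    mean_dwell_frames: float
    on_distance: float = 2.9
    off_distance: float = 4.5

    def __post_init__(self) -> None:
        if not 0.0 < self.occupancy < 1.0:
            raise ValueError("stationary occupancy must be in (0, 1)")
        if self.mean_dwell_frames < 1.0:
            raise ValueError("mean dwell must be >= 1 frame")


@dataclass
class DipoleSpec:
    """I.i.d. two-state hydroxyl mixture: trans (major) fraction per frame."""

    trans_fraction: float = 0.7
    charges: dict[str, float] | None = None   # default: shipped neutral synthetic set

    def __post_init__(self) -> None:
        if not 0.0 <= self.trans_fraction <= 1.0:
            raise ValueError("trans_fraction must be in [0, 1]")


def default_shell_specs() -> list[ShellResidueSpec]:
    """The stated chromophore pocket: 5 polar, 7 hydrophobic, 1 inert."""
    polar = [
        ShellResidueSpec("don1", "polar", 2.7, "OH"),
        ShellResidueSpec("don2", "polar", 2.8, "O2"),
        ShellResidueSpec("don3", "polar", 2.9, "N2"),
        ShellResidueSpec("don4", "polar", 3.0, "N3"),
        ShellResidueSpec("don5", "polar", 3.1, "N1"),
    ]
    hydrophobic = [
        ShellResidueSpec("hyd1", "hydrophobic", 3.5, "CB2"),
        ShellResidueSpec("hyd2", "hydrophobic", 3.6, "CD1"),
        ShellResidueSpec("hyd3", "hydrophobic", 3.6, "CD2"),
        ShellResidueSpec("hyd4", "hydrophobic", 3.7, "CE1"),
        ShellResidueSpec("hyd5", "hydrophobic", 3.7, "CE2"),
        ShellResidueSpec("hyd6", "hydrophobic", 3.8, "CG2"),
        ShellResidueSpec("hyd7", "hydrophobic", 3.9, "CB2", slot=1),
    ]
    inert = [ShellResidueSpec("pass1", "inert", 3.8, "C1")]
    return polar + hydrophobic + inert


def default_water_bridges() -> list[WaterBridgeSpec]:
    return [
        WaterBridgeSpec("wat1", chrom_atom="OH", n_partners=3, slot=1),
        WaterBridgeSpec("wat2", chrom_atom="O2", n_partners=3, slot=2),
    ]


@dataclass
class GeneratorSpec:
    """Full description of one synthetic system and its dynamics."""

    seed: int = 0
    n_frames: int = 750          # 75 ns analysed at 100 ps
    dt: float = 100.0            # ps
    sigma: float = 0.10          # Å, isotropic per-coordinate Gaussian noise
    sigma_overrides: dict = field(default_factory=dict)   # (chain, res_seq, name) -> Å
    shell: list[ShellResidueSpec] = field(default_factory=default_shell_specs)
    water_bridges: list[WaterBridgeSpec] = field(default_factory=default_water_bridges)
    contacts: list[ContactSpec] = field(default_factory=list)
    dipole: DipoleSpec | None = field(default_factory=DipoleSpec)


@dataclass
class GeneratorManifest:
    """Ground truth for every requested observable, plus the seed."""

    seed: int
    chrom_chain: str = "A"
    chrom_res_seq: int = 66
    entities: list[dict] = field(default_factory=list)
    expected_counts: dict = field(default_factory=dict)
    ensemble: dict = field(default_factory=dict)

    def entity(self, label: str) -> dict:
        for e in self.entities:
            if e["label"] == label:
                return e
        raise KeyError(label)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))
        return json.dumps(asdict(self), default=_default, indent=1)


# ---------------------------------------------------------------------------
# Toy chromophore geometry (CRO-style names, planar, ideal-ish bond lengths)
# ---------------------------------------------------------------------------

def _chromophore_atoms() -> dict[str, np.ndarray]:
    coords: dict[str, np.ndarray] = {}
    # phenol ring: hexagon of radius 1.39 Å in the z=0 plane, CG2 toward +x bridge
    for name, ang in (("CG2", 0), ("CD1", 60), ("CE1", 120), ("CZ", 180),
                      ("CE2", 240), ("CD2", 300)):
        t = np.radians(ang)
        coords[name] = np.array([1.39 * np.cos(t), 1.39 * np.sin(t), 0.0])
    coords["OH"] = coords["CZ"] + np.array([-1.36, 0.0, 0.0])
    coords["CB2"] = coords["CG2"] + np.array([1.45, 0.0, 0.0])
    # imidazolinone: pentagon of radius 1.15 Å, CA2 vertex facing the bridge
    center = np.array([5.0, 0.8, 0.0])
    to_bridge = coords["CB2"] - center
    base = np.arctan2(to_bridge[1], to_bridge[0])
    for k, name in enumerate(("CA2", "C2", "N3", "C1", "N2")):
        t = base + k * 2 * np.pi / 5
        coords[name] = center + np.array([1.15 * np.cos(t), 1.15 * np.sin(t), 0.0])
    c2_dir = (coords["C2"] - center) / np.linalg.norm(coords["C2"] - center)
    coords["O2"] = center + (1.15 + 1.23) * c2_dir
    # pseudo-backbone stubs linking toward residues i-1 / i+1
    c1_dir = (coords["C1"] - center) / np.linalg.norm(coords["C1"] - center)
    coords["N1"] = coords["C1"] + 1.45 * _unit(c1_dir + np.array([0.0, 0.3, 0.4]))
    coords["CA1"] = coords["N1"] + 1.47 * _unit(np.array([0.4, 0.8, 0.6]))
    n3_dir = (coords["N3"] - center) / np.linalg.norm(coords["N3"] - center)
    coords["CA3"] = coords["N3"] + 1.45 * _unit(n3_dir + np.array([0.0, -0.3, 0.5]))
    coords["C3"] = coords["CA3"] + 1.52 * _unit(np.array([0.6, -0.6, 0.6]))
    coords["O3"] = coords["C3"] + 1.23 * _unit(np.array([0.3, -1.0, 0.1]))
    return coords


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = _unit(np.cross(u, helper))
    return e1, np.cross(u, e1)


# residue templates: (atom name, offset along placement axis, two perpendicular
# offsets), anchor first at the origin, remaining atoms strictly farther out
_TEMPLATES: dict[str, tuple[str, list[tuple[str, float, float, float]]]] = {
    "polar": ("SER", [
        ("OG", 0.0, 0.0, 0.0), ("CB", 1.2, 0.5, 0.2), ("CA", 2.5, 0.3, -0.4),
        ("N", 3.3, 1.2, 0.3), ("C", 3.4, -0.9, 0.2), ("O", 4.5, -1.1, 0.5),
    ]),
    "hydrophobic": ("LEU", [
        ("CD1", 0.0, 0.0, 0.0), ("CG", 1.1, 0.6, 0.3), ("CD2", 1.3, 1.9, 0.4),
        ("CB", 2.4, 0.2, -0.5), ("CA", 3.7, 0.6, 0.2), ("N", 4.3, 1.7, -0.2),
        ("C", 4.5, -0.5, 0.6), ("O", 5.6, -0.6, 0.9),
    ]),
    "inert": ("GLY", [
        ("CA", 0.0, 0.0, 0.0), ("N", 1.1, 0.7, 0.2),
        ("C", 1.2, -0.9, 0.3), ("O", 2.3, -1.2, 0.5),
    ]),
}


def _fibonacci_directions(n: int = 2400) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)))


def _place_residue(kind: str, origin: np.ndarray, u: np.ndarray,
                   res_seq: int, res_name_override: str | None = None) -> list[Atom]:
    res_name, template = _TEMPLATES[kind]
    res_name = res_name_override or res_name
    e1, e2 = _perp_basis(u)
    atoms = []
    for name, t, a, b in template:
        pos = origin + t * u + a * e1 + b * e2
        atoms.append(Atom(0, name, "", res_name, "A", res_seq, "",
                          np.round(pos, 3)))
    return atoms


# ---------------------------------------------------------------------------
# make_toy_structure
# ---------------------------------------------------------------------------

class _Placer:
    """Greedy deterministic placement of shell entities around the chromophore.

    Candidate directions come from a fixed golden-spiral lattice; the first
    direction whose tentative residue passes every no-side-effect rule is
    accepted, so identical specs always yield identical structures.
    """

    HBOND_GUARD = 3.35       # unintended polar pairs must exceed this, Å
    APOLAR_GUARD = 4.05      # unintended apolar-carbon pairs, Å
    CLEARANCE = 2.4          # steric clearance between entities, Å

    def __init__(self, chrom_atoms: list[Atom]):
        from .contacts import is_apolar_carbon, polar_capability
        self._polar_fn = polar_capability
        self._apolar_fn = is_apolar_carbon
        self.chrom_atoms = [a for a in chrom_atoms if not a.is_hydrogen]
        self.chrom_xyz = np.array([a.xyz for a in self.chrom_atoms])
        self.chrom_polar = np.array([bool(polar_capability(a)) for a in self.chrom_atoms])
        self.chrom_apolar = np.array([is_apolar_carbon(a) for a in self.chrom_atoms])
        self.chrom_name_index = {a.name: k for k, a in enumerate(self.chrom_atoms)}
        self.directions = _fibonacci_directions()
        self.placed: list[Atom] = []
        self.water_pos: dict[str, np.ndarray] = {}       # water label -> O position
        self.partner_of: dict[int, str] = {}             # res_seq -> water label

    def _feasible(self, atoms: list[Atom], kind: str, target: float,
                  anchor_chrom: int, via_water: str | None) -> bool:
        xyz = np.array([a.xyz for a in atoms])
        d = np.linalg.norm(xyz[:, None, :] - self.chrom_xyz[None, :, :], axis=-1)
        # designated chromophore atom must be the strict nearest, at the target
        if abs(d[0, anchor_chrom] - target) > 0.005:
            return False
        other = np.ones(d.shape[1], dtype=bool)
        other[anchor_chrom] = False
        if d[0, other].min() <= target + 0.02:
            return False
        if d[1:].size and d[1:].min() <= target + 0.05:
            return False
        # no unintended polar / apolar interactions with the chromophore
        for i, a in enumerate(atoms):
            a_polar = bool(self._polar_fn(a))
            a_apolar = self._apolar_fn(a)
            for k in range(d.shape[1]):
                intended = (i == 0 and k == anchor_chrom and kind in ("polar", "water"))
                if a_polar and self.chrom_polar[k] and d[i, k] <= self.HBOND_GUARD and not intended:
                    return False
                intended_h = (kind == "hydrophobic")
                if a_apolar and self.chrom_apolar[k] and d[i, k] <= self.APOLAR_GUARD and not intended_h:
                    return False
        # steric clearance and water-neighbourhood discipline vs placed entities
        for i, a in enumerate(atoms):
            a_polar = bool(self._polar_fn(a))
            for b in self.placed:
                if (via_water is not None and i == 0 and b.is_water
                        and np.array_equal(b.xyz, self.water_pos[via_water])):
                    continue   # the intended bridge leg; its length is fixed by construction
                dist = float(np.linalg.norm(a.xyz - b.xyz))
                if dist < self.CLEARANCE:
                    return False
                # no accidental H-bond into an existing water bridge
                if a_polar and b.is_water and dist <= self.HBOND_GUARD:
                    return False
                if kind == "water" and bool(self._polar_fn(b)) and dist <= self.HBOND_GUARD:
                    return False
        return True

    def place_entity(self, kind: str, label: str, chrom_atom: str, target: float,
                     res_seq: int, res_name: str | None = None) -> tuple[list[Atom], dict]:
        if chrom_atom not in self.chrom_name_index:
            raise InfeasiblePlacementError(f"{label}: unknown chromophore atom {chrom_atom!r}")
        anchor_chrom = self.chrom_name_index[chrom_atom]
        x = self.chrom_xyz[anchor_chrom]
        for u in self.directions:
            origin = np.round(x + target * u, 3)
            if kind == "water":
                atoms = [Atom(0, "O", "", "HOH", "A", res_seq, "", origin, hetero=True)]
            else:
                atoms = _place_residue(kind, origin, u, res_seq, res_name)
            if self._feasible(atoms, kind, target, anchor_chrom, None):
                self.placed.extend(atoms)
                entity = {
                    "label": label, "kind": kind, "res_seq": res_seq,
                    "res_name": atoms[0].res_name, "anchor_atom": atoms[0].name,
                    "chrom_atom": chrom_atom, "target_min_distance": target,
                    "direction": u.tolist(),
                }
                return atoms, entity
        raise InfeasiblePlacementError(f"{label}: no feasible direction at {target} Å from {chrom_atom}")

    def place_partner(self, wb: WaterBridgeSpec, k: int, res_seq: int) -> tuple[list[Atom], dict]:
        w = self.water_pos[wb.label]
        anchor_chrom = self.chrom_name_index[wb.chrom_atom]
        x = self.chrom_xyz[anchor_chrom]
        u_w = _unit(w - x)
        d1, d2, dc = wb.leg1, wb.leg2, wb.partner_chrom_distance
        cosphi = (dc ** 2 - d1 ** 2 - d2 ** 2) / (2.0 * d1 * d2)
        if not -1.0 <= cosphi <= 1.0:
            raise InfeasiblePlacementError(
                f"{wb.label}: bridge triangle {d1}/{d2}/{dc} Å is not realizable")
        sinphi = np.sqrt(1.0 - cosphi ** 2)
        e1, e2 = _perp_basis(u_w)
        label = f"{wb.label}_p{k + 1}"
        for psi in np.linspace(0.0, 2.0 * np.pi, 181)[:-1]:
            direction = cosphi * u_w + sinphi * (np.cos(psi) * e1 + np.sin(psi) * e2)
            p = np.round(w + d2 * direction, 3)
            u_p = _unit(p - w)
            atoms = _place_residue("polar", p, u_p, res_seq)
            if self._feasible(atoms, "bridge_partner", dc, anchor_chrom, wb.label):
                # re-check the water leg after rounding
                if abs(np.linalg.norm(atoms[0].xyz - w) - d2) > 0.01:
                    continue
                self.placed.extend(atoms)
                self.partner_of[res_seq] = wb.label
                entity = {
                    "label": label, "kind": "bridge_partner", "res_seq": res_seq,
                    "res_name": atoms[0].res_name, "anchor_atom": atoms[0].name,
                    "chrom_atom": wb.chrom_atom, "target_min_distance": dc,
                    "via_water": wb.label, "direction": u_p.tolist(),
                }
                return atoms, entity
        raise InfeasiblePlacementError(f"{label}: no feasible bridge azimuth")


def make_toy_structure(spec: GeneratorSpec) -> tuple[Structure, GeneratorManifest]:
    """Build the toy mini-protein described by ``spec`` and its manifest.

    Coordinates are quantized to 0.001 Å so PDB round-trips are exact;
    realized minimum distances match the requested targets to < 0.01 Å or
    an :class:`InfeasiblePlacementError` is raised.
    """
    chrom_coords = _chromophore_atoms()
    atoms: list[Atom] = []
    for name, pos in chrom_coords.items():
        atoms.append(Atom(0, name, "", "CRO", "A", 66, "", np.round(pos, 3), hetero=True))
    # hydroxyl proton, trans to the carbonyl by default
    u_oc = _unit(chrom_coords["O2"] - chrom_coords["OH"])
    h_pos = chrom_coords["OH"] - 0.96 * u_oc
    atoms.append(Atom(0, "HO", "", "CRO", "A", 66, "", np.round(h_pos, 3),
                      element="H", hetero=True))

    placer = _Placer(atoms)
    manifest = GeneratorManifest(seed=spec.seed)
    entities: list[dict] = []

    res_seq = 101
    for srs in spec.shell:
        res_atoms, entity = placer.place_entity(
            srs.kind, srs.label, srs.chrom_atom, srs.min_distance, res_seq)
        atoms.extend(res_atoms)
        entities.append(entity)
        res_seq += 1

    water_seq = 201
    partner_seq = 301
    for wb in spec.water_bridges:
        w_atoms, entity = placer.place_entity("water", wb.label, wb.chrom_atom, wb.leg1, water_seq)
        atoms.extend(w_atoms)
        entities.append(entity)
        placer.water_pos[wb.label] = w_atoms[0].xyz
        for k in range(wb.n_partners):
            p_atoms, p_entity = placer.place_partner(wb, k, partner_seq)
            atoms.extend(p_atoms)
            entities.append(p_entity)
            partner_seq += 1
        water_seq += 1

    s = Structure(atoms=atoms, metadata={"origin": "fpchrom synthetic toy"})
    for i, a in enumerate(s.atoms, start=1):
        a.serial = i
    manifest.entities = entities
    _verify_placement(s, manifest)
    manifest.expected_counts = _expected_counts(manifest)
    return s, manifest


def _verify_placement(s: Structure, manifest: GeneratorManifest,
                      hbond_cutoff: float = 3.3, hydrophobic_cutoff: float = 4.0) -> None:
    """Check every entity realizes its target and causes no side interactions."""
    from .contacts import is_apolar_carbon, polar_capability   # local import: avoid cycle

    chrom_idx = [i for i, a in enumerate(s.atoms)
                 if a.res_seq == manifest.chrom_res_seq and not a.is_hydrogen]
    chrom_xyz = np.array([s.atoms[i].xyz for i in chrom_idx])
    problems: list[str] = []
    by_seq = {e["res_seq"]: e for e in manifest.entities}

    for rref, indices in s.residues():
        if rref.res_seq == manifest.chrom_res_seq:
            continue
        ent = by_seq.get(rref.res_seq)
        heavy = [i for i in indices if not s.atoms[i].is_hydrogen]
        xyz = np.array([s.atoms[i].xyz for i in heavy])
        dmat = np.linalg.norm(xyz[:, None, :] - chrom_xyz[None, :, :], axis=-1)
        dmin = float(dmat.min())
        if ent is None:
            problems.append(f"unexpected residue {rref}")
            continue
        ent["realized_min_distance"] = round(dmin, 4)
        if abs(dmin - ent["target_min_distance"]) > 0.01:
            problems.append(
                f"{ent['label']}: realized min distance {dmin:.3f} != target "
                f"{ent['target_min_distance']:.3f}")
        nearest = s.atoms[heavy[int(np.unravel_index(dmat.argmin(), dmat.shape)[0])]].name
        if nearest != ent["anchor_atom"]:
            problems.append(f"{ent['label']}: nearest atom is {nearest}, expected {ent['anchor_atom']}")
        # unintended direct H-bonds / hydrophobic contacts
        for i in heavy:
            a = s.atoms[i]
            for j, c in enumerate(chrom_idx):
                d = float(np.linalg.norm(a.xyz - s.atoms[c].xyz))
                ca = s.atoms[c]
                if (polar_capability(a) and polar_capability(ca) and d <= hbond_cutoff
                        and not (ent["kind"] in ("polar", "water") and a.name == ent["anchor_atom"])):
                    problems.append(f"{ent['label']}: unintended polar contact {a.name}..{ca.name} {d:.2f}")
                if (is_apolar_carbon(a) and is_apolar_carbon(ca) and d <= hydrophobic_cutoff
                        and ent["kind"] != "hydrophobic"):
                    problems.append(f"{ent['label']}: unintended apolar contact {a.name}..{ca.name} {d:.2f}")
    # bridge legs
    for ent in manifest.entities:
        if ent["kind"] != "bridge_partner":
            continue
        water = manifest.entity(ent["via_water"])
        w = s.atoms[s.find_atom("A", water["res_seq"], "O")].xyz
        p = s.atoms[s.find_atom("A", ent["res_seq"], ent["anchor_atom"])].xyz
        leg = float(np.linalg.norm(w - p))
        ent["realized_leg2"] = round(leg, 4)
        if leg > hbond_cutoff:
            problems.append(f"{ent['label']}: water leg {leg:.2f} exceeds {hbond_cutoff}")
    if problems:
        raise InfeasiblePlacementError("; ".join(problems))


def _expected_counts(manifest: GeneratorManifest, radius: float = 4.0,
                     hbond_cutoff: float = 3.3, hydrophobic_cutoff: float = 4.0) -> dict:
    shell = direct = mediated = hydrophobic = unclassified = waters = 0
    for e in manifest.entities:
        d = e["target_min_distance"]
        if e["kind"] == "water":
            waters += 1
            continue
        if d > radius:
            continue
        shell += 1
        if e["kind"] == "polar" and d <= hbond_cutoff:
            direct += 1
        elif e["kind"] == "bridge_partner":
            mediated += 1
        elif e["kind"] == "hydrophobic" and d <= hydrophobic_cutoff:
            hydrophobic += 1
        else:
            unclassified += 1
    return {
        "shell": shell, "direct_hbond": direct, "water_mediated": mediated,
        "hydrophobic": hydrophobic, "unclassified": unclassified, "n_waters": waters,
    }


# ---------------------------------------------------------------------------
# make_ensemble
# ---------------------------------------------------------------------------

def _markov_series(rng: np.random.Generator, n: int, occupancy: float,
                   mean_dwell: float) -> np.ndarray:
    """Two-state chain with given stationary occupancy and mean on-dwell."""
    b = 1.0 / mean_dwell                       # P(on -> off)
    a = occupancy * b / (1.0 - occupancy)      # P(off -> on)
    if a > 1.0:
        raise ValueError(
            f"occupancy {occupancy} with dwell {mean_dwell} frames requires "
            f"off->on probability {a:.3f} > 1")
    out = np.empty(n, dtype=bool)
    state = rng.random() < occupancy
    for i in range(n):
        out[i] = state
        r = rng.random()
        state = (r >= b) if state else (r < a)
    return out


def make_ensemble(
    base: Structure,
    spec: GeneratorSpec,
    manifest: GeneratorManifest | None = None,
) -> tuple[Ensemble, GeneratorManifest]:
    """Generate a synthetic ensemble on ``base`` with known dynamics.

    Frame i is the base coordinates plus i.i.d. Gaussian noise (per-atom σ),
    except: Markov-switched contact acceptors are pinned at the on/off
    distance along the placement axis from the (noisy) donor, and the
    hydroxyl proton is placed exactly in the sampled trans/cis geometry.
    Those atoms carry no noise of their own, so occupancy, dwell and state
    populations are exactly the recorded Markov/Bernoulli draws.
    """
    if spec.n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if manifest is None:
        manifest = GeneratorManifest(seed=spec.seed)
    rng = np.random.default_rng(spec.seed)
    n_atoms = len(base.atoms)
    base_xyz = base.coords

    sigma = np.full(n_atoms, float(spec.sigma))
    for (chain, seq, name), s_val in spec.sigma_overrides.items():
        sigma[base.find_atom(chain, seq, name)] = s_val

    chrom = identify_chromophore(base, manifest.chrom_chain)

    # resolve Markov-switched contacts
    toggled = []
    for cs in spec.contacts:
        ent = manifest.entity(cs.label)
        if ent["kind"] != "polar":
            raise ValueError(f"contact spec {cs.label!r} must reference a polar shell residue")
        donor_idx = chrom.index(ent["chrom_atom"])
        acceptor_idx = base.find_atom("A", ent["res_seq"], ent["anchor_atom"])
        u = np.asarray(ent["direction"])
        series = _markov_series(rng, spec.n_frames, cs.occupancy, cs.mean_dwell_frames)
        toggled.append((cs, donor_idx, acceptor_idx, u, series))
        sigma[acceptor_idx] = 0.0

    h_idx = chrom.hydroxyl_h_index
    states = None
    if spec.dipole is not None:
        if h_idx is None:
            raise ValueError("base structure has no hydroxyl proton; cannot impose dipole states")
        states = rng.random(spec.n_frames) < spec.dipole.trans_fraction   # True = trans
        sigma[h_idx] = 0.0
    oh_idx = chrom.index("OH")
    o2_idx = chrom.index("O2")

    noise = rng.normal(size=(spec.n_frames, n_atoms, 3)) * sigma[None, :, None]
    frames = base_xyz[None, :, :] + noise

    for cs, donor_idx, acceptor_idx, u, series in toggled:
        dist = np.where(series, cs.on_distance, cs.off_distance)
        frames[:, acceptor_idx] = frames[:, donor_idx] + dist[:, None] * u[None, :]
    if states is not None:
        axis = frames[:, o2_idx] - frames[:, oh_idx]
        axis /= np.linalg.norm(axis, axis=1, keepdims=True)
        sign = np.where(states, -1.0, 1.0)    # trans: away from carbonyl
        frames[:, h_idx] = frames[:, oh_idx] + 0.96 * sign[:, None] * axis

    frames = np.round(frames, 6)   # exact text round-trips

    ens = Ensemble(base, frames, dt=spec.dt, origin_label=f"fpchrom synthetic seed={spec.seed}")

    # ground truth bookkeeping
    centered = noise - noise.mean(axis=0, keepdims=True)
    realized_rmsf = np.sqrt(np.mean(np.sum(centered ** 2, axis=2), axis=0))
    contact_truth = {}
    for cs, donor_idx, acceptor_idx, u, series in toggled:
        runs = _run_lengths(series)
        contact_truth[cs.label] = {
            "occupancy": cs.occupancy,
            "mean_dwell_frames": cs.mean_dwell_frames,
            "series": series,
            "realized_pr_oc": float(series.mean()),
            "realized_mean_dwell_frames": float(runs.mean()) if runs.size else 0.0,
            "n_events": int(runs.size),
        }
    manifest.ensemble = {
        "n_frames": spec.n_frames, "dt": spec.dt,
        "sigma": sigma, "rmsf_closed_form": sigma * np.sqrt(3.0),
        "realized_rmsf": realized_rmsf,
        "frozen_atoms": np.flatnonzero(sigma == 0.0),
        "contacts": contact_truth,
    }
    if states is not None:
        manifest.ensemble["dipole"] = {
            "trans_fraction": spec.dipole.trans_fraction,
            "states": states,
            "realized_trans_fraction": float(states.mean()),
        }
    return ens, manifest


def _run_lengths(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=int)
    d = np.diff(np.concatenate(([0], x, [0])))
    return np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
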