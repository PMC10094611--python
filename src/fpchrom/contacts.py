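"""Geometric interaction detection around the chromophore in a static structure.

Crystal structures carry no hydrogens, so the hydrogen-bond criterion here is
heavy-atom based: a donor-capable and an acceptor-capable polar atom within a
distance cutoff (default 3.3 Å).  No donor-angle term is applied in static
mode — a documented limitation of hydrogen-free coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    Atom,
    AtomRef,
    ChromophoreModel,
    ResidueRef,
    Structure,
)

DEFAULT_HBOND_CUTOFF = 3.3      # Å, chromophore-shell convention
DEFAULT_HYDROPHOBIC_CUTOFF = 4.0  # Å, conventional van-der-Waals contact
DEFAULT_SHELL_RADIUS = 4.0      # Å


class ContactKind(str, Enum):
    HBOND = "hbond"
    WATER_MEDIATED = "water_mediated"
    HYDROPHOBIC = "hydrophobic"
    PI_PI = "pi_pi"


@dataclass
class ContactRecord:
    """One geometric interaction with its participants and metric.

    ``metric`` is a distance in Å (or an angle in degrees for π–π records);
    ``via_water`` names the bridging water for water-mediated H-bonds.
    """

    kind: ContactKind
    donor: AtomRef | None
    acceptor: AtomRef | None
    partners: tuple[ResidueRef, ResidueRef]
    metric: float
    via_water: ResidueRef | None = None

    def __post_init__(self) -> None:
        if self.metric <= 0:
            raise ValueError("contact metric must be positive")
        if self.kind == ContactKind.HBOND and (self.donor is None or self.acceptor is None):
            raise ValueError("hbond record requires donor and acceptor")
        if self.kind == ContactKind.WATER_MEDIATED and self.via_water is None:
            raise ValueError("water-mediated record requires via_water")


# ---------------------------------------------------------------------------
# Donor / acceptor capability table (heavy-atom convention)
# ---------------------------------------------------------------------------

# capability is 'donor', 'acceptor' or 'both'; side chains per residue type,
# His ND1/NE2 ambivalent, waters ambivalent, backbone N donor / O acceptor.
_SIDECHAIN_POLAR: dict[str, dict[str, str]] = {
    "SER": {"OG": "both"},
    "THR": {"OG1": "both"},
    "TYR": {"OH": "both"},
    "ASN": {"OD1": "acceptor", "ND2": "donor"},
    "GLN": {"OE1": "acceptor", "NE2": "donor"},
    "ASP": {"OD1": "acceptor", "OD2": "acceptor"},
    "GLU": {"OE1": "acceptor", "OE2": "acceptor"},
    "HIS": {"ND1": "both", "NE2": "both"},
    "LYS": {"NZ": "donor"},
    "ARG": {"NE": "donor", "NH1": "donor", "NH2": "donor"},
    "TRP": {"NE1": "donor"},
}

# weak sulfur acceptors, off by default
_SULFUR_POLAR: dict[str, dict[str, str]] = {
    "CYS": {"SG": "acceptor"},
    "MET": {"SD": "acceptor"},
}

# matured-chromophore polar atoms (CRO-style names)
_CHROMOPHORE_POLAR: dict[str, str] = {
    "N1": "donor",      # amino-terminal ring nitrogen
    "N2": "acceptor",   # imidazolinone =N-
    "N3": "both",
    "O2": "acceptor",   # imidazolinone carbonyl
    "O3": "acceptor",
    "OH": "both",       # phenolic hydroxyl
    "OG1": "both",      # Thr65-derived variants
}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}
# chromophore pseudo-backbone (links to residues i-1 / i+1)
_CHROM_BACKBONE = {"N1", "C3", "O3", "CA1", "CA3", "N", "CA", "C", "O"}


def polar_capability(atom: Atom, include_sulfur: bool = False) -> str | None:
    """Return 'donor' / 'acceptor' / 'both' for H-bond-capable heavy atoms."""
    if atom.is_water:
        return "both" if atom.element == "O" else None
    if atom.name == "N" and atom.res_name != "PRO":
        return "donor"
    if atom.name in ("O", "OXT"):
        return "acceptor"
    cap = _SIDECHAIN_POLAR.get(atom.res_name, {}).get(atom.name)
    if cap:
        return cap
    if include_sulfur:
        cap = _SULFUR_POLAR.get(atom.res_name, {}).get(atom.name)
        if cap:
            return cap
    if atom.res_name not in _STANDARD_AA:
        cap = _CHROMOPHORE_POLAR.get(atom.name)
        if cap:
            return cap
        # unknown hetero residue: any N/O treated as ambivalent
        if atom.element in ("N", "O"):
            return "both"
    return None


# ---------------------------------------------------------------------------
# Apolar carbon table (carbon not bonded to N/O, by name convention)
# ---------------------------------------------------------------------------

_APOLAR_CARBONS: dict[str, set[str]] = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "PRO": {"CB", "CG"},
    "MET": {"CB", "CG", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "LYS": {"CB", "CG", "CD"},
    "ARG": {"CB", "CG"},
    "GLN": {"CB", "CG"},
    "GLU": {"CB", "CG"},
    "ASN": {"CB"},
    "ASP": {"CB"},
    "HIS": {"CB"},
    "CYS": {"CB"},
    "THR": {"CG2"},
}

# chromophore apolar carbons: bridge + phenol ring carbons not bearing O/N
_CHROM_APOLAR = {"CB2", "CG2", "CD1", "CD2", "CE1", "CE2", "CB1", "CG1"}


def is_apolar_carbon(atom: Atom) -> bool:
    if atom.element != "C":
        return False
    if atom.res_name in _APOLAR_CARBONS:
        return atom.name in _APOLAR_CARBONS[atom.res_name]
    if atom.res_name in _STANDARD_AA or atom.is_water:
        return False
    return atom.name in _CHROM_APOLAR


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def _are_covalent_neighbours(a: Atom, b: Atom) -> bool:
    """Backbone-link exclusion: sequence-adjacent backbone atoms share 1-2/1-3 bonds."""
    if a.chain_id != b.chain_id or abs(a.res_seq - b.res_seq) != 1:
        return False
    bb_a = a.name in _BACKBONE_NAMES or (a.res_name not in _STANDARD_AA and a.name in _CHROM_BACKBONE)
    bb_b = b.name in _BACKBONE_NAMES or (b.res_name not in _STANDARD_AA and b.name in _CHROM_BACKBONE)
    return bb_a and bb_b


def find_hbonds(
    s: Structure,
    selection_a: Sequence[int],
    selection_b: Sequence[int],
    cutoff: float = DEFAULT_HBOND_CUTOFF,
    include_sulfur: bool = False,
) -> list[ContactRecord]:
    """Heavy-atom hydrogen bonds between two atom selections.

    One record per donor/acceptor-compatible polar pair with distance
    ≤ ``cutoff``; covalently bonded and same-residue pairs are excluded.
    Records are sorted by distance.  Symmetric in its two selections.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not selection_a or not selection_b:
        raise ValueError("selections must be non-empty")

    polar_a = [(i, polar_capability(s.atoms[i], include_sulfur)) for i in selection_a]
    polar_a = [(i, c) for i, c in polar_a if c]
    polar_b = [(i, polar_capability(s.atoms[i], include_sulfur)) for i in selection_b]
    polar_b = [(i, c) for i, c in polar_b if c]
    if not polar_a or not polar_b:
        warnings.warn("empty polar-atom set in a selection; no H-bonds possible", stacklevel=2)
        return []

    xyz_a = np.array([s.atoms[i].xyz for i, _ in polar_a])
    xyz_b = np.array([s.atoms[i].xyz for i, _ in polar_b])
    pairs = cKDTree(xyz_a).query_ball_tree(cKDTree(xyz_b), r=cutoff)

    seen: set[tuple[int, int]] = set()
    records: list[ContactRecord] = []
    for ia, hits in enumerate(pairs):
        i, cap_i = polar_a[ia]
        for ib in hits:
            j, cap_j = polar_b[ib]
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            a, b = s.atoms[i], s.atoms[j]
            if (a.chain_id, a.res_seq, a.i_code) == (b.chain_id, b.res_seq, b.i_code):
                continue
            if _are_covalent_neighbours(a, b):
                continue
            i_donates = cap_i in ("donor", "both") and cap_j in ("acceptor", "both")
            j_donates = cap_j in ("donor", "both") and cap_i in ("acceptor", "both")
            if not (i_donates or j_donates):
                continue
            seen.add(key)
            d = float(np.linalg.norm(a.xyz - b.xyz))
            donor, acceptor = (a, b) if i_donates else (b, a)
            records.append(ContactRecord(
                kind=ContactKind.HBOND,
                donor=donor.ref(), acceptor=acceptor.ref(),
                partners=(a.residue_ref(), b.residue_ref()),
                metric=d,
            ))
    records.sort(key=lambda r: r.metric)
    return records


def find_water_mediated(
    s: Structure,
    chrom: ChromophoreModel,
    cutoff: float = DEFAULT_HBOND_CUTOFF,
) -> list[ContactRecord]:
    """Water bridges chromophore···W···residue with both legs ≤ ``cutoff``.

    One record per (chromophore polar atom, water O, residue polar atom)
    triple; ``metric`` is the longer leg, ``via_water`` the bridging water.
    """
    chrom_res_seqs = chrom._res_seqs()
    chrom_chain = chrom.residue_ref.chain_id
    chrom_polar = [i for i in chrom.heavy_atom_indices() if polar_capability(s.atoms[i])]
    waters = [i for i, a in enumerate(s.atoms) if a.is_water and a.element == "O"]
    if not waters or not chrom_polar:
        return []
    other_polar = []
    for i, a in enumerate(s.atoms):
        if a.is_water or a.is_hydrogen:
            continue
        if a.chain_id == chrom_chain and a.res_seq in chrom_res_seqs:
            continue
        if polar_capability(a):
            other_polar.append(i)

    w_xyz = np.array([s.atoms[i].xyz for i in waters])
    c_xyz = np.array([s.atoms[i].xyz for i in chrom_polar])
    p_xyz = np.array([s.atoms[i].xyz for i in other_polar])
    w_tree = cKDTree(w_xyz)
    leg1 = cKDTree(c_xyz).query_ball_tree(w_tree, r=cutoff)   # chrom -> water
    leg2 = w_tree.query_ball_tree(cKDTree(p_xyz), r=cutoff)   # water -> residue

    records: list[ContactRecord] = []
    for ic, whits in enumerate(leg1):
        ci = chrom_polar[ic]
        for iw in whits:
            wi = waters[iw]
            d1 = float(np.linalg.norm(s.atoms[ci].xyz - s.atoms[wi].xyz))
            for ip in leg2[iw]:
                pi = other_polar[ip]
                d2 = float(np.linalg.norm(s.atoms[wi].xyz - s.atoms[pi].xyz))
                records.append(ContactRecord(
                    kind=ContactKind.WATER_MEDIATED,
                    donor=s.atoms[ci].ref(), acceptor=s.atoms[pi].ref(),
                    partners=(s.atoms[ci].residue_ref(), s.atoms[pi].residue_ref()),
                    metric=max(d1, d2),
                    via_water=s.atoms[wi].residue_ref(),
                ))
    records.sort(key=lambda r: r.metric)
    return records


def find_hydrophobic(
    s: Structure,
    chrom: ChromophoreModel,
    cutoff: float = DEFAULT_HYDROPHOBIC_CUTOFF,
) -> list[ContactRecord]:
    """Apolar-carbon contacts between the chromophore and other residues.

    Pairs of apolar carbons within ``cutoff`` are aggregated per residue;
    each record reports the residue's closest approach.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    chrom_res_seqs = chrom._res_seqs()
    chrom_chain = chrom.residue_ref.chain_id
    chrom_c = [i for i in chrom.heavy_atom_indices() if is_apolar_carbon(s.atoms[i])]
    other_c = [
        i for i, a in enumerate(s.atoms)
        if is_apolar_carbon(a) and not (a.chain_id == chrom_chain and a.res_seq in chrom_res_seqs)
    ]
    if not chrom_c or not other_c:
        return []
    c_xyz = np.array([s.atoms[i].xyz for i in chrom_c])
    o_xyz = np.array([s.atoms[i].xyz for i in other_c])
    hits = cKDTree(c_xyz).query_ball_tree(cKDTree(o_xyz), r=cutoff)

    best: dict[ResidueRef, float] = {}
    for ic, row in enumerate(hits):
        for io in row:
            a, b = s.atoms[chrom_c[ic]], s.atoms[other_c[io]]
            d = float(np.linalg.norm(a.xyz - b.xyz))
            rref = b.residue_ref()
            if rref not in best or d < best[rref]:
                best[rref] = d
    records = [
        ContactRecord(
            kind=ContactKind.HYDROPHOBIC, donor=None, acceptor=None,
            partners=(chrom.residue_ref, rref), metric=d,
        )
        for rref, d in best.items()
    ]
    records.sort(key=lambda r: r.metric)
    return records


@dataclass
class ShellReport:
    """Census of the chromophore's nearest residue shell with classification.

    The three classified subsets come from the direct-H-bond, water-bridge
    and hydrophobic detectors; a shell member may appear in more than one
    subset, and members matching none are listed as ``unclassified``.
    """

    shell_residues: list[ResidueRef]
    direct_hbond_residues: list[ResidueRef]
    water_mediated_residues: list[ResidueRef]
    hydrophobic_residues: list[ResidueRef]
    contacts: list[ContactRecord] = field(default_factory=list)
    radius: float = DEFAULT_SHELL_RADIUS

    @property
    def unclassified(self) -> list[ResidueRef]:
        classified = set(self.direct_hbond_residues) | set(self.water_mediated_residues) | set(self.hydrophobic_residues)
        return [r for r in self.shell_residues if r not in classified]


def shell_census(
    s: Structure,
    chrom: ChromophoreModel,
    radius: float = DEFAULT_SHELL_RADIUS,
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
    hydrophobic_cutoff: float = DEFAULT_HYDROPHOBIC_CUTOFF,
) -> ShellReport:
    """Residues with any heavy atom within ``radius`` of any chromophore
    heavy atom (waters and the chromophore itself excluded), classified by
    interaction type.

    The chromophore's covalent neighbour residues (the backbone links at
    either end) are excluded when their only atoms within the radius are
    the linking backbone atoms.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    chrom_idx = chrom.heavy_atom_indices()
    chrom_xyz = np.array([s.atoms[i].xyz for i in chrom_idx])
    tree = cKDTree(chrom_xyz)
    chrom_res_seqs = chrom._res_seqs()
    chrom_chain = chrom.residue_ref.chain_id

    # residues covalently linked to the chromophore termini
    link_seqs = {min(chrom_res_seqs) - 1, max(chrom_res_seqs) + 1}

    shell: list[ResidueRef] = []
    for rref, indices in s.residues(exclude_water=True):
        if rref.chain_id == chrom_chain and rref.res_seq in chrom_res_seqs:
            continue
        within = []
        for i in indices:
            a = s.atoms[i]
            if a.is_hydrogen:
                continue
            if tree.query_ball_point(a.xyz, r=radius):
                within.append(a.name)
        if not within:
            continue
        if rref.chain_id == chrom_chain and rref.res_seq in link_seqs:
            # drop if only the linking backbone atoms reach the shell
            if all(name in _BACKBONE_NAMES for name in within):
                continue
        shell.append(rref)

    shell_set = set(shell)
    chrom_sel = chrom_idx
    other_sel = [
        i for i, a in enumerate(s.atoms)
        if not a.is_water and not a.is_hydrogen
        and not (a.chain_id == chrom_chain and a.res_seq in chrom_res_seqs)
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hb = find_hbonds(s, chrom_sel, other_sel, cutoff=hbond_cutoff) if other_sel else []
    wm = find_water_mediated(s, chrom, cutoff=hbond_cutoff)
    hp = find_hydrophobic(s, chrom, cutoff=hydrophobic_cutoff)

    def _other(rec: ContactRecord) -> ResidueRef:
        p, q = rec.partners
        return q if (p.chain_id == chrom_chain and p.res_seq in chrom_res_seqs) else p

    direct = sorted({_other(r) for r in hb} & shell_set, key=lambda r: (r.chain_id, r.res_seq))
    mediated = sorted({_other(r) for r in wm} & shell_set, key=lambda r: (r.chain_id, r.res_seq))
    hydrophobic = sorted({_other(r) for r in hp} & shell_set, key=lambda r: (r.chain_id, r.res_seq))
    return ShellReport(
        shell_residues=shell,
        direct_hbond_residues=direct,
        water_mediated_residues=mediated,
        hydrophobic_residues=hydrophobic,
        contacts=hb + wm + hp,
        radius=radius,
    )


def contacts_to_tsv(records: Sequence[ContactRecord]) -> str:
    """One ContactRecord per line: kind, partners, atoms, metric, via_water."""
    lines = ["kind\tchain_a\tres_a\tatom_a\tchain_b\tres_b\tatom_b\tmetric\tvia_water"]
    for r in records:
        p, q = r.partners
        atom_a = r.donor.name if r.donor else ""
        atom_b = r.acceptor.name if r.acceptor else ""
        via = str(r.via_water) if r.via_water else ""
        lines.append(
            f"{r.kind.value}\t{p.chain_id}\t{p.res_name}{p.res_seq}\t{atom_a}\t"
            f"{q.chain_id}\t{q.res_name}{q.res_seq}\t{atom_b}\t{r.metric:.2f}\t{via}")
    return "\n".join(lines) + "\n"
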