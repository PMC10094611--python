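"""Dimer-interface quantification: buried surface area, cross-chain H-bonds
with the two-fold symmetry counting convention, and the hydrophobic cluster.

Buried ("contact") area is the total ΔSASA summed over both subunits:
SASA(A alone) + SASA(B alone) − SASA(A∪B), waters excluded.  The default
interface H-bond cutoff is 3.7 Å — deliberately looser than the 3.3 Å
chromophore-shell convention, so that long polar pairs around 3.6 Å at a
dimer seam are retained; both cutoffs are configurable per call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .contacts import ContactRecord, find_hbonds, is_apolar_carbon
from .structure_io import ResidueRef, Structure

#: element radii (Å) for the solvent-accessible surface
ELEMENT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
FALLBACK_RADIUS = 1.70
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960
DEFAULT_INTERFACE_HBOND_CUTOFF = 3.7


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa(
    s: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    indices: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Å² (Shrake–Rupley).

    Each atom's expanded sphere (vdW radius + probe) is sampled with
    ``n_points`` golden-spiral points; a point is accessible when outside
    every neighbour's expanded sphere.  ``indices`` restricts which atoms
    are *scored* (all atoms still occlude).  Unknown elements fall back to
    the carbon radius with a warning.
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable surface estimate")
    atoms = s.atoms
    n = len(atoms)
    if n == 0:
        return np.zeros(0)
    radii = np.empty(n)
    for i, a in enumerate(atoms):
        r = ELEMENT_RADII.get(a.element)
        if r is None:
            warnings.warn(f"unknown element {a.element!r} for atom {a.name}; using {FALLBACK_RADIUS} Å",
                          stacklevel=2)
            r = FALLBACK_RADIUS
        radii[i] = r + probe
    xyz = s.coords
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(xyz)
    score = range(n) if indices is None else indices
    out = np.zeros(n)
    rmax = radii.max()
    for i in score:
        pts = xyz[i] + radii[i] * sphere
        neigh = [j for j in tree.query_ball_point(xyz[i], r=radii[i] + rmax) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", pts - xyz[j], pts - xyz[j])
            accessible &= d2 > radii[j] ** 2
        out[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return out


def _chain_subset(s: Structure, chains: Iterable[str]) -> Structure:
    chains = {chains} if isinstance(chains, str) else set(chains)
    idx = [i for i, a in enumerate(s.atoms) if a.chain_id in chains and not a.is_water]
    if not idx:
        raise ValueError(f"no non-water atoms in chains {sorted(chains)}")
    return s.subset(idx)


def buried_area(
    s: Structure,
    chains_a: str | Iterable[str],
    chains_b: str | Iterable[str],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    half: bool = False,
) -> float:
    """Interface buried area between two chain sets, Å².

    Total ΔSASA over both subunits (≈ 2 × half-interface); pass
    ``half=True`` for the per-subunit convention.  Waters are excluded.
    Symmetric in its two arguments by construction.
    """
    set_a = {chains_a} if isinstance(chains_a, str) else set(chains_a)
    set_b = {chains_b} if isinstance(chains_b, str) else set(chains_b)
    if not set_a or not set_b:
        raise ValueError("chain sets must be non-empty")
    if set_a & set_b:
        raise ValueError(f"chain sets must be disjoint (both contain {sorted(set_a & set_b)})")
    sub_a = _chain_subset(s, set_a)
    sub_b = _chain_subset(s, set_b)
    both = _chain_subset(s, set_a | set_b)
    area = sasa(sub_a, probe, n_points).sum() + sasa(sub_b, probe, n_points).sum() \
        - sasa(both, probe, n_points).sum()
    area = float(max(area, 0.0))
    return area / 2.0 if half else area


@dataclass
class InterfaceReport:
    """Summary of one dimer interface.

    ``hbonds`` is the unique cross-chain bond list; ``hbond_count_total``
    applies the two-fold symmetry convention when ``doubling_applied``:
    a bond whose partners are the same residue on the two chains counts
    once, every other bond twice.
    """

    chains_a: frozenset[str]
    chains_b: frozenset[str]
    buried_area: float
    hbonds: list[ContactRecord]
    hbond_count_total: int
    hydrophobic_cluster: list[ResidueRef]
    doubling_applied: bool
    hbond_cutoff: float = DEFAULT_INTERFACE_HBOND_CUTOFF

    def to_dict(self) -> dict:
        return {
            "chains_a": sorted(self.chains_a),
            "chains_b": sorted(self.chains_b),
            "buried_area_A2": round(self.buried_area, 1),
            "hbond_count_total": self.hbond_count_total,
            "doubling_applied": self.doubling_applied,
            "hbond_cutoff_A": self.hbond_cutoff,
            "hbonds": [
                {
                    "donor": f"{r.donor.chain_id}:{r.donor.res_name}{r.donor.res_seq}:{r.donor.name}",
                    "acceptor": f"{r.acceptor.chain_id}:{r.acceptor.res_name}{r.acceptor.res_seq}:{r.acceptor.name}",
                    "distance_A": round(r.metric, 2),
                }
                for r in self.hbonds
            ],
            "hydrophobic_cluster": [str(r) for r in self.hydrophobic_cluster],
        }


def _bond_signature(r: ContactRecord) -> frozenset:
    """Chain-blind unordered signature of a bond: {(res_seq, res_name, atom)}₂."""
    return frozenset({
        (r.donor.res_seq, r.donor.res_name, r.donor.name),
        (r.acceptor.res_seq, r.acceptor.res_name, r.acceptor.name),
    })


def interface_hbonds(
    s: Structure,
    chains_a: str | Iterable[str],
    chains_b: str | Iterable[str],
    cutoff: float = DEFAULT_INTERFACE_HBOND_CUTOFF,
    doubling: bool = True,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    compute_area: bool = True,
    hydrophobic_cutoff: float = 4.0,
) -> InterfaceReport:
    """Cross-chain hydrogen bonds and the hydrophobic cluster at an interface.

    Detection runs on the coordinates as deposited; the two-fold doubling is
    purely a reporting convention (the structure's own second copy of a bond
    may deviate from perfect symmetry, so counting uses the unique list).
    """
    set_a = {chains_a} if isinstance(chains_a, str) else set(chains_a)
    set_b = {chains_b} if isinstance(chains_b, str) else set(chains_b)
    if set_a & set_b:
        raise ValueError(f"chain sets must be disjoint (both contain {sorted(set_a & set_b)})")
    sel_a = [i for i, a in enumerate(s.atoms) if a.chain_id in set_a and not a.is_water and not a.is_hydrogen]
    sel_b = [i for i, a in enumerate(s.atoms) if a.chain_id in set_b and not a.is_water and not a.is_hydrogen]
    if not sel_a or not sel_b:
        raise ValueError("empty chain selection")
    raw = find_hbonds(s, sel_a, sel_b, cutoff=cutoff)

    # deduplicate symmetry copies by chain-blind signature, keep shortest
    unique: dict[frozenset, ContactRecord] = {}
    for r in raw:
        sig = _bond_signature(r)
        if sig not in unique or r.metric < unique[sig].metric:
            unique[sig] = r
    bonds = sorted(unique.values(), key=lambda r: r.metric)

    if doubling:
        total = 0
        for r in bonds:
            self_symmetric = (r.donor.res_seq, r.donor.res_name) == (r.acceptor.res_seq, r.acceptor.res_name)
            total += 1 if self_symmetric else 2
    else:
        total = len(bonds)

    # hydrophobic cluster: residues with cross-chain apolar-carbon contacts
    apolar_a = [i for i in sel_a if is_apolar_carbon(s.atoms[i])]
    apolar_b = [i for i in sel_b if is_apolar_carbon(s.atoms[i])]
    cluster: set[tuple[int, str]] = set()
    refs: dict[tuple[int, str], ResidueRef] = {}
    if apolar_a and apolar_b:
        xa = np.array([s.atoms[i].xyz for i in apolar_a])
        xb = np.array([s.atoms[i].xyz for i in apolar_b])
        hits = cKDTree(xa).query_ball_tree(cKDTree(xb), r=hydrophobic_cutoff)
        for ia, row in enumerate(hits):
            for ib in row:
                for i in (apolar_a[ia], apolar_b[ib]):
                    a = s.atoms[i]
                    key = (a.res_seq, a.res_name)
                    cluster.add(key)
                    refs.setdefault(key, a.residue_ref())
    cluster_refs = [refs[k] for k in sorted(cluster)]

    area = buried_area(s, set_a, set_b, probe=probe, n_points=n_points) if compute_area else float("nan")
    return InterfaceReport(
        chains_a=frozenset(set_a), chains_b=frozenset(set_b),
        buried_area=area, hbonds=bonds, hbond_count_total=total,
        hydrophobic_cluster=cluster_refs, doubling_applied=doubling,
        hbond_cutoff=cutoff,
    )
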