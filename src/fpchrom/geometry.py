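"""Rigid-body superposition and chromophore geometry.

Least-squares (Kabsch) fitting, probe-atom displacement between two fitted
structures, ring least-squares planes, inter-plane angles (acute convention)
and minimum side-chain distances.  Degrees and ångströms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import Structure


class PairingError(ValueError):
    """Fit selections could not be matched 1:1; message lists the misses."""


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class Superposition:
    """Optimal rigid transform mapping mobile onto reference: x' = R·x + t."""

    rotation: np.ndarray      # 3×3, det = +1
    translation: np.ndarray   # Å
    rmsd: float               # Å over the fit atoms
    n_fit_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise PairingError(f"need >= 3 paired atoms, got shapes {mobile.shape}/{reference.shape}")
    # collinearity check via the second principal moment
    centered = mobile - mobile.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-8 * max(svals[0], 1.0):
        raise DegenerateGeometryError("fit atoms are collinear; superposition is ill-defined")
    mu_m, mu_r = mobile.mean(axis=0), reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - mu_r, mobile - mu_m)
    R = rot.as_matrix()
    t = mu_r - R @ mu_m
    rmsd = float(rssd / np.sqrt(mobile.shape[0]))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_fit_atoms=mobile.shape[0])


def _pair_selection(
    mobile: Structure,
    reference: Structure,
    fit_selection: str | Sequence[tuple[int, str]] = "ca",
    chain_mobile: str | None = None,
    chain_reference: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair atoms by (res_seq, atom name) between the two structures.

    ``fit_selection='ca'`` uses Cα atoms of residues common to both (the
    intersection — mutation sites contribute backbone only); an explicit
    list of (res_seq, name) must resolve in both or a PairingError lists
    the misses.
    """
    def table(s: Structure, chain: str | None) -> dict[tuple[int, str], np.ndarray]:
        out = {}
        for a in s.atoms:
            if chain is not None and a.chain_id != chain:
                continue
            if a.is_water:
                continue
            out.setdefault((a.res_seq, a.name), a.xyz)
        return out

    tab_m = table(mobile, chain_mobile)
    tab_r = table(reference, chain_reference)
    if fit_selection == "ca":
        keys = sorted(k for k in tab_m if k[1] == "CA" and k in tab_r)
        if len(keys) < 3:
            raise PairingError("fewer than 3 common CA atoms between structures")
    elif fit_selection == "heavy":
        keys = sorted(k for k in tab_m if k in tab_r)
    else:
        keys = list(fit_selection)
        missing = [k for k in keys if k not in tab_m or k not in tab_r]
        if missing:
            raise PairingError(f"fit atoms unmatched in one structure: {missing}")
    return (np.array([tab_m[k] for k in keys]), np.array([tab_r[k] for k in keys]))


def superpose(
    mobile: Structure,
    reference: Structure,
    fit_selection: str | Sequence[tuple[int, str]] = "ca",
    chain_mobile: str | None = None,
    chain_reference: str | None = None,
) -> Superposition:
    """Least-squares optimal rigid-body fit of ``mobile`` onto ``reference``."""
    m, r = _pair_selection(mobile, reference, fit_selection, chain_mobile, chain_reference)
    return _kabsch(m, r)


def atom_shift(
    mobile: Structure,
    reference: Structure,
    fit_selection: str | Sequence[tuple[int, str]] = "ca",
    probe_atom: tuple[str, int, str] | str = "OH",
    chain_mobile: str | None = None,
    chain_reference: str | None = None,
) -> float:
    """Displacement (Å) of one probe atom after rigid-body fitting.

    ``probe_atom`` is (chain, res_seq, name) or a bare atom name searched in
    the fitted chains (the phenolic OH for mutant-vs-precursor shifts).
    """
    sup = superpose(mobile, reference, fit_selection, chain_mobile, chain_reference)

    def locate(s: Structure, chain_hint: str | None) -> np.ndarray:
        if isinstance(probe_atom, tuple):
            chain, res_seq, name = probe_atom
            return s.atoms[s.find_atom(chain, res_seq, name)].xyz
        for a in s.atoms:
            if a.name == probe_atom and (chain_hint is None or a.chain_id == chain_hint) and not a.is_water:
                return a.xyz
        raise KeyError(f"probe atom {probe_atom!r} not found")

    p_m = locate(mobile, chain_mobile)
    p_r = locate(reference, chain_reference)
    return float(np.linalg.norm(sup.apply(p_m) - p_r))


@dataclass
class RingPlane:
    """Least-squares plane through a ring: centroid, unit normal, planarity RMS."""

    centroid: np.ndarray
    normal: np.ndarray
    planarity_rms: float


def ring_plane(coords: np.ndarray) -> RingPlane:
    """Best-fit plane via the smallest principal direction of the coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3 or coords.shape[1] != 3:
        raise ValueError("ring_plane needs an (n>=3, 3) coordinate array")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-8 * max(svals[0], 1.0):
        raise DegenerateGeometryError("ring atoms are collinear; plane is ill-defined")
    normal = vt[2]
    # deterministic sign: first nonzero component positive
    for c in normal:
        if abs(c) > 1e-12:
            if c < 0:
                normal = -normal
            break
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return RingPlane(centroid=centroid, normal=normal / np.linalg.norm(normal), planarity_rms=rms)


def plane_angle(p: RingPlane, q: RingPlane) -> float:
    """Acute angle between two planes, degrees, in [0, 90]."""
    c = abs(float(np.dot(p.normal, q.normal)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors, degrees, in [0, 180]."""
    u, v = np.asarray(u, float), np.asarray(v, float)
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def min_sidechain_distance(
    s: Structure,
    res_a: tuple[str, int],
    atoms_a: Sequence[str],
    res_b: tuple[str, int],
    atoms_b: Sequence[str],
) -> float:
    """Minimum pairwise distance (Å) between two named atom sets.

    The His-vs-hydroxyl convention is {ND1, NE2} against {OH}.
    """
    def gather(res: tuple[str, int], names: Sequence[str]) -> np.ndarray:
        chain, seq = res
        pts = [a.xyz for a in s.atoms if a.chain_id == chain and a.res_seq == seq and a.name in set(names)]
        if not pts:
            raise ValueError(f"no atoms {list(names)} in residue {chain}:{seq}")
        return np.array(pts)

    xa = gather(res_a, atoms_a)
    xb = gather(res_b, atoms_b)
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    return float(d.min())
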