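"""Dynamic observables on conformational ensembles.

Per-residue RMSF after least-squares fitting, contact occupancy and
lifetime statistics, π–π stacking occupancy, and the chromophore
dipole-moment state analysis (modulus, orientation to the phenol CG2→CZ
axis, cis/trans hydroxyl classification).

Conventions: a frame's contact state is boolean under a geometric
criterion; lifetimes are maximal runs of consecutive presence times the
frame spacing dt (ps); dipole moments are in debye (1 e·Å = 4.8032 D).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import ring_plane, vector_angle, _kabsch
from .structure_io import ChromophoreModel, Ensemble

E_ANGSTROM_TO_DEBYE = 4.8032

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

STATE_MAJOR_TRANS = "major_trans"
STATE_MINOR_CIS = "minor_cis"


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

@dataclass
class RMSFProfile:
    """Per-residue RMSF (Å) plus the per-atom values behind it."""

    entries: list[tuple[str, int, str, float]]   # (chain, res_seq, res_name, rmsf)
    per_atom: np.ndarray
    fit_selection: str
    atom_scope: str

    def value(self, chain: str, res_seq: int) -> float:
        for c, seq, _, v in self.entries:
            if c == chain and seq == res_seq:
                return v
        raise KeyError(f"residue {chain}:{res_seq} not in profile")


def _kabsch_batch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched Kabsch: optimal rotations mapping each frame's fit atoms onto
    ``reference``.  Returns (rotations, mobile centroids, reference centroid)."""
    mu = mobile.mean(axis=1, keepdims=True)              # (F, 1, 3)
    ref_mu = reference.mean(axis=0)
    h = np.einsum("fni,nj->fij", mobile - mu, reference - ref_mu)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("fji,fkj->fik", vt, u)))
    sign = np.ones((mobile.shape[0], 3))
    sign[:, 2] = d
    rot = np.einsum("fji,fj,fkj->fik", vt, sign, u)      # V diag(1,1,d) U^T
    return rot, mu, ref_mu


def _fit_frames(frames: np.ndarray, fit_idx: np.ndarray, n_iter: int = 3) -> np.ndarray:
    """Least-squares fit every frame onto the (iteratively refined) average."""
    fitted = frames.copy()
    ref = fitted[0, fit_idx]
    for _ in range(n_iter):
        rot, mu, ref_mu = _kabsch_batch(fitted[:, fit_idx], ref)
        fitted = np.einsum("fni,fij->fnj", fitted - mu, np.transpose(rot, (0, 2, 1))) + ref_mu
        ref = fitted[:, fit_idx].mean(axis=0)
    return fitted


def rmsf(
    e: Ensemble,
    fit_selection: str = "ca",
    atom_scope: str = "sidechain_heavy",
    equil_fraction: float = 0.25,
) -> RMSFProfile:
    """Per-residue RMSF over the equilibrated tail of an ensemble.

    The leading ``equil_fraction`` of frames is discarded (default: keep
    the final 75%).  Frames are rigid-body fitted to the average structure
    on ``fit_selection`` ('ca' or 'heavy'); per-atom RMSF is the root mean
    squared deviation from the mean position, and the per-residue value is
    the unweighted mean over ``atom_scope`` atoms ('sidechain_heavy',
    'heavy' or 'ca').  Glycine, lacking a side chain, falls back to Cα.
    """
    n0 = int(np.floor(e.n_frames * equil_fraction))
    frames = e.frames[n0:]
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames after equilibration trimming")
    atoms = e.topology.atoms
    if fit_selection == "ca":
        fit_idx = np.array([i for i, a in enumerate(atoms) if a.name == "CA" and not a.is_water])
    elif fit_selection == "heavy":
        fit_idx = np.array([i for i, a in enumerate(atoms) if not a.is_hydrogen and not a.is_water])
    else:
        raise ValueError(f"unknown fit_selection {fit_selection!r}")
    if fit_idx.size < 3:
        raise ValueError("fit selection resolves to fewer than 3 atoms")

    fitted = _fit_frames(frames, fit_idx)
    mean = fitted.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))

    entries = []
    for rref, indices in e.topology.residues(exclude_water=True):
        if atom_scope == "sidechain_heavy":
            scope = [i for i in indices
                     if not atoms[i].is_hydrogen and atoms[i].name not in _BACKBONE_NAMES]
            if not scope:  # Gly
                scope = [i for i in indices if atoms[i].name == "CA"]
        elif atom_scope == "heavy":
            scope = [i for i in indices if not atoms[i].is_hydrogen]
        elif atom_scope == "ca":
            scope = [i for i in indices if atoms[i].name == "CA"]
        else:
            raise ValueError(f"unknown atom_scope {atom_scope!r}")
        if not scope:
            continue
        entries.append((rref.chain_id, rref.res_seq, rref.res_name, float(per_atom[scope].mean())))
    return RMSFProfile(entries=entries, per_atom=per_atom,
                       fit_selection=fit_selection, atom_scope=atom_scope)


# ---------------------------------------------------------------------------
# Contact occupancy / lifetimes
# ---------------------------------------------------------------------------

@dataclass
class OccupancySeries:
    """Per-frame presence of one contact (or contact group) with summaries.

    ``pr_oc`` is the exact fraction of present frames; lifetimes are maximal
    runs of consecutive presence × dt.  For grouped series,
    ``mean_count_per_frame`` is the mean number of member contacts present
    per frame (for a single contact it equals pr_oc).
    """

    label: str
    present: np.ndarray           # bool per frame
    dt: float                     # ps
    mean_count_per_frame: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.mean_count_per_frame is None:
            self.mean_count_per_frame = float(self.present.mean()) if self.present.size else 0.0

    @property
    def pr_oc(self) -> float:
        return float(self.present.mean()) if self.present.size else 0.0

    @property
    def event_lengths(self) -> np.ndarray:
        """Lengths (frames) of maximal runs of presence."""
        x = self.present.astype(int)
        if x.size == 0:
            return np.zeros(0, dtype=int)
        d = np.diff(np.concatenate(([0], x, [0])))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        return ends - starts

    @property
    def n_events(self) -> int:
        return int(self.event_lengths.size)

    @property
    def mean_lifetime(self) -> float:
        """Mean event duration, ps; 0.0 when no events."""
        lengths = self.event_lengths
        return float(lengths.mean() * self.dt) if lengths.size else 0.0


@dataclass
class HBondCriterion:
    """Geometric H-bond test on ensemble frames.

    With a hydrogen given: donor–acceptor distance ≤ d_max AND
    H–donor–acceptor angle ≤ angle_max (default 3.5 Å / 30°).  Without
    hydrogens (heavy-atom fallback) the criterion is distance-only at
    3.3 Å, matching static-structure practice.
    """

    label: str
    donor: int
    acceptor: int
    hydrogen: int | None = None
    d_max: float = None  # type: ignore[assignment]
    angle_max: float = 30.0

    def __post_init__(self) -> None:
        if self.d_max is None:
            self.d_max = 3.5 if self.hydrogen is not None else 3.3

    def evaluate(self, frames: np.ndarray) -> np.ndarray:
        n_atoms = frames.shape[1]
        for idx in (self.donor, self.acceptor) + ((self.hydrogen,) if self.hydrogen is not None else ()):
            if not 0 <= idx < n_atoms:
                raise IndexError(f"criterion {self.label!r}: atom index {idx} outside topology ({n_atoms} atoms)")
        d_vec = frames[:, self.acceptor] - frames[:, self.donor]
        dist = np.linalg.norm(d_vec, axis=1)
        ok = dist <= self.d_max
        if self.hydrogen is not None:
            h_vec = frames[:, self.hydrogen] - frames[:, self.donor]
            cosang = np.einsum("ij,ij->i", h_vec, d_vec) / (
                np.linalg.norm(h_vec, axis=1) * dist + 1e-300)
            ok &= np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= self.angle_max
        return ok


def contact_occupancy(
    e: Ensemble,
    criteria: Sequence[HBondCriterion],
    group_label: str | None = None,
) -> list[OccupancySeries]:
    """Occupancy series for each criterion, plus one grouped series when
    ``group_label`` is given (present = any member present; the group's
    ``mean_count_per_frame`` is the mean number of members present)."""
    out = [OccupancySeries(c.label, c.evaluate(e.frames), dt=e.dt) for c in criteria]
    if group_label is not None and out:
        stack = np.stack([s.present for s in out])
        out.append(OccupancySeries(
            group_label, stack.any(axis=0), dt=e.dt,
            mean_count_per_frame=float(stack.sum(axis=0).mean()),
        ))
    return out


def pipi_occupancy(
    e: Ensemble,
    ring_a: Sequence[int],
    ring_b: Sequence[int],
    d_max: float = 5.5,
    angle_max: float = 30.0,
    label: str = "pi_pi",
) -> OccupancySeries:
    """π–π stacking presence: ring-centroid distance ≤ d_max AND
    inter-plane angle ≤ angle_max, per frame."""
    ring_a = np.asarray(ring_a, dtype=int)
    ring_b = np.asarray(ring_b, dtype=int)
    if ring_a.size < 3 or ring_b.size < 3:
        raise ValueError("each ring needs >= 3 atoms")
    present = np.empty(e.n_frames, dtype=bool)
    for k in range(e.n_frames):
        pa = ring_plane(e.frames[k, ring_a])
        pb = ring_plane(e.frames[k, ring_b])
        d = float(np.linalg.norm(pa.centroid - pb.centroid))
        ang = float(np.degrees(np.arccos(np.clip(abs(np.dot(pa.normal, pb.normal)), -1, 1))))
        present[k] = (d <= d_max) and (ang <= angle_max)
    return OccupancySeries(label, present, dt=e.dt)


# ---------------------------------------------------------------------------
# Dipole-moment states
# ---------------------------------------------------------------------------

@dataclass
class DipoleSeries:
    """Per-frame chromophore-fragment dipole moment.

    The fragment may carry net charge, making the moment origin-dependent;
    the reference point (fragment heavy-atom centroid) is therefore part of
    the contract and reported in ``reference_point``.
    """

    dm_vector: np.ndarray        # (n_frames, 3), debye
    axis_angle: np.ndarray       # degrees vs CG2→CZ, in [0, 180]
    reference_point: str
    net_charge: float
    state: np.ndarray | None = None   # per-frame state labels after classification

    @property
    def dm_modulus(self) -> np.ndarray:
        return np.linalg.norm(self.dm_vector, axis=1)


def dipole_series(
    e: Ensemble,
    chrom: ChromophoreModel,
    include_hydroxyl_h: bool = True,
) -> DipoleSeries:
    """Fragment dipole moment per frame from partial charges.

    dm = Σᵢ qᵢ (rᵢ − r_ref) with r_ref the fragment heavy-atom centroid of
    that frame, converted to debye; the orientation is the angle to the
    phenol-ring CG2→CZ vector.  Every fragment atom must have a charge.
    """
    if chrom.charges is None:
        raise ValueError("chromophore model carries no charge table")
    frag = chrom.fragment_indices()
    atoms = e.topology.atoms
    names = [atoms[i].name for i in frag]
    missing = [n for n in names if n not in chrom.charges]
    if missing:
        raise ValueError(f"missing partial charges for chromophore atoms: {', '.join(sorted(missing))}")
    idx = list(frag)
    q = [chrom.charges[n] for n in names]
    if include_hydroxyl_h and chrom.hydroxyl_h_index is not None:
        h_name = atoms[chrom.hydroxyl_h_index].name
        if h_name in chrom.charges:
            idx.append(chrom.hydroxyl_h_index)
            q.append(chrom.charges[h_name])
    q = np.asarray(q)

    frag_arr = np.asarray(frag)
    idx_arr = np.asarray(idx)
    ref = e.frames[:, frag_arr].mean(axis=1)                       # (n, 3)
    disp = e.frames[:, idx_arr] - ref[:, None, :]                  # (n, m, 3)
    dm = np.einsum("m,nmk->nk", q, disp) * E_ANGSTROM_TO_DEBYE

    cg2, cz = chrom.index("CG2"), chrom.index("CZ")
    axis = e.frames[:, cz] - e.frames[:, cg2]
    cosang = np.einsum("nk,nk->n", dm, axis) / (
        np.linalg.norm(dm, axis=1) * np.linalg.norm(axis, axis=1) + 1e-300)
    angles = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    return DipoleSeries(
        dm_vector=dm, axis_angle=angles,
        reference_point="fragment heavy-atom centroid",
        net_charge=float(q.sum()),
    )


def classify_states(
    d: DipoleSeries,
    e: Ensemble,
    chrom: ChromophoreModel,
) -> tuple[DipoleSeries, dict]:
    """Assign each frame to the trans (major) or cis (minor) hydroxyl state.

    The phenolic O–H bond vector is compared with the direction from the
    phenol oxygen to the imidazolinone carbonyl oxygen: an angle < 90°
    (proton pointing toward the carbonyl) is cis, otherwise trans.  Requires
    the hydroxyl proton in the topology — frames cannot be classified from
    heavy atoms alone, and no silent proxy is used.
    """
    if chrom.hydroxyl_h_index is None:
        raise ValueError("hydroxyl hydrogen absent from topology; cis/trans state undefined")
    oh = chrom.index("OH")
    o2 = chrom.index("O2")
    h = chrom.hydroxyl_h_index
    ohv = e.frames[:, h] - e.frames[:, oh]
    toward = e.frames[:, o2] - e.frames[:, oh]
    cosang = np.einsum("nk,nk->n", ohv, toward) / (
        np.linalg.norm(ohv, axis=1) * np.linalg.norm(toward, axis=1) + 1e-300)
    theta = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    state = np.where(theta < 90.0, STATE_MINOR_CIS, STATE_MAJOR_TRANS)
    d.state = state

    mod = d.dm_modulus
    summary: dict[str, dict[str, float]] = {}
    n = state.size
    for name in (STATE_MAJOR_TRANS, STATE_MINOR_CIS):
        mask = state == name
        entry = {"population": float(mask.sum()) / n}
        if mask.any():
            entry.update(
                dm_mean=float(mod[mask].mean()), dm_sd=float(mod[mask].std()),
                angle_mean=float(d.axis_angle[mask].mean()), angle_sd=float(d.axis_angle[mask].std()),
            )
        summary[name] = entry
    return d, summary


@dataclass
class Density2D:
    """Normalized 2D probability density over (dm_modulus, axis_angle)."""

    mod_edges: np.ndarray
    angle_edges: np.ndarray
    density: np.ndarray        # (n_mod_bins, n_angle_bins)

    def integral(self) -> float:
        areas = np.outer(np.diff(self.mod_edges), np.diff(self.angle_edges))
        return float((self.density * areas).sum())

    def mode(self) -> tuple[float, float]:
        """(modulus, angle) at the density maximum (bin centers)."""
        i, j = np.unravel_index(np.argmax(self.density), self.density.shape)
        return (
            float(0.5 * (self.mod_edges[i] + self.mod_edges[i + 1])),
            float(0.5 * (self.angle_edges[j] + self.angle_edges[j + 1])),
        )


def density2d(d: DipoleSeries, bins: int | tuple = 50) -> Density2D:
    """Normalized 2D histogram of dipole modulus vs axis angle."""
    mod = d.dm_modulus
    if mod.size == 0:
        raise ValueError("empty dipole series")
    hist, mod_edges, angle_edges = np.histogram2d(mod, d.axis_angle, bins=bins, density=True)
    if hist.size == 0 or np.any(np.diff(mod_edges) <= 0) or np.any(np.diff(angle_edges) <= 0):
        raise ValueError("degenerate bin specification")
    return Density2D(mod_edges=mod_edges, angle_edges=angle_edges, density=hist)
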