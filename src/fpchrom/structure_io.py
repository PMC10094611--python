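"""Read/write PDB-format structures and multi-frame ensembles.

Fixed-column PDB reading (ATOM/HETATM/MODEL/ENDMDL/TER/CRYST1) with an
explicit alt-loc policy, plus a whitespace XYZ-per-frame dialect for
conformational ensembles.  Coordinates are orthogonal ångströms throughout;
no symmetry expansion is performed (deposited files are taken verbatim).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

#: canonical chromophore atom names (CRO-style) for the three moieties
IMIDAZOLINONE_RING = ("C1", "N2", "CA2", "C2", "N3")
PHENOL_RING = ("CG2", "CD1", "CD2", "CE1", "CE2", "CZ")
BRIDGE = ("CA2", "CB2", "CG2")
CARBONYL_O = "O2"
PHENOL_OH = "OH"

#: residue names commonly used for matured GFP-family chromophores
CHROMOPHORE_RESNAMES = {"CRO", "CR2", "CR8", "GYS", "GYC", "CSY", "NRQ", "CFY"}


class PDBParseError(ValueError):
    """Malformed fixed-column record; message names the offending line."""


class ModelNotFoundError(KeyError):
    pass


class ChromophoreNotFoundError(LookupError):
    pass


class ChromophoreIntegrityError(ValueError):
    """Chromophore candidate found but ring atoms are missing."""


@dataclass(frozen=True)
class AtomRef:
    """Lightweight handle naming one atom: (chain, res_seq, res_name, atom name)."""

    chain_id: str
    res_seq: int
    res_name: str
    name: str

    def residue(self) -> "ResidueRef":
        return ResidueRef(self.chain_id, self.res_seq, self.res_name)


@dataclass(frozen=True)
class ResidueRef:
    chain_id: str
    res_seq: int
    res_name: str

    def __str__(self) -> str:  # e.g. E:HIS148
        return f"{self.chain_id}:{self.res_name}{self.res_seq}"


@dataclass
class Atom:
    """One ATOM/HETATM record; coordinates in Å, b_factor in Å²."""

    serial: int
    name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    xyz: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    element: str = ""
    hetero: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: xyz must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not self.element:
            self.element = _element_from_name(self.name)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    def ref(self) -> AtomRef:
        return AtomRef(self.chain_id, self.res_seq, self.res_name, self.name)

    def residue_ref(self) -> ResidueRef:
        return ResidueRef(self.chain_id, self.res_seq, self.res_name)


def _element_from_name(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return ""
    # two-letter elements occurring in protein work (CA/NA are ambiguous with
    # alpha-carbon / sodium-vs-amide names and resolved as C/N instead)
    if len(stripped) == 2 and stripped.upper() in {"FE", "ZN", "MG", "MN", "CL", "BR"}:
        return stripped.capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


@dataclass
class Structure:
    """Flat, ordered atom container for one model of a PDB entry."""

    atoms: list[Atom] = field(default_factory=list)
    model_id: int = 1
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array, file order."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.atoms)}, 3)")
        for atom, row in zip(self.atoms, coords):
            atom.xyz = row.copy()

    def copy(self) -> "Structure":
        out = Structure(model_id=self.model_id, metadata=dict(self.metadata))
        for a in self.atoms:
            out.atoms.append(
                Atom(a.serial, a.name, a.alt_loc, a.res_name, a.chain_id, a.res_seq,
                     a.i_code, a.xyz.copy(), a.occupancy, a.b_factor, a.element, a.hetero)
            )
        return out

    # -- selection helpers -------------------------------------------------
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def atom_indices(
        self,
        chain: str | Iterable[str] | None = None,
        res_seq: int | Iterable[int] | None = None,
        names: Iterable[str] | None = None,
        heavy_only: bool = False,
        exclude_water: bool = False,
    ) -> list[int]:
        chains = None if chain is None else ({chain} if isinstance(chain, str) else set(chain))
        seqs = None if res_seq is None else ({res_seq} if isinstance(res_seq, int) else set(res_seq))
        nameset = None if names is None else set(names)
        out = []
        for i, a in enumerate(self.atoms):
            if chains is not None and a.chain_id not in chains:
                continue
            if seqs is not None and a.res_seq not in seqs:
                continue
            if nameset is not None and a.name not in nameset:
                continue
            if heavy_only and a.is_hydrogen:
                continue
            if exclude_water and a.is_water:
                continue
            out.append(i)
        return out

    def find_atom(self, chain: str, res_seq: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain_id == chain and a.res_seq == res_seq and a.name == name:
                return i
        raise KeyError(f"atom {chain}:{res_seq}:{name} not found")

    def residues(self, chain: str | None = None, exclude_water: bool = False) -> Iterator[tuple[ResidueRef, list[int]]]:
        """Yield (ResidueRef, atom indices) in file order."""
        current: tuple | None = None
        bucket: list[int] = []
        for i, a in enumerate(self.atoms):
            if chain is not None and a.chain_id != chain:
                continue
            if exclude_water and a.is_water:
                continue
            key = (a.chain_id, a.res_seq, a.i_code, a.res_name)
            if key != current:
                if current is not None:
                    yield ResidueRef(current[0], current[1], current[3]), bucket
                current, bucket = key, []
            bucket.append(i)
        if current is not None:
            yield ResidueRef(current[0], current[1], current[3]), bucket

    def subset(self, indices: Sequence[int]) -> "Structure":
        out = Structure(model_id=self.model_id, metadata=dict(self.metadata))
        for i in indices:
            a = self.atoms[i]
            out.atoms.append(
                Atom(a.serial, a.name, a.alt_loc, a.res_name, a.chain_id, a.res_seq,
                     a.i_code, a.xyz.copy(), a.occupancy, a.b_factor, a.element, a.hetero)
            )
        return out


# ---------------------------------------------------------------------------
# PDB parsing / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        alt_loc = line[16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip()
        res_seq = int(line[22:26])
        i_code = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        b_field = line[60:66].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        b_factor = float(b_field) if b_field else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {line.rstrip()!r}") from exc
    return Atom(serial, name, alt_loc, res_name, chain_id, res_seq, i_code,
                np.array([x, y, z]), occupancy, b_factor, element,
                hetero=line.startswith("HETATM"))


def _apply_altloc_policy(atoms: list[Atom]) -> tuple[list[Atom], int]:
    """Keep the highest-occupancy conformer per atom site (ties: blank/'A' first)."""
    best: dict[tuple, tuple[float, str, int]] = {}
    for i, a in enumerate(atoms):
        key = (a.chain_id, a.res_seq, a.i_code, a.res_name, a.name)
        rank = (a.occupancy, a.alt_loc == "" and " " or a.alt_loc)
        prev = best.get(key)
        # higher occupancy wins; on ties the lexicographically earliest alt_loc
        # (blank sorts before 'A') already stored wins
        if prev is None or a.occupancy > prev[0] or (a.occupancy == prev[0] and rank[1] < prev[1]):
            best[key] = (a.occupancy, rank[1], i)
    keep = sorted(idx for _, _, idx in best.values())
    kept = [atoms[i] for i in keep]
    for a in kept:
        a.alt_loc = ""
    return kept, len(atoms) - len(kept)


def parse_pdb(text: str, model: int | str = "first") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Parameters
    ----------
    text:
        Full PDB-format file contents.
    model:
        ``"first"`` (default) takes the first MODEL block (or the whole file
        when no MODEL records exist); an integer selects that MODEL number.

    Raises
    ------
    PDBParseError
        On a malformed fixed-column record (the message names the line).
    ModelNotFoundError
        When the requested MODEL number is absent.
    """
    models: dict[int, list[Atom]] = {}
    cryst1 = None
    current_model = None
    seen_model_record = False
    order: list[int] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            seen_model_record = True
            try:
                current_model = int(line[10:14])
            except ValueError as exc:
                raise PDBParseError(f"malformed MODEL record at line {lineno}") from exc
            if current_model not in models:
                models[current_model] = []
                order.append(current_model)
        elif rec == "ENDMDL":
            current_model = None
        elif rec in ("ATOM  ", "HETATM"):
            atom = _parse_atom_line(line, lineno)
            mid = current_model if current_model is not None else (order[0] if (seen_model_record and order) else 1)
            if not seen_model_record:
                mid = 1
            if mid not in models:
                models[mid] = []
                order.append(mid)
            models[mid].append(atom)
        elif rec == "CRYST1":
            cryst1 = line.rstrip()
    if not any(models.values()):
        raise PDBParseError("no ATOM/HETATM records found")

    if model == "first":
        model_id = order[0] if order else 1
    else:
        model_id = int(model)
        if model_id not in models:
            raise ModelNotFoundError(f"MODEL {model_id} not present (available: {sorted(models)})")
    atoms, n_dropped = _apply_altloc_policy(models[model_id])
    meta = {"altloc_policy": "highest-occupancy", "altloc_dropped": n_dropped}
    if cryst1:
        meta["cryst1"] = cryst1
    return Structure(atoms=atoms, model_id=model_id, metadata=meta)


def _format_atom_line(a: Atom, serial: int) -> str:
    rec = "HETATM" if a.hetero else "ATOM  "
    # PDB convention: 1-3 char names start in column 14 unless 4 chars long
    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
    return (
        f"{rec}{serial:5d} {name:<4s}{a.alt_loc or ' ':1s}{a.res_name:>3s} "
        f"{a.chain_id or ' ':1s}{a.res_seq:4d}{a.i_code or ' ':1s}   "
        f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.b_factor:6.2f}          {a.element:>2s}"
    )


def write_pdb(s: Structure, model_records: bool = False) -> str:
    """Serialize a Structure back to PDB text (fixed columns)."""
    lines = []
    if "cryst1" in s.metadata:
        lines.append(s.metadata["cryst1"])
    if model_records:
        lines.append(f"MODEL     {s.model_id:4d}")
    for i, a in enumerate(s.atoms, start=1):
        lines.append(_format_atom_line(a, i))
    if model_records:
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Chromophore identification
# ---------------------------------------------------------------------------

@dataclass
class ChromophoreModel:
    """Atom bookkeeping for a matured GFP-type chromophore.

    The three moieties of the conjugated system — imidazolinone ring,
    aryl-alkene bridge, phenolic ring — are resolved by CRO-style atom
    names; CG2 (ring carbon bonded to the bridge) and CZ (para carbon
    bearing the hydroxyl) define the phenol axis used in dipole analysis.
    """

    structure: Structure
    residue_ref: ResidueRef
    atom_index: dict[str, int]            # canonical name -> index into structure.atoms
    hydroxyl_h_index: int | None = None
    charges: dict[str, float] | None = None

    @property
    def imidazolinone_ring(self) -> list[AtomRef]:
        return [self.structure.atoms[self.atom_index[n]].ref() for n in IMIDAZOLINONE_RING]

    @property
    def bridge(self) -> list[AtomRef]:
        return [self.structure.atoms[self.atom_index[n]].ref() for n in BRIDGE]

    @property
    def phenol_ring(self) -> list[AtomRef]:
        names = PHENOL_RING + (PHENOL_OH,)
        return [self.structure.atoms[self.atom_index[n]].ref() for n in names]

    @property
    def carbonyl_O(self) -> AtomRef:
        return self.structure.atoms[self.atom_index[CARBONYL_O]].ref()

    def heavy_atom_indices(self) -> list[int]:
        """All heavy-atom indices of the chromophore residue (or triad)."""
        res_indices = set(self.atom_index.values())
        out = []
        for i, a in enumerate(self.structure.atoms):
            same_res = (a.chain_id == self.residue_ref.chain_id
                        and a.res_seq in self._res_seqs())
            if (same_res or i in res_indices) and not a.is_hydrogen:
                out.append(i)
        return sorted(set(out))

    def fragment_indices(self) -> list[int]:
        """Heavy atoms of the conjugated fragment (ring + bridge + phenol + O2/OH)."""
        names = set(IMIDAZOLINONE_RING) | set(BRIDGE) | set(PHENOL_RING) | {CARBONYL_O, PHENOL_OH}
        return sorted(self.atom_index[n] for n in names if n in self.atom_index)

    def _res_seqs(self) -> set[int]:
        return {self.structure.atoms[i].res_seq for i in self.atom_index.values()
                if self.structure.atoms[i].chain_id == self.residue_ref.chain_id}

    def index(self, name: str) -> int:
        return self.atom_index[name]

    def coords(self, name: str) -> np.ndarray:
        return self.structure.atoms[self.atom_index[name]].xyz


REQUIRED_CHROMOPHORE_ATOMS = set(IMIDAZOLINONE_RING) | {CARBONYL_O, "CB2"} | set(PHENOL_RING) | {PHENOL_OH}

#: mapping used when the chromophore is modelled as an uncyclized G-Y-G triad:
#: canonical CRO name -> (triad position 0/1/2, residue atom name)
_TRIAD_MAP = {
    "C1": (0, "C"), "N2": (1, "N"), "CA2": (1, "CA"), "C2": (1, "C"), "N3": (2, "N"),
    "O2": (1, "O"), "CB2": (1, "CB"),
    "CG2": (1, "CG"), "CD1": (1, "CD1"), "CD2": (1, "CD2"),
    "CE1": (1, "CE1"), "CE2": (1, "CE2"), "CZ": (1, "CZ"), "OH": (1, "OH"),
}


def identify_chromophore(
    s: Structure,
    chain: str,
    triad: tuple[int, int, int] | None = None,
    charges: dict[str, float] | None = None,
) -> ChromophoreModel:
    """Locate the chromophore in ``chain`` and resolve its moieties.

    Looks for a single hetero-residue with CRO-style atom names; a
    contiguous Gly-Tyr-Gly triad may instead be flagged explicitly via
    ``triad`` (three residue numbers).  Fails rather than guessing when
    ring atoms are missing.
    """
    if triad is not None:
        idx: dict[str, int] = {}
        missing = []
        for cname, (pos, aname) in _TRIAD_MAP.items():
            try:
                idx[cname] = s.find_atom(chain, triad[pos], aname)
            except KeyError:
                missing.append(f"{triad[pos]}:{aname}")
        if missing:
            raise ChromophoreIntegrityError(f"triad chromophore incomplete; missing atoms: {', '.join(missing)}")
        rref = s.atoms[idx["CA2"]].residue_ref()
        model = ChromophoreModel(s, rref, idx, charges=charges)
        model.hydroxyl_h_index = _find_hydroxyl_h(s, idx)
        return model

    candidates = []
    for rref, indices in s.residues(chain=chain, exclude_water=True):
        names = {s.atoms[i].name for i in indices}
        if rref.res_name in CHROMOPHORE_RESNAMES or REQUIRED_CHROMOPHORE_ATOMS <= names:
            candidates.append((rref, indices, names))
    if not candidates:
        raise ChromophoreNotFoundError(
            f"no chromophore residue found in chain {chain!r} "
            f"(looked for residue names {sorted(CHROMOPHORE_RESNAMES)} or CRO-style atom sets)")
    rref, indices, names = candidates[0]
    missing = sorted(REQUIRED_CHROMOPHORE_ATOMS - names)
    if missing:
        raise ChromophoreIntegrityError(
            f"chromophore {rref} incomplete; missing atoms: {', '.join(missing)}")
    idx = {s.atoms[i].name: i for i in indices if s.atoms[i].name in REQUIRED_CHROMOPHORE_ATOMS}
    model = ChromophoreModel(s, rref, idx, charges=charges)
    model.hydroxyl_h_index = _find_hydroxyl_h(s, idx, indices)
    return model


def _find_hydroxyl_h(s: Structure, idx: dict[str, int], res_indices: Sequence[int] | None = None) -> int | None:
    """The hydroxyl proton: any H within 1.2 Å of the phenolic OH oxygen."""
    oh = s.atoms[idx[PHENOL_OH]].xyz
    pool = res_indices if res_indices is not None else range(len(s.atoms))
    for i in pool:
        a = s.atoms[i]
        if a.is_hydrogen and np.linalg.norm(a.xyz - oh) <= 1.2:
            return i
    return None


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

@dataclass
class Ensemble:
    """Ordered coordinate frames sharing one topology; dt is frame spacing (ps)."""

    topology: Structure
    frames: np.ndarray          # (n_frames, n_atoms, 3) Å
    dt: float = 100.0
    origin_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.topology.atoms):
            raise ValueError(
                f"frames shape {self.frames.shape} incompatible with topology of "
                f"{len(self.topology.atoms)} atoms")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def structure_at(self, frame: int) -> Structure:
        s = self.topology.copy()
        s.set_coords(self.frames[frame])
        return s


class EnsembleShapeError(ValueError):
    pass


def read_ensemble(
    source: str | Iterable[str],
    topology: Structure,
    dt: float | None = None,
    origin_label: str = "",
) -> Ensemble:
    """Read a multi-MODEL PDB or XYZ-dialect ensemble text into an Ensemble.

    ``source`` is the file *contents* (or an iterable of per-frame PDB
    contents).  Frame atom counts must match the topology; a mismatch
    raises :class:`EnsembleShapeError` naming the frame.
    """
    if not isinstance(source, str):
        frames = []
        for k, text in enumerate(source):
            s = parse_pdb(text)
            if len(s.atoms) != len(topology.atoms):
                raise EnsembleShapeError(
                    f"frame {k}: {len(s.atoms)} atoms != topology {len(topology.atoms)}")
            frames.append(s.coords)
        return Ensemble(topology, np.array(frames), dt=dt or 100.0, origin_label=origin_label)

    stripped = source.lstrip()
    if stripped[:6] in ("ATOM  ", "HETATM", "MODEL ", "CRYST1", "HEADER", "REMARK"):
        return _read_multimodel_pdb(source, topology, dt, origin_label)
    return _read_xyz_frames(source, topology, dt, origin_label)


def _read_multimodel_pdb(text: str, topology: Structure, dt, origin_label) -> Ensemble:
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for line in text.splitlines():
        if line.startswith("MODEL"):
            current = []
        elif line.startswith("ENDMDL"):
            if current is not None:
                blocks.append(current)
            current = None
        elif line[:6] in ("ATOM  ", "HETATM") :
            if current is None:
                current = []
                blocks.append(current)
            current.append(line)
    frames = []
    for k, block in enumerate(blocks):
        atoms = [_parse_atom_line(line, 0) for line in block]
        if len(atoms) != len(topology.atoms):
            raise EnsembleShapeError(f"frame {k}: {len(atoms)} atoms != topology {len(topology.atoms)}")
        frames.append(np.array([a.xyz for a in atoms]))
    if not frames:
        raise PDBParseError("no coordinate frames found")
    return Ensemble(topology, np.array(frames), dt=dt or 100.0, origin_label=origin_label)


def _read_xyz_frames(text: str, topology: Structure, dt, origin_label) -> Ensemble:
    """XYZ dialect: header line ``natoms dt_ps``, then natoms × 'name x y z' per frame."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise PDBParseError("empty ensemble file")
    head = lines[0].split()
    try:
        natoms = int(head[0])
        file_dt = float(head[1]) if len(head) > 1 else None
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed XYZ header line: {lines[0]!r}") from exc
    if natoms != len(topology.atoms):
        raise EnsembleShapeError(f"header: {natoms} atoms != topology {len(topology.atoms)}")
    body = lines[1:]
    if len(body) % natoms != 0:
        raise EnsembleShapeError(
            f"frame {len(body) // natoms}: truncated ({len(body) % natoms} trailing lines)")
    n_frames = len(body) // natoms
    frames = np.empty((n_frames, natoms, 3))
    for f in range(n_frames):
        for i in range(natoms):
            parts = body[f * natoms + i].split()
            frames[f, i] = [float(parts[-3]), float(parts[-2]), float(parts[-1])]
    return Ensemble(topology, frames, dt=dt or file_dt or 100.0, origin_label=origin_label)


def write_ensemble_xyz(e: Ensemble, precision: int = 6) -> str:
    """Serialize an Ensemble in the XYZ dialect (header 'natoms dt_ps')."""
    buf = io.StringIO()
    buf.write(f"{e.frames.shape[1]} {e.dt:g}\n")
    names = [a.name for a in e.topology.atoms]
    fmt = f"{{}} {{:.{precision}f}} {{:.{precision}f}} {{:.{precision}f}}\n"
    for frame in e.frames:
        for name, (x, y, z) in zip(names, frame):
            buf.write(fmt.format(name, x, y, z))
    return buf.getvalue()


def write_ensemble_pdb(e: Ensemble) -> str:
    """Serialize an Ensemble as a multi-MODEL PDB."""
    out = []
    s = e.topology.copy()
    for k in range(e.n_frames):
        s.set_coords(e.frames[k])
        out.append(f"MODEL     {k + 1:4d}")
        for i, a in enumerate(s.atoms, start=1):
            out.append(_format_atom_line(a, i))
        out.append("ENDMDL")
    out.append("END")
    return "\n".join(out) + "\n"


def load_charge_table(text: str) -> dict[str, float]:
    """Parse a two-column 'atom_name charge_e' table ('#' comments allowed)."""
    charges: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        parts = body.split()
        if len(parts) != 2:
            raise ValueError(f"charge table line {lineno}: expected 'atom_name charge', got {line!r}")
        charges[parts[0]] = float(parts[1])
    return charges
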