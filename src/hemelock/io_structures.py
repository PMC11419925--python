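"""Coordinate I/O and geometric trajectory observables.

Structures are carried as plain atom lists parsed from fixed-column PDB
records; a multi-model PDB file (MODEL/ENDMDL blocks sharing one topology)
plays the role of a trajectory, so ensembles are testable without any MD
engine or binary trajectory format.  Residue numbering follows the mature
lignin-peroxidase convention in which the propeptide occupies residues
-7..-1; flexible termini (-7..-1 and 329..344) are excluded from RMSD by
default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    PDBParseError,
    SelectionError,
    TopologyMismatchError,
)

logger = logging.getLogger(__name__)

#: Default flexible-terminus residue ranges excluded from RMSD.
DEFAULT_TERMINAL_EXCLUSION = ((-7, -1), (329, 344))


@dataclass(frozen=True)
class Atom:
    """One atom of a coordinate record (PDB column conventions)."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    coords: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"atom {self.name}: non-finite coordinates")

    @property
    def key(self) -> tuple[str, int, str]:
        """(chain, residue number, atom name) identity triple."""
        return (self.chain_id, self.residue_seq, self.name)


@dataclass
class Structure:
    """An ordered atom list representing one coordinate snapshot."""

    atoms: list[Atom]
    numbering_note: str = "mature-protein numbering (propeptide -7..-1)"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a Structure must contain at least one atom")
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValueError(f"duplicate atom identity {dup}")

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in file order, Å."""
        return np.asarray([a.coords for a in self.atoms], dtype=float)

    @property
    def atom_keys(self) -> list[tuple[str, int, str]]:
        return [a.key for a in self.atoms]

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_name, a.chain_id,
                 a.residue_seq, tuple(float(x) for x in xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return Structure(atoms, self.numbering_note)

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        """Atoms grouped by (chain, residue number, residue name)."""
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault((a.chain_id, a.residue_seq, a.residue_name), []).append(a)
        return out


@dataclass
class Trajectory:
    """Frames sharing one topology, optionally time-stamped (ns)."""

    frames: list[Structure]
    frame_times: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a Trajectory must contain at least one frame")
        ref = self.frames[0].atom_keys
        for i, fr in enumerate(self.frames[1:], start=1):
            if fr.atom_keys != ref:
                raise TopologyMismatchError(
                    f"frame {i} atom topology differs from frame 0"
                )
        if self.frame_times is not None:
            t = self.frame_times
            if len(t) != len(self.frames):
                raise ValueError("frame_times length mismatch")
            if any(b <= a for a, b in zip(t, t[1:])):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class AtomSelection:
    """A resolved, duplicate-free index list into a Structure."""

    description: str
    indices: list[int]

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise SelectionError(f"duplicate indices in selection {self.description!r}")


def select(
    structure: Structure,
    chain: str | None = None,
    atom_names: Iterable[str] | None = None,
    residue_ranges: Sequence[tuple[int, int]] | None = None,
    exclude_residue_ranges: Sequence[tuple[int, int]] | None = None,
    residue_names: Iterable[str] | None = None,
    description: str | None = None,
) -> AtomSelection:
    """Build an AtomSelection from chain / residue-range / name predicates.

    ``residue_ranges`` and ``exclude_residue_ranges`` are inclusive
    (start, stop) pairs; exclusion is applied after inclusion.
    """
    names = set(atom_names) if atom_names is not None else None
    rnames = set(residue_names) if residue_names is not None else None

    def in_ranges(seq: int, ranges) -> bool:
        return any(lo <= seq <= hi for lo, hi in ranges)

    idx: list[int] = []
    for i, a in enumerate(structure.atoms):
        if chain is not None and a.chain_id != chain:
            continue
        if names is not None and a.name not in names:
            continue
        if rnames is not None and a.residue_name not in rnames:
            continue
        if residue_ranges is not None and not in_ranges(a.residue_seq, residue_ranges):
            continue
        if exclude_residue_ranges is not None and in_ranges(
            a.residue_seq, exclude_residue_ranges
        ):
            continue
        idx.append(i)
    desc = description or (
        f"chain={chain} names={sorted(names) if names else 'any'} "
        f"ranges={residue_ranges} excl={exclude_residue_ranges}"
    )
    return AtomSelection(desc, idx)


def ca_selection(
    structure: Structure,
    exclude_residue_ranges: Sequence[tuple[int, int]] = DEFAULT_TERMINAL_EXCLUSION,
) -> AtomSelection:
    """Cα atoms with the flexible termini excluded (the default RMSD set)."""
    return select(
        structure,
        atom_names=["CA"],
        exclude_residue_ranges=exclude_residue_ranges,
        description=f"CA excluding {exclude_residue_ranges}",
    )


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str]:
    """Parse one ATOM/HETATM record; returns (atom, altloc)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        residue_name = line[17:20].strip()
        chain_id = line[21] if line[21] != " " else "A"
        residue_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed coordinate record: {exc}") from exc
    if not element:
        # fall back on the atom-name convention: first alphabetic character
        element = next((c for c in name if c.isalpha()), "")
        if element and name[:2] in {"FE", "ZN", "MG", "MN", "CU"}:
            element = name[:2].capitalize()
    if not element:
        raise PDBParseError(f"line {lineno}: cannot infer element for atom {name!r}")
    try:
        atom = Atom(serial, name, element.upper() if len(element) == 1 else element,
                    residue_name, chain_id, residue_seq, (x, y, z))
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: {exc}") from exc
    return atom, altloc


def read_pdb(path) -> Structure | Trajectory:
    """Read a PDB file into a Structure (no MODEL records) or Trajectory.

    HETATM records (the heme) are retained.  Alternate locations other than
    blank or 'A' are dropped and counted in the log.  Unbalanced
    MODEL/ENDMDL blocks or per-model topology differences raise.
    """
    models: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    saw_model = False
    n_altloc_dropped = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if in_model:
                    raise PDBParseError(f"line {lineno}: nested MODEL record")
                in_model = True
                saw_model = True
                current = []
            elif rec == "ENDMDL":
                if not in_model:
                    raise PDBParseError(f"line {lineno}: ENDMDL without MODEL")
                in_model = False
                models.append(current)
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                atom, altloc = _parse_atom_line(line, lineno)
                if altloc not in (" ", "A"):
                    n_altloc_dropped += 1
                    continue
                current.append(atom)
    if in_model:
        raise PDBParseError("file ended inside an unterminated MODEL block")
    if n_altloc_dropped:
        logger.info("dropped %d alternate-location atoms (altloc not ' '/'A')",
                    n_altloc_dropped)

    if not saw_model:
        if not current:
            raise PDBParseError(f"{path}: no ATOM/HETATM records found")
        return Structure(current)

    if current:
        # coordinate records outside MODEL blocks in a multi-model file
        raise PDBParseError("coordinate records found outside MODEL blocks")
    frames = []
    for i, atoms in enumerate(models):
        if not atoms:
            raise PDBParseError(f"MODEL {i + 1} contains no atoms")
        frames.append(Structure(atoms))
    ref = frames[0].atom_keys
    for i, fr in enumerate(frames[1:], start=1):
        if len(fr.atoms) != len(ref):
            raise TopologyMismatchError(
                f"MODEL {i + 1} has {len(fr.atoms)} atoms, MODEL 1 has {len(ref)}"
            )
    return Trajectory(frames)  # Trajectory re-checks full key ordering


def _format_atom_line(a: Atom, serial: int) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    record = "HETATM" if a.residue_name in ("HEM", "HOH") or a.residue_name.startswith("HE") else "ATOM  "
    x, y, z = a.coords
    el = a.element[:2].rjust(2)
    return (
        f"{record}{serial:>5d} {name:<4.4s} {a.residue_name:>3.3s} {a.chain_id}"
        f"{a.residue_seq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {el}"
    )


def write_pdb(obj: Structure | Trajectory, path) -> None:
    """Write a Structure or a multi-model Trajectory in fixed-column PDB."""
    frames = obj.frames if isinstance(obj, Trajectory) else [obj]
    multi = isinstance(obj, Trajectory)
    with open(path, "w") as fh:
        for m, frame in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:>4d}\n")
            for i, a in enumerate(frame.atoms, start=1):
                fh.write(_format_atom_line(a, i) + "\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Superposition, RMSD, distance traces
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: Structure,
    reference: Structure,
    selection: AtomSelection,
) -> tuple[Structure, np.ndarray, np.ndarray]:
    """Least-squares rigid-body alignment of ``mobile`` onto ``reference``.

    Returns the transformed structure plus the proper rotation matrix R and
    translation t such that ``x_aligned = R @ (x - mobile_centroid) + t``.
    """
    if len(selection.indices) < 3:
        raise DegenerateGeometryError(
            f"superposition needs >=3 atoms, got {len(selection.indices)}"
        )
    mob = mobile.coords[selection.indices]
    ref = reference.coords[selection.indices]
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    mob0 = mob - mob_c
    if np.linalg.matrix_rank(mob0, tol=1e-8) < 2:
        raise DegenerateGeometryError("selected atoms are collinear")
    rot, _ = Rotation.align_vectors(ref - ref_c, mob0)
    R = rot.as_matrix()
    new_coords = (mobile.coords - mob_c) @ R.T + ref_c
    return mobile.with_coords(new_coords), R, ref_c


def rmsd(
    frame: Structure,
    reference: Structure,
    selection: AtomSelection,
    superpose: bool = False,
) -> float:
    """Root-mean-square coordinate deviation over the selection, Å."""
    if not selection.indices:
        raise SelectionError("RMSD over an empty selection")
    if superpose:
        frame, _, _ = kabsch_superpose(frame, reference, selection)
    d = frame.coords[selection.indices] - reference.coords[selection.indices]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def rmsd_trace(
    traj: Trajectory,
    reference: Structure,
    selection: AtomSelection,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD against a fixed reference."""
    return np.asarray(
        [rmsd(fr, reference, selection, superpose=superpose) for fr in traj.frames]
    )


@dataclass
class DistanceTrace:
    """Per-frame distance between two atoms with summary statistics."""

    distances: np.ndarray
    mean: float
    sd: float
    degenerate: bool = False  # single-frame summary: sd not estimable
    atom_a: tuple[str, int, str] = field(default=("", 0, ""))
    atom_b: tuple[str, int, str] = field(default=("", 0, ""))


def _resolve_single(frame: Structure, selector: dict) -> int:
    sel = select(frame, **selector)
    if len(sel.indices) != 1:
        raise SelectionError(
            f"selector {selector} resolved to {len(sel.indices)} atoms (need 1)"
        )
    return sel.indices[0]


def distance_trace(
    traj: Trajectory,
    atom_a: dict,
    atom_b: dict,
    frame_range: tuple[int, int] | None = None,
) -> DistanceTrace:
    """Euclidean distance between two single-atom selectors per frame.

    ``atom_a``/``atom_b`` are keyword dictionaries for :func:`select` and
    must resolve to exactly one atom.  ``frame_range`` restricts the trace
    to frames [start, end) before summarizing.  The summary reports the
    sample (n-1) standard deviation; a single-frame trace reports sd = 0
    and is flagged degenerate.
    """
    ia = _resolve_single(traj.frames[0], atom_a)
    ib = _resolve_single(traj.frames[0], atom_b)
    frames = traj.frames
    if frame_range is not None:
        frames = frames[frame_range[0]: frame_range[1]]
        if not frames:
            raise SelectionError(f"frame_range {frame_range} selects no frames")
    d = np.asarray(
        [np.linalg.norm(fr.coords[ia] - fr.coords[ib]) for fr in frames]
    )
    degenerate = len(d) < 2
    sd = 0.0 if degenerate else float(np.std(d, ddof=1))
    return DistanceTrace(
        d, float(np.mean(d)), sd, degenerate,
        traj.frames[0].atoms[ia].key, traj.frames[0].atoms[ib].key,
    )


def trace_to_tsv(values: np.ndarray, path, label: str,
                 frame_times: list[float] | None = None) -> None:
    """Write a per-frame trace as tidy TSV with a commented header."""
    with open(path, "w") as fh:
        fh.write(f"# trace: {label}\n")
        fh.write("frame_index\ttime_ns\tvalue\n")
        for i, v in enumerate(values):
            t = "" if frame_times is None else f"{frame_times[i]:g}"
            fh.write(f"{i}\t{t}\t{v:.6f}\n")
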