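"""Census of heme-propionate non-bond interactions.

Detects hydrogen bonds, carbon hydrogen bonds and salt bridges between the
carboxylate oxygens of the heme propionate groups (A and D) and amino-acid
donors, using heavy-atom geometric criteria: donor-acceptor distance
d <= 3.4 Å for nitrogen/oxygen donors, d <= 3.8 Å for carbon/sulfur donors,
with both the X-D-A and D-A-Y angles in [90°, 180°] (X a heavy atom bonded
to the donor, Y the carboxylate carbon); Arg/Lys contacts are salt bridges
when the charged-nitrogen-to-oxygen distance is <= 5.6 Å, with no angle
condition.  Hydrogen positions are never required.

Per-frame events are aggregated into per-residue, per-category interaction
frequencies I and mean distances D, the inputs of the stability index.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ContractViolation, UnresolvedGeometryError
from .io_structures import Structure, Trajectory

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class Category(str, Enum):
    """Interaction categories entering the interaction score."""

    BB_CH = "BB_CH"   # backbone carbon hydrogen bond (Cα donor)
    SC_H = "SC_H"     # sidechain hydrogen bond (N/O donor)
    SC_CH = "SC_CH"   # sidechain carbon hydrogen bond (C/S donor)
    SC_SB = "SC_SB"   # sidechain salt bridge (Arg/Lys charged group)


_CLASS_TO_CATEGORY = {
    "backbone_carbon": Category.BB_CH,
    "sidechain_polar": Category.SC_H,
    "sidechain_carbon": Category.SC_CH,
    "sidechain_charged": Category.SC_SB,
}


@dataclass(frozen=True)
class GeometricCriteria:
    """Distance/angle cutoffs; defaults are the published criteria."""

    d_max_NO: float = 3.4
    d_max_SC: float = 3.8
    d_max_saltbridge: float = 5.6
    angle_min: float = 90.0
    angle_max: float = 180.0

    def __post_init__(self) -> None:
        if not (0 < self.d_max_NO <= self.d_max_SC <= self.d_max_saltbridge):
            raise ValueError("require 0 < d_max_NO <= d_max_SC <= d_max_saltbridge")
        if not (0 <= self.angle_min < self.angle_max <= 180):
            raise ValueError("require 0 <= angle_min < angle_max <= 180")

    def d_max_for_element(self, element: str) -> float:
        return self.d_max_NO if element in ("N", "O") else self.d_max_SC


@dataclass(frozen=True)
class DonorSpec:
    """One candidate donor heavy atom of a residue type."""

    residue_name: str
    atom_name: str
    donor_class: str  # backbone_carbon | sidechain_polar | sidechain_carbon
    antecedent_atoms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.antecedent_atoms:
            raise ValueError("a donor needs at least one antecedent atom")
        if self.donor_class not in _CLASS_TO_CATEGORY:
            raise ValueError(f"unknown donor class {self.donor_class!r}")

    @property
    def element(self) -> str:
        # PDB heavy-atom names start with the element letter
        return self.atom_name[0]

    @property
    def category(self) -> Category:
        return _CLASS_TO_CATEGORY[self.donor_class]


@dataclass(frozen=True)
class AcceptorSpec:
    """One carboxylate oxygen of a heme propionate group."""

    group: str            # "A" or "D"
    atom_name: str        # O1A / O2A / O1D / O2D
    antecedent_atoms: tuple[str, ...]  # the carboxylate carbon (Y vertex)

    def __post_init__(self) -> None:
        if not self.atom_name.startswith("O"):
            raise ValueError("acceptor atoms are carboxylate oxygens")


def default_acceptors(groups: Iterable[str] = ("A", "D")) -> list[AcceptorSpec]:
    """Both propionate carboxylates by default; restrict via ``groups``."""
    out = []
    for g in groups:
        if g not in ("A", "D"):
            raise ValueError(f"unknown propionate group {g!r}")
        out.append(AcceptorSpec(g, f"O1{g}", (f"CG{g}",)))
        out.append(AcceptorSpec(g, f"O2{g}", (f"CG{g}",)))
    return out


@dataclass
class DonorDictionary:
    """Donor definitions per residue type plus the salt-bridge atom sets."""

    donors: dict[str, list[DonorSpec]]
    salt_bridge_atoms: dict[str, tuple[str, ...]]

    def for_residue(self, residue_name: str) -> list[DonorSpec]:
        return self.donors.get(residue_name, [])


def load_donor_dictionary(path=None) -> DonorDictionary:
    """Load donor definitions from YAML (packaged defaults when path=None)."""
    if path is None:
        text = resources.files("hemelock.data").joinpath("donors.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)

    donors: dict[str, list[DonorSpec]] = defaultdict(list)
    bb = raw.get("backbone")
    if bb:
        for res in STANDARD_RESIDUES:
            donors[res].append(
                DonorSpec(res, bb["atom"], "backbone_carbon", tuple(bb["antecedents"]))
            )
    for klass in ("sidechain_polar", "sidechain_carbon"):
        for res, atoms in (raw.get(klass) or {}).items():
            for atom, ants in atoms.items():
                donors[res].append(DonorSpec(res, atom, klass, tuple(ants)))
    sb = {res: tuple(atoms) for res, atoms in (raw.get("salt_bridge") or {}).items()}
    return DonorDictionary(dict(donors), sb)


@dataclass(frozen=True)
class InteractionEvent:
    """One detected contact in one frame."""

    frame_index: int
    donor_residue: tuple[str, int, str]   # (chain, residue number, residue name)
    donor_atom: str
    acceptor_group: str
    acceptor_atom: str
    category: Category
    d: float
    angle_xda: float   # NaN for salt bridges
    angle_day: float   # NaN for salt bridges


def angle_deg(a: np.ndarray, vertex: np.ndarray, c: np.ndarray) -> float:
    """Angle a-vertex-c in degrees."""
    u = np.asarray(a, float) - np.asarray(vertex, float)
    v = np.asarray(c, float) - np.asarray(vertex, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbond(
    donor: DonorSpec,
    donor_xyz,
    antecedent_xyz: Mapping[str, Sequence[float]],
    acceptor: AcceptorSpec,
    acceptor_xyz,
    acceptor_antecedent_xyz: Mapping[str, Sequence[float]],
    criteria: GeometricCriteria = GeometricCriteria(),
    frame_index: int = 0,
    donor_residue: tuple[str, int, str] | None = None,
) -> InteractionEvent | None:
    """Test one donor/acceptor atom pair against the (carbon) H-bond criteria.

    The pair qualifies when d is within the donor-element cutoff and at
    least one (X, Y) antecedent combination places both the X-D-A and the
    D-A-Y angle inside the angular window; the accepted combination's
    angles are recorded on the event.
    """
    xs = {n: antecedent_xyz[n] for n in donor.antecedent_atoms if n in antecedent_xyz}
    if not xs:
        raise UnresolvedGeometryError(
            f"no antecedent of donor {donor.residue_name}:{donor.atom_name} "
            f"(need one of {donor.antecedent_atoms}) has coordinates"
        )
    ys = {n: acceptor_antecedent_xyz[n]
          for n in acceptor.antecedent_atoms if n in acceptor_antecedent_xyz}
    if not ys:
        raise UnresolvedGeometryError(
            f"acceptor antecedent {acceptor.antecedent_atoms} of "
            f"{acceptor.atom_name} has no coordinates"
        )
    d_xyz = np.asarray(donor_xyz, float)
    a_xyz = np.asarray(acceptor_xyz, float)
    d = float(np.linalg.norm(d_xyz - a_xyz))
    if d > criteria.d_max_for_element(donor.element):
        return None
    for x in xs.values():
        xda = angle_deg(x, d_xyz, a_xyz)
        if not (criteria.angle_min <= xda <= criteria.angle_max):
            continue
        for y in ys.values():
            day = angle_deg(d_xyz, a_xyz, y)
            if criteria.angle_min <= day <= criteria.angle_max:
                return InteractionEvent(
                    frame_index,
                    donor_residue or ("", 0, donor.residue_name),
                    donor.atom_name, acceptor.group, acceptor.atom_name,
                    donor.category, d, xda, day,
                )
    return None


def detect_salt_bridge(
    residue_name: str,
    charged_atom_xyz: Mapping[str, Sequence[float]],
    acceptor: AcceptorSpec,
    acceptor_xyz,
    criteria: GeometricCriteria = GeometricCriteria(),
    frame_index: int = 0,
    donor_residue: tuple[str, int, str] | None = None,
) -> InteractionEvent | None:
    """Salt-bridge test: min charged-N to carboxylate-O distance <= cutoff."""
    if residue_name not in ("ARG", "LYS"):
        raise ContractViolation(f"salt bridges require ARG/LYS, got {residue_name}")
    if not charged_atom_xyz:
        raise UnresolvedGeometryError(f"{residue_name}: no charged-group atoms present")
    a_xyz = np.asarray(acceptor_xyz, float)
    best_atom, best_d = None, np.inf
    for name, xyz in charged_atom_xyz.items():
        d = float(np.linalg.norm(np.asarray(xyz, float) - a_xyz))
        if d < best_d:
            best_atom, best_d = name, d
    if best_d > criteria.d_max_saltbridge:
        return None
    return InteractionEvent(
        frame_index, donor_residue or ("", 0, residue_name), best_atom,
        acceptor.group, acceptor.atom_name, Category.SC_SB, best_d,
        float("nan"), float("nan"),
    )


def scan_frame(
    frame: Structure,
    donors: DonorDictionary | None = None,
    acceptors: Sequence[AcceptorSpec] | None = None,
    criteria: GeometricCriteria = GeometricCriteria(),
    heme_resname: str = "HEM",
    frame_index: int = 0,
    salt_bridge_priority: bool = False,
) -> list[InteractionEvent]:
    """Census all qualifying donor/acceptor pairs in one frame.

    Donor definitions whose donor atom or whose antecedents are absent from
    the frame are skipped (counted in the log) — fragments and termini need
    not carry the full residue.  With ``salt_bridge_priority`` a
    charged-group atom that forms a salt bridge does not additionally count
    as a hydrogen-bond donor toward the same acceptor; by default both
    events are recorded, the two criteria being independent.
    """
    if donors is None:
        donors = load_donor_dictionary()
    if acceptors is None:
        acceptors = default_acceptors()

    residues = frame.residues()
    heme = {key: {a.name: np.asarray(a.coords) for a in atoms}
            for key, atoms in residues.items() if key[2] == heme_resname}
    if not heme:
        raise ContractViolation(f"frame contains no {heme_resname} residue")
    heme_atoms: dict[str, np.ndarray] = {}
    for atoms in heme.values():
        heme_atoms.update(atoms)

    acc_list = []
    for acc in acceptors:
        if acc.atom_name in heme_atoms:
            acc_list.append((acc, heme_atoms[acc.atom_name]))
    n_skipped = 0
    events: list[InteractionEvent] = []
    for key, atoms in residues.items():
        chain, seq, resname = key
        if resname == heme_resname:
            continue
        coords = {a.name: np.asarray(a.coords) for a in atoms}
        for spec in donors.for_residue(resname):
            if spec.atom_name not in coords:
                continue
            ants = {n: coords[n] for n in spec.antecedent_atoms if n in coords}
            if not ants:
                n_skipped += 1
                continue
            for acc, acc_xyz in acc_list:
                ev = detect_hbond(
                    spec, coords[spec.atom_name], ants, acc, acc_xyz,
                    heme_atoms, criteria, frame_index, donor_residue=key,
                )
                if ev is not None:
                    events.append(ev)
        sb_atoms = donors.salt_bridge_atoms.get(resname)
        if sb_atoms:
            charged = {n: coords[n] for n in sb_atoms if n in coords}
            if charged:
                for acc, acc_xyz in acc_list:
                    ev = detect_salt_bridge(
                        resname, charged, acc, acc_xyz, criteria,
                        frame_index, donor_residue=key,
                    )
                    if ev is not None:
                        events.append(ev)
    if n_skipped:
        logger.debug("skipped %d donors with unresolved antecedents", n_skipped)
    if salt_bridge_priority:
        sb_pairs = {
            (e.donor_residue, e.acceptor_atom)
            for e in events if e.category is Category.SC_SB
        }
        charged_names = {
            n for atoms in donors.salt_bridge_atoms.values() for n in atoms
        }
        events = [
            e for e in events
            if e.category is Category.SC_SB
            or e.donor_atom not in charged_names
            or (e.donor_residue, e.acceptor_atom) not in sb_pairs
        ]
    return events


def scan_trajectory(
    traj: Trajectory,
    donors: DonorDictionary | None = None,
    acceptors: Sequence[AcceptorSpec] | None = None,
    criteria: GeometricCriteria = GeometricCriteria(),
    heme_resname: str = "HEM",
    salt_bridge_priority: bool = False,
) -> list[InteractionEvent]:
    """scan_frame applied to every frame, frame indices preserved."""
    if donors is None:
        donors = load_donor_dictionary()
    if acceptors is None:
        acceptors = default_acceptors()
    events: list[InteractionEvent] = []
    for i, frame in enumerate(traj.frames):
        events.extend(
            scan_frame(frame, donors, acceptors, criteria, heme_resname,
                       frame_index=i, salt_bridge_priority=salt_bridge_priority)
        )
    return events


@dataclass
class InteractionSummary:
    """Per-residue, per-category frequency I and mean distance D."""

    table: pd.DataFrame  # columns: chain, residue_seq, residue_name,
    #                      category, I, D, n_events, n_frames
    n_frames: int
    mode: str

    def category_stats(
        self, residue_seq: int, chain: str | None = None
    ) -> dict[Category, tuple[float, float]]:
        """(I, D) for each category for one residue; absent => (0, NaN)."""
        t = self.table[self.table.residue_seq == residue_seq]
        if chain is not None:
            t = t[t.chain == chain]
        out = {c: (0.0, float("nan")) for c in Category}
        for _, row in t.iterrows():
            out[Category(row.category)] = (float(row.I), float(row.D))
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# interaction summary: mode={self.mode} "
                     f"n_frames={self.n_frames}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def aggregate(
    events: Sequence[InteractionEvent],
    n_frames: int,
    mode: str = "frame_fraction",
    residue_filter: Iterable[int] | None = None,
) -> InteractionSummary:
    """Aggregate events into the frequency/distance summary.

    ``mode='frame_fraction'`` counts the fraction of frames in which the
    residue shows >=1 event of the category; ``mode='events_per_frame'``
    counts total events divided by the frame count.  D is the mean of the
    event distances over all events of the (residue, category) cell.
    """
    if n_frames < 1:
        raise ContractViolation("aggregate needs >=1 scanned frame")
    if mode not in ("frame_fraction", "events_per_frame"):
        raise ValueError(f"unknown frequency mode {mode!r}")
    keep = set(residue_filter) if residue_filter is not None else None

    cells: dict[tuple, dict] = {}
    for e in events:
        chain, seq, resname = e.donor_residue
        if keep is not None and seq not in keep:
            continue
        key = (chain, seq, resname, e.category.value)
        cell = cells.setdefault(key, {"frames": set(), "dists": []})
        cell["frames"].add(e.frame_index)
        cell["dists"].append(e.d)

    rows = []
    for (chain, seq, resname, cat), cell in sorted(cells.items()):
        if mode == "frame_fraction":
            freq = len(cell["frames"]) / n_frames
        else:
            freq = len(cell["dists"]) / n_frames
        rows.append({
            "chain": chain, "residue_seq": seq, "residue_name": resname,
            "category": cat, "I": freq, "D": float(np.mean(cell["dists"])),
            "n_events": len(cell["dists"]), "n_frames": n_frames,
        })
    table = pd.DataFrame(
        rows, columns=["chain", "residue_seq", "residue_name", "category",
                       "I", "D", "n_events", "n_frames"],
    )
    return InteractionSummary(table, n_frames, mode)


def events_to_tsv(events: Sequence[InteractionEvent], path) -> None:
    """Write the raw event list as tidy TSV."""
    with open(path, "w") as fh:
        fh.write("frame\tchain\tdonor_res_seq\tdonor_res_name\tdonor_atom\t"
                 "acceptor_group\tacceptor_atom\tcategory\td\t"
                 "angle_XDA\tangle_DAY\n")
        for e in events:
            chain, seq, resname = e.donor_residue
            fh.write(
                f"{e.frame_index}\t{chain}\t{seq}\t{resname}\t{e.donor_atom}\t"
                f"{e.acceptor_group}\t{e.acceptor_atom}\t{e.category.value}\t"
                f"{e.d:.4f}\t{e.angle_xda:.2f}\t{e.angle_day:.2f}\n"
            )
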