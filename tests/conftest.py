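"""Shared fixtures: tiny structures and an independent census oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

from hemelock.interactions import GeometricCriteria, load_donor_dictionary
from hemelock.io_structures import Atom, Structure

HEME_FRAGMENT = {
    "FE": (0.0, 0.0, 6.0),
    "CGA": (0.0, 0.0, 0.0),
    "O1A": (1.25, 0.0, 0.0),
    "O2A": (-1.25, 0.0, 0.0),
    "CGD": (25.0, 0.0, 0.0),
    "O1D": (26.25, 0.0, 0.0),
    "O2D": (23.75, 0.0, 0.0),
}

# atom sets of the residue types used in randomized frames
RESIDUE_ATOMS = {
    "ALA": ["N", "CA", "CB"],
    "SER": ["N", "CA", "CB", "OG"],
    "CYS": ["N", "CA", "CB", "SG"],
    "LYS": ["N", "CA", "CB", "CG", "CE", "NZ"],
    "ARG": ["N", "CA", "CB", "CG", "CD", "CZ", "NE", "NH1", "NH2"],
    "HIS": ["N", "CA", "CB", "CG", "CD2", "CE1", "ND1", "NE2"],
}


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def make_random_frame(rng: np.random.Generator, n_residues: int = 3) -> Structure:
    """A heme fragment plus residues with uniformly random atom positions."""
    atoms = []
    serial = 1
    for name, xyz in HEME_FRAGMENT.items():
        el = "FE" if name == "FE" else name[0]
        atoms.append(Atom(serial, name, el, "HEM", "X", 400, xyz))
        serial += 1
    resnames = rng.choice(list(RESIDUE_ATOMS), size=n_residues)
    for i, resname in enumerate(resnames):
        for aname in RESIDUE_ATOMS[resname]:
            xyz = tuple(rng.uniform(-6.5, 6.5, 3))
            atoms.append(Atom(serial, aname, _element_of(aname), str(resname),
                              "A", 10 + i, xyz))
            serial += 1
    return Structure(atoms)


def _angle(a, b, c) -> float:
    u = np.asarray(a) - np.asarray(b)
    v = np.asarray(c) - np.asarray(b)
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def oracle_scan(frame: Structure,
                criteria: GeometricCriteria = GeometricCriteria()) -> set:
    """Exhaustive all-pairs evaluation of the detection criteria.

    Written independently of the scanner (plain loops and the raw rules);
    returns a set of (residue_seq, donor_atom, acceptor_atom, category,
    rounded distance) tuples for comparison.
    """
    donors = load_donor_dictionary()
    coords_by_res: dict = {}
    for a in frame.atoms:
        coords_by_res.setdefault((a.chain_id, a.residue_seq, a.residue_name),
                                 {})[a.name] = np.asarray(a.coords)
    heme = {}
    for key, cmap in coords_by_res.items():
        if key[2] == "HEM":
            heme.update(cmap)
    acceptors = []
    for g in ("A", "D"):
        for o in (f"O1{g}", f"O2{g}"):
            if o in heme and f"CG{g}" in heme:
                acceptors.append((o, heme[o], heme[f"CG{g}"]))

    found = set()
    for (chain, seq, resname), cmap in coords_by_res.items():
        if resname == "HEM":
            continue
        for spec in donors.for_residue(resname):
            if spec.atom_name not in cmap:
                continue
            ants = [cmap[x] for x in spec.antecedent_atoms if x in cmap]
            if not ants:
                continue
            dpos = cmap[spec.atom_name]
            el = spec.atom_name[0]
            cutoff = criteria.d_max_NO if el in "NO" else criteria.d_max_SC
            for oname, opos, ypos in acceptors:
                d = float(np.linalg.norm(dpos - opos))
                if d > cutoff:
                    continue
                ok = False
                for x in ants:
                    if not (criteria.angle_min <= _angle(x, dpos, opos)
                            <= criteria.angle_max):
                        continue
                    if (criteria.angle_min <= _angle(dpos, opos, ypos)
                            <= criteria.angle_max):
                        ok = True
                        break
                if ok:
                    found.add((seq, spec.atom_name, oname,
                               spec.category.value, round(d, 6)))
        sb = donors.salt_bridge_atoms.get(resname)
        if sb:
            present = [(n, cmap[n]) for n in sb if n in cmap]
            if present:
                for oname, opos, _ in acceptors:
                    best = min(present,
                               key=lambda p: np.linalg.norm(p[1] - opos))
                    d = float(np.linalg.norm(best[1] - opos))
                    if d <= criteria.d_max_saltbridge:
                        found.add((seq, best[0], oname, "SC_SB", round(d, 6)))
    return found


def events_as_set(events) -> set:
    return {(e.donor_residue[1], e.donor_atom, e.acceptor_atom,
             e.category.value, round(e.d, 6)) for e in events}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
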