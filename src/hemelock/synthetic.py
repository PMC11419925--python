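"""Synthetic inputs with known ground truth.

Every pipeline stage can be exercised without an MD engine or downloaded
structures: heme-pocket ensembles are built by explicit geometric
construction (donor positions solved from target distance and angles, so
window membership is guaranteed and noiseless limits are exact), variant
panels follow a known linear melting-temperature law, and kinetics series
are sampled from exact exponential-decay and Michaelis-Menten curves.
Geometry is constructed, not simulated: there is no force field, solvent
or physical realism, only the degrees of freedom the detection criteria
measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .interactions import Category, GeometricCriteria
from .io_structures import Atom, Structure, Trajectory
from .kinetics import ActivityTimeSeries, SaturationSeries
from .model import (
    PUBLISHED_TM_MODEL,
    PUBLISHED_WEIGHTS,
    VOLUMES,
    LinearTmModel,
    VariantPanel,
    WeightVector,
    hemelock_index,
)

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

# ---------------------------------------------------------------------------
# Heme pocket trajectories
# ---------------------------------------------------------------------------

# Minimal heme fragment: iron plus both propionate carboxylates.  O2A is
# placed trans to O1A across CGA so that any donor constructed on the O1A
# side fails the D-A-Y angle window at O2A — donors interact with exactly
# the oxygen they were built against.
_HEME_ATOMS = {
    "FE": (0.0, 0.0, 6.0),
    "CGA": (0.0, 0.0, 0.0),
    "O1A": (1.25, 0.0, 0.0),
    "O2A": (-1.25, 0.0, 0.0),
    "CGD": (25.0, 0.0, 0.0),
    "O1D": (26.25, 0.0, 0.0),
    "O2D": (23.75, 0.0, 0.0),
}


@dataclass(frozen=True)
class DonorSite:
    """One programmed donor residue of a synthetic pocket.

    ``residue_name``/``donor_atom``/``antecedent_atom`` must agree with the
    donor dictionary the scanner will use (e.g. ALA CA with antecedent N for
    a backbone donor, SER OG with CB, LYS NZ with CE for a salt bridge).
    Angles are clipped to [120°, 178°] after jitter so that the antecedent
    atom itself can never wander inside a detection cutoff.
    """

    residue_name: str
    residue_seq: int
    donor_atom: str
    antecedent_atom: str
    category: Category
    occupancy: float
    nominal_d: float
    nominal_xda: float = 150.0
    nominal_day: float = 150.0
    jitter_d: float = 0.0        # Å, Gaussian, clipped inside the window
    jitter_angle: float = 0.0    # degrees
    azimuth_deg: float = 0.0     # separates multiple donors around the axis


@dataclass
class PocketSpec:
    """Generator settings for one synthetic heme-pocket ensemble."""

    donors: list[DonorSite]
    n_frames: int = 100
    seed: int = 0
    criteria: GeometricCriteria = field(default_factory=GeometricCriteria)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for d in self.donors:
            if not (0.0 <= d.occupancy <= 1.0):
                raise ValueError(f"occupancy {d.occupancy} outside [0, 1]")
            if d.jitter_d < 0 or d.jitter_angle < 0:
                raise ValueError("jitter must be >= 0")
            cutoff = (self.criteria.d_max_saltbridge
                      if d.category is Category.SC_SB
                      else self.criteria.d_max_for_element(d.donor_atom[0]))
            if not (1.5 < d.nominal_d <= cutoff):
                raise ValueError(
                    f"{d.residue_name}{d.residue_seq}: nominal distance "
                    f"{d.nominal_d} outside the {d.category.value} window (<= {cutoff})"
                )
            if not (self.criteria.angle_min < d.nominal_xda <= self.criteria.angle_max
                    and self.criteria.angle_min < d.nominal_day <= self.criteria.angle_max):
                raise ValueError("nominal angles outside the angular window")


@dataclass
class SiteTruth:
    """Realized placement statistics for one donor site."""

    site: DonorSite
    placed: np.ndarray            # per-frame bool
    distances: np.ndarray         # per-frame realized donor-acceptor distance

    @property
    def frame_fraction(self) -> float:
        return float(np.mean(self.placed))

    @property
    def mean_placed_distance(self) -> float:
        return float(np.mean(self.distances[self.placed])) if self.placed.any() else float("nan")


@dataclass
class PocketGroundTruth:
    """Everything the generator knows about a pocket ensemble."""

    spec: PocketSpec
    sites: list[SiteTruth]

    def site_for(self, residue_seq: int) -> SiteTruth:
        for s in self.sites:
            if s.site.residue_seq == residue_seq:
                return s
        raise KeyError(residue_seq)


def _donor_position(d: float, day: float, azimuth: float) -> np.ndarray:
    """Donor coordinates at distance d from O1A with D-A-Y angle ``day``."""
    a = np.asarray(_HEME_ATOMS["O1A"])
    y_hat = np.array([-1.0, 0.0, 0.0])  # O1A -> CGA
    phi = math.radians(azimuth)
    p_hat = np.array([0.0, math.cos(phi), math.sin(phi)])
    th = math.radians(day)
    return a + d * (math.cos(th) * y_hat + math.sin(th) * p_hat)


def _antecedent_position(donor: np.ndarray, xda: float) -> np.ndarray:
    """Antecedent 1.5 Å from the donor at the requested X-D-A angle."""
    a = np.asarray(_HEME_ATOMS["O1A"])
    a_hat = (a - donor) / np.linalg.norm(a - donor)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(a_hat, ref)) > 0.95:
        ref = np.array([0.0, 1.0, 0.0])
    q = np.cross(a_hat, ref)
    q /= np.linalg.norm(q)
    xi = math.radians(xda)
    return donor + 1.5 * (math.cos(xi) * a_hat + math.sin(xi) * q)


_ANGLE_CLIP = (120.0, 178.0)


def make_pocket_trajectory(spec: PocketSpec) -> tuple[Trajectory, PocketGroundTruth]:
    """Build a multi-model ensemble with programmed interaction occupancy.

    In each frame each donor is placed inside its criteria window with
    probability equal to its occupancy (distance and angles Gaussian-
    jittered, then clipped inside the window) and well outside every cutoff
    otherwise.  The returned ground truth records the realized per-frame
    placements and distances.
    """
    rng = np.random.default_rng(spec.seed)
    frames: list[Structure] = []
    placed_flags = {d.residue_seq: np.zeros(spec.n_frames, bool) for d in spec.donors}
    realized_d = {d.residue_seq: np.zeros(spec.n_frames) for d in spec.donors}

    for f in range(spec.n_frames):
        atoms: list[Atom] = []
        serial = 1
        for site in spec.donors:
            placed = bool(rng.random() < site.occupancy)
            cutoff = (spec.criteria.d_max_saltbridge
                      if site.category is Category.SC_SB
                      else spec.criteria.d_max_for_element(site.donor_atom[0]))
            if placed:
                d = site.nominal_d + rng.normal(0.0, site.jitter_d) if site.jitter_d else site.nominal_d
                d = float(np.clip(d, 2.0, cutoff))
                xda = site.nominal_xda + (rng.normal(0.0, site.jitter_angle) if site.jitter_angle else 0.0)
                day = site.nominal_day + (rng.normal(0.0, site.jitter_angle) if site.jitter_angle else 0.0)
                xda = float(np.clip(xda, *_ANGLE_CLIP))
                day = float(np.clip(day, *_ANGLE_CLIP))
            else:
                d = 8.0 + abs(rng.normal(0.0, 0.5))
                xda, day = site.nominal_xda, site.nominal_day
            placed_flags[site.residue_seq][f] = placed
            realized_d[site.residue_seq][f] = d
            dpos = _donor_position(d, day, site.azimuth_deg)
            xpos = _antecedent_position(dpos, xda)
            el_d = site.donor_atom[0]
            el_x = site.antecedent_atom[0]
            atoms.append(Atom(serial, site.donor_atom, el_d, site.residue_name,
                              "A", site.residue_seq, tuple(map(float, dpos))))
            serial += 1
            atoms.append(Atom(serial, site.antecedent_atom, el_x, site.residue_name,
                              "A", site.residue_seq, tuple(map(float, xpos))))
            serial += 1
        for name, xyz in _HEME_ATOMS.items():
            el = "FE" if name == "FE" else name[0]
            atoms.append(Atom(serial, name, el, "HEM", "X", 400, xyz))
            serial += 1
        frames.append(Structure(atoms))

    truth = PocketGroundTruth(
        spec,
        [SiteTruth(s, placed_flags[s.residue_seq], realized_d[s.residue_seq])
         for s in spec.donors],
    )
    return Trajectory(frames), truth


def default_pocket_spec(
    occupancy: float = 1.0,
    n_frames: int = 100,
    seed: int = 0,
    jitter_d: float = 0.0,
    jitter_angle: float = 0.0,
) -> PocketSpec:
    """A three-donor pocket: backbone Cα, sidechain hydroxyl, Lys salt bridge."""
    donors = [
        DonorSite("ALA", 181, "CA", "N", Category.BB_CH, occupancy, 3.5,
                  jitter_d=jitter_d, jitter_angle=jitter_angle, azimuth_deg=0.0),
        DonorSite("SER", 82, "OG", "CB", Category.SC_H, occupancy, 3.0,
                  jitter_d=jitter_d, jitter_angle=jitter_angle, azimuth_deg=120.0),
        DonorSite("LYS", 39, "NZ", "CE", Category.SC_SB, occupancy, 5.0,
                  jitter_d=jitter_d, jitter_angle=jitter_angle, azimuth_deg=240.0),
    ]
    return PocketSpec(donors, n_frames=n_frames, seed=seed)


# ---------------------------------------------------------------------------
# Variant panels
# ---------------------------------------------------------------------------


@dataclass
class PanelSpec:
    """Generator settings for a synthetic variant panel.

    Per-variant interaction statistics are drawn so that the weighted
    component scores stay inside the spans observed on the real panel
    (backbone term <= 0.75, sidechain term <= 0.35) and melting
    temperatures follow Tm = a*index + b plus Gaussian noise.
    """

    residues: list[str]
    weights: WeightVector = PUBLISHED_WEIGHTS
    tm_model: LinearTmModel = field(
        default_factory=lambda: LinearTmModel(PUBLISHED_TM_MODEL.slope,
                                              PUBLISHED_TM_MODEL.intercept))
    sigma_tm: float = 0.0
    seed: int = 0
    size_only: bool = False   # zero all interaction terms

    def __post_init__(self) -> None:
        if len(set(self.residues)) < 3:
            raise ValueError("need >= 3 distinct residue identities")
        if self.sigma_tm < 0:
            raise ValueError("sigma_tm must be >= 0")


@dataclass
class PanelGroundTruth:
    """True parameters and noiseless values behind a synthetic panel."""

    weights: WeightVector
    tm_model: LinearTmModel
    indices: np.ndarray
    tm_true: np.ndarray


def make_variant_panel(spec: PanelSpec) -> tuple[VariantPanel, PanelGroundTruth]:
    """Draw a variant panel whose Tm follows a known linear law."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for aa in spec.residues:
        aa = aa.upper()
        if spec.size_only:
            stats = dict(BBCHI=0.0, BBCHD=float("nan"), SCHI=0.0, SCHD=float("nan"),
                         SCCHI=0.0, SCCHD=float("nan"), SCSBI=0.0, SCSBD=float("nan"))
        else:
            stats = dict(
                BBCHI=rng.uniform(0.0, 0.8), BBCHD=rng.uniform(3.3, 3.8),
                SCHI=rng.uniform(0.0, 1.0), SCHD=rng.uniform(2.8, 3.4),
                SCCHI=rng.uniform(0.0, 0.6), SCCHD=rng.uniform(3.2, 3.8),
                SCSBI=rng.uniform(0.0, 0.8), SCSBD=rng.uniform(3.5, 5.6),
            )
        name = "WT" if aa == "VAL" else f"V181{_AA3_TO_1[aa]}"
        rows.append({"variant": name, "aa181": aa, **stats})
    table = pd.DataFrame(rows)
    # disambiguate repeated identities
    dup = table.variant.duplicated(keep=False)
    if dup.any():
        table.loc[dup, "variant"] = [
            f"{v}_{i}" for i, v in zip(table.index[dup], table.variant[dup])
        ]

    panel_for_index = VariantPanel(table.assign(Tm_obs=50.0))
    indices = panel_for_index.indices(spec.weights, VOLUMES)
    tm_true = spec.tm_model.slope * indices + spec.tm_model.intercept
    noise = rng.normal(0.0, spec.sigma_tm, len(indices)) if spec.sigma_tm else 0.0
    table["Tm_obs"] = tm_true + noise
    return VariantPanel(table), PanelGroundTruth(
        spec.weights, spec.tm_model, indices, tm_true
    )


# ---------------------------------------------------------------------------
# Kinetics series
# ---------------------------------------------------------------------------


@dataclass
class DecayTruth:
    kd: float
    sigma_ln: float
    seed: int


def make_decay_series(
    kd: float = 0.01,
    times_min=None,
    sigma_ln: float = 0.0,
    seed: int = 0,
    temperature: str = "55C",
) -> tuple[ActivityTimeSeries, DecayTruth]:
    """Residual-activity decay exp(-kd t) with lognormal measurement noise.

    The t = 0 point is the normalization reference and carries no noise.
    """
    if times_min is None:
        times_min = np.linspace(0.0, 300.0, 11)
    times_min = np.asarray(times_min, float)
    rng = np.random.default_rng(seed)
    a = np.exp(-kd * times_min)
    if sigma_ln:
        noise = rng.normal(0.0, sigma_ln, len(times_min))
        noise[0] = 0.0
        a = a * np.exp(noise)
    return (ActivityTimeSeries(times_min, a, temperature),
            DecayTruth(kd, sigma_ln, seed))


@dataclass
class SaturationTruth:
    kcat: float
    km_uM: float
    vmax: float
    enzyme_conc_uM: float
    cv: float
    seed: int


#: Substrate grid spanning the assayed 50-2000 µM range.
DEFAULT_CONCENTRATIONS_UM = (50.0, 100.0, 200.0, 400.0, 800.0, 1200.0, 1600.0, 2000.0)


def make_saturation_series(
    kcat: float = 10.0,
    km_uM: float = 200.0,
    enzyme_conc_uM: float = 0.02,
    concentrations_uM=DEFAULT_CONCENTRATIONS_UM,
    cv: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    temperature: str = "25C",
) -> tuple[SaturationSeries, SaturationTruth]:
    """Michaelis-Menten rates on the standard substrate grid.

    ``cv`` is the per-point coefficient of variation; with replicates the
    grid is tiled and each point drawn independently.
    """
    s = np.tile(np.asarray(concentrations_uM, float), replicates)
    vmax = kcat * enzyme_conc_uM
    v = vmax * s / (km_uM + s)
    if cv:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + cv * rng.normal(0.0, 1.0, len(s)))
        v = np.clip(v, 0.0, None)
    return (SaturationSeries(s, v, temperature),
            SaturationTruth(kcat, km_uM, vmax, enzyme_conc_uM, cv, seed))
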