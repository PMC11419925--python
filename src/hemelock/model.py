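"""The HemeLock stability index and its linear melting-temperature model.

The index scores how firmly the heme cofactor is locked into its pocket by
the residue at the key heme-contacting position (residue 181 in PcLiP01):

    interaction score = w1*BBCHI/BBCHD + w2*SCHI/SCHD
                      + w3*SCCHI/SCCHD + w4*SCSBI/SCSBD
    size score        = w5 / (sidechain volume of the residue, Å³)
    HemeLock index    = interaction score + size score
    Tm (°C)           = a * index + b

where the I are per-category interaction frequencies and the D the
corresponding mean donor-acceptor distances (Å).  All scores are treated
as dimensionless.  The published fit on the PcLiP01 V181X panel is
w1 = 2.974, w2 = 0.9201, w3 = w4 = 0, w5 = 282.3, a = 4.995, b = 42.86;
a per-isozyme one-dimensional refinement of w5 is provided for transferring
the model to homologous isozymes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ContractViolation, DegenerateFitError
from .interactions import Category, InteractionSummary

# ---------------------------------------------------------------------------
# Residue volumes
# ---------------------------------------------------------------------------

_VOL_BOUNDS = (50.0, 250.0)


def load_volume_table(path=None) -> dict[str, float]:
    """Residue sidechain-volume table (Å³); packaged Zamyatnin scale by default."""
    if path is None:
        text = resources.files("hemelock.data").joinpath("residue_volumes.csv").read_text()
        df = pd.read_csv(io.StringIO(text))
    else:
        df = pd.read_csv(path)
    table = dict(zip(df.residue.str.upper(), df.volume_A3.astype(float)))
    if len(table) != 20:
        raise ValueError(f"volume table must cover the 20 canonical residues, got {len(table)}")
    if not all(_VOL_BOUNDS[0] < v < _VOL_BOUNDS[1] for v in table.values()):
        raise ValueError("residue volumes outside the plausible (50, 250) Å³ window")
    if not (table["GLY"] == min(table.values()) and table["TRP"] == max(table.values())):
        raise ValueError("volume table violates the Gly-smallest/Trp-largest ordering")
    return table


VOLUMES: dict[str, float] = load_volume_table()

# ---------------------------------------------------------------------------
# Weights and linear model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeightVector:
    """Non-negative weights of the four interaction terms plus the size term."""

    w1: float  # backbone carbon hydrogen bond
    w2: float  # sidechain hydrogen bond
    w3: float  # sidechain carbon hydrogen bond
    w4: float  # sidechain salt bridge
    w5: float  # size term, Å³-scaled

    def __post_init__(self) -> None:
        for name in ("w1", "w2", "w3", "w4", "w5"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3, self.w4, self.w5])

    def replace_w5(self, w5: float) -> "WeightVector":
        return WeightVector(self.w1, self.w2, self.w3, self.w4, w5)


#: Published weights fitted on the PcLiP01 WT + V181X panel.
PUBLISHED_WEIGHTS = WeightVector(2.974, 0.9201, 0.0, 0.0, 282.3)

#: Isozyme-specific size-term refinements.
ISOZYME_W5 = {"PcLiP01": 282.3, "PcLiP05": 233.1, "PcLiP09": 223.3}


@dataclass
class LinearTmModel:
    """Tm = slope * index + intercept, with OLS diagnostics."""

    slope: float          # °C per index unit
    intercept: float      # °C
    r2: float = float("nan")
    mse: float = float("nan")
    n: int = 0
    slope_se: float = float("nan")
    intercept_se: float = float("nan")

    def ci95(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """t-based 95% confidence intervals for (slope, intercept)."""
        if self.n < 3:
            raise ContractViolation("confidence intervals need n >= 3")
        t = stats.t.ppf(0.975, self.n - 2)
        return (
            (self.slope - t * self.slope_se, self.slope + t * self.slope_se),
            (self.intercept - t * self.intercept_se, self.intercept + t * self.intercept_se),
        )


#: Published linear Tm model.
PUBLISHED_TM_MODEL = LinearTmModel(slope=4.995, intercept=42.86)


@dataclass
class ScoreBreakdown:
    """Per-term decomposition of one HemeLock index."""

    bb_ch_term: float
    sc_h_term: float
    sc_ch_term: float
    sc_sb_term: float
    size_score: float

    @property
    def interaction_score(self) -> float:
        return self.bb_ch_term + self.sc_h_term + self.sc_ch_term + self.sc_sb_term

    @property
    def hemelock_index(self) -> float:
        return self.interaction_score + self.size_score


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

CategoryStats = Mapping[Category, tuple[float, float]]


def _term(freq: float, dist: float, weight: float) -> float:
    if freq < 0:
        raise ContractViolation(f"negative interaction frequency {freq}")
    if freq == 0:
        return 0.0  # zero-frequency category contributes exactly 0
    if not (dist > 0):
        raise ContractViolation(f"positive frequency with non-positive distance {dist}")
    return weight * freq / dist


def interaction_score(stats_by_cat: CategoryStats, weights: WeightVector) -> float:
    """Sum of the four weighted frequency/distance ratios."""
    return (
        _term(*stats_by_cat.get(Category.BB_CH, (0.0, float("nan"))), weights.w1)
        + _term(*stats_by_cat.get(Category.SC_H, (0.0, float("nan"))), weights.w2)
        + _term(*stats_by_cat.get(Category.SC_CH, (0.0, float("nan"))), weights.w3)
        + _term(*stats_by_cat.get(Category.SC_SB, (0.0, float("nan"))), weights.w4)
    )


def size_score(
    amino_acid: str,
    w5: float = PUBLISHED_WEIGHTS.w5,
    volumes: Mapping[str, float] = VOLUMES,
) -> float:
    """w5 divided by the residue's sidechain volume; decreasing in volume."""
    aa = amino_acid.upper()
    if aa not in volumes:
        raise KeyError(f"unknown residue code {amino_acid!r}")
    return w5 / volumes[aa]


def hemelock_index(
    stats_by_cat: CategoryStats,
    amino_acid: str,
    weights: WeightVector = PUBLISHED_WEIGHTS,
    volumes: Mapping[str, float] = VOLUMES,
) -> ScoreBreakdown:
    """Full score breakdown for one variant."""
    return ScoreBreakdown(
        bb_ch_term=_term(*stats_by_cat.get(Category.BB_CH, (0.0, float("nan"))), weights.w1),
        sc_h_term=_term(*stats_by_cat.get(Category.SC_H, (0.0, float("nan"))), weights.w2),
        sc_ch_term=_term(*stats_by_cat.get(Category.SC_CH, (0.0, float("nan"))), weights.w3),
        sc_sb_term=_term(*stats_by_cat.get(Category.SC_SB, (0.0, float("nan"))), weights.w4),
        size_score=size_score(amino_acid, weights.w5, volumes),
    )


def index_from_summary(
    summary: InteractionSummary,
    residue_seq: int,
    amino_acid: str,
    weights: WeightVector = PUBLISHED_WEIGHTS,
    volumes: Mapping[str, float] = VOLUMES,
) -> ScoreBreakdown:
    """Convenience: index of the residue at ``residue_seq`` from a census."""
    return hemelock_index(summary.category_stats(residue_seq), amino_acid,
                          weights, volumes)


def predict_tm(index, model: LinearTmModel = PUBLISHED_TM_MODEL):
    """Melting temperature (°C) for a HemeLock index under the linear model."""
    if not (np.isfinite(model.slope) and np.isfinite(model.intercept)):
        raise ContractViolation("model coefficients must be finite")
    return model.slope * np.asarray(index, float) + model.intercept


# ---------------------------------------------------------------------------
# Variant panels
# ---------------------------------------------------------------------------

PANEL_STAT_COLUMNS = ["BBCHI", "BBCHD", "SCHI", "SCHD",
                      "SCCHI", "SCCHD", "SCSBI", "SCSBD"]

_COL_TO_CAT = {
    ("BBCHI", "BBCHD"): Category.BB_CH,
    ("SCHI", "SCHD"): Category.SC_H,
    ("SCCHI", "SCCHD"): Category.SC_CH,
    ("SCSBI", "SCSBD"): Category.SC_SB,
}


@dataclass
class VariantPanel:
    """Variant identity, per-category interaction statistics and observed Tm.

    The table carries one row per variant with columns ``variant``,
    ``aa181`` (3-letter code of the residue at the key position), the eight
    frequency/distance columns of :data:`PANEL_STAT_COLUMNS`, and
    ``Tm_obs`` (°C).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"variant", "aa181", "Tm_obs"} - set(self.table.columns)
        if missing:
            raise ValueError(f"panel missing columns {sorted(missing)}")
        bad = ~self.table.aa181.str.upper().isin(VOLUMES)
        if bad.any():
            raise ValueError(f"unknown residue codes: {self.table.aa181[bad].tolist()}")
        tm = self.table.Tm_obs.astype(float)
        if ((tm <= 0) | (tm >= 120)).any():
            raise ValueError("Tm values outside (0, 120) °C")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_csv(cls, path) -> "VariantPanel":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def row_stats(self, row) -> dict[Category, tuple[float, float]]:
        out = {}
        for (icol, dcol), cat in _COL_TO_CAT.items():
            freq = float(row.get(icol, 0.0) or 0.0)
            dist = float(row.get(dcol) or float("nan"))
            out[cat] = (freq, dist)
        return out

    def indices(
        self,
        weights: WeightVector = PUBLISHED_WEIGHTS,
        volumes: Mapping[str, float] = VOLUMES,
    ) -> np.ndarray:
        """HemeLock index of every variant row."""
        vals = []
        for _, row in self.table.iterrows():
            bd = hemelock_index(self.row_stats(row), row.aa181, weights, volumes)
            vals.append(bd.hemelock_index)
        return np.asarray(vals)

    @property
    def tm_obs(self) -> np.ndarray:
        return self.table.Tm_obs.to_numpy(dtype=float)


def load_tm_fixture() -> pd.DataFrame:
    """Measured PcLiP01 variant melting temperatures shipped with the package."""
    text = resources.files("hemelock.data").joinpath("pclip01_tm_panel.csv").read_text()
    return pd.read_csv(io.StringIO(text))


def tm_gains(table: pd.DataFrame, reference: str = "WT") -> pd.DataFrame:
    """Per-variant Tm gain over a reference variant (ΔTm, °C)."""
    ref_rows = table[table.variant == reference]
    if len(ref_rows) != 1:
        raise ContractViolation(f"reference variant {reference!r} not found exactly once")
    ref_tm = float(ref_rows.Tm_obs.iloc[0])
    out = table[["variant", "Tm_obs"]].copy()
    out["dTm"] = out.Tm_obs.astype(float) - ref_tm
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _ols(x: np.ndarray, y: np.ndarray) -> LinearTmModel:
    n = len(x)
    if n < 2:
        raise DegenerateFitError("OLS needs >= 2 observations")
    if np.ptp(x) == 0:
        raise DegenerateFitError("all indices identical: slope not identifiable")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        # constant response: slope 0, R^2 reported as 0 by convention
        return LinearTmModel(0.0, float(y.mean()), 0.0, 0.0, n, 0.0, 0.0)
    res = stats.linregress(x, y)
    yhat = res.slope * x + res.intercept
    ssr = float(np.sum((y - yhat) ** 2))
    return LinearTmModel(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=1.0 - ssr / sst, mse=ssr / n, n=n,
        slope_se=float(res.stderr), intercept_se=float(res.intercept_stderr),
    )


def fit_model(
    panel: VariantPanel,
    fixed_weights: WeightVector | None = None,
    anchor_w5: float = PUBLISHED_WEIGHTS.w5,
    volumes: Mapping[str, float] = VOLUMES,
    seed: int = 0,
    n_starts: int = 8,
) -> tuple[WeightVector, LinearTmModel]:
    """Fit the weight vector and the linear Tm map on a variant panel.

    With ``fixed_weights`` only (slope, intercept) are fitted by OLS.
    Otherwise w1..w4 are optimized (non-negative) for the best coefficient
    of determination by seeded multi-start bounded least squares, with the
    size weight anchored at ``anchor_w5`` — the overall weight scale is not
    identifiable (a positive rescaling is absorbed by the slope), so the
    canonical solution fixes w5 and only the weight ratios are meaningful.
    """
    if len(panel) < 3:
        raise ContractViolation("fit_model needs a panel of >= 3 variants")
    y = panel.tm_obs

    if fixed_weights is not None:
        return fixed_weights, _ols(panel.indices(fixed_weights, volumes), y)

    def indices_for(w14: np.ndarray) -> np.ndarray:
        w = WeightVector(*np.clip(w14, 0, None), anchor_w5)
        return panel.indices(w, volumes)

    def residuals(w14: np.ndarray) -> np.ndarray:
        x = indices_for(w14)
        if np.ptp(x) == 0:
            return y - y.mean()
        res = stats.linregress(x, y)
        return y - (res.slope * x + res.intercept)

    rng = np.random.default_rng(seed)
    starts = [np.ones(4)] + [rng.uniform(0.0, 5.0, 4) for _ in range(n_starts - 1)]
    best, best_sse = None, np.inf
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(0.0, np.inf), xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:  # a pathological start is simply skipped
            continue
        sse = float(np.sum(sol.fun ** 2))
        if sse < best_sse:
            best, best_sse = sol.x, sse
    if best is None:
        raise DegenerateFitError("weight optimization failed from every start")
    weights = WeightVector(*np.clip(best, 0, None), anchor_w5)
    model = _ols(panel.indices(weights, volumes), y)
    return weights, model


@dataclass
class RefitResult:
    """Outcome of the per-isozyme one-dimensional w5 refinement."""

    w5: float
    mse_before: float
    mse_after: float
    weights: WeightVector


def refit_w5(
    panel: VariantPanel,
    base_weights: WeightVector = PUBLISHED_WEIGHTS,
    model: LinearTmModel = PUBLISHED_TM_MODEL,
    volumes: Mapping[str, float] = VOLUMES,
) -> RefitResult:
    """Refine the size weight w5 for one isozyme, all else held fixed.

    Predicted Tm is linear in w5 (Tm = a*(interaction score + w5/V) + b),
    so the squared-error objective is an exactly solvable parabola; the
    minimizer is clipped at 0 to keep the weight admissible.
    """
    if len(panel) < 2:
        raise DegenerateFitError("refit_w5 needs >= 2 variants")
    y = panel.tm_obs
    iscores = np.array([
        interaction_score(panel.row_stats(row), base_weights)
        for _, row in panel.table.iterrows()
    ])
    vols = np.array([volumes[row.aa181.upper()] for _, row in panel.table.iterrows()])
    u = model.slope / vols                       # d(pred)/d(w5)
    c = model.slope * iscores + model.intercept - y
    denom = float(np.sum(u * u))
    if denom == 0:
        raise DegenerateFitError("slope 0 or degenerate volumes: w5 not identifiable")
    w5 = max(0.0, float(-np.sum(c * u) / denom))
    mse_before = float(np.mean((c + base_weights.w5 * u) ** 2))
    mse_after = float(np.mean((c + w5 * u) ** 2))
    return RefitResult(w5, mse_before, mse_after, base_weights.replace_w5(w5))


@dataclass
class EvalResult:
    """Fit diagnostics plus the per-variant residual table."""

    r2: float
    mse: float
    residuals: pd.DataFrame  # variant, Tm_obs, Tm_pred, residual


def evaluate(
    panel: VariantPanel,
    weights: WeightVector = PUBLISHED_WEIGHTS,
    model: LinearTmModel = PUBLISHED_TM_MODEL,
    volumes: Mapping[str, float] = VOLUMES,
) -> EvalResult:
    """R² (1 - SSres/SStot), MSE (n denominator) and residuals on a panel."""
    x = panel.indices(weights, volumes)
    y = panel.tm_obs
    yhat = predict_tm(x, model)
    ssr = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else (1.0 if ssr == 0 else 0.0)
    table = pd.DataFrame({
        "variant": panel.table.variant,
        "Tm_obs": y, "Tm_pred": yhat, "residual": yhat - y,
    })
    return EvalResult(r2, ssr / len(y), table)


def binding_energy(e_complex: float, e_ligand: float, e_receptor: float) -> float:
    """Binding energy as complex minus ligand minus receptor (common units)."""
    for v in (e_complex, e_ligand, e_receptor):
        if not np.isfinite(v):
            raise ContractViolation("binding_energy requires finite inputs")
    return e_complex - e_ligand - e_receptor
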