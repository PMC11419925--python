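"""End-to-end orchestration: scan → aggregate → score → predict.

Runs are driven by a :class:`RunConfig`; unspecified criteria fall back to
the published defaults, the configuration is echoed verbatim into the
output directory, and every output file carries a provenance header with
the package version and the configuration hash, so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import HemelockError
from .interactions import (
    GeometricCriteria,
    aggregate,
    default_acceptors,
    events_to_tsv,
    load_donor_dictionary,
    scan_trajectory,
)
from .io_structures import Structure, Trajectory, read_pdb
from .model import (
    PUBLISHED_TM_MODEL,
    PUBLISHED_WEIGHTS,
    LinearTmModel,
    ScoreBreakdown,
    VariantPanel,
    WeightVector,
    index_from_summary,
    predict_tm,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings of one scan-and-score run."""

    trajectories: dict[str, str]          # variant label -> PDB path
    aa181: dict[str, str]                 # variant label -> 3-letter code
    outdir: str = "hemelock_out"
    residue_seq: int = 181
    criteria: GeometricCriteria = field(default_factory=GeometricCriteria)
    frequency_mode: str = "frame_fraction"
    propionate_groups: tuple[str, ...] = ("A", "D")
    salt_bridge_priority: bool = False
    heme_resname: str = "HEM"
    donor_config: str | None = None
    weights: WeightVector = PUBLISHED_WEIGHTS
    tm_model: LinearTmModel = field(
        default_factory=lambda: LinearTmModel(PUBLISHED_TM_MODEL.slope,
                                              PUBLISHED_TM_MODEL.intercept))
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["propionate_groups"] = list(self.propionate_groups)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return f"# hemelock {__version__} config={config.config_hash()} seed={config.seed}\n"


def run_scan_score(config: RunConfig) -> dict[str, ScoreBreakdown]:
    """Scan every variant trajectory, aggregate, and score the key residue.

    Writes per-variant ``<variant>.events.tsv`` and ``<variant>.summary.tsv``
    plus a combined ``scores.tsv`` and the echoed configuration into
    ``config.outdir``; returns the per-variant score breakdowns.
    """
    if not config.trajectories:
        raise HemelockError("no input trajectories configured")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(
        _provenance(config) + yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    donors = load_donor_dictionary(config.donor_config)
    acceptors = default_acceptors(config.propionate_groups)

    breakdowns: dict[str, ScoreBreakdown] = {}
    rows = []
    for variant, path in sorted(config.trajectories.items()):
        try:
            obj = read_pdb(path)
        except (OSError, HemelockError) as exc:
            raise HemelockError(f"stage=read variant={variant}: {exc}") from exc
        traj = obj if isinstance(obj, Trajectory) else Trajectory([obj])
        try:
            events = scan_trajectory(
                traj, donors, acceptors, config.criteria, config.heme_resname,
                salt_bridge_priority=config.salt_bridge_priority,
            )
            summary = aggregate(events, traj.n_frames, config.frequency_mode)
        except HemelockError as exc:
            raise HemelockError(f"stage=scan variant={variant}: {exc}") from exc
        events_to_tsv(events, outdir / f"{variant}.events.tsv")
        with open(outdir / f"{variant}.summary.tsv", "w") as fh:
            fh.write(_provenance(config))
        with open(outdir / f"{variant}.summary.tsv", "a") as fh:
            summary.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        bd = index_from_summary(
            summary, config.residue_seq, config.aa181[variant], config.weights
        )
        breakdowns[variant] = bd
        rows.append({
            "variant": variant,
            "bb_ch_term": bd.bb_ch_term, "sc_h_term": bd.sc_h_term,
            "sc_ch_term": bd.sc_ch_term, "sc_sb_term": bd.sc_sb_term,
            "interaction_score": bd.interaction_score,
            "size_score": bd.size_score,
            "hemelock_index": bd.hemelock_index,
            "tm_pred": float(predict_tm(bd.hemelock_index, config.tm_model)),
        })
    with open(outdir / "scores.tsv", "w") as fh:
        fh.write(_provenance(config))
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, float_format="%.6g")
    return breakdowns


def run_predict(
    panel: VariantPanel,
    weights: WeightVector = PUBLISHED_WEIGHTS,
    model: LinearTmModel = PUBLISHED_TM_MODEL,
    out_path=None,
) -> pd.DataFrame:
    """Predicted-Tm table with observed/predicted/difference columns.

    ``difference`` is predicted minus observed.
    """
    if model is None or not hasattr(model, "slope"):
        raise HemelockError("no Tm model available")
    idx = panel.indices(weights)
    pred = predict_tm(idx, model)
    table = pd.DataFrame({
        "variant": panel.table.variant,
        "hemelock_index": idx,
        "observed": panel.tm_obs,
        "predicted": pred,
        "difference": pred - panel.tm_obs,
    })
    if out_path is not None:
        table.to_csv(out_path, sep="\t", index=False, float_format="%.6g")
    return table


def save_model(weights: WeightVector, model: LinearTmModel, path,
               note: str = "") -> None:
    """Persist a fitted model as structured text."""
    payload = {
        "weights": {f"w{i}": float(getattr(weights, f"w{i}")) for i in range(1, 6)},
        "slope": float(model.slope), "intercept": float(model.intercept),
        "r2": None if pd.isna(model.r2) else float(model.r2),
        "n": model.n, "note": note, "tool": f"hemelock {__version__}",
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_model(path) -> tuple[WeightVector, LinearTmModel]:
    raw = yaml.safe_load(Path(path).read_text())
    w = raw["weights"]
    weights = WeightVector(w["w1"], w["w2"], w["w3"], w["w4"], w["w5"])
    model = LinearTmModel(raw["slope"], raw["intercept"],
                          r2=raw.get("r2") or float("nan"), n=raw.get("n", 0))
    return weights, model
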