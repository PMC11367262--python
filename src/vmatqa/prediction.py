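"""Gamma-passing-rate prediction from arc features.

A gradient-boosted tree regressor maps 19 numeric features of an arc — the
ten complexity metrics plus nine plan/delivery parameters — to its expected
gamma passing rate (%).  The model mirrors the clinical deployment pattern:
train on a historical cohort of (features, measured GPR) rows, then score
every newly approved arc; per-feature additive attributions explain each
prediction to the planner.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .complexity import DEFAULT_LIMITS, METRIC_NAMES, MachineLimits, compute_all
from .errors import ValidationError
from .plan_model import Arc, arc_geometry
from .complexity import _gantry_deltas  # shared wrap-aware gantry arithmetic

PLAN_FEATURE_NAMES = (
    "total_mu",
    "mu_per_deg",
    "mean_gantry_speed",
    "mean_dose_rate",
    "dose_rate_std",
    "equiv_square_field",
    "n_control_points",
    "arc_length_deg",
    "mean_aperture_area",
)

FEATURE_NAMES: tuple[str, ...] = METRIC_NAMES + PLAN_FEATURE_NAMES

DEFAULT_CONFIG = {
    "n_estimators": 300,
    "max_depth": 4,
    "learning_rate": 0.08,
    "min_child_weight": 4.0,
}


def assemble_features(
    arc: Arc, limits: MachineLimits = DEFAULT_LIMITS
) -> dict[str, float]:
    """The deterministic 19-feature vector of an arc, in canonical order."""
    metrics = compute_all(arc, limits).as_dict()

    geo = arc_geometry(arc)
    w = arc.meterset_weights()
    dmu = np.diff(w) * arc.total_mu
    dgantry = _gantry_deltas(arc.gantry_angles())
    arc_len = float(dgantry.sum())
    dt = np.maximum(
        dgantry / limits.max_gantry_speed, dmu / (limits.max_dose_rate / 60.0)
    )
    dt = np.where(dt > 0, dt, np.nan)
    t_total = float(np.nansum(dt))
    gantry_speed = float(arc_len / t_total) if t_total > 0 else 0.0
    seg_dr = dmu / dt * 60.0
    mean_dr = float(np.nansum(seg_dr * dt) / t_total) if t_total > 0 else 0.0
    dr_std = float(np.nanstd(seg_dr))

    # union aperture area (same construction as beam modulation)
    widths = geo["width"].max(axis=0)
    union_area = 0.0
    for i in range(geo["gap"].shape[1]):
        ks = np.nonzero(geo["open"][:, i])[0]
        if len(ks) == 0:
            continue
        ivals = sorted(zip(geo["lo"][ks, i], geo["hi"][ks, i]))
        length, (cur_lo, cur_hi) = 0.0, ivals[0]
        for lo, hi in ivals[1:]:
            if lo > cur_hi:
                length += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        union_area += (length + cur_hi - cur_lo) * widths[i]

    features = dict(metrics)
    features.update(
        {
            "total_mu": float(arc.total_mu),
            "mu_per_deg": float(arc.total_mu / arc_len) if arc_len > 0 else 0.0,
            "mean_gantry_speed": gantry_speed,
            "mean_dose_rate": mean_dr,
            "dose_rate_std": dr_std,
            "equiv_square_field": float(np.sqrt(union_area)),
            "n_control_points": float(arc.n_control_points),
            "arc_length_deg": arc_len,
            "mean_aperture_area": float(geo["area"].mean()),
        }
    )
    return {name: features[name] for name in FEATURE_NAMES}


def _to_matrix(table: pd.DataFrame, feature_names: tuple[str, ...]) -> np.ndarray:
    missing = [c for c in feature_names if c not in table.columns]
    if missing:
        raise ValidationError(f"feature columns missing from table: {missing}")
    x = table[list(feature_names)].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite feature values")
    return x


@dataclass
class GPRModel:
    """A trained GPR regressor with its frozen feature contract."""

    booster: xgb.Booster
    feature_names: tuple[str, ...] = FEATURE_NAMES
    metadata: dict = field(default_factory=dict)
    version: str = "1"

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Predicted GPR (%) per row, clipped to [0, 100]."""
        x = _to_matrix(table, self.feature_names)
        raw = self.booster.predict(xgb.DMatrix(x))
        return np.clip(raw, 0.0, 100.0)

    def predict_raw(self, table: pd.DataFrame) -> np.ndarray:
        return self.booster.predict(xgb.DMatrix(_to_matrix(table, self.feature_names)))

    def save(self, path) -> None:
        payload = {
            "version": self.version,
            "feature_names": list(self.feature_names),
            "metadata": self.metadata,
            "booster": self.booster.save_raw("json").decode(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "GPRModel":
        with open(path) as fh:
            payload = json.load(fh)
        booster = xgb.Booster()
        booster.load_model(bytearray(payload["booster"].encode()))
        return cls(
            booster=booster,
            feature_names=tuple(payload["feature_names"]),
            metadata=payload["metadata"],
            version=payload.get("version", "1"),
        )


def train_model(
    table: pd.DataFrame,
    config: dict | None = None,
    seed: int = 0,
    label_column: str = "gpr",
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> GPRModel:
    """Fit the gradient-boosted regressor on (features, measured GPR) rows.

    Deterministic for a fixed seed (single-threaded training); requires at
    least 50 rows with finite labels in [0, 100].
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    if len(table) < 50:
        raise ValidationError(f"need >= 50 training rows, got {len(table)}")
    y = table[label_column].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("non-finite GPR labels")
    if y.min() < 0 or y.max() > 100:
        raise ValidationError("GPR labels must lie in [0, 100]")
    x = _to_matrix(table, feature_names)

    params = {
        "objective": "reg:squarederror",
        "max_depth": int(cfg["max_depth"]),
        "eta": float(cfg["learning_rate"]),
        "min_child_weight": float(cfg["min_child_weight"]),
        "seed": int(seed),
        "nthread": 1,
    }
    booster = xgb.train(
        params, xgb.DMatrix(x, label=y), num_boost_round=int(cfg["n_estimators"])
    )
    meta = {
        "n": int(len(table)),
        "seed": int(seed),
        "hyperparameters": cfg,
        "date": _dt.date.today().isoformat(),
    }
    return GPRModel(booster=booster, feature_names=feature_names, metadata=meta)


def predict_gpr(model: GPRModel, features: dict[str, float] | pd.DataFrame) -> float:
    """Predicted GPR (%) for a single feature vector."""
    if isinstance(features, dict):
        extra = set(features) - set(model.feature_names)
        missing = set(model.feature_names) - set(features)
        if extra or missing:
            raise ValidationError(
                f"feature mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}"
            )
        features = pd.DataFrame([features])
    return float(model.predict(features)[0])


@dataclass(frozen=True)
class EvaluationReport:
    mae: float
    sensitivity: float | None
    specificity: float | None
    n_test: int
    action_limit: float


def evaluate_model(
    model: GPRModel,
    table: pd.DataFrame,
    action_limit: float = 90.0,
    label_column: str = "gpr",
) -> EvaluationReport:
    """Held-out MAE plus failure-detection sensitivity/specificity.

    Sensitivity is the fraction of truly failing arcs (label < limit) that
    the model also predicts below the limit; specificity the analogue for
    passing arcs.  Either is ``None`` when its class is absent.
    """
    y = table[label_column].to_numpy(dtype=float)
    pred = model.predict(table)
    mae = float(np.mean(np.abs(pred - y)))
    fail = y < action_limit
    sens = float(np.mean(pred[fail] < action_limit)) if fail.any() else None
    spec = float(np.mean(pred[~fail] >= action_limit)) if (~fail).any() else None
    return EvaluationReport(
        mae=mae,
        sensitivity=sens,
        specificity=spec,
        n_test=len(y),
        action_limit=action_limit,
    )


def feature_attribution(
    model: GPRModel, features: dict[str, float] | pd.DataFrame
) -> pd.DataFrame:
    """Signed additive per-feature contributions to the (raw) prediction.

    Returns one row per input row with a column per feature plus ``baseline``;
    contributions + baseline sum to the unclipped prediction (additive
    attribution contract), so clipping at 0/100 can introduce a bounded
    discrepancy only for extreme arcs.
    """
    if isinstance(features, dict):
        features = pd.DataFrame([features])
    x = _to_matrix(features, model.feature_names)
    contribs = model.booster.predict(xgb.DMatrix(x), pred_contribs=True)
    cols = list(model.feature_names) + ["baseline"]
    return pd.DataFrame(contribs, columns=cols)
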