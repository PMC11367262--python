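"""Lean Six Sigma process monitoring of VMAT plan complexity.

Historical per-arc metric distributions, stratified by treatment site,
define specification limits at the 5th and 95th percentiles.  A new arc's
metrics are flagged against these limits; each metric also carries a
*complexity direction* so that an out-of-spec value can be classified as
lying in the high-complexity region (small gaps and small MCS mean *more*
complex, large TGI means more complex, and so on).

Two arc-level rules follow: an arc is a *defect* of the optimization
process when more than five of its ten metrics fall outside the limits, and
*at risk* of QA failure when more than five lie in the high-complexity
region.  A plan is at risk when a strict majority of its arcs are at risk,
or when its mean predicted gamma passing rate falls below the action limit.
The daily "Poka Yoke" scan applies this decision to every approved plan in
a directory and writes a report per plan, copying at-risk reports into an
outbox directory that a mail hook can watch.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .complexity import DEFAULT_LIMITS, METRIC_NAMES, MachineLimits, compute_all
from .errors import ValidationError
from .plan_model import Plan, read_rtplan
from .prediction import GPRModel, assemble_features, feature_attribution

logger = logging.getLogger(__name__)

MIN_STRATUM_SIZE = 20
POOLED_SITE = "__pooled__"


class Direction(Enum):
    HIGH_IS_COMPLEX = "high"
    LOW_IS_COMPLEX = "low"


#: Which end of each metric's distribution is the high-complexity region.
DEFAULT_DIRECTIONS: dict[str, Direction] = {
    "q1_mlc_gap": Direction.LOW_IS_COMPLEX,
    "median_mlc_gap": Direction.LOW_IS_COMPLEX,
    "mcs": Direction.LOW_IS_COMPLEX,
    "sas10": Direction.HIGH_IS_COMPLEX,
    "mean_tgi": Direction.HIGH_IS_COMPLEX,
    "mi_total": Direction.HIGH_IS_COMPLEX,
    "bi": Direction.HIGH_IS_COMPLEX,
    "bm": Direction.HIGH_IS_COMPLEX,
    "edge_metric": Direction.HIGH_IS_COMPLEX,
    "lt_al": Direction.HIGH_IS_COMPLEX,
}


class FlagStatus(Enum):
    IN_SPEC = "in_spec"
    LOW_OUTLIER = "low_outlier"
    HIGH_OUTLIER = "high_outlier"


@dataclass(frozen=True)
class MetricFlag:
    metric: str
    status: FlagStatus
    is_high_complexity: bool


@dataclass
class SpecificationLimits:
    """Per-(site, metric) 5th/95th-percentile specification limits."""

    limits: dict[str, dict[str, dict[str, float]]]
    baseline_label: str = ""

    def sites(self) -> list[str]:
        return [s for s in self.limits if s != POOLED_SITE]

    def usable(self, site: str) -> bool:
        entry = self.limits.get(site)
        return bool(entry) and all(
            entry[m]["n"] >= MIN_STRATUM_SIZE for m in entry
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"baseline_label": self.baseline_label, "limits": self.limits}, fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "SpecificationLimits":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(limits=payload["limits"], baseline_label=payload.get("baseline_label", ""))


def build_limits(
    table: pd.DataFrame,
    stratify_by: str = "site",
    lower_pct: float = 5.0,
    upper_pct: float = 95.0,
    baseline_label: str = "",
) -> SpecificationLimits:
    """Percentile specification limits from a per-arc metrics table.

    The table needs the ten metric columns plus the stratification column.
    A pooled stratum over all rows is always included (key ``__pooled__``)
    for use as a fallback on unknown sites.  Strata with fewer than
    20 rows are kept but marked unusable.
    """
    missing = [m for m in METRIC_NAMES if m not in table.columns]
    if missing:
        raise ValidationError(f"metrics table lacks columns: {missing}")
    out: dict[str, dict[str, dict[str, float]]] = {}

    def stratum_limits(rows: pd.DataFrame) -> dict[str, dict[str, float]]:
        entry = {}
        for m in METRIC_NAMES:
            vals = rows[m].to_numpy(dtype=float)
            entry[m] = {
                "low": float(np.percentile(vals, lower_pct)),
                "high": float(np.percentile(vals, upper_pct)),
                "n": int(len(vals)),
            }
        return entry

    for site, rows in table.groupby(stratify_by):
        out[str(site)] = stratum_limits(rows)
        if len(rows) < MIN_STRATUM_SIZE:
            logger.warning(
                "stratum %r has only %d arcs (<%d): marked unusable",
                site, len(rows), MIN_STRATUM_SIZE,
            )
    out[POOLED_SITE] = stratum_limits(table)
    return SpecificationLimits(limits=out, baseline_label=baseline_label)


def flag_metrics(
    metrics: dict[str, float],
    limits: SpecificationLimits,
    site: str,
    directions: dict[str, Direction] = DEFAULT_DIRECTIONS,
) -> list[MetricFlag]:
    """Flag each metric against its site's specification limits.

    Values strictly outside [low, high] are outliers (a value exactly on a
    limit is in spec); an outlier on the metric's complex side is marked
    ``is_high_complexity``.
    """
    if site not in limits.limits:
        raise ValidationError(
            f"unknown treatment site {site!r}; known sites: {sorted(limits.sites())}"
        )
    entry = limits.limits[site]
    flags = []
    for m in METRIC_NAMES:
        v = float(metrics[m])
        lo, hi = entry[m]["low"], entry[m]["high"]
        if v < lo:
            status = FlagStatus.LOW_OUTLIER
        elif v > hi:
            status = FlagStatus.HIGH_OUTLIER
        else:
            status = FlagStatus.IN_SPEC
        direction = directions[m]
        high_cx = (
            status is FlagStatus.HIGH_OUTLIER
            and direction is Direction.HIGH_IS_COMPLEX
        ) or (
            status is FlagStatus.LOW_OUTLIER and direction is Direction.LOW_IS_COMPLEX
        )
        flags.append(MetricFlag(metric=m, status=status, is_high_complexity=high_cx))
    return flags


def arc_is_defect(flags: list[MetricFlag]) -> bool:
    """Defect of the optimization process: more than five metrics out of spec."""
    return sum(f.status is not FlagStatus.IN_SPEC for f in flags) > 5


def arc_at_risk(flags: list[MetricFlag]) -> bool:
    """At risk of QA failure: more than five metrics in the high-complexity region."""
    return sum(f.is_high_complexity for f in flags) > 5


def plan_at_risk(
    arc_flags: list[list[MetricFlag]],
    predicted_gprs: list[float],
    action_limit: float = 90.0,
) -> tuple[bool, str]:
    """Plan-level decision and the clause that triggered it.

    A plan is at risk when a strict majority of its arcs are at risk
    (complexity clause; an exact tie does not trigger) or when the mean
    predicted GPR falls below the action limit.
    """
    if not arc_flags or len(arc_flags) != len(predicted_gprs):
        raise ValidationError("need matching, non-empty flag and prediction lists")
    n_risk = sum(arc_at_risk(f) for f in arc_flags)
    majority = n_risk > len(arc_flags) / 2.0
    low_gpr = float(np.mean(predicted_gprs)) < action_limit
    if majority and low_gpr:
        return True, "both"
    if majority:
        return True, "complexity-majority"
    if low_gpr:
        return True, "predicted-GPR"
    return False, ""


# ---------------------------------------------------------------------------
# Six Sigma arithmetic and cohort summaries
# ---------------------------------------------------------------------------

def dpmo(sigma_level: float, shift: float = 1.5) -> float:
    """Defects per million opportunities at a sigma level.

    Uses the conventional one-sided definition with a long-term mean shift
    (default 1.5 sigma): 1e6 times the standard-normal upper-tail probability
    beyond (sigma_level - shift).  dpmo(6) = 3.4, the Six Sigma touchstone.
    """
    if shift < 0 or sigma_level < shift:
        raise ValidationError("require sigma_level >= shift >= 0")
    return float(1e6 * stats.norm.sf(sigma_level - shift))


def compare_distributions(pre: list[float], post: list[float]) -> dict:
    """Two-sided Mann-Whitney comparison of two GPR samples.

    Returns the U statistic, p-value, and each sample's median and
    quartiles, formatted as ``median [Q1, Q3]`` strings.
    """
    pre_a, post_a = np.asarray(pre, float), np.asarray(post, float)
    if len(pre_a) == 0 or len(post_a) == 0:
        raise ValidationError("both samples must be non-empty")
    u, p = stats.mannwhitneyu(pre_a, post_a, alternative="two-sided")

    def summary(a: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(a, [25, 50, 75])
        return {
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "formatted": f"{med:.1f} % [{q1:.1f}, {q3:.1f}]%",
        }

    return {"U": float(u), "p_value": float(p), "pre": summary(pre_a), "post": summary(post_a)}


def occupancy_summary(
    table: pd.DataFrame,
    limits: SpecificationLimits,
    directions: dict[str, Direction] = DEFAULT_DIRECTIONS,
    stratify_by: str = "site",
) -> pd.DataFrame:
    """Fraction of arcs below/above the specification limits, per site and metric.

    ``frac_low``/``frac_high`` are the occupancies of the low/high *metric*
    tails; ``frac_low_complexity``/``frac_high_complexity`` reorient them by
    each metric's complexity direction (the monitoring table of interest).
    Sites absent from the limits are reported with NaN occupancies.
    """
    rows = []
    for site, grp in table.groupby(stratify_by):
        known = str(site) in limits.limits
        for m in METRIC_NAMES:
            if known:
                lo = limits.limits[str(site)][m]["low"]
                hi = limits.limits[str(site)][m]["high"]
                vals = grp[m].to_numpy(dtype=float)
                frac_low = float(np.mean(vals < lo))
                frac_high = float(np.mean(vals > hi))
            else:
                frac_low = frac_high = float("nan")
            swap = directions[m] is Direction.LOW_IS_COMPLEX
            rows.append(
                {
                    "site": site,
                    "metric": m,
                    "n": len(grp),
                    "frac_low": frac_low,
                    "frac_high": frac_high,
                    "frac_low_complexity": frac_high if swap else frac_low,
                    "frac_high_complexity": frac_low if swap else frac_high,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Risk reports and the daily Poka Yoke scan
# ---------------------------------------------------------------------------

@dataclass
class ArcReport:
    beam_id: str
    metrics: dict[str, float]
    flags: list[MetricFlag]
    predicted_gpr: float
    defect: bool
    at_risk: bool
    attributions: dict[str, float] = field(default_factory=dict)


@dataclass
class RiskReport:
    plan_id: str
    site: str
    timestamp: str
    arcs: list[ArcReport]
    plan_at_risk: bool
    reason: str
    mean_predicted_gpr: float

    def to_dict(self) -> dict:
        return {
            "plan_id": self.plan_id,
            "site": self.site,
            "timestamp": self.timestamp,
            "plan_at_risk": self.plan_at_risk,
            "reason": self.reason,
            "mean_predicted_gpr": self.mean_predicted_gpr,
            "arcs": [
                {
                    "beam_id": a.beam_id,
                    "metrics": a.metrics,
                    "flags": {
                        f.metric: {
                            "status": f.status.value,
                            "high_complexity": f.is_high_complexity,
                        }
                        for f in a.flags
                    },
                    "predicted_gpr": a.predicted_gpr,
                    "defect": a.defect,
                    "at_risk": a.at_risk,
                    "attributions": a.attributions,
                }
                for a in self.arcs
            ],
        }

    def to_html(self) -> str:
        rows = []
        for a in self.arcs:
            cells = "".join(
                f"<td class={f.status.value}>{a.metrics[f.metric]:.3g}</td>"
                for f in a.flags
            )
            rows.append(
                f"<tr><td>{a.beam_id}</td>{cells}"
                f"<td>{a.predicted_gpr:.1f}</td><td>{a.at_risk}</td></tr>"
            )
        header = "".join(f"<th>{m}</th>" for m in METRIC_NAMES)
        status = "AT RISK" if self.plan_at_risk else "ok"
        return (
            "<html><head><style>"
            "td.low_outlier{background:#9ecae1}td.high_outlier{background:#fc9272}"
            "</style></head><body>"
            f"<h2>Plan {self.plan_id} ({self.site}) — {status}"
            f"{' [' + self.reason + ']' if self.reason else ''}</h2>"
            f"<p>Mean predicted GPR: {self.mean_predicted_gpr:.1f} %</p>"
            f"<table border=1><tr><th>arc</th>{header}"
            "<th>pred GPR</th><th>at risk</th></tr>"
            + "".join(rows)
            + "</table></body></html>"
        )


def analyze_plan(
    plan: Plan,
    limits: SpecificationLimits,
    model: GPRModel,
    directions: dict[str, Direction] = DEFAULT_DIRECTIONS,
    machine_limits: MachineLimits = DEFAULT_LIMITS,
    action_limit: float = 90.0,
    unknown_site_policy: str = "error",
) -> RiskReport:
    """Full per-plan risk assessment: metrics, flags, prediction, decision."""
    site = plan.treatment_site
    if site not in limits.limits:
        if unknown_site_policy == "pooled":
            site = POOLED_SITE
        else:
            raise ValidationError(
                f"unknown treatment site {plan.treatment_site!r}; "
                f"known sites: {sorted(limits.sites())}"
            )
    arc_reports = []
    for arc in plan.arcs:
        features = assemble_features(arc, machine_limits)
        metrics = {m: features[m] for m in METRIC_NAMES}
        flags = flag_metrics(metrics, limits, site, directions)
        pred = float(model.predict(pd.DataFrame([features]))[0])
        attr = feature_attribution(model, features).iloc[0].to_dict()
        arc_reports.append(
            ArcReport(
                beam_id=arc.beam_id,
                metrics=metrics,
                flags=flags,
                predicted_gpr=pred,
                defect=arc_is_defect(flags),
                at_risk=arc_at_risk(flags),
                attributions={k: float(v) for k, v in attr.items()},
            )
        )
    at_risk, reason = plan_at_risk(
        [a.flags for a in arc_reports],
        [a.predicted_gpr for a in arc_reports],
        action_limit,
    )
    return RiskReport(
        plan_id=plan.plan_id,
        site=plan.treatment_site,
        timestamp=_dt.datetime.now().isoformat(timespec="seconds"),
        arcs=arc_reports,
        plan_at_risk=at_risk,
        reason=reason,
        mean_predicted_gpr=float(np.mean([a.predicted_gpr for a in arc_reports])),
    )


def daily_scan(
    plan_dir,
    limits: SpecificationLimits,
    model: GPRModel,
    out_dir,
    directions: dict[str, Direction] = DEFAULT_DIRECTIONS,
    machine_limits: MachineLimits = DEFAULT_LIMITS,
    action_limit: float = 90.0,
    unknown_site_policy: str = "error",
    force: bool = False,
) -> list[RiskReport]:
    """End-of-day Poka Yoke batch scan of a directory of RT Plan files.

    Writes one JSON + HTML report per newly seen plan under
    ``out_dir/reports``, mirrors at-risk reports into ``out_dir/outbox``
    (the e-mail hook point), and records processed plan ids in a state file
    so that re-runs are idempotent unless *force* is set.  Unreadable plans
    are logged and skipped.
    """
    plan_dir, out_dir = Path(plan_dir), Path(out_dir)
    reports_dir = out_dir / "reports"
    outbox = out_dir / "outbox"
    reports_dir.mkdir(parents=True, exist_ok=True)
    outbox.mkdir(parents=True, exist_ok=True)
    state_path = out_dir / "scan_state.json"
    seen: list[str] = []
    if state_path.exists() and not force:
        seen = json.loads(state_path.read_text()).get("processed", [])

    reports = []
    for path in sorted(plan_dir.glob("*.dcm")):
        try:
            plan = read_rtplan(path)
        except Exception as exc:  # scan must survive a broken file
            logger.error("skipping unreadable plan %s: %s", path.name, exc)
            continue
        if plan.plan_id in seen and not force:
            continue
        try:
            report = analyze_plan(
                plan, limits, model, directions, machine_limits,
                action_limit, unknown_site_policy,
            )
        except ValidationError as exc:
            logger.error("skipping plan %s: %s", plan.plan_id, exc)
            continue
        reports.append(report)
        seen.append(plan.plan_id)
        (reports_dir / f"{plan.plan_id}.json").write_text(
            json.dumps(report.to_dict(), indent=1)
        )
        (reports_dir / f"{plan.plan_id}.html").write_text(report.to_html())
        if report.plan_at_risk:
            (outbox / f"{plan.plan_id}.json").write_text(
                json.dumps(report.to_dict(), indent=1)
            )
    state_path.write_text(json.dumps({"processed": seen}, indent=1))
    return reports
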