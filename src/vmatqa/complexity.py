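"""Per-arc VMAT complexity metrics.

Ten metrics are computed for each arc, each summarizing one aspect of how
aggressively the optimizer modulated the machine:

====================  =====================================================
``q1_mlc_gap``        first quartile of the pooled open MLC gap sizes (mm)
``median_mlc_gap``    median of the same distribution (mm)
``sas10``             small-aperture score: fraction of open gaps < 10 mm
``mean_tgi``          mean tongue-and-groove index (aperture irregularity)
``mcs``               modulation complexity score (shape x area variability)
``mi_total``          modulation index for total modulation (MLC dynamics
                      weighted by gantry-speed and dose-rate variability)
``bi``                beam irregularity: non-circularity of the aperture
``bm``                beam modulation: dose delivered through apertures
                      small relative to the union aperture
``edge_metric``       MLC side-edge length per unit aperture area (1/mm)
``lt_al``             mean leaf travel per degree of gantry arc (mm/deg)
====================  =====================================================

Aperture-shape metrics (TGI, irregularity, edge metric, beam modulation) are
meterset-weighted over control points, each control point carrying the
meterset fraction of the segment that ends at it.  This convention makes
every weighted metric invariant under splitting a control point into two
identical halves of the delivered MU, and under re-normalization of the
cumulative weights.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import ClosedApertureError, ValidationError
from .plan_model import DEFAULT_MIN_GAP, Arc, arc_geometry

METRIC_NAMES = (
    "q1_mlc_gap",
    "median_mlc_gap",
    "sas10",
    "mean_tgi",
    "mcs",
    "mi_total",
    "bi",
    "bm",
    "edge_metric",
    "lt_al",
)


@dataclass(frozen=True)
class MachineLimits:
    """Delivery-system limits used by the segment timing model."""

    max_leaf_speed: float = 25.0      # mm/s
    max_gantry_speed: float = 6.0     # deg/s
    max_dose_rate: float = 600.0      # MU/min

    def __post_init__(self) -> None:
        if min(self.max_leaf_speed, self.max_gantry_speed, self.max_dose_rate) <= 0:
            raise ValidationError("machine limits must all be positive")


DEFAULT_LIMITS = MachineLimits()


@dataclass(frozen=True)
class ComplexityVector:
    """The ten per-arc complexity metrics, in canonical order."""

    q1_mlc_gap: float
    median_mlc_gap: float
    sas10: float
    mean_tgi: float
    mcs: float
    mi_total: float
    bi: float
    bm: float
    edge_metric: float
    lt_al: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in METRIC_NAMES])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _geometry(arc: Arc, min_gap: float) -> dict[str, np.ndarray]:
    geo = arc_geometry(arc, min_gap)
    if not np.any(geo["open"]):
        raise ClosedApertureError(
            f"arc {arc.beam_id}: no open aperture at any control point"
        )
    return geo


def _cp_weights(arc: Arc) -> np.ndarray:
    """Meterset weight per control point: the fraction of the segment ending
    at it (first control point carries zero)."""
    w = arc.meterset_weights()
    out = np.zeros(len(w))
    out[1:] = np.diff(w)
    total = out.sum()
    if total <= 0:
        raise ValidationError(f"arc {arc.beam_id}: zero total meterset span")
    return out / total


def _weighted_mean(values: np.ndarray, weights: np.ndarray, mask: np.ndarray) -> float:
    wsum = weights[mask].sum()
    if wsum <= 0:  # MU delivered only at closed control points: unweighted fallback
        return float(values[mask].mean())
    return float(np.sum(values[mask] * weights[mask]) / wsum)


def _gantry_deltas(angles: np.ndarray) -> np.ndarray:
    """Per-segment absolute gantry rotation, shortest path across 0/360."""
    d = np.diff(angles)
    return np.abs((d + 180.0) % 360.0 - 180.0)


def _pooled_gaps(geo: dict[str, np.ndarray]) -> np.ndarray:
    return geo["gap"][geo["open"]]


# ---------------------------------------------------------------------------
# individual metrics
# ---------------------------------------------------------------------------

def gap_quantiles(arc: Arc, min_gap: float = DEFAULT_MIN_GAP) -> tuple[float, float]:
    """First quartile and median of the pooled open-gap distribution (mm).

    Gaps from every control point are pooled unweighted; quantiles use
    linear interpolation between order statistics.
    """
    gaps = _pooled_gaps(_geometry(arc, min_gap))
    return float(np.percentile(gaps, 25)), float(np.percentile(gaps, 50))


def small_aperture_score(
    arc: Arc, threshold: float = 10.0, min_gap: float = DEFAULT_MIN_GAP
) -> float:
    """Fraction of pooled open MLC gaps strictly smaller than *threshold* mm."""
    gaps = _pooled_gaps(_geometry(arc, min_gap))
    return float(np.mean(gaps < threshold))


def mean_tgi(arc: Arc, min_gap: float = DEFAULT_MIN_GAP) -> float:
    """Meterset-weighted mean tongue-and-groove index.

    Per control point TGI = S / (S + G), with S the exposed adjacent-leaf
    side-step length and G the summed open gap length; 0 for a rectangular
    aperture, approaching 1 as side steps dominate the opening.
    """
    geo = _geometry(arc, min_gap)
    s = geo["side_edge"]
    g = geo["gap"].sum(axis=1)
    open_cp = geo["area"] > 0
    tgi = np.zeros(len(s))
    tgi[open_cp] = s[open_cp] / (s[open_cp] + g[open_cp])
    return _weighted_mean(tgi, _cp_weights(arc), open_cp)


def mcs(arc: Arc, min_gap: float = DEFAULT_MIN_GAP) -> float:
    """Modulation complexity score for a VMAT arc, in (0, 1].

    Per control point, the aperture-area variability AAV is the open area
    normalized by the area each leaf pair ever exposes over the arc, and the
    leaf-sequence variability LSV measures how uniform each bank's leaf-tip
    profile is.  Segment contributions average the two bounding control
    points and are weighted by the segment meterset fraction; an arc of
    identical rectangular apertures scores exactly 1.
    """
    geo = _geometry(arc, min_gap)
    gap = geo["gap"]
    open_mask = geo["open"]

    per_pair_max = gap.max(axis=0)
    denom = per_pair_max.sum()
    aav = gap.sum(axis=1) / denom if denom > 0 else np.zeros(gap.shape[0])

    K = gap.shape[0]
    lsv = np.ones(K)
    for k in range(K):
        idx = np.nonzero(open_mask[k])[0]
        if len(idx) < 2:
            continue
        term = 1.0
        for bank in ("lo", "hi"):
            pos = geo[bank][k, idx]
            pmax = pos.max() - pos.min()
            if pmax <= 0:
                continue
            diffs = np.abs(np.diff(pos))
            term *= np.sum(pmax - diffs) / ((len(idx) - 1) * pmax)
        lsv[k] = term

    dw = np.diff(arc.meterset_weights())
    dw = dw / dw.sum()
    val = np.sum(0.5 * (aav[:-1] + aav[1:]) * 0.5 * (lsv[:-1] + lsv[1:]) * dw)
    return float(val)


def mi_total(
    arc: Arc,
    limits: MachineLimits = DEFAULT_LIMITS,
    min_gap: float = DEFAULT_MIN_GAP,
    f_step: float = 0.01,
) -> float:
    """Modulation index for total modulation.

    Builds a segment timing model (duration limited by gantry speed or dose
    rate), derives leaf speeds and accelerations, and integrates over
    f in [0, 2] the weighted fraction Z(f) of (leaf, segment) samples whose
    speed exceeds f standard deviations of the speed distribution or whose
    acceleration exceeds f standard deviations of the acceleration
    distribution.  Segments are weighted up when gantry speed or dose rate
    changes, so the index also responds to those modulations.
    """
    if arc.n_control_points < 3:
        raise ValidationError(f"arc {arc.beam_id}: mi_total needs >= 3 control points")
    geo = _geometry(arc, min_gap)
    ever_open = geo["open"].any(axis=0)
    if not np.any(ever_open):
        raise ClosedApertureError(f"arc {arc.beam_id}: all leaf pairs closed")

    w = arc.meterset_weights()
    dmu = np.diff(w) * arc.total_mu
    dgantry = _gantry_deltas(arc.gantry_angles())
    dt = np.maximum(dgantry / limits.max_gantry_speed, dmu / (limits.max_dose_rate / 60.0))
    bad = np.nonzero(dt <= 0)[0]
    if len(bad):
        raise ValidationError(
            f"arc {arc.beam_id}: zero-duration segment {int(bad[0])}"
        )

    bank_a = np.stack([cp.bank_a_positions for cp in arc.control_points])
    bank_b = np.stack([cp.bank_b_positions for cp in arc.control_points])
    travel = np.concatenate(
        [np.abs(np.diff(bank_a[:, ever_open], axis=0)),
         np.abs(np.diff(bank_b[:, ever_open], axis=0))],
        axis=1,
    )                                           # (K-1, 2*n_open)
    speed = travel / dt[:, None]

    accel = np.zeros_like(speed)
    mid_dt = 0.5 * (dt[:-1] + dt[1:])
    accel[1:] = np.diff(speed, axis=0) / mid_dt[:, None]

    sigma_v = float(speed.std())
    sigma_a = float(accel[1:].std()) if speed.shape[0] > 1 else 0.0

    gantry_speed = dgantry / dt
    dose_rate = dmu / dt * 60.0
    w_seg = np.ones(len(dt))
    w_seg[1:] = (1.0 + np.abs(np.diff(gantry_speed)) / limits.max_gantry_speed) * (
        1.0 + np.abs(np.diff(dose_rate)) / limits.max_dose_rate
    )

    f_grid = np.arange(0.0, 2.0 + f_step / 2, f_step)
    hit = (speed[None, :, :] > f_grid[:, None, None] * sigma_v) | (
        np.abs(accel)[None, :, :] > f_grid[:, None, None] * sigma_a
    )
    z = np.sum(hit * w_seg[None, :, None], axis=(1, 2)) / (
        w_seg.sum() * speed.shape[1]
    )
    return float(np.trapezoid(z, f_grid))


def beam_irregularity(arc: Arc, min_gap: float = DEFAULT_MIN_GAP) -> float:
    """Meterset-weighted aperture irregularity: perimeter**2 / (4 pi area).

    Equals 1 for a disc and 4/pi for a square; larger for jagged apertures.
    """
    geo = _geometry(arc, min_gap)
    open_cp = geo["area"] > 0
    ai = np.zeros(len(geo["area"]))
    ai[open_cp] = geo["perimeter"][open_cp] ** 2 / (4.0 * np.pi * geo["area"][open_cp])
    return _weighted_mean(ai, _cp_weights(arc), open_cp)


def beam_modulation(arc: Arc, min_gap: float = DEFAULT_MIN_GAP) -> float:
    """Fraction of the union aperture left uncovered by the average segment.

    BM = 1 - sum_k w_k A_k / A_union, where A_union is the area of the
    union over control points of the exposed per-pair intervals.  0 when all
    apertures coincide; approaches 1 when each segment covers only a sliver
    of the total irradiated region.
    """
    geo = _geometry(arc, min_gap)
    widths = geo["width"].max(axis=0)
    union_area = 0.0
    for i in range(geo["gap"].shape[1]):
        ks = np.nonzero(geo["open"][:, i])[0]
        if len(ks) == 0:
            continue
        ivals = sorted(zip(geo["lo"][ks, i], geo["hi"][ks, i]))
        length = 0.0
        cur_lo, cur_hi = ivals[0]
        for lo, hi in ivals[1:]:
            if lo > cur_hi:
                length += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        length += cur_hi - cur_lo
        union_area += length * widths[i]
    if union_area <= 0:
        raise ClosedApertureError(f"arc {arc.beam_id}: empty union aperture")
    weights = _cp_weights(arc)
    return float(1.0 - np.sum(weights * geo["area"]) / union_area)


def edge_metric(arc: Arc, min_gap: float = DEFAULT_MIN_GAP) -> float:
    """Meterset-weighted MLC side-edge length per unit aperture area (1/mm).

    Side edges are the horizontal faces of the aperture polygon: exposed
    steps between adjacent open pairs plus the end caps of each open run.
    """
    geo = _geometry(arc, min_gap)
    open_cp = geo["area"] > 0
    em = np.zeros(len(geo["area"]))
    em[open_cp] = (geo["side_edge"][open_cp] + geo["cap_edge"][open_cp]) / geo["area"][
        open_cp
    ]
    return _weighted_mean(em, _cp_weights(arc), open_cp)


def leaf_travel_per_arc_length(
    arc: Arc, min_gap: float = DEFAULT_MIN_GAP
) -> float:
    """Mean total leaf travel (mm) divided by the gantry arc length (deg).

    The mean runs over the leaves of both banks belonging to pairs that are
    ever open; the arc length accumulates shortest-path segment rotations,
    so an arc crossing 0/360 is measured by what the gantry actually swept.
    """
    geo = _geometry(arc, min_gap)
    arc_len = _gantry_deltas(arc.gantry_angles()).sum()
    if arc_len <= 0:
        raise ValidationError(f"arc {arc.beam_id}: zero gantry arc length")
    ever_open = geo["open"].any(axis=0)
    bank_a = np.stack([cp.bank_a_positions for cp in arc.control_points])
    bank_b = np.stack([cp.bank_b_positions for cp in arc.control_points])
    travel_a = np.abs(np.diff(bank_a[:, ever_open], axis=0)).sum(axis=0)
    travel_b = np.abs(np.diff(bank_b[:, ever_open], axis=0)).sum(axis=0)
    lt = float(np.concatenate([travel_a, travel_b]).mean())
    return lt / float(arc_len)


def compute_all(
    arc: Arc,
    limits: MachineLimits = DEFAULT_LIMITS,
    min_gap: float = DEFAULT_MIN_GAP,
) -> ComplexityVector:
    """All ten metrics for one arc."""
    q1, med = gap_quantiles(arc, min_gap)
    return ComplexityVector(
        q1_mlc_gap=q1,
        median_mlc_gap=med,
        sas10=small_aperture_score(arc, min_gap=min_gap),
        mean_tgi=mean_tgi(arc, min_gap),
        mcs=mcs(arc, min_gap),
        mi_total=mi_total(arc, limits, min_gap),
        bi=beam_irregularity(arc, min_gap),
        bm=beam_modulation(arc, min_gap),
        edge_metric=edge_metric(arc, min_gap),
        lt_al=leaf_travel_per_arc_length(arc, min_gap),
    )
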