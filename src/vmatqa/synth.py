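"""Synthetic VMAT arcs, cohorts, QA labels, and dose-grid pairs.

Every other module is exercised on data from here, so no clinical dataset
is required.  An arc is generated from an elliptical target outline: at
modulation ``m = 0`` the aperture is a static conformal (rectangular-field)
arc — every metric then takes its degenerate textbook value (MCS = 1,
MeanTGI = 0, ...) — and as ``m`` rises toward 1 the leaf tips follow the
ellipse, gaps shrink, and smooth per-leaf sinusoidal perturbations of
amplitude proportional to ``m`` animate the banks.  The fraction of
strongly moving leaves also grows with ``m`` so that scale-free dynamics
indices respond to the dial as well.  The dial therefore orders every
directed complexity metric stochastically, which is the property the
monitoring and prediction layers rely on.

GPR labels are simulated with a logistic link on the directed, standardized
complexity metrics plus Gaussian noise; the default coefficients are
calibrated so that roughly 6 % of arcs in a default cohort fall below the
90 % action limit, matching the strong class imbalance such QA programs
face in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .complexity import METRIC_NAMES
from .gamma import DoseGrid
from .plan_model import Arc, ControlPoint, Plan
from .prediction import FEATURE_NAMES, assemble_features
from .spc import DEFAULT_DIRECTIONS, Direction


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic arc generator."""

    modulation: float = 0.5          # m in [0, 1]
    n_control_points: int = 178
    n_leaf_pairs: int = 40
    leaf_width: float = 5.0          # mm
    semi_axis_x: float = 30.0        # ellipse target half-width (mm)
    semi_axis_y: float = 60.0        # ellipse target half-height (mm)
    site: str = "generic"
    seed: int = 0
    mu_per_cp: float = 2.0           # baseline MU per control point

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation <= 1.0:
            raise ValueError("modulation must lie in [0, 1]")


def generate_arc(config: GeneratorConfig, beam_id: str = "arc1") -> Arc:
    """One synthetic VMAT arc; bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    m = config.modulation
    K, n = config.n_control_points, config.n_leaf_pairs
    half_span = n * config.leaf_width / 2.0
    boundaries = np.linspace(-half_span, half_span, n + 1)
    centers = 0.5 * (boundaries[:-1] + boundaries[1:])

    a, b = config.semi_axis_x, config.semi_axis_y
    inside = np.abs(centers) < b
    ellipse = np.zeros(n)
    ellipse[inside] = np.sqrt(1.0 - (centers[inside] / b) ** 2)
    # blend: rectangle at m = 0 -> elliptical outline at m = 1
    half_width = a * ((1.0 - m) + m * ellipse) * inside
    gap = 2.0 * half_width * (1.0 - 0.8 * m)

    # per-leaf-pair perturbation parameters; a growing fraction of pairs
    # moves strongly as m rises, changing the shape (not just the scale)
    # of the leaf-speed distribution
    active = rng.uniform(size=n) < 0.25 + 0.75 * m
    amp_center = np.where(active, 10.0, 0.8) * m
    amp_bank = np.where(active, 7.0, 0.5) * m
    phase_c = rng.uniform(0, 2 * np.pi, size=n)
    phase_a = rng.uniform(0, 2 * np.pi, size=n)
    phase_b = rng.uniform(0, 2 * np.pi, size=n)
    freq = rng.integers(1, 5, size=n)

    t = np.arange(K)[:, None] / max(K - 1, 1)        # (K, 1)
    wiggle_c = amp_center * np.sin(2 * np.pi * (freq * t + phase_c / (2 * np.pi)))
    wiggle_a = amp_bank * np.sin(2 * np.pi * (freq * t + phase_a / (2 * np.pi)))
    wiggle_b = amp_bank * np.sin(2 * np.pi * (freq * t + phase_b / (2 * np.pi)))

    bank_a = wiggle_c - gap / 2.0 + wiggle_a
    bank_b = wiggle_c + gap / 2.0 + wiggle_b
    # close pairs squeezed shut; park closed pairs at the field centre
    squeezed = bank_b - bank_a < 0.8
    mid = 0.5 * (bank_a + bank_b)
    bank_a = np.where(squeezed | ~inside, mid, bank_a)
    bank_b = np.where(squeezed | ~inside, mid, bank_b)

    jaw_x = (float(bank_a.min() - 2.0), float(bank_b.max() + 2.0))
    open_rows = np.abs(centers) < b
    jaw_y = (
        float(boundaries[:-1][open_rows].min()),
        float(boundaries[1:][open_rows].max()),
    )

    gantry = (181.0 + 358.0 * np.arange(K) / (K - 1)) % 360.0
    weights = np.arange(K) / (K - 1)
    total_mu = config.mu_per_cp * K

    cps = [
        ControlPoint(
            index=k,
            gantry_angle=float(gantry[k]),
            cumulative_meterset_weight=float(weights[k]),
            bank_a_positions=bank_a[k],
            bank_b_positions=bank_b[k],
            jaw_x=jaw_x,
            jaw_y=jaw_y,
            dose_rate=600.0,
        )
        for k in range(K)
    ]
    arc = Arc(
        beam_id=beam_id,
        machine="synthetic-linac",
        energy="6",
        total_mu=float(total_mu),
        control_points=cps,
        leaf_boundaries=boundaries,
        treatment_site=config.site,
    )
    arc.validate()
    return arc


def generate_plan(
    config: GeneratorConfig, plan_id: str, n_arcs: int = 2
) -> Plan:
    """A plan of *n_arcs* arcs sharing the config's site and modulation."""
    rng = np.random.default_rng(config.seed)
    arcs = []
    for i in range(n_arcs):
        jitter = float(np.clip(config.modulation + rng.normal(0, 0.02), 0, 1))
        sub = replace(
            config, modulation=jitter, seed=int(rng.integers(0, 2**31 - 1))
        )
        arcs.append(generate_arc(sub, beam_id=f"{plan_id}-arc{i + 1}"))
    return Plan(
        plan_id=plan_id,
        arcs=arcs,
        treatment_site=config.site,
    )


def generate_cohort(
    n_plans: int,
    site_mix: dict[str, float] | None = None,
    modulation_range: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
    base_config: GeneratorConfig = GeneratorConfig(),
    arcs_per_plan: tuple[int, int] = (1, 3),
) -> tuple[list[Plan], pd.DataFrame]:
    """A cohort of plans plus the per-arc feature table (interchange CSV).

    The table holds one row per arc with ``plan_id``, ``beam_id``, ``site``
    and all 19 model features (the first ten of which are the complexity
    metrics); it is the input both for baseline building and for training.
    """
    if site_mix is None:
        site_mix = {"generic": 1.0}
    sites = list(site_mix)
    probs = np.array([site_mix[s] for s in sites], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)

    plans, rows = [], []
    for p in range(n_plans):
        site = sites[rng.choice(len(sites), p=probs)]
        mod = float(rng.uniform(*modulation_range))
        cfg = replace(
            base_config,
            modulation=mod,
            site=site,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        n_arcs = int(rng.integers(arcs_per_plan[0], arcs_per_plan[1] + 1))
        plan = generate_plan(cfg, plan_id=f"plan{p:04d}", n_arcs=n_arcs)
        plans.append(plan)
        for arc in plan.arcs:
            row = {"plan_id": plan.plan_id, "beam_id": arc.beam_id, "site": site,
                   "modulation": mod}
            row.update(assemble_features(arc))
            rows.append(row)
    table = pd.DataFrame(rows)
    return plans, table


#: Logistic label-model coefficients (see module docstring).  The intercept
#: and scale are calibrated once so the default cohort yields about 6 % of
#: arcs below the 90 % action limit.
DEFAULT_LABEL_CONFIG = {
    "intercept": 3.0,
    "scale": 1.3,
    "weights": {name: 1.0 for name in METRIC_NAMES},
    "noise_sd": 2.0,
}


def simulate_gpr_labels(
    table: pd.DataFrame,
    weights: dict[str, float] | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
    intercept: float | None = None,
    scale: float | None = None,
) -> np.ndarray:
    """Synthetic GPR labels (%) for a per-arc metrics table.

    label = 70 + 30 * logistic(intercept - scale * u) + N(0, noise_sd),
    clipped to [70, 100], where u is the mean of the standardized metrics
    oriented so that larger u means more complex.  Stands in for measured
    passing rates: complex arcs fail more often, with irreducible noise.
    """
    cfg = DEFAULT_LABEL_CONFIG
    weights = cfg["weights"] if weights is None else weights
    noise_sd = cfg["noise_sd"] if noise_sd is None else noise_sd
    intercept = cfg["intercept"] if intercept is None else intercept
    scale = cfg["scale"] if scale is None else scale

    rng = np.random.default_rng(seed)
    z_sum = np.zeros(len(table))
    w_total = 0.0
    for name, w in weights.items():
        if w == 0.0:
            continue
        vals = table[name].to_numpy(dtype=float)
        sd = vals.std()
        z = (vals - vals.mean()) / sd if sd > 0 else np.zeros(len(vals))
        if DEFAULT_DIRECTIONS[name] is Direction.LOW_IS_COMPLEX:
            z = -z
        z_sum += w * z
        w_total += abs(w)
    u = z_sum / w_total if w_total > 0 else z_sum
    systematic = 70.0 + 30.0 / (1.0 + np.exp(-(intercept - scale * u)))
    labels = systematic + rng.normal(0.0, noise_sd, size=len(table))
    return np.clip(labels, 70.0, 100.0)


def _gaussian_field(
    rng: np.random.Generator, shape: tuple[int, int], spacing: float
) -> np.ndarray:
    """Reference dose: a few Gaussian blobs, peak-normalized to 100."""
    ny, nx = shape
    y = np.arange(ny)[:, None] * spacing
    x = np.arange(nx)[None, :] * spacing
    field_ = np.zeros(shape)
    for _ in range(rng.integers(2, 5)):
        cy = rng.uniform(0.25, 0.75) * ny * spacing
        cx = rng.uniform(0.25, 0.75) * nx * spacing
        sig = rng.uniform(3.5, 6.0)
        amp = rng.uniform(0.5, 1.0)
        field_ += amp * np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2 * sig**2))
    return 100.0 * field_ / field_.max()


def generate_dose_pair(
    kind: str = "identical",
    shape: tuple[int, int] = (50, 50),
    spacing: float = 0.5,
    scale: float = 1.03,
    shift_mm: tuple[float, float] = (0.0, 2.0),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[DoseGrid, DoseGrid]:
    """A (reference, evaluated) dose-grid pair for gamma testing.

    Kinds: ``identical``; ``scaled`` (evaluated = scale * reference);
    ``shifted`` (evaluated displaced rigidly by *shift_mm*); ``noisy``
    (additive Gaussian noise of *noise_sd* % of the maximum).
    """
    rng = np.random.default_rng(seed)
    ref_values = _gaussian_field(rng, shape, spacing)
    reference = DoseGrid(values=ref_values, spacing=(spacing, spacing))
    if kind == "identical":
        evaluated = DoseGrid(values=ref_values.copy(), spacing=(spacing, spacing))
    elif kind == "scaled":
        evaluated = DoseGrid(values=ref_values * scale, spacing=(spacing, spacing))
    elif kind == "shifted":
        evaluated = DoseGrid(
            values=ref_values.copy(),
            spacing=(spacing, spacing),
            origin=(shift_mm[0], shift_mm[1]),
        )
    elif kind == "noisy":
        noisy = ref_values + rng.normal(0, noise_sd, size=shape)
        evaluated = DoseGrid(
            values=np.clip(noisy, 0.0, None), spacing=(spacing, spacing)
        )
    else:
        raise ValueError(f"unknown dose-pair kind {kind!r}")
    return reference, evaluated
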