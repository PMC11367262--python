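"""Shared fixtures: hand-built arcs and seeded synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import vmatqa as v
from vmatqa.plan_model import Arc, ControlPoint
from vmatqa.synth import GeneratorConfig, generate_cohort, simulate_gpr_labels

WIDE = (-200.0, 200.0)

#: scaled-down arc geometry used for cohort fixtures (fewer control points
#: than a clinical arc; the metric definitions are size-agnostic)
COHORT_CONFIG = GeneratorConfig(n_control_points=60)


def make_arc(
    bank_a,
    bank_b,
    boundaries,
    weights=None,
    gantry=None,
    jaw_x=WIDE,
    jaw_y=WIDE,
    total_mu=100.0,
    beam_id="test-arc",
) -> Arc:
    """Build an arc from (K, N) leaf-position arrays with minimal ceremony."""
    bank_a = np.atleast_2d(np.asarray(bank_a, dtype=float))
    bank_b = np.atleast_2d(np.asarray(bank_b, dtype=float))
    K = bank_a.shape[0]
    if weights is None:
        weights = np.linspace(0.0, 1.0, K)
    if gantry is None:
        gantry = (181.0 + 358.0 * np.arange(K) / max(K - 1, 1)) % 360.0
    cps = [
        ControlPoint(
            index=k,
            gantry_angle=float(gantry[k]),
            cumulative_meterset_weight=float(weights[k]),
            bank_a_positions=bank_a[k],
            bank_b_positions=bank_b[k],
            jaw_x=jaw_x,
            jaw_y=jaw_y,
        )
        for k in range(K)
    ]
    arc = Arc(
        beam_id=beam_id,
        machine="unit",
        energy="6",
        total_mu=total_mu,
        control_points=cps,
        leaf_boundaries=np.asarray(boundaries, dtype=float),
        treatment_site="generic",
    )
    arc.validate()
    return arc


def square_arc(side: float = 10.0, n_cp: int = 4) -> Arc:
    """Static square aperture of the given side, two 5 mm leaf pairs."""
    n_pairs = max(2, int(round(side / 5.0)))
    a = np.full((n_cp, n_pairs), -side / 2)
    b = np.full((n_cp, n_pairs), side / 2)
    return make_arc(a, b, np.linspace(-side / 2, side / 2, n_pairs + 1))


@pytest.fixture(scope="session")
def cohort_table() -> pd.DataFrame:
    """5000-arc synthetic feature table with simulated GPR labels.

    ``gpr`` carries the noisy label (sigma = 2) and ``gpr_true`` the
    noiseless systematic passing rate of the generative model.
    """
    _, table = generate_cohort(2550, seed=101, base_config=COHORT_CONFIG)
    table = table.iloc[:5000].reset_index(drop=True)
    table["gpr"] = simulate_gpr_labels(table, seed=102)
    table["gpr_true"] = simulate_gpr_labels(table, noise_sd=0.0, seed=102)
    return table


@pytest.fixture(scope="session")
def split_cohort(cohort_table):
    """(train, test) split of the first 2000 labelled arcs."""
    sub = cohort_table.iloc[:2000]
    return sub.iloc[:1500].reset_index(drop=True), sub.iloc[1500:].reset_index(drop=True)


@pytest.fixture(scope="session")
def trained_model(split_cohort):
    train, _ = split_cohort
    return v.train_model(train, seed=7)


MONITOR_CONFIG = GeneratorConfig(n_control_points=30)


@pytest.fixture(scope="session")
def monitor_setup(tmp_path_factory):
    """Baseline limits + trained model + a 10-plan scan directory containing
    exactly one constructed high-complexity plan."""
    from vmatqa.plan_model import write_rtplan
    from vmatqa.spc import build_limits
    from vmatqa.synth import generate_plan
    from dataclasses import replace

    root = tmp_path_factory.mktemp("monitor")
    _, baseline = generate_cohort(
        80, modulation_range=(0.15, 0.6), seed=301, base_config=MONITOR_CONFIG
    )
    baseline["gpr"] = simulate_gpr_labels(baseline, seed=302)
    limits = build_limits(baseline, baseline_label="synthetic-baseline")
    model = v.train_model(baseline, seed=303)

    plan_dir = root / "plans"
    plan_dir.mkdir()
    rng = np.random.default_rng(304)
    for i in range(9):
        cfg = replace(
            MONITOR_CONFIG,
            modulation=float(rng.uniform(0.25, 0.45)),
            seed=int(rng.integers(2**31)),
        )
        write_rtplan(
            generate_plan(cfg, f"ok{i:02d}", n_arcs=2), plan_dir / f"ok{i:02d}.dcm"
        )
    hot = replace(MONITOR_CONFIG, modulation=0.95, seed=305)
    write_rtplan(generate_plan(hot, "hot00", n_arcs=2), plan_dir / "hot00.dcm")
    return {"limits": limits, "model": model, "plan_dir": plan_dir,
            "baseline": baseline}
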