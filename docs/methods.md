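# Methods

This note records the models implemented by `vmatqa`, the conventions chosen
where the underlying definitions are genuinely open, what the synthetic data
do and do not emulate, and the numerical choices that affect results.

## Aperture geometry

All metrics are functions of the *clipped open aperture* at each control
point. Coordinates are IEC 61217 at the isocenter plane, in mm; bank A is
the left (smaller-x) leaf bank. For leaf pair *i* the exposed interval is
`[max(A_i, x1), min(B_i, x2)]` over the y-strip between consecutive leaf
boundaries intersected with the jaw-y window. A pair counts as **open** when
its clipped gap exceeds 0.5 mm — parked "closed" pairs retain a
sub-millimetre dosimetric gap that would otherwise pollute the gap
distribution; the threshold is configurable (`min_gap`).

The open region is a union of rectangles stacked along y. Its boundary
decomposes exactly into:

* **leaf-end faces**: two vertical segments per open pair, each the strip
  width;
* **side steps**: at each boundary between two *open* strips, the symmetric
  difference of their exposed intervals (equal to `|ΔxA| + |ΔxB|` when the
  intervals overlap; the symmetric difference clips the step to the exposed
  extent when they do not);
* **cap edges**: at boundaries where exactly one side is open (including the
  outer ends of each open run), the full gap length.

Perimeter = leaf ends + side steps + caps. The tongue-and-groove index uses
side steps only (S); the edge metric uses side steps + caps, because the cap
of an open run is physically an exposed leaf side as well.

## Metric conventions

* **Meterset weighting.** Aperture-shape metrics (TGI, BI, BM, edge metric)
  are weighted per control point by the meterset fraction of the segment
  *ending* at it (the first control point carries zero). This convention
  makes all weighted metrics exactly invariant under re-normalization of
  cumulative weights and under splitting a control point's MU into identical
  halves. MCS is inherently a segment quantity (it averages the two bounding
  control points), so its split-invariance holds for piecewise-constant
  delivery, which is the delivery model under which "splitting a control
  point" is well defined.
* **Gap pooling.** Gap quantiles and the small-aperture score pool the open
  gaps of all control points unweighted; quantiles interpolate linearly
  between order statistics.
* **MI_total timing model.** Segment duration is the maximum of the
  gantry-limited and dose-rate-limited times (defaults: 6 deg/s, 600 MU/min,
  25 mm/s leaf speed). Leaf speeds are per-segment finite differences,
  accelerations differences of consecutive speeds over mid-segment
  durations. Z(f) is the weighted fraction of (leaf, segment) samples whose
  speed or |acceleration| exceeds f standard deviations of the respective
  distribution, each segment weighted by
  (1 + |Δ gantry speed|/max)(1 + |Δ dose rate|/max); the integral over
  f ∈ [0, 2] uses the trapezoid rule on a 0.01 grid (refinement to 1e-4
  changes the value by < 5e-3 on test arcs).
* **Gantry arc length** accumulates per-segment shortest-path rotations, so
  an arc running 181° → 179° through 0° measures 358°, not 2°.
* **Beam irregularity** of a rectilinear aperture cannot approach 1: a
  staircase approximating a disc has Manhattan perimeter 8R in the fine-leaf
  limit, so BI converges to 16/π² ≈ 1.62 there (verified by a refinement
  test). BI = 1 is attainable only by a genuinely circular boundary.

## Gamma analysis

Global normalization uses the reference (calculated) maximum; the low-dose
cut-off masks reference points, and γ ≤ 1 counts as passing, with a 1e-9
relative guard against floating-point ties at the boundary (a uniform +3 %
scaling under a 3 % tolerance must pass *at* the maximum-dose point). The
production search interpolates the evaluated grid bilinearly on a 0.1 mm
lattice within 3× the distance tolerance of each reference point; gamma
values above 3 are therefore upper bounds, which leaves the passing rate
exact. The brute-force oracle searches a 10× bilinearly upsampled evaluated
grid exhaustively, pruned only by the provably sufficient dose-only bound at
zero distance. On grids with 1 mm spacing the two candidate lattices
coincide and the implementations agree exactly; this is how the
cross-validation tests are configured.

## GPR prediction

The regressor is an xgboost tree ensemble (squared error, 300 rounds, depth
4, learning rate 0.08, single-threaded for determinism), trained on a table
of 19 features: the ten metrics plus total MU, MU per degree, mean gantry
speed, mean and standard deviation of the segment dose rate, the equivalent
square side √A_union of the union aperture, the number of control points,
the arc length, and the mean aperture area. Predictions are clipped to
[0, 100] %. Attributions come from the ensemble's additive contribution
decomposition (`pred_contribs`), which sums to the *unclipped* prediction;
clipping can introduce a bounded discrepancy only for extreme arcs.
Sensitivity/specificity are evaluated per arc against the 90 % action limit.

## Monitoring rules

Specification limits are the 5th/95th percentiles per treatment site
(linear interpolation); strata under 20 arcs are kept but marked unusable,
and a pooled stratum serves as the opt-in fallback for unknown sites.
Values exactly on a limit are in spec (strict inequalities). The complexity
direction of each metric fixes which tail is "high complexity": small gaps
and small MCS mean more complex; large values of the remaining seven mean
more complex. "More than five" is strictly > 5 in both arc rules, and "most
of its arcs" is a strict majority — an exact tie (1 of 2 arcs) does not
trigger the complexity clause, a deliberately conservative reading; the
predicted-GPR clause provides the safety net. The per-plan predicted GPR is
the unweighted mean over arcs. DPMO uses the conventional one-sided 1.5σ
long-term-shift definition (so the 6σ touchstone is 3.4 per million);
equality of sigma level and shift is allowed (tail beyond zero = 50 %).

The daily scan records processed plan ids in a state file, making re-runs
idempotent; unreadable or unknown-site plans are logged and skipped rather
than aborting the batch. E-mail dispatch is replaced by an outbox directory
plus the CLI's exit code 2, so any scheduler can attach a notification hook.

## Synthetic data

The generator emulates the *statistical* structure of VMAT arcs, not their
dosimetry. Leaf tips outline an ellipse whose half-widths blend from a
rectangle at modulation m = 0 (so the static conformal arc hits the exact
degenerate metric values MCS = 1, TGI = 0, BM = 0, LT/AL = 0) toward the
elliptical target as m grows; gaps shrink by a factor (1 − 0.8 m); smooth
per-leaf sinusoidal perturbations of amplitude ∝ m animate both banks, and
the fraction of strongly moving leaves grows with m so that the scale-free
MI_total also responds to the dial. Meterset weights are uniform, the
gantry sweeps 358° from 181°, and total MU is `mu_per_cp × n_control_points`.
Over a cohort with m ~ U(0, 1), every directed metric tracks the dial with
|Spearman ρ| ≥ 0.89.

GPR labels follow `70 + 30·logistic(3.0 − 1.3·u) + N(0, σ)`, clipped to
[70, 100], where u is the mean of the standardized metrics oriented toward
complexity. The intercept and scale were calibrated once so that ≈ 6 % of a
default cohort falls below the 90 % action limit, reproducing the strong
class imbalance of real QA programs; σ defaults to 2 percentage points.
Because labels are clipped at 100, the irreducible MAE of a perfect
predictor is slightly *below* the folded-normal value 2√(2/π) ≈ 1.6.

What passing tests therefore show: the metric kernel, rules and model
behave correctly on data with the documented ordering and imbalance
structure. What they do not show: absolute metric scales match any clinical
cohort (the one-line literature descriptions admit multiple
operationalizations, and only ordering/direction is relied on downstream),
or that the label model reflects real linac deliverability.

Dose-grid pairs are sums of 2–4 Gaussian blobs (σ ∈ [3.5, 6] mm, peak 100)
on a 0.5 mm grid by default; blob widths are chosen so fields contain
genuinely flat peaks, where a 5 % global scaling cannot be rescued by the
1 mm distance search — the physically interesting failure mode.

## Problem sizes

Cohort-level tests and the acceptance script use arcs of 60 control points
(30 for the scan fixtures) and 40 leaf pairs, cohorts of 2000 labelled arcs
with a 1500/500 split, 10 000-row baselines for self-flag rates, 200 000
rows for the independence defect-rate check, and 20 random 50×50 dose-grid
pairs for the oracle cross-validation; the generator's clinical-fidelity
default remains 178 control points per arc.

## Known limitations

2D gamma only; no fluence or dose calculation; no couch/collimator model;
DICOM support covers the RTPLAN subset needed for VMAT beams (dynamic arcs
with MLCX + asymmetric jaws) and single-frame RTDOSE; site labels are
matched as free text; hyperparameter tuning of the regressor is out of
scope.
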