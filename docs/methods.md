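# Methods

## The model

`actiprofile` models one person's minute-level activity-intensity
distribution (Actigraph counts/min or MIMS units/min from a hip-worn
accelerometer) as a **piecewise exponential distribution**: the probability
density of spending a minute at intensity $x$ is

$$f(x) \propto \exp\{\ell(x)\},\qquad
\ell(x) = a + \sum_{k} s_k \cdot \big|[x_{\min}, x] \cap \text{segment}_k\big|,$$

where $\ell$ is continuous piecewise linear with three breakpoints
$b_1 < b_2 < b_3$ and four segment slopes $s_1,\dots,s_4 < 0$.  The
segments correspond to the canonical sedentary / light / moderate /
vigorous (SED/LA/MA/VA) intensity levels; the breakpoints are therefore
*individualized cut-points* between levels, and the slopes are per-level
exponential decay rates of the likelihood of sustaining higher intensity.
On the natural-log scale the model is a continuous piecewise line, so it is
fit by segmented linear regression on the log of the empirical histogram.

## Data preparation

Four filters precede fitting, in this order (participant and minute counts
are reported after every step):

1. **Wear filter** — at least 600 recorded minutes/day on at least 3 days;
   whole participants are removed, never individual days.
2. **Implausibility cap** — minutes above 12,000 counts/min removed; MIMS
   has no cap.
3. **Tail-outlier removal** — after binning (bin width 100 counts or
   0.5 MIMS), an occupied bin with no other occupied bin within the tail
   gap (1,000 counts or 50 MIMS) is removed; one (highest-x) isolated bin
   per pass, repeated to a fixed point, which makes the operation
   idempotent.  Survivors keep their original probability denominators (no
   re-normalization — a re-normalization would only shift every log point
   by a constant, which the fit is invariant to).
4. **Sparse-distribution filter** — participants with fewer than five
   occupied bins are removed.

Bins are half-open $[kw,(k+1)w)$ with the representative $x$ at the
midpoint (configurable to the left edge); a value on an edge belongs to the
upper bin.  Zero-intensity minutes participate in binning (the first bin
holds them); non-wear detection is out of scope.  Occupied bins then yield
points $(x_k, \ln p_k)$.

## Fitting

For fixed breakpoints the model is linear in its remaining parameters via
the hinge basis $(1,\; x - x_0,\; \max(0, x-b_k))$, so the inner problem is
solved exactly by linear least squares (minimal-norm when a candidate
leaves a segment empty, so the search can traverse such regions).  The
outer problem — the breakpoints — is a bounded quasi-Newton (L-BFGS-B)
descent with numerical gradients (step 0.01 bin widths) from
literature-informed starts:

| unit   | $b_1$ bound (start) | $b_2$ bound (start) | $b_3$ bound (start) |
|--------|--------------------|--------------------|--------------------|
| counts | 20–200 (100)       | 1500–2500 (1951)   | 4000–7000 (5725)   |
| MIMS   | 0.5–1.5 (1.0)      | 2–20 (5)           | 5–50 (30)          |

Strict ordering is kept by a minimum separation of one bin width
(violating candidates are projected and quadratically penalized).  If the
single descent does not reach an essentially exact fit, a deterministic
multi-start refines it: the grid of bound endpoints/midpoints plus the best
three vectors of a coarse 7-per-dimension scan.  The returned SSE never
exceeds the SSE at the configured start.  Points are unweighted by default
(each occupied bin counts once); weighting by bin minutes is available as
an option.  $y$ is centred before optimisation (restored in the
intercept) so results do not depend on probability normalization.

Fit quality is $R^2 = 1 - SS_{res}/SS_{tot}$ on the log points ($SS_{tot}$
about the mean of $y$; exact fits return 1, constant-$y$ degenerate inputs
return $-\infty$).

An exhaustive grid search over ordered breakpoint triples
(`grid_oracle`) serves as an independent reference optimum in the tests; it
shares nothing with the descent path.

### Identifiability at the sedentary boundary

With bin width 100 counts and $b_1 \in [20,200]$, exactly one histogram bin
lies below the first breakpoint.  The hinge design then has one more degree
of freedom than the sub-$b_1$ data constrain, and the SSE is *exactly flat*
in $b_1$ over the interval between the first two bin midpoints: $b_1$ and
$s_1$ form a set-valued argmin (any $b_1$ pairs with an $s_1$ that
reproduces the single sedentary point).  Consequences, measured on
simulated data: $b_2$–$b_3$, $s_2$–$s_4$, $R^2$ and the fitted curve are
stable and reproducible, while $s_1$ has a median relative error of roughly
25% and $b_1$ is only localized to within about a bin.  This is a property
of the study design (bin width comparable to the sedentary segment), not of
the optimizer; consumers should treat $s_1$ as descriptive.  All invariance
tests therefore assert the identified quantities.

## Profile classification

Fixed decision order (each participant gets exactly one label):

1. fewer than 5 log points strictly above $b_3$ → **non_vigorous**; the
   participant is refit with 2 breakpoints / 3 segments and that refit's
   $R^2$ is reported;
2. else if model-to-empirical AUC over the vigorous region ≤ 0.70 →
   **extremely_active**.  Both AUCs use the trapezoidal rule on the
   empirical $x$ grid above $b_3$, on the linear probability scale (a
   vigorous spike then dominates the empirical area, which is the intended
   signature); the highest-$x$ point is excluded from *both* curves so the
   supports match.  If fewer than two points survive the exclusion the
   ratio is undefined and the participant falls through;
3. else if $R^2 < 0.9$ → **outlier**;
4. else **moderately_active** if
   $|\arctan s_2 - \arctan s_3|$ exceeds the angle threshold
   (0.001 rad for counts, 0.1 rad for MIMS), otherwise **consistent**.

Computing the AUC on the linear rather than log scale, and the symmetric
tail-point exclusion, were open design choices; both are configurable
(`auc_scale`).

## Synthetic generator

The generator treats the fitted log-linear model as an exact density —
minutes are i.i.d. draws from $f$ on $[0, x_{\max}]$ ($x_{\max}$ = 12,000
counts or 100 MIMS for normalizability) via a segment multinomial plus
truncated-exponential inverse-CDF per segment.  Optional features map to
the profile archetypes:

* **truncation at $b_3$** — non-vigorous;
* **lognormal spike** above $b_3$ (habitual very-vigorous exercise;
  default location 7,900 counts / 59 MIMS, log-sd 0.06, weight 0.05) —
  extremely active.  The weight is calibrated at construction so the spike
  decisively dominates the vigorous-region area (a weight near 0.03 leaves
  the AUC ratio straddling the 0.70 threshold);
* **smooth log-scale perturbation** (`noise_sd`, random-phase sinusoids on
  the sub-vigorous range, sd 1.5) — outlier.  The perturbation is
  correlated rather than i.i.d. per bin because i.i.d. lognormal noise
  inflates the empirical vigorous AUC by $\approx e^{\sigma^2/2}$ relative
  to the log-space fit (Jensen), which mimics the extreme-activity
  signature instead of generic misfit.  Where the vigorous search band
  lies above $b_2$ (counts) the perturbation stops below that band, so a
  fitted $b_3$ can never land inside it; MIMS bounds overlap
  ($b_3 \in [5,50]$ vs $b_2 \in [2,20]$), so the MIMS outlier and
  non-vigorous archetypes are intrinsically less reliable — a documented
  limitation of those bounds, not of the classifier.

Default study conditions, chosen for realism and stated once:

* archetype wear: 9 days × 1260 min/day (≈ the NHANES cohort averages of
  8.9 days and 1273 min/day);
* parameter-recovery runs: 200,000 minutes per participant;
* reference counts rates $(-0.04, -0.0015, -0.0006, -0.0002)$ put ≈70% of
  minutes below $b_1$ (sedentary-dominant free-living adults) while keeping
  the vigorous range occupied at these sample sizes;
* archetype rates are chosen so the occupied histogram has the geometry
  each profile needs: the non-vigorous density dies out well below the
  vigorous search band; the others keep an occupied tail beyond any
  feasible fitted $b_3$; and the light/moderate slope contrast sits clearly
  on the intended side of the angle threshold (consistent: $s_2=s_3$;
  moderately active: $\arctan$ gap ≈ 0.0015 rad vs the 0.001 threshold).
  Steep-then-shallow ($s_2=-0.002$, $s_3=-0.0005$) is used for the
  moderately-active counts archetype because shallow-then-steep
  combinations with a clear angle gap extinguish the vigorous tail at
  realistic wear.

What the generator does **not** emulate: diurnal autocorrelation, activity
bouts, within-day wear gaps, device artefacts, or between-day
non-stationarity.  Passing tests therefore demonstrate that the pipeline
recovers its own generative family and separates the profile geometries —
not that free-living humans follow the model; that evidence must come from
cohort data.

## Numerical choices

* L-BFGS-B: `ftol=1e-14`, `gtol=1e-12`, max 500 iterations, gradient step
  0.01 bin widths; ordering penalty weight $10^6$ on squared bin-width
  violations.
* "Essentially exact" multi-start trigger: SSE $> 10^{-10}\max(SS_{tot},1)$.
* Final breakpoints are clamped strictly inside the data range (and their
  bounds) while preserving the one-bin-width separation.
* Degenerate inputs: empty series and sub-5-bin histograms raise; a failed
  fit marks the participant an outlier with a reason code instead of
  aborting a cohort run.
* The grid oracle's refinement is guaranteed monotone only for nested
  (dyadic, $g \to 2g-1$) grids.

## Known limitations

* $s_1$/$b_1$ weak identifiability at literature bin widths (above).
* MIMS archetype reliability under overlapping $b_2$/$b_3$ bounds (above).
* The AUC-ratio rule needs at least two vigorous points after the tail
  exclusion; participants just above the 5-point rule can have an
  undefined ratio and are then judged on $R^2$ and slope angles only.
* Cohort heatmap axis binning is heuristic (equal ln-probability steps
  spanning the observed range) and configurable.
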