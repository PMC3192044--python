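# Methods

## The problem

Macropod growth has two regimes. In-pouch growth is fast, sigmoidal and
tightly canalised; after pouch vacation (~207 days in the Tasmanian
pademelon) growth slows abruptly and between-animal variability rises
sharply. A single sigmoid fitted to lifetime cross-sectional data describes
neither phase well, and classical "broken-stick" pairs of curves forced
through a common point leave a slope discontinuity at the break. The SJ2P
(smoothly-joining two-phase) model removes both defects: a Verhulst
logistic describes the pouch phase, a Brody (monomolecular) curve the
post-pouch phase, and the two are constrained to share value *and* slope at
the join age `j`, so lifetime growth is one continuous, once-differentiable
curve. A continuous monotone curve can be inverted, which is the practical
point: ageing culled wild animals from a pes or head measurement.

## Model

Logistic (pouch) branch, ages `t ≤ j`:

    L(t) = A + K·L0 / ((K − L0)·e^(−r·t) + L0)

`A` is a lower-asymptote offset (mm, may be negative), `K` the logistic
span (mm; upper asymptote `A + K`), `L0` the core value at birth (mm,
`0 < L0 < K`), `r` the intrinsic rate (month⁻¹). The inflection sits at
`ln((K−L0)/L0)/r` with value `A + K/2` and maximum slope `rK/4`.

Brody (post-pouch) branch, ages `t > j`:

    L(t) = B·(1 − C·e^(−k·t))

`B` the mature asymptote (mm), `C ∈ (0,1)` an adjustment for non-zero
birth size, `k` the maturing rate (month⁻¹).

Six parameters are free: `(C, K, L0, k, j, r)`. The join constraints
determine the rest in closed form, in a deliberately triangular order:

1. slope continuity — the logistic core slope `s` at `j` (independent of
   `A`) must equal the Brody slope, giving `B = s·e^(k·j)/(C·k)`;
2. value continuity — `A = B·(1 − C·e^(−k·j)) − core(j)`.

For any free parameters inside their domain, `s > 0`, so the join is
mathematically always feasible; the `InfeasibleJoinError` guards numeric
underflow only (a logistic fully saturated at `j`, e.g. very large `r·j`,
where `s` rounds to zero).

## Units

The canonical age unit is a month of exactly 28 days. All printed
month↔day conversions in the source material are exact multiples of 28
(7.86 mo ↔ 220.08 d; 11.56 mo ↔ 323.68 d; 8.31 mo ↔ 232.68 d), which
pins the convention. Two families run on days: the linear pouch
head-growth model (its slope, 0.2452 mm, is per day) and the legacy
log-hyperbola comparator. Every parameter record and fit report carries
its `age_unit`.

## Fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`,
method `trf`) with deterministic seeded multi-start (default 8 starts:
data-driven base values — span-based `K`/`B`, rise-time-based rates — plus
log-uniform jitter up to ×3). Domain violations inside the optimiser
(e.g. `L0 ≥ K`, which box bounds cannot express) return a large penalty
residual; with sane starts the optimiser does not visit that region.
Standard errors are Gauss–Newton, `diag((JᵀJ)⁻¹·s²)^{1/2}` with
`s² = RSS/(n−p)`. Non-convergence (including constant-valued data, which
makes every family unidentifiable) is a reportable result state with
`converged=False`, not an exception.

**Boundary (ridge) reporting.** Two classic pathologies of bounded least
squares on growth data are reported as non-convergence rather than as
silent estimates. First, the near-linear ridge: when noise tilts a dataset
toward a straight-line trend, the asymptote parameter (Brody `B`, logistic
span `K`, offset-Brody `b`) escapes toward infinity with the rate
collapsing to zero; default bounds cap asymptote-like parameters at
3×max(observed)+10 mm, and a fit stranded at that cap is flagged
`converged=False` ("unidentified ridge") — the same datasets make
Newton-type fitters fail with singular gradients. Second, a profiled join
age pinned to the edge of its search window while the RSS is still
decreasing there: the minimiser lies outside the window, so the returned
`j` would be an artifact of the window rather than of the data, and the
fit is flagged `converged=False` ("join-age estimate at the search
boundary"). Replicated recovery studies exclude non-converged fits and
report the exclusion count.

The join age is estimated by RSS profiling: 20 grid points over
`[0.6, 1.8] × 7.393` months (7.393 = 207/28, the prior pouch-vacation
age), a 5-parameter fit at each grid `j` (warm-started from the
neighbouring grid solution), ties broken toward smaller `j`, then a
bounded golden-section refinement between the neighbouring grid points
(`xatol = 1e-3` months) and a final joint 6-parameter fit started there.
The grid scan runs at a looser optimiser tolerance than the final fit —
it only has to rank join ages.
Every candidate passes through the constraint solver, so continuity holds
at every iterate. With `fix_j` set (e.g. 207 days), only the five
remaining parameters are estimated. Data entirely on one side of the grid
raise a data error rather than silently fitting one phase.

## Goodness of fit

`R² = 1 − SSE/SST`, adjusted with the standard `(n−1)/(n−p−1)` correction;
`RMSE = sqrt(SSE/n)` (divisor `n`, i.e. the biased residual standard
deviation — the divisor is recorded in every report so comparisons stay
explicit). Because post-pouch variance is several-fold the pouch variance,
statistics are also computed per phase, partitioning at the model's own
fitted `j` (a record at exactly `j` counts as pouch). A side with fewer
than `p+2` records is reported absent, not fabricated.

## Synthetic data

The generator emulates the two-cohort study design behind the model: a
captive pouch-young cohort (n=68, ages 0.7–7.4 months, low noise) and a
cross-sectional cull cohort (n=97 per sex of 230 total, molar-eruption
ages 17–80 months, high noise). Noise is Gaussian, homoscedastic within a
cohort and heteroscedastic across cohorts, with the shipped scenarios'
standard deviations set to the published per-phase RMSEs (4.91 mm pouch
pes; 9.85/9.19 mm male/female cull pes; 4.32 mm pouch head) — a noise
model is nowhere stated, so RMSE-matched Gaussian is the minimal
assumption. Cull ages are uniform on [17, 80] months (no age histogram is
published; this is a documented stand-in). Pouch-young records are sexed
"indifferent", matching field practice. Values are floored at 0.1 mm so
every record satisfies the positive-measurement invariant. Not emulated:
molar-eruption ageing error, cull sampling bias, cohort/environmental
effects, within-animal correlation. A green recovery test therefore
establishes that the estimator returns the generating parameters under
the stated design — not that the published field estimates are correct.

## Known limitations and honest failures

* The published **female** SJ2P free-parameter row is internally
  inconsistent with the smooth-join algebra: its logistic (r=0.94) is
  saturated long before j=11.56 months, so the derived constants come out
  `B ≈ 12.3 mm`, `A ≈ −101 mm` — a "true" curve that is negative through
  most of the pouch phase and nearly flat afterwards. After the 0.1 mm
  floor, the female scenario carries essentially no join-age signal, and
  the female join-recovery check fails by construction. The scenario ships
  exactly as stated rather than being adjusted to pass; the male row gives
  a well-defined monotone curve and recovers cleanly.
* Derived constants for the male row (`A ≈ 181.7`, `B ≈ 380.8 mm`) are
  biologically implausible for a pademelon pes; the published rows cannot
  be reconciled with the separately-published single-phase Brody fits
  under any continuity algebra. Fidelity here is to the stated
  constraints, not to reconciling every printed row.
* Under the two-cohort design there are no observations between the oldest
  pouch animal (7.4 months) and the youngest culled animal (17 months), so
  the join age is only weakly identified inside that gap: the RSS profile
  is nearly flat there, the sampling distribution of the profiled `j` is
  right-skewed into the gap, and its replicate-mean overshoots the
  generating value even though the median recovers it — the male
  join-recovery test documents this at its stated tolerance. Designs with
  weaning-age animals do not have this pathology.
* Inversion (`invert_sj2p`) assumes the derived model is globally
  monotone, which holds whenever the free parameters are in-domain.
* Only the logistic→Brody join is implemented. The constraint solver is
  written against the generic slope interface, so other pairs are
  possible in principle, but they are untested and unexposed.
* Mixed-effects / longitudinal growth models are out of scope; every
  record is an independent animal.
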