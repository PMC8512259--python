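# Methods

## Scope and model

The package studies how four heterogeneity sources — cross-sensor,
cross-subject, joint cross-sensor + cross-subject, and cross-scenario —
affect wrist-accelerometer activity recognition, and whether unsupervised
domain adaptation with the geodesic flow kernel (GFK) repairs the damage.
All data are synthetic: the generator is a first-class, tested component
whose job is to reproduce the *statistical structure* of heterogeneous
wrist data, not wrist biomechanics.

## Synthetic data generator

**Task templates.** Each of the ten occupational tasks is a gravity
component of 9.80665 m/s² along a task-specific wrist orientation plus a
quasi-periodic component (task-specific fundamental 0.5–4.5 Hz, one
harmonic, a slow ±30 % amplitude envelope at 0.1 Hz, a lognormal per-bout
amplitude factor with σ = 0.2) plus Gaussian motion noise.  Sitting and
standing are static (gravity + noise only).  Orientations and fundamentals
were chosen once so that several tasks share nearby orientations or nearby
frequencies: with the default noise level (1.2 m/s² at heterogeneity 1)
classes overlap the way noisy wrist data do, which is what makes domain
shifts consequential.  A trivially separable cohort would mask every
heterogeneity effect.

**Subjects.** A subject is a per-axis gain (lognormal, σ = 0.12·L), a
wrist-orientation rotation (random axis, angle ~ N(0, 0.15·L rad)), a tempo
factor on the fundamentals (lognormal, σ = 0.08·L) and a motion-noise
level (1.2·lognormal(0, 0.25·L) m/s²), where L is the cohort's
heterogeneity level.  L = 0 produces identical subjects exactly (unit gain,
identity rotation, tempo 1).  An optional outlier subject is drawn at a
multiple of L (default 3×) to emulate a cohort member whose anthropometry
departs from the rest.

**Sensors.** A sensor model observes the ideal m/s² motion: resampling
onto a uniform or jittered timestamp grid (i.i.d. normal inter-sample
intervals, fractional σ = `jitter`), an optional fixed mounting-orientation
offset, full-scale range clipping, multiplicative scale error, conversion
to the native unit (g/64, g or m/s²), additive bias and measurement noise
in native units, and dropout (Poisson events with |normal| durations,
plus explicit deterministic gap intervals for testing).  Two devices worn
simultaneously share one ideal series per session and differ only through
their models.

The default device pair is a 32 Hz, g/64, ±2 g reference wristband versus
an unevenly sampled ~26 Hz, g-unit, ±8 g device with bias, scale error, a
12/−8/15° mounting offset, a higher noise floor and sporadic dropouts.
The range difference matters most: clipping is a task-dependent
nonlinearity that survives per-feature z-scoring, so it shifts the
*subspace* structure of the feature cloud — the component that ROD can see
and GFK can align.  Marginal effects (unit, bias, scale, band attenuation
from resampling) are largely absorbed by feature standardization.

**Scenarios.** `separate` lays out one contiguous block per task in
canonical order (default 60 s ± 20 % per block).  `mixed` shuffles one
short bout of every task within each of 7 circuits (default 10 s bouts),
excluding typing by construction; an optional total duration rescales the
bouts to tile it exactly.  The mixed defaults are a scaled-down circuit
protocol — about 10 minutes rather than a full hour — chosen so a session
still contains ~7 bouts per task while keeping simulation affordable;
`total_s` restores any desired length.

**What the generator does not emulate** — and therefore what passing tests
cannot show about real data: realistic limb kinematics, fatigue drift and
other non-stationarities, annotation errors, task transitions (bouts abut
exactly), null-class activity, and device-specific filter responses.

## Preprocessing and features

Units are converted to m/s² (g64 → value/64 × 9.80665, g → value ×
9.80665).  Recordings are linearly resampled onto an exact 1/32 s grid
spanning [t_first, t_last]; a grid point whose bracketing raw gap exceeds
1 s is marked invalid instead of interpolated, and grid points coinciding
with raw samples inherit their validity (making the operation idempotent).
Windows (10 s/320 samples, or 4 s/128 samples for mixed-scenario work) tile
each annotated interval from its start; a window is emitted only if it lies
wholly inside one interval and touches no invalid sample.  Alignment to the
interval start guarantees single-task windows without needing a
transition-label policy.

Each axis of a window is decomposed with `db4` (four vanishing moments,
8 taps) into detail bands d1–d5 and the level-5 approximation a5, using
**periodization** boundary handling so coefficient counts halve per level
and the transform is exactly orthogonal (energy-conserving) — which is
what makes the decomposition testable against a matrix-construction
oracle.  The 12 per-band statistics are mean, RMS, mean absolute
deviation, population SD, min, max, median, 25th/75th percentiles, energy
entropy, and zero-/mean-crossing counts.  Entropy is the Shannon entropy
of the normalized squared-coefficient distribution (wavelet energy
entropy), with 0·ln 0 := 0 and an all-zero band scoring 0; crossings count
strict sign changes (exact zeros do not count — a measure-zero choice on
continuous data).  Feature order is axis-major, then band (d1…d5, a5),
then statistic: 3 × 6 × 12 = 216 regardless of window length.

Standardization is per domain: source and target are each z-scored with
their own column statistics (columns with SD < 1e-12 are centered only).
Target features — never labels — are legitimately available in
unsupervised adaptation, and per-domain scaling is standard practice in
subspace-based methods.  The benchmark arm, by contrast, is a *source-only*
model: a linear SVM trained and applied with the source scaler alone, with
no target information whatsoever.  This operationalizes "directly applying"
a trained classifier to a new domain; giving the benchmark the target's own
scaler would smuggle in a large part of the adaptation being measured.

## GFK, SDM and ROD

Subspaces are PCA bases of the column-centered, z-scored feature matrices
(no labels used).  Principal angles come from the SVDs
P_Sᵀ P_T = U₁ Γ Vᵀ and R_Sᵀ P_T = −U₂ Σ Vᵀ (R_S the orthogonal
complement), with singular values clipped to [0, 1] before arccos and
angles ascending in [0, π/2].  Columns of U₂ belonging to near-zero sines
are completed deterministically by Gram–Schmidt against the identified
columns; they carry zero weight in the flow.  The geodesic
φ(t) = P_S U₁ Γ(t) − R_S U₂ Σ(t) integrates in closed form to
G = Ω Λ Ωᵀ with Ω = [P_S U₁, R_S U₂] and per-angle Λ entries

    aᵢ = ½ + sin 2θᵢ / 4θᵢ,   bᵢ = (cos 2θᵢ − 1) / 4θᵢ,
    cᵢ = ½ − sin 2θᵢ / 4θᵢ,

with the θ → 0 limits (1, 0, 0) taken below 1e-12.  The closed form is
validated in the test suite against 2001-node composite-Simpson quadrature
of ∫φ(t)φ(t)ᵀdt on random subspace pairs (≤ 1e-8 elementwise), and the
sign convention is pinned by the identity φ(1) = P_T V.

The subspace dimension is selected with the subspace disagreement measure:
for each d, α_d and β_d are the largest principal angles between the
source/target PCA subspace and the pooled-data PCA subspace, and
D(d) = ½[sin α_d + sin β_d]; d* is the smallest d with D(d) ≥ 1 − 1e-6,
else d_max.  d_max is structurally capped at
⌊min(D, n_S − 1, n_T − 1)/2⌋ and defaults to a configured cap (10–20 in
the experiment configurations) for speed.

ROD for an ordered domain pair is (1/d) Σᵢ θᵢ·[KL(Sᵢ‖Tᵢ) + KL(Tᵢ‖Sᵢ)]
where Sᵢ, Tᵢ are univariate Gaussians fitted to the data projected on the
aligned principal directions P_S U₁ eᵢ and P_T V eᵢ; the symmetrized
Gaussian KL is computed in closed form with variances floored at 1e-12.
It is zero for identical domains and symmetric in its arguments.  In the
experiments ROD is computed at a small fixed dimension (default 5, capped
structurally) rather than at the SDM d*: with tens of windows per domain
the deep PCA directions are sampling noise, the SDM profile saturates at
d_max for every pair alike, and an ROD built on them cannot rank
candidate sources.  The leading directions are stable and carry the real
between-domain differences.

## Classification and evaluation

The adaptation arm trains a C-SVM (one-vs-one, C = 1 by default) on the
precomputed kernel x_iᵀ G x_j over labelled source windows and predicts
target windows through x_tᵀ G x_s.  The benchmark arm is the source-only
linear SVM described above.  Both arms consume identical windows per
experiment (paired design).

Per-task F1 is 2PR/(P+R); when a task's precision denominator (times
predicted) or recall denominator (times present) is zero the F1 is
*undefined* and reported as `-`, never as 0.  The overall F1 — the
unweighted mean of per-task F1 — is undefined whenever any per-task F1 is;
aggregations over subjects skip undefined entries and report the excluded
count.  Accuracy is the exact-match fraction and is always defined.

## Experiments

* **Cross-sensor** — per subject, device-1 windows (labelled) → device-2
  windows of the same session.
* **Cross-subject** — device 1 only; per target subject, the k candidates
  with the lowest ROD are pooled into one source domain (single GFK/SVM
  fit); the benchmark pools k uniformly random candidates (`random_draws`
  seeded draws, default 1).  The reported RO̅D is the mean over *all*
  candidates (headline) with the selected-k mean also recorded, since
  "average ROD per subject" admits both readings.
* **Joint** — candidates contribute device-1 data, the target is the
  subject's device-2 data.
* **Cross-scenario** — pooled separate-scenario group versus pooled
  mixed-scenario group, 4-s windows for both, typing excluded.  With
  `same_cohort_groups` the two groups are the same subjects, isolating
  task-timeline dispersion as the only shift.
* **k-sensitivity** — accuracy and defined-F1 means versus k for both
  arms, with Table-style excluded-case counts.

Cohort sizes in the shipped test and acceptance configurations are 3–5
subjects with 40–60 s task blocks and 10 seeds per claim; these sizes were
chosen so each directional claim rests on 30–120 paired measurements while
a full acceptance run stays in the minutes range.  Determinism is
end-to-end: every stochastic component draws from a child seed derived
from one master seed via `SeedSequence`.

## Known limitations

* GFK helps when the domain shift is (approximately) a linear
  transformation of correlated features; shifts that scramble feature
  marginals nonlinearly are absorbed by per-domain scaling or remain
  unrepaired.  The cross-scenario experiment deliberately exhibits the
  null case: the adaptation arm can be marginally *worse* there, since
  projecting onto a low-dimensional subspace discards information without
  a compensating alignment gain.
* The ROD ranking degrades as windows per domain shrink; the fixed small
  ROD dimension mitigates but does not remove this.
* Undefined-F1 bookkeeping means overall-F1 comparisons silently condition
  on "no fully-missed task", exactly as the excluded-case counts document.
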