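# Methods

## Model

We simulate point or hard-sphere particles undergoing Brownian motion
inside (or constrained to) a closed, smoothly moving domain Ω_t ⊂ ℝ^d with
boundary Γ_t, outward normal **n**_t and boundary velocity **v**_t. The
probability density P of a single interior particle obeys the diffusion
equation with a moving-boundary flux condition,

    ∂P/∂t = D ∇²P  in Ω_t,     D ∂P/∂n = −(v_t·n_t) P  on Γ_t,

which is the unique boundary condition compatible with conservation of
probability (Leibniz rule plus the divergence theorem applied to the
shrinking/growing domain). For a static domain it reduces to the familiar
zero-Neumann (reflecting) condition. Note the diffusive flux carries the
factor D; writing the condition as ∇P = −(v·n)P without it is dimensionally
inconsistent, and the reference solver below uses the conservative form.

For a species living *on* the boundary surface the density obeys a
surface-diffusion equation with an advective term that carries the density
along with the moving surface,

    ∂P/∂t = D ∇²_Γ P − v_t·∇P,

where ∇²_Γ is the Laplace–Beltrami (surface) operator.

Assumptions: particle–boundary and particle–particle events are treated as
independent within one step (the probability of simultaneous reaction and
wall collision is negligible at small dt); boundaries are rigid prescribed
motions — no advective flow field is induced in the interior (relevant for
growing domains, where pure Brownian steps plus re-mapping carry no
outward drift); no Robin/semi-permeable boundaries.

## Steppers

**Volume stepper.** Per step of length dt, in this order: (1) every
particle takes an independent Gaussian increment, per-coordinate variance
2·D_i·dt, draws ordered (particle, coordinate); (2) the clock advances to
t+dt; any particle outside Ω_{t+dt}, or closer to Γ_{t+dt} than its own
radius ρ_i, is re-inserted: a point particle moves to (1−k)x + k·p with p
the closest boundary point (k = 1 places it on the boundary, k = 2 reflects
through p; default k = 1, configurable); a finite-radius particle is placed
at p and moved inward along the normal by ρ_i, regardless of k. On
non-convex domains the mapped point can land outside again; the map is
re-applied up to 10 times, then the step fails loudly. (3) Overlapping
hard-sphere pairs within a replicate are pushed apart symmetrically along
their centre line until the distance equals the radius sum, iterated to a
cap of 50 sweeps; exactly coincident centres separate along a seeded random
direction. (4) Reactions, then photobleaching. Snapshots snap to the
nearest completed step.

**Surface stepper.** Gaussian increment in the full ambient space, then
advective carry by v_t(x)·dt, then closest-point projection onto Γ_{t+dt}
(projecting onto the *new* surface keeps the on-surface invariant exact at
each timestamp, which the order of operations otherwise leaves ambiguous).
Taking the Gaussian step in the ambient space rather than the tangent
plane is justified in the small-dt limit: the surface is locally flat and
the projection of a Brownian motion is again a Brownian motion. For the
circle the projection contributes an O(dt) radial correction only; the
angular increment has mean 0 and variance 2·D·dt/r_t² (verified as a test
invariant).

**Boundary velocity.** Analytic where available (circle: radial with
magnitude ṙ_t). Otherwise the nearest-point map defines it: v_t(x) =
(closest point on Γ_{t+dt} − x)/dt, i.e. each membrane point is carried to
its nearest point at the subsequent time. This is an assumption, not a
measurement — real nuclear envelopes need not move this way.

**Reactions.** After movement, every eligible pair (species match, same
replicate, separation ≤ λ) fires with its channel probability; eligible
pairs are processed in ascending distance and a consumed particle drops
out of later pairs, so each particle reacts at most once per step.
Placement: unary→1 product at the reactant's position; binary→1 at the
reactants' midpoint; binary→2 at the reactants' positions; unary→2 at
randomly opposite poles of a sphere centred on the reactant whose diameter
is the largest reaction threshold in the system. Products are appended
after the step's channels have all run, so a product never reacts in the
step that created it. No germinate-recombination corrections and no
detection of crossings between step endpoints.

**Photobleaching.** Inside a spherical bleach region each particle is
removed by an independent Bernoulli trial with probability k_deg·dt (the
construction requires k_deg·dt ≤ 1). The region's centre may be a function
of time; in the dividing-nucleus experiment it sits at the membrane point
above the mother-lobe centre, expressed in the construction frame and
co-moving with the recentring translation.

## Geometries

All three domains implement one interface: strict membership, closest
boundary point, outward normal, boundary velocity, each valid on the
domain's time interval.

**Shrinking circle** (2-D): radius linear from r_s at t = 0 to r_e at
t_e, constant afterwards. All queries are analytic. The projection of the
exact centre is non-unique; the tie-break picks the boundary point with
smallest x, then smallest y.

**Elongating dumbbell** (3-D, rotationally symmetric about x, mirror
symmetric in x): two spheres of radius R joined by an open cylinder of
radius d; bridge length l(t) = 0, L·(t−T1), L·(T2−T1) on the three
schedule segments. The sphere centres sit at ±(l/2 + R − o) with
o = R − sqrt(R² − d²), the unique offset for which the sphere
cross-section at the bridge aperture is exactly d — spheres and cylinder
meet without a gap. Both spheres translate symmetrically as the bridge
inserts at the centre (an interpretation: the bridge could instead
insert on one side only, which would break the mirror symmetry).

**Dividing nucleus** (3-D, axisymmetric): mother and daughter lobes are
prolate ellipsoids of revolution (semi-axes (r_xm, r_ym) and (r_xd,
r_yd)), each truncated where its cross-section radius equals the bridge
radius w so the bridge aperture and the ellipsoid coincide, joined by a
cylinder of length l. The six parameters come from a time-stamped frame
table and are interpolated linearly between frames, so the geometry
changes smoothly at every step. The whole shape is translated along x so
the volume centroid sits at the origin at all times; the centroid is
evaluated in closed form from the piecewise-quadratic cross-section
profile ρ²(x′) (the test suite checks it against independent quadrature of
the membership indicator).

**Closest points on axisymmetric shapes** reduce to a 2-D projection onto
the profile curve in the (x, ρ) half-plane: per primitive (sphere arc —
analytic radial projection with angle clamping; cylinder segment — clamp;
ellipse arc — 33-point angular scan plus 12 safeguarded Newton iterations
of the stationarity condition, endpoints always candidates), then the
global minimum. Projection is idempotent to 1e−9 on these geometries.
On-axis points have a ring of minimisers; the tie-break picks smallest x,
then smallest y, then smallest z.

## Reference solutions

**Angular solver (surface of the shrinking circle).** In the angle θ from
the positive y-axis the moving-boundary surface problem becomes a fixed
periodic diffusion equation with time-varying coefficient D/r_t², solved
by the explicit scheme P_i ← (1−2a)P_i + a(P_{i−1}+P_{i+1}) with
a = δt·D/(r_t²h²) and circular indexing. With N grid nodes spanning
[−π, π] at spacing h = 2π/(N−1), the first and last node are the same
physical point; the implementation therefore advances the N−1 distinct
nodes and restores the duplicated endpoint as a ghost for output, which
makes conservation and the uniform equilibrium exact. Default N = 401 and
δt = half the stability bound h²·min_t r_t²/(2D); a δt above the bound is
rejected with the bound named. The solver is validated against a
closed-form time-changed wrapped Gaussian (angular variance
2D∫₀ᵗ r_τ⁻² dτ) and converges at second order in h.

**Radial solver (volume of the shrinking circle).** On the rescaled
coordinate u = r/s(t), s = r_t − ρ (the boundary a finite-radius particle
can touch is effectively pulled in by ρ), the moving boundary becomes
fixed, and the per-u mass density m(u,t) satisfies the conservation law
∂m/∂t = ∂F/∂u with flux F = 2πD·u·∂Q/∂u + 2π·s·ṡ·u²·Q, where Q(u,t) is the
probability density. The conservative flux form makes the boundary
condition trivial: with D·∂P/∂n = −(v·n)P the flux vanishes identically at
u = 1 (and at the axis), so the explicit finite-volume update conserves
total probability to round-off. Defaults: 200 cells, δt = 0.4× the
diffusive stability bound (also capped by the advective CFL); central
differencing is adequate because the cell Péclet number stays ≪ 1 for all
benchmark parameters. This solver replaces the deforming-mesh commercial
solver used for the original volume benchmarks; it is validated against
the static-disc equilibrium and the fast/slow analytic limits below.

**Analytic limits.** Fast diffusion: P(R<r) = R²/(r_t−ρ)² (uniform at all
times). Slow diffusion: uniform over the *initial* disc with the swept
mass piled at the wall, P(R<r) = R^d/(r_s−ρ)^d for R < r_t−ρ and 1 at the
wall. Volume MSD in the slow regime: ⟨x_t²⟩ = 4(r_t²/r_s²)Dt + (2/r_s²)[
(r_s⁴−r_t⁴)/4 − (2/3)r_t(r_s³−r_t³) + (r_t²/2)(r_s²−r_t²) ] — free
diffusers weighted by the instantaneous free fraction plus the mass swept
by the wall. Surface MSD limits: r_s² + r_e² (uniform at the end time) and
(r_s − r_t)² (zero diffusion, particle riding the boundary).

### Comparison conventions for the closed forms

The analytic limits are asymptotic (D → ∞, D → 0); at any finite D their
systematic error is nonzero while the Monte-Carlo 99% half-width shrinks
as n^(−1/2), so "inside the error bars at all times" cannot literally hold
at large n. The validation tests therefore allow the error bar **plus**
the identifiable leading correction:

* volume MSD: 4Dt·(1 − r_t²/r_s²), the gap between the instantaneous-
  fraction free term and the full free-space term (exactly the closed
  form's stated ambiguity);
* surface zero-D MSD: r_s·r_t·Var(θ_t) with Var(θ_t) = 2D∫₀ᵗ r_τ⁻² dτ,
  the leading tangential contribution (a factor 1.5 guards its own
  higher-order terms);
* slow/fast CDF limits keep the plain band criterion; near the moving wall
  the slow limit has a boundary layer of width ~D/|ṙ| that the band
  criterion penalises honestly (see Limitations).

CDF agreement with the *reference solvers* (not limits) uses the plain
criterion: the empirical CDF must lie within the 99% binomial band at
≥ 95% of 200 evaluation points per snapshot time.

## Estimators and error models

Empirical CDF: p̂ at each evaluation point with half-width
2.56·sqrt(p̂(1−p̂)/n) — the normal approximation to the binomial at 99%
confidence (2.56 is the 99.5 percentile of the standard normal). MSD: mean
of per-replicate squared displacements from the initial position, with
half-width 2.56·s/√n by default (a plain-SEM convention is switchable; the
99% convention is the default). Anomalous exponent α:
unweighted least squares of log MSD on log t over a window (α<1
sub-diffusive, α>1 super-diffusive). Histograms use the Freedman–Diaconis
bin width 2·IQR·n^(−1/3), with a warned equal-width fallback at zero IQR.
Bimodality of a histogram is declared when the 3-bin moving-average
smoothed counts have ≥ 2 local maxima, each at least 10% of the global
maximum, separated by a trough below 80% of the smaller peak — a
deliberately mechanical stand-in for a visual judgement.

## Synthetic nucleus trajectory

The dividing-nucleus geometry in the original experiment came from
manually measured confocal frames (50-s spacing) that were never
published. The package ships a clearly-labelled synthetic 5-frame, 50-s
trajectory (micrometre units, ~200 s of anaphase): mother lobe shrinking
slightly (r_xm 1.30→1.15, r_ym 1.00→0.88), daughter growing (r_xd
0.55→1.00, r_yd 0.48→0.80), bridge elongating (l 0.5→2.8) and thinning (w
0.30→0.24) — magnitudes typical of a budding-yeast nucleus. It reproduces
the *structure* of the measured data (smooth interpolation, growing
daughter, elongating bridge) but not the measured values; photobleaching
outcomes on it are therefore compared directionally (moving vs static,
mother vs daughter), never against the published protein counts, which
depend on the unpublished geometry.

## Default parameters

| parameter | meaning | default | units |
|---|---|---|---|
| dt | stepper time step | per scenario | s |
| k | escape-mapping parameter | 1 | — |
| ρ_i | particle hard-sphere radius | 0 | length |
| λ | reaction threshold (centre separation) | per channel | length |
| r_photo | bleach-spot radius | 0.17 (nucleus preset) | μm |
| k_deg | bleach rate inside the spot | 2 (nucleus preset) | 1/s |
| N | angular-solver nodes | 401 | — |
| n_cells | radial-solver cells | 200 | — |
| remap cap | escape re-mapping iterations | 10 | — |

Scenario presets carry the benchmark values (circle: r_s = 5, r_e = 3,
t_e = 5 s, D ∈ {5, 0.5, 0.05}, dt ∈ {1e−5, 1e−4, 1e−3} matched to D;
dumbbell: R = 3, d = 0.5, L = 0.01/s, T1 = 2e5 s, T2 = 2.01e5 s,
D = 0.0025, dt = 1/3 s; nucleus: D = 0.25 μm²/s, dt = 5e−5 s, 300
proteins × 3 replicates). Every source of randomness descends from an
integer seed; replicate r draws from a counter-based stream keyed
(seed, r), so replicate-level parallelism cannot change results. Batched
benchmark drivers advance all replicates in lockstep from a single
(seed, 0)-keyed stream and are bit-reproducible for a fixed batch size.

## Problem sizes used by the test suite

The validation tests run on one CPU in tens of minutes total, using: 2 000
replicates for CDF comparisons (the benchmark's own convergence check
found 2 000 and 10 000 replicates indistinguishable); 400–1 000 replicates
at the smallest time steps (dt = 1e−5); 10 000 replicates only for the MSD
error-bar magnitude; 2 000 dumbbell reaction events time-capped at
2.1e5 s (~1% censored); nucleus photobleaching at 300 proteins × 3
replicates with dt = 0.025 s. The dumbbell reaction-time distribution has
mean ≈ 4e4 s, so only ~1% of pairs survive to the bridge-elongation phase;
a second histogram mode at the elongation window needs event counts of
order 5e4 (the original experiment's size) to rise above
Freedman–Diaconis bin noise, and the elongation-phase concentration
checks are reported at the scaled size with that caveat.

On the dumbbell reaction threshold: the published account gives both 0.4
(text) and 0.2 (caption). Pilot measurements show the choice changes the
mean reaction time by ~1.5× (2.8e4 s vs 4.2e4 s) and hence the survival to
the elongation phase by e²; only λ = 0.2 leaves enough late pairs for the
published late-reaction mode to be observable at all, so the preset uses
λ = 0.2 and the package documents the alternative.

## Numerical choices

Strict-interior membership everywhere (a particle exactly on Γ_t is
outside Ω_t but is accepted as the k = 1 mapping target). Projection
tolerance 1e−9; on-surface tolerance for initial conditions 1e−6.
Finite-radius clearance uses a 1e−9 relative slack to absorb round-off.
Time-interval validity checks clamp inputs within 1e−9 of the interval
edge (accumulated floating-point drift of t = n·dt). Snapshot times snap
to the nearest completed step. The centroid recentring and lobe-dividing
plane ("middle of the bridge") are recomputed per query; particles exactly
on the dividing plane count as mother.

## Limitations

* Robin (semi-permeable) boundaries, inter-step reaction detection,
  germinate-recombination corrections and induced advection in growing
  domains are out of scope.
* The k = 1/k = 2 escape maps are first-order boundary treatments: the
  stepper's CDF bias near the wall is O(sqrt(D·dt)) and the two schemes'
  difference shrinks as dt → 0 (verified as a convergence property).
* The slow-diffusion closed forms ignore the D/|ṙ| boundary layer; CDF
  comparisons against them degrade within that layer by construction.
* Nearest-point boundary velocity is an assumption about membrane motion.
* Passing the photobleaching direction checks on the synthetic nucleus
  shows the machinery behaves as the moving-boundary theory predicts; it
  does not validate against measured yeast geometry, which is unpublished.
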