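# Methods

`blephagrip` quantifies the suction attachment of net-winged midge
(Blephariceridae) larvae, which cling to rock in torrential alpine streams
using six ventral suction organs. The package implements four measurement
models — centrifuge force assay, suction-stress estimation, an elastica bound
on the stiffness of the disc's spine-like microtrichia, and surface-roughness
metrology — together with the group-comparison statistics and synthetic-data
generators needed to exercise every stage without external data.

## Centrifuge force assay

A specimen of mass `m` sitting at radius `r` on a spinning platform detaches
at rotation frequency `f`; the attachment force is the centripetal force

    F = m (2 pi f)^2 r,

and the dimensionless force per body weight is `(2 pi f)^2 r / g` (mass
cancels, so body size drops out of performance comparisons). Defaults:
`g = 9.81 m s^-2`, frequency ceiling 75 rps (the rig's safety limit); both
configurable.

*Censoring.* Specimens that never detach at the ceiling are assigned the
maximum centripetal acceleration of a detached conspecific (their own ceiling
acceleration is kept if it is already higher); force is then recomputed with
the censored specimen's own mass and radius. The substitution never lowers an
acceleration and is idempotent. A species with only censored trials is an
error — there is no defensible substitute.

*Repeats.* Each larva is spun 2–4 times; the highest force per individual is
its peak. The rule is applied uniformly to all species.

CSV interface uses mg/mm/mN for readability; all internal arithmetic is SI.
Floats are written with `%.10g`, which makes read → write round trips
value-exact and byte-stable.

## Suction stress

Stress = peak force / contact area, bracketed by two area assumptions:

* conservative: six organs loaded, fitted-circle area including the outer
  fringe layer (which lies outside the suction seal);
* realistic: `organs_in_contact` organs (default 3) and the fringe (default
  33% of imaged area) excluded, i.e.
  `realistic = conservative / ((1 - fringe_fraction) * organs_in_contact / n_organs)`.

Stresses are computed per individual (its own peak force over its own
representative disc area times organ count), then summarised as mean ± SD
across individuals. This ordering matters: the mean of per-individual
realistic stresses equals `mean(conservative)/0.335` only when forces and
areas are homogeneous, so pooled-ratio shortcuts are deliberately avoided.

## Microtrichia stiffness bound (elastica)

A microtrichium is modelled as an inclined cylindrical cantilever: length
`L = 6.7 um`, diameter `D = 0.56 um`, resting angle `alpha = 45 deg` to the
substrate (scanned 40–50 deg), loaded at the tip by
`F = 11.6 mN / 6 organs / ~34,300 tips ≈ 56 nN` perpendicular to the
substrate. Tip adhesion and friction are neglected; the load direction is
constant (not follower). Since microtrichia are never observed in side
contact, the cuticle modulus must exceed the critical value at which the tip
tangent would reach the substrate plane.

With tangent angle `theta(s)` measured from the substrate, moment balance
gives the pendulum equation `EI theta'' = F cos(theta)` with `theta = alpha`
at the clamped base and zero curvature at the free tip. Its first integral at
the side-contact margin (`theta_tip = 0`) yields

    L sqrt(F / (E I)) = K(1/2) - F_inc(phi_a | 1/2),
    phi_a = arcsin( sin((90 deg - alpha)/2) / p ),   p^2 = 1/2,

so the critical modulus is

    E_crit = F L^2 / ( I [K(1/2) - F_inc(phi_a | 1/2)]^2 ),   I = pi D^4 / 64.

`E_crit` is linear in `F`, quadratic in `L`, scales as `D^-4`, and decreases
monotonically with `alpha` (steep spines resist flattening; nearly flat ones
flatten at any stiffness — the bound diverges logarithmically as
`alpha -> 0`). The complement of the surface angle appears in the elliptic
amplitude because the load is perpendicular to the substrate; at
`alpha = 45 deg` the amplitude coincidentally equals `arcsin(sin(alpha/2)/p)`.
For the measured geometry the bound spans 0.29–0.37 GPa over 40–50 deg,
i.e. 0.3–0.4 GPa at one significant figure: the cuticle must be at least
about 0.3 GPa stiff, comparable to wood.

*Numerical oracle.* `elastica_side_contact` solves the same boundary-value
problem by shooting: integration starts at the free tip (zero curvature) and
an event terminates at the first crossing of the clamp angle, which keeps the
root-find on the monotone equilibrium branch (at loads far beyond critical
the unconstrained elastica also has oscillatory equilibria that would confuse
a naive residual). `critical_modulus_numeric` root-finds the marginal load
parameter directly (`via="margin"`, default) or brackets the modulus by
bisection on the side-contact outcome (`via="bisect"`); both agree with the
closed form to ~1e-6 relative, far inside the 5% consistency requirement the
tests enforce. ODE tolerances: rtol 1e-8, 201 arc-length nodes.

Tip counts are carried exactly (`49,000 x 0.7 = 34,300`); rounding to the
nearest thousand is applied only in reports.

## Surface metrology

Roughness of a height map (after plane, mean, or no detrending; plane removal
is the default, matching interferometry practice): `Ra` = mean absolute
deviation, `Rq` = RMS deviation, `PV` = max − min of the detrended surface.
Ra/Rq are always measured about the mean of the retained surface, so all
modes are offset-invariant and `Ra <= Rq <= PV` holds identically. Masked
pixels are excluded from both the fit and the statistics.

Shape-from-focus reconstructs heights from a focal Z-stack: the per-pixel
focus measure is the local variance (default 9 px window) of a 3×3 Laplacian
response; height is the z of the sharpest plane, refined by 3-point parabolic
interpolation across the argmax; pixels whose best response falls below 1e-3
of the global maximum are masked as textureless. Accuracy on synthetic stacks
at ≥ 20 dB SNR: median height error within one z-step. At height
discontinuities (e.g. ridge–groove edges) reconstruction is inherently
ambiguous — sharp texture bleeds across the edge — so step heights are best
recovered from level medians rather than raw extrema.

## Synthetic data

The generators define the study conditions; they are pure functions of
(parameters, seed).

* *Force trials*: per-body-weight peaks are lognormal (forces are positive
  and right-skewed, consistent with log10-transformation before testing),
  moment-matched on the arithmetic scale to the measured species profiles —
  585 ± 330 (*L. cordata*), 324 ± 153 (*L. cinerascens*), 1120 ± 282
  (*H. lugubris*) body weights on smooth substrate. Substrate multipliers
  scale the whole distribution: larvae 1 / 0.5 / 0.25 for smooth /
  micro-rough / coarse-rough (the measured twofold micro-rough drop; coarse
  continues the observed ordering), stick insect 1 / 1/16 / 1 (measured
  16-fold micro-rough drop, smooth ≈ coarse-rough). The stick-insect absolute
  level (40 ± 15 body weights) is an assumed placeholder — only its fold
  changes are empirical. Draws convert to detachment frequency via
  `f = sqrt(bw g / r) / (2 pi)`; draws beyond the 75 rps ceiling are emitted
  censored at the ceiling, so the censoring rule sees realistic inputs
  (~5–10% censored for *H. lugubris* at the default 0.07 m radius, matching
  the observed 14/136 rate). Radius (not reported per trial in the source
  experiments) defaults to 0.07 m; masses are uniform on 2–12 mg, back-solved
  from the 11.6 mN ≈ 1000–1400 body-weight peak of a few-mg larva.
* *Rough surfaces*: Gaussian random fields by spectral synthesis with a
  Gaussian correlation kernel, rescaled after mean-detrend so the measured
  `Ra` hits the target exactly.
* *Z-stacks*: a band-limited speckle texture (guaranteeing focus signal
  everywhere) blurred per plane with Gaussian width
  `defocus_slope * |z - h(x,y)|` (slope 0.8 px per um of defocus at unit
  pitch), approximated over ≤16 quantised defocus distances with per-pixel
  linear interpolation (exact for few-level maps), plus additive Gaussian
  noise.

What the generators do not emulate: behavioural variation within individuals
(repeats are i.i.d.), substrate-dependent censoring biases beyond the
ceiling, optical artefacts (vignetting, depth-dependent magnification,
speckle decorrelation), or non-stationary roughness. Passing tests therefore
validate the estimators' arithmetic and statistical calibration, not
instrument-specific systematics.

## Statistics

`kruskal_dunn`: Kruskal–Wallis H with midrank tie correction (scipy),
followed by Dunn's pairwise z tests — pooled-variance
`N(N+1)/12 - sum(t^3 - t)/(12(N-1))` with two-sided normal p-values —
adjusted by Bonferroni–Holm step-down. Dunn's test is implemented in-package;
Holm via statsmodels. Rank-based, hence identical on raw and log values.
`anova_tukey_log`: one-way ANOVA on log10 values with Tukey HSD (statsmodels);
Tukey p-values are already family-wise. Fold changes are ratios of
back-transformed mean log10 values, i.e. geometric means. Degenerate
all-identical inputs return H (or F) = 0 with p = 1 rather than erroring.

A Monte-Carlo calibration (1,000 null replicates, three groups of 20) checks
the Kruskal–Wallis rejection rate at alpha = 0.05 stays within [0.03, 0.07].

## Problem sizes and determinism

Test and demo problem sizes are desk-scale by design: 64×64–128×128 maps,
15-plane stacks, 5,000-draw moment-recovery checks, a 45-point
(angle × load × length) elastica cross-validation grid. Every stochastic
stage takes an explicit seed (`numpy.random.default_rng`); the pipeline
spawns per-stage seeds from one root seed and records config, seed and
version in its provenance block.

## Known limitations

* The stress model treats the contact as a uniformly loaded circle; organ-
  level pressure distributions and seal mechanics are out of scope.
* The elastica bound assumes equal load sharing among ~34,300 tips and a
  constant-direction tip load; friction/adhesion at the tip would raise the
  effective bound.
* Array-level interactions between microtrichia, and attachment on rough
  substrates where fewer tips engage, are not modelled.
* Published group statistics (chi-square/F values) depend on the raw trial
  data and are not reproduction targets; the pipelines reproduce the
  direction and approximate magnitude of the effects on synthetic data.
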