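# Methods

`tissuemech` implements the quantitative toolbox used to characterise the
mechanics of embryonic tissues during the ectoderm-to-mesoderm transition:
tension inference from cell doublets, micropipette-aspiration (MPA) rheology,
explant spreading statistics and single-cell fluorescence/motility operators.
Raw microscopy for the original experiments is not publicly deposited, so the
package ships first-class synthetic-data generators with known ground truth;
every estimator is validated by forward-simulate / inverse-measure round
trips.

## Doublet mechanics

**Model.** At each contact vertex of a two-cell doublet, three interfacial
tensions balance: the cortical tensions `Ct_A`, `Ct_B` along the free
surfaces and the contact tension `T_AB` along the cell–cell interface. In
equilibrium the three tension vectors close a triangle (Neumann triangle),
giving the closed forms

- forward: `cos θ_X = (T_AB² + Ct_X² − Ct_Y²) / (2 T_AB Ct_X)`
- inverse (normal balance): `Ct_A/Ct_B = sin θ_B / sin θ_A`
- inverse (tangential balance): `T_AB = Ct_A cos θ_A + Ct_B cos θ_B`

where `θ_X` is the angle between cell X's free-surface tangent and the
continuation of the contact interface past the vertex. A stable contact
requires the triangle inequality `|Ct_A − Ct_B| < T_AB < Ct_A + Ct_B`;
outside it the generator and the validators raise a "no stable contact"
error (point contact above, engulfment below). For homotypic doublets
(`Ct_A = Ct_B = Ct`) the contact tension reduces to `T = 2 Ct cos θ̄` with
`θ̄ = (θ_A + θ_B)/2`, and the adhesiveness index is `α = 1 − cos θ̄ ∈ [0, 1]`
(0 = no adhesion, vanishing contact; 1 = maximal adhesion, 90° contact
angle). α is reported for homotypic doublets only; a measured asymmetry
`|θ_A − θ_B|` beyond a configurable tolerance (default 15°) flags the vertex
because it violates the symmetry assumption.

**Synthetic doublets.** Tensions fix only angles; cell size is a free
parameter. We close the geometry by giving *both* free surfaces the same
radius of curvature `radius_a` (default 50 µm, a typical blastula cell
radius). Young–Laplace then sets the internal pressures
`P_X = Ct_X / radius_a` and the contact curvature
`κ_c = (P_A − P_B)/T_AB`, bulging into the lower-tension cell. This closure
is exactly compatible with the Neumann angles: the contact tangent tilt at a
vertex is `β = (θ_B − θ_A)/2` and the contact half-chord is
`h = radius_a · sin((θ_A + θ_B)/2)` (both provable from the sine/cosine
laws; the identity is exercised by the round-trip tests). Outlines are
sampled as three circular arcs (default 200 points each) with optional
Gaussian positional jitter.

**Angle measurement.** At each vertex a circle is fitted (geometric
total-least-squares, Kasa-initialised) to the points of each arc within a
window of 20 % of the arc length from the vertex; tangents come from the
fitted circles, so curved heterotypic interfaces need no chord
approximation. Collinear windows (straight contacts) fall back to an SVD
line fit. Circle fitting over a fractional window is robust to sampling
jitter where finite differencing is not; with 0.05 µm jitter the mean
absolute angle error stays below 1°.

**Aggregation.** Per-doublet values are the mean of the doublet's two
vertices (bleb-flanked vertices are excluded before any statistic);
per-condition values are medians over doublets; relative contact tension
`relT` is rescaled so the reference condition's median is 1. Heterotypic
`Ct` ratios chain conditions to the reference cell type via the optional
`ct_scale` mapping.

## Micropipette aspiration

**Model.** An explant (radius `R_0`) aspirated into a pipette (radius `R_p`)
at pressure `ΔP` creeps at the slow viscous rate
`v_asp = R_p (ΔP − P_c) / (3π η)`; after pressure release it retracts at
`v_ret = R_p P_c / (3π η)`, where `P_c = 2γ (1/R_p − 1/R_0)` is the critical
pressure of the Laplace law. Inverting:

- `η = R_p ΔP / (3π (v_asp + v_ret))` (Pa·s; micron factors cancel)
- `P_c = ΔP · v_ret / (v_asp + v_ret)` (exact identity by construction)
- `γ = P_c / (2 (1/R_p − 1/R_0))`, reported in mN/m

The short-term "stiffness" indicator `L20` is the deformation 20 s after
aspiration onset (baseline-subtracted by default; toggleable), independent of
any rheological model and of the slow-phase fitting configuration.

**Phase segmentation.** The fast passive phase is the first 20 s after onset
and after release. Slow windows start after an additional settle gap
(default 10 s) so residual elastic creep does not bias the viscous slope,
and are trimmed from the left until an OLS line reaches `R² ≥ 0.95`; a
window whose trend is not resolvable above the noise floor (total variance
within a few residual variances) is accepted as is, since R² is meaningless
there and the OLS slope is already optimal — this handles near-zero
retraction (γ → 0) gracefully. The retraction fit stops where the tongue has
fully recoiled (L = 0; the generator floors and flags such traces). All
windows and R² values are echoed in the output for audit. Slow windows
shorter than 30 s raise "insufficient slow phase"; in parameter sweeps the
low-viscosity/high-tension corner (full recoil within ~40 s of release)
therefore yields an explicit failure rather than a silent bad fit.

**Synthetic traces.** The generator adds a single-exponential elastic jump
(amplitude `l_fast`, time constant `tau_fast`) to the piecewise-linear
viscous flow. The exponential is a stand-in — no specific short-term
rheology is claimed — and the estimators never depend on its form (the
settle gap skips it). Defaults follow the experimental protocol: 1 Hz
sampling, release at 240 s, 250 Pa with the 100-µm pipette or 220 Pa with
the 125-µm pipette, tissue-scale parameters η ≈ 1.3×10⁴ Pa·s, γ ≈ 5 mN/m.
Recovery sweeps use the large-pipette protocol because it keeps
`P_c < ΔP` over the whole γ ∈ [0.5, 10] mN/m range.

## Explant dynamics

Areas are normalised to the first frame, with named time points (60 and
170 min) read by nearest-frame lookup within one frame interval (default
2.5 min), since frame grids differ across movies. Retraction events — the
abrupt contractions punctuating mesoderm spreading, marked only visually in
the source experiments — are defined here operationally as maximal
decreasing runs of ≥ 2 frames with cumulative fractional drop ≥ 5 % (both
configurable). Dispersion is the ratio of mean Delaunay-triangle areas
between 170 min and 30 min (the onset of spreading); no sliver/boundary
triangles are excluded by default (an optional layer filter exists, and the
triangle-sum-equals-hull-area property is oracle-checked in the tests).
Intercalation is the ratio of basal-layer nucleus counts; a zero basal
count at the start time raises, since morphant explants with nearly empty
basal layers make the ratio meaningless. The nuclei generator scales a
uniform point cloud isotropically about its centroid, adds Brownian jitter
and Poisson-distributed newly intercalating nuclei placed uniformly in the
current hull; it does not model directed motion, cell division or loss.

## Fluorescence and motility operators

- **Cluster fraction**: background-subtracted summed intensity inside the
  cluster mask over the whole ventral mask. The cluster threshold is robust
  (`median + k·MAD`, k = 3 by default, inside the ventral mask) because the
  original mask construction is unspecified; the threshold is configurable
  and logged. The fraction is a ratio of linear functionals, hence invariant
  to expression level.
- **Cortical / contact enrichment**: means along polyline line scans with a
  3-px averaging width (scan width was unstated), background-subtracted.
  Contact enrichment divides by *twice* the free-edge signal because a
  contact contains two apposed membranes; both the normalised and the raw
  ratio are reported.
- **Membrane-mask pipeline**: Gaussian filter (σ = 1 px) → global background
  (1st percentile) → local background (rolling ball, radius 25 px) → Otsu →
  skeletonize → one 3×3 dilation to a 3-px band (≈1.5 µm at 0.5 µm/px).
  The two background rounds are named but not specified in the source
  protocol; percentile + rolling ball are the conventional choices. Measured
  channels are reported as band mean minus the complementary-mask
  (cytoplasmic) mean. An empty mask raises with per-stage pixel counts.
- **Colocalization**: Pearson on paired pixels in the ROI; Manders M1/M2
  with per-channel Otsu thresholds inside the ROI by default (the common
  JaCoP convention), fully configurable — note M1 = M2 = 1 for identical
  images only with zero thresholds.
- **Morphometry**: area, `4πA/P²` circularity (Crofton perimeter, clipped to
  1), ventral/max-projection area ratio. Blebs are excluded upstream.
- **Track speed**: mean of consecutive-frame speeds within frames 10–40
  (25–100 min at 2.5 min/frame); per-morphology means are taken over steps
  whose both endpoints share a label. Tracks not covering the window are
  used on the overlap with a warning.
- **Adhesion**: percentage of cells remaining adherent; statistics are per
  experiment (the unit of replication in the rotation assay).

## Numerical choices and limitations

Degrees are used at all angle interfaces; lengths in µm, times in s (MPA) or
min (tracks/explants); pressures in Pa, tensions in mN/m or relative units.
Angle force balances are undefined within `sin θ < 10⁻³` of 0/180° and
return NaN with a warning. All generators draw from one seeded
`numpy.random.Generator` per call and record the seed; the end-to-end
pipeline derives stage seeds from a single root seed, making result bundles
bit-identical across reruns.

The synthetic data emulate geometry, creep kinetics and intensity
compartments — not optics (no PSF, no depth attenuation), not blebbing
dynamics, not active migration, and only 2-D cross-sections of doublets.
Passing round trips therefore demonstrate correctness of the estimators
under the stated models, not robustness to segmentation error or imaging
artefacts in real recordings. Absolute tension calibration is out of scope
(all doublet tensions are relative); condition-level values from the
original recordings are not reproducible without the raw movies, and the
package makes no attempt to restate them. Problem sizes in the test-suite
round trips (50 tension triples, 100 aspiration traces, 1,000 image pairs,
cohorts of tens of doublets) were chosen as the smallest sizes at which the
medians and invariants are stable.
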