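# Models and methods

This note records the models behind `lipidfoam`, the parameter choices and
their rationale, the numerical details, and what the synthetic-data
generator does and does not emulate.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The foam network

A lipid foam is represented as a planar graph of junctions (vertices, µm
coordinates, y up) with edges (bilayer segments) and compartments (ordered
vertex cycles).  Interior junctions have degree exactly 3 — the three-way
meeting of bilayer films — and boundary vertices (clipped by the field of
view, or of lower degree) are flagged and excluded from shape and
fluctuation summaries, since their polygons are artefacts of clipping.

Two builders are provided.  The honeycomb builder gives the perfect
hexagonal reference (shape index p/√A = 3.7224).  The disordered builder
jitters a triangular lattice of cell centres and takes the Voronoi
tessellation, clipped to the lattice box by mirror padding.  The jitter
standard deviation is 0.4 × `disorder` × spacing; this factor was set by
computing the jitter → mean-shape-index curve once, so that `disorder = 0.3`
lands at s ≈ 3.79, inside the 3.75–3.85 range typical of
centrifugation-prepared foams, while `disorder = 0` reduces exactly to the
honeycomb.  Degenerate (degree ≥ 4) Voronoi junctions are handled by
retrying with an infinitesimal seed perturbation; they are measure-zero
under jitter and never arise from the triangular base lattice.

### Tensions

Leaflet zipping relates bilayer and monolayer tension through
γ_B = 2 γ_ML cos φ (contact angle φ < 90°); the two functions are exact
inverses and both reject unphysical inputs (γ_B > 2 γ_ML).  Aspiration
tension uses γ_c = g·|ΔP|·R_p with the geometric factor g = 1/2 of a
hemispherical cap spanning the pipette mouth, exposed as a parameter since
other cap geometries differ only in g.  Packing stability is classified by
γ_B/γ_ML against the confluence threshold 0.23 and the rigidity-transition
value 2.

### Junction mechanics and T1

The mechanical energy is E = Σ_e T_e L_e + Σ_c (K_A/2)(A_c − A_c0)², line
tension plus compartment area elasticity.  The area term is essential: line
tension alone contributes only transverse stiffness (one rank per edge), so
a degree-3 network is floppy at quadratic order, and simulated thermal
fluctuations would be set by anharmonic terms rather than by the Hessian.
Physically the aqueous compartments are incompressible on the experimental
timescales, which is exactly what the area term encodes.  K_A defaults to
4·mean(T_e)/L³ (L the mean edge length), making area modes comparably stiff
to tension modes; with this term the simulated passive variance agrees with
the analytic linear response (equipartition over the Hessian) to within 2%.

Single-junction relaxation minimises Σ γ_i |x − p_i| (the generalised
Fermat point) by gradient descent with backtracking, so the energy never
increases; if one tension dominates the other two (subgradient condition
|Σ_{j≠i} γ_j û_j| ≤ γ_i at pin i) the minimum is the pin itself and is
returned directly.  Equal tensions give 120° inter-edge angles to < 0.5°.

The T1 operator swaps the two compartments flanking an edge with the two
end compartments, updating the four cycles and rotating the edge 90° about
its midpoint (oriented so each endpoint stays on the side of the
compartment that keeps it).  It preserves vertex degree, compartment count
and the Euler characteristic, and is an involution on the topology.  The
detector reports an event when an edge length dips below a collapse
threshold (default 0.5 µm — well under the 20–50 µm compartment scale,
above tracking noise; the threshold is a free parameter) and subsequently
re-grows; NaN gaps split the search into contiguous runs.

## Junction fluctuations

### Single-junction model

A junction in its effective harmonic trap obeys the overdamped Langevin
equation b dx/dt = −k x + √(2 kB T_eff b) ξ(t) with k = 2π f0 b.  Defaults
are the experimental scale: b = 0.5 µN·s/m, f0 = 0.9×10⁻³ Hz, T = 298 K
(kB·T = 4.11×10⁻²¹ J), T_eff/T = 1 for heat-killed controls and 6.5 for
dense live swimmers.  Integration is Euler–Maruyama run as an AR(1) filter;
the config validator refuses dt ≥ 1/(2π f0)/10.  The one-sided spectrum in
Hz is

S(f) = 4 kB T_eff / b / [(2π)² (f² + f0²)]   (m²/Hz per coordinate),

whose integral is the stationary variance kB T_eff/k per axis.

### Spectral estimation and fitting

Spectra are Welch periodograms on the full track with linear detrending
(blocking to 60 s would destroy the sub-mHz knee), Hann window, one segment
per track, averaged across tracks; the radial mode sums the x and y spectra
so the PSD integrates to the total 2D variance (Parseval is enforced to 5%
in tests).  Fits run on log S vs log f with equal weight per log-frequency
bin, implemented as per-point weights 1/(points per bin) so a noiseless
model spectrum is recovered to machine precision; the lowest decade is
down-weighted by half against window bias, and frequencies above a fifth of
the maximum are dropped to avoid the aliased band near Nyquist (the f⁻²
tail folds back at the sampling frequency).

A single spectrum constrains only the pair (T_eff/b, f0): the level
C = 4 kB T_eff/b and the corner.  Identification therefore follows the
paired experimental design: the **passive** fit fixes T_eff = T and returns
b = 4 kB T/C; the **active** fit fixes b (and optionally f0) from the
paired control and returns T_eff/T.  `n_axes` declares how many coordinates
were summed into the input spectrum (2 for radial input — x and y fitted
jointly).  On simulated ensembles at the default parameters (10 min, 1 Hz,
20 tracks per condition) the recovered drag is within ~10% and T_eff/T
within ~10–15%, dominated by periodogram noise; the corner frequency itself
is poorly resolved because the 600-s record puts the first frequency bin
(1.7 mHz) above f0 — the fitted amplitude, which carries b and T_eff, is
insensitive to this.

### Blocked statistics

Displacement and edge statistics use non-overlapping 60-s blocks, each
re-centred on its own mean (drift suppression).  Per-block amplitude is the
rms radial displacement about the block centre; the fluctuation-map
statistic is the maximum over blocks, the occupancy-model statistic the
mean radial distance.  Edge deviations pool L − L̄ (block mean L̄) over
blocks with at least 10 valid common frames.  The effective tension is
γ_e = kB T/σ with σ the pooled edge-length **variance** in m² — the only
dimensionally consistent reading, giving a sub-µm length scale
(σ = 1.33×10⁻¹³ m² ↔ γ_e = 3.1×10⁻⁸ N/m at 298 K).

## Active forcing and the displacement law

The displacement law Δϑ = c·(3 η τ A/4R²)·(v² Φ/γ_e) uses, by default, the
stated working values η = 10 mPa·s (as printed; water itself is ~1 mPa·s,
so this is treated as an effective-medium viscosity), τ = 1 s, A = 200 µm²,
v = 3.5 µm/s, γ_e = 3.1×10⁻⁸ N/m, and an explicit geometric prefactor c
(default 1).  Two arithmetic consequences are exposed rather than asserted:
at c = 1 a slope of 16.4 µm inverts to R = 6.0 µm, and a bacterium-sized
R = 2 µm requires c ≈ 0.111.  The vectorial occupancy places the three
compartment fractions on unit vectors 120° apart; in the analysis of real
networks the directions are the actual centroid-to-junction unit vectors,
whose vector sum coincides with the idealised Φ for symmetric junctions and
removes the common mode exactly.

### Network forcing construction

In `simulate_network_dynamics` the active force of compartment c is built
from the target displacement field u_c (each of c's junctions displaced
away from the centroid by `displacement_per_phi_um`·Φ_c) as the static
force pattern F_c = H u_c, with H the network Hessian.  This construction
was chosen after measuring that the naive alternative — outward forces of
one calibrated magnitude — reproduces the law only for an isolated loaded
compartment: the elastic response of the network is long-ranged (a loaded
compartment acts as a 2D pressure source with slowly decaying displacement
field), and with every compartment loaded the cross-talk buries the local
law entirely.  With F_c = H u_c the mean displacement field equals the
target for any superposition of loaded compartments, by construction.
Each pattern is modulated by one shared Ornstein–Uhlenbeck factor per
compartment (mean 1, relative sd `active_fluctuation` = 1 by default,
correlation time τ = 1 s, clipped at zero because swim pressure cannot
pull, with the clipping gain divided out of the mean), so junctions of one
compartment share a force history — the origin of the spatial correlations
the correlation analysis measures.  Displacement targets are capped at 4%
of the compartment diameter: beyond a few percent the inflation mode
softens (line tension exerts a constant, not linear, restoring force along
it) and eventually buckles, and the linear calibration would no longer
hold.

Activity in a scenario enters **only** through this forcing: the thermal
bath stays at T, and the elevated effective temperature of active samples
emerges from the forcing spectrum instead of being imposed as a hotter
bath.  This keeps the enhanced fluctuations spatially structured, as shared
forcing requires.  An optional bath multiplier remains for emulating
unresolved isotropic agitation.

A finite lattice with pinned boundary breaks the three-fold symmetry of
equal loading: the residual mean displacement of an equally-loaded central
junction is ~0.2 µm on a 5×5 lattice, falling to ~0.06 µm at 9×9, an order
of magnitude below matched single-compartment loading.  Tests assert the
ratio and the baseline rather than exact zero.

### Generator defaults

Where no measured value exists, defaults were chosen once for realism:
edge line tension 10⁻¹² N, set so the passive junction displacement SD is
≈ 0.26 µm (matching the kB T/γ_e ≈ 0.36 µm passive edge scale) and the
network relaxation frequency ≈ 2×10⁻² Hz; bacterium footprint 2 µm² (a
0.8 × 2.5 µm rod projected); occupancy counts Poisson with mean 10,
truncated at 40 by redraw; 15 µm honeycomb edges (20–50 µm compartments);
imaging at 1 frame/s for 10 min, 0.5 µm pixels, 0.6 µm PSF.

## Swimmers

Active Brownian particles move at constant speed with rotational diffusion
D_r = 1/τ, giving the heading correlation exp(−t/τ), and reflect specularly
off the compartment walls; each contact is logged with position, incidence
angle and momentum transfer per unit mass (2 v cos θ).  The integrator
refuses time steps with v·dt above a tenth of the shortest wall segment.
In a 40 µm compartment at v = 3.5 µm/s and τ = 1 s a swimmer hits the wall
several times per minute.

The tracking speed estimator corrects the frame-rate bias: at Δt comparable
to τ the naive mean |Δr|/Δt underestimates v (≈ 2.9 µm/s at Δt = τ = 1 s),
so the estimator inverts the closed-form mean-square displacement
MSD(Δt) = 2 v² τ² (Δt/τ + e^(−Δt/τ) − 1), which restores the estimate to
within a few percent; residual bias comes from wall collisions.

## Imaging

Rendering rasterises edges as anti-aliased lines (junctions are brightest
because three edges overlap), blurs with a Gaussian PSF, draws swimmer
footprints as disks in the bacteria channel, and optionally adds Poisson
shot noise plus Gaussian read noise; stacks are quantised to 8 bits, the
scale on which the tracking threshold tolerance (default 50) is defined.
Ground truth (junction positions in stack coordinates, occupancies, the
binarisation threshold) is emitted alongside.

Detection finds local maxima of the smoothed membrane frame above a
threshold relative to the frame maximum (scale-invariant), suppressed to a
minimum separation; on noise-free renders every interior junction is found
within one pixel.  Tracking takes the brightest pixel of the smoothed ROI
per frame, flags frames whose maximum drops more than the tolerance below
the track's running maximum, and optionally refines by the 3×3 intensity
centroid (raw argmax is the compatibility default).  QC removes tracks with
frame-to-frame jumps beyond a threshold or more than 20% invalid frames.
Occupancy is the foreground fraction of the binarised bacteria channel per
compartment polygon (Otsu per frame by default; fixed threshold for exact
fixtures).

## Spatial correlation

Displacement series (block-re-centred radial magnitude by default; vector
components optional) are correlated pairwise at zero lag; pairs need ≥ 30
common frames and are binned by mean separation (10 µm bins).  Significance
uses a circular-shift permutation null (95% level).  The correlation length
is the first distance at which the baseline-subtracted curve falls below
the threshold, linearly interpolated; a curve already insignificant in the
first bin reports 0 with a "no correlation" flag, and one still significant
at the largest distance reports that distance as "censored".  Hotspot maps
give each junction's largest within-window displacement from the window
mean.

## What the generator does not emulate

No hydrodynamic or steric swimmer–swimmer interactions; no membrane
wrapping or adhesion of swimmers; no curvature-resolved (decorated)
junctions; no 3D structure; no plastic events in the Langevin network (the
T1 operator acts on topology separately, and the dynamics stay in the
linear neighbourhood of the reference configuration by the 4% displacement
cap); photobleaching, stage drift beyond what 60-s blocking removes, and
non-Gaussian camera noise are absent.  Passing the synthetic recovery tests
therefore demonstrates the correctness of the estimators under the stated
models, not their robustness to every artefact of real microscopy.

## Limitations

* The corner frequency of the slow junction dynamics is below the
  resolution of a 10-min record; only the paired amplitude information is
  reliably identified, as reflected in the passive/active fit design.
* The displacement-law slope in a scenario is recovered with the
  ground-truth rest positions as reference; with real data a reference must
  come from a passive control or long-time mean, adding bias that is not
  modelled here.
* The membrane point-force response is the quasi-static linearised bound
  with a bending-length cap on the inner cutoff; it reproduces the
  conclusion that mN/m membranes deform sub-nanometrically, but it is not a
  dynamic membrane solver.
* Problem sizes in tests and the acceptance script (5×5–7×7 lattices,
  10-min records, 20-track ensembles) are the package's standard desk-scale
  conditions; statistics at these sizes carry the sampling errors quoted in
  the tests.
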