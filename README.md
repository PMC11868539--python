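# lipidfoam

Analysis and simulation toolkit for **lipid-foam prototissues**: synthetic
tissues made of micrometre-scale aqueous compartments separated by lipid
bilayers, which meet at three-way junctions like the films of a dry foam or
the cell boundaries of a confluent epithelium.  When swimming bacteria are
encapsulated in the compartments, their collisions with the bilayers generate
tension fluctuations that displace the junctions, broaden the edge-length
distributions and can drive T1 neighbour exchanges — the hallmarks of active
tissue fluidisation.

The package is aimed at people quantifying such systems (or their models):
it covers the geometry and mechanics of the foam, the statistics of junction
fluctuations, the active-matter model that links bacterial occupancy to
junction displacement, and a full synthetic-data generator so that every
analysis stage can be validated against known ground truth without any
microscope.

## What it computes

**Foam geometry and tension balance** (`foam_geometry`).  Degree-3 junction
networks (regular honeycomb or jittered-Voronoi disordered foams), the shape
index `s = p/√A` (3.722 for hexagonal packing; ≈ 3.81 at the rigidity
transition of vertex models), the leaflet-zipping relation
`γ_B = 2 γ_ML cos φ` with its inverse, micropipette-aspiration tension from
the Laplace law, force balance and relaxation of junctions (120° at equal
tensions), and the T1 topological operator with an event detector.

**Synthetic data** (`synthetic_data`).  Overdamped Ornstein–Uhlenbeck
junction dynamics in a harmonic trap (drag `b`, corner frequency `f0`,
effective temperature `T_eff`); whole-network Langevin dynamics with
per-compartment active swim-pressure forcing; confined active Brownian
swimmers (speed 3.5 µm/s, persistence ≈ 1 s) with a wall-collision log;
truncated-Poisson occupancy sampling; and rendering of two-channel
(membrane dye + bacteria) micrograph stacks with ground truth.

**Image analysis** (`image_analysis`).  Junction detection and per-frame
brightest-pixel tracking in ROIs (threshold tolerance on an 8-bit scale,
optional sub-pixel refinement), bacterial occupancy per compartment from the
binarised bacteria channel, track QC, and a persistence-corrected swimmer
speed estimator.

**Fluctuation statistics** (`fluctuation_stats`).  1-minute block
re-centring, displacement and edge-deviation statistics (`L − L̄`), Welch
spectra, and fits of the junction-fluctuation spectrum

```
S(f) = 4 kB T_eff / b / [(2π)² (f² + f0²)]
```

in the paired passive/active design: the heat-killed control fixes the drag
`b`, the active fit returns `T_eff/T`.  The effective tension follows from
passive edge fluctuations as `γ_e = kB T / σ`.

**Active inference** (`active_inference`).  The vectorial occupancy
`Φ = |Φ₁ + Φ₂ + Φ₃|` on directions 120° apart, the swim-pressure
displacement law

```
Δϑ = c · (3 η τ A / 4 R²) · (v² Φ / γ_e)
```

with zero-intercept slope fitting and inversion for the swimmer–membrane
interaction radius `R`, plus the point-force membrane response
`h = F/(2πγ) · ln(r_max/r_min)` that bounds direct membrane deformation to
sub-nanometre scales at mN/m tensions.

**Spatial correlation** (`spatial_correlation`).  Zero-lag displacement
cross-correlation versus junction distance, correlation length with a
permutation-null significance criterion, and 60-s hotspot maps.

## Worked example

Simulate a matched active / heat-killed pair of 5×5 foams (15 µm edges,
10 min at 1 frame/s) and run the full analysis chain:

```python
import pathlib
import lipidfoam as lf
from lipidfoam import cli

root = pathlib.Path("runs")
active = lf.ScenarioConfig(seed=1, n_rows=5, n_cols=5, duration_s=600,
                           mode="active", render=False, simulate_swimmers=False)
passive = active.model_copy(update={"mode": "heat-killed"})
cli.run_simulate(active, root / "active")
cli.run_simulate(passive, root / "passive")
cli.run_analyze(root / "passive", root / "out_passive", cli.AnalyzeConfig())
report = cli.run_analyze(root / "active", root / "out_active",
                         cli.AnalyzeConfig(), passive_dir=root / "passive")
```

which prints, for the keys of `report`:

```
mean shape index     : 3.722
edge fluctuation SD  : 0.708 um
Teff/T (active)      : 11.2
drag b               : 0.41 uN s/m
slope of d(Phi)      : 17.3 um
R at c=1             : 5.9 um
correlation length   : 37 um
```

Reading: the honeycomb sits at the hexagonal-packing shape index; the active
sample's edge-length fluctuations are ~3× broader than the heat-killed
control (0.71 vs 0.22 µm), which the spectral fit expresses as an elevated
effective temperature; the fitted junction drag is of the order of a few
tenths of a µN·s/m; the mean junction displacement grows linearly with the
occupancy imbalance Φ with a slope near the generator's 16.4 µm, inverting
to an interaction radius of ~6 µm at unit geometric prefactor; and junction
motion is positively correlated up to roughly a compartment diameter.

The same pipeline runs from the shell:

```
lipidfoam simulate --seed 1 --out runs/active
lipidfoam track   --bundle runs/active --out runs/tracked
lipidfoam analyze --bundle runs/active --passive runs/passive --out runs/out
lipidfoam report  --analysis runs/out --out runs/figs
```

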