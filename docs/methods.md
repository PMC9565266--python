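# Methods

## The diagnostic

Interior ocean flow is close to adiabatic: water moves predominantly along
surfaces of constant potential density (isopycnals), and mesoscale eddies
stir tracers along those surfaces while mixing moves tracers across them.
A nutrient budget formed in fixed depth levels conflates these pathways,
because isopycnals heave through the z-grid as eddies pass.  This package
recasts z-level finite-volume model diagnostics into an isopycnal-layer
budget

    d(h Pσ)/dt = −∇σ·(Fσ h) − h ∂F_d/∂d + h Bσ

per density layer and water column: tendency of layer tracer content,
convergence of the along-isopycnal transport, convergence of the diapycnal
(cross-isopycnal) flux, and the biological net source.  The along-layer
transport is further split into a mean and an eddy part,

    F̄σh = (Fσh)_mean + (Fσh)_eddy,     (Fσh)_mean = ū σ P̄σ h̄,

with the eddy part defined as the exact residual, so it collects every
covariance of the fluctuating velocity, concentration and layer thickness
(bolus and stirring fluxes alike).

## Coordinate transform

The transform is geometric and exactly conservative:

1. **Fine-grid refinement.** Every cell is split into `ceil(h/target_dz)`
   equal sub-cells (`target_dz` = 2 m by default; it controls how finely a
   density interface can cut through a cell).  Extensive quantities
   (content, face fluxes, sources) are divided equally among a cell's
   sub-cells, so sums are preserved exactly.  σ₀ is linearly interpolated
   from cell centers to sub-cell centers, with constant extrapolation past
   the outermost centers.
2. **Sorting and binning.** Density inversions are removed by a stable
   vertical sort of each fine profile, then each sub-cell goes to the bin
   with `edge_low < σ₀ ≤ edge_high` (upper-closed; any fixed convention
   conserves, this one makes ties deterministic).  Default edges run
   22.8–27.6 kg m⁻³ at 0.2 spacing; results are aggregated into four
   macro layers bounded by σ₀ = 24.0, 26.0 and 26.8 (surface, upper
   thermocline, lower thermocline, abyssal remainder).
3. **Face fluxes.** A horizontal face inherits the arithmetic mean of the
   two adjacent columns' fine σ₀ profiles, time-averaged between the two
   instants bounding the interval, and each fine sub-face flux is assigned
   to the layer occupying that segment.  This symmetric choice keeps the
   binned face transports summing exactly to the z-integrated ones.
4. **Diapycnal fluxes by residual closure.** The diapycnal volume flux
   through each layer interface is diagnosed from the layer-thickness
   budget integrated from the seafloor up (seafloor flux zero), and the
   diapycnal tracer flux identically from the layer tracer budget
   including the source.  Every per-layer budget therefore closes to
   round-off *by construction*; the information content of the check moves
   to the surface: the accumulated surface residual must reproduce the
   input's (normally zero) surface flux, and a relative discrepancy above
   1e-9 raises an error flagging inconsistent input.  The explicitly
   supplied vertical diffusive flux, interpolated to the interface depths,
   is carried separately as a diagnostic attribution (`Fd_dif`).

Outcropped or vanished layers keep zero thickness and zero fluxes but stay
in every array, so budgets remain well defined as layers appear and
disappear.  Interface depths inside the layered product are cumulative
layer thicknesses (exactly consistent with the binning); the standalone
isopycnal-depth operation interpolates linearly and is what the
gyre-interior mask uses.

## Time conventions

States (thickness, σ₀, tracer) are instantaneous; face fluxes and sources
are means over the interval between consecutive instants.  This is the
only convention under which the discrete budget can close exactly.  Budget
averages over a window are arithmetic means over intervals (the window
tendency telescopes to the endpoint contents divided by the elapsed time);
uniform interval length is asserted.

## Reynolds decomposition

The mean component realizes the "product of time means" with
thickness-weighted means: the layer velocity enters through the time-mean
layer *volume transport* V̄, and the face concentration through the time
mean of the per-interval transport-weighted face concentration
`T_adv/V` (for intervals with zero face volume transport, the
content-derived concentration of the adjacent columns stands in).  Under
this weighting the eddy residual vanishes identically whenever the flow
and the layer geometry are steady, no matter how the tracer field drifts —
which is the defining property of an eddy flux.  Along-layer parameterized
diffusive transports belong to the total but not to the mean product, so
they appear in the eddy residual.  The weighting convention is recorded in
the output metadata; additivity `total = mean + eddy` is exact because the
eddy is stored as the residual.

The biological source decomposes the same way: the residual between the
time-mean layer source and the product of independently averaged layer
thickness and intensive rate captures the thickness–rate covariance
(rectification by isopycnal heaving).

## Regional budgets

The basin-band budget integrates the macro-layer terms over a latitude
band (default 12–42°N) that must be zonally closed — edge columns are
required to be land-flanked or at the closed domain boundary, and the
operation refuses (naming the open columns) rather than silently including
zonal leakage.  Meridional boundary transports, mean and eddy, are
reported at both bounds with positive into the band.  The gyre
recirculation interior is the set of columns where the time-mean
σ₀ = 26.8 isopycnal lies strictly deeper than 450 m; its budget reports
the same terms integrated over the mask, with the lateral exchange across
the jagged mask edge carried by the integrated mean/eddy convergences.
Map smoothing uses a 2-D Gaussian kernel (SD one grid point, truncated at
4 SD) with kernel weights renormalized over ocean cells, so constants are
preserved over the ocean and no mass bleeds into land.

## The synthetic eddying gyre

The generator produces the statistical structure the analysis assumes,
not a dynamical ocean model:

* **Grid and basin.** Closed rectangular basin, 40×40 columns spanning
  5–45°N × 40° of longitude, 20 fixed z-levels over 800 m (10 × 20 m
  above 10 × 68 m).  Cell thicknesses are constant in time and uniform per
  level (no partial bottom cells).
* **Circulation.** A steady, surface-intensified double-gyre corner
  streamfunction (nondivergent per level; the subtropical cell dominates
  and stays north of 12°N) plus a meridional overturning cell with
  upwelling confined to the southern flank, a northward surface branch
  above ~100 m, a southward return through the thermocline and sinking at
  the northern flank.  The vertical velocity is closed cell-by-cell from
  continuity, so volume budgets are exact.
* **Eddies.** Two propagating sinusoidal streamfunction modes (default
  3 and 5 zonal wavelengths, westward phase speed 0.25 m s⁻¹, seeded
  random phases) stir tracer along layers; the density field is displaced
  by a heave proportional to the same eddy pattern (40 m at the reference
  amplitude, decaying with depth over 600 m), so isopycnals move and layer
  thicknesses fluctuate coherently with the eddy velocities.  Setting the
  eddy amplitude to zero disables both stirring and heaving.
* **Density.** σ₀ is prescribed, not prognostic: an exponential background
  profile spanning ~23–27.6 kg m⁻³, displaced by a bowl-shaped doming
  (+150 m at the gyre center, −150 m at the flanks) and by the eddy heave.
  Prescription guarantees the field stays controlled and spans the
  analysis bins.
* **Nutrient cycle.** Uptake at rate 1/(20 d) above the 100 m euphotic
  depth; 85% of each column's uptake is redistributed instantaneously
  below the euphotic depth with a 250 m e-folding, the remainder leaves as
  bottom export; restoring toward 2.2 mmol m⁻³ at 1/(15 d) in the southern
  flank belt (south of 10°N, 50–400 m) maintains the upwelling nutrient
  pool.  Redistribution is instantaneous, so no sinking-speed state is
  carried.  Vertical diffusivity (default 3×10⁻⁵ m² s⁻¹) supplies the
  upward diffusive leak; the horizontal diffusivity
  defaults to zero so that, with eddies switched off, the along-layer eddy
  residual vanishes identically (upwind advection supplies lateral
  smoothing).
* **Exactness.** Advection is first-order upwind; every face flux and
  source actually applied is accumulated into the recorded interval
  means, so the discrete z-level budget closes to round-off and the
  layered budgets close by construction.  Identical seed and configuration
  give bitwise identical output.
* **Initial tracer.** A pure depth profile mapped from the *background*
  stratification (0.05 mmol m⁻³ at the surface to 2.0 at depth),
  emulating a ventilated thermocline with no lateral structure; flank
  enrichment then builds up from restoring and upwelling during spin-up
  (40 output intervals = 120 days by default, before 60 diagnosed
  intervals at the 3-day cadence).

What the generator does *not* emulate: geostrophic turbulence (eddies are
two deterministic waves, not a spectrum), salinity/temperature dynamics,
a prognostic ecosystem, bathymetry and coastlines, submesoscale motions,
and air–sea exchange.  Passing tests therefore demonstrate the
*diagnostic machinery* — conservation, closure, the exactness and sign
conventions of the decomposition — and the qualitative relay structure on
a controlled flow, not quantitative fidelity to any particular ocean
state.

## Problem sizes and numerical choices

The bundled study conditions are 40×40×20 columns and 60 three-day
intervals (a 6 h model step, 12 steps per interval); the refinement
sensitivity analysis uses a 12-interval window at 4/2/1 m fine grids,
where halving the fine grid from 2 m to 1 m moves domain-integrated
macro-layer budget terms by about 1% (and by less than the 4 m → 2 m
difference, i.e. convergence is monotone).  Closure tolerances: 1e-10 for
the z-level consistency check, 1e-9 for the layered surface residual and
per-layer budgets, 1e-12 for conservation of column sums.  Ties in
density binning go to the lighter layer (upper-closed bins); density
inversions are sorted, not left in place.  Degenerate inputs: a grid with
a single unbounded density bin reproduces the z-column budget exactly;
always-vanished layers yield zero mean and eddy transports.

## Known limitations

* Cell thicknesses must be uniform per level across ocean columns and
  constant in time (fixed z-level grids without partial bottom cells);
  violating input raises a geometry error rather than silently binning.
* The parameterized diffusive flux is binned on its native faces; no
  isoneutral rotation is applied.
* The mean/eddy *split* (not the total) depends on the recorded weighting
  convention; alternative weightings redistribute transport between the
  two parts.
* Only σ₀ is supported as the layering variable (no σ₂ or neutral
  density).
* NetCDF products are written in NetCDF-3 (64-bit offset) via the SciPy
  backend.
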