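# Numerical methods and conventions

This document records the numerical choices behind each module, the unit
conventions, and the verification strategy of the test suite.

## Units

All internal quantities are SI (m, s, Pa, kg).  Clinical units appear only
at interfaces: pressures in mmHg (1 mmHg = 133.322 Pa), flows in ml/s,
compliances in ml/mmHg.  The Windkessel module works in clinical units
throughout because RCR parameters are conventionally stated in them.

## Mesh and discrete operators (`mesh.py`)

Tetrahedral meshes with linear (P1) shape functions.  Cell gradients are
exact for affine fields; node-centred gradients/vorticity are cell values
volume-averaged over adjacent tets.  Nodal volumes are lumped (¼ of each
adjacent tet); wall-node areas are lumped triangle thirds.  Inverted tets
are canonicalized by a vertex swap at construction; zero-volume cells are
rejected.  Point location uses a centroid k-d tree with barycentric
containment; points outside the mesh fall back to clipped nearest-cell
extrapolation and are flagged.

## Time grids and cycle integrals (`fields.py`)

Fields store one cardiac cycle on a uniform snapshot grid with the periodic
convention value(T) = value(0) (the closing snapshot is not stored).  Under
this convention the trapezoidal rule over the closed cycle assigns every
snapshot the same weight dt, which makes several test oracles exact
(two-phase OSI, phantom tear volumes).

Analysis planes carry their own areal quadrature (triangulated disc or
polygon, centroid rule), independent of the mesh; flux through a plane is
Σ (v·n) w.

## Inlet velocity profiles (`ivp.py`)

The reference (`4d`) profile is built from per-timeframe inlet samples:

1. each frame's contour is registered to the fixed inlet patch by a 2D
   similarity Procrustes fit with angular correspondence, optionally
   followed by a Gaussian-kernel displacement field with Tikhonov weight
   (`rigidity`); a residual above 20% of the inlet radius raises;
   fold-overs are detected via Delaunay orientation flips;
2. mapped samples are interpolated onto a fixed intermediate grid
   (linear, nearest fallback at the rim);
3. a cubic spline over three tiled cycles (central cycle evaluated)
   resamples in time; a final barycentric interpolation moves the profile
   onto the inlet nodes, whose perimeter is zeroed for no-slip.

Derived variants: `flat` imposes Q(t)/A uniformly along the patch normal
(flux matched because the same quadrature weights define both Q and A);
`tp` keeps only the normal component pointwise (flux preserved bitwise);
`scaled` multiplies all components by a constant, scaling stroke volume by
exactly that factor.

## Windkessel network (`windkessel.py`)

Central pressure targets from a brachial pair: P_d = P_d′ and
P_s = 0.83 P_s′ + 0.15 P_d′; MAP estimate P_d + PP/3.

The 0D model is an imposed inflow feeding a zero-resistance junction with
all RCR outlets in parallel and zero distal pressure.  Implicit (backward)
Euler at 1 ms with a single LU factorization of the constant system matrix;
cyclic periodicity is declared when systolic and diastolic junction
pressures change by <1% between cycles.  A cycle mass-balance diagnostic
uses the integrator's own quadrature (closes to <0.1%).

Tuning: total resistances R_tot,i = MAP/Q̄_i; the split R1/R_tot is a per
outlet input; compliances share a common time constant whose global scale
is found by bracketed Brent root-finding on the simulated pulse pressure;
a small outer fixed-point loop on the working (MAP, PP) set-points absorbs
the difference between the clinical MAP estimate and the simulated
waveform's mean-to-extremes relation.  The scaled-flow case re-tunes with
flow targets multiplied by the scale factor and unchanged pressure targets.

## Wall shear stress (`wss.py`)

The velocity gradient at a wall node is the volume-weighted average of
adjacent cell gradients; the viscous traction 2 μ(γ̇) D·n (outward normal)
is projected onto the wall tangent plane.  Viscosity is Newtonian by
default (μ = 3.5 mPa·s, ρ = 1056 kg/m³); Carreau–Yasuda parameters may be
supplied.

Indices over one cycle: TAWSS = (1/T)∫|τ|dt, OSI = ½(1 − |∫τ|/∫|τ|),
RRT = 1/|mean shear vector|, ECAP = OSI/TAWSS.  Nodes with zero shear all
cycle are flagged undefined (NaN); RRT is +inf where only the mean vector
vanishes.

**Extraction accuracy.**  Two discretization error sources were measured by
a convergence study: (a) radial wall-layer spacing relative to the Stokes
layer thickness δ = √(2ν/ω) (first-order), and (b) the azimuthal chord
sagitta of the polygonal wall contaminating the near-wall gradient (the
dominant term for steady flow).  Test meshes were selected from that study
to put the scheme inside the 5% verification bound: Poiseuille at
10 rings × 90 azimuthal points (0.09% error) and Womersley α = 5.5 at
14 × 96 (2.6% error).  Higher α needs proportionally finer wall grading.

## Helicity (`helicity.py`)

Helicity density H_k = v·ω with cell-centred quadrature: exact P1 curl per
cell, velocity at the centroid, cell-volume weights.  This makes volume
integrals of linear integrands exact, so a mirror-antisymmetric flow has
h1 = 0 to roundoff on a centred mesh.  h1/h2 are time–volume averages of
H_k and |H_k| per region and window; h3 = h1/h2 ∈ [−1, 1].  The default
systole window ends at the first down-crossing of Q_in through 5% of its
peak (fallback 0.35 T).  LNH = H_k/(|v||ω|) is node-centred, clamped to
[−1, 1], zero under a small-denominator guard.

## Snapshot POD (`pod.py`)

Mean-subtracted snapshots, Gram matrix under a weighted inner product
(lumped nodal volumes for velocity, lumped wall areas for wall shear;
uniform optional), `eigh`, modes normalized and sign-fixed (largest
component positive).  Eigenvalues follow the snapshot-sum convention
λ_k = Σ_t a_k(t)², so Σλ equals total weighted fluctuating energy and the
relative truncation error at rank k is exactly √(Σ_{j>k} λ_j / Σλ)
(Parseval) — asserted against brute-force reconstruction in the tests.
Under uniform weighting the eigenvalues equal the squared singular values
of the snapshot matrix (SVD oracle).

## Clinical metrics (`compare.py`)

Transmural pressure TMP(t) = P_TL − P_FL (reported in mmHg, cycle mean by
periodic trapezoid).  False-lumen ejection fraction
FLEF = 100 · V_retro / SV, where V_retro integrates the negative part of
the tear flux (normal oriented TL → FL).  Growth is 100·(A₂ − A₁)/A₁ per
station; profiles from different sources are joined by nearest station
within half the minimum station spacing.  Pearson correlations exclude
non-finite pairs and flag zero-variance inputs instead of fabricating r.

## Pipeline (`pipeline.py`, `cli.py`)

`run_experiment` writes a fixed artefact set — pressure targets, tuned WK3
parameters (reference + scaled), inlet summaries, regional shear indices,
case-vs-baseline difference statistics, helicity indices, clinical metrics,
and `provenance.json` — with `%.10g` float formatting and no timestamps, so
reruns are byte-identical.  Cases missing inputs simply contribute no rows.
`haemopost demo` runs the whole chain on the synthetic two-lumen phantom.

## Verification strategy

Every numeric claim is tested against an independent oracle:

- closed forms (Poiseuille/Womersley velocity, flow and wall shear; the
  resistive divider of the 0D network; Beltrami LNH = ±1; solid-body
  helicity 2ΩW);
- exact algebraic identities (RRT/ECAP relations, the two-phase OSI value
  (1 − √2/2)/2, POD Parseval and SVD equivalences, affine invariance of
  Pearson correlation);
- prescribed phantom quantities (TMP = 2 mmHg, FLEF = 100·1.5/70%,
  triangular tear lobes with kinks on snapshot times so trapezoid
  integration reproduces the prescribed volumes exactly);
- property-based tests (hypothesis, derandomized) for scaling laws, index
  bounds and target ordering.

`tests/test_acceptance.py` contains one test per acceptance criterion;
`scripts/acceptance.py --seed N --out results/acceptance.json` emits the
acceptance target (`t1`: the rounded central systolic pressure target,
127 mmHg, from the reference brachial measurement 138/81 mmHg).
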