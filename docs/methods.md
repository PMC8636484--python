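# Methods

## Problem and model

`carinaflow` models the haemodynamic environment that a circulating
tumour cell (CTC) meets where a large blood vessel (calibre ~2 mm)
splits into two daughters. Flow decelerates in front of the apex of the
bifurcation (the *carina*), producing a stagnation zone of very low
velocity. A cell carried on a streamline close to the dividing
streamline enters this zone, lingers, and thus gains time to interact
with the vessel wall — the physical precondition for adhesion and
arrest. The package quantifies that mechanism: how large the
low-velocity zone is, how long cells reside near the carina, how many
of the seeded cells ever get there, and how these observables respond
to the bifurcation angle and to the viscosity of the carrier medium.

### Carrier flow

The medium is an incompressible Newtonian fluid in steady laminar flow:

    div v = 0
    rho (v . grad) v = -grad p + mu lap v

with a prescribed flow rate Q at the inlet (fully developed parabolic
profile by default), no-slip walls, and zero-pressure outlets. At the
reference conditions (Q = 3 mL/min, 2 mm semicircular section, mu =
1.46–2.29 mPa s, rho = 1000 kg/m3) the channel Reynolds number
Re = rho v D_h / mu is 17–27, far inside the laminar regime; the solver
refuses configurations beyond Re = 500.

**Dimensionality.** The physical duct is three-dimensional with a
semicircular cross-section. The package solves the 2-D mid-plane
problem: the stagnation zone, its angle dependence and its viscosity
dependence are planar phenomena, and the mid-plane is where the
carina-approach dynamics live. The 2-D problem is driven so that the
mid-plane mean inlet speed equals the 3-D mean speed Q/A of the
semicircular section (v = 3.18 cm/s at reference conditions), which
preserves the velocity scale and the Reynolds number. Regime
diagnostics (Re, hydraulic diameter D_h = 4A/P = 1.222 mm) always use
the true 3-D section. Every area this package reports is a mid-plane
area; quantitative transfer to the 3-D duct is approximate and is
flagged as the main limitation below.

### Particles

CTC analogues are rigid spheres, by default D_p = 14 um and rho_p =
1.05 g/mL, one-way coupled to the flow (20,000 cells in millilitres of
medium do not alter the field). Each obeys

    m_p dv/dt = F_d + F_g,
    F_d = 1/2 C_d rho A_p |v_s| v_s,       v_s = v_fluid - v_particle,
    C_d = 24/Re_p (1 + 0.15 Re_p^0.687),   Re_p = rho |v_s| D_p / mu,
    F_g = m_p g   (optionally buoyancy-corrected, (rho_p - rho) V_p g).

The Schiller–Naumann correlation is valid for Re_p below ~800; in
practice Re_p stays below ~0.5 here (its largest value occurs in the
first instants after a particle is seeded at rest), so the drag is
essentially Stokesian. Gravity is out-of-plane by default — the device
mid-plane is horizontal — and can be put in plane via configuration;
with in-plane gravity and buoyancy enabled the integrator recovers the
Stokes settling speed (rho_p - rho) g D_p^2 / 18 mu = 3.66 um/s.

## Numerics

### Meshing

Geometries are parametric: opening angle alpha (between daughter
centrelines), calibre (= parent and daughter width), branch lengths
(>= 5 calibres, an entrance-length margin), and a sharp or blunt
(circular-arc fillet) carina. The upper half-domain is covered with
boundary points, two offset point layers hugging the no-slip walls, a
hexagonal interior lattice and a refinement disc of radius 0.2 calibre
around the apex (local spacing one third of the bulk target size); a
Delaunay triangulation filtered to the half-polygon is mirrored about
the symmetry axis. Building the mesh from a mirrored half guarantees
exact reflection symmetry of the discretisation, so the solver's
symmetry checks test physics, not meshing noise.

### Flow solver

Taylor–Hood P2/P1 finite elements with Newton iteration on the
convective term, started from the Stokes solution; the saddle-point
systems are solved by sparse LU. Zero-pressure outlets are realised as
the do-nothing natural boundary condition. Convergence demands a
relative residual (against the boundary-data load norm) below 1e-5
(configurable); Newton typically needs 3–5 iterations at Re ~ 30. The
parabolic inlet profile is quadratic and therefore represented exactly
by P2, which is why the solver reproduces plane Poiseuille flow to
machine precision and why the maximum velocity (1.5 v on the parent
centreline) is mesh-independent to rounding. Continuity is enforced
weakly; the L2 divergence norm is O(h) relative to the shear scale,
about 1% at the default resolution. Global mass imbalance is below
1e-10 of the inlet flux.

### Particle integration

The relaxation time tau_p = rho_p D_p^2 / 18 mu is ~8 us while
convective steps are ~1 ms, so explicit integration of the drag term
would be hopelessly stiff. Instead the Schiller–Naumann factor is
frozen over each step, making the drag linear with effective time
constant tau = tau_p / (1 + 0.15 Re_p^0.687), and the resulting linear
ODE is solved exactly (exponential update for velocity and its integral
for position). The carrier velocity is interpolated linearly within
cells (a point-location structure makes this vectorisable over the
whole ensemble) and evaluated at a midpoint-predicted position, so the
tracer limit is a second-order (RK2) streamline integrator. Steps adapt
to the local cell transit time (CFL 0.25, bounds 10 ns–2 ms). A
particle terminates by leaving through an outlet, by approaching a wall
closer than D_p/2 (`wall_contact` — the physics-only surrogate for the
adhesion step, which is not modelled), or by exhausting `max_time`
(30 s default); every seeded particle reaches exactly one terminal
state, so the status census always sums to the ensemble size. No
randomness enters the integration; given the seeding RNG seed, runs are
bit-reproducible.

### Carina observables

* **Carina region**: disc of radius 5 D_p (70 um, configurable) about
  the carina tip (apex, or arc nose when blunt). A trajectory "enters"
  if its closest approach (measured per linear sub-step segment) is
  inside; the **carina fraction** is the fraction of seeded
  trajectories that enter.
* **Residence time**: time a trajectory spends inside the region,
  accumulated with exact segment/disc chord intersections. Summary
  statistics (mean/SD) are over the particles that entered.
* **Low-velocity area**: area where |v| < 1% (configurable) of the mean
  inlet speed, integrated exactly for the cell-linear speed field,
  restricted to a half-disc window of radius 0.2 calibre *upstream* of
  the carina tip. The upstream restriction is deliberate: every no-slip
  wall carries a thin low-speed band at any angle and viscosity, and
  the daughter inner walls run downstream from the tip, so a full-disc
  window would mostly measure wall-band length (which *decreases* as
  slender wedges leave the window) instead of the stagnation zone. The
  upstream half-disc contains no walls for any opening angle and
  isolates the quantity of interest. No canonical velocity cut defines
  "extremely low velocity"; the threshold used is always reported with
  the area.

### Sweeps and mesh independence

Angle and viscosity sweeps rerun the identical scenario varying one
parameter, with identical seeds, and attach monotonicity verdicts. The
mesh-independence study solves the same scenario at three target cell
sizes (default calibre/10, /20, /40, each halving the previous) and
compares the controls — maximum velocity and mean carina residence time
— between the two finest levels against a 5% criterion.

## Synthetic data and oracles

No external data exist; all inputs are configuration. The seeding
module places particles across the inlet (uniform by default, matching
cells distributed throughout the cross-section; flow-weighted and
centreline variants available) with a D_p/2 wall margin, from a named,
seedable RNG recorded in every artifact. The analytic module provides
the closed-form references the solvers are tested against: plane
Poiseuille flow, Stokes settling, exponential drag relaxation, and
chord transit times. These oracles are dependency-free of the code they
test. Passing against them establishes correctness of the discretised
operators at desk scale; it does not validate the biological fidelity
of the 2-D, rigid-sphere, adhesion-free model against real vessels.

## Default parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| calibre | 2 | mm | large-vessel scale studied |
| angle | 90 (sweep 30/45/90) | deg | reference + sweep values |
| parent/branch length | 10 | mm | 5 calibres, entrance margin |
| Q | 3 | mL/min | perfusion rate studied |
| rho | 1000 | kg/m3 | aqueous media |
| mu | 1.46 / 1.935 / 2.29 | mPa s | non-conditioned / FBS / methylcellulose |
| D_p, rho_p | 14, 1050 | um, kg/m3 | CTC size and density |
| n particles | 20,000 | — | ensemble size studied |
| solver tolerance | 1e-5 | — | convergence monitor value |
| carina radius | 5 D_p = 70 | um | "very close to the wall", order a cell radius scale |
| area threshold | 1% of mean inlet speed | — | reported with every area |
| blunt radius | 0.2 | mm | plausible fillet, configurable (no published value) |

Problem sizes used by the test suite and the acceptance script: default
runs at cell size calibre/16 (~12k cells) with the full 20,000-particle
ensemble; the refinement study at calibre/10, /20, /40 (~5k/18k/68k
cells) with 4,000 particles; monotonicity sweeps with small ensembles,
since the low-velocity area needs no particles.

## Design notes and limitations

* **Scheme choice.** The contract (Poiseuille to <1e-3, mass balance to
  0.5%, symmetric split, mesh independence) pins behaviour, not the
  discretisation; Taylor–Hood + Newton was chosen for its clean
  convergence at these Reynolds numbers and exactness on quadratic
  profiles.
* **Residence-time statistics are ensemble-composition dependent.** The
  mean over entering particles has a heavy tail: trajectories nearer
  the dividing streamline reside longer (logarithmically diverging at
  the exact stagnation streamline), so the mean grows slowly with
  ensemble size, and viscosity changes act both on per-particle times
  and on *which* particles enter (higher viscosity admits fewer,
  longer-staying cells). Comparisons therefore always use identical
  seeds, and the reported quantity is the per-run mean over entrants.
* **Carina-fraction sensitivity to the region radius.** In the 2-D
  mid-plane model the approach distances follow stagnation-flow
  scaling, so the fraction grows ~quadratically with the region radius:
  ~0.1% of trajectories pass within 2 D_p of the tip, ~0.6% within the
  default 5 D_p, ~2% within 10 D_p (reference conditions). Statements
  about "the" fraction are meaningful only together with the radius,
  which the package always reports.
* **Not modelled:** pulsatility, non-Newtonian rheology (media are
  measurably shear-thinning; the Newtonian values used are those at the
  relevant shear rates), red blood cells, particle deformability, lift
  forces, Brownian motion, adhesion kinetics, 3-D secondary flows.
  `wall_contact` flags arrest candidates; actual arrest depends on
  biology outside this model's scope.
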