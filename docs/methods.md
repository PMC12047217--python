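# Methods

## Scope and intent

`reefplan` re-implements, as a reusable and tested pipeline, the spatial
prioritization workflow used for small-island marine protected areas:
habitat maps plus human-use costs feed a Marxan-style simulated-annealing
reserve selector; repeated runs give per-unit selection frequencies; the
frequencies are zoned; and protection-target scenarios are compared. No
satellite imagery is ingested and no real island geometry is reproduced:
the seascape is synthetic, with the statistical and spatial structure the
analysis assumes, so every downstream result here characterizes the
machinery, not any particular island.

## Planning units

The planning region is a rectangle in a planar metric CRS (metres, origin
at the lower-left corner), tessellated by flat-top regular hexagons of
side 15 m (area (3√3/2)·15² ≈ 584.57 m² = 0.0585 ha). A hexagon belongs to
the tessellation iff its centroid lies inside the half-open extent
(0 ≤ x < W, 0 ≤ y < H). Because rim hexagons are counted whole, the lattice
anchor is chosen by a small deterministic grid search (16 offsets per axis
plus the extent-centred offset) minimizing the difference between
tessellated and extent area; on region-scale extents the two agree to
about 0.1% and the default 544.03 ha square yields 9,308 units. Adjacency
links the six neighbours at centroid distance √3·side, each sharing an
edge of length `side`; edges on the extent boundary have no neighbour and
count as exposed.

## Synthetic seascape

The default `SeascapeSpec` encodes the study conditions of a fringing-reef
island:

* extent: a square of 544.03 ha; island: a central ellipse with semi-axes
  500 × 380 m (~60 ha of land, locked out at cost 3 as land use);
* habitats: coral reef 23.55 ha fringing the island (normalized elliptical
  shore distance ρ ∈ (1, 1.45]), seagrass 29.42 ha in the northern waters,
  mangrove 11.81 ha in a south-east shore band (ρ ∈ (1, 1.6], bearing
  −120°…30°), totalling 64.78 ha;
* cost features: a residential patch on the north-west shore (cost 3,
  lockout), a dock just offshore of it and two floating net cages in open
  water (cost 1, seed status — present in every starting solution); all
  other water costs 0. A footprint smaller than the lattice pitch claims
  its nearest planning unit, and a unit covered by both a lockout and a
  seed footprint is a configuration error reported with the offending ids.

Habitats are painted by ranking each sector's units on Gaussian-smoothed
uniform noise (length scale 80 m at full size) and filling greedily until
the target area is met; the marginal unit receives a fractional amount, so
realized totals equal their targets exactly. Habitats are exclusive within
a unit, resolved mangrove > coral > seagrass. One integer seed drives all
randomness.

On the printed hectares the key-habitat shares are 36.35% coral, 45.41%
seagrass and 18.23% mangrove; published summaries of the same composition
round the mangrove share variously (18.24%/18.41%), and the generator
targets the hectare values, not any rounded share.

What the generator does *not* emulate: real shoreline geometry, habitat
patchiness driven by bathymetry and wave exposure, mixed-habitat pixels,
and a spatially heterogeneous cost surface (costs here are exactly the
categorical 0/1/3 scores). Passing tests therefore demonstrate the
correctness and calibration behaviour of the machinery under realistic
structure, not agreement with any real island's selection outcomes, whose
unit counts, hectares and costs are map-dependent.

Geometrically similar instances at reduced area (`SeascapeSpec.scaled`,
`SeascapeSpec.test_profile` at ~1,500 units ≈ 87.7 ha) shrink linear
dimensions by √scale and areal targets by scale, preserving composition
and the island's relative footprint. The package's default working size
for demonstrations and the test suite is the ~1,500-unit profile with 50
restarts of 10⁴ proposals; the full-size instance with 1,000 restarts of
10⁶ proposals is the production configuration.

## Objective and annealer

```
total = Σ cost_i + BLM · boundary(S) + Σ_f SPF_f · max(0, (target_f − held_f)/target_f)
```

The shortfall penalty is normalized so a feature missing its target
entirely contributes exactly its SPF; this makes SPF directly comparable
to cost units (SPF ≥ 100 × the maximum unit cost guarantees targets are
met on feasible instances, a property the acceptance suite checks).
Boundary is the exposed edge length in metres: 6·side per selected unit
minus twice the shared edges inside the system.

Annealing uses single-unit flips drawn uniformly from the non-locked
units (seed units are locked in by default; `seeds_locked=False` makes
them ordinary units that merely start selected). The temperature schedule
is geometric, T_k = T₀·αᵏ with α set so the final temperature is 10⁻⁴·T₀
over the run; T₀ defaults to the 95th percentile of |Δtotal| over 1,000
probe flips from the initial system, so early moves are almost all
accepted. The best system seen anywhere in the trajectory is returned,
with ties broken toward lower total, then fewer units (and, where full
tie-breaking is needed — the exhaustive oracle and across repeated runs —
lexicographically smaller id sets). Setting `t_init=0` gives pure greedy
descent, which the tests use to verify monotone improvement.

`brute_force_optimum` enumerates all subsets of up to 20 free units and is
the exact oracle: on 100 random ≤12-unit instances the annealer must match
it in at least 95% of trials and may never beat it (best-seen tracking
makes the annealed objective an upper bound).

Repeated runs derive per-run seeds from a master seed via
`numpy.random.SeedSequence.spawn`, making the whole frequency ensemble
reproducible. Calibration follows standard practice: SPF is the smallest
grid value whose best solution meets every target; BLM is the knee of the
best-solution cost-versus-boundary curve, located as the sweep point of
maximum perpendicular distance to the chord joining the curve's endpoints.
A grid with no satisfying SPF raises a calibration error carrying the full
sweep table.

## Zoning and comparison statistics

Selection frequencies are scaled to 0–1000 (1000 × count / runs). The
printed priority bands overlap at their endpoints, so the package fixes a
half-open convention: [750, 1000] core (closed at the top), [500, 750)
utilization, [250, 500) sustainable fisheries, (0, 250) other, exactly 0
nonpriority. Zone-area tables fold nonpriority into "other" by default to
match the four-row reporting layout; the partition always sums to the
tessellated area. The overlay table intersects the core zone with the
habitat table; impact magnitude is a plain percent change against the
baseline scenario; conservation cost efficiency is SPU/CC, reported at
4 decimals (full precision retained). SPU, CC and boundary length are
taken from the best solution of each scenario's run ensemble — the
published comparisons report one value per scenario and this is the one
a Marxan "best solution" output supplies.

## Classification accuracy

The habitat-mapping stage is represented by its decision-level machinery:
`svm_decision` evaluates f(x) = Σ αᵢyᵢK(x, xᵢ) + b for linear and RBF
kernels (default γ = 1/d), with the sign rule for binary decisions and
one-vs-rest argmax voting for the three-habitat problem (ties go to the
first class in model order). Training is delegated to scikit-learn's
maximum-margin solver, whose fitted dual coefficients are extracted into
`SVMModel`; the tests cross-check `svm_decision` against the trainer's own
decision function on held-out points. Cohen's kappa is computed from the
confusion matrix (rows = reference class) as (p_o − p_e)/(1 − p_e); the
degenerate p_e = 1 case returns 1 for perfect agreement and 0 otherwise.
Synthetic segments are per-class Gaussian draws of 8 band-mean reflectance
features; with the default spectra and standardized features a one-vs-rest
fit reaches kappa ≥ 0.8 on a held-out split — the accuracy regime reported
for shallow-water habitat maps — without claiming any real map's value.

## Numerical choices and edge cases

* Float comparisons in the solver use 1e−9 absolute tolerances; objective
  decomposition (total = cost + BLM·boundary + penalty) is exact to 1e−9.
* Selection-frequency scores outside [0, 1000] and negative shortfall
  inputs are errors, not clamped.
* The dat-file writer renders floats via `repr` (lossless round trip) and
  sorts `puvspr.dat` by planning unit then feature; the reader accepts
  comma-, tab- or space-separated files and reports the file and line of
  any malformed row. Instances read from files carry absolute targets, so
  write → read → write reproduces files byte-for-byte.
* Pipeline stage seeds are the first four bytes of SHA-256 of
  `"{stage}:{master_seed}"`, keeping every stage independently
  reproducible; manifests inventory outputs by SHA-256 checksum (the JSONL
  log, which contains wall-clock timings, is deliberately excluded).

## Known limitations

* The annealer is the classic fixed-schedule variant: no adaptive
  annealing, no iterative-improvement post-processing, no zoning-aware
  (multi-zone) objective.
* The exhaustive oracle is limited to 20 free units by design.
* Hexagon areas are not clipped at the extent boundary; area bookkeeping
  treats rim units as whole, which is accurate to ~0.1% at region scale
  but biased on extents only a few hexagons wide.
* The synthetic cost surface is categorical; published cost totals in the
  tens of thousands per scenario imply a continuous, map-derived cost
  layer that is not modelled here, so absolute SPU/CC magnitudes are not
  comparable to published ones even though the efficiency arithmetic is.
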