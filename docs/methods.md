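# Methods

## Model

The access index is a hybrid of two floating-catchment traditions: the
multi-mode two-step model (population split into per-mode subpopulations,
each with its own travel times and catchment test) and the enhanced
two-step model (a continuous distance-decay weight inside each catchment).
Both steps use the Gaussian weight truncated at the catchment threshold,
and the (β, d0) pair is always the one belonging to the **demand cell's**
urban/rural class — in step 1 the facility's denominator weights each cell
with that cell's own decay, and in step 2 a cell weights the reachable
ratios with the same decay. This demand-side keying is what makes the
construction an exact redistribution of supply:

    Σ_i P_i A_i = Σ_j R_j · D_j = Σ_j S_j   (over facilities with D_j > 0),

where D_j is facility j's decay-weighted demand. The identity is tested to
1e-9 on random instances; it also underlies the package's interpretation of
city-level results (see "Behaviour" below). Catchment membership is tested
on the penalised travel time — the 15-minute minibus penalty is part of
total travel time, so a minibus trip must have base time ≤ d0 − 15 to
count.

Assumptions inherited from the study design: both modes share the road
travel times (no mode-specific speeds — only the fixed penalty separates
them); no walking legs, turn restrictions, one-way streets or congestion;
the screening-eligible population is proxied by total population; supply is
a head-count of screening professionals with no quality or preference
weighting. Variable per-facility catchments and competition (3SFCA-style)
are deliberately out of scope.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| d0 urban / rural | 40 / 90 | min | stated urban and rural travel-time budgets |
| ε (decay at d0) | 0.01 | — | operationalises "the curve approaches zero" at the threshold; β = d0²/ln(1/ε) ⇒ 347.44 / 1758.9 min² |
| minibus penalty | 15 | min | shared minibus pick-up/drop-off overhead |
| urban split | 80/20 taxi/minibus | — | stated urban mode shares |
| rural split | 20/80 taxi/minibus | — | stated rural mode shares |
| urban threshold | 20,000 | persons | settlement size that counts as urban |
| zones | 6 | — | natural-breaks classes on positive A |
| endpoint snap | 1 | m | digitisation jitter when joining segments |
| point snap | 500 | m | grid centroids are off-road by construction |

Settlements are queen-adjacency (8-neighbour) connected components of
populated cells: the permissive reading, so towns are not split across
diagonal gaps. Raising the threshold can only shrink the urban set
(monotonicity is tested).

## Numerical choices

* Unreachable OD pairs are `+inf` and decay to weight 0; a facility whose
  weighted demand is zero gets R = 0 with an `empty_catchment` flag rather
  than an error (an isolated facility is a legitimate scenario).
* Fisher–Jenks is solved exactly by dynamic programming on the sorted
  values (O(k·n²)); ties in the objective break toward the earliest split,
  so zoning is deterministic. Equal values always share a class. With fewer
  than k distinct positive values the class count degrades gracefully.
  Zone 1 is the highest-access class; zero-access cells form a seventh
  "outside" category excluded from the break optimisation.
* Shortest paths need only costs, so tie-breaking among equal-cost paths is
  irrelevant; Dijkstra results are checked against a Floyd–Warshall
  enumeration in the tests.
* Zero-length segments and segments collapsing to a point after snapping
  are rejected into the topology report, never silently dropped; parallel
  edges keep the shorter segment.
* Client→cell matching is containment in the square cell footprint, then
  nearest centroid within 2 cell sizes; unmatched clients are kept and
  reported as "outside".
* The sensitivity sweep re-zones each scenario's surface with its own
  natural breaks (each scenario is reported the way a standalone run would
  be); deltas against the baseline are therefore comparisons of
  classifications, not of a frozen zonation.

## Synthetic scenario generator

The generator emulates the *structure* of the study region, not its
geography: four cities at fixed fractional positions mirroring the real
arrangement (the second city ~42 km northeast of the first, the fourth
~44 km southeast, the third ~39 km beyond it, i.e. about 1.5 h of network
travel from the first city's services), each with a street grid whose
intersections coincide with population-cell centroids (major central axes,
residential side streets), inter-city highways along the minimum spanning
tree, radial roads continuing each city's axes outward, and rural
residential spurs with branches off each highway. City populations follow a
discretised Gaussian around the center and sum exactly to the configured
totals (largest-remainder rounding). Rural cells sit within 400 m of a
rural road (inside the 500 m snap tolerance by construction), are kept with
probability 0.55 and carry village-scale populations (600–2400), which puts
the rural share of regional population near ~26% — chosen to reflect a
predominantly rural state; the slow-road spur tails extend beyond every
catchment so an "outside" population exists. Clients are drawn urban with
probability 0.69, then proportional to cell population within the stratum,
then uniformly inside the cell.

What the generator does **not** emulate: real geography and LandScan
values, geocoding failure (about a third of real addresses could not be
geocoded; generated clients always have coordinates), land-cover masking
(accepted as a pre-applied input), and any correlation between client
status and access itself. Passing tests therefore demonstrate the
correctness and qualitative behaviour of the method, not empirical access
levels in the real region.

## Behaviour worth knowing about

Supply conservation pins a city's population-weighted mean access near
S_local/P_city, scaled down by the share of the facility's weighted demand
that comes from outside the city. That mechanism drives the qualitative
pattern the default scenario reproduces: the first city (33 of 55
professionals) tops the surface; the third city's 10 professionals over
~108k people beat the second city's 10 over ~425k; and the small fourth
city's 2 professionals, diluted further by a proportionally large rural
hinterland, put it in the bottom class. The exact class membership of the
two low-ratio cities is sensitive to the rural settlement sample (their
intrinsic ratios differ by only ~6%), which is why the replication check is
run seed-controlled at the default conditions.

## Problem sizes

Default scenario: ~1,400 road segments, ~440 populated cells, 5 facilities,
400 clients — a deliberate desk-scale stylisation of the study region
(~5,600 digitised segments, thousands of LandScan cells) that keeps a full
pipeline run under a few seconds while exercising every code path;
verification batteries use 100 random instances of ≤50 cells × ≤5
facilities and ≤20-node networks.
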