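# Methods

## Scope and model

The package disaggregates three families of biodiversity statistics to
the units of a country-based regionalization scheme: (i) species
richness, endemism and threatened-percentage bounds from Red List
assessments joined to country-coded occurrence records; (ii) each unit's
weighted annual contribution to a taxon's global Red List Index (RLI)
change; (iii) dissolved-polygon coverage statistics for important sites
(IBA/AZE) and protected areas, including a Monte Carlo trend of the
proportion of sites wholly protected when establishment dates are partly
missing.  A scheme is any table mapping ISO3 codes to (region,
subregion); subregions must partition regions, and non-country *special
units* (the high seas, "ABNJ"; IPBES's "Excluded" Antarctic unit) carry
their own occurrence records and geometries.  Transcriptions of the GEO
and IPBES schemes (206 countries each) are bundled.

## Species metrics

Occurrence and endemism are record-driven, not map-driven: a species
occurs in a unit when it has a record in a member country after removing
vagrant, uncertain-origin and introduced records, and is endemic when all
its qualifying records fall inside the unit.  Unknown origin tokens are
kept as native with a logged warning — only the three named classes are
ever excluded — and reintroduced populations count as native.  High-seas
(ABNJ) occurrence is taken from explicit ABNJ records rather than GIS
analysis, keeping the tabulation geometry-free; endemism to ABNJ is
rejected with a warning since no species in scope occurs only on the high
seas, and an ABNJ record prevents endemism to any country-based unit.

The threatened percentage of a species set is bracketed by the three DD
assumptions (none / proportionally / all threatened).  Not Evaluated
species are excluded from the assessed total; only EX is subtracted from
denominators, so EW remains in them.  Zero denominators yield
not-applicable (empty output fields), never exceptions.  Percentages are
written to one decimal; full precision is kept internally.

## RLI downscaling

Category changes are ranked on LC=0 … CR=4, with EW, EX and CR flagged
Possibly Extinct / Possibly Extinct in the Wild together at 5.  A
recorded genuine category pair decomposes into |Δrank| unit steps of
sign −sign(Δrank) (risk increase = −1), so a two-category deterioration
counts −2; DD and NE endpoints are not rankable and such changes are
excluded.  Per-unit annual contributions multiply each species' net
steps by its range fraction in the unit and divide by the assessment
period length.  Range fractions must sum to 1 per species and level
within 1e−6; deviations raise rather than being silently renormalized,
because the additivity of the decomposition (unit values summing to the
global net annual change, checked to 1e−9) depends on it.  Netting steps
per species before weighting is algebraically identical to weighting
each change separately under this linear formula.

## Coverage statistics

All geometry is planar shapely work; callers with geographic coordinates
supply an equal-area transform callable (identity by default — the
synthetic world is already equal-area).  Overlapping polygons are
dissolved before any area is measured.  Site *counts* and mean sizes
assign each site to the unit containing its representative interior
point, so a site straddling a boundary is counted exactly once
(`contains`, not `intersects`, so a representative point lying exactly
on a shared boundary — a measure-zero event — is counted nowhere rather
than twice); *percentage cover* instead uses true geometric intersection
with each unit, so straddling sites contribute area to both sides.
Consequently a region's dissolved area equals the sum over the
subregions that partition it, but per-unit site counts need not nest.
Invalid geometries get one zero-buffer/make-valid repair attempt and are
dropped with a log message on failure (or rejected outright in strict
mode).  Point-only protected-area records are excluded from coverage by
default; an optional mode replaces them by circles of their reported
area.

## Protection trend with date imputation

"Wholly covered" defaults to ≥ 98% of site area covered by the dissolved
union of active protected areas — the module's most consequential free
parameter, chosen to tolerate boundary-digitization slivers; 1.0 gives
strict containment and is configurable everywhere the statistic is
exposed.  Undated protected areas draw establishment years uniformly
with replacement from the dated protected areas of the same country and
realm when that country has at least five dated ones, else from the
realm-wide (global) pool; draws are independent across protected areas
and replicates.  Per year, the statistic is the percentage of sites
whose covering union (protected areas with year ≤ that year) meets the
threshold; the median and 2.5/97.5 empirical percentiles (linear
interpolation) across replicates form the reported trend and envelope.
Units with no sites are omitted rather than zero-filled.

Per-site overlap geometries are clipped once; per-replicate coverage is
resolved through a memoized cache of dissolved areas per active subset
of a site's overlapping protected areas.  This is an exactness-preserving
optimization: the union of cached site-clipped geometries for a subset
equals the site-clipped union of those protected areas, and replicates
only permute years, so subsets recur.

## Synthetic world

Countries are unit grid cells split into a western land half and an
eastern sea half, with a high-seas strip (ABNJ) beyond the grid; two
schemes partition the same countries into contiguous blocks so that both
a GEO-like and an IPBES-like disaggregation are exercised on one world.
Species ranges are contiguous country runs (55% single-country by
default, occasionally spilling into a far country), so most species are
single-region endemics — emulating the endemism-dominated structure the
downscaling relies on, by mechanism rather than by targeting any
particular percentage.  Categories come from a Red-List-like mixture
(54% LC, 12% DD, 23% threatened, small EX/EW mass); range fractions are
Dirichlet weights over a species' countries (plus ABNJ where present)
aggregated to units, so they sum to one per level by construction.
Genuine changes occur at rate 0.18 with 75% deteriorations and 15%
two-category moves; draws whose implied start category falls off the
ordering are skipped rather than sign-flipped, so the bias acts on the
feasible pool and the realized net change varies by seed.  Sites and
protected areas are axis-aligned rectangles; about half the protected
areas target a site (fully, with a small margin, or covering a 40–70%
slice, so some sites become wholly covered only by a union), the rest
are placed at random.  Establishment years are uniform on 1962–2012, and
14.3% of terrestrial / 8.6% of marine protected areas have their year
masked by default (rounded to nearest, always leaving at least five
dated per realm), with true years retained in the truth record.  The
default assessment period is 1988–2012, matching the multi-assessment
era of comprehensively assessed vertebrate groups.

Each component (species, occurrence noise, changes, sites, protected
areas, masking) has its own RNG stream spawned from the master seed, so
enlarging one component does not shift another's draws.  A `WorldTruth`
record is computed by direct enumeration at generation time — counting
statistics exactly, geometric percentages via direct unions — and the
test suite additionally checks the pipeline against fully independent
oracles (nested-loop tabulation; a 1000×1000 cell-centre rasterization
for dissolved areas).

What the synthetic world does **not** emulate: geodesy and real
coastlines (all areas are exact planar quantities, so the equal-area
transform is the identity), real taxonomies and biogeography, point-only
protected-area records, degazettement, and site-establishment dynamics.
Passing tests therefore demonstrate the correctness of the
disaggregation machinery, not properties of any real-world dataset.

## Problem sizes and numerical choices

Default world: 24 countries, 250 species in three groups, 42 sites, 80
protected areas, years 1962–2012, 1,000 trend replicates (the Monte
Carlo checks in the test suite use 200 replicates over 50 generator
seeds, and smaller worlds of 12–20 countries, which is ample for the
envelope-containment property being verified).  Tolerances: range
fraction sums 1e−6; RLI additivity 1e−9; rasterization agreement 1%
absolute at 1000×1000; imputation-frequency checks at 3 standard errors.
Ties and degenerate inputs: zero denominators → not-applicable; empty
unions → zero area; units without sites dropped from trend products;
identical establishment years are unioned in one step so ordering among
them is immaterial.

## Known limitations

- Shapefile input is not supported; geometries travel as GeoJSON.
- No management-category or governance breakdowns of protected areas.
- The global RLI time series itself is out of scope; the package
  computes each unit's contribution to its annual change, with range
  fractions supplied as inputs.
- The realm-wide imputation fallback pool is global per realm, not
  per region.
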