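# biodisagg

Regional disaggregation of global biodiversity indicators.

Regional environmental assessments (the UNEP Global Environment Outlook
and the IPBES regional assessments) need globally consistent biodiversity
statistics broken down by their own region and subregion schemes, which
group countries by policy relevance rather than biogeography.  This
package implements the disaggregation machinery that turns three kinds of
global inputs — species extinction-risk assessments with country-coded
occurrences, important-site polygons (Important Bird & Biodiversity
Areas, Alliance for Zero Extinction sites), and protected-area polygons
with establishment years — into per-unit summary tables, for any
country→(region, subregion) scheme.  Transcriptions of the GEO and IPBES
regionalizations ship with the package, and a synthetic-world generator
provides fully ground-truthed inputs at desk scale.

## What it computes

**Species richness, endemism and threatened fractions.**  A species
*occurs* in a unit if it has a qualifying occurrence record (vagrant,
uncertain-origin and introduced records excluded) in at least one member
country; it is *endemic* if its qualifying occurrences fall entirely
inside the unit.  Per (unit × taxonomic group), Red List category counts
are tabulated and the percentage threatened (CR+EN+VU) is reported as a
best estimate bracketed by bounds that resolve the Data Deficient (DD)
ambiguity:

```
lower = 100 (CR+EN+VU)    / (assessed − EX)        all DD non-threatened
best  = 100 (CR+EN+VU)    / (assessed − EX − DD)   DD threatened like the rest
upper = 100 (CR+EN+VU+DD) / (assessed − EX)        all DD threatened
```

**Downscaled Red List Index change.**  Each unit's weighted annual
contribution to a taxon's global Red List Index trend is

```
value(u) = [ Σ_s  net_steps(s) · fraction(s, u) ] / years
```

where `net_steps(s)` sums a species' genuine single-category moves (−1
per move of increasing extinction risk, +1 per decreasing move, on the
ordering LC < NT < VU < EN < CR < {EW, EX, CR Possibly Extinct}) and
`fraction(s, u)` is the share of its range inside the unit.  Because
fractions sum to 1 per species, the unit values partition the global
annual change exactly.

**Dissolved coverage.**  Counts, mean sizes and percentage coverage of
IBA and AZE site layers per unit, and the percentage of each unit's land
and sea covered by terrestrial and marine protected areas, all measured
after dissolving (unioning) overlapping polygons so overlap is never
double-counted.

**Protection trends under missing dates.**  The per-year percentage of
sites wholly covered (≥ 98% of site area by default) by protected areas
established by that year.  Protected areas with unknown establishment
years draw a year at random from the dated protected areas of the same
country and realm (realm-wide pool when the country has fewer than five
dated ones); repeating this for many replicates yields a median trend
with a 95% confidence envelope.

## Worked example

```
$ biodisagg synthesize --out demo/world --seed 7
world written to demo/world (seed=7)

$ biodisagg run-all --world-dir demo/world --out demo/products --n-reps 200 --seed 7
wrote 14 product files to demo/products
```

Fourteen CSVs are written — seven products for each of the two generated
schemes, named `<Product>_<SCHEME>.csv` (Total_Species, Endemic_Species,
Red_List_Index, IBAs_AZEs, PAs, Protected_IBAs, Protected_AZEs).  The
species table starts:

```
# tool=biodisagg 0.1.0 seed=7 threshold=0.98 n_reps=200
unit,level,group,EX,EW,CR,EN,VU,NT,LC,DD,NE,total,pct_lower,pct_best,pct_upper
GEO-Region-1,region,all,0,2,0,4,9,3,26,12,0,56,23.2,29.5,44.6
GEO-Region-1,region,mammals,0,1,0,2,3,1,10,3,0,20,25.0,29.4,40.0
```

Read: 56 species of all groups occur in GEO-Region-1; with 12 of them
Data Deficient the percentage threatened is 29.5% (bounds 23.2–44.6%).
The trend product gives one row per unit and year:

```
unit,level,year,median_pct,ci_low,ci_high
GEO-Region-1,region,1962,0.0,0.0,0.0
...
GEO-Sub-4.2,subregion,2012,50.0,50.0,50.0
```

i.e. by 2012 half of that subregion's IBAs are wholly covered by
protected areas, with a degenerate envelope where no undated protected
area can change the answer.  Repeating `run-all` with the same seed
reproduces every file byte-for-byte.

Real data can be substituted for any synthetic input: schemes as CSV
(`country_name,iso3,region,subregion`), assessments and occurrences as
CSV, sites/protected areas/unit land-sea splits as GeoJSON (see
`biodisagg.io` for the exact attribute names).  Geometries should be in
an equal-area projection, or an equal-area transform callable can be
passed to the coverage functions.

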