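"""Self-contained synthetic world with recorded ground truth.

The generator lays countries out as square grid cells on a plane, each
split into a land half (west) and a sea half (east), with one extra
high-seas strip ("ABNJ") east of the grid.  Two regionalization schemes
partition the same countries into contiguous region/subregion blocks, so
the same downstream machinery that disaggregates real indicators by GEO
and IPBES units can be exercised against both.  Species are assigned
contiguous country ranges (most are single-country or single-region
endemics), Red List categories from a configurable mixture, genuine and
non-genuine category-change histories, and range fractions that sum to
one over each level's units.  Sites (IBA/AZE) and protected areas are
axis-aligned rectangles with controlled overlap; a configurable fraction
of protected areas per realm has its establishment year masked, with the
true year retained in the truth record.

Every downstream statistic is recorded in a :class:`WorldTruth` computed
by direct enumeration during generation, so pipeline outputs can be
compared against generation-time bookkeeping.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union

from .coverage import ProtectedAreaRecord, SiteRecord, UnitGeometry
from .regions import RegionScheme, SchemeEntry, UnitLevel
from .rli import AssessmentPeriod
from .species import ASSESSED_CATEGORIES, CATEGORIES, THREATENED
from .trends import DEFAULT_THRESHOLD

__all__ = ["WorldSpec", "World", "WorldTruth", "generate_world", "mask_pa_years"]

_RANK_TO_CAT = ["LC", "NT", "VU", "EN", "CR", "EX"]
_CAT_TO_RANK = {"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4, "EW": 5, "EX": 5}


class WorldSpecError(ValueError):
    """The requested world is infeasible (e.g. more subregions than countries)."""


@dataclass
class WorldSpec:
    """Study conditions for one synthetic world.

    Defaults give a desk-scale world whose statistical structure mirrors
    the global datasets the pipeline is designed for: several
    comprehensively assessed taxonomic groups with a realistic category
    mixture including a sizeable Data Deficient share, ranges spanning
    one to a handful of countries with endemism dominating, signed
    genuine category changes biased towards deterioration, overlapping
    site and protected-area polygons, and undated protected-area
    fractions of 14.3% (terrestrial) / 8.6% (marine).
    """

    n_countries: int = 24
    cell_size: float = 10.0
    #: scheme name -> (n_regions, n_subregions_per_region)
    schemes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"GEO": (4, 2), "IPBES": (3, 2)}
    )
    species_per_group: dict[str, int] = field(
        default_factory=lambda: {"mammals": 80, "birds": 100, "amphibians": 70}
    )
    category_mix: dict[str, float] = field(
        default_factory=lambda: {
            "EX": 0.02,
            "EW": 0.01,
            "CR": 0.05,
            "EN": 0.08,
            "VU": 0.10,
            "NT": 0.08,
            "DD": 0.12,
            "LC": 0.54,
        }
    )
    pe_flag_prob: float = 0.10  # P(PE | CR)
    pew_flag_prob: float = 0.05  # P(PEW | CR)
    endemism_prob: float = 0.55  # single-country ranges
    mean_countries_per_range: float = 3.0
    region_spillover_prob: float = 0.12
    abnj_prob: float = 0.04
    vagrant_rate: float = 0.05
    introduced_rate: float = 0.04
    uncertain_rate: float = 0.03
    change_rate: float = 0.18
    two_step_prob: float = 0.15
    deterioration_prob: float = 0.75
    nongenuine_rate: float = 0.05
    period: tuple[int, int] = (1988, 2012)
    n_sites: dict[str, int] = field(default_factory=lambda: {"IBA": 30, "AZE": 12})
    marine_site_fraction: float = 0.2
    n_pas: int = 80
    pa_site_targeting_prob: float = 0.55
    pa_full_cover_prob: float = 0.45
    pa_year_range: tuple[int, int] = (1962, 2012)
    undated_fraction: dict[str, float] = field(
        default_factory=lambda: {"terrestrial": 0.143, "marine": 0.086}
    )
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    def validate(self) -> None:
        for name, (nr, ns) in self.schemes.items():
            if nr * ns > self.n_countries:
                raise WorldSpecError(
                    f"scheme {name!r}: {nr} regions x {ns} subregions exceed "
                    f"{self.n_countries} countries"
                )
        tot = sum(self.category_mix.values())
        if abs(tot - 1.0) > 1e-9:
            raise WorldSpecError(f"category mixture sums to {tot}, not 1")
        for f in self.undated_fraction.values():
            if not (0.0 <= f < 1.0):
                raise WorldSpecError("undated fraction must be in [0, 1)")
        if self.period[1] <= self.period[0]:
            raise WorldSpecError("assessment period must have positive span")


@dataclass
class WorldTruth:
    """Generation-time bookkeeping for every downstream statistic."""

    #: (scheme, level, mode) -> table shaped like species tabulation output
    species_tables: dict[tuple[str, str, str], pd.DataFrame]
    #: scheme -> (unit, level, taxon, weighted_annual_change)
    rli: dict[str, pd.DataFrame]
    #: scheme -> (unit, level, site_type, n, mean_size_km2, pct_cover)
    site_stats: dict[str, pd.DataFrame]
    #: scheme -> (unit, level, pct_land, pct_sea)
    pa_stats: dict[str, pd.DataFrame]
    #: pa_id -> true establishment year (before masking)
    true_years: dict[str, int]
    #: scheme -> (unit, level, site_type, year, pct) using true years
    trend_true: dict[str, pd.DataFrame]
    #: species_id -> net signed genuine steps
    net_steps: pd.Series


@dataclass
class World:
    spec: WorldSpec
    schemes: dict[str, RegionScheme]
    assessments: pd.DataFrame
    occurrences: pd.DataFrame
    changes: pd.DataFrame
    events: pd.DataFrame
    range_fractions: pd.DataFrame
    sites: list[SiteRecord]
    pas: list[ProtectedAreaRecord]
    unit_geometries: dict[str, dict[str, UnitGeometry]]
    period: AssessmentPeriod
    truth: WorldTruth | None = None

    @property
    def years(self) -> list[int]:
        return list(range(self.spec.pa_year_range[0], self.spec.pa_year_range[1] + 1))


# ---------------------------------------------------------------------------
# layout helpers


def _country_codes(n: int) -> list[str]:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    codes = []
    for combo in itertools.product(letters, repeat=3):
        codes.append("".join(combo))
        if len(codes) == n:
            return codes
    raise WorldSpecError("too many countries")


def _grid_shape(n: int) -> tuple[int, int]:
    cols = math.ceil(math.sqrt(n))
    rows = math.ceil(n / cols)
    return cols, rows


def _partition(items: list[str], n_blocks: int) -> list[list[str]]:
    return [list(b) for b in np.array_split(np.array(items), n_blocks)]


def _build_scheme(
    name: str, codes: list[str], n_regions: int, n_sub: int
) -> RegionScheme:
    entries = []
    for ri, block in enumerate(_partition(codes, n_regions), start=1):
        region = f"{name}-Region-{ri}"
        for si, sub in enumerate(_partition(block, n_sub), start=1):
            label = f"{name}-Sub-{ri}.{si}"
            for code in sub:
                entries.append(SchemeEntry(f"Country {code}", code, region, label))
    return RegionScheme(name=name, entries=entries, special_units=["ABNJ"])


# ---------------------------------------------------------------------------
# generation


def generate_world(spec: WorldSpec | None = None, compute_truth: bool = True) -> World:
    """Generate all pipeline inputs plus (optionally) the truth record."""
    spec = spec or WorldSpec()
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_species, rng_noise, rng_changes, rng_sites, rng_pas, rng_mask = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    codes = _country_codes(spec.n_countries)
    cols, _rows = _grid_shape(spec.n_countries)
    cell = spec.cell_size
    land: dict[str, object] = {}
    sea: dict[str, object] = {}
    for i, code in enumerate(codes):
        x0, y0 = (i % cols) * cell, (i // cols) * cell
        land[code] = box(x0, y0, x0 + cell / 2, y0 + cell)
        sea[code] = box(x0 + cell / 2, y0, x0 + cell, y0 + cell)
    n_grid_rows = math.ceil(spec.n_countries / cols)
    abnj_geom = box(cols * cell, 0, (cols + 1) * cell, n_grid_rows * cell)

    schemes = {
        name: _build_scheme(name, codes, nr, ns)
        for name, (nr, ns) in spec.schemes.items()
    }

    # ---- species, categories, occurrences --------------------------------
    cats = list(spec.category_mix)
    cat_p = np.array([spec.category_mix[c] for c in cats])
    species_rows, occ_rows = [], []
    ranges: dict[str, list[str]] = {}
    has_abnj: dict[str, bool] = {}
    weights: dict[str, np.ndarray] = {}
    sp_idx = 0
    for group, n_sp in spec.species_per_group.items():
        for _ in range(n_sp):
            sid = f"sp{sp_idx:04d}"
            sp_idx += 1
            if rng_species.random() < spec.endemism_prob:
                k = 1
            else:
                k = 2 + int(rng_species.poisson(max(spec.mean_countries_per_range - 2, 0.0)))
            start = int(rng_species.integers(spec.n_countries))
            rng_countries = [codes[j] for j in range(start, min(start + k, spec.n_countries))]
            if rng_species.random() < spec.region_spillover_prob and k > 1:
                far = codes[int(rng_species.integers(spec.n_countries))]
                if far not in rng_countries:
                    rng_countries[-1] = far
            rng_countries = list(dict.fromkeys(rng_countries))
            abnj = rng_species.random() < spec.abnj_prob
            cat = cats[int(rng_species.choice(len(cats), p=cat_p))]
            flag = "none"
            if cat == "CR":
                u = rng_species.random()
                if u < spec.pe_flag_prob:
                    flag = "PE"
                elif u < spec.pe_flag_prob + spec.pew_flag_prob:
                    flag = "PEW"
            species_rows.append((sid, group, cat, flag))
            ranges[sid] = rng_countries
            has_abnj[sid] = abnj
            n_units = len(rng_countries) + (1 if abnj else 0)
            weights[sid] = rng_species.dirichlet(np.ones(n_units))
            for c in rng_countries:
                occ_rows.append((sid, c, "native"))
            if abnj:
                occ_rows.append((sid, "ABNJ", "native"))
            # noise records in the three excluded origin classes
            for rate, origin in (
                (spec.vagrant_rate, "vagrant"),
                (spec.introduced_rate, "introduced"),
                (spec.uncertain_rate, "uncertain"),
            ):
                if rng_noise.random() < rate:
                    other = codes[int(rng_noise.integers(spec.n_countries))]
                    if other not in rng_countries:
                        occ_rows.append((sid, other, origin))
    assessments = pd.DataFrame(
        species_rows, columns=["species_id", "group", "category", "flag"]
    )
    occurrences = pd.DataFrame(occ_rows, columns=["species_id", "unit_code", "origin"])

    # ---- range fractions over units, per scheme and level ----------------
    frac_rows = []
    for sid, countries in ranges.items():
        w = weights[sid]
        labels = countries + (["ABNJ"] if has_abnj[sid] else [])
        for sname, scheme in schemes.items():
            for level in UnitLevel:
                agg: dict[str, float] = {}
                for lab, wt in zip(labels, w):
                    unit = lab if lab == "ABNJ" else scheme.unit_of(lab, level)
                    agg[unit] = agg.get(unit, 0.0) + float(wt)
                for unit, f in agg.items():
                    frac_rows.append((sname, level.value, sid, unit, f))
    range_fractions = pd.DataFrame(
        frac_rows, columns=["scheme", "level", "species_id", "unit", "fraction"]
    )

    # ---- genuine and non-genuine category-change histories ---------------
    change_rows = []
    net_steps: dict[str, int] = {}
    flags = assessments.set_index("species_id")["flag"]
    for sid, cat in assessments.set_index("species_id")["category"].items():
        if cat in ("DD", "NE"):
            continue
        flag = flags[sid]
        end_rank = 5 if flag in ("PE", "PEW") else _CAT_TO_RANK[cat]
        if rng_changes.random() < spec.change_rate:
            steps = 2 if rng_changes.random() < spec.two_step_prob else 1
            sign = -1 if rng_changes.random() < spec.deterioration_prob else 1
            # deteriorating history ends higher on the risk ordering:
            # start = end - steps; infeasible draws are skipped, not
            # flipped, so the sign bias acts on the feasible pool only
            start_rank = end_rank - steps if sign == -1 else end_rank + steps
            if 0 <= start_rank <= 5:
                cat_start = _RANK_TO_CAT[start_rank]
                cat_end = cat  # rank(cat, flag) == end_rank by construction
                change_rows.append(
                    (sid, cat_start, cat_end, "none", flag, True)
                )
                net_steps[sid] = sign * steps
        elif rng_changes.random() < spec.nongenuine_rate:
            r0 = int(rng_changes.integers(6))
            r1 = int(rng_changes.integers(6))
            change_rows.append(
                (sid, _RANK_TO_CAT[r0], _RANK_TO_CAT[r1], "none", "none", False)
            )
    changes = pd.DataFrame(
        change_rows,
        columns=["species_id", "cat_start", "cat_end", "flag_start", "flag_end", "genuine"],
    )
    ev_rows = [
        (sid, int(np.sign(n)))
        for sid, n in net_steps.items()
        for _ in range(abs(n))
    ]
    events = pd.DataFrame(ev_rows, columns=["species_id", "step"])
    net_series = pd.Series(net_steps, dtype=int, name="net_steps")

    # ---- sites ------------------------------------------------------------
    sites: list[SiteRecord] = []
    site_country: dict[str, str] = {}
    for stype, n in spec.n_sites.items():
        for i in range(n):
            realm = "marine" if rng_sites.random() < spec.marine_site_fraction else "terrestrial"
            c = codes[int(rng_sites.integers(spec.n_countries))]
            half = sea[c] if realm == "marine" else land[c]
            geom = _random_rect(half, rng_sites, min_frac=0.12, max_frac=0.4)
            sid = f"{stype}-{i + 1:03d}"
            sites.append(SiteRecord(sid, stype, geom, realm))
            site_country[sid] = c

    # ---- protected areas ---------------------------------------------------
    pas: list[ProtectedAreaRecord] = []
    true_years: dict[str, int] = {}
    y0, y1 = spec.pa_year_range
    for i in range(spec.n_pas):
        pa_id = f"PA-{i + 1:04d}"
        year = int(rng_pas.integers(y0, y1 + 1))
        if sites and rng_pas.random() < spec.pa_site_targeting_prob:
            target = sites[int(rng_pas.integers(len(sites)))]
            c = site_country[target.site_id]
            realm = target.realm
            half = sea[c] if realm == "marine" else land[c]
            if rng_pas.random() < spec.pa_full_cover_prob:
                geom = target.geometry.buffer(0.05 * spec.cell_size, join_style="mitre")
                geom = geom.intersection(half)
            else:
                geom = _partial_cover(target.geometry, rng_pas)
        else:
            c = codes[int(rng_pas.integers(spec.n_countries))]
            realm = "marine" if rng_pas.random() < 0.25 else "terrestrial"
            half = sea[c] if realm == "marine" else land[c]
            geom = _random_rect(half, rng_pas, min_frac=0.1, max_frac=0.5)
        pas.append(ProtectedAreaRecord(pa_id, c, realm, geom, year))
        true_years[pa_id] = year

    pas = mask_pa_years(pas, spec.undated_fraction, rng_mask)

    # ---- unit geometries ---------------------------------------------------
    unit_geometries: dict[str, dict[str, UnitGeometry]] = {}
    for sname, scheme in schemes.items():
        geoms: dict[str, UnitGeometry] = {}
        for level in UnitLevel:
            for unit in scheme.units(level, include_special=False):
                members = scheme.members(unit, level)
                geoms[unit] = UnitGeometry(
                    unit,
                    land=unary_union([land[c] for c in members]),
                    sea=unary_union([sea[c] for c in members]),
                )
        geoms["ABNJ"] = UnitGeometry("ABNJ", land=None, sea=abnj_geom)
        unit_geometries[sname] = geoms

    period = AssessmentPeriod(*spec.period)
    world = World(
        spec=spec,
        schemes=schemes,
        assessments=assessments,
        occurrences=occurrences,
        changes=changes,
        events=events,
        range_fractions=range_fractions,
        sites=sites,
        pas=pas,
        unit_geometries=unit_geometries,
        period=period,
    )
    if compute_truth:
        world.truth = _compute_truth(
            world, ranges, has_abnj, net_series, site_country, true_years
        )
    return world


def _random_rect(half, rng: np.random.Generator, min_frac: float, max_frac: float):
    x0, y0, x1, y1 = half.bounds
    w = (x1 - x0) * rng.uniform(min_frac, max_frac)
    h = (y1 - y0) * rng.uniform(min_frac, max_frac)
    px = rng.uniform(x0, x1 - w)
    py = rng.uniform(y0, y1 - h)
    return box(px, py, px + w, py + h)


def _partial_cover(site_geom, rng: np.random.Generator):
    """Rectangle covering a random 40-70% slice of a site's bounds."""
    x0, y0, x1, y1 = site_geom.bounds
    frac = rng.uniform(0.4, 0.7)
    side = int(rng.integers(4))
    if side == 0:
        return box(x0, y0, x0 + (x1 - x0) * frac, y1)
    if side == 1:
        return box(x1 - (x1 - x0) * frac, y0, x1, y1)
    if side == 2:
        return box(x0, y0, x1, y0 + (y1 - y0) * frac)
    return box(x0, y1 - (y1 - y0) * frac, x1, y1)


def mask_pa_years(
    pas: list[ProtectedAreaRecord],
    undated_fraction: dict[str, float],
    rng: np.random.Generator,
) -> list[ProtectedAreaRecord]:
    """Remove establishment years from the stated per-realm fraction.

    The masked count is rounded to nearest, capped so at least five dated
    protected areas remain per realm (the country-pool rule needs a
    populated realm-wide fallback pool).
    """
    out = list(pas)
    for realm, frac in undated_fraction.items():
        if frac == 0.0:
            continue
        idx = [i for i, p in enumerate(out) if p.realm == realm]
        n = len(idx)
        desired = round(frac * n)
        cap = max(n - 5, 0)
        n_mask = min(desired, cap)
        if desired > 0 and cap == 0:
            raise WorldSpecError(
                f"cannot mask any of {n} {realm} protected areas while "
                "leaving 5 dated ones"
            )
        chosen = rng.choice(len(idx), size=n_mask, replace=False) if n_mask else []
        for j in chosen:
            p = out[idx[int(j)]]
            out[idx[int(j)]] = ProtectedAreaRecord(
                p.pa_id, p.country_code, p.realm, p.geometry, None, p.reported_area
            )
    return out


# ---------------------------------------------------------------------------
# truth bookkeeping (direct enumeration, no calls into the analysis modules)


def _compute_truth(
    world: World,
    ranges: dict[str, list[str]],
    has_abnj: dict[str, bool],
    net_steps: pd.Series,
    site_country: dict[str, str],
    true_years: dict[str, int],
) -> WorldTruth:
    spec = world.spec
    groups = list(spec.species_per_group)
    cat_of = world.assessments.set_index("species_id")["category"].to_dict()
    group_of = world.assessments.set_index("species_id")["group"].to_dict()
    occ_units: dict[str, set[str]] = {
        sid: set(r) | ({"ABNJ"} if has_abnj[sid] else set())
        for sid, r in ranges.items()
    }

    species_tables: dict[tuple[str, str, str], pd.DataFrame] = {}
    rli_tabs: dict[str, pd.DataFrame] = {}
    for sname, scheme in world.schemes.items():
        for level in UnitLevel:
            member_sets = {
                u: (
                    {"ABNJ"}
                    if u in scheme.special_units
                    else set(scheme.members(u, level))
                )
                for u in scheme.units(level)
            }
            for mode in ("occurring", "endemic"):
                rows = []
                for unit, members in member_sets.items():
                    if mode == "occurring":
                        chosen = {
                            s for s, units in occ_units.items() if units & members
                        }
                    else:
                        chosen = {
                            s
                            for s, units in occ_units.items()
                            if units and units <= members
                        }
                        if unit == "ABNJ":
                            chosen = set()
                    for g in ["all", *groups]:
                        sub = (
                            chosen
                            if g == "all"
                            else {s for s in chosen if group_of[s] == g}
                        )
                        counts = {c: 0 for c in CATEGORIES}
                        for s in sub:
                            counts[cat_of[s]] += 1
                        assessed = sum(counts[c] for c in ASSESSED_CATEGORIES)
                        thr = sum(counts[c] for c in THREATENED)
                        dd, ex = counts["DD"], counts["EX"]
                        rows.append(
                            {
                                "unit": unit,
                                "level": level.value,
                                "group": g,
                                **counts,
                                "total": assessed,
                                "pct_lower": 100 * thr / (assessed - ex)
                                if assessed - ex > 0
                                else None,
                                "pct_best": 100 * thr / (assessed - ex - dd)
                                if assessed - ex - dd > 0
                                else None,
                                "pct_upper": 100 * (thr + dd) / (assessed - ex)
                                if assessed - ex > 0
                                else None,
                            }
                        )
                species_tables[(sname, level.value, mode)] = pd.DataFrame(rows)

        # RLI truth: net steps x fractions / years
        frac = world.range_fractions[world.range_fractions["scheme"] == sname]
        rows = []
        for level in UnitLevel:
            fl = frac[frac["level"] == level.value]
            for g in ["all", *groups]:
                per_unit: dict[str, float] = {u: 0.0 for u in scheme.units(level)}
                for sid, n in net_steps.items():
                    if g != "all" and group_of[sid] != g:
                        continue
                    for _, r in fl[fl["species_id"] == sid].iterrows():
                        per_unit[r["unit"]] += n * r["fraction"]
                for u, v in per_unit.items():
                    rows.append(
                        {
                            "unit": u,
                            "level": level.value,
                            "taxon": g,
                            "weighted_annual_change": v / world.period.years,
                        }
                    )
        rli_tabs[sname] = pd.DataFrame(rows)

    # ---- geometry truth ----------------------------------------------------
    site_stats: dict[str, pd.DataFrame] = {}
    pa_stats: dict[str, pd.DataFrame] = {}
    trend_true: dict[str, pd.DataFrame] = {}
    years = world.years
    for sname, scheme in world.schemes.items():
        geoms = world.unit_geometries[sname]
        srows, prows, trows = [], [], []
        for level in UnitLevel:
            for unit in scheme.units(level):
                ug = geoms[unit]
                total = ug.total
                members = (
                    {"ABNJ"} if unit in scheme.special_units
                    else set(scheme.members(unit, level))
                )
                for stype in ("IBA", "AZE"):
                    insite = [
                        s
                        for s in world.sites
                        if s.site_type == stype and site_country[s.site_id] in members
                    ]
                    n = len(insite)
                    mean_size = sum(s.geometry.area for s in insite) / n if n else None
                    clipped = [
                        s.geometry.intersection(total)
                        for s in world.sites
                        if s.site_type == stype
                    ]
                    merged = unary_union([g for g in clipped if not g.is_empty])
                    pct = 100.0 * merged.area / total.area
                    srows.append(
                        {
                            "unit": unit,
                            "level": level.value,
                            "site_type": stype,
                            "n": n,
                            "mean_size_km2": mean_size,
                            "pct_cover": pct,
                        }
                    )
                    # trend truth with true years, per unit x site type
                    if n:
                        cover_years = [
                            _true_cover_year(s, world.pas, true_years, spec.threshold)
                            for s in insite
                        ]
                        for y in years:
                            pct_y = (
                                100.0
                                * sum(1 for cy in cover_years if cy is not None and cy <= y)
                                / n
                            )
                            trows.append(
                                {
                                    "unit": unit,
                                    "level": level.value,
                                    "site_type": stype,
                                    "year": y,
                                    "pct": pct_y,
                                }
                            )
                pl, ps = _true_pa_pct(world.pas, ug)
                prows.append(
                    {"unit": unit, "level": level.value, "pct_land": pl, "pct_sea": ps}
                )
        site_stats[sname] = pd.DataFrame(srows)
        pa_stats[sname] = pd.DataFrame(prows)
        trend_true[sname] = pd.DataFrame(trows)

    return WorldTruth(
        species_tables=species_tables,
        rli=rli_tabs,
        site_stats=site_stats,
        pa_stats=pa_stats,
        true_years=true_years,
        trend_true=trend_true,
        net_steps=net_steps,
    )


def _true_cover_year(site, pas, true_years, threshold) -> int | None:
    hits = [
        (true_years[p.pa_id], p.geometry)
        for p in pas
        if p.geometry is not None and p.geometry.intersects(site.geometry)
    ]
    hits.sort(key=lambda t: t[0])
    acc = None
    for year, g in hits:
        acc = g if acc is None else unary_union([acc, g])
        if acc.intersection(site.geometry).area / site.geometry.area >= threshold:
            return year
    return None


def _true_pa_pct(pas, ug: UnitGeometry) -> tuple[float | None, float | None]:
    out = []
    for realm, base in (("terrestrial", ug.land), ("marine", ug.sea)):
        if base is None or base.is_empty:
            out.append(None)
            continue
        geoms = [p.geometry for p in pas if p.realm == realm and p.geometry is not None]
        merged = unary_union(geoms) if geoms else None
        pct = 0.0 if merged is None else 100.0 * merged.intersection(base).area / base.area
        out.append(pct)
    return out[0], out[1]
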