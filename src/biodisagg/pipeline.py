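"""End-to-end product assembly over a loaded world bundle.

Glues the per-module tabulations into the seven per-scheme product
tables (species totals, endemics, downscaled Red List Index, site
coverage, protected-area coverage, and the two protection-trend series).
"""

from __future__ import annotations

import pandas as pd

from .coverage import tabulate_pa_coverage, tabulate_site_coverage
from .regions import RegionScheme, UnitLevel
from .rli import events_from_category_pair, tabulate_rli
from .species import tabulate_units
from .trends import DEFAULT_THRESHOLD, tabulate_trends

__all__ = ["decompose_changes", "compute_products"]


def decompose_changes(changes: pd.DataFrame) -> pd.DataFrame:
    """Expand recorded category pairs into signed single-step events."""
    rows = []
    for _, r in changes.iterrows():
        f0 = r.get("flag_start")
        f1 = r.get("flag_end")
        f0 = None if pd.isna(f0) or f0 in ("", "none") else f0
        f1 = None if pd.isna(f1) or f1 in ("", "none") else f1
        for ev in events_from_category_pair(
            r["cat_start"], r["cat_end"], bool(r["genuine"]), f0, f1, r["species_id"]
        ):
            rows.append({"species_id": ev.species_id, "step": ev.step})
    return pd.DataFrame(rows, columns=["species_id", "step"])


def _units_by_level(scheme: RegionScheme) -> dict[str, list[str]]:
    return {lvl.value: scheme.units(lvl) for lvl in UnitLevel}


def compute_products(
    bundle,
    n_reps: int = 1000,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """All product tables, keyed by output file stem."""
    events = decompose_changes(bundle.changes)
    groups_map = bundle.assessments.set_index("species_id")["group"]
    out: dict[str, pd.DataFrame] = {}
    for sname, scheme in bundle.schemes.items():
        ubl = _units_by_level(scheme)
        for mode, product in (("occurring", "Total_Species"), ("endemic", "Endemic_Species")):
            parts = [
                tabulate_units(
                    scheme, lvl, bundle.assessments, bundle.occurrences, mode
                )
                for lvl in UnitLevel
            ]
            out[f"{product}_{sname}"] = pd.concat(parts, ignore_index=True)

        frac = bundle.range_fractions[bundle.range_fractions["scheme"] == sname]
        out[f"Red_List_Index_{sname}"] = tabulate_rli(
            events, frac, bundle.period, scheme, groups=groups_map
        )

        geoms = bundle.unit_geometries[sname]
        out[f"IBAs_AZEs_{sname}"] = tabulate_site_coverage(bundle.sites, geoms, ubl)
        out[f"PAs_{sname}"] = tabulate_pa_coverage(bundle.pas, geoms, ubl)

        trend = tabulate_trends(
            bundle.sites, bundle.pas, geoms, ubl, bundle.years,
            n_reps=n_reps, threshold=threshold, seed=seed,
        )
        cols = ["unit", "level", "year", "median_pct", "ci_low", "ci_high"]
        for stype, product in (("IBA", "Protected_IBAs"), ("AZE", "Protected_AZEs")):
            sub = trend[trend["site_type"] == stype]
            sub = sub.sort_values(["level", "unit", "year"]).reset_index(drop=True)
            out[f"{product}_{sname}"] = sub[cols] if len(sub) else pd.DataFrame(columns=cols)
    return out
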