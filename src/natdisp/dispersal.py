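"""From identified birds to natal-dispersal records.

A dispersal record links a bird's natal nest to the nest of its first
documented breeding attempt with egg-laying: the natal dispersal
distance (NDD) is the great-circle distance between the two nests, the
bearing the initial compass direction of the movement. Local densities
at both nests are looked up in the *expected year of recruitment* — the
first observed breeding year for birds first seen breeding at 4 cy or
younger, otherwise the first year the bird was at least 4 cy old, the
territory existed and it was not known to be occupied by another bird
of the same sex. (Ages are in calendar years, cy: the hatch year is
1 cy.)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .geo import great_circle_distance, initial_bearing

logger = logging.getLogger(__name__)

MIN_BREEDING_AGE_CY = 3  # earliest recorded breeding age in the species
DEFAULT_RECRUIT_AGE_CY = 4  # median age at first breeding (GPS-tracked birds)


@dataclass(frozen=True)
class NatalPeriods:
    """Natal-year windows of the two demographic phases.

    The models use a narrower growth window than the direction analysis,
    mirroring the cohorts available to each.
    """

    stagnation: Tuple[int, int] = (2012, 2014)
    growth: Tuple[int, int] = (2015, 2018)
    growth_direction: Tuple[int, int] = (2015, 2020)

    def classify(self, natal_year: int) -> Optional[str]:
        if self.stagnation[0] <= natal_year <= self.stagnation[1]:
            return "stagnation"
        if self.growth[0] <= natal_year <= self.growth[1]:
            return "growth"
        return None

    def classify_direction(self, natal_year: int) -> Optional[str]:
        if self.stagnation[0] <= natal_year <= self.stagnation[1]:
            return "stagnation"
        if self.growth_direction[0] <= natal_year <= self.growth_direction[1]:
            return "growth"
        return None


def filter_breeding_encounters(encounters: pd.DataFrame, nests: pd.DataFrame,
                               return_rejected: bool = False):
    """Retain encounters that document an actual breeding attempt.

    Four criteria, all required: the bird is at least 3 cy old; the
    encounter is assigned to a nesting territory known (active) in that
    year; breeding status was confirmed by observation; and egg-laying
    occurred there that year. The earliest retained event per bird is
    its first detected breeding.
    """
    known = set(zip(nests["territory_id"].astype(str), nests["year"].astype(int)))
    enc = encounters.copy()
    reasons = []
    for row in enc.itertuples(index=False):
        terr = None if pd.isna(row.assigned_territory) else str(row.assigned_territory)
        if int(row.age_cy) < MIN_BREEDING_AGE_CY:
            reasons.append("underage")
        elif terr is None:
            reasons.append("no_territory")
        elif (terr, int(row.year)) not in known:
            reasons.append("unknown_territory")
        elif not bool(row.breeding_confirmed):
            reasons.append("breeding_unconfirmed")
        elif not bool(row.egg_laying):
            reasons.append("no_egg_laying")
        else:
            reasons.append(None)
    enc["reject_reason"] = reasons
    valid = enc[enc["reject_reason"].isna()].drop(columns="reject_reason")
    if return_rejected:
        return valid, enc[enc["reject_reason"].notna()]
    return valid


def first_breeding_events(valid_encounters: pd.DataFrame) -> pd.DataFrame:
    """Earliest valid breeding event per bird (bird_id, territory, year, method)."""
    if len(valid_encounters) == 0:
        return pd.DataFrame(columns=["bird_id", "breeding_territory",
                                     "first_breeding_year", "method"])
    enc = valid_encounters.sort_values(["bird_id", "year"])
    first = enc.groupby("bird_id", as_index=False).first()
    out = first[["bird_id", "assigned_territory", "year"]].rename(columns={
        "assigned_territory": "breeding_territory", "year": "first_breeding_year"})
    out["method"] = first["method"] if "method" in first.columns else "ring"
    return out


def expected_recruitment_year(natal_year: int, first_breeding_year: int,
                              territory_first_year: int,
                              occupied_years: Iterable[int] = (),
                              recruit_age_cy: int = DEFAULT_RECRUIT_AGE_CY) -> int:
    """Rule-assigned year a bird is expected to have entered the territory.

    ``occupied_years`` are the years the breeding territory was known to
    be occupied by *another* bird of the same sex; gaps in monitoring
    count as not known to be occupied.
    """
    age_at_first = first_breeding_year - natal_year + 1
    if age_at_first <= recruit_age_cy:
        return int(first_breeding_year)
    occupied = set(int(y) for y in occupied_years)
    earliest_age_year = natal_year + recruit_age_cy - 1
    for year in range(max(earliest_age_year, territory_first_year),
                      first_breeding_year + 1):
        if year not in occupied or year == first_breeding_year:
            return int(year)
    logger.warning("no qualifying recruitment year; falling back to first "
                   "observed breeding year %s", first_breeding_year)
    return int(first_breeding_year)


def build_dispersal_records(identities: pd.DataFrame, nests: pd.DataFrame,
                            density_table: Optional[pd.DataFrame] = None,
                            periods: NatalPeriods = NatalPeriods(),
                            occupancy: Optional[pd.DataFrame] = None,
                            recruit_age_cy: int = DEFAULT_RECRUIT_AGE_CY,
                            ) -> pd.DataFrame:
    """Assemble one dispersal record per identified bird.

    Parameters
    ----------
    identities
        One row per bird: ``bird_id, sex, natal_territory, natal_year,
        breeding_territory, first_breeding_year`` plus optional
        ``methods`` (e.g. ``"dna+ring"``) and ``inconsistent`` columns.
    nests
        Territory coordinates (first occurrence per territory is used;
        nests are treated as stationary within a territory).
    density_table
        Long (territory_id, year, density) table; missing lookups yield
        null densities but a defined NDD.
    occupancy
        Long (territory_id, year, sex, occupant) table of known
        occupants used by the recruitment-year rule; rows whose
        ``occupant`` equals the focal bird's id are ignored.
    """
    coords = nests.drop_duplicates("territory_id").set_index("territory_id")
    terr_first = nests.groupby("territory_id")["year"].min().to_dict()
    dens: Dict[Tuple[str, int], float] = {}
    if density_table is not None:
        dens = {(str(r.territory_id), int(r.year)): float(r.density)
                for r in density_table.itertuples(index=False)}
    occ: Dict[Tuple[str, str], Dict[int, str]] = {}
    if occupancy is not None:
        for r in occupancy.itertuples(index=False):
            occ.setdefault((str(r.territory_id), str(r.sex)), {})[
                int(r.year)] = str(r.occupant)

    rows = []
    for row in identities.itertuples(index=False):
        natal_terr = None if pd.isna(row.natal_territory) else str(row.natal_territory)
        if natal_terr is None or natal_terr not in coords.index:
            logger.warning("dropping %s: natal nest coordinates missing", row.bird_id)
            continue
        breed_terr = str(row.breeding_territory)
        if breed_terr not in coords.index:
            logger.warning("dropping %s: breeding nest coordinates missing", row.bird_id)
            continue
        a = coords.loc[natal_terr]
        b = coords.loc[breed_terr]
        ndd = great_circle_distance((a.lon, a.lat), (b.lon, b.lat))
        bearing = (initial_bearing((a.lon, a.lat), (b.lon, b.lat))
                   if ndd > 0 else np.nan)
        by_year = occ.get((breed_terr, str(row.sex)), {})
        focal_keys = {str(row.bird_id)}
        occupied = [y for y, who in by_year.items() if who not in focal_keys]
        rec_year = expected_recruitment_year(
            int(row.natal_year), int(row.first_breeding_year),
            int(terr_first.get(breed_terr, int(row.first_breeding_year))),
            occupied, recruit_age_cy)
        nd = dens.get((natal_terr, rec_year), np.nan)
        bd = dens.get((breed_terr, rec_year), np.nan)
        dd = (math.log(bd) - math.log(nd)
              if np.isfinite(nd) and np.isfinite(bd) else np.nan)
        rows.append({
            "bird_id": row.bird_id, "sex": row.sex,
            "natal_territory": natal_terr, "natal_year": int(row.natal_year),
            "breeding_territory": breed_terr,
            "first_breeding_year": int(row.first_breeding_year),
            "recruitment_year": rec_year,
            "ndd": float(ndd), "bearing": bearing,
            "natal_density": nd, "breeding_density": bd,
            "density_difference": dd,
            "natal_period": periods.classify(int(row.natal_year)),
            "natal_period_direction": periods.classify_direction(int(row.natal_year)),
            "methods": getattr(row, "methods", "dna"),
            "inconsistent": bool(getattr(row, "inconsistent", False)),
        })
    return pd.DataFrame(rows)


def merge_identities(*identity_tables: pd.DataFrame) -> pd.DataFrame:
    """Combine per-method identity tables into one row per bird.

    Each input has columns ``bird_id, breeding_territory,
    first_breeding_year, method``. The combined first breeding is the
    earliest over methods; methods reporting a *different* territory for
    that same earliest year raise a flagged inconsistency (the record is
    kept, flagged, with the lexicographically first territory).
    """
    frames = [t for t in identity_tables if t is not None and len(t)]
    if not frames:
        return pd.DataFrame(columns=["bird_id", "breeding_territory",
                                     "first_breeding_year", "methods",
                                     "inconsistent"])
    allr = pd.concat(frames, ignore_index=True)
    rows = []
    for bird_id, grp in allr.groupby("bird_id"):
        y0 = int(grp["first_breeding_year"].min())
        at_y0 = grp[grp["first_breeding_year"] == y0]
        terrs = sorted(set(at_y0["breeding_territory"].astype(str)))
        rows.append({
            "bird_id": bird_id,
            "breeding_territory": terrs[0],
            "first_breeding_year": y0,
            "methods": "+".join(sorted(set(grp["method"].astype(str)))),
            "inconsistent": len(terrs) > 1,
        })
    return pd.DataFrame(rows)
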