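"""Synthetic natal-dispersal studies with known ground truth.

The real study system — a philopatric raptor population monitored over a
decade, with chicks marked by ringing, GPS tags and DNA profiling and
breeders re-identified from shed feathers — withholds its nest
coordinates and genotypes. This module generates complete surrogate
studies with the same table schemas and the same qualitative structure:

* a two-phase territory history (stagnation then exponential growth)
  on a planar km frame, exported as WGS84 coordinates through a local
  equal-area projection so the spherical code paths are exercised;
* sibling-rich Mendelian microsatellite genotypes at a 9-locus primary
  and an 8-locus extended panel, with per-locus allelic dropout;
* sex-specific lognormal dispersal kernels with optional
  density-dependent settlement;
* incomplete detection for each of the three marking methods.

Every stochastic draw flows from one :class:`numpy.random.Generator`
seeded by ``SimConfig.seed``, so studies are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotypes import EXTENDED_LOCI, PRIMARY_LOCI
from .geo import LocalEqualAreaProjection, haversine_km, initial_bearing


def _default_kernel() -> dict:
    # medians 57.6 km (females) and 35.9 km (males), as observed in the
    # study population; common shape parameter
    return {"female": (math.log(57.6), 0.85), "male": (math.log(35.9), 0.85)}


def _default_detection() -> dict:
    return {
        "chick_dna": 0.38,      # chicks DNA-profiled (631 of 1660 ringed)
        "adult_feather": 0.55,  # resident's shed feather found+typed, per year
        "ring_resight": 0.06,   # breeding ring-read, per breeding year
        "gps_tag": 0.043,       # chicks fitted with a GPS tag (71 of 1660)
        "gps_reliability": 0.6, # tag still working at first breeding
    }


def _default_growth() -> dict:
    # stagnation 2011-2014, then exponential growth tripling the
    # population by the final year
    return {"stagnation": 1.01, "growth": 1.13}


@dataclass
class SimConfig:
    """Study-generator configuration; defaults emulate the study system."""

    region_extent: Tuple[float, float] = (150.0, 150.0)  # km
    n_years: int = 12
    start_year: int = 2011
    initial_territories: int = 133
    growth_rate_by_period: dict = field(default_factory=_default_growth)
    growth_start_year: int = 2015  # first year of the growth period
    min_nest_spacing: float = 5.0  # km
    attraction_weight: float = 0.7
    territory_diameter: float = 10.9  # km; sets the attraction annulus
    n_primary_loci: int = 9
    n_extended_loci: int = 8
    n_alleles: int = 8
    allele_freq_prior: float = 1.0  # Dirichlet concentration per locus
    dropout_rate: float = 0.05
    sex_ratio: float = 0.5  # proportion female among chicks
    ndd_kernel: dict = field(default_factory=_default_kernel)  # sex -> (meanlog, sdlog)
    density_pref: float = 0.0  # settlement weight on (log natal - log candidate) density
    detection: dict = field(default_factory=_default_detection)
    recruit_age_cy: int = 4  # calendar-year age at recruitment
    max_deferrals: int = 4
    breeding_success: float = 0.5  # pair-years producing a brood
    brood_probs: Tuple[float, ...] = (0.6, 0.35, 0.05)  # P(brood size = 1, 2, 3)
    juvenile_survival: float = 0.35  # chick survives to recruitment age
    adult_mortality: float = 0.12  # per resident per year
    floater_mortality: float = 0.10  # per deferred floater per year
    center_lonlat: Tuple[float, float] = (19.5, 47.2)
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if self.min_nest_spacing <= 0:
            raise ValueError("min_nest_spacing must be > 0")
        for rate in self.growth_rate_by_period.values():
            if rate <= 0:
                raise ValueError("growth rates must be > 0")
        for p in (self.attraction_weight, self.dropout_rate, self.sex_ratio,
                  self.breeding_success, self.juvenile_survival,
                  self.adult_mortality, self.floater_mortality,
                  *self.detection.values()):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.n_alleles < 1:
            raise ValueError("each locus needs at least one allele")

    @property
    def years(self) -> range:
        return range(self.start_year, self.start_year + self.n_years)

    def rate_for(self, year: int) -> float:
        key = "growth" if year >= self.growth_start_year else "stagnation"
        return self.growth_rate_by_period[key]

    def projection(self) -> LocalEqualAreaProjection:
        return LocalEqualAreaProjection(*self.center_lonlat)


# ---------------------------------------------------------------------------
# Nest dynamics
# ---------------------------------------------------------------------------

def simulate_nest_dynamics(config: SimConfig,
                           rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Simulate the territory history: one row per active nest per year.

    Initial territories are placed uniformly with a hard minimum
    spacing; each later year adds Poisson((rate - 1) * N) territories,
    each seeded near an existing nest (uniform in an annulus of one to
    two territory diameters) with probability ``attraction_weight``,
    otherwise uniformly. Territories persist once created. Raises if the
    region cannot host the requested territories at the minimum spacing.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    W, H = config.region_extent
    spacing = config.min_nest_spacing
    # hexagonal packing bound as a cheap feasibility screen
    capacity = (W / spacing + 1) * (H / spacing + 1)
    if config.initial_territories > capacity:
        raise ValueError(
            f"region {W}x{H} km cannot host {config.initial_territories} "
            f"territories at {spacing} km spacing")

    xs: list = []
    ys: list = []

    def _try_place(x, y) -> bool:
        if not (0 <= x <= W and 0 <= y <= H):
            return False
        if xs:
            d2 = (np.array(xs) - x) ** 2 + (np.array(ys) - y) ** 2
            if d2.min() < spacing ** 2:
                return False
        xs.append(x)
        ys.append(y)
        return True

    def _place_uniform() -> bool:
        for _ in range(2000):
            if _try_place(rng.uniform(0, W), rng.uniform(0, H)):
                return True
        return False

    for _ in range(config.initial_territories):
        if not _place_uniform():
            raise ValueError("region too small to place initial territories "
                             "at the requested minimum spacing")

    first_year = np.full(config.initial_territories, config.start_year, dtype=int)
    D = config.territory_diameter
    for year in list(config.years)[1:]:
        n_prev = len(xs)
        lam = max(config.rate_for(year) - 1.0, 0.0) * n_prev
        n_new = rng.poisson(lam)
        for _ in range(n_new):
            placed = False
            if rng.random() < config.attraction_weight:
                for _ in range(200):
                    anchor = rng.integers(0, len(xs))
                    radius = rng.uniform(D, 2 * D)
                    angle = rng.uniform(0, 2 * math.pi)
                    if _try_place(xs[anchor] + radius * math.cos(angle),
                                  ys[anchor] + radius * math.sin(angle)):
                        placed = True
                        break
            if not placed and not _place_uniform():
                raise ValueError("region saturated: cannot place new territory "
                                 "at the requested minimum spacing")
        first_year = np.concatenate([first_year, np.full(len(xs) - len(first_year),
                                                         year, dtype=int)])

    proj = config.projection()
    x_arr = np.asarray(xs) - W / 2.0
    y_arr = np.asarray(ys) - H / 2.0
    lon, lat = proj.inverse(x_arr, y_arr)
    terr_ids = [f"T{i:04d}" for i in range(len(xs))]
    rows = []
    for year in config.years:
        active = first_year <= year
        for i in np.nonzero(active)[0]:
            rows.append({"territory_id": terr_ids[i], "year": int(year),
                         "lon": round(float(lon[i]), 5),
                         "lat": round(float(lat[i]), 5), "active": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genotype primitives
# ---------------------------------------------------------------------------

def locus_names(config: SimConfig) -> list:
    names = list(PRIMARY_LOCI[: config.n_primary_loci])
    if config.n_primary_loci > len(PRIMARY_LOCI):
        names += [f"P{i}" for i in range(len(PRIMARY_LOCI), config.n_primary_loci)]
    ext = list(EXTENDED_LOCI[: config.n_extended_loci])
    if config.n_extended_loci > len(EXTENDED_LOCI):
        ext += [f"E{i}" for i in range(len(EXTENDED_LOCI), config.n_extended_loci)]
    return names + ext


def draw_allele_frequencies(config: SimConfig,
                            rng: np.random.Generator) -> np.ndarray:
    """Per-locus allele frequency vectors, shape (n_loci, n_alleles)."""
    n_loci = config.n_primary_loci + config.n_extended_loci
    if config.n_alleles == 1:
        return np.ones((n_loci, 1))
    return rng.dirichlet([config.allele_freq_prior] * config.n_alleles,
                         size=n_loci)


def sample_founder_genotypes(freqs: np.ndarray, n: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` unrelated genotypes in Hardy-Weinberg proportions.

    Returns an int array of shape (n, n_loci, 2); allele codes index the
    frequency vectors.
    """
    n_loci, n_alleles = freqs.shape
    out = np.empty((n, n_loci, 2), dtype=np.int16)
    for l in range(n_loci):
        out[:, l, :] = rng.choice(n_alleles, size=(n, 2), p=freqs[l])
    return out


def sample_child_genotypes(mothers: np.ndarray, fathers: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """Mendelian inheritance: one allele per parent per locus, uniformly."""
    n, n_loci, _ = mothers.shape
    pick_m = rng.integers(0, 2, size=(n, n_loci))
    pick_f = rng.integers(0, 2, size=(n, n_loci))
    child = np.empty_like(mothers)
    idx = np.arange(n)[:, None], np.arange(n_loci)[None, :]
    child[:, :, 0] = mothers[idx[0], idx[1], pick_m]
    child[:, :, 1] = fathers[idx[0], idx[1], pick_f]
    return child


def apply_dropout(genotypes: np.ndarray, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Erase whole-locus calls independently with the given probability."""
    out = genotypes.copy()
    if rate > 0:
        miss = rng.random(genotypes.shape[:2]) < rate
        out[miss] = -1
    return out


# ---------------------------------------------------------------------------
# Dispersal settlement
# ---------------------------------------------------------------------------

def _settlement_score(dist_km: np.ndarray, target_km: float,
                      cand_logdens: Optional[np.ndarray],
                      natal_logdens: Optional[float],
                      density_pref: float) -> np.ndarray:
    score = -np.abs(np.log((dist_km + 0.5) / target_km))
    if density_pref != 0.0 and cand_logdens is not None and natal_logdens is not None:
        score = score + density_pref * (natal_logdens - cand_logdens)
    return score


def simulate_dispersal(config: SimConfig, nests: pd.DataFrame,
                       birds: pd.DataFrame,
                       vacancies: Optional[pd.DataFrame] = None,
                       densities: Optional[pd.DataFrame] = None,
                       rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Settle recruiting birds into vacant territories.

    Each bird becomes eligible in the year it reaches the recruitment
    age (``recruit_age_cy``), draws a target distance from its sex's
    lognormal kernel and takes the vacant same-sex territory maximising
    a score of distance match and (optionally) density preference. Birds
    finding no vacancy are deferred to the next year as floaters, up to
    ``max_deferrals`` times.

    Parameters
    ----------
    birds
        Columns ``bird_id``, ``sex``, ``natal_territory``, ``natal_year``.
    vacancies
        Columns ``territory_id``, ``year``, ``sex``; defaults to every
        territory being open to both sexes in its first active year.
    densities
        Optional long density table (territory_id, year, density) used
        by the density-preference term.

    Returns the dispersal fields of the truth table: breeding territory
    and year, realised great-circle NDD (km), bearing, deferral count
    and a ``settled`` flag.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    coords = nests.drop_duplicates("territory_id").set_index("territory_id")
    if vacancies is None:
        first = nests.groupby("territory_id")["year"].min().reset_index()
        vacancies = pd.concat([first.assign(sex=s) for s in ("male", "female")])
    vac: Dict[int, Dict[str, set]] = {}
    for row in vacancies.itertuples(index=False):
        vac.setdefault(int(row.year), {"male": set(), "female": set()})[
            str(row.sex)].add(str(row.territory_id))
    dens = None
    if densities is not None:
        dens = {(str(r.territory_id), int(r.year)): float(r.density)
                for r in densities.itertuples(index=False)}

    queue = []  # (eligible_year, deferrals, bird row, target)
    for row in birds.itertuples(index=False):
        year0 = int(row.natal_year) + config.recruit_age_cy - 1
        meanlog, sdlog = config.ndd_kernel[str(row.sex)]
        target = float(np.exp(rng.normal(meanlog, sdlog)))
        queue.append([year0, 0, row, target])

    out = []
    all_years = sorted(set(y for y, *_ in queue) | set(vac))
    max_year = max(all_years) + config.max_deferrals + 1
    year = min(all_years)
    while year <= max_year and queue:
        todo = [q for q in queue if q[0] == year]
        rng.shuffle(todo)
        for q in todo:
            queue.remove(q)
            _, deferrals, row, target = q
            open_terrs = sorted(vac.get(year, {}).get(str(row.sex), set()))
            if not open_terrs:
                if deferrals < config.max_deferrals:
                    queue.append([year + 1, deferrals + 1, row, target])
                else:
                    out.append(_unsettled(row, deferrals))
                continue
            natal = coords.loc[str(row.natal_territory)]
            clon = coords.loc[open_terrs, "lon"].to_numpy(float)
            clat = coords.loc[open_terrs, "lat"].to_numpy(float)
            dist = haversine_km(natal.lon, natal.lat, clon, clat)
            cand_ld = natal_ld = None
            if dens is not None:
                cand_ld = np.array([
                    math.log(dens.get((t, year), np.nan)) for t in open_terrs])
                nd = dens.get((str(row.natal_territory), year))
                natal_ld = math.log(nd) if nd else None
            score = _settlement_score(dist, target, cand_ld, natal_ld,
                                      config.density_pref)
            j = int(np.argmax(score))
            chosen = open_terrs[j]
            vac[year][str(row.sex)].discard(chosen)
            ndd = float(dist[j])
            brg = (initial_bearing((natal.lon, natal.lat), (clon[j], clat[j]))
                   if ndd > 0 else np.nan)
            out.append({
                "bird_id": row.bird_id, "sex": row.sex,
                "natal_territory": row.natal_territory,
                "natal_year": int(row.natal_year),
                "breeding_territory": chosen, "first_breeding_year": year,
                "recruitment_year": year, "ndd_km": ndd, "bearing": brg,
                "target_km": target, "deferrals": deferrals, "settled": True,
            })
        year += 1
    for q in queue:  # never reached an eligible year within the horizon
        out.append(_unsettled(q[2], q[1]))
    return pd.DataFrame(out)


def _unsettled(row, deferrals) -> dict:
    return {"bird_id": row.bird_id, "sex": row.sex,
            "natal_territory": row.natal_territory,
            "natal_year": int(row.natal_year), "breeding_territory": None,
            "first_breeding_year": np.nan, "recruitment_year": np.nan,
            "ndd_km": np.nan, "bearing": np.nan, "target_km": np.nan,
            "deferrals": deferrals, "settled": False}


# ---------------------------------------------------------------------------
# Full-study engine: demography, pedigree and imperfect observation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """A complete synthetic study: observed tables plus ground truth."""

    config: SimConfig
    nests: pd.DataFrame        # territory_id, year, lon, lat, active
    individuals: pd.DataFrame  # bird_id, hatch_year, natal_territory, sex, marking
    genotypes: pd.DataFrame    # sample_id, locus, allele1, allele2 (long)
    samples: pd.DataFrame      # sample_id, kind, bird_id?, territory_id, year, sex
    encounters: pd.DataFrame   # bird_id, year, age_cy, lon, lat, assigned_territory,
                               # breeding_confirmed, egg_laying
    truth: pd.DataFrame        # per marked chick: natal/breeding truth + parents
    allele_freqs: np.ndarray   # (n_loci, n_alleles)

    def write(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.nests.to_csv(out / "nests.csv", index=False)
        self.individuals.to_csv(out / "individuals.csv", index=False)
        self.genotypes.to_csv(out / "genotypes.csv", index=False)
        self.samples.to_csv(out / "samples.csv", index=False)
        self.encounters.to_csv(out / "encounters.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


class _Demography:
    """Year-by-year population engine behind :func:`simulate_study`."""

    def __init__(self, config: SimConfig, nests: pd.DataFrame,
                 rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.nests = nests
        self.coords = nests.drop_duplicates("territory_id").set_index("territory_id")
        self.first_year = nests.groupby("territory_id")["year"].min().to_dict()
        self.freqs = draw_allele_frequencies(config, rng)
        self.genotype: Dict[str, np.ndarray] = {}
        self.birds: Dict[str, dict] = {}
        self.residents: Dict[str, dict] = {}
        self.floaters: list = []
        self.settlements: list = []
        self.residency: list = []  # (territory, year, sex, bird_id)
        self._n_birds = 0

    # -- bird factories -----------------------------------------------------

    def _new_id(self, prefix: str) -> str:
        self._n_birds += 1
        return f"{prefix}{self._n_birds:05d}"

    def _founder(self, sex: str) -> str:
        bid = self._new_id("A")
        self.birds[bid] = {"sex": sex, "hatch_year": None, "natal_territory": None,
                           "mother": None, "father": None, "founder": True,
                           "marking": set()}
        self.genotype[bid] = sample_founder_genotypes(self.freqs, 1, self.rng)[0]
        return bid

    def _chick(self, sex: str, year: int, terr: str, mother: str, father: str) -> str:
        bid = self._new_id("B")
        det = self.cfg.detection
        marking = {"ring"}
        if self.rng.random() < det["chick_dna"]:
            marking.add("dna")
        if self.rng.random() < det["gps_tag"]:
            marking.add("gps")
        self.birds[bid] = {"sex": sex, "hatch_year": year, "natal_territory": terr,
                           "mother": mother, "father": father, "founder": False,
                           "marking": marking}
        return bid

    # -- the annual cycle ---------------------------------------------------

    def run(self) -> None:
        for year in self.cfg.years:
            self._open_new_territories(year)
            if year > self.cfg.start_year:
                self._mortality()
            self._recruit(year)
            self._immigrate()
            self._breed(year)
            for terr, occ in self.residents.items():
                for sex in ("male", "female"):
                    if occ[sex] is not None:
                        self.residency.append((terr, year, sex, occ[sex]))

    def _open_new_territories(self, year: int) -> None:
        for terr, fy in self.first_year.items():
            if fy == year:
                self.residents[terr] = {"male": None, "female": None}

    def _mortality(self) -> None:
        for occ in self.residents.values():
            for sex in ("male", "female"):
                if occ[sex] is not None and self.rng.random() < self.cfg.adult_mortality:
                    occ[sex] = None

    def _recruit(self, year: int) -> None:
        cfg = self.cfg
        eligible = [f for f in self.floaters if f["eligible_year"] <= year]
        self.rng.shuffle(eligible)
        for fl in eligible:
            self.floaters.remove(fl)
            bird = self.birds[fl["bird_id"]]
            sex = bird["sex"]
            open_terrs = sorted(t for t, occ in self.residents.items()
                                if occ[sex] is None)
            if not open_terrs:
                self._defer(fl, year)
                continue
            natal = self.coords.loc[bird["natal_territory"]]
            clon = self.coords.loc[open_terrs, "lon"].to_numpy(float)
            clat = self.coords.loc[open_terrs, "lat"].to_numpy(float)
            dist = haversine_km(natal.lon, natal.lat, clon, clat)
            cand_ld = natal_ld = None
            if cfg.density_pref != 0.0:
                # crude occupancy-based proxy available mid-simulation:
                # settlement preference uses nest-neighbourhood crowding
                cand_ld = self._crowding(open_terrs)
                natal_ld = float(self._crowding([bird["natal_territory"]])[0])
            score = _settlement_score(dist, fl["target_km"], cand_ld, natal_ld,
                                      cfg.density_pref)
            j = int(np.argmax(score))
            chosen = open_terrs[j]
            self.residents[chosen][sex] = fl["bird_id"]
            ndd = float(dist[j])
            brg = (initial_bearing((natal.lon, natal.lat), (clon[j], clat[j]))
                   if ndd > 0 else np.nan)
            self.settlements.append({
                "bird_id": fl["bird_id"], "sex": sex,
                "natal_territory": bird["natal_territory"],
                "natal_year": bird["hatch_year"], "breeding_territory": chosen,
                "first_breeding_year": year, "recruitment_year": year,
                "ndd_km": ndd, "bearing": brg, "deferrals": fl["deferrals"]})

    def _crowding(self, terrs) -> np.ndarray:
        """log crowding proxy: count of active nests within 2 diameters."""
        all_lon = self.coords.loc[list(self.residents), "lon"].to_numpy(float)
        all_lat = self.coords.loc[list(self.residents), "lat"].to_numpy(float)
        out = np.empty(len(terrs))
        for i, t in enumerate(terrs):
            c = self.coords.loc[t]
            d = haversine_km(c.lon, c.lat, all_lon, all_lat)
            out[i] = math.log(max((d < 2 * self.cfg.territory_diameter).sum(), 1))
        return out

    def _defer(self, fl: dict, year: int) -> None:
        if (fl["deferrals"] < self.cfg.max_deferrals
                and self.rng.random() > self.cfg.floater_mortality):
            fl["deferrals"] += 1
            fl["eligible_year"] = year + 1
            self.floaters.append(fl)

    def _immigrate(self) -> None:
        for occ in self.residents.values():
            for sex in ("male", "female"):
                if occ[sex] is None:
                    occ[sex] = self._founder(sex)

    def _breed(self, year: int) -> None:
        cfg = self.cfg
        sizes = np.arange(1, len(cfg.brood_probs) + 1)
        mothers, fathers, terrs = [], [], []
        for terr, occ in self.residents.items():
            if occ["male"] is None or occ["female"] is None:
                continue
            if self.rng.random() >= cfg.breeding_success:
                continue
            brood = int(self.rng.choice(sizes, p=cfg.brood_probs))
            for _ in range(brood):
                mothers.append(occ["female"])
                fathers.append(occ["male"])
                terrs.append(terr)
        if not mothers:
            return
        gm = np.stack([self.genotype[m] for m in mothers])
        gf = np.stack([self.genotype[f] for f in fathers])
        kids = sample_child_genotypes(gm, gf, self.rng)
        for i, terr in enumerate(terrs):
            sex = "female" if self.rng.random() < cfg.sex_ratio else "male"
            bid = self._chick(sex, year, terr, mothers[i], fathers[i])
            self.genotype[bid] = kids[i]
            if self.rng.random() < cfg.juvenile_survival:
                meanlog, sdlog = cfg.ndd_kernel[sex]
                self.floaters.append({
                    "bird_id": bid, "deferrals": 0,
                    "eligible_year": year + cfg.recruit_age_cy - 1,
                    "target_km": float(np.exp(self.rng.normal(meanlog, sdlog)))})


def simulate_pedigree_genotypes(config: SimConfig, nests: pd.DataFrame,
                                rng: Optional[np.random.Generator] = None,
                                ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the demographic engine and return bird genotypes + truth table.

    Genotypes are the per-bird observed calls (per-locus dropout applied
    once per bird); the truth table carries natal origin, parents, sex
    and — for recruited birds — the realised dispersal fields.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    demo = _Demography(config, nests, rng)
    demo.run()
    loci = locus_names(config)
    ids = sorted(demo.genotype)
    gt = np.stack([demo.genotype[b] for b in ids])
    gt = apply_dropout(gt, config.dropout_rate, rng)
    genotypes = _long_genotypes(ids, gt, loci)
    truth = _truth_table(demo)
    return genotypes, truth


def _long_genotypes(sample_ids, gt: np.ndarray, loci) -> pd.DataFrame:
    n, L, _ = gt.shape
    sid = np.repeat(sample_ids, L)
    loc = np.tile(loci, n)
    a1 = gt[:, :, 0].ravel().astype(float)
    a2 = gt[:, :, 1].ravel().astype(float)
    a1[a1 < 0] = np.nan
    a2[a2 < 0] = np.nan
    return pd.DataFrame({"sample_id": sid, "locus": loc,
                         "allele1": a1, "allele2": a2})


def _truth_table(demo: _Demography) -> pd.DataFrame:
    settled = {s["bird_id"]: s for s in demo.settlements}
    rows = []
    for bid, b in demo.birds.items():
        if b["founder"]:
            continue
        s = settled.get(bid, {})
        rows.append({
            "bird_id": bid, "sex": b["sex"], "hatch_year": b["hatch_year"],
            "natal_territory": b["natal_territory"],
            "mother": b["mother"], "father": b["father"],
            "marking": "+".join(sorted(b["marking"])),
            "breeding_territory": s.get("breeding_territory"),
            "first_breeding_year": s.get("first_breeding_year", np.nan),
            "recruitment_year": s.get("recruitment_year", np.nan),
            "ndd_km": s.get("ndd_km", np.nan),
            "bearing": s.get("bearing", np.nan),
            "deferrals": s.get("deferrals", np.nan),
        })
    return pd.DataFrame(rows).sort_values("bird_id").reset_index(drop=True)


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Generate a full synthetic study with imperfect observation.

    Runs nest dynamics and the demographic engine, then overlays the
    three marking methods: chick DNA profiles and feather samples from
    breeding residents (each with their own dropout), ring resightings
    of breeding birds, and GPS-documented first breedings. All
    randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    nests = simulate_nest_dynamics(config, rng)
    demo = _Demography(config, nests, rng)
    demo.run()
    cfg = config
    det = cfg.detection
    loci = locus_names(cfg)

    truth = _truth_table(demo)
    individuals = truth[["bird_id", "sex", "hatch_year", "natal_territory",
                         "marking"]].rename(columns={"hatch_year": "natal_year"})

    sample_rows, gt_ids, gt_arrays = [], [], []
    # chick DNA profiles (one armpit-feather sample per profiled chick)
    for bid, b in demo.birds.items():
        if b["founder"] or "dna" not in b["marking"]:
            continue
        sid = f"C_{bid}"
        sample_rows.append({"sample_id": sid, "kind": "chick", "bird_id": bid,
                            "territory_id": b["natal_territory"],
                            "year": b["hatch_year"], "sex": b["sex"]})
        gt_ids.append(sid)
        gt_arrays.append(demo.genotype[bid])
    # shed feathers of breeding residents, per territory-year
    n_feather = 0
    for terr, year, sex, bid in demo.residency:
        if rng.random() >= det["adult_feather"]:
            continue
        n_feather += 1
        sid = f"F{n_feather:05d}"
        sample_rows.append({"sample_id": sid, "kind": "feather", "bird_id": bid,
                            "territory_id": terr, "year": year,
                            "sex": demo.birds[bid]["sex"]})
        gt_ids.append(sid)
        gt_arrays.append(demo.genotype[bid])
    gt = apply_dropout(np.stack(gt_arrays), cfg.dropout_rate, rng) if gt_arrays \
        else np.zeros((0, len(loci), 2), dtype=np.int16)
    genotypes = _long_genotypes(gt_ids, gt, loci)
    samples = pd.DataFrame(sample_rows)

    # ring resightings and GPS breeding records
    coords = demo.coords
    settled = {s["bird_id"]: s for s in demo.settlements}
    breeding_years: Dict[str, list] = {}
    for terr, year, sex, bid in demo.residency:
        breeding_years.setdefault(bid, []).append((terr, year))
    enc_rows = []
    for bid, s in settled.items():
        b = demo.birds[bid]
        gps_live = "gps" in b["marking"] and rng.random() < det["gps_reliability"]
        for terr, year in sorted(breeding_years.get(bid, []), key=lambda t: t[1]):
            seen_ring = "ring" in b["marking"] and rng.random() < det["ring_resight"]
            seen_gps = gps_live and year == s["first_breeding_year"]
            if not (seen_ring or seen_gps):
                continue
            c = coords.loc[terr]
            enc_rows.append({
                "bird_id": bid, "year": year,
                "age_cy": year - b["hatch_year"] + 1,
                "lon": c.lon, "lat": c.lat, "assigned_territory": terr,
                "breeding_confirmed": True, "egg_laying": True,
                "method": "gps" if seen_gps and not seen_ring else "ring"})
    # floater resightings: immature, non-breeding observations
    for fl_bid, b in demo.birds.items():
        if b["founder"] or b["hatch_year"] is None:
            continue
        if rng.random() < det.get("floater_resight", 0.02):
            year = b["hatch_year"] + 1
            if year in cfg.years:
                enc_rows.append({
                    "bird_id": fl_bid, "year": year, "age_cy": 2,
                    "lon": cfg.center_lonlat[0], "lat": cfg.center_lonlat[1],
                    "assigned_territory": None, "breeding_confirmed": False,
                    "egg_laying": False, "method": "ring"})
    encounters = pd.DataFrame(enc_rows, columns=[
        "bird_id", "year", "age_cy", "lon", "lat", "assigned_territory",
        "breeding_confirmed", "egg_laying", "method"])

    return SyntheticStudy(config=cfg, nests=nests, individuals=individuals,
                          genotypes=genotypes, samples=samples,
                          encounters=encounters, truth=truth,
                          allele_freqs=demo.freqs)
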