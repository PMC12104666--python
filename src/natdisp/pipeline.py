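"""End-to-end analysis pipeline.

Takes the observed study tables (nests, individuals, long-format
genotypes with a sample register, encounters), re-identifies dispersing
birds by the three marking routes (genotype matching, ring reads, GPS
breeding records), assembles dispersal records with local densities,
and runs the full statistical analysis: sex-specific median NDDs with
sign-test CIs, the two mixed-model sets with backward reduction,
natal-vs-breeding density correlations with Holm adjustment, the
density-by-year trend, Rayleigh tests of dispersal direction by sex and
period, the kernel-density mode of breeding densities and the natal
density of zero predicted density difference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import stats as nds
from .density import DEFAULT_R_TRUNC_KM, yearly_density_table
from .dispersal import (NatalPeriods, build_dispersal_records,
                        filter_breeding_encounters, first_breeding_events,
                        merge_identities)
from .genotypes import (LocusPanel, MultilocusGenotype, allele_frequencies,
                        compare_genotypes, multilocus_pi, pi_sib_locus,
                        two_step_identify)

logger = logging.getLogger(__name__)


def genotypes_from_long(genotypes: pd.DataFrame,
                        samples: Optional[pd.DataFrame] = None,
                        ) -> Dict[str, MultilocusGenotype]:
    """Build genotype objects from a long table (sample_id, locus, allele1, allele2).

    Blank alleles mark an untyped locus. Molecular sex is taken from the
    sample register when provided.
    """
    sex_by_sample: Dict[str, str] = {}
    if samples is not None and "sex" in samples.columns:
        sex_by_sample = dict(zip(samples["sample_id"].astype(str),
                                 samples["sex"].astype(str)))
    out: Dict[str, MultilocusGenotype] = {}
    for sid, grp in genotypes.groupby("sample_id", sort=False):
        calls = {}
        for r in grp.itertuples(index=False):
            if pd.isna(r.allele1) or pd.isna(r.allele2):
                continue
            calls[str(r.locus)] = (int(r.allele1), int(r.allele2))
        out[str(sid)] = MultilocusGenotype(str(sid), calls,
                                           sex_by_sample.get(str(sid), "unknown"))
    return out


def cluster_feathers(feathers: Sequence[MultilocusGenotype],
                     panel: LocusPanel = LocusPanel()) -> Dict[str, int]:
    """Group feather samples of one territory into putative individuals.

    Samples with identical genotypes on >= 7 co-typed primary loci and
    concordant sex are taken as the same bird. Used only for occupancy
    bookkeeping, so a conservative exact-match rule suffices.
    """
    clusters: List[List[MultilocusGenotype]] = []
    assign: Dict[str, int] = {}
    for s in feathers:
        placed = False
        for ci, members in enumerate(clusters):
            rep = members[0]
            n, m = compare_genotypes(s, rep, panel.primary_loci)
            if n >= 7 and m == 0 and (s.sex == rep.sex or "unknown" in (s.sex, rep.sex)):
                members.append(s)
                assign[s.sample_id] = ci
                placed = True
                break
        if not placed:
            clusters.append([s])
            assign[s.sample_id] = len(clusters) - 1
    return assign


@dataclass
class AnalysisResult:
    """Everything the statistical layer computes for one study."""

    records: pd.DataFrame
    medians: pd.DataFrame  # per sex: median, lower, upper, achieved_conf, n
    model1: "nds.CoefficientTable"  # response log(NDD)
    model2: "nds.CoefficientTable"  # response density difference
    correlations: pd.DataFrame
    rayleigh: pd.DataFrame  # per sex x natal period
    trend: "nds.TrendResult"
    kde_mode: float
    zero_crossing: Optional["nds.ZeroCrossing"]
    scaling_natal_density: "nds.Scaling"
    pi_sib_primary: Optional[float] = None
    pi_sib_full: Optional[float] = None

    def summary(self) -> dict:
        med = self.medians.set_index("sex")
        out = {
            "n_records": int(len(self.records)),
            "median_ndd_male": float(med.loc["male", "median"]) if "male" in med.index else None,
            "median_ndd_female": float(med.loc["female", "median"]) if "female" in med.index else None,
            "density_trend_slope": self.trend.slope,
            "kde_mode_breeding_density": self.kde_mode,
            "zero_crossing_density": self.zero_crossing.density if self.zero_crossing else None,
        }
        if "sex[female]" in self.model1:
            out["sex_effect_log_ndd"] = self.model1.estimate("sex[female]")
        return out

    def write(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "dispersal.csv", index=False)
        self.medians.to_csv(out / "medians.csv", index=False)
        self.model1.table.to_csv(out / "coefficients_model1.csv", index=False)
        self.model2.table.to_csv(out / "coefficients_model2.csv", index=False)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.rayleigh.to_csv(out / "rayleigh.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, default=float)


def identify_dispersers(individuals: pd.DataFrame, genotypes: pd.DataFrame,
                        samples: pd.DataFrame, encounters: pd.DataFrame,
                        nests: pd.DataFrame,
                        panel: LocusPanel = LocusPanel()):
    """Re-identify breeding birds by DNA, ring and GPS routes.

    Returns ``(identities, occupancy, genotype_objects)``: one identity
    row per bird with natal origin and first documented breeding, an
    occupancy table of known same-sex occupants per territory-year, and
    the parsed genotype objects (for reliability statistics).
    """
    gobjs = genotypes_from_long(genotypes, samples)
    smp = samples.set_index("sample_id")
    chick_ids = [s for s in gobjs if smp.loc[s, "kind"] == "chick"]
    feather_ids = [s for s in gobjs if smp.loc[s, "kind"] == "feather"]
    chicks = [gobjs[s] for s in chick_ids]
    feathers = [gobjs[s] for s in feather_ids]

    matches = two_step_identify(chicks, feathers, panel, keep_rejected=False)
    accepted = [m for m in matches if m.accepted]
    if any(m.conflict for m in matches):
        logger.warning("%d conflicted matches held for review",
                       sum(m.conflict for m in matches))

    # DNA identities: chick sample -> bird; matched feathers -> breeding events
    bird_of_chick = dict(zip(smp.index, smp["bird_id"])) if "bird_id" in smp.columns else {}
    dna_rows = []
    feather_bird: Dict[str, str] = {}  # feather sample -> identified bird
    by_chick: Dict[str, list] = {}
    for m in accepted:
        by_chick.setdefault(m.chick_id, []).append(m.adult_id)
    for chick_sid, feather_sids in by_chick.items():
        bird_id = str(bird_of_chick.get(chick_sid, chick_sid))
        events = [(int(smp.loc[f, "year"]), str(smp.loc[f, "territory_id"]))
                  for f in feather_sids]
        y0 = min(e[0] for e in events)
        terr = sorted(t for y, t in events if y == y0)[0]
        dna_rows.append({"bird_id": bird_id, "breeding_territory": terr,
                         "first_breeding_year": y0, "method": "dna"})
        for f in feather_sids:
            feather_bird[f] = bird_id
    dna_ids = pd.DataFrame(dna_rows)

    # ring / GPS identities from validated breeding encounters
    valid = filter_breeding_encounters(encounters, nests)
    enc_ids = first_breeding_events(valid)

    identities = merge_identities(dna_ids, enc_ids)
    if len(identities):
        ind = individuals.set_index("bird_id")
        identities = identities[identities["bird_id"].isin(ind.index)]
        identities = identities.assign(
            sex=[ind.loc[b, "sex"] for b in identities["bird_id"]],
            natal_territory=[ind.loc[b, "natal_territory"] for b in identities["bird_id"]],
            natal_year=[int(ind.loc[b, "natal_year"]) for b in identities["bird_id"]],
        )
        identities = identities[identities["sex"].isin(["male", "female"])]

    occupancy = _occupancy_table(feathers, smp, feather_bird, valid, panel)
    return identities, occupancy, gobjs


def _occupancy_table(feathers, smp, feather_bird, valid_encounters, panel):
    """Known same-sex occupants per territory-year from feathers + ring reads."""
    rows = []
    by_terr: Dict[str, list] = {}
    for s in feathers:
        by_terr.setdefault(str(smp.loc[s.sample_id, "territory_id"]), []).append(s)
    for terr, terr_feathers in by_terr.items():
        assign = cluster_feathers(terr_feathers, panel)
        for s in terr_feathers:
            occupant = feather_bird.get(s.sample_id, f"{terr}/c{assign[s.sample_id]}")
            rows.append({"territory_id": terr,
                         "year": int(smp.loc[s.sample_id, "year"]),
                         "sex": s.sex, "occupant": occupant})
    for r in valid_encounters.itertuples(index=False):
        rows.append({"territory_id": str(r.assigned_territory), "year": int(r.year),
                     "sex": "unknown", "occupant": str(r.bird_id)})
    occ = pd.DataFrame(rows).drop_duplicates()
    return occ


def analyse_dispersal(records: pd.DataFrame,
                      density_table: Optional[pd.DataFrame] = None,
                      periods: NatalPeriods = NatalPeriods(),
                      alpha: float = 0.05) -> AnalysisResult:
    """Run the full statistical layer on assembled dispersal records."""
    rec = records[records["sex"].isin(["male", "female"])].copy()

    medians = pd.DataFrame([
        {"sex": sex, "n": len(grp),
         **nds.median_ci_sign(grp["ndd"]).__dict__}
        for sex, grp in rec.groupby("sex") if len(grp)
    ])[["sex", "n", "median", "lower", "upper", "achieved_conf"]]

    # model data: log-NDD requires positive distance; model 1 needs natal
    # density, model 2 both densities; natal period must be classifiable
    m = rec[(rec["ndd"] > 0) & rec["natal_period"].notna()].copy()
    m1 = m[np.isfinite(m["natal_density"])].copy()
    scaled_nd, sc_nd = nds.scaled_log(m1["natal_density"])
    m1["log_ndd"] = np.log(m1["ndd"])
    m1["log_natal_density"] = scaled_nd
    model1 = nds.fit_lmm_reduced(
        m1, response="log_ndd",
        main_effects=["sex", "log_natal_density", "natal_period"],
        quadratic=["log_natal_density"],
        random=("natal_territory", "natal_year"),
        references={"sex": "male", "natal_period": "stagnation"},
        alpha=alpha)

    m2 = m[np.isfinite(m["density_difference"])].copy()
    z_nd2, sc_nd2 = nds.scaled_log(m2["natal_density"])
    z_ndd, _sc_ndd = nds.scaled_log(m2["ndd"])
    m2["log_natal_density"] = z_nd2
    m2["log_ndd"] = z_ndd
    model2 = nds.fit_lmm_reduced(
        m2, response="density_difference",
        main_effects=["sex", "log_natal_density", "log_ndd", "natal_period"],
        quadratic=["log_natal_density", "log_ndd"],
        random=("natal_territory", "natal_year"),
        references={"sex": "male", "natal_period": "stagnation"},
        alpha=alpha)

    pairs = {}
    for sex, grp in m2.groupby("sex"):
        if len(grp) >= 3:
            pairs[sex] = (grp["natal_density"].to_numpy(),
                          grp["breeding_density"].to_numpy())
    correlations = nds.pearson_holm(pairs) if pairs else pd.DataFrame(
        columns=["label", "n", "r", "p_raw", "p_adj"])

    ray_rows = []
    dirs = rec[(rec["ndd"] > 0) & rec["bearing"].notna()
               & rec["natal_period_direction"].notna()]
    for (period, sex), grp in dirs.groupby(["natal_period_direction", "sex"]):
        if len(grp) >= 3:
            res = nds.rayleigh_test(grp["bearing"])
            ray_rows.append({"natal_period": period, "sex": sex, "n": res.n,
                             "mean_angle": res.mean_angle, "r": res.r, "p": res.p})
    rayleigh = pd.DataFrame(ray_rows, columns=["natal_period", "sex", "n",
                                               "mean_angle", "r", "p"])

    trend = (nds.density_trend(density_table)
             if density_table is not None and len(density_table) else None)

    bd = m2["breeding_density"].to_numpy()
    mode = nds.kde_mode(bd) if bd.size >= 5 else np.nan

    crossing = None
    try:
        lo, hi = (float(np.log(m2["natal_density"]).min()),
                  float(np.log(m2["natal_density"]).max()))
        crossing = nds.zero_crossing_density(model2, sc_nd2,
                                             observed_log_range=(lo, hi))
    except (ValueError, KeyError):
        logger.warning("zero-crossing density undefined for this fit")

    return AnalysisResult(records=rec, medians=medians, model1=model1,
                          model2=model2, correlations=correlations,
                          rayleigh=rayleigh, trend=trend, kde_mode=float(mode),
                          zero_crossing=crossing, scaling_natal_density=sc_nd2)


def run_pipeline(nests: pd.DataFrame, individuals: pd.DataFrame,
                 genotypes: pd.DataFrame, samples: pd.DataFrame,
                 encounters: pd.DataFrame,
                 r_trunc: float = DEFAULT_R_TRUNC_KM,
                 periods: NatalPeriods = NatalPeriods(),
                 external_nests: Optional[pd.DataFrame] = None,
                 exclusion_boundary=None) -> AnalysisResult:
    """Full pipeline from observed tables to the analysis result."""
    density_table = yearly_density_table(nests, r_trunc, external_nests,
                                         exclusion_boundary)
    identities, occupancy, gobjs = identify_dispersers(
        individuals, genotypes, samples, encounters, nests)
    records = build_dispersal_records(identities, nests, density_table,
                                      periods, occupancy)
    result = analyse_dispersal(records, density_table, periods)

    # panel reliability from the breeding-adult (feather) reference sample
    panel = LocusPanel()
    smp = samples.set_index("sample_id")
    adults = [g for sid, g in gobjs.items() if smp.loc[sid, "kind"] == "feather"]
    if adults:
        freqs = allele_frequencies(adults, panel.all_loci)
        prim = [pi_sib_locus(freqs[l]) for l in panel.primary_loci if freqs[l].size]
        full = [pi_sib_locus(freqs[l]) for l in panel.all_loci if freqs[l].size]
        if prim:
            result.pi_sib_primary = multilocus_pi(prim)
        if full:
            result.pi_sib_full = multilocus_pi(full)
    return result
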