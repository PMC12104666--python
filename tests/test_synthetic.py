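"""The synthetic study generator: nest dynamics, pedigrees, dispersal."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from natdisp.geo import haversine_km
from natdisp.synthetic import (SimConfig, apply_dropout,
                               draw_allele_frequencies, locus_names,
                               sample_child_genotypes,
                               sample_founder_genotypes, simulate_dispersal,
                               simulate_nest_dynamics,
                               simulate_pedigree_genotypes, simulate_study)


def tiny_cfg(**kw):
    base = dict(region_extent=(100.0, 100.0), n_years=6, initial_territories=25,
                seed=3)
    base.update(kw)
    return SimConfig(**base)


class TestNestDynamics:
    def test_no_growth_keeps_counts_constant(self):
        cfg = tiny_cfg(growth_rate_by_period={"stagnation": 1.0, "growth": 1.0})
        nests = simulate_nest_dynamics(cfg)
        counts = nests.groupby("year").size()
        assert counts.nunique() == 1
        assert counts.iloc[0] == 25

    def test_exponential_growth_matches_closed_form_expectation(self):
        # E[N_t] = N_0 * rate^t with Poisson increments
        cfg = SimConfig(region_extent=(200.0, 200.0), n_years=12,
                        initial_territories=130, min_nest_spacing=3.0,
                        growth_rate_by_period={"stagnation": 1.10, "growth": 1.10},
                        seed=0)
        finals = []
        for seed in range(25):
            nests = simulate_nest_dynamics(SimConfig(**{**cfg.__dict__, "seed": seed}))
            finals.append(nests.groupby("year").size().iloc[-1])
        expected = 130 * 1.10 ** 11  # ~371
        assert np.mean(finals) == pytest.approx(expected, rel=0.07)

    def test_minimum_spacing_enforced_every_year(self):
        cfg = tiny_cfg(min_nest_spacing=5.0)
        nests = simulate_nest_dynamics(cfg)
        for _, sub in nests.groupby("year"):
            lon = sub["lon"].to_numpy()
            lat = sub["lat"].to_numpy()
            for i in range(len(sub)):
                d = haversine_km(lon[i], lat[i], np.delete(lon, i), np.delete(lat, i))
                # coordinates are rounded to 5 decimals (~1 m) on export
                assert d.min() >= 5.0 - 0.01

    def test_territories_persist_once_created(self):
        nests = simulate_nest_dynamics(tiny_cfg())
        first = nests.groupby("territory_id")["year"].min()
        last = nests.groupby("territory_id")["year"].max()
        years = nests["year"].max()
        assert (last == years).all()
        assert (nests.groupby("territory_id").size()
                == years - first + 1).all()

    def test_impossible_packing_fails_loudly(self):
        with pytest.raises(ValueError, match="cannot host|too small"):
            simulate_nest_dynamics(SimConfig(region_extent=(10.0, 10.0),
                                             initial_territories=500,
                                             min_nest_spacing=5.0))


class TestPedigreeGenotypes:
    def test_zero_dropout_types_every_locus(self):
        cfg = tiny_cfg(dropout_rate=0.0)
        nests = simulate_nest_dynamics(cfg)
        genotypes, truth = simulate_pedigree_genotypes(cfg, nests)
        assert genotypes[["allele1", "allele2"]].notna().all().all()
        per_sample = genotypes.groupby("sample_id").size()
        assert (per_sample == 17).all()

    def test_monomorphic_loci_fix_every_individual(self):
        cfg = tiny_cfg(n_alleles=1, dropout_rate=0.0)
        nests = simulate_nest_dynamics(cfg)
        genotypes, _ = simulate_pedigree_genotypes(cfg, nests)
        assert (genotypes["allele1"] == 0).all()
        assert (genotypes["allele2"] == 0).all()

    def test_dropout_rate_realised(self, rng):
        gt = sample_founder_genotypes(np.full((10, 4), 0.25), 2000, rng)
        dropped = apply_dropout(gt, 0.2, rng)
        miss = (dropped[:, :, 0] < 0).mean()
        assert miss == pytest.approx(0.2, abs=0.01)
        # a locus is erased whole, never half
        assert ((dropped[:, :, 0] < 0) == (dropped[:, :, 1] < 0)).all()

    def test_children_inherit_one_allele_per_parent(self, rng):
        freqs = draw_allele_frequencies(tiny_cfg(), rng)
        mothers = sample_founder_genotypes(freqs, 500, rng)
        fathers = sample_founder_genotypes(freqs, 500, rng)
        kids = sample_child_genotypes(mothers, fathers, rng)
        for i in (0, 123, 499):
            for l in range(kids.shape[1]):
                assert kids[i, l, 0] in mothers[i, l]
                assert kids[i, l, 1] in fathers[i, l]

    def test_truth_table_links_parents(self):
        cfg = tiny_cfg()
        nests = simulate_nest_dynamics(cfg)
        _, truth = simulate_pedigree_genotypes(cfg, nests)
        assert truth["mother"].notna().all()
        assert truth["father"].notna().all()
        assert truth["natal_territory"].isin(nests["territory_id"]).all()


class TestSimulateDispersal:
    @staticmethod
    def dense_setup(n_birds, kernel=None, seed=0):
        cfg = SimConfig(region_extent=(260.0, 260.0), n_years=12,
                        initial_territories=300, min_nest_spacing=4.0,
                        attraction_weight=0.4,
                        ndd_kernel=kernel or
                        {"female": (np.log(57.6), 0.85),
                         "male": (np.log(35.9), 0.85)},
                        seed=seed)
        rng = np.random.default_rng(seed)
        nests = simulate_nest_dynamics(cfg, rng)
        terrs = nests["territory_id"].unique()
        birds = pd.DataFrame({
            "bird_id": [f"B{i}" for i in range(n_birds)],
            "sex": rng.choice(["male", "female"], n_birds),
            "natal_territory": rng.choice(terrs[: len(terrs) // 2], n_birds),
            "natal_year": rng.integers(2012, 2019, n_birds),
        })
        years = sorted(nests["year"].unique())
        vac = pd.concat([
            pd.DataFrame({"territory_id": terrs, "year": y, "sex": s})
            for y in range(min(years), max(years) + 6) for s in ("male", "female")])
        return cfg, nests, birds, vac, rng

    def test_realised_distances_follow_the_configured_kernel(self):
        cfg, nests, birds, vac, rng = self.dense_setup(220, seed=2)
        out = simulate_dispersal(cfg, nests, birds, vacancies=vac, rng=rng)
        settled = out[out["settled"]]
        assert settled["settled"].mean() > 0.95
        for sex, (meanlog, sdlog) in cfg.ndd_kernel.items():
            x = np.log(settled.loc[settled["sex"] == sex, "ndd_km"])
            _, p = sps.kstest(x, "norm", args=(meanlog, sdlog))
            assert p > 0.005

    def test_identical_kernels_yield_no_sex_difference(self):
        kernel = {"female": (np.log(45.0), 0.8), "male": (np.log(45.0), 0.8)}
        cfg, nests, birds, vac, rng = self.dense_setup(300, kernel=kernel, seed=4)
        out = simulate_dispersal(cfg, nests, birds, vacancies=vac, rng=rng)
        s = out[out["settled"]]
        _, p = sps.mannwhitneyu(s.loc[s["sex"] == "male", "ndd_km"],
                                s.loc[s["sex"] == "female", "ndd_km"])
        assert p > 0.01

    def test_no_vacancies_defers_then_logs_floaters(self):
        cfg, nests, birds, _, rng = self.dense_setup(10, seed=6)
        empty_vac = pd.DataFrame(columns=["territory_id", "year", "sex"])
        out = simulate_dispersal(cfg, nests, birds.head(5), vacancies=empty_vac,
                                 rng=rng)
        assert (~out["settled"]).all()
        assert (out["deferrals"] == cfg.max_deferrals).all()

    def test_recorded_ndd_is_the_realised_great_circle_distance(self):
        cfg, nests, birds, vac, rng = self.dense_setup(40, seed=8)
        out = simulate_dispersal(cfg, nests, birds, vacancies=vac, rng=rng)
        coords = nests.drop_duplicates("territory_id").set_index("territory_id")
        s = out[out["settled"]]
        for row in s.head(20).itertuples(index=False):
            a = coords.loc[row.natal_territory]
            b = coords.loc[row.breeding_territory]
            assert row.ndd_km == pytest.approx(
                float(haversine_km(a.lon, a.lat, b.lon, b.lat)), abs=1e-9)


class TestReproducibility:
    def test_same_seed_same_study(self):
        cfg = tiny_cfg(seed=99)
        a = simulate_study(cfg)
        b = simulate_study(tiny_cfg(seed=99))
        pd.testing.assert_frame_equal(a.nests, b.nests)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.encounters, b.encounters)

    def test_different_seeds_differ(self):
        a = simulate_study(tiny_cfg(seed=1))
        b = simulate_study(tiny_cfg(seed=2))
        assert not a.nests.equals(b.nests)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"n_years": 1},
        {"min_nest_spacing": 0.0},
        {"dropout_rate": 1.5},
        {"growth_rate_by_period": {"stagnation": -0.1, "growth": 1.1}},
        {"n_alleles": 0},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            tiny_cfg(**kw)

    def test_locus_names_cover_both_panels(self):
        names = locus_names(tiny_cfg())
        assert len(names) == 17 and len(set(names)) == 17


def test_study_tables_have_expected_schemas(default_study):
    st = default_study
    assert {"territory_id", "year", "lon", "lat", "active"} <= set(st.nests.columns)
    assert {"bird_id", "natal_year", "natal_territory", "sex",
            "marking"} <= set(st.individuals.columns)
    assert {"sample_id", "locus", "allele1", "allele2"} <= set(st.genotypes.columns)
    assert {"sample_id", "kind", "territory_id", "year"} <= set(st.samples.columns)
    assert {"bird_id", "year", "age_cy", "breeding_confirmed",
            "egg_laying"} <= set(st.encounters.columns)
    recruits = st.truth[st.truth["breeding_territory"].notna()]
    # every breeding territory exists in the nest table for the breeding year
    nest_years = set(zip(st.nests["territory_id"], st.nests["year"]))
    assert all((t, int(y)) in nest_years for t, y in zip(
        recruits["breeding_territory"], recruits["first_breeding_year"]))


def test_write_round_trip(tmp_path, perfect_study):
    perfect_study.write(tmp_path)
    nests = pd.read_csv(tmp_path / "nests.csv")
    pd.testing.assert_frame_equal(nests, perfect_study.nests)
    assert (tmp_path / "truth.csv").exists()
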