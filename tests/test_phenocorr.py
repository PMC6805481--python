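"""Corrected-phenotype derivation: adjustment formulas, HYS coding,
pedigree BLUP and the reliability filter."""

import numpy as np
import pandas as pd
import pytest

from pigpred.core import DataError, Pedigree, pearson
from pigpred.mme import VarianceComponents
from pigpred.phenocorr import (adjust_age, adjust_bft, build_fixed_effects,
                               derive_yc, fit_pedigree_blup,
                               prepare_trait_dataset, season_of)
from pigpred.simpop import SimConfig, simulate

from conftest import make_pedigree


class TestAdjustments:
    def test_identity_at_100kg(self):
        assert adjust_age(160.0, 100.0, "male") == pytest.approx(160.0)
        assert adjust_bft(12.0, 100.0, "male") == pytest.approx(12.0)

    @pytest.mark.parametrize("args,expected", [
        ((160.0, 110.0, "male"), 150.0705),
        ((160.0, 110.0, "female"), 149.6741),
    ])
    def test_age_adjustment_values(self, args, expected):
        # oracle: direct evaluation of age + (100-w)*(age-CF)/w
        age, w, sex = args
        cf = {"male": 50.775, "female": 46.415}[sex]
        by_hand = age + (100 - w) * (age - cf) / w
        assert adjust_age(*args) == pytest.approx(by_hand, abs=1e-10)
        assert adjust_age(*args) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("args,expected", [
        ((12.0, 110.0, "male"), 10.9767),
        ((12.0, 90.0, "female"), 13.2066),
    ])
    def test_bft_adjustment_values(self, args, expected):
        bft, w, sex = args
        cf = {"male": -7.277, "female": -9.440}[sex]
        by_hand = bft + (100 - w) * bft / (w - cf)
        assert adjust_bft(*args) == pytest.approx(by_hand, abs=1e-10)
        assert adjust_bft(*args) == pytest.approx(expected, abs=1e-3)

    def test_invalid_weight_rejected(self):
        with pytest.raises(DataError):
            adjust_age(160.0, 0.0, "male")

    def test_out_of_range_weight_warns_but_computes(self):
        with pytest.warns(UserWarning, match="85-130"):
            v = adjust_age(150.0, 80.0, "male")
        assert np.isfinite(v)


class TestSeasons:
    @pytest.mark.parametrize("month,season", [
        (1, 1), (2, 1), (3, 2), (5, 2), (6, 3), (8, 3), (9, 4), (11, 4),
    ])
    def test_four_windows(self, month, season):
        _, s = season_of(pd.Timestamp(2014, month, 15))
        assert s == season

    def test_december_rolls_into_next_winter(self):
        year, s = season_of(pd.Timestamp(2014, 12, 5))
        assert (year, s) == (2015, 1)

    def test_same_level_for_same_herd_year_season(self):
        rec = pd.DataFrame({
            "record_date": ["2014-01-10", "2014-02-20", "2014-07-01"],
            "herd": ["h1", "h1", "h1"], "sex": [1, 2, 1],
        })
        codes = build_fixed_effects(rec, "repeated")
        assert codes.iloc[0] == codes.iloc[1]
        assert codes.iloc[0] != codes.iloc[2]

    def test_missing_dates_dropped(self):
        rec = pd.DataFrame({"record_date": ["2014-01-10", None],
                            "herd": ["h1", "h1"], "sex": [1, 1]})
        codes = build_fixed_effects(rec, "repeated")
        assert len(codes) == 1


def _toy_dataset(values, ids, kind="single_record", litters=None):
    rec = pd.DataFrame({
        "id": ids, "trait": "T", "parity": 0,
        "litter": litters if litters is not None else ids,
        "herd": "h", "sex": 1, "record_date": "2014-05-15",
        "value": values, "measured_weight": np.nan,
    })
    return prepare_trait_dataset(rec, "T", kind)


VC = VarianceComponents(sigma2={"a": 0.4, "litter": 0.1}, sigma2_e=0.5,
                        loglik=0.0, converged=True)


class TestPedigreeBlup:
    def test_constant_phenotypes_zero_ebv(self):
        ped = make_pedigree([("1", "0", "0"), ("2", "0", "0"), ("3", "1", "2"),
                             ("4", "1", "2")])
        ds = _toy_dataset([5.0] * 4, ["1", "2", "3", "4"])
        fit = fit_pedigree_blup(ds, ped, variance_components=VC)
        assert np.allclose(fit.ebv.to_numpy(), 0.0, atol=1e-10)

    def test_unphenotyped_progeny_gets_parent_mean(self):
        ped = make_pedigree([("1", "0", "0"), ("2", "0", "0"), ("3", "0", "0"),
                             ("4", "0", "0"), ("5", "1", "2")])
        rng = np.random.default_rng(0)
        ds = _toy_dataset(rng.normal(size=4), ["1", "2", "3", "4"])
        fit = fit_pedigree_blup(ds, ped, variance_components=VC)
        assert fit.ebv["5"] == pytest.approx(
            0.5 * (fit.ebv["1"] + fit.ebv["2"]), abs=1e-10)

    def test_ebv_tracks_tbv_on_simulation(self, small_sim):
        ds = prepare_trait_dataset(small_sim.records, "AGE", "single_record",
                                   measurement="age100")
        fit = fit_pedigree_blup(ds, small_sim.pedigree, variance_components=VC)
        tbv = small_sim.truth.tbv["AGE"]
        common = fit.ebv.index.intersection(tbv.index)
        assert pearson(fit.ebv.loc[common], tbv.loc[common]) > 0.3

    def test_ebv_scale_linearly_reliability_invariant(self):
        ped = make_pedigree([("1", "0", "0"), ("2", "0", "0"), ("3", "1", "2"),
                             ("4", "1", "2"), ("5", "1", "2")])
        rng = np.random.default_rng(1)
        y = rng.normal(size=5)
        ds1 = _toy_dataset(y, ped.ids)
        ds2 = _toy_dataset(3.0 * y, ped.ids)
        vc2 = VarianceComponents(sigma2={"a": 0.4 * 9, "litter": 0.1 * 9},
                                 sigma2_e=0.5 * 9, loglik=0.0)
        f1 = fit_pedigree_blup(ds1, ped, variance_components=VC)
        f2 = fit_pedigree_blup(ds2, ped, variance_components=vc2)
        assert np.allclose(f2.ebv.to_numpy(), 3.0 * f1.ebv.to_numpy())
        assert np.allclose(f2.reliability.to_numpy(), f1.reliability.to_numpy())


class TestDeriveYc:
    def _fake_fit(self, ebv, rel, residuals):
        from pigpred.phenocorr import EBVResult

        return EBVResult(ebv=pd.Series(ebv), reliability=pd.Series(rel),
                         residuals=residuals, vc=VC, solution=None)

    def test_repeated_mean_residual(self):
        res = pd.DataFrame({"id": ["s1", "s1"], "residual": [0.5, -0.5]})
        fit = self._fake_fit({"s1": 1.2}, {"s1": 0.9}, res)
        out = derive_yc(fit, "NBA", "repeated")
        assert out.table["y_c"].iloc[0] == pytest.approx(1.2)

    def test_production_single_residual(self):
        res = pd.DataFrame({"id": ["a"], "residual": [0.3]})
        fit = self._fake_fit({"a": 1.2}, {"a": 0.9}, res)
        out = derive_yc(fit, "AGE", "single_record")
        assert out.table["y_c"].iloc[0] == pytest.approx(1.5)

    def test_reliability_filter(self):
        res = pd.DataFrame({"id": ["a", "b"], "residual": [0.1, 0.1]})
        fit = self._fake_fit({"a": 1.0, "b": 1.0}, {"a": 0.29, "b": 0.31}, res)
        out = derive_yc(fit, "AGE", "single_record")
        assert out.table["id"].tolist() == ["b"]

    def test_yc_beats_raw_phenotype_as_tbv_proxy(self):
        """Averaged over seeds, cor(y_c, TBV) >= cor(raw adjusted, TBV)."""
        gains = []
        for seed in range(6):
            cfg = SimConfig(founders_per_pop=30, generations=3,
                            n_seq_markers=400, n_chip_markers=80, n_qtl=20,
                            n_populations=1, seed=700 + seed)
            sim = simulate(cfg)
            ds = prepare_trait_dataset(sim.records, "AGE", "single_record",
                                       measurement="age100")
            fit = fit_pedigree_blup(ds, sim.pedigree, variance_components=VC)
            out = derive_yc(fit, "AGE", "single_record", reliability_min=0.0)
            tbv = sim.truth.tbv["AGE"]
            ids = out.table["id"]
            raw = sim.records[sim.records["trait"] == "AGE"] \
                .groupby("id")["value"].mean()  # as recorded, off 100 kg
            c_yc = pearson(out.table["y_c"], tbv.loc[ids])
            c_raw = pearson(raw.loc[ids], tbv.loc[ids])
            gains.append(c_yc - c_raw)
        assert np.mean(gains) > 0
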