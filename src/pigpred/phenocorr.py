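"""Corrected phenotypes from pedigree BLUP.

Production records (days to 100 kg, backfat) are first adjusted to the
100-kg scale with national-program correction factors.  Per-population
pedigree BLUP then yields EBVs, record residuals and reliabilities; the
corrected phenotype y_c is EBV plus the (mean) residual, and animals
with reliability below 0.3 are removed.  y_c replaces the raw
phenotype downstream to avoid double-counting parental information.

Reproduction traits use a repeatability model (herd-year-season fixed
effects; additive, permanent-environment and residual random effects).
Production traits use an animal model with herd-year-season-sex fixed
effects and a litter random effect, fitted univariately per trait.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DataError, Pedigree
from .mme import (BlupSolution, ModelSpec, RandomTerm, VarianceComponents,
                  identity_term, incidence, reml, solve_blup)
from .relmat import HInverseParts, a_inverse
from .simpop import CF_AGE, CF_BFT, _season

log = logging.getLogger(__name__)

RELIABILITY_MIN = 0.3


# ---------------------------------------------------------------------------
# 100-kg adjustments


def adjust_age(measured_age: float, measured_weight: float, sex: str) -> float:
    """Days to 100 kg: age + (100 - w) * (age - CF) / w.

    ``sex`` is ``"male"`` or ``"female"``; records are expected between
    85 and 130 kg (out-of-range values are still adjusted, with a
    warning).
    """
    if measured_weight <= 0:
        raise DataError("measured weight must be positive")
    _check_weight(measured_weight)
    cf = CF_AGE[_sex_key(sex)]
    return measured_age + (100.0 - measured_weight) * (measured_age - cf) / measured_weight


def adjust_bft(measured_bft: float, measured_weight: float, sex: str) -> float:
    """Backfat at 100 kg: bft + (100 - w) * bft / (w - CF)."""
    if measured_weight <= 0:
        raise DataError("measured weight must be positive")
    _check_weight(measured_weight)
    cf = CF_BFT[_sex_key(sex)]
    if measured_weight == cf:
        raise DataError("weight equals the correction factor; division by zero")
    return measured_bft + (100.0 - measured_weight) * measured_bft / (measured_weight - cf)


def _sex_key(sex) -> str:
    if sex in ("male", 1, "1", "M"):
        return "male"
    if sex in ("female", 2, "2", "F"):
        return "female"
    raise DataError(f"unknown sex code {sex!r}")


def _check_weight(w: float) -> None:
    if not 85.0 <= w <= 130.0:
        warnings.warn(f"measured weight {w} kg outside the 85-130 kg recording range")


# ---------------------------------------------------------------------------
# fixed effects


def season_of(date: pd.Timestamp) -> tuple[int, int]:
    """(season year, season level); December counts toward the next year's
    winter so the Dec-Feb window stays one level."""
    s = _season(date.month)
    year = date.year + 1 if date.month == 12 else date.year
    return year, s


def build_fixed_effects(records: pd.DataFrame, trait_kind: str) -> pd.Series:
    """Herd-year-season (reproduction) or herd-year-season-sex (production)
    code per record; records with missing dates are dropped with a log entry."""
    dates = pd.to_datetime(records["record_date"], errors="coerce")
    keep = dates.notna()
    if (~keep).any():
        log.warning("dropping %d records with missing dates", int((~keep).sum()))
    codes = []
    for i in records.index[keep]:
        year, season = season_of(dates[i])
        code = f"{records.at[i, 'herd']}-{year}-{season}"
        if trait_kind == "single_record":
            code += f"-{records.at[i, 'sex']}"
        codes.append(code)
    return pd.Series(codes, index=records.index[keep])


# ---------------------------------------------------------------------------
# trait dataset and pedigree BLUP


@dataclass
class TraitDataset:
    """Records for one trait, ready for the animal model."""

    trait: str
    kind: str  # "repeated" | "single_record"
    records: pd.DataFrame  # id, value, hys, (litter)

    @property
    def ids(self) -> list[str]:
        return self.records["id"].tolist()


def prepare_trait_dataset(records: pd.DataFrame, trait: str, kind: str,
                          measurement: str = "none") -> TraitDataset:
    """Select one trait's records, apply 100-kg adjustment, code fixed effects."""
    rec = records.loc[records["trait"] == trait].copy()
    if rec.empty:
        raise DataError(f"no records for trait {trait!r}")
    if measurement == "age100":
        rec["value"] = [adjust_age(v, w, s) for v, w, s in
                        zip(rec["value"], rec["measured_weight"], rec["sex"])]
    elif measurement == "bft100":
        rec["value"] = [adjust_bft(v, w, s) for v, w, s in
                        zip(rec["value"], rec["measured_weight"], rec["sex"])]
    hys = build_fixed_effects(rec, kind)
    rec = rec.loc[hys.index]
    rec["hys"] = hys
    cols = ["id", "value", "hys"] + (["litter"] if kind == "single_record" else [])
    return TraitDataset(trait=trait, kind=kind,
                        records=rec[cols + ["parity"]].reset_index(drop=True))


@dataclass
class EBVResult:
    """EBV, reliability and per-record residuals from pedigree BLUP."""

    ebv: pd.Series  # all pedigree animals
    reliability: pd.Series
    residuals: pd.DataFrame  # id, residual (one row per record)
    vc: VarianceComponents
    solution: BlupSolution


def fit_pedigree_blup(dataset: TraitDataset, pedigree: Pedigree,
                      variance_components: VarianceComponents | None = None,
                      estimate: bool = False) -> EBVResult:
    """Animal-model BLUP with A^-1 in the mixed-model equations.

    Repeated traits add a permanent-environment term, production traits
    a litter term.  Variance components are taken as given, or
    REML-estimated on the same model when ``estimate`` is requested
    (the additive covariance is then the dense A of the phenotyped
    pedigree).  Reliability is 1 - PEV / sigma2_a from the inverse of
    the coefficient matrix.
    """
    rec = dataset.records
    y = rec["value"].to_numpy(dtype=float)
    X, hys_levels = incidence(rec["hys"])
    if np.linalg.matrix_rank(X.T @ X) < X.shape[1]:
        raise DataError("confounded fixed-effect levels in the HYS design")

    ped_ids = pedigree.ids
    unknown = set(rec["id"]) - set(ped_ids)
    if unknown:
        raise DataError(f"phenotyped animals missing from pedigree: {sorted(unknown)[:5]}")
    Za, _ = incidence(rec["id"], ped_ids)
    ainv = a_inverse(pedigree)
    animal = RandomTerm(label="a", Z=Za, level_ids=list(ped_ids),
                        inv_parts=HInverseParts(a_inv=ainv,
                                                correction=np.zeros((0, 0)),
                                                ids=list(ped_ids),
                                                genotyped_ids=[]))
    terms = [animal]
    if dataset.kind == "repeated":
        terms.append(identity_term("pe", rec["id"]))
    else:
        terms.append(identity_term("litter", rec["litter"]))

    vc = variance_components
    if vc is None:
        if not estimate:
            raise DataError("supply variance components or set estimate=True")
        from .relmat import a_matrix

        A = a_matrix(pedigree)
        dense_animal = RandomTerm(label="a", Z=Za, level_ids=list(ped_ids),
                                  covariance=A.values)
        vc = reml(ModelSpec(y=y, X=X, terms=[dense_animal] + terms[1:]))
    sol = solve_blup(ModelSpec(y=y, X=X, terms=terms), vc, compute_pev=True)

    ebv = pd.Series(sol.u["a"], index=ped_ids)
    rel = pd.Series(1.0 - sol.pev["a"] / vc.sigma2["a"], index=ped_ids).clip(0.0, 1.0)
    other = "pe" if dataset.kind == "repeated" else "litter"
    u_other = sol.series(other)
    fitted = X @ sol.beta + Za @ sol.u["a"]
    fitted = fitted + u_other.loc[
        rec["id"] if dataset.kind == "repeated" else rec["litter"]].to_numpy()
    residuals = pd.DataFrame({"id": rec["id"], "residual": y - fitted})
    return EBVResult(ebv=ebv, reliability=rel, residuals=residuals, vc=vc,
                     solution=sol)


@dataclass
class CorrectedPhenotypes:
    """y_c per animal passing the reliability filter."""

    trait: str
    table: pd.DataFrame  # id, y_c, reliability

    def series(self) -> pd.Series:
        return self.table.set_index("id")["y_c"]


def derive_yc(ebv: EBVResult, trait: str, trait_kind: str,
              reliability_min: float = RELIABILITY_MIN) -> CorrectedPhenotypes:
    """y_c = EBV + mean(residuals) (repeated) or EBV + residual (single).

    Only phenotyped animals receive a y_c; animals whose EBV
    reliability falls below the threshold are removed.
    """
    res = ebv.residuals
    if res.empty:
        raise DataError("no residuals available; fit the model first")
    if trait_kind == "repeated":
        per_animal = res.groupby("id")["residual"].mean()
    else:
        counts = res.groupby("id").size()
        if (counts > 1).any():
            raise DataError("single-record trait has repeated records")
        per_animal = res.set_index("id")["residual"]
    yc = ebv.ebv.loc[per_animal.index] + per_animal
    rel = ebv.reliability.loc[per_animal.index]
    keep = rel >= reliability_min
    table = pd.DataFrame({"id": per_animal.index[keep],
                          "y_c": yc[keep].to_numpy(),
                          "reliability": rel[keep].to_numpy()})
    return CorrectedPhenotypes(trait=trait, table=table.reset_index(drop=True))


def pooled_variance_components(records: pd.DataFrame, pedigree: Pedigree,
                               trait: str, kind: str,
                               measurement: str = "none") -> VarianceComponents:
    """One REML fit on the pooled records of every population.

    Herd is part of the HYS fixed-effect coding, so pooling does not mix
    contemporary groups; the pedigree relationship matrix is
    block-diagonal across closed populations.  Pooling stabilises the
    variance-ratio estimates that single small herds cannot support,
    especially for low-heritability reproduction traits.
    """
    ds = prepare_trait_dataset(records[records["trait"] == trait], trait, kind,
                               measurement)
    rec = ds.records
    y = rec["value"].to_numpy(dtype=float)
    X, _ = incidence(rec["hys"])
    from .relmat import a_matrix

    # restrict the pedigree to ancestors of phenotyped animals' populations
    Za, _ = incidence(rec["id"], pedigree.ids)
    A = a_matrix(pedigree)
    animal = RandomTerm(label="a", Z=Za, level_ids=list(pedigree.ids),
                        covariance=A.values)
    if kind == "repeated":
        other = identity_term("pe", rec["id"])
    else:
        other = identity_term("litter", rec["litter"])
    return reml(ModelSpec(y=y, X=X, terms=[animal, other]))


def corrected_phenotypes_per_population(records: pd.DataFrame, pedigree: Pedigree,
                                        trait: str, kind: str,
                                        measurement: str = "none",
                                        variance_components=None,
                                        estimate: bool = True) -> CorrectedPhenotypes:
    """Fit pedigree BLUP within each population and pool the y_c tables.

    When no variance components are supplied and ``estimate`` is set,
    they are REML-estimated once on the pooled data (see
    :func:`pooled_variance_components`) and reused for every
    population's BLUP fit.
    """
    meta = pedigree.table.set_index("id")
    vc = variance_components
    if vc is None:
        if not estimate:
            raise DataError("supply variance components or set estimate=True")
        vc = pooled_variance_components(records, pedigree, trait, kind,
                                        measurement)
    tables = []
    for pop in sorted(meta["population"].unique()):
        pop_ids = set(meta.index[meta["population"] == pop])
        rec_pop = records[records["id"].isin(pop_ids) & (records["trait"] == trait)]
        if rec_pop.empty:
            continue
        sub_ped = Pedigree(pedigree.table[pedigree.table["id"].isin(pop_ids)].copy())
        ds = prepare_trait_dataset(rec_pop, trait, kind, measurement)
        fit = fit_pedigree_blup(ds, sub_ped, variance_components=vc)
        tables.append(derive_yc(fit, trait, kind).table)
    if not tables:
        raise DataError(f"no populations with records for {trait!r}")
    return CorrectedPhenotypes(trait=trait,
                               table=pd.concat(tables, ignore_index=True))
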