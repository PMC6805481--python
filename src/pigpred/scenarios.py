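"""The experimental design: reference/validation splits and the
reference-set x method x panel accuracy grid.

Validation animals are the younger genotyped animals of one
population, selected by a birth-date split; reference animals are the
remaining phenotyped animals of the scenario's reference populations
(for across-population scenarios the validation population is excluded
from the reference entirely).  Each scenario fits its method on the
reference data only and reports the Pearson correlation between GEBV
and corrected phenotype in the validation set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assoc import FeatureSet, features_from_gwas, features_from_qtl, mlm_scan, \
    qtl_regions_from_table
from .core import DataError, GenotypePanel, Pedigree, RelationshipMatrix, pearson
from .mme import (ModelSpec, RandomTerm, genomic_term, intercept_model, reml,
                  solve_blup, fit_gfblup)
from .relmat import g_matrix, h_inverse, make_gw

log = logging.getLogger(__name__)

METHODS = ("GBLUP", "ssGBLUP", "GFBLUP_QTL", "GFBLUP_GWAS")


# ---------------------------------------------------------------------------
# population-structure PCA


def pca_structure(G: RelationshipMatrix | None = None,
                  panel: GenotypePanel | None = None, n_components: int = 10):
    """Principal components of the centred genomic relationship matrix.

    Returns ``(coords, shares)``: per-individual component coordinates
    and each component's fraction of total variance.  If more
    components are requested than individuals allow, the list is
    truncated with a log entry.
    """
    if G is None:
        if panel is None:
            raise DataError("supply a G matrix or a genotype panel")
        G = g_matrix(panel)
    n = len(G.ids)
    if n < 2:
        raise DataError("need at least two individuals for PCA")
    J = np.eye(n) - np.ones((n, n)) / n
    Gc = J @ G.values @ J
    vals, vecs = np.linalg.eigh(Gc)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    k = min(n_components, n - 1)
    if k < n_components:
        log.info("PCA truncated to %d components for %d individuals", k, n)
    total = vals.sum() if vals.sum() > 0 else 1.0
    coords = pd.DataFrame(vecs[:, :k] * np.sqrt(vals[:k]),
                          index=G.ids, columns=[f"PC{i + 1}" for i in range(k)])
    return coords, vals[:k] / total


# ---------------------------------------------------------------------------
# splits and scenarios


def split_validation(meta: pd.DataFrame, population: str, split_date: str,
                     reference_populations: list[str],
                     candidate_ids: list[str] | None = None):
    """Forward (birth-date) split into reference and validation ids.

    ``meta`` needs columns ``id, population, birth_date``.  Validation
    animals are those of ``population`` born strictly after
    ``split_date``; reference animals are the remaining animals of the
    reference populations (validation animals never appear there).
    """
    m = meta.copy()
    if candidate_ids is not None:
        m = m[m["id"].isin(set(candidate_ids))]
    dates = pd.to_datetime(m["birth_date"], errors="coerce")
    if dates.isna().any():
        raise DataError("birth dates missing or unparseable")
    cut = pd.Timestamp(split_date)
    val_mask = (m["population"] == population) & (dates > cut)
    validation = m.loc[val_mask, "id"].tolist()
    if not validation:
        raise DataError(f"empty validation set for {population} after {split_date}")
    ref_mask = m["population"].isin(reference_populations) & ~m["id"].isin(validation)
    if population not in reference_populations:
        ref_mask &= m["population"] != population
    reference = m.loc[ref_mask, "id"].tolist()
    return reference, validation


@dataclass(frozen=True)
class Scenario:
    """One cell of the accuracy grid."""

    trait: str
    reference_populations: tuple[str, ...]
    validation_population: str
    method: str
    panel: str  # chip | seq | seq_pruned
    split_date: str
    gwas_p_cutoff: float = 1e-3
    qtl_halfwidth_bp: int = 500_000

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise DataError(f"unknown method {self.method!r}")

    @property
    def reference_label(self) -> str:
        return "+".join(self.reference_populations)


@dataclass
class ScenarioResult:
    scenario: Scenario
    n_reference: int
    n_validation: int
    accuracy: float
    variance_components: dict[str, float] = field(default_factory=dict)
    note: str = ""


@dataclass
class DataBundle:
    """Everything a scenario needs: pedigree, panels, y_c, QTL regions."""

    pedigree: Pedigree
    panels: dict[str, GenotypePanel]
    yc: pd.DataFrame  # id, trait, y_c, reliability
    qtl_table: pd.DataFrame | None = None  # marker, chrom, pos, trait(, effect)
    cache: dict = field(default_factory=dict)  # per-panel G / H reuse

    def meta(self) -> pd.DataFrame:
        return self.pedigree.table[["id", "population", "birth_date"]]

    def yc_series(self, trait: str) -> pd.Series:
        sub = self.yc[self.yc["trait"] == trait]
        return sub.set_index("id")["y_c"]

    def qtl_regions(self, trait: str):
        if self.qtl_table is None:
            raise DataError("no QTL table in the bundle")
        t = self.qtl_table[self.qtl_table["trait"] == trait]
        table = pd.DataFrame({"chrom": t["chrom"], "start": t["pos"],
                              "end": t["pos"], "trait_category": t["trait"],
                              "source": "truth"})
        return qtl_regions_from_table(table)


def run_scenario(scenario: Scenario, bundle: DataBundle,
                 seed: int = 0) -> ScenarioResult:
    """Fit one method on the reference data and score the validation set."""
    panel = bundle.panels.get(scenario.panel)
    if panel is None:
        raise DataError(f"panel {scenario.panel!r} not in bundle "
                        f"(have {sorted(bundle.panels)})")
    yc = bundle.yc_series(scenario.trait)
    meta = bundle.meta()
    genotyped = set(panel.ids)

    ref_ids, val_ids = split_validation(
        meta, scenario.validation_population, scenario.split_date,
        list(scenario.reference_populations))
    val_ids = [a for a in val_ids if a in genotyped and a in yc.index]
    if not val_ids:
        raise DataError("no genotyped validation animals with y_c")
    ref_ids = [a for a in ref_ids if a in yc.index and a not in set(val_ids)]
    if scenario.method != "ssGBLUP":
        ref_ids = [a for a in ref_ids if a in genotyped]
    if len(ref_ids) < 10:
        raise DataError(f"reference set too small ({len(ref_ids)} animals)")

    if scenario.method == "ssGBLUP":
        result = _run_ssgblup(scenario, bundle, panel, yc, ref_ids, val_ids)
    elif scenario.method == "GBLUP":
        result = _run_gblup(panel, yc, ref_ids, val_ids, bundle.cache)
    else:
        result = _run_gfblup(scenario, bundle, panel, yc, ref_ids, val_ids)
    gebv_val, vc, note = result
    acc = pearson(gebv_val, yc.loc[val_ids].to_numpy())
    return ScenarioResult(scenario=scenario, n_reference=len(ref_ids),
                          n_validation=len(val_ids), accuracy=acc,
                          variance_components=vc, note=note)


def _run_gblup(panel, yc, ref_ids, val_ids, cache=None):
    both = ref_ids + val_ids
    key = ("G", panel.label, panel.n_markers)
    if cache is not None:
        # G over all panel animals (allele frequencies from the full
        # genotyped set) computed once per panel, then subset
        if key not in cache:
            cache[key] = g_matrix(panel)
        G = cache[key].subset(both)
    else:
        G = g_matrix(panel.subset_ids(both))
    y = yc.loc[ref_ids].to_numpy()
    term = genomic_term("g", ref_ids, G)
    model = intercept_model(y, [term])
    vc = reml(model)
    sol = solve_blup(model, vc)
    gebv = sol.series("g")
    return gebv.loc[val_ids].to_numpy(), _vc_dict(vc), ""


def _run_ssgblup(scenario, bundle, panel, yc, ref_ids, val_ids):
    ped = bundle.pedigree
    key = ("H", panel.label, panel.n_markers)
    if key in bundle.cache:
        parts, Hm = bundle.cache[key]
    else:
        genotyped = [a for a in panel.ids if a in set(ped.ids)]
        Gw = make_gw(panel.subset_ids(genotyped), ped)
        parts = h_inverse(ped, Gw, genotyped)
        # variance estimation uses dense H once; solving uses the parts
        H = np.linalg.inv(parts.assemble())
        Hm = RelationshipMatrix(ids=ped.ids, values=0.5 * (H + H.T), kind="H")
        bundle.cache[key] = (parts, Hm)
    y = yc.loc[ref_ids].to_numpy()
    vc = reml(intercept_model(y, [genomic_term("g", ref_ids, Hm)]))
    Zg, _ = _indicator(ref_ids, ped.ids)
    term = RandomTerm(label="g", Z=Zg, level_ids=list(ped.ids), inv_parts=parts)
    sol = solve_blup(ModelSpec(y=y, X=np.ones((y.size, 1)), terms=[term]), vc)
    gebv = sol.series("g")
    return gebv.loc[val_ids].to_numpy(), _vc_dict(vc), ""


def _run_gfblup(scenario, bundle, panel, yc, ref_ids, val_ids):
    both = ref_ids + val_ids
    sub = panel.subset_ids(both)
    ref_panel = panel.subset_ids(ref_ids)
    y_ref = yc.loc[ref_ids].to_numpy()
    note = ""
    if scenario.method == "GFBLUP_GWAS":
        scan = mlm_scan(y_ref, ref_panel)
        feat = features_from_gwas(scan, scenario.gwas_p_cutoff, scenario.trait)
    else:
        regions = bundle.qtl_regions(scenario.trait)
        feat = features_from_qtl(regions, panel, scenario.qtl_halfwidth_bp,
                                 trait_category=scenario.trait)
    if len(feat) == 0:
        note = "empty feature set; fell back to GBLUP"
        log.warning("%s", note)
        gebv, vcd, _ = _run_gblup(panel, yc, ref_ids, val_ids)
        return gebv, vcd, note
    sol, vc, ids = fit_gfblup(y_ref, ref_ids, feat.markers, sub)
    total = pd.Series(sol.total(["f", "r"]), index=ids)
    return total.loc[val_ids].to_numpy(), _vc_dict(vc), note


def _indicator(record_ids, level_ids):
    from .mme import incidence

    return incidence(record_ids, list(level_ids))


def _vc_dict(vc) -> dict[str, float]:
    d = {f"sigma2_{k}": float(v) for k, v in vc.sigma2.items()}
    d["sigma2_e"] = float(vc.sigma2_e)
    return d


# ---------------------------------------------------------------------------
# the grid


def default_scenarios(traits, populations, split_date, panels=("chip", "seq",
                                                               "seq_pruned"),
                      methods=METHODS,
                      validation_by_trait: dict | None = None) -> list[Scenario]:
    """The single / combined / across reference-set pattern per trait.

    For a validation population A and a companion population B the
    reference sets are {A}, {A, B} and {B} -- the within-population,
    combined-population and across-population rows of the accuracy
    tables.  ``validation_by_trait`` overrides which population
    validates a given trait (by default the first listed), mirroring
    how real studies pick the validation herd per trait from data
    availability.
    """
    pops = list(populations)
    validation_by_trait = validation_by_trait or {}
    out = []
    for trait in traits:
        val = validation_by_trait.get(trait, pops[0])
        others = [p for p in pops if p != val]
        ref_sets = [(val,), tuple([val] + others)] + [tuple(others)]
        for ref in ref_sets:
            for method in methods:
                for panel in panels:
                    out.append(Scenario(trait=trait, reference_populations=ref,
                                        validation_population=val, method=method,
                                        panel=panel, split_date=split_date))
    return out


def scenario_grid(scenarios: list[Scenario], bundle: DataBundle,
                  master_seed: int = 0) -> pd.DataFrame:
    """Run every scenario with a deterministic per-scenario child seed.

    Individual failures are recorded (NaN accuracy plus the error
    message) and the grid continues.  Returns a long-format frame; use
    :func:`pivot_grid` for the tables-style layout.
    """
    child_seeds = np.random.SeedSequence(master_seed).spawn(len(scenarios))
    rows = []
    for sc, ss in zip(scenarios, child_seeds):
        seed = int(ss.generate_state(1)[0] % (2 ** 31))
        try:
            res = run_scenario(sc, bundle, seed=seed)
            rows.append({
                "trait": sc.trait, "reference": sc.reference_label,
                "validation": sc.validation_population, "method": sc.method,
                "panel": sc.panel, "n_ref": res.n_reference,
                "n_val": res.n_validation, "accuracy": res.accuracy,
                "note": res.note,
            })
        except Exception as exc:  # noqa: BLE001 - grid keeps going
            log.warning("scenario %s failed: %s", sc, exc)
            rows.append({
                "trait": sc.trait, "reference": sc.reference_label,
                "validation": sc.validation_population, "method": sc.method,
                "panel": sc.panel, "n_ref": 0, "n_val": 0,
                "accuracy": float("nan"), "note": f"failed: {exc}",
            })
    return pd.DataFrame(rows)


def pivot_grid(grid: pd.DataFrame) -> pd.DataFrame:
    """Reference-set x method/panel layout mirroring the accuracy tables."""
    g = grid.copy()
    g["method_panel"] = g["method"] + "_" + g["panel"]
    return g.pivot_table(index=["validation", "reference", "method_panel"],
                         columns="trait", values="accuracy", aggfunc="first")
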