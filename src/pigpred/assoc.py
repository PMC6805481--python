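"""Mixed-linear-model association scan and GFBLUP feature sets.

The scan fits, per marker, ``y_c = 1*mu + Z g + x b + e`` with a
polygenic term ``g ~ N(0, G sigma2_g)``.  Variance components are
estimated once and reused across markers (the usual
population-parameters-previously-determined shortcut), and each
marker's effect gets a Wald p-value.  Feature sets for GFBLUP come
either from the scan (markers at or below a p-value cutoff) or from
QTL regions standardised to fixed windows around their midpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats

from .core import DataError, GenotypePanel, RelationshipMatrix
from .mme import VarianceComponents, genomic_term, intercept_model, reml
from .relmat import g_matrix

log = logging.getLogger(__name__)


def mlm_scan(y_c: np.ndarray, panel: GenotypePanel,
             G: RelationshipMatrix | None = None,
             include_polygenic: bool = True,
             vc: VarianceComponents | None = None) -> pd.DataFrame:
    """Marker-by-marker association scan on the reference animals.

    ``y_c`` must align with ``panel.ids`` (reference data only).  With
    ``include_polygenic=False`` the polygenic term is dropped and each
    test reduces to ordinary least squares.  Monomorphic markers are
    recorded with ``p = 1`` and flagged.

    Returns a frame with columns
    ``marker, chrom, pos, beta, se, p, monomorphic``.
    """
    y = np.asarray(y_c, dtype=float).ravel()
    n = panel.n_individuals
    if y.size != n:
        raise DataError("y_c length must match the panel's individuals")
    M = panel.imputed_dosages()

    if include_polygenic:
        Gm = G if G is not None else g_matrix(panel)
        if list(Gm.ids) != list(panel.ids):
            Gm = Gm.subset(list(panel.ids))
        if vc is None:
            vc = reml(intercept_model(y, [genomic_term("g", panel.ids, Gm)]))
        V = vc.sigma2["g"] * Gm.values + vc.sigma2_e * np.eye(n)
        c, low = sla.cho_factor(V, lower=True)
        Vi = sla.cho_solve((c, low), np.eye(n))
        scale_known = True
    else:
        Vi = np.eye(n)
        scale_known = False

    one = np.ones(n)
    Vi1 = Vi @ one
    Viy = Vi @ y
    W = Vi @ M  # n x m
    a11 = float(one @ Vi1)
    c1 = float(one @ Viy)
    a12 = one @ W  # per marker
    a22 = np.einsum("ij,ij->j", M, W)
    c2 = M.T @ Viy

    det = a11 * a22 - a12 ** 2
    mono = M.std(axis=0) == 0.0
    det_safe = np.where(mono | (det <= 0), np.nan, det)
    beta = (a11 * c2 - a12 * c1) / det_safe
    var_beta = a11 / det_safe
    if not scale_known:
        # OLS: scale by the per-marker residual variance estimate
        mu = (a22 * c1 - a12 * c2) / det_safe
        resid_ss = (y @ y) - mu * c1 - beta * c2
        var_beta = var_beta * resid_ss / max(n - 2, 1)
    se = np.sqrt(var_beta)
    z2 = (beta / se) ** 2
    p = stats.chi2.sf(z2, df=1)
    p = np.where(mono | np.isnan(p), 1.0, p)
    out = panel.markers[["marker", "chrom", "pos"]].copy()
    out["beta"] = np.where(mono, 0.0, beta)
    out["se"] = se
    out["p"] = p
    out["monomorphic"] = mono
    return out


@dataclass
class QtlRegion:
    """One QTL interval (1-based, inclusive)."""

    chrom: str
    start_bp: int
    end_bp: int
    trait_category: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise DataError("QTL region start must be <= end")
        self.chrom = str(self.chrom)

    @property
    def midpoint(self) -> int:
        return (self.start_bp + self.end_bp) // 2


@dataclass
class FeatureSet:
    """Marker ids defining a GFBLUP genomic feature."""

    markers: list[str]
    definition: str
    trait: str = ""

    def __len__(self) -> int:
        return len(self.markers)


def features_from_gwas(result: pd.DataFrame, p_cutoff: float,
                       trait: str = "") -> FeatureSet:
    """Markers with p <= cutoff; empty result signals a GBLUP fallback."""
    if not 0.0 < p_cutoff <= 1.0:
        raise DataError("p_cutoff must lie in (0, 1]")
    hits = result.loc[result["p"] <= p_cutoff, "marker"].tolist()
    if not hits:
        log.info("no marker passes p <= %g; caller should fall back to GBLUP",
                 p_cutoff)
    return FeatureSet(markers=hits, definition=f"gwas(p<={p_cutoff:g})",
                      trait=trait)


def features_from_qtl(regions: list[QtlRegion], panel: GenotypePanel,
                      bin_halfwidth_bp: int = 500_000,
                      trait_category: str | None = None) -> FeatureSet:
    """Markers inside standardized windows around QTL midpoints.

    Each region is replaced by ``[midpoint - h, midpoint + h]``
    (inclusive bounds on both ends); regions on chromosomes absent from
    the panel are skipped with a log entry.  Shared markers across
    overlapping windows appear once.
    """
    if trait_category is not None:
        regions = [r for r in regions if r.trait_category == trait_category]
    chroms = set(panel.markers["chrom"])
    pos = panel.markers["pos"].to_numpy()
    chrom_arr = panel.markers["chrom"].to_numpy()
    names = panel.markers["marker"].to_numpy()
    hits: set[str] = set()
    for r in regions:
        if r.chrom not in chroms:
            log.info("QTL region on chrom %s absent from panel; skipped", r.chrom)
            continue
        mid = r.midpoint
        lo, hi = mid - bin_halfwidth_bp, mid + bin_halfwidth_bp
        mask = (chrom_arr == r.chrom) & (pos >= lo) & (pos <= hi)
        hits.update(names[mask])
    ordered = [m for m in names if m in hits]
    return FeatureSet(markers=ordered,
                      definition=f"qtl(halfwidth={bin_halfwidth_bp})",
                      trait=trait_category or "")


def qtl_regions_from_table(table: pd.DataFrame) -> list[QtlRegion]:
    """Build regions from a (chrom, start, end, trait_category, source) frame."""
    return [QtlRegion(chrom=row["chrom"], start_bp=int(row["start"]),
                      end_bp=int(row["end"]),
                      trait_category=str(row.get("trait_category", "")),
                      source=str(row.get("source", "")))
            for _, row in table.iterrows()]
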