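"""Marker quality control and imputation-accuracy metrics.

QC removes non-autosomal markers, markers with MAF < 0.01 and markers
with call rate < 90% (in that order), then mean-imputes the remaining
missing dosages.  LD pruning removes one marker of every within-window
pair whose genotype correlation r^2 reaches the threshold (0.9 by
default).  Imputation accuracy is summarised per marker by the
genotype concordance rate (CR) and the squared Pearson correlation
between imputed and true dosages -- the empirical analogue of the
model-based allelic R-squared (AR2) an imputation program reports --
with MAF-binned means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AUTOSOMES, DataError, GenotypePanel, pearson

log = logging.getLogger(__name__)

#: variants below this truth-MAF are flagged and excluded from bin means
TRUTH_MAF_FLOOR = 9.9e-5


@dataclass
class QcReport:
    removed: dict[str, int]
    retained_markers: list[str]
    thresholds: dict[str, float]

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def qc_filter(panel: GenotypePanel, maf_min: float = 0.01,
              call_rate_min: float = 0.90,
              autosomes_only: bool = True) -> tuple[GenotypePanel, QcReport]:
    """Apply the chip/sequence QC filters in declared order."""
    removed = {"non_autosomal": 0, "maf": 0, "call_rate": 0}
    keep = np.ones(panel.n_markers, dtype=bool)
    if autosomes_only:
        auto = panel.markers["chrom"].isin(AUTOSOMES).to_numpy()
        removed["non_autosomal"] = int((~auto).sum())
        keep &= auto
    maf = panel.maf()
    low = keep & (maf < maf_min)
    removed["maf"] = int(low.sum())
    keep &= ~low
    cr = panel.call_rate()
    bad_cr = keep & (cr < call_rate_min)
    removed["call_rate"] = int(bad_cr.sum())
    keep &= ~bad_cr
    if not keep.any():
        raise DataError("no markers left after QC")
    out = panel.subset_markers(keep)
    out.dosages = out.imputed_dosages()
    report = QcReport(removed=removed, retained_markers=out.marker_ids,
                      thresholds={"maf_min": maf_min,
                                  "call_rate_min": call_rate_min})
    return out, report


def ld_prune(panel: GenotypePanel, r2_max: float = 0.9,
             window_markers: int = 50, step: int = 5,
             rule: str = "maf", seed: int | None = None
             ) -> tuple[GenotypePanel, QcReport]:
    """Greedy windowed LD pruning on genotype correlation.

    Within each sliding window (per chromosome, position-sorted), every
    pair with r^2 >= ``r2_max`` loses one member.  The default rule
    removes the lower-MAF marker (tie: the higher map index) for
    reproducibility; ``rule="random"`` picks a random member of the
    pair with the supplied seed.
    """
    if rule not in ("maf", "random"):
        raise DataError("rule must be 'maf' or 'random'")
    rng = np.random.default_rng(seed) if rule == "random" else None
    M = panel.imputed_dosages()
    maf = panel.maf()
    drop = np.zeros(panel.n_markers, dtype=bool)
    for chrom in panel.markers["chrom"].unique():
        idx = np.flatnonzero((panel.markers["chrom"] == chrom).to_numpy())
        idx = idx[np.argsort(panel.markers["pos"].to_numpy()[idx], kind="stable")]
        if len(idx) < 2:
            continue
        start = 0
        while start < len(idx):
            window = idx[start:start + window_markers]
            cols = np.array([j for j in window if not drop[j]])
            if len(cols) >= 2:
                Mw = M[:, cols]
                sd = Mw.std(axis=0)
                ok = sd > 0
                with np.errstate(invalid="ignore", divide="ignore"):
                    C = np.corrcoef(Mw[:, ok], rowvar=False)
                live = cols[ok]
                r2 = C ** 2
                np.fill_diagonal(r2, 0.0)
                for a_pos in range(len(live)):
                    ja = live[a_pos]
                    if drop[ja]:
                        continue
                    for b_pos in np.flatnonzero(r2[a_pos] >= r2_max):
                        if b_pos <= a_pos:
                            continue
                        jb = live[b_pos]
                        if drop[ja]:
                            break
                        if drop[jb]:
                            continue
                        if rng is not None:
                            victim = ja if rng.random() < 0.5 else jb
                        elif maf[ja] < maf[jb]:
                            victim = ja
                        elif maf[jb] < maf[ja]:
                            victim = jb
                        else:
                            victim = max(ja, jb)
                        drop[victim] = True
            if start + window_markers >= len(idx):
                break
            start += step
    out = panel.subset_markers(~drop, label=panel.label + "_pruned"
                               if not panel.label.endswith("_pruned") else panel.label)
    report = QcReport(removed={"ld_prune": int(drop.sum())},
                      retained_markers=out.marker_ids,
                      thresholds={"r2_max": r2_max,
                                  "window_markers": window_markers, "step": step})
    return out, report


# ---------------------------------------------------------------------------
# imputation metrics


#: MAF bins: 0.01-wide up to 0.05, then 0.05-wide up to 0.5
MAF_BIN_EDGES = np.concatenate([np.arange(0.0, 0.05, 0.01),
                                np.arange(0.05, 0.501, 0.05)])


@dataclass
class ImputationAccuracy:
    per_marker: pd.DataFrame  # marker, maf, cr, r2, flagged
    bins: pd.DataFrame  # bin_low, bin_high, mean_cr, mean_r2, n_markers

    @property
    def mean_cr(self) -> float:
        return float(self.per_marker.loc[~self.per_marker["flagged"], "cr"].mean())


def imputation_metrics(imputed: GenotypePanel, truth: GenotypePanel,
                       maf_floor: float = TRUTH_MAF_FLOOR) -> ImputationAccuracy:
    """Concordance rate and dosage r^2 per marker with MAF-binned means.

    CR is the fraction of identical hard genotypes (rounded dosages);
    r^2 is the squared Pearson correlation of imputed vs true dosages.
    Markers with truth MAF below ``maf_floor`` or zero-variance truth
    dosages are flagged and excluded from the bin means.
    """
    if imputed.marker_ids != truth.marker_ids or imputed.ids != truth.ids:
        raise DataError("imputed and truth panels must match in markers and ids")
    Mi = imputed.imputed_dosages()
    Mt = truth.imputed_dosages()
    hard_i = np.rint(Mi)
    hard_t = np.rint(Mt)
    cr = (hard_i == hard_t).mean(axis=0)
    maf = truth.maf()
    rows = []
    for j, mk in enumerate(truth.marker_ids):
        sd_t = Mt[:, j].std()
        flagged = maf[j] < maf_floor or sd_t == 0.0
        if flagged or Mi[:, j].std() == 0.0:
            r2 = np.nan
        else:
            r2 = pearson(Mi[:, j], Mt[:, j]) ** 2
        rows.append((mk, maf[j], cr[j], r2, flagged))
    per_marker = pd.DataFrame(rows, columns=["marker", "maf", "cr", "r2", "flagged"])
    usable = per_marker[~per_marker["flagged"]]
    bins = []
    edges = MAF_BIN_EDGES
    for lo, hi in zip(edges[:-1], edges[1:]):
        sub = usable[(usable["maf"] >= lo) & (usable["maf"] < hi)]
        bins.append((lo, hi, sub["cr"].mean(), sub["r2"].mean(), len(sub)))
    bins = pd.DataFrame(bins, columns=["bin_low", "bin_high", "mean_cr",
                                       "mean_r2", "n_markers"])
    return ImputationAccuracy(per_marker=per_marker, bins=bins)


def simulate_imputation_error(panel: GenotypePanel, base_error: float = 0.01,
                              maf_slope: float = 0.5,
                              seed: int | None = 0) -> GenotypePanel:
    """Corrupt a truth panel with an MAF-dependent imputation error model.

    With probability ``base_error + maf_slope * (0.5 - maf)`` a
    genotype is replaced by a Hardy-Weinberg draw at the marker's
    allele frequency -- rare variants are imputed worst, mirroring how
    imputation accuracy degrades as MAF decreases.
    """
    rng = np.random.default_rng(seed)
    M = panel.imputed_dosages().copy()
    p = panel.allele_freq()
    err = np.clip(base_error + maf_slope * (0.5 - panel.maf()), 0.0, 1.0)
    n = panel.n_individuals
    for j in range(panel.n_markers):
        hit = rng.random(n) < err[j]
        if hit.any():
            M[hit, j] = rng.binomial(2, p[j], size=int(hit.sum()))
    return GenotypePanel(ids=list(panel.ids), dosages=M,
                         markers=panel.markers.copy(),
                         label=panel.label + "_imputed")
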