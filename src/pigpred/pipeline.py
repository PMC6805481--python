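"""Glue from simulated (or loaded) raw data to a scenario-ready bundle.

Runs the corrected-phenotype step per trait and population, applies
marker QC and LD pruning to the sequence panel, and packages the chip,
sequence and pruned-sequence panels with the y_c table and the QTL
truth regions.
"""

from __future__ import annotations

import logging

import pandas as pd

from .core import Pedigree
from .marker_qc import ld_prune, qc_filter
from .scenarios import DataBundle
from .simpop import SimData
from .phenocorr import corrected_phenotypes_per_population

log = logging.getLogger(__name__)


def derive_all_yc(simdata: SimData, estimate_vc: bool = True) -> pd.DataFrame:
    """Corrected phenotypes for every trait, per population."""
    tables = []
    for spec in simdata.config.trait_specs:
        vc = None
        if not estimate_vc:
            from .mme import VarianceComponents

            other = "pe" if spec.kind == "repeated" else "litter"
            vc = VarianceComponents(
                sigma2={"a": spec.h2, other: spec.rep_or_litter_var_ratio},
                sigma2_e=1.0 - spec.h2 - spec.rep_or_litter_var_ratio,
                loglik=0.0, converged=True)
        corr = corrected_phenotypes_per_population(
            simdata.records, simdata.pedigree, spec.name, spec.kind,
            measurement=spec.measurement, variance_components=vc,
            estimate=estimate_vc)
        t = corr.table.copy()
        t.insert(1, "trait", spec.name)
        tables.append(t)
    return pd.concat(tables, ignore_index=True)


def assemble_bundle(simdata: SimData, estimate_vc: bool = False,
                    prune_r2: float = 0.9) -> DataBundle:
    """QC, prune, and derive y_c; returns the scenario-ready bundle.

    ``estimate_vc`` switches the pedigree-BLUP step from the trait
    specification's variance ratios to a fresh REML fit per population
    (slower; the analysis drivers use it, the simulation loops in the
    test-suite use the known ratios).
    """
    chip, _ = qc_filter(simdata.chip_panel)
    seq, _ = qc_filter(simdata.seq_panel)
    pruned, rep = ld_prune(seq, r2_max=prune_r2)
    log.info("LD pruning removed %d of %d sequence markers",
             rep.removed["ld_prune"], seq.n_markers)
    yc = derive_all_yc(simdata, estimate_vc=estimate_vc)
    return DataBundle(pedigree=simdata.pedigree,
                      panels={"chip": chip, "seq": seq, "seq_pruned": pruned},
                      yc=yc, qtl_table=simdata.qtl_table)


def study_config(seed: int = 1) -> "SimConfig":
    """The default simulated study design.

    A small validation herd (pop1) beside a larger companion population
    (pop2) of the same breed, mildly diverged (Fst ~ 0.05), sharing 50
    QTL; a 1500-marker sequence-density panel with a 250-marker
    evenly-spaced chip subset; four non-overlapping generations of
    which the last three are genotyped.
    """
    from .simpop import SimConfig

    return SimConfig(founders_per_pop=(60, 100), generations=4,
                     dams_per_sire=5, progeny_per_dam=4,
                     n_seq_markers=1500, n_chip_markers=250, n_qtl=50,
                     genotyped_generations=3, divergence=0.05,
                     seed=seed % (2 ** 31))


def default_split_date(simdata: SimData) -> str:
    """Split so the final simulated generation forms the validation set."""
    cfg = simdata.config
    return f"{cfg.base_year + cfg.generations - 1}-12-31"
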