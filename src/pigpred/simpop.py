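"""Synthetic multi-population pig breeding data.

Generates the statistical structure the prediction pipeline assumes:
two or more diverged populations of one breed, a multi-generation
pedigree with birth dates and herd-year-season structure, a
sequence-density marker panel with a chip-density subset, shared QTL
across populations, and repeated-record reproduction traits plus
single-record production traits with a litter effect.

Divergence follows the Balding-Nichols model: an ancestral frequency
``p0 ~ Uniform(0.1, 0.9)`` per marker, and per-population frequencies
drawn from a Beta distribution with mean ``p0`` and variance
``divergence * p0 * (1 - p0)``, so ``divergence`` acts as an Fst-like
knob.  Gene dropping uses Poisson recombination on a uniform genetic
map (default one Morgan per chromosome, i.e. ~1 cM/Mb on a 100-Mb
chromosome).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DataError, GenotypePanel, Pedigree

log = logging.getLogger(__name__)

# correction factors for adjusting production records to 100 kg
# (days-to-100kg and backfat; male, female) -- national-program constants
CF_AGE = {"male": 50.775, "female": 46.415}
CF_BFT = {"male": -7.277, "female": -9.440}


@dataclass
class TraitSpec:
    """One simulated trait.

    ``kind`` is ``"repeated"`` (reproduction trait, repeated records
    across parities, permanent-environment effect) or
    ``"single_record"`` (production trait, one record, litter effect).
    ``h2`` is the narrow-sense heritability on the adjusted-phenotype
    scale; ``rep_or_litter_var_ratio`` the permanent-environment (or
    litter) variance as a fraction of phenotypic variance.
    ``measurement`` optionally marks the trait as recorded off the
    100-kg scale: ``"age100"`` emits measured age/weight pairs and
    ``"bft100"`` measured backfat/weight pairs that must be adjusted
    back to 100 kg downstream.
    """

    name: str
    kind: str
    h2: float
    rep_or_litter_var_ratio: float = 0.10
    parities: int = 3
    mean: float = 0.0
    measurement: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in ("repeated", "single_record"):
            raise DataError(f"unknown trait kind {self.kind!r}")
        if not 0.0 < self.h2 < 1.0:
            raise DataError(f"h2 must lie in the open interval (0, 1); got {self.h2}")
        if not 0.0 <= self.rep_or_litter_var_ratio < 1.0:
            raise DataError("rep_or_litter_var_ratio must lie in [0, 1)")
        if self.h2 + self.rep_or_litter_var_ratio >= 1.0:
            raise DataError("h2 + rep_or_litter_var_ratio must be < 1")


def default_trait_specs() -> list[TraitSpec]:
    """Reproduction trait at h2 ~ 0.08 and production trait at h2 ~ 0.38.

    These anchor the heritability range reported for litter-size and
    days-to-100-kg traits in Yorkshire populations (0.07-0.09 and
    0.19-0.38 respectively).
    """
    return [
        TraitSpec(name="NBA", kind="repeated", h2=0.08,
                  rep_or_litter_var_ratio=0.10, parities=5, mean=11.0),
        TraitSpec(name="AGE", kind="single_record", h2=0.38,
                  rep_or_litter_var_ratio=0.10, mean=160.0, measurement="age100"),
    ]


@dataclass
class SimConfig:
    """Knobs for the synthetic breeding-data generator."""

    n_populations: int = 2
    founders_per_pop: int | tuple[int, ...] = 80
    generations: int = 4
    dams_per_sire: int = 4
    progeny_per_dam: int = 3
    n_chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    n_seq_markers: int = 4000
    n_chip_markers: int = 400
    n_qtl: int = 80
    divergence: float = 0.05
    map_length_morgan: float = 1.0
    founder_pool_haplotypes: int = 30  # ancestral haplotypes per population
    founder_segment_cm: float = 10.0  # mean mosaic segment length in founders
    founder_block_cm: float = 1.0  # LD-block scale of the ancestral pool
    chip_subset: str = "even"  # "even" (commercial-chip style) or "random"
    genotyped_generations: int = 3  # last k generations are genotyped
    hys_sd: float = 0.3  # SD of herd-year-season fixed effects (phenotypic SD units)
    base_year: int = 2010
    trait_specs: list[TraitSpec] = field(default_factory=default_trait_specs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chip_markers > self.n_seq_markers:
            raise DataError("n_chip_markers must be <= n_seq_markers")
        if self.n_qtl >= self.n_seq_markers:
            raise DataError("n_qtl must be < n_seq_markers")
        if self.divergence < 0 or self.divergence >= 1:
            raise DataError("divergence must lie in [0, 1)")
        if self.generations < 1:
            raise DataError("generations must be >= 1")
        if self.chip_subset not in ("even", "random"):
            raise DataError("chip_subset must be 'even' or 'random'")
        if len(self.founders_list()) != self.n_populations:
            raise DataError("founders_per_pop list must match n_populations")

    def founders_list(self) -> list[int]:
        """Founder count per population (a scalar applies to all)."""
        f = self.founders_per_pop
        if isinstance(f, (list, tuple)):
            return [int(x) for x in f]
        return [int(f)] * self.n_populations


@dataclass
class TrueGeneticValues:
    """Ground truth: QTL effects and per-animal true breeding values."""

    qtl_effects: dict[str, pd.Series]  # trait -> effect per QTL marker id
    tbv: pd.DataFrame  # index animal id, one column per trait


@dataclass
class SimData:
    """Everything one simulation run produces."""

    config: SimConfig
    pedigree: Pedigree
    seq_panel: GenotypePanel
    chip_panel: GenotypePanel
    records: pd.DataFrame  # phenotype records (long format)
    truth: TrueGeneticValues
    qtl_table: pd.DataFrame  # marker, chrom, pos, trait, effect

    @property
    def genotyped_ids(self) -> list[str]:
        return list(self.seq_panel.ids)


# ---------------------------------------------------------------------------
# founders


def _marker_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(config.n_chromosomes, config.n_seq_markers // config.n_chromosomes)
    per_chrom[: config.n_seq_markers % config.n_chromosomes] += 1
    rows = []
    k = 0
    for c in range(config.n_chromosomes):
        pos = np.sort(rng.integers(1, config.chrom_length_bp + 1, size=per_chrom[c]))
        # resolve position ties so the map is strictly increasing
        pos = np.maximum.accumulate(pos + np.arange(len(pos)))
        for p in pos:
            rows.append((f"m{k:06d}", str(c + 1), int(p), "A", "B"))
            k += 1
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos", "a1", "a2"])


def _ancestral_pool(pop_freq: np.ndarray, K: int, chrom_slices,
                    config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """K ancestral haplotypes whose allele counts match the target
    frequencies (randomized rounding).

    Which pool members carry the allele is decided by a ranking of the
    members that persists along the chromosome within blocks of mean
    length ``founder_block_cm``: markers inside one block have nested
    carrier sets, so tightly linked variants are in strong LD (as at
    sequence density in a real genome) while the marginal frequencies
    stay exactly on target.
    """
    m = pop_freq.size
    expect = K * pop_freq
    counts = np.floor(expect).astype(int)
    counts += (rng.random(m) < (expect - counts)).astype(int)
    pool = np.zeros((K, m), dtype=np.int8)
    cm_per_bp = config.map_length_morgan * 100.0 / config.chrom_length_bp
    for sl, pos in chrom_slices:
        chrom_cm = config.chrom_length_bp * cm_per_bp
        n_blocks = 1 + rng.poisson(chrom_cm / config.founder_block_cm)
        cuts = np.sort(rng.integers(1, config.chrom_length_bp + 1,
                                    size=n_blocks - 1))
        block = np.searchsorted(cuts, pos, side="right")
        ranks = np.empty((K, n_blocks), dtype=np.int64)
        for b in range(n_blocks):
            ranks[:, b] = rng.permutation(K)
        idx = np.arange(sl.start, sl.stop)
        pool[:, idx] = ranks[:, block] < counts[idx]
    return pool


def _mosaic_haplotype(pool: np.ndarray, markers: pd.DataFrame, chrom_slices,
                      config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """One founder haplotype as a recombinant mosaic of the pool."""
    K, m = pool.shape
    out = np.empty(m, dtype=np.int8)
    cm_per_bp = config.map_length_morgan * 100.0 / config.chrom_length_bp
    for sl, pos in chrom_slices:
        n_seg = 1 + rng.poisson(config.map_length_morgan * 100.0
                                / config.founder_segment_cm)
        cuts = np.sort(rng.integers(1, config.chrom_length_bp + 1,
                                    size=n_seg - 1))
        sources = rng.integers(K, size=n_seg)
        seg = np.searchsorted(cuts, pos, side="right")
        idx = np.arange(sl.start, sl.stop)
        out[sl] = pool[sources[seg], idx]
    return out


def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw founder haplotypes for each population.

    Returns ``(panel, populations, haplotypes, markers, pop_freqs)``
    where ``haplotypes`` has shape ``(n_founders, 2, n_markers)``.
    Ancestral frequencies are Uniform(0.1, 0.9); population frequencies
    are Balding-Nichols perturbations controlled by ``divergence``.
    Within each population, founder haplotypes are recombinant mosaics
    of a small ancestral pool, giving the within-population LD and
    background relatedness a closed nucleus herd carries (without it a
    chip panel could not tag QTL at all).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    markers = _marker_map(config, rng)
    m = len(markers)
    p0 = rng.uniform(0.1, 0.9, size=m)
    if config.divergence == 0.0:
        pop_freqs = np.tile(p0, (config.n_populations, 1))
    else:
        # Beta with mean p0 and variance d*p0*(1-p0): shape a = p0*(1-d)/d
        lam = (1.0 - config.divergence) / config.divergence
        pop_freqs = rng.beta(p0 * lam, (1.0 - p0) * lam,
                             size=(config.n_populations, m))
        bad = (pop_freqs <= 0) | (pop_freqs >= 1)
        if bad.any():
            warnings.warn("divergence pushed allele frequencies to the boundary; clipping")
            pop_freqs = np.clip(pop_freqs, 1e-6, 1 - 1e-6)
    chrom_slices = _chrom_slices(markers)
    n_fs = config.founders_list()
    haplos = np.empty((sum(n_fs), 2, m), dtype=np.int8)
    ids, pops = [], []
    row = 0
    for p in range(config.n_populations):
        pool = _ancestral_pool(pop_freqs[p], config.founder_pool_haplotypes,
                               chrom_slices, config, rng)
        for k in range(n_fs[p]):
            for h in range(2):
                haplos[row, h] = _mosaic_haplotype(
                    pool, markers, chrom_slices, config, rng)
            ids.append(f"P{p + 1}F{k:04d}")
            pops.append(f"pop{p + 1}")
            row += 1
    panel = GenotypePanel(ids=ids, dosages=haplos.sum(axis=1).astype(float),
                          markers=markers, label="seq")
    return panel, pops, haplos, markers, pop_freqs


def _chrom_slices(markers: pd.DataFrame):
    out = []
    for c in sorted(markers["chrom"].unique(), key=int):
        idx = np.flatnonzero((markers["chrom"] == c).to_numpy())
        out.append((slice(idx[0], idx[-1] + 1),
                    markers["pos"].to_numpy()[idx[0]: idx[-1] + 1]))
    return out


# ---------------------------------------------------------------------------
# pedigree drop-down


def _meiosis(haplo: np.ndarray, markers: pd.DataFrame, chrom_slices,
             config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a parent's two haplotypes with Poisson crossovers."""
    gamete = np.empty(haplo.shape[1], dtype=np.int8)
    for sl, pos in chrom_slices:
        n_x = rng.poisson(config.map_length_morgan)
        start = int(rng.integers(2))
        if n_x == 0:
            gamete[sl] = haplo[start, sl]
            continue
        cuts = np.sort(rng.integers(1, config.chrom_length_bp + 1, size=n_x))
        seg = start + np.searchsorted(cuts, pos, side="right")
        pick = (seg % 2).astype(np.int8)
        idx = np.arange(sl.start, sl.stop)
        gamete[sl] = haplo[pick, idx]
    return gamete


def simulate_pedigree_and_dropdown(config: SimConfig, founders, rng=None):
    """Drop founder haplotypes through a non-overlapping-generation pedigree.

    Each generation mates ``S`` sires to ``S * dams_per_sire`` dams with
    ``progeny_per_dam`` offspring per litter, where
    ``S = min(founder males, founder females // dams_per_sire)`` is held
    constant, so the total count is ``founders + generations * S * D * P``.
    Progeny sexes alternate within litters.  Birth years advance by one
    per generation with a random month so date-based validation splits
    are exercisable; herd equals population.
    """
    panel, pops, haplos, markers, _ = founders
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    m = len(markers)
    chrom_slices = _chrom_slices(markers)

    rows = []  # id, sire, dam, sex, birth_date, population, herd, generation
    all_haplos = [haplos]
    id_index: dict[str, int] = {}

    def add_animal(aid, sire, dam, sex, year, pop, gen):
        month = int(rng.integers(1, 13))
        day = int(rng.integers(1, 29))
        rows.append((aid, sire, dam, sex, f"{year:04d}-{month:02d}-{day:02d}",
                     pop, pop, gen))
        id_index[aid] = len(rows) - 1

    n_fs = config.founders_list()
    for p in range(config.n_populations):
        n_f = n_fs[p]
        for k in range(n_f):
            sex = 1 if k < n_f // 2 else 2
            add_animal(f"P{p + 1}F{k:04d}", "0", "0", sex, config.base_year,
                       f"pop{p + 1}", 0)

    new_haplos = []
    for p in range(config.n_populations):
        n_f = n_fs[p]
        n_males0 = n_f // 2
        n_fem0 = n_f - n_males0
        S = min(n_males0, n_fem0 // config.dams_per_sire)
        if S < 1:
            raise DataError("not enough founders for the requested mating structure")
        pop = f"pop{p + 1}"
        prev = [r for r in rows if r[5] == pop and r[7] == 0]
        for g in range(1, config.generations + 1):
            males = [r[0] for r in prev if r[3] == 1]
            females = [r[0] for r in prev if r[3] == 2]
            need_dams = S * config.dams_per_sire
            if len(males) < S or len(females) < need_dams:
                raise DataError(f"generation {g} of {pop}: not enough parents")
            sires = [males[i] for i in rng.permutation(len(males))[:S]]
            dams = [females[i] for i in rng.permutation(len(females))[:need_dams]]
            litter_rows = []
            for si, sire in enumerate(sires):
                for dj in range(config.dams_per_sire):
                    dam = dams[si * config.dams_per_sire + dj]
                    litter = si * config.dams_per_sire + dj
                    for k in range(config.progeny_per_dam):
                        sex = 1 if (k + litter) % 2 == 0 else 2
                        aid = f"P{p + 1}G{g}N{len(litter_rows):04d}"
                        add_animal(aid, sire, dam, sex, config.base_year + g, pop, g)
                        litter_rows.append((aid, sire, dam))
            # gametes
            gen_h = np.empty((len(litter_rows), 2, m), dtype=np.int8)
            for i, (aid, sire, dam) in enumerate(litter_rows):
                for j, parent in enumerate((sire, dam)):
                    ph = _get_haplo(parent, id_index, all_haplos, new_haplos,
                                    sum(n_fs))
                    gen_h[i, j] = _meiosis(ph, markers, chrom_slices, config, rng)
            new_haplos.append((pop, g, [r[0] for r in litter_rows], gen_h))
            prev = [rows[id_index[a]] for a, _, _ in litter_rows]

    # assemble haplotypes in pedigree row order
    full = np.empty((len(rows), 2, m), dtype=np.int8)
    full[: haplos.shape[0]] = haplos
    for pop, g, aids, gh in new_haplos:
        for i, aid in enumerate(aids):
            full[id_index[aid]] = gh[i]

    ped = Pedigree(pd.DataFrame(
        [r[:7] for r in rows],
        columns=["id", "sire", "dam", "sex", "birth_date", "population", "herd"],
    ))
    order = [id_index[a] for a in ped.ids]
    full = full[order]
    all_panel = GenotypePanel(ids=ped.ids, dosages=full.sum(axis=1).astype(float),
                              markers=markers, label="seq")
    return ped, all_panel, full


def _get_haplo(aid, id_index, all_haplos, new_haplos, n_founders):
    idx = id_index[aid]
    if idx < n_founders:
        return all_haplos[0][idx]
    for pop, g, aids, gh in new_haplos:
        try:
            return gh[aids.index(aid)]
        except ValueError:
            continue
    raise KeyError(aid)


# ---------------------------------------------------------------------------
# chip subset and QTL / phenotypes


def chip_subset(seq_panel: GenotypePanel, n_chip: int, mode: str = "even",
                rng: np.random.Generator | None = None) -> GenotypePanel:
    """Chip panel as a strict subset of the sequence panel markers.

    ``"even"`` picks markers evenly spaced by map order within each
    chromosome, mimicking commercial chip design; ``"random"`` draws a
    uniform subset.
    """
    m = seq_panel.n_markers
    if n_chip > m:
        raise DataError("chip size exceeds sequence panel")
    if mode == "random":
        rng = rng if rng is not None else np.random.default_rng(0)
        keep = np.sort(rng.choice(m, size=n_chip, replace=False))
    else:
        keep = np.unique(np.round(np.linspace(0, m - 1, n_chip)).astype(int))
    mask = np.zeros(m, dtype=bool)
    mask[keep] = True
    return seq_panel.subset_markers(mask, label="chip")


def assign_qtl_and_phenotypes(config: SimConfig, panel: GenotypePanel,
                              pedigree: Pedigree,
                              rng: np.random.Generator | None = None):
    """Sample QTL, build TBV, and emit phenotype records.

    QTL are drawn uniformly from the sequence markers per trait with
    standard-normal effects, then rescaled so the realized variance of
    TBV among phenotyped animals equals ``h2`` (phenotypic variance is
    1 on the adjusted scale).  Repeated traits produce ``parities``
    records per sow sharing a permanent-environment value, with
    herd-year-season fixed effects; single-record traits get one record
    per animal with a litter effect and herd-year-season-sex effects.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    ped_t = pedigree.table
    dosages = panel.dosages
    pos = {a: i for i, a in enumerate(panel.ids)}
    rows_order = np.array([pos[a] for a in ped_t["id"]])
    M = dosages[rows_order]  # pedigree order
    non_founder = (ped_t["sire"] != "0") | (ped_t["dam"] != "0")

    qtl_effects: dict[str, pd.Series] = {}
    tbv_cols = {}
    qtl_rows = []
    records = []
    birth = pd.to_datetime(ped_t["birth_date"])
    hys_cache: dict[tuple, float] = {}

    def hys_effect(key):
        if key not in hys_cache:
            hys_cache[key] = float(rng.normal(0.0, config.hys_sd))
        return hys_cache[key]

    # litters: dam + own generation group
    litter_of = ped_t["dam"].astype(str) + "/" + birth.dt.year.astype(str)
    litter_of = np.where(non_founder, litter_of, "founder")

    for spec in config.trait_specs:
        qtl_idx = np.sort(rng.choice(panel.n_markers, size=config.n_qtl, replace=False))
        eff = rng.normal(size=config.n_qtl)
        tbv_raw = M[:, qtl_idx] @ eff
        pheno_mask = non_founder.to_numpy().copy()
        if spec.kind == "repeated":
            pheno_mask &= (ped_t["sex"] == 2).to_numpy()
        sd = tbv_raw[pheno_mask].std()
        if sd == 0:
            raise DataError("degenerate QTL draw: zero TBV variance")
        scale = np.sqrt(spec.h2) / sd
        eff = eff * scale
        tbv = tbv_raw * scale
        tbv = tbv - tbv[pheno_mask].mean()
        qtl_effects[spec.name] = pd.Series(
            eff, index=panel.markers["marker"].to_numpy()[qtl_idx])
        tbv_cols[spec.name] = pd.Series(tbv, index=ped_t["id"].to_numpy())
        for j, e in zip(qtl_idx, eff):
            mk = panel.markers.iloc[j]
            qtl_rows.append((mk["marker"], mk["chrom"], mk["pos"], spec.name, e))

        var_env = 1.0 - spec.h2 - spec.rep_or_litter_var_ratio
        if spec.kind == "repeated":
            pe = rng.normal(0.0, np.sqrt(spec.rep_or_litter_var_ratio),
                            size=len(ped_t))
            for i in np.flatnonzero(pheno_mask):
                aid = ped_t["id"].iloc[i]
                herd = ped_t["herd"].iloc[i]
                for par in range(1, spec.parities + 1):
                    year = birth.iloc[i].year + par
                    month = int(rng.integers(1, 13))
                    date = f"{year:04d}-{month:02d}-15"
                    value = (spec.mean + hys_effect((spec.name, herd, year,
                                                     _season(month)))
                             + tbv[i] + pe[i]
                             + rng.normal(0.0, np.sqrt(var_env)))
                    records.append((aid, spec.name, par, litter_of[i], herd,
                                    int(ped_t["sex"].iloc[i]), date, value,
                                    np.nan, np.nan))
        else:
            lit_eff: dict[str, float] = {}
            for i in np.flatnonzero(pheno_mask):
                aid = ped_t["id"].iloc[i]
                herd = ped_t["herd"].iloc[i]
                lit = str(litter_of[i])
                if lit not in lit_eff:
                    lit_eff[lit] = float(rng.normal(
                        0.0, np.sqrt(spec.rep_or_litter_var_ratio)))
                rec_date = birth.iloc[i] + pd.Timedelta(days=160)
                sex = int(ped_t["sex"].iloc[i])
                adjusted = (spec.mean + hys_effect((spec.name, herd, rec_date.year,
                                                    _season(rec_date.month), sex))
                            + tbv[i] + lit_eff[lit]
                            + rng.normal(0.0, np.sqrt(var_env)))
                value, weight = _deadjust(adjusted, spec, sex, rng)
                records.append((aid, spec.name, 0, lit, herd, sex,
                                rec_date.strftime("%Y-%m-%d"), value,
                                weight, adjusted))

    rec = pd.DataFrame(records, columns=[
        "id", "trait", "parity", "litter", "herd", "sex", "record_date",
        "value", "measured_weight", "true_adjusted"])
    truth = TrueGeneticValues(qtl_effects=qtl_effects,
                              tbv=pd.DataFrame(tbv_cols))
    qtl_table = pd.DataFrame(
        qtl_rows, columns=["marker", "chrom", "pos", "trait", "effect"])
    return rec, truth, qtl_table


def _season(month: int) -> int:
    """Four seasons: 1 = Dec-Feb, 2 = Mar-May, 3 = Jun-Aug, 4 = Sep-Nov."""
    return {12: 1, 1: 1, 2: 1, 3: 2, 4: 2, 5: 2,
            6: 3, 7: 3, 8: 3, 9: 4, 10: 4, 11: 4}[month]


def _deadjust(adjusted: float, spec: TraitSpec, sex: int,
              rng: np.random.Generator):
    """Convert a 100-kg-scale value to a measured record off 100 kg.

    Inverts the national-program adjustment formulas so the downstream
    correction recovers the simulated value exactly.
    """
    if spec.measurement == "none":
        return adjusted, np.nan
    weight = float(rng.uniform(85.0, 130.0))
    key = "male" if sex == 1 else "female"
    if spec.measurement == "age100":
        cf = CF_AGE[key]
        measured = (weight * adjusted + (100.0 - weight) * cf) / 100.0
    elif spec.measurement == "bft100":
        cf = CF_BFT[key]
        measured = adjusted * (weight - cf) / (100.0 - cf)
    else:
        raise DataError(f"unknown measurement {spec.measurement!r}")
    return measured, weight


# ---------------------------------------------------------------------------
# one-call driver


def simulate(config: SimConfig) -> SimData:
    """Run the full generator: founders -> drop-down -> QTL/phenotypes."""
    rng = np.random.default_rng(config.seed)
    founders = simulate_founders(config, rng)
    ped, seq_panel, _ = simulate_pedigree_and_dropdown(config, founders, rng)
    records, truth, qtl_table = assign_qtl_and_phenotypes(
        config, seq_panel, ped, rng)
    chip = chip_subset(seq_panel, config.n_chip_markers, config.chip_subset, rng)
    gen_cut = config.generations - config.genotyped_generations
    genotyped = [a for a, s, d, b in zip(ped.table["id"], ped.table["sire"],
                                         ped.table["dam"], ped.table["birth_date"])
                 if int(b[:4]) - config.base_year > gen_cut]
    if not genotyped:
        genotyped = ped.ids
    return SimData(
        config=config,
        pedigree=ped,
        seq_panel=seq_panel.subset_ids(genotyped),
        chip_panel=chip.subset_ids(genotyped),
        records=records,
        truth=truth,
        qtl_table=qtl_table,
    )
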