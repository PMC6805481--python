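# Methods

`pigpred` re-creates, on simulated data, the full analysis chain used to
evaluate genomic prediction when reference populations of the same pig
breed but different genetic backgrounds are combined, and when
chip-density genotypes are replaced by (LD-pruned) sequence-density
genotypes. This note documents the models, the simulator, the numerical
choices, and the limitations a reader should keep in mind.

## Models

**Corrected phenotypes.** Raw production records (days to 100 kg, backfat)
are first adjusted to the 100-kg scale with the national-program
correction factors (AGE: CF 50.775 males / 46.415 females; BFT: −7.277 /
−9.440):

    AGE = age + (100 − w)·(age − CF)/w        BFT = bft + (100 − w)·bft/(w − CF)

Pedigree BLUP then supplies EBVs: a single-trait repeatability model for
reproduction traits (herd-year-season fixed effects; additive,
permanent-environment and residual random effects) and a univariate
animal model with a litter random effect for production traits
(herd-year-season-sex fixed effects). Season has four levels (Dec–Feb,
Mar–May, Jun–Aug, Sep–Nov); December is assigned to the following year's
winter so each winter is one level. The corrected phenotype is
y_c = EBV + mean(record residuals) for a sow with repeated records, and
y_c = EBV + residual for a single-record animal. Animals whose EBV
reliability 1 − PEV/σ²_a falls below 0.3 are removed. y_c, not the raw
record, is the response in all genomic models, which avoids
double-counting parental information.

The two production traits are fitted univariately rather than as a
bivariate pair: the downstream pipeline consumes per-trait y_c only, and
a genetic-correlation structure would add parameters the desk-scale data
cannot support.

**Relationship matrices.** A is built by the tabular method with
inbreeding; A⁻¹ by Henderson's rules with inbreeding coefficients from a
Meuwissen–Luo-style recursion (cross-checked against dense inversion).
G is VanRaden method 1, G = ZZ′/(2Σp(1−p)) with Z = M − 2p and p the
observed frequencies in the genotyped set; monomorphic markers are
dropped with a logged count. For single-step evaluation G is rescaled to
Ga = Gβ + α so that its average diagonal and off-diagonal match those of
A22 (the genotyped block of the full tabular A), blended as
Gw = 0.95·Ga + 0.05·A22 to avoid singularity, and assembled into

    H⁻¹ = A⁻¹ + [[Gw⁻¹ − A22⁻¹, 0], [0, 0]]

stored as parts (sparse A⁻¹ plus the dense genotyped-block correction);
an assembler produces the dense H⁻¹ on demand and dense H is never
formed inside the solver.

**Mixed models.** One engine covers all families. GBLUP:
y_c = 1μ + Zg + e with g ~ N(0, Gσ²_g). ssGBLUP replaces G by H so
non-genotyped phenotyped animals contribute; the MME use the H⁻¹ parts
directly. GFBLUP adds a second genomic effect: y_c = 1μ + Zf + Zr + e,
where G_f is built exactly like G from the feature marker set and G_r
from the complement; the reported genomic value is f̂ + r̂ (the total
genomic merit — how the two components combine for ranking is otherwise
unspecified, and their sum is the model's total genetic prediction).
Because G is kept as a scaled cross-product, s_f·G_f + s_r·G_r with
s = 2Σp(1−p) recombines to s·G exactly, which the tests assert.

**REML.** Variance components maximise the restricted likelihood.
Models with one random term besides the residual use an exact spectral
path: eigendecompose ZKZ′ once and profile the likelihood over the
variance ratio (grid plus bounded scalar refinement), which is fast and
deterministic. Multi-term models use AI-REML with step-halving; any
proposal that leaves the parameter space or lowers the likelihood falls
back to an EM-REML step, which provably never decreases it. Variances
are floored at 1e-8·var(y); components pinned at the floor with a
negative gradient are fixed at the boundary and re-enter if their
gradient turns positive. Convergence requires a relative log-likelihood
change below 1e-8 and either a parameter change below 1e-6 or a
near-zero gradient. For the H-based model the engine assembles a dense H
once (inverse of the assembled H⁻¹) for variance estimation only; at the
scales this package targets (a few thousand animals) that is cheap, and
the BLUP solve still goes through the parts.

Variance components for the corrected-phenotype step are REML-estimated
once on the pooled records of all populations and reused by each
population's BLUP fit. Herd is part of the HYS coding, so pooling mixes
no contemporary groups; single small herds cannot estimate an h² of
0.08 with useful precision (±0.04 at a few hundred sows), and a
per-herd estimate that noisy throws entire herds across the 0.3
reliability threshold.

**Association scan and features.** The scan fits, per marker,
y_c = 1μ + Zg + xb + e with the polygenic covariance G built once from
the scanned panel; variance components are estimated once and reused
for all markers (P3D), and each marker gets a Wald p-value. A flag
drops the polygenic term, reducing each test to OLS. Feature sets come
from the scan (markers at p ≤ cutoff, grid 1e-1…1e-7) or from QTL
regions standardised to ±100/500/1000 kb windows around region
midpoints (inclusive bounds, 1-based coordinates). The scan uses
reference animals only, and GFBLUP-GWAS features are re-derived from
each scenario's own reference set. Leave-one-chromosome-out kinship is
not used; the proximal-contamination bias this admits is accepted and
shared by all scenarios.

**Marker QC and imputation metrics.** QC removes, in order,
non-autosomal markers, markers with MAF < 0.01 and markers with call
rate < 0.90, then mean-imputes residual missing genotypes. LD pruning
removes one member of every within-window pair with genotype r² ≥ 0.9
(window 50 markers, step 5 — the window parameters are a package
default, configurable). The removed member is the lower-MAF marker
(tie: higher map index) for reproducibility; a seeded random-victim
mode matches the looser "random pair" description. Imputation accuracy
is summarised per marker by the genotype concordance rate CR and by the
squared Pearson correlation between imputed and true dosages. The
latter is the empirical analogue of a model-based allelic R² — true
posterior-based AR2 cannot be recomputed without genotype
probabilities, and the label makes the distinction explicit. Markers
with truth-MAF below 9.9e-5 are flagged and excluded from the MAF-bin
means (bins 0.01-wide to 0.05, then 0.05-wide to 0.5).

**Scenario evaluation.** Validation animals are the genotyped animals
of one population born after a split date; reference animals are the
remaining y_c-carrying animals of the scenario's reference populations
(the validation population is excluded entirely in across-population
scenarios; GBLUP/GFBLUP references are restricted to genotyped
animals, ssGBLUP references keep all). Accuracy is the raw Pearson
correlation between GEBV and y_c in the validation set, not divided by
√h². Variance components are re-estimated per scenario from its own
reference data. Grid runs derive one child seed per scenario from a
master seed; per-panel G and H are cached across scenarios.

## The simulator

The generator supplies the statistical structure the analysis assumes,
with ground truth for parameter-recovery tests.

* **Populations.** Balding–Nichols divergence: ancestral frequency
  p₀ ~ U(0.1, 0.9) per marker; each population's frequency is Beta with
  mean p₀ and variance d·p₀(1−p₀), so `divergence` = d is an Fst-like
  knob (verified against Hudson's estimator on founders, d = 0.1
  recovered within ±0.03).
* **Within-population LD.** Each population's founder haplotypes are
  recombinant mosaics (mean segment 10 cM) of a pool of 30 ancestral
  haplotypes whose allele-carrier assignments persist along the
  chromosome in ~1 cM blocks. Marginal frequencies stay exactly on
  target (randomized-rounding allele counts), while tightly linked
  variants get the strong LD of sequence data and the population gets
  the background relatedness of a closed nucleus herd. Without this, a
  chip panel cannot tag QTL at all and chip-based prediction collapses
  to zero — the single most important realism ingredient here.
* **Pedigree.** Non-overlapping generations; S sires × S·D dams × P
  progeny per litter with S = min(founder males, founder females ÷ D)
  held constant, so the animal count is founders + G·S·D·P exactly.
  Progeny sexes alternate within litters. Meioses place Poisson
  crossovers on a uniform 1 cM/Mb map (1 Morgan per 100-Mb
  chromosome). Birth years advance one per generation with random
  months, so date-based forward validation splits work. Herd equals
  population.
* **Panels.** The chip is an evenly spaced (by map order) strict subset
  of the sequence panel, mimicking commercial chip design; a random
  subset is available. The last `genotyped_generations` generations
  are genotyped.
* **Traits.** QTL are drawn uniformly from sequence markers per trait
  (so most QTL are absent from the chip) with normal effects shared
  across populations, rescaled so the realised var(TBV) among
  phenotyped animals equals h² on a unit phenotypic variance.
  Reproduction traits (default h² = 0.08, repeatability ratio 0.10,
  five parities) give sows repeated records with herd-year-season
  effects and a permanent-environment term; production traits (default
  h² = 0.38, litter ratio 0.10) give every non-founder animal one
  record with herd-year-season-sex effects and a full-sib litter
  effect. AGE-type traits are emitted as measured age/weight pairs off
  the 100-kg scale by inverting the adjustment formula, so the
  correction step is exercised end to end. HYS effects are N(0, 0.3²)
  per level.
* **Imputation error model.** A truth panel is corrupted by replacing
  each genotype, with probability base + slope·(0.5 − MAF), by a
  Hardy–Weinberg draw at the marker's frequency: rare variants impute
  worst, reproducing the accuracy-versus-MAF shape.

**The default study** (`pigpred.pipeline.study_config`): a small herd
(60 founders) beside a larger one (100 founders), four generations
(1440 animals, 960 genotyped), 1500 sequence markers with a 250-marker
chip subset, 50 shared QTL per trait, divergence 0.05. Note that the
knob sets founder-level Fst; four generations of drift in closed herds
roughly double the realised value (≈0.10 here), which is itself
realistic for unconnected farms.

## What the simulation does and does not show

Passing tests demonstrate that the machinery is correct (matrix
identities, solver dualities, estimator calibration) and that the
qualitative study findings emerge under the assumed data-generating
process: a combined reference helps a small single reference when QTL
are shared; across-population prediction benefits from a panel carrying
the causal variants; imputation-style dosage r² rises with MAF;
single-step evaluation beats genotyped-only GBLUP when many phenotyped
animals are ungenotyped. They do not show that real accuracy values are
reproduced: the real populations are orders of magnitude deeper (73k
pedigree animals, 19M imputed variants), real LD decays continuously
rather than in pool blocks, there is no selection in the simulated
pedigree, and the LD pruning that removes 78% of real sequence variants
removes only a few percent here. Absolute accuracies are therefore not
comparable to the published tables; directions and orderings are.

## Numerical choices and degenerate inputs

* Dense symmetric solves (Cholesky) throughout; desk scale keeps every
  matrix below a few thousand rows. A22 is extracted from the full
  tabular A, honouring pedigree depth.
* The Ga rescaling system is singular when avg.diag(G) equals
  avg.offdiag(G); this raises an explicit error.
* A feature G_f with fewer markers than animals is rank-deficient; the
  solver's GLS path (û = σ²KZ′Py) handles it without inverting K, and
  the MME path is reserved for terms with an inverse representation.
* An empty GWAS feature set falls back to GBLUP with a logged note; a
  feature covering all markers removes the remainder term rather than
  flooring its variance.
* Monomorphic scan markers get p = 1 and a flag. Zero-variance truth
  dosages make r² undefined; such markers are flagged and excluded from
  bin means.
* Reliabilities are clipped to [0, 1]; EBVs scale linearly with the
  phenotype and reliabilities are scale-invariant (tested).
* Same seed, same outputs, byte-identical on disk (tested on the grid
  and the CLI writers).

## Known limitations

* The reliability ≥ 0.3 filter is knife-edged for the h² = 0.08 trait at
  this scale: terminal-generation sows sit near 0.3, so their pass rate
  swings with the REML draw. The analysis therefore validates the
  reproduction trait on the larger herd. Real evaluations with deep
  pedigrees do not sit on this edge.
* P3D (one variance-component fit per scan) slightly misstates
  per-marker variances relative to exact per-marker REML; the type-I
  error calibration test bounds the practical effect.
* The repeatability model treats parity effects as part of HYS rather
  than a separate fixed effect; the national-program model is not
  public, and the HYS-only form is the common published variant.
* No genotype imputation is performed — imputed panels come from the
  error model or external tools; the metrics module only scores them.
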