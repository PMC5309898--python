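# Methods

This note documents the statistical model behind each module, the defaults
that matter, what the synthetic data do and do not emulate, and the design
decisions taken where the analysis left genuine choices.

## Quartet statistics (`site_patterns`)

All quartet statistics are frequency-based. With derived-allele frequencies
(p1, p2, p3, p4) over (P1, P2, P3, outgroup), each segregating site carries
fractional pattern weights ABBA = (1−p1)p2p3(1−p4) and
BABA = p1(1−p2)p3(1−p4); a site at (0, 0.5, 1, 0) therefore counts as half
an ABBA site. Sites with any required group entirely missing are skipped
per statistic (complete-case).

**Sign convention.** D = (ΣBABA − ΣABBA)/(ΣBABA + ΣABBA), so positive D
means excess sharing between P1 and P3. This is deliberately the opposite
orientation from the Durand/Martin literature (which writes ABBA − BABA
with P2 as the sharing partner): here P1 is the hybrid radiation throughout
the D analyses, while the fd scan follows the fd literature's ordering
(P2 = recipient). The CLI takes explicit role names to avoid silent
misordering.

**Uncertainty.** Standard errors come from a weighted delete-one block
jackknife over contiguous blocks of 500 sites within scaffolds (the block
size is configurable; 500 sites is a compromise between block count and
within-block linkage at the simulator's default site density). Blocks are
weighted by size; for equal-size blocks the estimator reduces to the
textbook delete-one jackknife, which is how the tests validate it.
|z| ≥ 3 is flagged significant.

**F4 ratio.** For (((A,B)C)O) and hybrid X, α = f4(A,O;X,C)/f4(A,O;B,C),
where f4 is the mean per-site product of frequency differences. If
pX = α·pB + (1−α)·pC per site, the ratio's expectation is exactly α; drift
and sampling noise in X and B enter numerator and denominator symmetrically,
so the ratio-of-sums estimator is consistent. Since the choice of the
reference population A materially affects precision, `f4_ratio_sweep`
ranks candidate A populations by jackknife SE instead of hard-coding one.

## Five-population directional test (`fivepop`)

Single individuals are haploidized (one random allele at heterozygous
sites, re-drawn per tested combination from a seeded generator). Per site
without missing data, each ingroup allele is coded derived when it differs
from the outgroup allele. The eight patterns over ((P1,P2),(P3a,P3b)),O
feed four partitioned D statistics:

    D1  = (BABAA−ABBAA)/(BABAA+ABBAA)
    D2  = (BAABA−ABABA)/(BAABA+ABABA)
    D12 = (BABBA−ABBBA)/(BABBA+ABBBA)
    D3  = (BBBAA−BBABA)/(BBBAA+BBABA)

The D1/D2 completion follows the Eaton & Ree partitioned-D orientation and
is isolated in one function (`partitioned_d`) so the mapping can be revised
in one place. z-scores come from 100 bootstrap replicates resampling all
usable sites with replacement (implemented as a multinomial resample of the
per-site pattern classification, which is equivalent and fast). The
direction call: significant positive D12 with non-significant D3 → gene
flow P3→P1; significant D3 with non-significant D12 → P1→P3a (positive) or
P1→P3b (negative); both significant → ambiguous. A significant *negative*
D12 (sharing with P2, outside the tested directions) is reported ambiguous.

A caveat the simulations make visible: donor-side gene flow (P3a→P1)
leaves a small residual D3 proportional to the drift accumulated between
P3a and P3b since their split. At very large site counts this residual
becomes statistically significant and the call degrades to "ambiguous" —
a property of the statistic, not an implementation artefact. The test's
discrimination is therefore best when the within-pair splits are shallow
relative to the deep split, which is also the study system's situation.

## Window statistics (`window_scan`)

Windows are 0-based half-open; VCF input positions are 1-based; tracts are
emitted in BED convention. Terminal partial windows keep their nominal
span.

**fd** (10-kb default): S_obs = Σ(ABBA−BABA) with P2 the recipient;
S_max re-computes the weights with the donor set per site to whichever of
P2/P3 has the higher derived frequency. Windows with weighted pattern total
< 5 are missing; windows with negative D are set to 0 (only positive fd is
interpretable); fd is clamped to [0, 1]. The integer-phrased thresholds
("less than five", "exceeding one") are applied to the real-valued weighted
totals as ≥ 5 and > 1.

**Ancestry painting** (3-kb default): ABBA weight (1−pC)·pT·pN·(1−pO) vs
BBAA weight pC·pT·(1−pN)·(1−pO); windows with ABBA proportion ≥ 0.7 paint
as minor-parent (upper_nile) ancestry, ≤ 0.3 as major-parent (congolese);
weighted total ≤ 1 → no data. Scaffolds are dropped when the span of their
data-bearing windows is under 100 kb (configurable; "span with data" is the
reading adopted for the scaffold-length filter). Tract merging joins
consecutive same-colour windows, bridges exactly one interior no-data
window, and treats unassigned windows as breaks; tract ends exclude
trailing bridged windows.

**Expected tract length**: 1/((1−m)·r·t) bp for minor-ancestry proportion
m, recombination rate r per bp per generation and t generations since
admixture — 500 bp to 1 kb at m = 0.2, r = 2.5×10⁻⁸, t = 50,000–100,000.

## Allele sorting (`allele_sorting`)

Per-SNP FST is the multi-population Weir–Cockerham (1984) θ computed from
called genotype counts (negative estimates retained). The outlier null is a
deliberate simplification of hierarchical-island outlier machinery: a
neutral finite-island simulation (Balding–Nichols deme frequencies around a
uniform ancestral frequency, HWE genotype sampling at the observed sample
sizes) matched to the data's multi-locus θ by the method of moments, with
one-tailed P values computed within heterozygosity bins of equal null
occupancy. An empirical top-quantile mode is available for pipelines
without simulation. The simplification preserves the scientific content —
a one-tailed P < 0.05 high-FST flag conditioned on heterozygosity — without
reconstructing any specific legacy tool configuration.

Ancestry categories are evaluated on radiation-polymorphic SNPs with at
least 3 called individuals in each parental lineage, and are implemented
as **disjoint** (the enrichment figure logic requires it): (2) major parent
polymorphic; (3) major parent monomorphic, minor parent polymorphic;
(4) the parents fixed for alternative alleles; (1) one parental allele only.
An optional nested view (category 4 as the subset of 3) is exposed via a
flag. "Fixed" means all observed alleles identical among the called
individuals — no frequency tolerance, which is the honest reading at these
sample sizes. The weighted control frequency is folded to
min(f, 1−f) because the 14–18 % window is on the minor allele; the window
bounds are inclusive.

## Synthetic data (`synthetic_data`)

The generator is a drift-plus-tracts model, not a coalescent: ancestral
frequencies are uniform on (0.05, 0.95); lineages and daughter species
drift by Balding–Nichols draws; local ancestry along the chromosome is a
two-state Markov process with exponential tract lengths of mean
1/((1−α)·r·t) (minor) and 1/(α·r·t) (major). This reproduces every
statistical structure the analyses consume — frequency correlations with
tree topology, admixture-proportion expectations, tract-length laws,
divergently fixed loci — while staying fully deterministic under one seed.
Defaults are the study conditions: α = 0.2, r = 2.5×10⁻⁸, t = 100,000
generations, parental drift F = 0.2 on each side of the deep split,
10 diploids per group, 50,000 SNPs on a 20-Mb scaffold, outgroup fixed
ancestral at every site (so the alternate allele is the derived allele and
polarization is exact in tests).

What it does **not** emulate: linkage disequilibrium beyond the ancestry
tracts, genotyping error, reference bias, variable recombination or
mutation rate, selection beyond the optional BDM-sorting flag, and gene
flow after the initial pulse. Passing tests therefore demonstrate
correctness of the statistics under their own model assumptions, not
robustness to those real-data complications.

Three focused generators reuse the same machinery at the scale each check
needs:

* `simulate_quartet` — iid-site quartet with an optional frequency-level
  P3→P1 pulse; used for D-statistic type-I calibration (the jackknife z is
  conservative against the 5 % budget at |z| ≥ 3) and power.
* `simulate_fivepop_quintet` — single-diploid quintet with one-way
  introgression at the haplotype level; 50,000 sites by default, the scale
  at which all three directions are recovered reliably while the residual
  D3 discussed above stays below significance.
* `simulate_sorting_dataset` — frequency-level radiation (no tracts):
  species drift from the swarm frequency q0 = (1−α)pC + αpN with one drift
  law applied identically to every site. This makes neutral divergently
  fixed sites and the frequency-matched control set *exchangeable by
  construction* (both start at minor frequency α = 0.16), which is the
  exact null needed to verify the enrichment test's type-I behaviour; the
  BDM mode replaces the drift at fixed sites with a much larger variance
  (F ≈ 0.5), emulating sorting toward alternative fixation. Parental
  sample sizes default to 5 (major) and 9 (minor) diploids, the study's
  parental panel sizes.

For ancestry-painting checks, `shared_species_tracts=True` fixes one tract
realization per species (ancestry sorted to fixation within species), the
regime in which window painting of a diploid is informative; with
independent haplotypes, heterozygous-ancestry regions paint as unassigned,
which the tests also exercise.

The category classifier's agreement with the simulated truth depends on
parental sample size through rare-allele detection: under the default
frequency spectrum it reaches ~92 % at 20 diploids per parental group and
crosses 95 % at 50, which is the size the recovery test uses.

## Pipeline (`pipeline`, `cli`)

One config (YAML/JSON) drives simulate → filter → D/f4 → fivepop →
fd/blocks → sort-alleles with per-stage parameter blocks; defaults bake in
the analysis constants (|z| = 3, 100 bootstraps, 10-kb/5-pattern fd
windows, 3-kb/0.7/0.3/>1 ancestry windows, 0.84/0.16 weights, 14–18 %
control window, P < 0.05 outliers). The report records the package version,
a config hash, per-stage outputs, summary statistics and wall-clock time;
all randomness derives from the root seed through fixed per-stage
substreams, so re-running a config reproduces every statistic exactly.

## Numerical choices and degenerate inputs

* Zero ABBA+BABA totals, empty complete-case site sets, and ~0 f4
  denominators (|·| < 10⁻¹²) raise an undefined-statistic error rather
  than returning NaN silently; per-statistic NaN is used where the result
  object carries several statistics (partitioned D).
* Polarization uses the outgroup major allele as ancestral; exact 0.5/0.5
  outgroup ties and fully missing outgroups mark a site unpolarizable
  (excluded from polarized analyses).
* A zero bootstrap s.d. with nonzero D reports an infinite z with a
  warning; a control pair with no fixed differences reports Fisher p = 1
  with a warning; filters that remove every site warn and return an empty
  result.
* Depth filtering defaults to off (`min_depth=None`): depth thresholds are
  normally applied during variant calling, and different sub-analyses have
  historically used different cutoffs, so the threshold is exposed
  per-analysis instead of fixed globally.

## Problem sizes

Test-suite simulations use 2,000–50,000 sites and 1–50 diploids per group;
the acceptance script uses 20 replicates of 50,000 sites × 10 diploids.
These sizes were chosen so each check's sampling error is comfortably
below the tolerance it asserts.

## Known limitations

* The finite-island outlier null assumes equal deme sizes and a single F;
  strongly unbalanced sampling or hierarchical structure in real data
  would require extending the null.
* Pattern-count operations assume accurate outgroup polarization; ancestral
  misidentification is not modelled.
* The fd scan uses group allele frequencies; with a single diploid as
  recipient the frequencies take values {0, 0.5, 1}, which is supported but
  noisier per window.
* Tract painting resolution is bounded below by the window size (3 kb);
  true tracts shorter than a window are invisible, as the tract-length
  trend tests document.
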