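# Methods

## Scope and model

`halfsibsim` simulates closed recurrent-selection programs for diploid,
cross-pollinated species. An individual is two 0/1 haplotypes over a linkage
map; a trait is controlled by biallelic QTL with per-locus values
`AA -> +a`, `Aa -> d`, `aa -> -a`, summed over loci. Epistasis is
deliberately excluded (constructing a system with a nonzero epistatic
connectivity is an error, not a silent fallback), as are mutation,
migration, polyploidy and genotype-by-environment deviations: one
environment type is simulated, so all non-genetic variation enters through
a single plant-level residual.

## Genetic system

- **Map.** The default synthetic map places 63 QTL and 194 markers on 7
  linkage groups of 100 cM (the perennial-ryegrass karyotype), positions
  uniform within groups, counts split across groups by integer division.
  Marker loci segregate and recombine but carry no effects; they are
  excluded from Hamming-distance and fixation statistics, which are defined
  by favorable alleles.
- **Effects.** `a ~ N(0,1)` i.i.d. Dominance degrees are
  `d = u·|a|·sign(a)` with `u ~ U(0,1)` (partial) or `u ~ U(1,2)` (over);
  tying `sign(d)` to `sign(a)` keeps the favorable allele well defined at
  every locus. Model composition is a deterministic count split
  (round-half-up) assigned over a random permutation of loci: it makes
  "50% additive" exact per table rather than Bernoulli-approximate, at no
  cost to the effect distribution. Effects are used as drawn; no rescaling
  to a target genetic variance is applied.
- **Meiosis.** Haldane mapping function without interference: the
  transmitted strand switches between adjacent loci with probability
  `r = (1 - exp(-2·Δd/100))/2`, linkage groups assort independently. This
  is the simplest standard model consistent with a plain cM map; it will
  understate linkage drag relative to maps with crossover interference.
- **Founders.** Each founder carries exactly `⌊L/2⌋` heterozygous loci (a
  fresh random subset, random phase) and homozygous loci split evenly
  between the two classes (odd remainder to a coin-flipped class), so every
  locus starts at frequency 0.5 in expectation with heterozygosity 0.5 —
  the Hardy–Weinberg proportions for p = 0.5 after the first polycross.

## Families, trials and heritability

A crossing block of k parents is polycrossed into k half-sib families: each
member is the female of one family, and every progeny's male parent is
redrawn uniformly from the other k−1 members, so selfs never occur and the
pollen cloud is even in expectation. Families supply exactly the plants the
trial needs (`n_total = years·locations·reps·plants_per_plot`); no separate
selection nursery is simulated.

Phenotypes are `P = G + N(0, σ²_R)` per plant. The design cells carry no
systematic effects, so `σ²_R` pools all among- and within-plot error. It is
solved once, on the first cycle's families, from the target family-mean
heritability:

```
σ²_R = max(0, n_total·σ²_b·(1−h²)/h² − σ²_w)
```

with `σ²_b` the variance of true family genotypic means and `σ²_w` the mean
within-family genotypic variance, and then held fixed, so realized
heritability erodes as selection exhausts genetic variance — the intended
behavior of a trial protocol that does not change as the population
improves. A `recalibrate_each_cycle` flag exists for sensitivity analyses.

**Scaled-down trials.** Runtime scales with plants per cycle, so the
package's desk-scale experiments shrink the plot while keeping the
3-year × 3-location structure, recalibrating σ²_R at the reduced `n_total`
so the family-mean heritability target still holds. Consequence worth
knowing: σ²_R shrinks roughly proportionally to `n_total`, so per-plant
records get *more* accurate as the trial shrinks while the within-family
selection intensity (5 kept of `n_total`) gets weaker. Family-mean-driven
results (AHS dynamics, realized h²_fm) are invariant to this scaling in
distribution; within-family selection (the AWHS "best 5") is somewhat
stronger at reduced plot sizes than at the full 810 plants. Problem sizes
used by `scripts/acceptance.py`: 270 plants/family (3·3·3·10) for the
cycles-to-ΔG90 experiments at 10 replicate runs; 90 plants/family (3·3·1·10)
for the end-of-run Hamming panels (AWHS, h² = 0.9, N ∈ {50, 100}, 10 runs,
the panels where the across-scenario minimum is attained); the full
54-scenario ordering check in the test suite uses 30 plants/family and
paired seeds.

## Selection strategies

Both strategies advance `round_half_up(k·0.2)` families (minimum one) by
phenotypic family mean, ties broken toward the lower family index. AHS
keeps 5 random plants per advanced family; AWHS keeps the 5 best by
individual plant phenotype from the trial records — phenotypic, not
genotypic, since a breeder cannot observe G. With 20% × 5 the parental
population size is restored exactly for k ∈ {10, 50, 100}. The crossing
block is fully replaced by default; partial replacement overwrites a random
subset of slots and preserves block size.

Per cycle, the reported mean genotypic value averages *all* plants of the
advanced families (never a sampled representative); Hamming distance and
fixation rates are computed on the new crossing block. ΔG% normalizes
between-cycle gains by (ideal − founder mean); the ΔG90 *cycle* — the first
cycle reaching 90% of the 50-cycle cumulative gain — is invariant to any
positive affine normalization, which the suite tests explicitly. The
ΔG90-per-cycle rate divides the ΔG90 value by the cycles needed to reach
it (a cost-benefit rate: how much of the 90% gain each cycle bought), not
by the run length. Runs with no net gain report ΔG90 = 0 at cycle 0 and
are retained, not discarded.

## Experiment layer and reproducibility

The case-study factorial crosses 2 strategies × 3 genetic models × 3
heritabilities × 3 population sizes = 54 scenarios. Per run, fresh QTL
effects and founders are drawn; the synthetic map is fixed per scenario by
default (lower between-run variance) with a `per_run` mode available, since
a published map would be fixed but ours is itself random. Run-level
generators derive from `SeedSequence([base_seed, scenario_index,
run_index])`, making results independent of execution order and
byte-reproducible (the suite checks identical `summary.tsv` for identical
seeds). Failed runs are logged and excluded, with the completed-run count
recorded per scenario.

## What the generator does and does not emulate

The synthetic map spreads loci uniformly over equal-length groups. Real
forage maps cluster QTL and vary chromosome lengths; clustering increases
hitchhiking, which speeds the exhaustion of genetic variance and raises
end-of-run Hamming distance. Pooling all field error into one plant-level
residual likewise removes the within-plot error cancellation that makes
plant-vs-plant comparisons inside a plot more accurate than the pooled
variance implies. Both simplifications leave direction-level conclusions
intact — AWHS outperforms AHS everywhere, higher heritability accelerates
gain, larger populations preserve diversity, and Hamming distances order
additive < additive-dominance < dominance — but absolute cycle counts to
ΔG90 come out slower, and final Hamming distances cleaner, than a program
on a real clustered map with plot-structured error would show. Passing
tests therefore certify the machinery and the directional science, not
field-calibrated absolute timelines.

## Numerical choices and degenerate inputs

- Haplotypes are uint8 arrays `(n, 2, L)`; meiosis is vectorized with an
  XOR-scan over per-interval switch indicators, so one gamete costs one
  uniform draw per locus.
- Family counts and selected-family counts use round-half-up (never
  banker's rounding); at least one family always advances.
- A crossing block of one is rejected (selfing excluded leaves no pollen
  source). `h² = 0` is rejected (infinite noise); `h² = 1` clamps σ²_R to 0.
- Ties in within-family best-k selection resolve toward the lower plant
  index; exact-zero additive effects (probability zero under N(0,1)) would
  treat allele 1 as favorable.
- Result files are written with `%.17g` floats and read back with
  round-trip parsing, so series survive a disk round trip bit-exactly.

## Known limitations

Single environment type (no GE), no epistasis, no genomic or
marker-assisted selection, no reciprocal recurrent selection, diploid only,
no mutation or migration, balanced trials only. The ΔG% normalization
constant is a convention; compare ΔG90 *values* only within one
normalization, while cycle counts are normalization-free.
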