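# Methods

`matekin` analyses mate choice in socially monogamous birds from three data
streams: diploid microsatellite genotypes, MHC class I allele-presence
profiles, and brood records linking social parents to chicks. The question
it answers is whether observed pairings and offspring are more (or less)
genetically similar than expected if the year's reproductive adults had
paired at random.

## Statistics

**Internal relatedness (IR).** For a genotype with N typed loci, H of them
homozygous, and reference frequency f_i for each of the 2N allele copies,

    IR = (2H − Σ f_i) / (2N − Σ f_i).

IR is 1 iff fully homozygous and goes negative for heterozygotes carrying
rare alleles; offspring of genetically similar parents have elevated IR.
The sum runs over all 2N copies (so a fully heterozygous rare-allele
genotype is strongly negative); this reading is pinned by a brute-force
oracle in the tests. Missing loci drop out of H, N and the sum. IR requires
every observed allele to have positive reference frequency, so the
reference sample must contain the scored individuals or a superset.

**Pairwise relatedness (r).** The symmetric Queller–Goodnight estimator.
Per locus, for x = (a,b) against y = (c,d) with identity indicator I and
reference frequencies p:

    num_x = ½(I_ac + I_ad + I_bc + I_bd) − p_a − p_b
    den_x = 1 + I_ab − p_a − p_b

multilocus weighting is ratio-of-sums (Σ num / Σ den over loci), and
r = (r_x + r_y)/2. For unbiasedness the reference frequencies are
recomputed with the focal dyad excluded. Loci missing in either member, or
with both directional denominators zero (monomorphic), are dropped.
Expectation: 0.5 for parent–offspring, 0 for unrelated dyads; both are
verified by Mendelian simulation at 12 loci × 10 equifrequent alleles.

**MHC allele-sharing (D).** Passerine MHC class I co-amplifies several
duplicated loci, so genotypes are treated as allele-presence sets and
similarity as D = 2|a∩b| / (|a|+|b|) ∈ [0,1].

**Marker panel summary.** Per locus: allele count k, typed sample N,
observed heterozygosity, unbiased expected heterozygosity
2n/(2n−1)·(1−Σp²), and a Monte Carlo exact Hardy–Weinberg test. The HWE
statistic is the conditional probability of the genotype table given the
allele counts (computed as h·ln2 − Σ ln n_g!); the p-value is the add-one
corrected fraction of allele permutations with a table at most as probable
(default 10,000 permutations, seedable). A permutation test was preferred
over chi-square because microsatellite panels carry many rare alleles.

## Paternity assignment

For each chick, every genotyped adult male on the year's roster is scored
with the log likelihood ratio

    LOD = Σ_l ln[(1−ε)·T(g_c|g_m,g_f) + ε·P(g_c)]
        − Σ_l ln[(1−ε)·T(g_c|g_m) + ε·P(g_c)]

where T are Mendelian transition probabilities (paternal allele from the
candidate, vs from the population), P(g_c) the Hardy–Weinberg genotype
probability, and ε a per-locus genotyping-error rate under a simple mixture
model (with probability ε the observed genotype is a random HWE draw). The
mixture model is monotone in ε and reduces exactly to the pure Mendelian
ratio at ε = 0, which is how it is pinned in the tests (enumeration
oracle). When the mother is untyped at a locus, or Mendelian-incompatible
with the chick there, the motherless forms are used (dam marginalised over
population frequencies). With ε = 0 an excluded candidate scores −∞ rather
than raising.

Confidence is calibrated by simulation: offspring of known sires are
generated (true sire inside the pool with probability
`prop_candidates_sampled`, default 0.9 — the study systems this emulates
capture most but not all breeding males), all candidates scored, and
Δ = LOD(best) − LOD(second best) recorded. The strict threshold is the
smallest Δ at which ≥95% (configurable) of above-threshold best candidates
are the true sire; 10,000 simulated offspring by default. A chick whose
best male clears the strict threshold is assigned; an assigned sire other
than the brood's social father makes the chick extra-pair; everything else
is unassigned and excluded from extra-pair-specific denominators (but kept
in all-chick statistics).

Allele frequencies for paternity include genotyped chicks (as likelihood
software conventionally estimates frequencies from the full data file), so
every chick allele has positive frequency. The maternal-mismatch screen
flags chicks sharing no allele with the recorded mother at >2 loci; a brood
where every chick mismatches points to a colour-band misread rather than
brood parasitism.

## The random-mating null

Each of B iterations (default 1000) re-pairs every year's roster — females
without replacement (a female holds one nest), males with replacement (a
male can sire several females' young); both schemes are configurable — and
recomputes the statistic; iterations are pooled across years. Empirical
p-values use the add-one correction p_high = (1+#{null ≥ obs})/(B+1), and
both tails are always reported.

For chick-level statistics the null regenerates the observed number of
chicks *and mating pairs*: each social pair keeps its observed chick count,
and each chick keeps its observed extra-pair status — extra-pair chicks
draw an independent random sire other than the unit's social male. A
brood-level null that gives all of a unit's chicks a single father
under-disperses the observed statistic once extra-pair rates are
substantial (measured sd of the observed-vs-null z at 40% EPP: ≈0.83) and
makes the test noticeably conservative; preserving the mating-pair
structure restores calibration (type-I rate 0.035–0.055 at α = 0.05 over
200-dataset blocks). Without paternity assignments the engine degrades to
the brood-level null.

Under the default frequency reference (genotyped adults + chicks, needed
for allele coverage) observed chicks are scored leave-one-out — each
chick's own two copies per locus are removed from the counts before its
frequencies are taken — so in-sample observed chicks and out-of-sample
simulated chicks are on the same footing. With a user-supplied frequency
table the observed value uses it verbatim.

The three statistics (mean offspring IR, mean pair r, mean pair D) share
one pairing engine. Scopes select the observed entities: all chicks,
within-pair or extra-pair chicks, social pairs, or genetic pairs (female ×
assigned sire(s); with several sires per breeding event the per-sire values
are averaged within the event first).

## Synthetic populations

The generator emulates a small closed island passerine population:

| parameter | default | meaning |
| --- | --- | --- |
| `years` | 3 | breeding seasons; adults persist across years |
| `n_males`, `n_females` | 100, 100 | adults per sex |
| `n_pairs` | 40 | monitored social pairs per year |
| `n_loci` | 12 | microsatellite panel size |
| `alleles_per_locus` | 8–21 | per-locus allele count, drawn uniformly |
| `freq_concentration` | 1.0 | Dirichlet concentration of founder frequencies (gives Hexp ≈ 0.85 at k ≈ 14) |
| `n_sib_groups` | 0 | founders drawn as full-sib families (kin structure) |
| `theta` | 0 | social-mate preference: P(pair) ∝ exp(θ·r_true) |
| `epp_rate` | 0.4 | per-chick probability the sire is not the social male |
| `clutch_size` | 2–5 | eggs laid, uniform |
| `hatch_prob`, `fledge_prob` | 0.9, 0.7 | per-egg / per-chick Bernoulli |
| `n_mhc_alleles` | 37 | population-wide MHC variant pool |
| `missing_rate` | 0.02 | per-individual per-locus missing typing |

The preference kernel acts on *true pedigree* relatedness (0.5 within a
founder sib family, else 0), not on any estimator, so estimator noise stays
part of every downstream test. Extra-pair sires are uniform among other
males by default; `theta_ep` biases them by exp(θ_ep·r_true). MHC profiles
are inherited as haplotype halves: each parent transmits a random half
(rounded up) of its allele set, approximating multi-locus haplotype
transmission without modelling unresolvable locus structure. Chick
genotypes are Mendelian; missing typing is applied on top, so the recorded
data can hide a transmitting parent's allele — realistic, and the reason
the default frequency reference includes chicks.

What the generator does **not** emulate: spatial nest structure, adult
turnover/survival between years, within-year repeat clutches as separate
records, linkage between loci, null alleles or allele-specific genotyping
error, and MHC copy-number variation beyond the presence-set abstraction.
Passing tests therefore demonstrate correctness of the estimators and the
inference machinery under the stated model, not robustness to those
real-data complications.

## Numerical and design choices

- All randomness flows from numpy `Generator` objects; the pipeline spawns
  named substreams from one master seed, so full runs are byte-identical
  given the seed.
- Empirical p-values are never 0 (add-one correction).
- In Δ calibration, when the second-best LOD is −∞ (all rivals excluded)
  Δ = LOD(best) − 0; a single-male pool is handled the same way and warned
  about. If every simulated assignment already meets the confidence level
  the threshold is 0.
- Monomorphic loci: Hexp = 0, HWE p = 1; they are dropped from r (both
  denominators zero) and contribute 0 to LOD sums only through their
  (deterministic) transition probabilities.
- r(x, x) returns 1 by the algebraic identity num ≡ den, sidestepping the
  degenerate double-exclusion of a self-dyad.
- Problem sizes in the test suite and acceptance script (3 years ×
  15 pairs/year, 40+40 adults) sit inside the 15–49 monitored-pairs-per-year
  range the generator targets, and keep a full calibration run on one CPU
  in minutes.

## Known limitations

- The error model is a per-locus mixture, not an allele-level mistyping
  model; ε is a tuning knob, not an estimate of a lab error process.
- The rosters define "reproductive" adults as observed social parents plus
  assigned genetic sires; adults captured but never seen breeding are
  excluded unless `--all-adults` / `include_all_adults` widens the roster.
- The null test conditions on the observed extra-pair pattern; it tests
  *who* pairs with whom, not the extra-pair rate itself.
- GenePop files carry genotypes only; sex, stage, MHC and brood structure
  always enter through the CSV tables.
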