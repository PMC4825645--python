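# Methods

## Transmission model

Individuals are synchronous self-fertilizing hermaphrodites. A genotype is
an unordered map from allele id to dosage (0, 1, 2); parental origin is not
tracked because under selfing both gametes come from the same parent.
Loci are treated as unlinked and independent — linkage is never invoked by
the screen's inferential logic, and no map information exists for the
induced alleles — so multi-locus offspring distributions are products of
per-locus marginals: a heterozygous locus segregates {mm: 1/4, m+: 1/2,
++: 1/4}, homozygous loci transmit deterministically. Conditioning the
selfed offspring distribution on survival of an embryonic lethal
renormalizes the surviving classes and yields the 2 carrier : 1 wild-type
adult ratio that anchors the screen's segregation tests. The exact
distribution (`self_cross_distribution`) is verified in the test suite
against an independent brute-force enumeration of all 4^L ordered gamete
pairs for up to three loci.

## Allele classes and their expression

Each induced recessive allele has one functional class:

- **ZYGOTIC_LETHAL** — a homozygous embryo expresses the phenotype and dies
  before viability scoring with probability equal to the allele's
  *penetrance*; non-expressing homozygotes survive unlabelled.
- **STERILE_TYPE_I** (maternal effect) — an expressing homozygous mother
  lays fertilized eggs (perivitelline halo present) that are 100%
  nonviable, regardless of embryo genotype.
- **STERILE_TYPE_II** (non-egg-layer) — an expressing homozygous mother
  deposits no eggs at all.
- **VISIBLE_VIABLE** — homozygotes show a visible phenotype (e.g. golden
  yolk) with probability = penetrance but remain viable and fertile.

Sterility expression is drawn once per adult at maturity. A heterozygous
Type I mother expresses the maternal effect with probability
*maternal_dominance* (default 0). This models partial dominant maternal
effects: with dominance d, the sterile fraction among offspring of a
carrier is 1/4 + d/2 rather than the Mendelian 1/4, reproducing families
in which more than half — in the extreme all — reared offspring of a
carrier are sterile. Whether a family showing both Type I and Type II
sterility carries one pleiotropic allele or two alleles is biologically
open; the generator supports both (one allele per class, or any mix via
the class-probability map).

## The simulated screen

Generations follow P → F1 → F2 → F3 → F4. Each of the 47 founder families
draws a Poisson number of induced alleles; every F1 is heterozygous for all
of its genome's alleles (screened lineages are founded by fertile F1 fish
by construction). F2 fish are reared from the F1's selfed clutches, F3
embryos are scored from every adult F2 hermaphrodite, and in families where
a sterile F2 was found, F3 cohorts are reared from the fertile siblings and
their F4 clutches scored — the data backward genotyping consumes.

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| families | 47 | size of the confirmation screen |
| allele load | Poisson(0.575)/genome | with the class split below, P(≥1 zygotic lethal) = 1 − e^(−0.2875) ≈ 25%, the screen's zygotic hit rate |
| class probabilities | lethal 0.5, Type I 0.2, Type II 0.1, visible 0.2 | lethals dominate observed classes; both sterile types occur, Type I more often |
| penetrance range | (1.0, 1.0) | clean Mendelian conditions; observed per-family mutant fractions of 5–69% are emulated by widening the range |
| maternal dominance | 0 | simple recessive default; > 0 reproduces the high-sterile-fraction families |
| F2 cohort per family | uniform 2–13 | the screened per-family range |
| primary males | Bernoulli 3.6% per reared fish | the screen's printed male fraction (10/307 computes to 3.26%; the printed 3.6% is used); no genetic model of male determination exists, so the draw is genotype-independent |
| clutch size | Poisson(4) truncated at 25 per session | over a 24-session window this accumulates ~100 embryos per fish, matching per-fish means of 21–32 embryos |
| sessions | 3/week; eggless window 24 sessions | "no eggs for over two months" discretized at three collections per week |
| rearing survival | 0.9 | per-embryo hazard applied at rearing only (not during later clutch collection), the simplest censoring model |
| background nonviable / unfertilized rates | 0 / 0 | clean conditions by default; real clutches show substantial background nonviability, and both rates are configurable nuisance parameters |

All randomness flows from one `numpy` Generator seeded by the
configuration; reruns are byte-identical at the table level.

## Classification rules

Per parent, clutches are pooled across sessions. The calls, in order:

1. **Type I sterile** — ≥ 20 embryos scored and ≥ 90% nonviable or
   unfertilized. The 0.90 threshold is applied to the pooled fraction with
   no background correction.
2. **Type II sterile** — zero embryos over ≥ 24 observed sessions. The two
   sterile calls are mutually exclusive by construction (≥ 20 embryos vs
   none).
3. **Zygotic carrier** — a fertile fish with ≥ 2 embryos showing one of the
   family's phenotype labels. The original screen states no numeric
   threshold ("multiple carrier parents produced embryos displaying the
   same or new phenotypes"); ≥ 2 of ≥ 20 is this package's documented
   choice, keeping the analytic false-negative rate at
   P(≤1 mutant in 20 | p = 1/4) ≈ 2.4% while suppressing single-embryo
   mis-scores.
4. **Backward genotyping** — a parent with ≥ 1 sterile reared offspring is
   a carrier of the sterile allele (the call is never emitted without
   sterile evidence); a parent whose ≥ 8 reared offspring are all fertile
   is wild-type (residual miss probability 0.75⁸ ≈ 10%, consistent with the
   screen's own 90% framing); anything less stays */+. Fertile offspring of
   a confirmed sterile-allele carrier also stay */+ — they cannot be told
   apart from carriers without rearing their own progeny — while offspring
   of a backward-confirmed wild-type parent keep their wild-type call.

Fish with some data but not enough for any criterion are INDETERMINATE;
primary males are set aside before classification and excluded from
segregation counts. Family categories are the union of confirmed mutation
types ("Zygotic", "Sterile I/zygotic", "Sterile I and II/zygotic not
confirmed", ...).

## Design calculations

Detecting ≥ 1 homozygote among n independent individuals succeeds with
probability 1 − (1 − p)ⁿ, p = 1/4 under selfing and 1/16 under random
gonochoristic intracrosses. Two cohort-sizing conventions are offered:
STRICT (the exact probability must reach the target — the default for new
designs) and NEAREST_PERCENT, which compares probabilities rounded to the
nearest percent. The second exists because the classical printed numbers —
8 selfing fish and 35 intracrosses at the 90% level — have exact detection
probabilities of 0.8999 and 0.8955, both short of a strict 0.90 but both
rounding to 90%; the convention is an inference, labelled as such.

## Goodness-of-fit conventions

Pearson χ² with df = classes − 1 and no continuity correction, as used in
the original analyses. Expected counts come in two modes: EXACT fractional
expecteds (default), and PUBLISHED_INTEGER, which rounds each expected count to
the nearest integer and repairs the largest cell so the total is preserved
(281 split 1:2 becomes 94 and 187). The integer mode exists solely to
reproduce the printed statistics exactly; the difference is in the third
decimal. The result object reports the statistic, critical value, p-value,
and a `consistent_with_ratio` boolean; the original tables describe tiny
χ² values as "rejecting the null hypothesis", an inverted wording this
package does not adopt — `reject_null` here is True only when χ² exceeds
the critical value.

Per-family sterile percentages are 100·s/(s + */+) among reared offspring
of carrier parents, missing when no such offspring exist. One published
family percent (R103: printed 53.5/53.6%) is inconsistent with its own
printed counts (21/(21+18) = 53.85%) and is excluded from the reproduction
suite, with the computed value reported alongside.

## What the synthetic data does and does not emulate

The generator reproduces the screen's statistical skeleton: Mendelian
segregation under selfing, embryonic lethality, both sterility types with
penetrance and maternal dominance, clutch-session structure, rearing loss,
primary males, and allele loss in small cohorts. It does not model
linkage or recombination, mutation during propagation, outcrossing to
primary males (androdiecy), developmental staging, environmental
plasticity of phenotypes, or dose–response of the mutagen. Passing
parameter-recovery tests therefore show the decision rules are correct
under the stated stochastic model, not that they are robust to, e.g.,
linked alleles or phenotype mis-scoring beyond the background rates.

## Problem sizes

The test suite and acceptance script use 10,000-embryo and 5,000-adult
simulations for stochastic checks (3-binomial-SD tolerances), 40–60-family
screens for classifier recovery, 1,000 fuzz cases for the χ² oracle
comparison, and exact enumeration up to three loci — sizes at which every
check completes in seconds while keeping Monte-Carlo error well inside the
tolerance bands.
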