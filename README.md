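# selfscreen

Gene-drop simulation and analysis of simultaneous zygotic/sterile
forward-genetic screens in a self-fertilizing hermaphroditic vertebrate.

The mangrove killifish (*Kryptolebias marmoratus*) is the only known
self-fertilizing hermaphroditic vertebrate, which makes it unusually
efficient for forward-genetic screens: a heterozygous carrier (*m/+*) of an
ENU-induced recessive allele produces homozygotes among its own selfed
offspring at the Mendelian rate of 1/4, one full generation earlier than a
gonochoristic model like zebrafish, where a random F2×F2 intracross yields
homozygotes at only (1/2)·(1/2)·(1/4) = 1/16. A single screen can therefore
confirm zygotic (embryonic-lethal) mutations and simultaneously discover
sterile mutants — maternal-effect "Type I" fish whose fertilized eggs all
arrest, and non-egg-layer "Type II" fish with ovotestis or anatomical
defects.

`selfscreen` is aimed at geneticists designing or analyzing such screens.
It provides:

- **`selfscreen.genetics`** — exact Mendelian transmission under selfing:
  a heterozygote segregates 1:2:1, and conditioning on survival of an
  embryonic lethal gives the 2 carrier : 1 wild-type adult ratio.
- **`selfscreen.simulate`** — a forward simulator of the whole
  P→F1→F2→F3→F4 screen: Poisson allele load per mutagenized genome,
  per-allele penetrance, partial dominant maternal effects, clutch
  collection over discrete sessions, rearing losses, and primary males.
- **`selfscreen.classify`** — the screen's decision rules: a fish is
  Type I sterile when ≥ 90% of ≥ 20 scored embryos are nonviable or
  unfertilized, Type II sterile when it lays nothing over a two-month
  window, a zygotic carrier when its clutches repeat the family phenotype;
  backward genotyping resolves a parent's genotype from its reared
  offspring, leaving honestly undetermined fish in the */+ class.
- **`selfscreen.design`** — cohort sizing: detecting at least one
  homozygote among *n* individuals succeeds with probability
  1 − (1 − p)ⁿ, so a 90% detection level needs 8 selfing fish (p = 1/4)
  versus 35 gonochoristic intracrosses (p = 1/16).
- **`selfscreen.stats`** — Pearson χ² goodness-of-fit against Mendelian
  ratios (with the integer-rounded-expecteds convention of the original
  screen's tables), per-family sterile percentages, and Sum/Mean/Range
  cohort tables.

## Worked example

Test the observed F2 segregation of 92 wild-type : 189 zygotic carriers
against the 1:2 ratio expected when homozygous mutants die as embryos:

```python
>>> from selfscreen import segregation_test, Rounding
>>> r = segregation_test([92, 189], [1, 2], Rounding.PUBLISHED_INTEGER)
>>> print(r.to_frame())
         Observed  Expected  (Obs-exp)^2/exp
class_0        92      94.0         0.042553
class_1       189     187.0         0.021390
Total         281     281.0         0.063944
>>> r.consistent_with_ratio, round(r.p_value, 3)
(True, 0.8)
```

χ² = 0.064 is far below the df = 1 critical value of 3.84: the counts are
consistent with simple recessive inheritance. Cohort sizing for a sterile
screen at the 90% detection level:

```python
>>> from selfscreen import min_individuals, Convention
>>> min_individuals(0.90, 0.25, Convention.NEAREST_PERCENT)   # selfing
8
>>> min_individuals(0.90, 1/16, Convention.NEAREST_PERCENT)   # gonochoristic
35
```

Simulate a 47-family screen, classify every adult, and write all tables:

```sh
selfscreen report --seed 1 --out runs/demo
selfscreen gof --observed 14,32 --ratio 1:2 --rounding published
selfscreen reproduce   # rerun the published-table reproduction suite
```

## File formats

Pedigree TSV (one row per fish; selfing needs a single parent column, so
standard two-parent pedigree formats do not apply): `fish_id`, `family_id`,
`generation` (P, F1–F4), `parent_id`, `role`, `status`,
`sessions_observed`, optional `true_genotype`/`true_class`. Clutch TSV (one
row per embryo): `embryo_id`, `parent_id`, `session_index`, `fertilized`
(0/1), `viable` (0/1), `phenotype_labels` (semicolon-joined). Missing
values are `.`. Configuration and classification thresholds are flat JSON
files; unknown keys are rejected.

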