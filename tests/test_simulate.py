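"""Forward screen simulation: clutch mechanics, rearing, sterility
expression, and whole-screen statistical structure."""

import numpy as np
import pytest

from selfscreen import (
    AlleleClass,
    Fish,
    Genotype,
    MutantAllele,
    ScreenConfig,
    rear_cohort,
    simulate_clutch,
    simulate_screen,
)
from tests.conftest import make_mother


def within_3sd(frac, p, n):
    return abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)


def collect_embryos(mother, alleles, config, rng, n_min):
    embryos = []
    session = 0
    while len(embryos) < n_min:
        embryos.extend(simulate_clutch(mother, session, alleles, config, rng).embryos)
        session += 1
    return embryos


class TestSimulateClutch:
    def test_type_ii_mother_lays_nothing(self, sterile_ii_allele, rng):
        mother = make_mother(Genotype.from_dosages({"t": 2}), expressed="STERILE_II")
        config = ScreenConfig()
        for s in range(24):
            assert simulate_clutch(mother, s, {"t": sterile_ii_allele},
                                   config, rng).size == 0

    def test_type_i_mother_lays_fertilized_nonviable(self, sterile_i_allele, rng):
        mother = make_mother(Genotype.from_dosages({"s": 2}), expressed="STERILE_I")
        config = ScreenConfig(clutch_size_mean=20)
        embryos = collect_embryos(mother, {"s": sterile_i_allele}, config, rng, 100)
        assert all(e.fertilized for e in embryos)
        assert not any(e.viable_at_score for e in embryos)

    def test_partial_penetrance_mutant_fraction(self, rng):
        """m/+ mother, penetrance 0.6: mutant fraction near 0.25 * 0.6."""
        allele = MutantAllele("m", AlleleClass.ZYGOTIC_LETHAL, "curly tail",
                              penetrance=0.6)
        mother = make_mother(Genotype.from_dosages({"m": 1}))
        config = ScreenConfig(clutch_size_mean=20)
        embryos = collect_embryos(mother, {"m": allele}, config, rng, 10_000)
        frac = np.mean([bool(e.phenotype_labels) for e in embryos])
        assert within_3sd(frac, 0.15, len(embryos))

    def test_clutch_counts_are_conserved(self, zygotic_allele, rng):
        mother = make_mother(Genotype.from_dosages({"m": 1}))
        config = ScreenConfig(background_nonviable_rate=0.1, unfertilized_rate=0.05,
                              clutch_size_mean=10)
        for s in range(50):
            clutch = simulate_clutch(mother, s, {"m": zygotic_allele}, config, rng)
            n_viable = sum(e.viable_at_score for e in clutch.embryos)
            n_fert_nonviable = sum(
                e.fertilized and not e.viable_at_score for e in clutch.embryos)
            n_unfert = sum(not e.fertilized for e in clutch.embryos)
            assert n_viable + n_fert_nonviable + n_unfert == clutch.size
            assert not any(e.viable_at_score and not e.fertilized
                           for e in clutch.embryos)

    def test_non_adult_mother_rejected(self, zygotic_allele, rng):
        juvenile = make_mother(Genotype.wild_type())
        juvenile.status = "JUVENILE_DEATH"
        with pytest.raises(ValueError, match="not an adult"):
            simulate_clutch(juvenile, 0, {}, ScreenConfig(), rng)


class TestRearCohort:
    def _clutches(self, mother, alleles, config, rng, n_embryos):
        clutches = []
        session = 0
        n = 0
        while n < n_embryos:
            c = simulate_clutch(mother, session, alleles, config, rng)
            clutches.append(c)
            n += c.size
            session += 1
        return clutches

    def test_perfect_rearing_keeps_all_viable_embryos(self, zygotic_allele, rng):
        mother = make_mother(Genotype.from_dosages({"m": 1}))
        config = ScreenConfig(rearing_survival=1.0, primary_male_rate=0.0)
        clutches = self._clutches(mother, {"m": zygotic_allele}, config, rng, 200)
        reared = rear_cohort(clutches, {"m": zygotic_allele}, config, rng,
                             family_id="R001", generation="F2", id_prefix="x")
        n_viable = sum(c.n_viable for c in clutches)
        assert len(reared) == n_viable
        assert all(f.is_adult_hermaphrodite() for f in reared)

    def test_primary_male_rate_recovered(self, rng):
        mother = make_mother(Genotype.wild_type())
        config = ScreenConfig(rearing_survival=1.0, primary_male_rate=0.036,
                              clutch_size_mean=20)
        clutches = self._clutches(mother, {}, config, rng, 10_000)
        reared = rear_cohort(clutches, {}, config, rng,
                             family_id="R001", generation="F2", id_prefix="x")
        frac = np.mean([f.role == "PRIMARY_MALE" for f in reared])
        assert within_3sd(frac, 0.036, len(reared))

    def test_no_viable_embryos_yields_empty_cohort(self, sterile_i_allele, rng, caplog):
        mother = make_mother(Genotype.from_dosages({"s": 2}), expressed="STERILE_I")
        config = ScreenConfig(clutch_size_mean=5)
        clutches = self._clutches(mother, {"s": sterile_i_allele}, config, rng, 30)
        with caplog.at_level("WARNING"):
            reared = rear_cohort(clutches, {"s": sterile_i_allele}, config, rng,
                                 family_id="R001", generation="F3", id_prefix="x")
        assert reared == []
        assert "no viable embryos" in caplog.text

    def test_small_cohort_allele_loss_probability(self, zygotic_allele, rng):
        """P(both of 2 survivors are +/+) = (1/3)^2 = 1/9."""
        from selfscreen import sample_offspring

        parent = Genotype.from_dosages({"m": 1})
        n_rep, both_wt = 10_000, 0
        for _ in range(n_rep):
            survivors = []
            while len(survivors) < 2:
                g = sample_offspring(parent, rng)
                if not g.is_homozygous("m"):  # m/m lethal, penetrance 1
                    survivors.append(g)
            both_wt += all(g.is_wild_type() for g in survivors)
        assert within_3sd(both_wt / n_rep, 1 / 9, n_rep)


class TestSimulateScreen:
    def test_null_screen_is_all_wildtype(self):
        config = ScreenConfig(n_f1_families=4, alleles_per_genome_mean=0.0,
                              primary_male_rate=0.0, seed=1)
        result = simulate_screen(config)
        assert all(f.genotype.is_wild_type() for f in result.pedigree)
        assert all(e.viable_at_score for c in result.clutches for e in c.embryos)
        assert set(result.truth.values()) == {"WILD_TYPE"}

    def test_f1_founders_heterozygous_for_all_family_alleles(self):
        config = ScreenConfig(n_f1_families=30, alleles_per_genome_mean=2.0, seed=2)
        result = simulate_screen(config)
        for f in result.pedigree:
            if f.generation == "F1":
                family_alleles = [a for a in result.alleles if a.startswith(f.family_id)]
                assert all(f.genotype.dosage(a) == 1 for a in family_alleles)

    def test_sterile_homozygote_fraction_in_f2(self):
        """With one Type I allele per F1, ~25% of F2 adults are s/s."""
        config = ScreenConfig(
            n_f1_families=60,
            alleles_per_genome_mean=1.0,
            class_probabilities={AlleleClass.STERILE_TYPE_I: 1.0},
            f2_cohort_size_range=(10, 13),
            primary_male_rate=0.0,
            seed=5,
        )
        # force exactly one allele per genome: Poisson(1) can draw 0 or 2,
        # so restrict to families that drew exactly one
        result = simulate_screen(config)
        counts = {"s": 0, "n": 0}
        for f in result.pedigree:
            if f.generation != "F2" or not f.is_adult_hermaphrodite():
                continue
            family_alleles = [a for a in result.alleles if a.startswith(f.family_id)]
            if len(family_alleles) != 1:
                continue
            counts["n"] += 1
            counts["s"] += f.genotype.is_homozygous(family_alleles[0])
        assert counts["n"] > 100
        assert within_3sd(counts["s"] / counts["n"], 0.25, counts["n"])

    def test_carrier_fraction_among_surviving_f2(self):
        """One zygotic lethal per family, penetrance 1: 2/3 of surviving
        F2 adults are carriers."""
        config = ScreenConfig(
            n_f1_families=60,
            alleles_per_genome_mean=1.0,
            class_probabilities={AlleleClass.ZYGOTIC_LETHAL: 1.0},
            f2_cohort_size_range=(10, 13),
            primary_male_rate=0.0,
            seed=6,
        )
        result = simulate_screen(config)
        n = carriers = 0
        for f in result.pedigree:
            if f.generation != "F2" or not f.is_adult_hermaphrodite():
                continue
            family_alleles = [a for a in result.alleles if a.startswith(f.family_id)]
            if len(family_alleles) != 1:
                continue
            allele = family_alleles[0]
            assert not f.genotype.is_homozygous(allele)  # lethals never rear
            n += 1
            carriers += f.genotype.is_carrier(allele)
        assert n > 100
        assert within_3sd(carriers / n, 2 / 3, n)

    def test_maternal_dominance_raises_sterile_fraction(self):
        """Offspring of s/+ mothers: sterile fraction is 1/4 at zero
        maternal dominance and increases monotonically with it."""
        fracs = []
        for md in (0.0, 0.4, 0.8):
            config = ScreenConfig(maternal_dominance=md)
            rng = np.random.default_rng(11)
            allele = MutantAllele("s", AlleleClass.STERILE_TYPE_I, "maternal effect",
                                  maternal_dominance=md)
            mother = make_mother(Genotype.from_dosages({"s": 1}))
            clutches = []
            n = 0
            session = 0
            while n < 4000:
                c = simulate_clutch(mother, session, {"s": allele}, config, rng)
                clutches.append(c)
                n += c.size
                session += 1
            cfg2 = ScreenConfig(rearing_survival=1.0, primary_male_rate=0.0,
                                maternal_dominance=md)
            reared = rear_cohort(clutches, {"s": allele}, cfg2, rng,
                                 family_id="R001", generation="F3", id_prefix="x")
            frac = np.mean([f.expressed_sterile is not None for f in reared])
            fracs.append(frac)
        assert within_3sd(fracs[0], 0.25, 4000)
        # expected sterile fraction is 1/4 + md/2
        assert fracs[0] < fracs[1] < fracs[2]
        assert within_3sd(fracs[1], 0.25 + 0.2, 4000)

    def test_same_seed_gives_identical_tables(self, tmp_path):
        from selfscreen.io import write_clutches, write_pedigree

        config = ScreenConfig(n_f1_families=6, seed=13)
        for run in ("a", "b"):
            result = simulate_screen(ScreenConfig(n_f1_families=6, seed=13))
            write_pedigree(result.pedigree, tmp_path / f"ped_{run}.tsv",
                           truth=result.truth)
            write_clutches(result.clutches, tmp_path / f"clutch_{run}.tsv")
        assert (tmp_path / "ped_a.tsv").read_bytes() == \
            (tmp_path / "ped_b.tsv").read_bytes()
        assert (tmp_path / "clutch_a.tsv").read_bytes() == \
            (tmp_path / "clutch_b.tsv").read_bytes()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ScreenConfig(class_probabilities={AlleleClass.ZYGOTIC_LETHAL: 0.5})
        with pytest.raises(ValueError, match="primary_male_rate"):
            ScreenConfig(primary_male_rate=1.5)
        with pytest.raises(ValueError, match="unknown configuration keys"):
            ScreenConfig.from_json('{"bogus_key": 1}')
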