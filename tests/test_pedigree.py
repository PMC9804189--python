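"""Pedigree cleaning, kinship/F_ped, completeness, and demography."""

import datetime as dt

import numpy as np
import pytest

from breedpop.pedigree import (
    FEMALE, MALE, Pedigree, PedigreeRecord, clean_pedigree,
    completeness_by_generation, fraction_of_pups_breeding, generation_interval,
    litter_sizes, popular_sires, read_pedigree_csv, top_sire_contribution,
    write_pedigree_csv,
)
from oracles import path_counting_inbreeding

R = PedigreeRecord


def ped_of(*recs):
    return clean_pedigree(list(recs))[0]


# ----------------------------------------------------------------- cleaning

class TestCleaning:
    def test_impossible_birth_years_reset(self):
        ped, rep = clean_pedigree([R("a", birth_year=19981), R("b", birth_year=201),
                                   R("c", birth_year=1990)])
        assert ped.record("a").birth_year is None
        assert ped.record("b").birth_year is None
        assert ped.record("c").birth_year == 1990
        assert rep.n_year_reset == 2

    def test_child_born_before_parent_gets_unknown_date(self):
        ped, rep = clean_pedigree([
            R("sire", birth_year=2005, sex=MALE),
            R("kid", sire_id="sire", birth_year=2000,
              birth_date=dt.date(2000, 5, 1)),
        ])
        assert ped.record("kid").birth_year is None
        assert ped.record("kid").birth_date is None
        assert rep.n_dob_reset == 1

    def test_equal_parent_child_year_tolerated(self):
        ped, rep = clean_pedigree([R("p", birth_year=2000),
                                   R("k", dam_id="p", birth_year=2000)])
        assert ped.record("k").birth_year == 2000
        assert rep.n_dob_reset == 0

    def test_mutual_dam_cycle_broken_by_removing_a_dam_link(self):
        ped, rep = clean_pedigree([R("A", dam_id="B"), R("B", dam_id="A")])
        dams = [ped.record("A").dam_id, ped.record("B").dam_id]
        assert dams.count(None) == 1  # exactly one link cut
        assert len(rep.removed_links) == 1

    def test_dam_link_preferred_when_both_close_cycle(self):
        # C's sire and dam both sit on a loop back to C
        recs = [R("C", sire_id="S", dam_id="D"),
                R("S", dam_id="C"), R("D", dam_id="C")]
        ped, rep = clean_pedigree(recs)
        # resulting graph is acyclic (Pedigree construction would raise)
        assert len(ped) == 3
        assert rep.removed_links

    def test_duplicate_id_is_hard_error(self):
        with pytest.raises(ValueError, match="dup"):
            clean_pedigree([R("dup"), R("dup")])

    def test_self_parentage_removed_and_reported(self):
        ped, rep = clean_pedigree([R("x", sire_id="x")])
        assert ped.record("x").sire_id is None
        assert ("x", "x") in rep.removed_links

    def test_phantom_founders_created_for_dangling_parents(self):
        ped, rep = clean_pedigree([R("kid", sire_id="ghost")])
        assert rep.n_phantom_created == 1
        assert ped.record("ghost").phantom

    def test_cleaning_is_idempotent(self):
        recs = [R("A", dam_id="B", birth_year=19981), R("B", dam_id="A"),
                R("c", sire_id="ghost", birth_year=1990)]
        ped1, _ = clean_pedigree(recs)
        ped2, rep2 = clean_pedigree(list(ped1))
        assert rep2.n_year_reset == 0 and rep2.n_dob_reset == 0
        assert not rep2.removed_links and rep2.n_phantom_created == 0
        for rec in ped1:
            assert ped2.record(rec.id) == rec


# ----------------------------------------------------------------- kinship

def full_sib_family():
    return [R("gs", sex=MALE), R("gd", sex=FEMALE),
            R("f", sire_id="gs", dam_id="gd", sex=MALE),
            R("m", sire_id="gs", dam_id="gd", sex=FEMALE),
            R("kid", sire_id="f", dam_id="m")]


class TestKinship:
    def test_self_kinship_of_non_inbred_is_half(self):
        ped = ped_of(R("x"))
        assert ped.kinship("x", "x") == 0.5

    def test_parent_offspring_quarter(self):
        ped = ped_of(R("p", sex=MALE), R("q", sex=FEMALE),
                     R("kid", sire_id="p", dam_id="q"))
        assert ped.kinship("p", "kid") == 0.25

    def test_unrelated_founders_zero(self):
        ped = ped_of(R("x"), R("y"))
        assert ped.kinship("x", "y") == 0.0

    def test_symmetry(self):
        ped = ped_of(*full_sib_family())
        for a in ped.ids:
            for b in ped.ids:
                assert ped.kinship(a, b) == ped.kinship(b, a)

    def test_unknown_id_raises(self):
        ped = ped_of(R("x"))
        with pytest.raises(KeyError):
            ped.kinship("x", "nope")

    @pytest.mark.parametrize("build,expected", [
        (lambda: [R("f")], 0.0),                              # founder
        (full_sib_family, 0.25),                              # full sibs
        (lambda: [R("gs", sex=MALE), R("gd1"), R("gd2"),
                  R("f", sire_id="gs", dam_id="gd1", sex=MALE),
                  R("m", sire_id="gs", dam_id="gd2", sex=FEMALE),
                  R("kid", sire_id="f", dam_id="m")], 0.125),  # half sibs
    ])
    def test_f_ped_closed_forms(self, build, expected):
        ped = ped_of(*build())
        target = "kid" if "kid" in ped else "f"
        assert ped.inbreeding(target) == expected

    def test_f_ped_equals_parent_kinship(self):
        ped = ped_of(*full_sib_family())
        assert ped.inbreeding("kid") == ped.kinship("f", "m")

    def test_f_ped_matches_path_counting_oracle_on_random_pedigrees(self, rng):
        """Recursive tabular kinship == Wright path counting, pedigrees <= 6 gen."""
        for rep in range(25):
            parents = {}
            ids = []
            for g in range(6):
                for i in range(4):
                    id_ = f"g{g}i{i}"
                    if g == 0 or rng.random() < 0.2:
                        parents[id_] = (None, None)
                    else:
                        prev = [x for x in ids if x.startswith(f"g{g-1}")]
                        s, d = rng.choice(prev, size=2, replace=True)
                        parents[id_] = (str(s), str(d) if d != s else None)
                    ids.append(id_)
            recs = [R(i, sire_id=p[0], dam_id=p[1]) for i, p in parents.items()]
            ped = Pedigree(recs)
            for id_ in ids:
                assert ped.inbreeding(id_) == pytest.approx(
                    path_counting_inbreeding(parents, id_), abs=1e-12)


# ----------------------------------------------------------------- completeness

class TestCompleteness:
    def test_founder_cge_zero(self):
        assert ped_of(R("x")).complete_generation_equivalent("x") == 0.0

    def test_parents_only_cge_one(self):
        ped = ped_of(R("p"), R("q"), R("kid", sire_id="p", dam_id="q"))
        assert ped.complete_generation_equivalent("kid") == 1.0

    def test_three_complete_generations_cge_three(self):
        recs = []
        prev = []
        for g in range(4):  # g0 founders ... g3 the proband line
            layer = []
            for i in range(2 ** (3 - g)):
                id_ = f"g{g}i{i}"
                if g == 0:
                    recs.append(R(id_))
                else:
                    recs.append(R(id_, sire_id=f"g{g-1}i{2*i}", dam_id=f"g{g-1}i{2*i+1}"))
                layer.append(id_)
            prev = layer
        ped = ped_of(*recs)
        assert ped.complete_generation_equivalent(prev[0]) == 3.0

    def test_cge_monotone_in_known_ancestors(self):
        base = [R("p"), R("kid", sire_id="p")]
        more = [R("gp"), R("p", sire_id="gp"), R("kid", sire_id="p")]
        assert (ped_of(*more).complete_generation_equivalent("kid")
                > ped_of(*base).complete_generation_equivalent("kid"))

    def test_phantom_parent_counts_as_unknown(self):
        ped, _ = clean_pedigree([R("kid", sire_id="ghost")])
        assert ped.complete_generation_equivalent("kid") == 0.0

    def test_cohort_of_founders_zero_everywhere(self):
        ped = ped_of(R("a"), R("b"))
        tab = completeness_by_generation(ped, ["a", "b"], max_gen=3)
        assert (tab["proportion_known"] == 0).all()

    def test_parents_known_grandparents_not(self):
        ped = ped_of(R("p"), R("q"), R("kid", sire_id="p", dam_id="q"))
        tab = completeness_by_generation(ped, ["kid"], max_gen=2)
        assert tab.loc[tab.generation == 1, "proportion_known"].item() == 1.0
        assert tab.loc[tab.generation == 2, "proportion_known"].item() == 0.0

    def test_mixed_cohort_averages_slots(self):
        # one kid complete to gen 2, one founder: gen1 mean = (1 + 0)/2
        recs = [R("a"), R("b"), R("c"), R("d"),
                R("p", sire_id="a", dam_id="b"), R("q", sire_id="c", dam_id="d"),
                R("kid", sire_id="p", dam_id="q"), R("lone")]
        ped = ped_of(*recs)
        tab = completeness_by_generation(ped, ["kid", "lone"], max_gen=2)
        assert tab.loc[tab.generation == 1, "proportion_known"].item() == 0.5
        assert tab.loc[tab.generation == 2, "proportion_known"].item() == 0.5

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            completeness_by_generation(ped_of(R("x")), [], 2)

    def test_country_stratification(self):
        ped = ped_of(R("p"), R("nl", sire_id="p", country="NL"),
                     R("de", country="DE"))
        tab = completeness_by_generation(ped, ["nl", "de"], 1, group_by_country=True)
        nl = tab[tab.group == "NL"]["proportion_known"].item()
        de = tab[tab.group == "DE"]["proportion_known"].item()
        assert nl == 0.5 and de == 0.0


# ----------------------------------------------------------------- demography

def breeding_records(n_sires=1, pups_per_sire=40, n_other=20, year=2005):
    recs = [R(f"sire{i}", sex=MALE, birth_year=2000) for i in range(n_sires)]
    recs += [R("dam0", sex=FEMALE, birth_year=2000)]
    k = 0
    for i in range(n_sires):
        for _ in range(pups_per_sire):
            recs.append(R(f"pup{k}", sire_id=f"sire{i}", dam_id="dam0",
                          birth_year=year))
            k += 1
    for _ in range(n_other):
        recs.append(R(f"pup{k}", dam_id="dam0", birth_year=year))
        k += 1
    return recs


class TestDemography:
    def test_popular_sire_threshold_is_32(self):
        recs = breeding_records(n_sires=1, pups_per_sire=31)
        assert popular_sires(ped_of(*recs)) == []
        recs = breeding_records(n_sires=1, pups_per_sire=32)
        assert popular_sires(ped_of(*recs)) == [("sire0", 32)]

    def test_no_sires_recorded_empty(self):
        assert popular_sires(ped_of(R("a"), R("b"))) == []

    def test_one_dominant_sire_counted(self):
        recs = breeding_records(n_sires=1, pups_per_sire=40, n_other=20)
        assert popular_sires(ped_of(*recs)) == [("sire0", 40)]

    def test_single_sire_contributes_100(self):
        recs = breeding_records(n_sires=1, pups_per_sire=10, n_other=0)
        assert top_sire_contribution(ped_of(*recs), 2005) == 100.0

    def test_top10_of_29_in_100(self):
        recs = [R("dam0", sex=FEMALE)]
        k = 0
        for i in range(10):  # 10 sires, ~3 pups each: 29 total
            for _ in range(3 if i < 9 else 2):
                recs.append(R(f"p{k}", sire_id=f"s{i}", dam_id="dam0",
                              birth_year=2005))
                k += 1
        for _ in range(100 - k):  # 71 sireless pups
            recs.append(R(f"p{k}", dam_id="dam0", birth_year=2005))
            k += 1
        assert top_sire_contribution(ped_of(*recs), 2005) == pytest.approx(29.0)

    def test_contribution_no_births_raises(self):
        with pytest.raises(ValueError):
            top_sire_contribution(ped_of(R("x", birth_year=2000)), 1999)

    def test_generation_interval_examples(self):
        ped = ped_of(R("p", birth_year=1990), R("k", sire_id="p", birth_year=1997))
        assert generation_interval(ped) == 7.0
        recs = [R("a", birth_year=2000), R("b", birth_year=2001), R("c", birth_year=2000),
                R("k1", sire_id="a", birth_year=2004),
                R("k2", sire_id="b", birth_year=2006),
                R("k3", sire_id="c", birth_year=2006)]
        assert generation_interval(ped_of(*recs)) == pytest.approx(5.0)

    def test_generation_interval_needs_datable_pair(self):
        with pytest.raises(ValueError):
            generation_interval(ped_of(R("p"), R("k", sire_id="p")))

    def test_litter_by_dam_and_date(self):
        d = dt.date(2005, 3, 1)
        recs = [R("dam", sex=FEMALE)] + [
            R(f"p{i}", dam_id="dam", birth_date=d, birth_year=2005) for i in range(6)]
        sizes, mean = litter_sizes(ped_of(*recs))
        assert sizes == [6] and mean == 6.0

    def test_two_litters_mean(self):
        d1, d2 = dt.date(2005, 3, 1), dt.date(2006, 4, 1)
        recs = [R("dam", sex=FEMALE)]
        recs += [R(f"a{i}", dam_id="dam", birth_date=d1, birth_year=2005) for i in range(4)]
        recs += [R(f"b{i}", dam_id="dam", birth_date=d2, birth_year=2006) for i in range(8)]
        sizes, mean = litter_sizes(ped_of(*recs))
        assert sorted(sizes) == [4, 8] and mean == 6.0

    def test_year_fallback_key_uses_sire(self):
        # same dam, same year, different sires, no dates: two litters
        recs = [R("dam", sex=FEMALE), R("s1", sex=MALE), R("s2", sex=MALE),
                R("p1", dam_id="dam", sire_id="s1", birth_year=2005),
                R("p2", dam_id="dam", sire_id="s2", birth_year=2005)]
        sizes, _ = litter_sizes(ped_of(*recs))
        assert sorted(sizes) == [1, 1]

    def test_fraction_breeding(self):
        recs = [R(f"m{i}", sex=MALE) for i in range(20)]
        recs += [R("dam", sex=FEMALE)]
        recs += [R("k1", sire_id="m0", dam_id="dam"),
                 R("k2", sire_id="m1", dam_id="dam")]
        # k1, k2 have unknown sex so denominators are 20 males / 1 female
        male, female = fraction_of_pups_breeding(ped_of(*recs))
        assert male == pytest.approx(10.0)
        assert female == pytest.approx(100.0)

    def test_nobody_breeds(self):
        assert fraction_of_pups_breeding(ped_of(R("a", sex=MALE), R("b", sex=FEMALE))) == (0.0, 0.0)


# ----------------------------------------------------------------- I/O

def test_pedigree_csv_round_trip(tmp_path):
    recs = [R("a", sex=MALE, birth_year=2000, birth_date=dt.date(2000, 1, 2), country="NL"),
            R("b", sex=FEMALE, birth_year=2001),
            R("kid", sire_id="a", dam_id="b", birth_year=2004)]
    path = tmp_path / "ped.csv"
    write_pedigree_csv(recs, path)
    back = read_pedigree_csv(path)
    assert back == recs
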