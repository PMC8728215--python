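"""Closest interspecific ANI analysis and fuzzy/discrete species verdicts."""

import numpy as np
import pytest

from anispecies.ani import AniMatrix
from anispecies.discreteness import (
    InterspecificRecord,
    brute_force_interspecific_pairs,
    classify_species,
    closest_interspecific_pairs,
    closest_rep_pairs,
)
from anispecies.model import Accession, SpeciesCluster
from anispecies.synthetic import SyntheticSpec, generate_dataset, dataset_release


def _fixture(n_species=3, genomes_per_species=3, seed=0, fuzzy_rate=0.0):
    ds = generate_dataset(
        SyntheticSpec(
            n_species=n_species,
            genomes_per_species=genomes_per_species,
            species_per_genus=n_species,  # one genus
            fuzzy_pair_rate=fuzzy_rate,
        ),
        seed=seed,
    )
    release = None
    if fuzzy_rate == 0.0:
        release = dataset_release(ds)
    return ds, release


class TestClosestRepPairs:
    def test_maximum_ani_neighbour_chosen(self):
        clusters = [
            SpeciesCluster(f"GCA_{i:09d}.1", f"s__x sp{i}") for i in (1, 2, 3)
        ]
        taxonomy = {c.representative: f"d__;p__;c__;o__;f__;g__X;{c.species_label}"
                    for c in clusters}
        m = AniMatrix()
        m.set("GCA_000000001.1", "GCA_000000002.1", 92.0, 0.5)
        m.set("GCA_000000001.1", "GCA_000000003.1", 88.0, 0.5)
        pairs = dict(
            (a, (b, ani)) for a, b, ani in closest_rep_pairs(clusters, taxonomy, m)
        )
        assert pairs["s__x sp1"] == ("s__x sp2", 92.0)

    def test_singleton_genus_omitted(self):
        clusters = [SpeciesCluster("GCA_000000001.1", "s__only")]
        taxonomy = {clusters[0].representative: "d__;p__;c__;o__;f__;g__X;s__only"}
        assert closest_rep_pairs(clusters, taxonomy, AniMatrix()) == []

    def test_missing_pairs_fall_back_to_available(self):
        clusters = [
            SpeciesCluster(f"GCA_{i:09d}.1", f"s__x sp{i}") for i in (1, 2, 3)
        ]
        taxonomy = {c.representative: f"d__;p__;c__;o__;f__;g__X;{c.species_label}"
                    for c in clusters}
        m = AniMatrix()
        m.set("GCA_000000001.1", "GCA_000000003.1", 85.0, 0.4)
        pairs = dict(
            (a, (b, ani)) for a, b, ani in closest_rep_pairs(clusters, taxonomy, m)
        )
        assert pairs["s__x sp1"] == ("s__x sp3", 85.0)


class TestClosestInterspecificPairs:
    def test_heuristic_matches_brute_force_when_premise_holds(self):
        """On fixtures where species ANI bands are species-consistent the
        closest-representative shortcut is exact."""
        for seed in range(5):
            ds, release = _fixture(n_species=3, genomes_per_species=4, seed=seed)
            clusters = release.active_clusters()
            records, _ = closest_interspecific_pairs(
                clusters, ds.taxonomy, ds.matrix, seed=seed
            )
            brute = brute_force_interspecific_pairs(clusters, ds.taxonomy, ds.matrix)
            heuristic = {r.genome: r for r in records}
            exact = {r.genome: r for r in brute}
            assert heuristic.keys() == exact.keys()
            agreements = sum(
                heuristic[g].ani == exact[g].ani for g in exact
            )
            # premise violations are possible but must be rare and, when the
            # premise holds for a species, the per-genome answers are equal
            for g in exact:
                if heuristic[g].closest_species == exact[g].closest_species:
                    assert heuristic[g].ani == exact[g].ani
            assert agreements >= 0.8 * len(exact)

    def test_subsampling_caps_large_species(self):
        n = 200
        clusters = [
            SpeciesCluster(
                "GCA_000001000.1",
                "s__big",
                {f"GCA_{1000 + i:09d}.1" for i in range(n)},
            ),
            SpeciesCluster("GCA_000002000.1", "s__small"),
        ]
        taxonomy = {}
        m = AniMatrix()
        for c in clusters:
            for g in c.members:
                taxonomy[g] = f"d__;p__;c__;o__;f__;g__X;{c.species_label}"
        for g in clusters[0].members:
            m.set(g, "GCA_000002000.1", 90.0, 0.4)
        m.set("GCA_000001000.1", "GCA_000002000.1", 90.0, 0.4)
        records, log = closest_interspecific_pairs(
            clusters, taxonomy, m, subsample=150, seed=1
        )
        big = [r for r in records if r.species == "s__big"]
        assert len(big) == 150
        assert log and log[0][0] == "s__big" and log[0][1] == 150

    def test_subsample_reproducible_and_stable_across_species_additions(self):
        ds, release = _fixture(n_species=2, genomes_per_species=8, seed=3)
        clusters = release.active_clusters()
        r1, _ = closest_interspecific_pairs(clusters, ds.taxonomy, ds.matrix,
                                            subsample=4, seed=7)
        r2, _ = closest_interspecific_pairs(clusters, ds.taxonomy, ds.matrix,
                                            subsample=4, seed=7)
        assert r1 == r2

    def test_subsample_geq_size_equals_exhaustive(self):
        ds, release = _fixture(n_species=3, genomes_per_species=4, seed=4)
        clusters = release.active_clusters()
        a, _ = closest_interspecific_pairs(clusters, ds.taxonomy, ds.matrix,
                                           subsample=1000, seed=1)
        b, _ = closest_interspecific_pairs(clusters, ds.taxonomy, ds.matrix,
                                           subsample=1000, seed=99)
        assert a == b

    def test_wide_radius_species_excluded_as_subject_but_kept_as_target(self):
        clusters = [
            SpeciesCluster("GCA_000000001.1", "s__wide", radius=96.0),
            SpeciesCluster("GCA_000000002.1", "s__a"),
            SpeciesCluster("GCA_000000003.1", "s__b"),
        ]
        taxonomy = {c.representative: f"d__;p__;c__;o__;f__;g__X;{c.species_label}"
                    for c in clusters}
        m = AniMatrix()
        m.set("GCA_000000002.1", "GCA_000000001.1", 94.0, 0.5)
        m.set("GCA_000000002.1", "GCA_000000003.1", 90.0, 0.5)
        m.set("GCA_000000001.1", "GCA_000000003.1", 89.0, 0.5)
        records, _ = closest_interspecific_pairs(clusters, taxonomy, m)
        subjects = {r.species for r in records}
        assert "s__wide" not in subjects
        # the wide-radius species still serves as a search target
        assert any(r.closest_species == "s__wide" for r in records)

    def test_single_species_genus_contributes_nothing(self):
        clusters = [SpeciesCluster("GCA_000000001.1", "s__only")]
        taxonomy = {clusters[0].representative: "d__;p__;c__;o__;f__;g__X;s__only"}
        records, log = closest_interspecific_pairs(clusters, taxonomy, AniMatrix())
        assert records == [] and log == []


class TestClassifySpecies:
    def _rec(self, species, ani, i=0):
        return InterspecificRecord(
            genome=Accession.parse(f"GCA_{i + 1:09d}.1"),
            species=species,
            closest_genome=Accession.parse("GCA_000000999.1"),
            closest_species="s__other",
            ani=ani,
        )

    def test_rule_table(self):
        result = classify_species(
            [
                self._rec("s__discrete", 93.0, 0),
                self._rec("s__discrete", 92.0, 1),
                self._rec("s__fuzzy", 95.3, 2),
                self._rec("s__between", 94.5, 3),
            ]
        )
        assert result.verdicts == {
            "s__discrete": "discrete",
            "s__fuzzy": "fuzzy",
            "s__between": "intermediate",
        }

    def test_verdicts_mutually_exclusive_and_order_invariant(self):
        rng = np.random.default_rng(0)
        records = [
            self._rec(f"s__sp{i % 7}", float(rng.uniform(90, 97)), i)
            for i in range(60)
        ]
        fwd = classify_species(records)
        rev = classify_species(records[::-1])
        assert fwd.verdicts == rev.verdicts
        assert fwd.fuzzy_species_pct + fwd.discrete_species_pct \
            + fwd.intermediate_species_pct == pytest.approx(100.0)

    def test_fractions_over_pairs(self):
        result = classify_species(
            [self._rec("s__a", 95.5, 0), self._rec("s__a", 93.0, 1),
             self._rec("s__b", 90.0, 2), self._rec("s__b", 94.0, 3)]
        )
        assert result.fuzzy_pair_pct == pytest.approx(25.0)
        assert result.discrete_pair_pct == pytest.approx(75.0)

    def test_fuzzy_injection_detected_end_to_end(self):
        ds = generate_dataset(
            SyntheticSpec(n_species=2, genomes_per_species=4, species_per_genus=2,
                          fuzzy_pair_rate=1.0, fuzzy_band=(95.2, 95.8)),
            seed=6,
        )
        clusters = [
            SpeciesCluster(
                sorted(accs := [a for a, lbl in ds.truth.items() if lbl == label])[0],
                label,
                set(accs),
            )
            for label in ds.species_labels
        ]
        records, _ = closest_interspecific_pairs(clusters, ds.taxonomy, ds.matrix)
        result = classify_species(records)
        assert set(result.verdicts.values()) == {"fuzzy"}
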