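"""Release diffing, type-strain audit, representative updates, full workflow."""

import itertools

import numpy as np
import pytest

from anispecies.ani import AniMatrix
from anispecies.config import Config
from anispecies.model import (
    Accession,
    GenomeRecord,
    ModelError,
    SpeciesCluster,
    TypeStatus,
)
from anispecies.scoring import balanced_ani_score, quality_score
from anispecies.synthetic import (
    Perturbation,
    SyntheticSpec,
    dataset_release,
    generate_dataset,
    generate_release_pair,
)
from anispecies.updater import (
    detect_type_strain_conflicts,
    diff_releases,
    handle_suppressed_representative,
    handle_updated_assembly,
    update_release,
    update_representative,
)


def _record(acc, **kwargs):
    base = dict(accession=acc, completeness=90.0, contamination=1.0, contig_count=10)
    base.update(kwargs)
    return GenomeRecord(**base)


class TestDiffReleases:
    def test_set_logic(self):
        prev = [Accession.parse(a) for a in
                ("GCA_000000001.1", "GCA_000000002.1", "GCA_000000003.1")]
        cur = [_record("GCA_000000001.1"), _record("GCA_000000002.2"),
               _record("GCA_000000004.1")]
        d = diff_releases(prev, cur)
        assert {str(a) for a in d.unchanged} == {"GCA_000000001.1"}
        assert d.updated == {
            "GCA_000000002": (
                Accession.parse("GCA_000000002.1"), Accession.parse("GCA_000000002.2")
            )
        }
        assert {str(a) for a in d.new} == {"GCA_000000004.1"}
        assert {str(a) for a in d.lost} == {"GCA_000000003.1"}

    def test_assembly_version_bump_is_updated(self):
        d = diff_releases(
            [Accession.parse("GCF_004359525.1")], [_record("GCF_004359525.2")]
        )
        assert "GCF_004359525" in d.updated

    def test_identical_releases_all_unchanged(self):
        prev = [Accession.parse(f"GCA_{i:09d}.1") for i in range(1, 6)]
        cur = [_record(str(a)) for a in prev]
        d = diff_releases(prev, cur)
        assert d.unchanged == set(prev)
        assert not d.new and not d.updated and not d.lost

    def test_suppressed_current_genome_is_lost(self):
        prev = [Accession.parse("GCA_000000001.1")]
        d = diff_releases(prev, [_record("GCA_000000001.1", suppressed=True)])
        assert d.lost == set(prev)

    def test_version_decrease_treated_as_updated(self, caplog):
        d = diff_releases(
            [Accession.parse("GCA_000000001.2")], [_record("GCA_000000001.1")]
        )
        assert "GCA_000000001" in d.updated


class TestTypeStrainConflicts:
    def _cluster(self, members):
        return SpeciesCluster("GCA_000000001.1", "s__x",
                              {str(m) for m in members})

    def _records(self, accs, n_typed=None):
        out = {}
        for i, a in enumerate(accs):
            typed = n_typed is None or i < n_typed
            out[Accession.parse(a)] = _record(
                a,
                type_status=TypeStatus.TYPE_STRAIN_OF_SPECIES
                if typed
                else TypeStatus.NONE,
            )
        return out

    def test_divergent_type_genomes_flagged(self):
        accs = ["GCA_000000001.1", "GCA_000000002.1"]
        m = AniMatrix()
        m.set(*accs, 98.5, 0.9)
        (c,) = detect_type_strain_conflicts(
            [self._cluster(accs)], self._records(accs), m
        )
        assert c.min_pairwise_ani == 98.5
        assert not c.resolved

    def test_concordant_type_genomes_pass(self):
        accs = ["GCA_000000001.1", "GCA_000000002.1"]
        m = AniMatrix()
        m.set(*accs, 99.2, 0.9)
        assert detect_type_strain_conflicts(
            [self._cluster(accs)], self._records(accs), m
        ) == []

    def test_single_type_genome_never_flagged(self):
        accs = ["GCA_000000001.1", "GCA_000000002.1"]
        assert detect_type_strain_conflicts(
            [self._cluster(accs)], self._records(accs, n_typed=1), AniMatrix()
        ) == []

    def test_missing_ani_flagged_as_insufficient_data(self):
        accs = ["GCA_000000001.1", "GCA_000000002.1"]
        (c,) = detect_type_strain_conflicts(
            [self._cluster(accs)], self._records(accs), AniMatrix()
        )
        assert c.min_pairwise_ani is None

    @pytest.mark.parametrize("seed", range(10))
    def test_flag_iff_min_pairwise_below_threshold(self, seed):
        """Exhaustive pair enumeration oracle on randomized fixtures."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        accs = [f"GCA_{i:09d}.1" for i in range(1, n + 1)]
        m = AniMatrix()
        values = {}
        for a, b in itertools.combinations(accs, 2):
            v = float(rng.uniform(97.0, 100.0))
            values[(a, b)] = v
            m.set(a, b, v, 0.9)
        (flagged,) = detect_type_strain_conflicts(
            [self._cluster(accs)], self._records(accs), m
        ) or [None]
        expected = min(values.values()) < 99.0
        assert (flagged is not None) == expected
        if flagged is not None:
            assert flagged.min_pairwise_ani == pytest.approx(min(values.values()))


class TestRepresentativeUpdate:
    def test_new_type_strain_promotes(self):
        rep = _record("GCA_000000001.1")
        challenger = _record(
            "GCA_000000002.1", type_status=TypeStatus.TYPE_STRAIN_OF_SPECIES
        )
        m = AniMatrix()
        m.set(rep.accession, challenger.accession, 98.0, 0.9)
        scores = {r.accession: quality_score(r).total for r in (rep, challenger)}
        cluster = SpeciesCluster(rep.accession, "s__x")
        d = update_representative(cluster, rep, [challenger], m, scores)
        assert d.changed and d.reason == "type_strain_promotion"

    def test_small_quality_gain_rejected(self):
        # quality 310 vs 300 at ANI 99.9: needs 20 + 20*0.1 = 22, only 10
        rep = _record("GCA_000000001.1")
        challenger = _record("GCA_000000002.1")
        m = AniMatrix()
        m.set(rep.accession, challenger.accession, 99.9, 0.9)
        scores = {rep.accession: 300.0, challenger.accession: 310.0}
        cluster = SpeciesCluster(rep.accession, "s__x")
        d = update_representative(cluster, rep, [challenger], m, scores)
        assert not d.changed

    def test_no_challengers_keeps_representative(self):
        rep = _record("GCA_000000001.1")
        cluster = SpeciesCluster(rep.accession, "s__x")
        d = update_representative(cluster, rep, [], AniMatrix(),
                                  {rep.accession: 100.0})
        assert not d.changed
        assert d.new_representative == rep.accession


class TestSpecialCases:
    def test_updated_assembly_typically_wins(self):
        old = Accession.parse("GCA_000000001.1")
        new = _record("GCA_000000001.2")
        member = _record("GCA_000000002.1")
        m = AniMatrix()
        m.set(new.accession, old, 99.99, 0.99)
        m.set(member.accession, old, 98.0, 0.9)
        scores = {new.accession: 100.0, member.accession: 100.0}
        cluster = SpeciesCluster(old, "s__x", {member.accession})
        assert handle_updated_assembly(
            cluster, old, [new, member], m, scores
        ) == new.accession

    def test_divergent_update_promotes_sibling(self):
        old = Accession.parse("GCA_000000001.1")
        new = _record("GCA_000000001.2")
        sibling = _record("GCA_000000002.1")
        m = AniMatrix()
        m.set(new.accession, old, 80.6, 0.45)
        m.set(sibling.accession, old, 99.99, 0.95)
        scores = {new.accession: 150.0, sibling.accession: 100.0}
        cluster = SpeciesCluster(old, "s__x", {sibling.accession})
        assert handle_updated_assembly(
            cluster, old, [new, sibling], m, scores
        ) == sibling.accession

    def test_suppressed_rep_replaced_by_highest_bas(self):
        rep = Accession.parse("GCA_000000001.1")
        m1, m2 = _record("GCA_000000002.1"), _record("GCA_000000003.1")
        m = AniMatrix()
        m.set(m1.accession, rep, 99.0, 0.9)
        m.set(m2.accession, rep, 99.5, 0.9)
        scores = {m1.accession: 200.0, m2.accession: 60.0}
        cluster = SpeciesCluster(rep, "s__x", {m1.accession, m2.accession})
        winner = handle_suppressed_representative(cluster, [m1, m2], m, scores)
        assert winner == m1.accession
        assert balanced_ani_score(200.0, 99.0) > balanced_ani_score(60.0, 99.5)

    def test_suppressed_singleton_retires(self):
        rep = Accession.parse("GCA_000000001.1")
        cluster = SpeciesCluster(rep, "s__x")
        assert handle_suppressed_representative(cluster, [], AniMatrix(), {}) is None

    def test_bas_tie_breaks_to_smaller_accession(self):
        rep = Accession.parse("GCA_000000001.1")
        m1, m2 = _record("GCA_000000003.1"), _record("GCA_000000002.1")
        m = AniMatrix()
        m.set(m1.accession, rep, 99.0, 0.9)
        m.set(m2.accession, rep, 99.0, 0.9)
        scores = {m1.accession: 100.0, m2.accession: 100.0}
        cluster = SpeciesCluster(rep, "s__x", {m1.accession, m2.accession})
        assert str(
            handle_suppressed_representative(cluster, [m1, m2], m, scores)
        ) == "GCA_000000002.1"


class TestUpdateRelease:
    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_on_unchanged_genome_set(self, seed):
        ds = generate_dataset(
            SyntheticSpec(n_species=10, genomes_per_species=(1, 6)), seed=seed
        )
        prev = dataset_release(ds)
        new, report = update_release(prev, ds.records, ds.matrix)
        assert report.is_zero_change
        assert report.reps_unchanged == len(prev.active_clusters())
        assert new.cluster_of().keys() == prev.cluster_of().keys()

    def test_workflow_trace_divergent_assembly_update(self):
        """Updated assembly deeply divergent from its predecessor: the
        closest sibling is promoted and the new assembly founds a cluster."""
        pair = generate_release_pair(
            SyntheticSpec(n_species=4, genomes_per_species=(2, 4)),
            Perturbation(divergent_update=True),
            seed=2,
        )
        new, report = update_release(pair.prev, pair.current_records, pair.matrix)
        assert report.reasons() == {"assembly_updated": 1}
        assert report.new_species == 1
        promo = next(e for e in pair.expectations if e.kind == "assembly_updated")
        (change,) = report.rep_changes
        assert change.new == promo.expected_representative
        new_cluster_exp = next(e for e in pair.expectations if e.kind == "new_cluster")
        founded = [
            c for c in new.active_clusters()
            if c.representative == new_cluster_exp.genome
        ]
        assert len(founded) == 1 and founded[0].size == 1

    def test_singleton_suppression_retires_cluster(self):
        pair = generate_release_pair(
            SyntheticSpec(n_species=4, genomes_per_species=(1, 4)),
            Perturbation(n_suppress_singleton_reps=1),
            seed=3,
        )
        new, report = update_release(pair.prev, pair.current_records, pair.matrix)
        exp = next(e for e in pair.expectations if e.kind == "cluster_retired")
        assert report.retired == [exp.species_label]
        assert exp.species_label not in {
            c.species_label for c in new.active_clusters()
        }

    @pytest.mark.parametrize("seed", range(3))
    def test_all_reason_tags_match_ground_truth(self, seed):
        pair = generate_release_pair(
            SyntheticSpec(n_species=9, genomes_per_species=(2, 5)),
            Perturbation(
                n_suppress_singleton_reps=1,
                n_suppress_member_reps=1,
                n_update_rep_assembly=1,
                divergent_update=True,
                n_add_type_strain=1,
                n_quality_upgrade=1,
                n_new_genomes=2,
                n_new_species=1,
            ),
            seed=seed,
        )
        new, report = update_release(pair.prev, pair.current_records, pair.matrix)
        by_label = {c.species_label: c for c in new.active_clusters()}
        changes = {c.species_label: c for c in report.rep_changes}
        for e in pair.expectations:
            if e.kind == "assigned":
                assert e.genome in by_label[e.species_label].members
            elif e.kind == "new_cluster":
                assert any(
                    e.genome in c.members
                    and c.species_label not in {x.species_label
                                                for x in pair.prev.active_clusters()}
                    for c in new.active_clusters()
                )
            elif e.kind == "cluster_retired":
                assert e.species_label in report.retired
            elif e.kind == "assembly_update_retained":
                assert e.species_label not in changes
                assert by_label[e.species_label].representative \
                    == e.expected_representative
            else:
                assert changes[e.species_label].reason == e.kind
                assert changes[e.species_label].new == e.expected_representative

    def test_stability_under_pure_growth(self):
        pair = generate_release_pair(
            SyntheticSpec(n_species=6, genomes_per_species=(2, 4)),
            Perturbation(n_new_genomes=5),
            seed=4,
        )
        _, report = update_release(pair.prev, pair.current_records, pair.matrix)
        assert report.reps_changed == 0
        assert report.assign_diff == 0

    def test_unresolved_type_conflict_freezes_species(self):
        ds = generate_dataset(
            SyntheticSpec(n_species=3, genomes_per_species=3,
                          type_strains_per_species=2),
            seed=5,
        )
        prev = dataset_release(ds)
        # force one species' type genomes below the 99% agreement threshold
        label = prev.active_clusters()[0].species_label
        cluster = next(c for c in prev.active_clusters()
                       if c.species_label == label)
        typed = sorted(
            m for m in cluster.members
            if next(r for r in ds.records if r.accession == m).type_status
            is TypeStatus.TYPE_STRAIN_OF_SPECIES
        )
        ds.matrix.set(typed[0], typed[1], 97.0, 0.9)
        new, report = update_release(prev, ds.records, ds.matrix)
        conflicted = [c.species_label for c in report.conflicts]
        assert label in conflicted
        assert label in report.frozen_species
        # frozen species keeps its representative
        assert next(
            c.representative for c in new.active_clusters()
            if c.species_label == label
        ) == cluster.representative
        # resolution file unfreezes
        _, report2 = update_release(
            prev, ds.records, ds.matrix, resolutions={label: [typed[0]]}
        )
        assert label not in report2.frozen_species

    def test_conservation_accounting(self):
        pair = generate_release_pair(
            SyntheticSpec(n_species=8, genomes_per_species=(1, 5)),
            Perturbation(n_suppress_singleton_reps=1, n_new_genomes=3,
                         n_new_species=1),
            seed=6,
        )
        new, report = update_release(pair.prev, pair.current_records, pair.matrix)
        n_suppressed = sum(1 for r in pair.current_records if r.suppressed)
        assert len(new.genomes()) + report.qc_removed + n_suppressed \
            == len(pair.current_records)
        # every changed representative carries exactly one known reason
        valid = {"type_strain_promotion", "subspecies_type_promotion",
                 "higher_quality_bas", "assembly_updated",
                 "suppressed_rep_replaced", "cluster_retired"}
        assert all(c.reason in valid for c in report.rep_changes)
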