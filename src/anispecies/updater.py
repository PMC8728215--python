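"""Inter-release species-cluster update workflow.

Updating a release proceeds in four steps:

1. **Diff** — compare accessions between the previous and current genome
   sets to find new, updated (version-bumped) and lost/suppressed assemblies.
2. **QC** — remove genomes of insufficient quality from consideration.
3. **Type-strain audit** — species holding several genomes that all claim to
   be assembled from the type strain are flagged when any pair falls below
   99% ANI; such disagreements are resolved by a user-supplied resolution
   file, never automatically. Unresolved species are frozen to their prior
   state.
4. **Representative update and reclustering** — each previous representative
   is re-evaluated (suppressed representatives are replaced by the
   highest-BAS member or the cluster is retired; updated assemblies trigger
   a BAS election against the previous assembly; otherwise the best
   challenger must beat the incumbent's Balanced ANI Score by the
   replacement margin). All non-representative genomes are then re-assigned
   de novo and remaining genomes form new clusters.

Every representative change carries exactly one reason tag, and the final
accounting mirrors the release-notes layout (representatives
unchanged/changed, new species, genomes in same/different cluster,
suppressed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .ani import AniMatrix
from .clustering import assign_genomes, compute_radius, denovo_cluster
from .config import Config
from .model import (
    Accession,
    GenomeRecord,
    ModelError,
    Release,
    SpeciesCluster,
    TypeStatus,
    genus_from_taxonomy,
    records_by_base,
)
from .qc import passes_qc
from .scoring import balanced_ani_score, quality_score, should_replace

__all__ = [
    "ReleaseDiff",
    "TypeStrainConflict",
    "RepresentativeChange",
    "ChangeReport",
    "diff_releases",
    "detect_type_strain_conflicts",
    "update_representative",
    "handle_updated_assembly",
    "handle_suppressed_representative",
    "update_release",
]

logger = logging.getLogger(__name__)

# reason tags for representative changes
TYPE_STRAIN_PROMOTION = "type_strain_promotion"
SUBSPECIES_TYPE_PROMOTION = "subspecies_type_promotion"
HIGHER_QUALITY_BAS = "higher_quality_bas"
ASSEMBLY_UPDATED = "assembly_updated"
SUPPRESSED_REP_REPLACED = "suppressed_rep_replaced"
CLUSTER_RETIRED = "cluster_retired"


@dataclass
class ReleaseDiff:
    """Accession-level comparison of two genome sets, keyed by accession base."""

    new: set[Accession] = field(default_factory=set)
    updated: dict[str, tuple[Accession, Accession]] = field(default_factory=dict)
    unchanged: set[Accession] = field(default_factory=set)
    lost: set[Accession] = field(default_factory=set)

    def validate(self) -> None:
        groups = [
            {a.base for a in self.new},
            set(self.updated),
            {a.base for a in self.unchanged},
            {a.base for a in self.lost},
        ]
        seen: set[str] = set()
        for g in groups:
            if seen & g:
                raise ModelError(f"diff sets overlap on bases {sorted(seen & g)}")
            seen |= g


def diff_releases(
    prev_genomes: Iterable[Accession],
    current_records: Sequence[GenomeRecord],
) -> ReleaseDiff:
    """Classify genomes by directly comparing accession numbers.

    Same base and version: unchanged. Same base, different version: updated
    (a version decrease is logged and still treated as updated). Base only
    in the current set: new. Base only in the previous set, or present but
    suppressed at the source archive: lost.
    """
    prev_by_base: dict[str, Accession] = {}
    for a in prev_genomes:
        a = Accession.parse(a) if isinstance(a, str) else a
        if a.base in prev_by_base:
            raise ModelError(f"duplicate base {a.base} in previous release")
        prev_by_base[a.base] = a
    cur_by_base = records_by_base(current_records)

    diff = ReleaseDiff()
    for base, rec in cur_by_base.items():
        cur = rec.accession
        prev = prev_by_base.get(base)
        if rec.suppressed and prev is not None:
            diff.lost.add(prev)
        elif prev is None:
            diff.new.add(cur)
        elif prev.version == cur.version:
            diff.unchanged.add(cur)
        else:
            if cur.version < prev.version:
                logger.warning(
                    "accession %s version decreased (%d -> %d); treating as updated",
                    base,
                    prev.version,
                    cur.version,
                )
            diff.updated[base] = (prev, cur)
    for base, prev in prev_by_base.items():
        if base not in cur_by_base:
            diff.lost.add(prev)
    diff.validate()
    return diff


@dataclass
class TypeStrainConflict:
    """Several genomes claim the type strain of one species yet disagree by ANI."""

    species_label: str
    genomes: tuple[Accession, ...]
    min_pairwise_ani: float | None  # None when an ANI pair is missing
    evidence: dict[str, str] = field(default_factory=dict)
    resolution: tuple[Accession, ...] | None = None

    @property
    def resolved(self) -> bool:
        return self.resolution is not None


def detect_type_strain_conflicts(
    clusters: Sequence[SpeciesCluster],
    records: Mapping[Accession, GenomeRecord],
    ani_matrix: AniMatrix,
    threshold: float = 99.0,
) -> list[TypeStrainConflict]:
    """Flag species whose type-strain genomes fall below the ANI threshold.

    Only species with at least two genomes assembled from the type strain
    can conflict. A missing ANI value among the type genomes is flagged as
    insufficient data. Nothing is auto-resolved.
    """
    conflicts: list[TypeStrainConflict] = []
    for c in sorted(clusters, key=lambda x: x.species_label):
        if c.retired:
            continue
        type_genomes = sorted(
            m
            for m in c.members
            if m in records
            and records[m].type_status is TypeStatus.TYPE_STRAIN_OF_SPECIES
        )
        if len(type_genomes) < 2:
            continue
        min_ani: float | None = 100.0
        missing = False
        for i, a in enumerate(type_genomes):
            for b in type_genomes[i + 1 :]:
                ani = ani_matrix.ani(a, b)
                if ani is None:
                    missing = True
                elif min_ani is not None:
                    min_ani = min(min_ani, ani)
        if missing:
            conflicts.append(
                TypeStrainConflict(
                    species_label=c.species_label,
                    genomes=tuple(type_genomes),
                    min_pairwise_ani=None,
                    evidence={"note": "insufficient data: missing ANI pair"},
                )
            )
        elif min_ani is not None and min_ani < threshold:
            evidence = {
                "ncbi_type_flags": ";".join(
                    f"{m}={records[m].type_status.value}" for m in type_genomes
                ),
                "ncbi_taxonomy": ";".join(
                    f"{m}={records[m].ncbi_taxonomy}" for m in type_genomes
                ),
                "ssu_lengths": ";".join(
                    f"{m}={list(records[m].ssu_lengths)}" for m in type_genomes
                ),
            }
            conflicts.append(
                TypeStrainConflict(
                    species_label=c.species_label,
                    genomes=tuple(type_genomes),
                    min_pairwise_ani=min_ani,
                    evidence=evidence,
                )
            )
    return conflicts


@dataclass(frozen=True)
class RepresentativeChange:
    species_label: str
    old: Accession
    new: Accession | None  # None for retirements
    reason: str


@dataclass(frozen=True)
class RepUpdateDecision:
    new_representative: Accession
    changed: bool
    reason: str | None
    margin_achieved: float | None = None


def _classify_promotion(old: GenomeRecord, new: GenomeRecord) -> str:
    if (
        new.type_status is TypeStatus.TYPE_STRAIN_OF_SPECIES
        and old.type_status is not TypeStatus.TYPE_STRAIN_OF_SPECIES
    ):
        return TYPE_STRAIN_PROMOTION
    if (
        new.type_status is TypeStatus.TYPE_STRAIN_OF_SUBSPECIES
        and old.type_status
        not in (TypeStatus.TYPE_STRAIN_OF_SPECIES, TypeStatus.TYPE_STRAIN_OF_SUBSPECIES)
    ):
        return SUBSPECIES_TYPE_PROMOTION
    return HIGHER_QUALITY_BAS


def update_representative(
    cluster: SpeciesCluster,
    rep_record: GenomeRecord,
    candidates: Sequence[GenomeRecord],
    ani_matrix: AniMatrix,
    scores: Mapping[Accession, float],
    config: Config | None = None,
) -> RepUpdateDecision:
    """Evaluate the best challenger against the incumbent representative.

    The challenger with the highest BAS (relative to the incumbent) must
    beat the incumbent's BAS by the replacement margin; the change reason is
    classified as a type-strain promotion (species, then subspecies) before
    falling back to higher assembly quality.
    """
    config = config or Config()
    rep_acc = rep_record.accession
    best: tuple[float, Accession] | None = None
    for cand in candidates:
        if cand.accession == rep_acc:
            continue
        ani = ani_matrix.ani(cand.accession, rep_acc)
        if ani is None:
            continue
        bas = balanced_ani_score(scores[cand.accession], ani)
        if best is None or (-bas, cand.accession) < (-best[0], best[1]):
            best = (bas, cand.accession)
    if best is None:
        return RepUpdateDecision(rep_acc, False, None)
    challenger = next(c for c in candidates if c.accession == best[1])
    decision = should_replace(
        scores[rep_acc],
        scores[challenger.accession],
        ani_matrix.ani(challenger.accession, rep_acc),
        margin=config.bas_replacement_margin,
    )
    if not decision.replace:
        return RepUpdateDecision(rep_acc, False, None, decision.margin_achieved)
    reason = _classify_promotion(rep_record, challenger)
    logger.debug(
        "%s: representative %s replaced by %s (BAS %.2f vs %.2f, reason %s)",
        cluster.species_label,
        rep_acc,
        challenger.accession,
        decision.challenger_bas,
        decision.incumbent_bas,
        reason,
    )
    return RepUpdateDecision(
        challenger.accession, True, reason, decision.margin_achieved
    )


def _best_bas_to(
    anchor: Accession,
    candidates: Sequence[GenomeRecord],
    ani_matrix: AniMatrix,
    scores: Mapping[Accession, float],
) -> Accession | None:
    """Candidate with the highest BAS relative to ``anchor``; ties break to
    the smaller accession; candidates with no detectable ANI are ineligible."""
    best: tuple[float, Accession] | None = None
    for cand in candidates:
        ani = ani_matrix.ani(cand.accession, anchor)
        if ani is None:
            continue
        bas = balanced_ani_score(scores[cand.accession], ani)
        if best is None or (-bas, cand.accession) < (-best[0], best[1]):
            best = (bas, cand.accession)
    return None if best is None else best[1]


def handle_updated_assembly(
    cluster: SpeciesCluster,
    previous_assembly: Accession,
    candidates: Sequence[GenomeRecord],
    ani_matrix: AniMatrix,
    scores: Mapping[Accession, float],
) -> Accession | None:
    """Re-elect the representative after its assembly was updated at source.

    Every cluster member including the new assembly is scored by BAS to the
    *previous* assembly of the representative; the highest wins (typically
    the new assembly). Returns None when no candidate shows detectable ANI
    to the previous assembly.
    """
    return _best_bas_to(previous_assembly, candidates, ani_matrix, scores)


def handle_suppressed_representative(
    cluster: SpeciesCluster,
    candidates: Sequence[GenomeRecord],
    ani_matrix: AniMatrix,
    scores: Mapping[Accession, float],
) -> Accession | None:
    """Replace a suppressed representative with the member of highest BAS to it.

    Returns None when the cluster holds no other usable genome, in which
    case the species cluster is retired.
    """
    return _best_bas_to(cluster.representative, candidates, ani_matrix, scores)


@dataclass
class ChangeReport:
    """Release-to-release accounting of representative and assignment changes."""

    prev_release_id: str
    new_release_id: str
    prev_species_count: int = 0
    cur_species_count: int = 0
    reps_unchanged: int = 0
    rep_changes: list[RepresentativeChange] = field(default_factory=list)
    retired: list[str] = field(default_factory=list)
    new_species: int = 0
    prev_genome_count: int = 0
    cur_genome_count: int = 0
    assign_same: int = 0
    assign_diff: int = 0
    suppressed: int = 0
    qc_removed: int = 0
    conflicts: list[TypeStrainConflict] = field(default_factory=list)
    frozen_species: list[str] = field(default_factory=list)

    @property
    def reps_changed(self) -> int:
        return len(self.rep_changes)

    @property
    def is_zero_change(self) -> bool:
        return (
            not self.rep_changes
            and not self.retired
            and self.new_species == 0
            and self.assign_diff == 0
            and self.suppressed == 0
        )

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ch in self.rep_changes:
            out[ch.reason] = out.get(ch.reason, 0) + 1
        return out


def _taxonomy_for(label: str, template: str | None) -> str:
    """7-rank taxonomy string for a species label, reusing higher ranks of a
    template string when available."""
    ranks = ["d__", "p__", "c__", "o__", "f__", "g__", label]
    if template:
        parts = [p.strip() for p in template.split(";")]
        if len(parts) == 7:
            ranks[:6] = parts[:6]
    genus = label[3:].split(" ")[0] if label.startswith("s__") else ""
    if genus and ranks[5] == "g__":
        ranks[5] = f"g__{genus}"
    return ";".join(ranks)


def update_release(
    prev: Release,
    current_records: Sequence[GenomeRecord],
    ani_matrix: AniMatrix,
    config: Config | None = None,
    resolutions: Mapping[str, Sequence[Accession]] | None = None,
    new_species_names: Mapping[str, Sequence[Accession]] | None = None,
    new_release_id: str | None = None,
) -> tuple[Release, ChangeReport]:
    """Run the full update workflow: diff, QC, type audit, representative
    updates (including the updated-assembly and suppressed-representative
    special cases), re-assignment and de novo clustering.

    ``resolutions`` maps a species label to the genome(s) accepted as the
    true type strain; species with unresolved conflicts are frozen to their
    prior representative. Genome-to-cluster assignment is recomputed from
    scratch, so membership always reflects the updated representatives.
    """
    config = config or Config()
    resolutions = {
        k: tuple(Accession.parse(a) if isinstance(a, str) else a for a in v)
        for k, v in (resolutions or {}).items()
    }
    prev.validate()

    # ------------------------------------------------------------------ diff
    prev_genomes = prev.genomes()
    diff = diff_releases(prev_genomes, current_records)
    cur_by_base = records_by_base(current_records)
    cur_by_acc = {r.accession: r for r in current_records}

    # -------------------------------------------------------------------- qc
    verdicts = {r.accession: passes_qc(r, config.qc) for r in current_records}
    usable = {acc for acc, v in verdicts.items() if v.passed}
    qc_removed = sum(
        1
        for acc, v in verdicts.items()
        if not v.passed and not cur_by_acc[acc].suppressed
    )

    def present(member: Accession) -> GenomeRecord | None:
        """Current usable record for a previous member, matched by base."""
        rec = cur_by_base.get(member.base)
        if rec is None or rec.accession not in usable:
            return None
        return rec

    # ----------------------------------------------------- type-strain audit
    audit_clusters = []
    for c in prev.active_clusters():
        members_now = {
            rec.accession for m in c.members if (rec := present(m)) is not None
        }
        rep_now_rec = present(c.representative)
        rep = rep_now_rec.accession if rep_now_rec is not None else c.representative
        audit_clusters.append(
            SpeciesCluster(
                representative=rep,
                species_label=c.species_label,
                members=members_now,
            )
        )
    conflicts = detect_type_strain_conflicts(
        audit_clusters,
        cur_by_acc,
        ani_matrix,
        threshold=config.type_conflict_ani,
    )
    frozen: set[str] = set()
    for conflict in conflicts:
        if conflict.species_label in resolutions:
            conflict.resolution = resolutions[conflict.species_label]
        else:
            frozen.add(conflict.species_label)

    scores = {
        r.accession: quality_score(r, config.full_length_ssu).total
        for r in current_records
    }
    # demote non-chosen type genomes of resolved conflicts for this run
    for conflict in conflicts:
        if not conflict.resolved:
            continue
        chosen = set(conflict.resolution or ())
        for g in conflict.genomes:
            if g not in chosen and g in cur_by_acc:
                demoted = cur_by_acc[g].evolve(type_status=TypeStatus.NONE)
                scores[g] = quality_score(demoted, config.full_length_ssu).total
                cur_by_acc[g] = demoted

    # -------------------------------------------- step 4: representative fate
    report = ChangeReport(
        prev_release_id=prev.release_id,
        new_release_id=new_release_id or f"{prev.release_id}+1",
        prev_species_count=len(prev.active_clusters()),
        prev_genome_count=len(prev_genomes),
        cur_genome_count=len(current_records),
        suppressed=len(diff.lost),
        qc_removed=qc_removed,
        conflicts=conflicts,
        frozen_species=sorted(frozen),
    )

    new_usable = [
        cur_by_acc[a] for a in sorted(diff.new) if a in usable
    ]

    carried: list[SpeciesCluster] = []
    retired: list[SpeciesCluster] = []
    prior_radius: dict[str, float] = {}
    for c in sorted(prev.active_clusters(), key=lambda x: x.species_label):
        rep_old = c.representative
        rep_now = present(rep_old)
        members_now = [
            rec
            for m in c.members
            if (rec := present(m)) is not None
        ]
        others = [r for r in members_now if r.accession.base != rep_old.base]
        # new genomes inside the circumscription radius are eligible challengers
        if rep_now is not None:
            for r in new_usable:
                pair = ani_matrix.get(r.accession, rep_now.accession)
                if pair is not None and pair[0] >= c.radius and pair[1] >= config.af_threshold:
                    others.append(r)

        if rep_now is None:
            # representative suppressed / lost / failing QC
            new_rep = handle_suppressed_representative(c, others, ani_matrix, scores)
            if new_rep is None:
                retired.append(
                    SpeciesCluster(
                        representative=rep_old,
                        species_label=c.species_label,
                        members={rep_old},
                        radius=c.radius,
                        retired=True,
                    )
                )
                report.retired.append(c.species_label)
                report.rep_changes.append(
                    RepresentativeChange(c.species_label, rep_old, None, CLUSTER_RETIRED)
                )
                continue
            report.rep_changes.append(
                RepresentativeChange(
                    c.species_label, rep_old, new_rep, SUPPRESSED_REP_REPLACED
                )
            )
        elif c.species_label in frozen:
            new_rep = rep_now.accession
            report.reps_unchanged += 1
        elif rep_old.base in diff.updated:
            winner = handle_updated_assembly(
                c, rep_old, members_now, ani_matrix, scores
            )
            new_rep = winner if winner is not None else rep_now.accession
            if new_rep.base != rep_old.base:
                report.rep_changes.append(
                    RepresentativeChange(
                        c.species_label, rep_old, new_rep, ASSEMBLY_UPDATED
                    )
                )
            else:
                report.reps_unchanged += 1
        else:
            decision = update_representative(
                c, rep_now, others, ani_matrix, scores, config
            )
            new_rep = decision.new_representative
            if decision.changed:
                report.rep_changes.append(
                    RepresentativeChange(
                        c.species_label, rep_old, new_rep, decision.reason
                    )
                )
            else:
                report.reps_unchanged += 1

        prior_radius[c.species_label] = c.radius
        carried.append(
            SpeciesCluster(
                representative=new_rep,
                species_label=c.species_label,
                members={new_rep},
                radius=max(95.0, c.radius),
            )
        )

    # ------------------------------------- new named-species representatives
    taken_reps = {c.representative for c in carried}
    for name in sorted(new_species_names or {}):
        candidates = [
            cur_by_acc[Accession.parse(a) if isinstance(a, str) else a]
            for a in new_species_names[name]
            if (Accession.parse(a) if isinstance(a, str) else a) in cur_by_acc
        ]
        candidates = [
            r for r in candidates if r.accession in usable and r.accession not in taken_reps
        ]
        if not candidates:
            logger.warning("named species %s has no usable genomes; skipped", name)
            continue
        rep = min(candidates, key=lambda r: (-scores[r.accession], r.accession))
        carried.append(
            SpeciesCluster(representative=rep.accession, species_label=name,
                           members={rep.accession})
        )
        taken_reps.add(rep.accession)
        report.new_species += 1

    # ------------------------------------------- radii among carried clusters
    all_reps = [c.representative for c in carried]
    for c in carried:
        c.radius = compute_radius(
            c.representative,
            all_reps,
            ani_matrix,
            config,
            prior_radius=prior_radius.get(c.species_label),
        )

    # --------------------------------------------------- de novo reassignment
    rep_set = {c.representative for c in carried}
    pool = [
        r
        for r in current_records
        if r.accession in usable and r.accession not in rep_set
    ]
    decisions = assign_genomes(pool, carried, ani_matrix, config)
    by_rep = {c.representative: c for c in carried}
    unassigned: list[GenomeRecord] = []
    for d in decisions:
        if d.assigned_to is None:
            unassigned.append(cur_by_acc[d.genome])
        else:
            by_rep[d.assigned_to].members.add(d.genome)

    existing_labels = {c.species_label for c in carried} | {
        c.species_label for c in retired
    }
    genus_of = {
        r.accession: genus_from_taxonomy(r.ncbi_taxonomy) for r in unassigned
    }
    new_clusters = denovo_cluster(
        unassigned, ani_matrix, config, genus_of=genus_of,
        label_start=len(existing_labels) + 1,
    )
    for nc in new_clusters:  # avoid colliding with carried labels
        while nc.species_label in existing_labels:
            idx = int(nc.species_label.rsplit("sp", 1)[1]) + 1
            head = nc.species_label.rsplit("sp", 1)[0]
            nc.species_label = f"{head}sp{idx:06d}"
        existing_labels.add(nc.species_label)
    report.new_species += len(new_clusters)

    clusters = carried + new_clusters
    for nc in new_clusters:
        nc.radius = compute_radius(
            nc.representative, [c.representative for c in clusters], ani_matrix, config
        )

    # ---------------------------------------------------------------- output
    prev_tax_of_label = {
        c.species_label: prev.taxonomy.get(c.representative)
        for c in prev.active_clusters()
    }
    taxonomy: dict[Accession, str] = {}
    for c in clusters:
        tax = _taxonomy_for(c.species_label, prev_tax_of_label.get(c.species_label))
        for m in c.members:
            taxonomy[m] = tax
    new_release = Release(
        release_id=report.new_release_id,
        clusters=clusters + retired,
        taxonomy=taxonomy,
    )
    new_release.validate()

    # ------------------------------------------------- assignment accounting
    prev_cluster_of = prev.cluster_of()
    new_cluster_of = new_release.cluster_of()
    for m in prev_genomes:
        rec = present(m)
        if rec is None:
            continue
        prev_label = prev_cluster_of[m].species_label
        new_label = new_cluster_of[rec.accession].species_label
        if new_label == prev_label:
            report.assign_same += 1
        else:
            report.assign_diff += 1
    report.cur_species_count = len(new_release.active_clusters())

    # conservation: every current genome is exactly one of
    # {clustered, QC-failed, suppressed}
    clustered = new_release.genomes()
    n_suppressed_cur = sum(1 for r in current_records if r.suppressed)
    if len(clustered) + qc_removed + n_suppressed_cur != len(current_records):
        raise ModelError(
            "conservation violated: "
            f"{len(clustered)} clustered + {qc_removed} QC-failed + "
            f"{n_suppressed_cur} suppressed != {len(current_records)} input genomes"
        )
    return new_release, report
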