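"""De novo formation of ANI-based species clusters and genome assignment.

Species are delineated greedily: genomes are visited in descending quality
score and each unclustered genome founds a cluster that absorbs every
remaining genome within the ANI circumscription radius (and above the
alignment-fraction threshold) of the founder. Non-representative genomes are
then assigned to the cluster whose representative they are most similar to.
Both steps are deterministic for any input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .ani import AniMatrix
from .config import Config
from .model import Accession, GenomeRecord, SpeciesCluster
from .scoring import quality_score

__all__ = [
    "AssignmentDecision",
    "select_named_representatives",
    "denovo_cluster",
    "assign_genomes",
    "compute_radius",
    "placeholder_label",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssignmentDecision:
    genome: Accession
    assigned_to: Accession | None
    ani: float | None
    af: float | None
    tie_broken_by: str = "none"  # none | af | accession


def _score_order_key(records: Sequence[GenomeRecord], config: Config):
    scores = {
        r.accession: quality_score(r, config.full_length_ssu).total for r in records
    }

    def key(r: GenomeRecord):
        return (-scores[r.accession], r.accession)

    return key, scores


def select_named_representatives(
    species_members: Mapping[str, Sequence[GenomeRecord]],
    config: Config | None = None,
) -> dict[str, Accession]:
    """Pick one representative per named species by maximum quality score.

    Type-strain genomes win automatically through score dominance (their
    +1 000 000 term exceeds any combination of assembly-quality terms).
    Ties break to the lexicographically smaller accession. Species with no
    genomes are skipped with a warning.
    """
    config = config or Config()
    chosen: dict[str, Accession] = {}
    for name in sorted(species_members):
        members = list(species_members[name])
        if not members:
            logger.warning("species %s has no QC-passing genomes; skipped", name)
            continue
        key, _ = _score_order_key(members, config)
        chosen[name] = min(members, key=key).accession
    return chosen


def placeholder_label(genus: str, index: int) -> str:
    """Deterministic provisional species label, e.g. ``s__Bradyrhizobium sp000042``."""
    genus_name = genus[3:] if genus.startswith("g__") else genus
    if genus_name:
        return f"s__{genus_name} sp{index:06d}"
    return f"s__sp{index:06d}"


def denovo_cluster(
    records: Sequence[GenomeRecord],
    ani_matrix: AniMatrix,
    config: Config | None = None,
    genus_of: Mapping[Accession, str] | None = None,
    label_start: int = 1,
) -> list[SpeciesCluster]:
    """Greedy quality-ranked species clustering.

    Genomes are processed in descending quality score (ties by accession);
    each unclustered genome founds a cluster and absorbs all remaining
    unclustered genomes with ANI >= the default radius and AF >= the
    threshold to the founder. Cluster labels are deterministic placeholders
    keyed to representative accession order; real names can be injected
    afterwards via a mapping.
    """
    config = config or Config()
    key, _ = _score_order_key(records, config)
    ordered = sorted(records, key=key)
    clustered: set[Accession] = set()
    clusters: list[SpeciesCluster] = []
    for founder in ordered:
        if founder.accession in clustered:
            continue
        members = {founder.accession}
        clustered.add(founder.accession)
        for other in ordered:
            if other.accession in clustered:
                continue
            pair = ani_matrix.get(founder.accession, other.accession)
            if pair is None:
                continue
            ani, af = pair
            if ani >= config.ani_radius_default and af >= config.af_threshold:
                members.add(other.accession)
                clustered.add(other.accession)
        clusters.append(
            SpeciesCluster(
                representative=founder.accession,
                species_label="",  # filled below, keyed to accession order
                members=members,
                radius=config.ani_radius_default,
            )
        )
    for i, cluster in enumerate(sorted(clusters, key=lambda c: c.representative)):
        genus = (genus_of or {}).get(cluster.representative, "")
        cluster.species_label = placeholder_label(genus, label_start + i)
    return clusters


def assign_genomes(
    records: Sequence[GenomeRecord],
    clusters: Sequence[SpeciesCluster],
    ani_matrix: AniMatrix,
    config: Config | None = None,
) -> list[AssignmentDecision]:
    """Assign each genome to the highest-ANI representative that circumscribes it.

    A cluster is eligible when ANI to its representative >= the cluster
    radius and AF >= the threshold. Ties on ANI break by higher AF, then by
    smaller representative accession. Genomes satisfying no cluster come
    back unassigned (they feed :func:`denovo_cluster`).
    """
    config = config or Config()
    decisions: list[AssignmentDecision] = []
    active = [c for c in clusters if not c.retired]
    for r in sorted(records, key=lambda x: x.accession):
        candidates: list[tuple[float, float, Accession]] = []
        for c in active:
            if r.accession == c.representative:
                continue
            pair = ani_matrix.get(r.accession, c.representative)
            if pair is None:
                continue
            ani, af = pair
            if ani >= c.radius and af >= config.af_threshold:
                candidates.append((ani, af, c.representative))
        if not candidates:
            decisions.append(AssignmentDecision(r.accession, None, None, None))
            continue
        best_ani = max(a for a, _, _ in candidates)
        at_ani = [c for c in candidates if c[0] == best_ani]
        tie = "none"
        if len(at_ani) > 1:
            best_af = max(af for _, af, _ in at_ani)
            at_af = [c for c in at_ani if c[1] == best_af]
            tie = "af" if len(at_af) == 1 else "accession"
            at_ani = at_af
        ani, af, rep = min(at_ani, key=lambda c: c[2])
        decisions.append(AssignmentDecision(r.accession, rep, ani, af, tie))
    return decisions


def compute_radius(
    representative: Accession,
    other_representatives: Iterable[Accession],
    ani_matrix: AniMatrix,
    config: Config | None = None,
    prior_radius: float | None = None,
) -> float:
    """Circumscription radius for one representative.

    95 by default; if another retained representative lies within 95% ANI
    the radius is raised to that pairwise ANI so neither cluster absorbs the
    other, capped at ``config.radius_cap``. A prior-release radius above the
    default is carried forward.
    """
    config = config or Config()
    radius = config.ani_radius_default
    if prior_radius is not None:
        radius = max(radius, min(prior_radius, config.radius_cap))
    for other in other_representatives:
        if other == representative:
            continue
        ani = ani_matrix.ani(representative, other)
        if ani is not None and ani >= config.ani_radius_default:
            radius = max(radius, min(ani, config.radius_cap))
    return radius
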