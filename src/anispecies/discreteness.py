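"""Discreteness of ANI-based species boundaries.

Two related analyses:

* **Closest representative pairs** — for every species representative, the
  highest-ANI other representative within the same genus. A genetic
  discontinuity between species would show up as a gap in this distribution
  below the 95% circumscription threshold.
* **Closest interspecific genome pairs** — for every genome, the closest
  genome in a different species of the same genus. To keep the search
  tractable the target species is fixed per species: if the closest
  representative to species A's representative belongs to species B, every
  genome of A is searched against all genomes of B (heuristic; an exhaustive
  brute-force search is available for validation). Species containing more
  genomes than the subsample cap contribute a seeded random subset.

Species verdicts: *fuzzy* when one or more genomes has an interspecific ANI
>= 95%; *discrete* when no genome exceeds 94%; values strictly between fall
in an *intermediate* class that the two headline fractions do not cover.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ani import AniMatrix
from .config import Config
from .model import Accession, SpeciesCluster, genus_from_taxonomy

__all__ = [
    "InterspecificRecord",
    "DiscretenessResult",
    "closest_rep_pairs",
    "closest_interspecific_pairs",
    "brute_force_interspecific_pairs",
    "classify_species",
]

FUZZY = "fuzzy"
DISCRETE = "discrete"
INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class InterspecificRecord:
    """Closest interspecific neighbour of one genome."""

    genome: Accession
    species: str
    closest_genome: Accession
    closest_species: str
    ani: float


@dataclass
class DiscretenessResult:
    records: list[InterspecificRecord]
    verdicts: dict[str, str]  # species label -> fuzzy | discrete | intermediate
    subsample_log: list[tuple[str, int, int]] = field(default_factory=list)
    # (species, sampled n, per-species seed)

    @property
    def fuzzy_species_pct(self) -> float:
        return self._pct(FUZZY)

    @property
    def discrete_species_pct(self) -> float:
        return self._pct(DISCRETE)

    @property
    def intermediate_species_pct(self) -> float:
        return self._pct(INTERMEDIATE)

    def _pct(self, verdict: str) -> float:
        if not self.verdicts:
            return 0.0
        n = sum(1 for v in self.verdicts.values() if v == verdict)
        return 100.0 * n / len(self.verdicts)

    @property
    def fuzzy_pair_pct(self) -> float:
        """Fraction of per-genome closest pairs with ANI >= 95 (percent)."""
        if not self.records:
            return 0.0
        return 100.0 * sum(1 for r in self.records if r.ani >= 95.0) / len(self.records)

    @property
    def discrete_pair_pct(self) -> float:
        """Fraction of per-genome closest pairs with ANI <= 94 (percent)."""
        if not self.records:
            return 0.0
        return 100.0 * sum(1 for r in self.records if r.ani <= 94.0) / len(self.records)


def _genus_groups(
    clusters: Sequence[SpeciesCluster], taxonomy: Mapping[Accession, str]
) -> dict[str, list[SpeciesCluster]]:
    groups: dict[str, list[SpeciesCluster]] = {}
    for c in clusters:
        if c.retired:
            continue
        genus = genus_from_taxonomy(taxonomy.get(c.representative, ""))
        groups.setdefault(genus, []).append(c)
    return groups


def closest_rep_pairs(
    clusters: Sequence[SpeciesCluster],
    taxonomy: Mapping[Accession, str],
    ani_matrix: AniMatrix,
) -> list[tuple[str, str, float]]:
    """Per species, the maximum-ANI other representative in the same genus.

    Singleton genera are omitted; pairs with no measurable ANI to any
    intrageneric representative are omitted (below detection).
    """
    out: list[tuple[str, str, float]] = []
    for genus, group in sorted(_genus_groups(clusters, taxonomy).items()):
        if len(group) < 2:
            continue
        for c in sorted(group, key=lambda x: x.species_label):
            best: tuple[float, str] | None = None
            for other in group:
                if other is c:
                    continue
                ani = ani_matrix.ani(c.representative, other.representative)
                if ani is None:
                    continue
                if best is None or (-ani, other.species_label) < (-best[0], best[1]):
                    best = (ani, other.species_label)
            if best is not None:
                out.append((c.species_label, best[1], best[0]))
    return out


def _species_seed(base_seed: int, species_label: str) -> int:
    """Derive a per-species stream from one seed by hashing the label, so
    adding species does not reshuffle the subsampling of others."""
    return (base_seed * 1_000_003 + zlib.crc32(species_label.encode())) % (2**31)


def closest_interspecific_pairs(
    clusters: Sequence[SpeciesCluster],
    taxonomy: Mapping[Accession, str],
    ani_matrix: AniMatrix,
    subsample: int = 150,
    seed: int = 42,
) -> tuple[list[InterspecificRecord], list[tuple[str, int, int]]]:
    """Closest interspecific genome for each (sub)sampled genome.

    Only species in multi-species genera with the default circumscription
    radius of 95 are analysed; wider-radius species are exceptional cases
    but remain eligible as search targets. For species A the search is
    restricted to all genomes of species B, where B holds the closest
    intrageneric representative to A's representative.
    """
    rep_pairs = {a: b for a, b, _ in closest_rep_pairs(clusters, taxonomy, ani_matrix)}
    by_label = {c.species_label: c for c in clusters if not c.retired}
    records: list[InterspecificRecord] = []
    log: list[tuple[str, int, int]] = []
    for genus, group in sorted(_genus_groups(clusters, taxonomy).items()):
        if len(group) < 2:
            continue
        for c in sorted(group, key=lambda x: x.species_label):
            if c.radius > 95.0:
                continue  # exceptional wide-radius species: excluded as subjects
            target_label = rep_pairs.get(c.species_label)
            if target_label is None:
                continue
            target = by_label[target_label]
            members = sorted(c.members)
            if len(members) > subsample:
                sp_seed = _species_seed(seed, c.species_label)
                rng = np.random.default_rng(sp_seed)
                idx = rng.choice(len(members), size=subsample, replace=False)
                members = [members[i] for i in sorted(idx)]
                log.append((c.species_label, subsample, sp_seed))
            for g in members:
                best: tuple[float, Accession] | None = None
                for t in sorted(target.members):
                    ani = ani_matrix.ani(g, t)
                    if ani is None:
                        continue
                    if best is None or (-ani, t) < (-best[0], best[1]):
                        best = (ani, t)
                if best is not None:
                    records.append(
                        InterspecificRecord(
                            genome=g,
                            species=c.species_label,
                            closest_genome=best[1],
                            closest_species=target_label,
                            ani=best[0],
                        )
                    )
    return records, log


def brute_force_interspecific_pairs(
    clusters: Sequence[SpeciesCluster],
    taxonomy: Mapping[Accession, str],
    ani_matrix: AniMatrix,
) -> list[InterspecificRecord]:
    """Exhaustive closest-interspecific search (validation oracle).

    Examines every genome against all genomes of every other species in the
    same genus, with no subsampling and no closest-representative shortcut.
    """
    records: list[InterspecificRecord] = []
    for genus, group in sorted(_genus_groups(clusters, taxonomy).items()):
        if len(group) < 2:
            continue
        for c in sorted(group, key=lambda x: x.species_label):
            if c.radius > 95.0:
                continue
            for g in sorted(c.members):
                best: tuple[float, Accession, str] | None = None
                for other in group:
                    if other is c:
                        continue
                    for t in sorted(other.members):
                        ani = ani_matrix.ani(g, t)
                        if ani is None:
                            continue
                        cand = (ani, t, other.species_label)
                        if best is None or (-ani, t) < (-best[0], best[1]):
                            best = cand
                if best is not None:
                    records.append(
                        InterspecificRecord(
                            genome=g,
                            species=c.species_label,
                            closest_genome=best[1],
                            closest_species=best[2],
                            ani=best[0],
                        )
                    )
    return records


def classify_species(
    records: Iterable[InterspecificRecord],
    fuzzy_ani: float = 95.0,
    discrete_ani: float = 94.0,
    subsample_log: Sequence[tuple[str, int, int]] = (),
) -> DiscretenessResult:
    """Group per-genome records by species and apply the fuzzy/discrete rules.

    fuzzy: max interspecific ANI >= ``fuzzy_ani``; discrete: max <=
    ``discrete_ani``; anything strictly between is intermediate. The two
    verdicts are mutually exclusive by construction when
    ``fuzzy_ani > discrete_ani``.
    """
    records = list(records)
    max_by_species: dict[str, float] = {}
    for r in records:
        cur = max_by_species.get(r.species)
        if cur is None or r.ani > cur:
            max_by_species[r.species] = r.ani
    verdicts: dict[str, str] = {}
    for sp, m in max_by_species.items():
        if m >= fuzzy_ani:
            verdicts[sp] = FUZZY
        elif m <= discrete_ani:
            verdicts[sp] = DISCRETE
        else:
            verdicts[sp] = INTERMEDIATE
    return DiscretenessResult(
        records=records, verdicts=verdicts, subsample_log=list(subsample_log)
    )
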