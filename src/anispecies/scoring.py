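"""Genome quality score, ANI score, Balanced ANI Score and the replacement rule.

The quality score is a weighted sum over assembly and type-material
attributes whose magnitudes are tiered so nomenclatural priority dominates
assembly quality: a genome assembled from the type strain of a species
(+1 000 000) always outranks an effective type at NCBI (+100 000), which
outranks an NCBI representative genome (+10 000), and so on down to
continuous assembly-quality terms of magnitude ~100.

Representative replacement is governed by the Balanced ANI Score (BAS),

    BAS = 0.5 * ani_score + 0.5 * quality_score
    ani_score = 100 - 20 * (100 - ANI to the current representative)

so a challenger must be of increasingly higher quality the more it diverges
from the incumbent representative.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import GenomeRecord, TypeStatus

__all__ = [
    "ScoreBreakdown",
    "ReplacementDecision",
    "quality_score",
    "ani_score",
    "balanced_ani_score",
    "should_replace",
]

TYPE_SPECIES_SCORE = 1_000_000.0
NCBI_EFFECTIVE_TYPE_SCORE = 100_000.0
NCBI_REPRESENTATIVE_SCORE = 10_000.0
TYPE_SUBSPECIES_SCORE = 1_000.0
COMPLETE_GENOME_SCORE = 100.0
MAG_SAG_PENALTY = -100.0
FULL_LENGTH_SSU_BONUS = 10.0


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-criterion contributions to the quality score; `total` is their exact sum."""

    type_strain_species: float = 0.0
    ncbi_effective_type: float = 0.0
    ncbi_representative: float = 0.0
    type_strain_subspecies: float = 0.0
    complete_genome: float = 0.0
    checkm_term: float = 0.0
    mag_sag_penalty: float = 0.0
    contig_term: float = 0.0
    n_base_term: float = 0.0
    ssu_bonus: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.type_strain_species
            + self.ncbi_effective_type
            + self.ncbi_representative
            + self.type_strain_subspecies
            + self.complete_genome
            + self.checkm_term
            + self.mag_sag_penalty
            + self.contig_term
            + self.n_base_term
            + self.ssu_bonus
        )

    def as_dict(self) -> dict[str, float]:
        d = {
            "type_strain_species": self.type_strain_species,
            "ncbi_effective_type": self.ncbi_effective_type,
            "ncbi_representative": self.ncbi_representative,
            "type_strain_subspecies": self.type_strain_subspecies,
            "complete_genome": self.complete_genome,
            "checkm_term": self.checkm_term,
            "mag_sag_penalty": self.mag_sag_penalty,
            "contig_term": self.contig_term,
            "n_base_term": self.n_base_term,
            "ssu_bonus": self.ssu_bonus,
        }
        d["total"] = self.total
        return d


def quality_score(g: GenomeRecord, full_length_ssu: int = 1200) -> ScoreBreakdown:
    """Score an assembly; continuous terms are never rounded.

    ``full_length_ssu`` is the minimum annotated 16S gene length (nt) that
    earns the full-length bonus.
    """
    return ScoreBreakdown(
        type_strain_species=(
            TYPE_SPECIES_SCORE
            if g.type_status is TypeStatus.TYPE_STRAIN_OF_SPECIES
            else 0.0
        ),
        ncbi_effective_type=(
            NCBI_EFFECTIVE_TYPE_SCORE
            if g.type_status is TypeStatus.NCBI_EFFECTIVE_TYPE
            else 0.0
        ),
        ncbi_representative=(
            NCBI_REPRESENTATIVE_SCORE if g.ncbi_representative else 0.0
        ),
        type_strain_subspecies=(
            TYPE_SUBSPECIES_SCORE
            if g.type_status is TypeStatus.TYPE_STRAIN_OF_SUBSPECIES
            else 0.0
        ),
        complete_genome=COMPLETE_GENOME_SCORE if g.is_complete_assembly else 0.0,
        checkm_term=g.completeness - 5.0 * g.contamination,
        mag_sag_penalty=MAG_SAG_PENALTY if (g.is_mag or g.is_sag) else 0.0,
        contig_term=-5.0 * (g.contig_count / 100.0),
        n_base_term=-5.0 * (g.undetermined_bases / 10_000.0),
        ssu_bonus=(
            FULL_LENGTH_SSU_BONUS
            if any(length >= full_length_ssu for length in g.ssu_lengths)
            else 0.0
        ),
    )


def ani_score(ani: float) -> float:
    """``100 - 20 * (100 - ani)``; strongly negative for divergent genomes."""
    if not 0.0 <= ani <= 100.0:
        raise ValueError(f"ANI {ani} outside [0, 100]")
    return 100.0 - 20.0 * (100.0 - ani)


def balanced_ani_score(quality: float, ani: float) -> float:
    """BAS: equal-weight blend of divergence penalty and assembly quality."""
    return 0.5 * ani_score(ani) + 0.5 * quality


@dataclass(frozen=True)
class ReplacementDecision:
    replace: bool
    margin_achieved: float
    challenger_bas: float
    incumbent_bas: float


def should_replace(
    current_quality: float,
    challenger_quality: float,
    ani_challenger_to_current: float,
    margin: float = 10.0,
) -> ReplacementDecision:
    """Decide whether a challenger displaces the current representative.

    The incumbent's own BAS is evaluated at ANI = 100 (self identity).
    Replacement requires the challenger's BAS to reach the incumbent's BAS
    plus ``margin`` (inclusive at the boundary).
    """
    incumbent = balanced_ani_score(current_quality, 100.0)
    challenger = balanced_ani_score(challenger_quality, ani_challenger_to_current)
    achieved = challenger - incumbent
    return ReplacementDecision(
        replace=achieved >= margin,
        margin_achieved=achieved,
        challenger_bas=challenger,
        incumbent_bas=incumbent,
    )
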