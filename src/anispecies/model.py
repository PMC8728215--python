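"""Core domain types for ANI-based species clustering.

The unit of everything is a genome assembly (:class:`GenomeRecord`) identified
by a versioned NCBI-style accession (:class:`Accession`). Pairwise genome
similarity is expressed as average nucleotide identity (ANI, percent) plus an
alignment fraction (AF, fraction of fragments aligned) held in
:class:`AniEdge`. Species are modelled as clusters around a single
representative genome (:class:`SpeciesCluster`) with an ANI circumscription
radius, and a versioned collection of clusters plus taxonomy strings forms a
:class:`Release`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "Accession",
    "TypeStatus",
    "GenomeRecord",
    "AniEdge",
    "SpeciesCluster",
    "Release",
    "ModelError",
]


class ModelError(ValueError):
    """Raised when a domain invariant is violated."""


_ACCESSION_RE = re.compile(r"^(GC[AF]_\d+)\.(\d+)$")


@dataclass(frozen=True, order=True)
class Accession:
    """A versioned genome assembly accession, e.g. ``GCF_004359525.2``.

    Accessions compare by ``(base, version)``. GCA (GenBank) and GCF (RefSeq)
    prefixes are preserved and never unified: two assemblies mirrored under
    both databases are distinct records.
    """

    base: str
    version: int

    def __post_init__(self) -> None:
        if not re.fullmatch(r"GC[AF]_\d+", self.base):
            raise ModelError(f"invalid accession base {self.base!r}")
        if self.version < 1:
            raise ModelError(f"accession version must be >= 1, got {self.version}")

    @classmethod
    def parse(cls, text: str) -> "Accession":
        m = _ACCESSION_RE.fullmatch(text.strip())
        if m is None:
            raise ModelError(f"malformed accession {text!r}")
        return cls(m.group(1), int(m.group(2)))

    @property
    def source_db(self) -> str:
        """``refseq`` for GCF accessions, ``genbank`` for GCA."""
        return "refseq" if self.base.startswith("GCF") else "genbank"

    def with_version(self, version: int) -> "Accession":
        return Accession(self.base, version)

    def __str__(self) -> str:
        return f"{self.base}.{self.version}"


class TypeStatus(str, Enum):
    """Nomenclatural type-material status of an assembly.

    A record carries at most one status; the NCBI "representative genome"
    designation is an independent flag on :class:`GenomeRecord`.
    """

    TYPE_STRAIN_OF_SPECIES = "type_strain_of_species"
    NCBI_EFFECTIVE_TYPE = "ncbi_effective_type"
    TYPE_STRAIN_OF_SUBSPECIES = "type_strain_of_subspecies"
    NONE = "none"


@dataclass(frozen=True)
class GenomeRecord:
    """One genome assembly with identity, provenance, quality and type attributes.

    ``completeness`` and ``contamination`` are CheckM estimates in percent;
    ``undetermined_bases`` counts ambiguous (N) characters. ``ssu_lengths``
    lists the lengths (nt) of annotated 16S rRNA genes. Exactly one of
    MAG / SAG / isolate holds; isolate status is derived.
    """

    accession: Accession
    completeness: float = 0.0
    contamination: float = 0.0
    contig_count: int = 1
    undetermined_bases: int = 0
    is_complete_assembly: bool = False
    is_mag: bool = False
    is_sag: bool = False
    ssu_lengths: tuple[int, ...] = ()
    trna_count: int | None = None
    n50: int | None = None
    type_status: TypeStatus = TypeStatus.NONE
    ncbi_representative: bool = False
    ncbi_taxonomy: str = ""
    suppressed: bool = False
    multi_isolate_project: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.accession, str):  # convenience for terse construction
            object.__setattr__(self, "accession", Accession.parse(self.accession))
        if not 0.0 <= self.completeness <= 100.0:
            raise ModelError(
                f"{self.accession}: completeness {self.completeness} outside [0, 100]"
            )
        if self.contamination < 0.0:
            raise ModelError(
                f"{self.accession}: contamination {self.contamination} must be >= 0"
            )
        if self.contig_count < 0:
            raise ModelError(f"{self.accession}: negative contig count")
        if self.undetermined_bases < 0:
            raise ModelError(f"{self.accession}: negative undetermined base count")
        if self.is_mag and self.is_sag:
            raise ModelError(f"{self.accession}: cannot be both MAG and SAG")

    @property
    def is_isolate(self) -> bool:
        return not (self.is_mag or self.is_sag)

    @property
    def source_db(self) -> str:
        return self.accession.source_db

    def evolve(self, **changes) -> "GenomeRecord":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class AniEdge:
    """Directed ANI/AF value between a query and a reference genome."""

    query: Accession
    reference: Accession
    ani: float
    af: float

    def __post_init__(self) -> None:
        if isinstance(self.query, str):
            object.__setattr__(self, "query", Accession.parse(self.query))
        if isinstance(self.reference, str):
            object.__setattr__(self, "reference", Accession.parse(self.reference))
        if not 0.0 <= self.ani <= 100.0:
            raise ModelError(f"ANI {self.ani} outside [0, 100]")
        if not 0.0 <= self.af <= 1.0:
            raise ModelError(f"AF {self.af} outside [0, 1]")
        if self.query == self.reference and (self.ani != 100.0 or self.af != 1.0):
            raise ModelError(
                f"self-edge for {self.query} must have ani=100, af=1 "
                f"(got ani={self.ani}, af={self.af})"
            )


@dataclass
class SpeciesCluster:
    """A species: one representative genome, its circumscription radius and members.

    The radius is the ANI threshold (percent) within which genomes belong to
    this species; 95 by default, above 95 only when another retained species
    representative lies within 95% ANI of this one.
    """

    representative: Accession
    species_label: str
    members: set[Accession] = field(default_factory=set)
    radius: float = 95.0
    retired: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.representative, str):
            self.representative = Accession.parse(self.representative)
        self.members = {
            Accession.parse(m) if isinstance(m, str) else m for m in self.members
        }
        self.members.add(self.representative)
        if self.radius < 95.0:
            raise ModelError(
                f"{self.species_label}: circumscription radius {self.radius} < 95"
            )

    @property
    def size(self) -> int:
        return len(self.members)

    def validate(self) -> None:
        if self.representative not in self.members:
            raise ModelError(
                f"{self.species_label}: representative {self.representative} "
                "not among members"
            )


def species_from_taxonomy(taxonomy: str) -> str:
    """Extract the species rank (``s__...``) from a 7-rank taxonomy string."""
    for rank in taxonomy.split(";"):
        rank = rank.strip()
        if rank.startswith("s__"):
            return rank
    return ""


def genus_from_taxonomy(taxonomy: str) -> str:
    """Extract the genus rank (``g__...``) from a 7-rank taxonomy string."""
    for rank in taxonomy.split(";"):
        rank = rank.strip()
        if rank.startswith("g__"):
            return rank
    return ""


@dataclass
class Release:
    """A versioned set of species clusters plus a taxonomy for every member."""

    release_id: str
    clusters: list[SpeciesCluster] = field(default_factory=list)
    taxonomy: dict[Accession, str] = field(default_factory=dict)

    def active_clusters(self) -> list[SpeciesCluster]:
        return [c for c in self.clusters if not c.retired]

    def genomes(self) -> set[Accession]:
        out: set[Accession] = set()
        for c in self.active_clusters():
            out |= c.members
        return out

    def cluster_of(self) -> dict[Accession, SpeciesCluster]:
        mapping: dict[Accession, SpeciesCluster] = {}
        for c in self.active_clusters():
            for m in c.members:
                mapping[m] = c
        return mapping

    def validate(self) -> None:
        """Check release invariants; raise :class:`ModelError` on violation."""
        seen: dict[Accession, str] = {}
        for c in self.active_clusters():
            c.validate()
            for m in c.members:
                if m in seen:
                    raise ModelError(
                        f"genome {m} belongs to both {seen[m]} and {c.species_label}"
                    )
                seen[m] = c.species_label
        for c in self.active_clusters():
            for m in c.members:
                tax = self.taxonomy.get(m)
                if tax is None:
                    raise ModelError(f"genome {m} has no taxonomy entry")
                sp = species_from_taxonomy(tax)
                if sp != c.species_label:
                    raise ModelError(
                        f"genome {m}: taxonomy species {sp!r} disagrees with "
                        f"cluster label {c.species_label!r}"
                    )


def records_by_accession(records: Iterable[GenomeRecord]) -> dict[Accession, GenomeRecord]:
    out: dict[Accession, GenomeRecord] = {}
    for r in records:
        if r.accession in out:
            raise ModelError(f"duplicate accession {r.accession}")
        out[r.accession] = r
    return out


def records_by_base(records: Iterable[GenomeRecord]) -> dict[str, GenomeRecord]:
    """Index records by accession base; at most one version per base expected."""
    out: dict[str, GenomeRecord] = {}
    for r in records:
        if r.accession.base in out:
            raise ModelError(
                f"two versions of {r.accession.base} in one release"
            )
        out[r.accession.base] = r
    return out
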