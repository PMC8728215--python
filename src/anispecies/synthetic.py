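"""Synthetic fixtures with planted species structure.

Everything the engine consumes — metadata tables, ANI/AF matrices, release
pairs with known expected outcomes, and FASTA sequence sets — can be
generated here so the whole pipeline is testable without downloading
genomes. ANI values are sampled directly from configurable bands in the
default mode (within-species identities well above the 95% circumscription
radius, between-species identities below it, optional "fuzzy" bands
straddling the boundary); the sequence mode exists to exercise the built-in
fragment ANI estimator end to end.

All outputs are deterministic functions of an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .ani import AniMatrix
from .clustering import denovo_cluster
from .config import Config
from .model import Accession, GenomeRecord, Release, SpeciesCluster, TypeStatus

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "Perturbation",
    "Expectation",
    "ReleasePair",
    "generate_dataset",
    "generate_release_pair",
    "generate_sequences",
    "mutate_sequence",
]

_TAX_PREFIX = "d__Bacteria;p__Fixturota;c__Fixturia;o__Fixturales;f__Fixturaceae"


@dataclass(frozen=True)
class SyntheticSpec:
    """Statistical shape of a planted-species dataset.

    ANI bands are (low, high) percent bounds of uniform distributions; in
    separable mode (no fuzzy injection) the within band must lie strictly
    above the between band.
    """

    n_species: int = 10
    genomes_per_species: int | tuple[int, int] = (3, 8)
    species_per_genus: int = 3
    within_ani: tuple[float, float] = (96.5, 99.9)
    between_ani: tuple[float, float] = (78.0, 93.0)
    fuzzy_pair_rate: float = 0.0
    fuzzy_band: tuple[float, float] = (94.2, 96.0)
    completeness: tuple[float, float] = (85.0, 100.0)
    contamination: tuple[float, float] = (0.0, 4.0)
    contig_range: tuple[int, int] = (1, 300)
    undetermined_range: tuple[int, int] = (0, 20_000)
    mag_fraction: float = 0.3
    type_strains_per_species: int = 1
    within_af: tuple[float, float] = (0.75, 0.98)
    between_af: tuple[float, float] = (0.20, 0.60)

    def __post_init__(self) -> None:
        for name in ("within_ani", "between_ani", "fuzzy_band"):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi <= 100:
                raise ValueError(f"{name} bounds {lo}-{hi} invalid")
        if self.fuzzy_pair_rate == 0.0 and self.between_ani[1] >= self.within_ani[0]:
            raise ValueError(
                "infeasible bands: between-species ANI overlaps within-species "
                "ANI without fuzzy injection"
            )
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")


@dataclass
class SyntheticDataset:
    records: list[GenomeRecord]
    matrix: AniMatrix
    truth: dict[Accession, str]  # planted partition: genome -> species label
    taxonomy: dict[Accession, str]
    species_labels: list[str]
    fuzzy_species: set[str] = field(default_factory=set)

    def records_of(self, label: str) -> list[GenomeRecord]:
        return [r for r in self.records if self.truth[r.accession] == label]


def _species_sizes(spec: SyntheticSpec, rng: np.random.Generator) -> list[int]:
    if isinstance(spec.genomes_per_species, int):
        return [spec.genomes_per_species] * spec.n_species
    lo, hi = spec.genomes_per_species
    return [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_species)]


def _accession(species_idx: int, genome_idx: int) -> Accession:
    return Accession(f"GCA_{(species_idx + 1) * 1000 + genome_idx:09d}", 1)


def generate_dataset(
    spec: SyntheticSpec,
    seed: int,
    sizes: Sequence[int] | None = None,
) -> SyntheticDataset:
    """Sample genomes and a symmetric ANI/AF matrix consistent with the
    planted partition.

    One designated type-strain genome per species by default (configurable,
    including >= 2 for type-conflict fixtures); all records pass the default
    QC gate by construction. Genomes in different genera have no ANI edge
    (below detection). Fully reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    sizes = list(sizes) if sizes is not None else _species_sizes(spec, rng)
    if len(sizes) != spec.n_species:
        raise ValueError("sizes length must equal n_species")

    records: list[GenomeRecord] = []
    truth: dict[Accession, str] = {}
    taxonomy: dict[Accession, str] = {}
    labels: list[str] = []
    genus_of_species: list[str] = []
    members: list[list[Accession]] = []

    for s in range(spec.n_species):
        genus_idx = s // spec.species_per_genus
        genus = f"Genus{genus_idx + 1:03d}"
        label = f"s__{genus} sp{s + 1:03d}"
        labels.append(label)
        genus_of_species.append(genus)
        accs: list[Accession] = []
        for j in range(sizes[s]):
            acc = _accession(s, j)
            accs.append(acc)
            is_type = j < spec.type_strains_per_species
            is_mag = (not is_type) and rng.random() < spec.mag_fraction
            completeness = float(rng.uniform(*spec.completeness))
            record = GenomeRecord(
                accession=acc,
                completeness=completeness,
                contamination=float(rng.uniform(*spec.contamination)),
                contig_count=int(rng.integers(*spec.contig_range)),
                undetermined_bases=int(rng.integers(*spec.undetermined_range)),
                is_complete_assembly=(not is_mag) and rng.random() < 0.15,
                is_mag=is_mag,
                ssu_lengths=(1530,) if rng.random() < (0.3 if is_mag else 0.85) else (),
                type_status=(
                    TypeStatus.TYPE_STRAIN_OF_SPECIES if is_type else TypeStatus.NONE
                ),
                ncbi_taxonomy=f"{_TAX_PREFIX};g__{genus};{label}",
            )
            records.append(record)
            truth[acc] = label
            taxonomy[acc] = f"{_TAX_PREFIX};g__{genus};{label}"
        members.append(accs)

    matrix = AniMatrix(policy="max")
    fuzzy_species: set[str] = set()
    for s in range(spec.n_species):
        for i, a in enumerate(members[s]):
            for b in members[s][i + 1 :]:
                matrix.set(
                    a, b,
                    float(rng.uniform(*spec.within_ani)),
                    float(rng.uniform(*spec.within_af)),
                )
    for s in range(spec.n_species):
        for t in range(s + 1, spec.n_species):
            if genus_of_species[s] != genus_of_species[t]:
                continue  # below detection across genera
            fuzzy_pair = rng.random() < spec.fuzzy_pair_rate
            if fuzzy_pair:
                fuzzy_species |= {labels[s], labels[t]}
            band = spec.fuzzy_band if fuzzy_pair else spec.between_ani
            # between-species divergence is a property of the species pair:
            # one mean per pair, small per-genome jitter around it
            jitter = min(0.3, (band[1] - band[0]) / 2)
            mean = float(rng.uniform(band[0] + jitter, band[1] - jitter))
            for a in members[s]:
                for b in members[t]:
                    matrix.set(
                        a, b,
                        mean + float(rng.uniform(-jitter, jitter)),
                        float(rng.uniform(*spec.between_af)),
                    )
    return SyntheticDataset(
        records=records,
        matrix=matrix,
        truth=truth,
        taxonomy=taxonomy,
        species_labels=labels,
        fuzzy_species=fuzzy_species,
    )


def dataset_release(
    dataset: SyntheticDataset, release_id: str = "R01", config: Config | None = None
) -> Release:
    """Cluster a separable dataset and package it as a release carrying the
    planted species names."""
    config = config or Config()
    clusters = denovo_cluster(dataset.records, dataset.matrix, config)
    for c in clusters:
        c.species_label = dataset.truth[c.representative]
    taxonomy = {
        acc: dataset.taxonomy[acc] for c in clusters for acc in c.members
    }
    release = Release(release_id=release_id, clusters=clusters, taxonomy=taxonomy)
    release.validate()
    return release


@dataclass(frozen=True)
class Perturbation:
    """What happens between two releases, with rates the tests can assert on."""

    n_new_genomes: int = 0            # new MAG members of existing species
    n_new_species: int = 0            # entirely novel species (de novo expected)
    n_suppress_singleton_reps: int = 0
    n_suppress_member_reps: int = 0   # representative suppressed, cluster survives
    n_update_rep_assembly: int = 0    # benign assembly version bump
    divergent_update: bool = False    # updated assembly deeply divergent from old
    divergent_update_ani: float = 80.6
    divergent_sibling_ani: float = 99.99
    n_add_type_strain: int = 0        # new type-strain genome joins a cluster
    n_quality_upgrade: int = 0        # new clearly higher-quality genome


@dataclass(frozen=True)
class Expectation:
    kind: str  # reason tag, or assigned / new_cluster / retirement
    species_label: str
    expected_representative: Accession | None = None
    genome: Accession | None = None


@dataclass
class ReleasePair:
    prev: Release
    prev_records: list[GenomeRecord]
    current_records: list[GenomeRecord]
    matrix: AniMatrix
    expectations: list[Expectation]
    dataset: SyntheticDataset


def generate_release_pair(
    spec: SyntheticSpec,
    perturbation: Perturbation,
    seed: int,
    config: Config | None = None,
) -> ReleasePair:
    """Build release t, apply a perturbation, and attach ground-truth
    expectations about what the update workflow must report.

    Clusters targeted by type-strain or quality-upgrade perturbations need a
    non-type representative, and the divergent-update scenario tests the ANI
    term of the BAS election rather than type dominance, so those scenarios
    generate the base dataset without designated type strains.
    """
    from .scoring import balanced_ani_score, quality_score

    config = config or Config()
    rng = np.random.default_rng(seed)
    needs_typeless = (
        perturbation.n_add_type_strain
        or perturbation.n_quality_upgrade
        or perturbation.divergent_update
    )
    base_spec = spec
    if needs_typeless and spec.type_strains_per_species:
        base_spec = replace(spec, type_strains_per_species=0)

    # force cluster sizes required by the perturbation, in species order
    n_targeted = (
        perturbation.n_suppress_singleton_reps
        + perturbation.n_suppress_member_reps
        + perturbation.n_update_rep_assembly
        + int(perturbation.divergent_update)
        + perturbation.n_add_type_strain
        + perturbation.n_quality_upgrade
    )
    if n_targeted > base_spec.n_species:
        raise ValueError(
            f"perturbation touches {n_targeted} species but only "
            f"{base_spec.n_species} generated"
        )
    sizes = _species_sizes(base_spec, rng)
    idx = 0
    for _ in range(perturbation.n_suppress_singleton_reps):
        sizes[idx] = 1
        idx += 1
    for _ in range(perturbation.n_suppress_member_reps):
        sizes[idx] = max(sizes[idx], 2)
        idx += 1
    for _ in range(perturbation.n_update_rep_assembly):
        idx += 1
    if perturbation.divergent_update:
        sizes[idx] = max(sizes[idx], 2)
        idx += 1
    needed = idx + perturbation.n_add_type_strain + perturbation.n_quality_upgrade
    if needed > base_spec.n_species:
        raise ValueError(
            f"perturbation touches {needed} species but only "
            f"{base_spec.n_species} generated"
        )

    dataset = generate_dataset(base_spec, int(rng.integers(2**31)), sizes=sizes)
    prev = dataset_release(dataset, "R01", config)
    cluster_by_label = {c.species_label: c for c in prev.active_clusters()}
    scores = {
        r.accession: quality_score(r, config.full_length_ssu).total
        for r in dataset.records
    }

    current = {r.accession: r for r in dataset.records}
    matrix = AniMatrix(policy=dataset.matrix.policy, pairs=dict(dataset.matrix.pairs))
    expectations: list[Expectation] = []
    next_new_base = 900_000  # accession bases for genomes new in release t+1

    def fresh_accession() -> Accession:
        nonlocal next_new_base
        next_new_base += 1
        return Accession(f"GCA_{next_new_base:09d}", 1)

    labels = dataset.species_labels
    idx = 0

    for _ in range(perturbation.n_suppress_singleton_reps):
        label = labels[idx]
        idx += 1
        rep = cluster_by_label[label].representative
        current[rep] = current[rep].evolve(suppressed=True)
        expectations.append(Expectation("cluster_retired", label))

    for _ in range(perturbation.n_suppress_member_reps):
        label = labels[idx]
        idx += 1
        c = cluster_by_label[label]
        rep = c.representative
        current[rep] = current[rep].evolve(suppressed=True)
        survivors = sorted(m for m in c.members if m != rep)
        best = min(
            survivors,
            key=lambda m: (-balanced_ani_score(scores[m], matrix.ani(m, rep)), m),
        )
        expectations.append(
            Expectation("suppressed_rep_replaced", label, expected_representative=best)
        )

    for _ in range(perturbation.n_update_rep_assembly):
        label = labels[idx]
        idx += 1
        c = cluster_by_label[label]
        old = c.representative
        new = old.with_version(old.version + 1)
        current[new] = current.pop(old).evolve(accession=new)
        # the updated assembly is nearly identical to the old one
        for (a, b), (ani, af) in list(matrix.pairs.items()):
            if a == str(old) or b == str(old):
                other = b if a == str(old) else a
                matrix.set(str(new), other, ani, af)
        matrix.set(str(new), str(old), 99.95, 0.99)
        expectations.append(
            Expectation("assembly_update_retained", label, expected_representative=new)
        )

    if perturbation.divergent_update:
        label = labels[idx]
        idx += 1
        c = cluster_by_label[label]
        old = c.representative
        new = old.with_version(old.version + 1)
        current[new] = current.pop(old).evolve(accession=new)
        # the planted sibling is the highest-quality survivor and the closest
        # genome to the previous assembly, so it must win the BAS election;
        # the corrected assembly resembles nothing else in the release and
        # must found a new cluster
        survivors = sorted(m for m in c.members if m != old)
        sibling = min(survivors, key=lambda m: (-scores[m], m))
        matrix.set(str(sibling), str(old), perturbation.divergent_sibling_ani, 0.95)
        matrix.set(str(new), str(old), perturbation.divergent_update_ani, 0.45)
        expectations.append(
            Expectation("assembly_updated", label, expected_representative=sibling)
        )
        expectations.append(Expectation("new_cluster", label, genome=new))

    for _ in range(perturbation.n_add_type_strain):
        label = labels[idx]
        idx += 1
        c = cluster_by_label[label]
        acc = fresh_accession()
        current[acc] = GenomeRecord(
            accession=acc,
            completeness=float(rng.uniform(92, 100)),
            contamination=float(rng.uniform(0, 1)),
            contig_count=int(rng.integers(1, 50)),
            ssu_lengths=(1530,),
            type_status=TypeStatus.TYPE_STRAIN_OF_SPECIES,
            ncbi_taxonomy=dataset.taxonomy[c.representative],
        )
        matrix.set(acc, c.representative, 98.5, 0.9)
        for m in sorted(c.members):
            if m != c.representative:
                matrix.set(acc, m, float(rng.uniform(*base_spec.within_ani)),
                           float(rng.uniform(*base_spec.within_af)))
        expectations.append(
            Expectation("type_strain_promotion", label, expected_representative=acc)
        )

    for _ in range(perturbation.n_quality_upgrade):
        label = labels[idx]
        idx += 1
        c = cluster_by_label[label]
        acc = fresh_accession()
        current[acc] = GenomeRecord(
            accession=acc,
            completeness=100.0,
            contamination=0.0,
            contig_count=1,
            is_complete_assembly=True,
            ncbi_representative=True,
            ssu_lengths=(1530,),
            ncbi_taxonomy=dataset.taxonomy[c.representative],
        )
        matrix.set(acc, c.representative, 99.8, 0.95)
        for m in sorted(c.members):
            if m != c.representative:
                matrix.set(acc, m, float(rng.uniform(*base_spec.within_ani)),
                           float(rng.uniform(*base_spec.within_af)))
        expectations.append(
            Expectation("higher_quality_bas", label, expected_representative=acc)
        )

    untouched = labels[idx:]
    if perturbation.n_new_genomes and not untouched:
        raise ValueError("no unperturbed species left to receive new genomes")
    for _ in range(perturbation.n_new_genomes):
        label = untouched[int(rng.integers(0, len(untouched)))]
        c = cluster_by_label[label]
        acc = fresh_accession()
        current[acc] = GenomeRecord(
            accession=acc,
            completeness=80.0,
            contamination=3.0,
            contig_count=250,
            is_mag=True,
            ncbi_taxonomy=dataset.taxonomy[c.representative],
        )
        matrix.set(acc, c.representative, float(rng.uniform(*base_spec.within_ani)),
                   float(rng.uniform(*base_spec.within_af)))
        expectations.append(Expectation("assigned", label, genome=acc))

    for k in range(perturbation.n_new_species):
        accs = [fresh_accession() for _ in range(int(rng.integers(1, 4)))]
        for i, acc in enumerate(accs):
            current[acc] = GenomeRecord(
                accession=acc,
                completeness=float(rng.uniform(85, 100)),
                contamination=float(rng.uniform(0, 3)),
                contig_count=int(rng.integers(1, 200)),
                ncbi_taxonomy=f"{_TAX_PREFIX};g__GenusNew;s__",
            )
            for other in accs[:i]:
                matrix.set(acc, other, float(rng.uniform(*base_spec.within_ani)),
                           float(rng.uniform(*base_spec.within_af)))
        expectations.append(Expectation("new_cluster", f"novel_{k}", genome=accs[0]))

    return ReleasePair(
        prev=prev,
        prev_records=dataset.records,
        current_records=sorted(current.values(), key=lambda r: r.accession),
        matrix=matrix,
        expectations=expectations,
        dataset=dataset,
    )


_BASES = np.array(list("ACGT"))


def mutate_sequence(seq: str, d: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``d`` (no indels)."""
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < d
    if mask.any():
        shifts = rng.integers(1, 4, size=int(mask.sum()))
        codes = np.searchsorted(_BASES, arr[mask])
        arr[mask] = _BASES[(codes + shifts) % 4]
    return "".join(arr)


@dataclass(frozen=True)
class ExpectedAni:
    query: str
    reference: str
    ani: float
    tolerance: float


def generate_sequences(
    out_dir: str | Path,
    seed: int,
    n_species: int = 2,
    divergences: Sequence[float] = (0.01, 0.03),
    genome_len: int = 30_000,
) -> tuple[dict[str, Path], list[ExpectedAni]]:
    """Write FASTA assemblies with known divergence for estimator tests.

    Each species gets one random ancestor (its first member) plus one member
    per entry of ``divergences``, created by seeded point substitutions at
    rate d so the expected ANI to the ancestor is 100 x (1 - d). Returns the
    file paths keyed by accession and the expected ANI table with binomial
    tolerance bounds; cross-species pairs are expected not to align.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    expected: list[ExpectedAni] = []
    for s in range(n_species):
        ancestor = "".join(rng.choice(_BASES, size=genome_len))
        accs = [f"GCA_{(s + 1) * 100 + j:09d}.1" for j in range(len(divergences) + 1)]
        seqs = [ancestor] + [mutate_sequence(ancestor, d, rng) for d in divergences]
        for acc, seq in zip(accs, seqs):
            path = out_dir / f"{acc}.fna"
            path.write_text(f">{acc}\n{seq}\n")
            paths[acc] = path
        for acc, d in zip(accs[1:], divergences):
            # four-sigma binomial band around the expected identity, floor 0.5
            sigma = 100.0 * float(np.sqrt(d * (1 - d) / genome_len))
            expected.append(
                ExpectedAni(acc, accs[0], 100.0 * (1.0 - d), max(0.5, 4 * sigma))
            )
    return paths, expected
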