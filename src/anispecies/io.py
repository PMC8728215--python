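"""Readers and writers for the standard tabular formats the engine touches.

* genome metadata tables (GTDB-style tab-separated dialect; unknown columns
  are ignored so real release files drop in unchanged),
* FastANI 5-column output and a symmetrized edge table,
* species-cluster tables and 7-rank taxonomy tables.

All files are UTF-8, tab-delimited, with deterministic row order (sorted by
accession) so writers round-trip losslessly through the matching readers.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

from .model import (
    Accession,
    AniEdge,
    GenomeRecord,
    ModelError,
    Release,
    SpeciesCluster,
    TypeStatus,
)

__all__ = [
    "FormatError",
    "read_metadata",
    "write_metadata",
    "read_fastani",
    "read_ani_edges",
    "write_ani_edges",
    "read_taxonomy",
    "write_taxonomy",
    "read_sp_clusters",
    "write_sp_clusters",
    "write_release",
    "read_release",
]


class FormatError(ValueError):
    """A file does not conform to its expected format."""


_TRUE = {"t", "true", "1", "yes"}
_FALSE = {"f", "false", "0", "no", ""}

_TYPE_DESIGNATIONS = {
    "type strain of species": TypeStatus.TYPE_STRAIN_OF_SPECIES,
    "effective type strain of species": TypeStatus.NCBI_EFFECTIVE_TYPE,
    "type strain of subspecies": TypeStatus.TYPE_STRAIN_OF_SUBSPECIES,
    "none": TypeStatus.NONE,
    "": TypeStatus.NONE,
}
_TYPE_DESIGNATIONS_OUT = {
    TypeStatus.TYPE_STRAIN_OF_SPECIES: "type strain of species",
    TypeStatus.NCBI_EFFECTIVE_TYPE: "effective type strain of species",
    TypeStatus.TYPE_STRAIN_OF_SUBSPECIES: "type strain of subspecies",
    TypeStatus.NONE: "none",
}

METADATA_COLUMNS = [
    "accession",
    "checkm_completeness",
    "checkm_contamination",
    "contig_count",
    "ambiguous_bases",
    "n50_contigs",
    "ssu_lengths",
    "trna_count",
    "ncbi_assembly_level",
    "ncbi_genome_category",
    "type_designation",
    "ncbi_refseq_category",
    "ncbi_taxonomy",
    "suppressed",
    "multi_isolate_project",
]


def _parse_bool(text: str, line_no: int, column: str) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise FormatError(f"line {line_no}: cannot parse boolean {text!r} in {column}")


def _get(row: dict, column: str, default: str = "") -> str:
    v = row.get(column)
    return default if v is None or v == "" else v


def read_metadata(path: str | Path) -> list[GenomeRecord]:
    """Read a GTDB-style metadata TSV into genome records.

    ``accession`` is the only mandatory column; every other field defaults to
    a neutral value (completeness 0, contamination 0, one contig, no 16S,
    not suppressed, ...). MAG/SAG status is derived from the
    ``ncbi_genome_category`` text; NCBI representative status from
    ``ncbi_refseq_category``. Malformed rows are reported with their line
    numbers.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected a header row")
        if "accession" not in reader.fieldnames:
            raise FormatError(f"{path}: missing mandatory column 'accession'")
        for row in reader:
            line_no = reader.line_num
            try:
                records.append(_record_from_row(row, line_no))
            except ModelError as exc:
                raise FormatError(f"line {line_no}: {exc}") from exc
    return records


def _record_from_row(row: dict, line_no: int) -> GenomeRecord:
    accession = Accession.parse(_get(row, "accession"))
    category = _get(row, "ncbi_genome_category").lower()
    is_mag = "derived from metagenome" in category or "metagenome-assembled" in category
    is_sag = "derived from single cell" in category or "single amplified" in category
    designation = _get(row, "type_designation").strip().lower()
    if designation not in _TYPE_DESIGNATIONS:
        raise FormatError(
            f"line {line_no}: unknown type_designation {designation!r}"
        )
    refseq_cat = _get(row, "ncbi_refseq_category").lower()
    ssu_raw = _get(row, "ssu_lengths")
    try:
        ssu_lengths = tuple(int(x) for x in ssu_raw.split(",") if x.strip())
        n50_raw = _get(row, "n50_contigs")
        trna_raw = _get(row, "trna_count")
        return GenomeRecord(
            accession=accession,
            completeness=float(_get(row, "checkm_completeness", "0")),
            contamination=float(_get(row, "checkm_contamination", "0")),
            contig_count=int(_get(row, "contig_count", "1")),
            undetermined_bases=int(_get(row, "ambiguous_bases", "0")),
            n50=int(n50_raw) if n50_raw else None,
            ssu_lengths=ssu_lengths,
            trna_count=int(trna_raw) if trna_raw else None,
            is_complete_assembly=_get(row, "ncbi_assembly_level").strip().lower()
            == "complete genome",
            is_mag=is_mag,
            is_sag=is_sag,
            type_status=_TYPE_DESIGNATIONS[designation],
            ncbi_representative="representative genome" in refseq_cat
            or "reference genome" in refseq_cat,
            ncbi_taxonomy=_get(row, "ncbi_taxonomy"),
            suppressed=_parse_bool(_get(row, "suppressed"), line_no, "suppressed"),
            multi_isolate_project=_parse_bool(
                _get(row, "multi_isolate_project"), line_no, "multi_isolate_project"
            ),
        )
    except ValueError as exc:
        if isinstance(exc, (FormatError, ModelError)):
            raise
        raise FormatError(f"line {line_no}: {exc}") from exc


def write_metadata(records: Iterable[GenomeRecord], path: str | Path) -> None:
    path = Path(path)
    rows = sorted(records, key=lambda r: r.accession)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(METADATA_COLUMNS)
        for r in rows:
            category = ""
            if r.is_mag:
                category = "derived from metagenome"
            elif r.is_sag:
                category = "derived from single cell"
            w.writerow(
                [
                    str(r.accession),
                    repr(r.completeness),
                    repr(r.contamination),
                    r.contig_count,
                    r.undetermined_bases,
                    "" if r.n50 is None else r.n50,
                    ",".join(str(x) for x in r.ssu_lengths),
                    "" if r.trna_count is None else r.trna_count,
                    "Complete Genome" if r.is_complete_assembly else "Contig",
                    category,
                    _TYPE_DESIGNATIONS_OUT[r.type_status],
                    "representative genome" if r.ncbi_representative else "na",
                    r.ncbi_taxonomy,
                    "t" if r.suppressed else "f",
                    "t" if r.multi_isolate_project else "f",
                ]
            )


def _strip_to_accession(path_text: str) -> str:
    name = path_text.rsplit("/", 1)[-1]
    for suffix in (".gz", ".fna", ".fa", ".fasta"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


def read_fastani(path: str | Path) -> list[AniEdge]:
    """Parse native FastANI output: query, reference, ANI, mapped, total fragments.

    The alignment fraction is computed as mapped / total fragments; file
    paths are stripped down to accessions.
    """
    path = Path(path)
    edges: list[AniEdge] = []
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 5:
                raise FormatError(
                    f"{path}:{line_no}: expected 5 whitespace-separated columns, "
                    f"got {len(parts)}"
                )
            query, reference, ani_s, mapped_s, total_s = parts
            try:
                ani = float(ani_s)
                mapped = int(mapped_s)
                total = int(total_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from exc
            if total == 0:
                raise FormatError(
                    f"{path}:{line_no}: total fragment count is zero"
                )
            try:
                edges.append(
                    AniEdge(
                        query=_strip_to_accession(query),
                        reference=_strip_to_accession(reference),
                        ani=ani,
                        af=mapped / total,
                    )
                )
            except ModelError as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from exc
    return edges


def read_ani_edges(path: str | Path) -> list[AniEdge]:
    """Read the package's own symmetrized edge table (query, reference, ani, af)."""
    path = Path(path)
    edges: list[AniEdge] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["query", "reference", "ani", "af"]:
            raise FormatError(f"{path}: unexpected header {header}")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{line_no}: expected 4 columns")
            try:
                edges.append(
                    AniEdge(parts[0], parts[1], float(parts[2]), float(parts[3]))
                )
            except (ValueError, ModelError) as exc:
                raise FormatError(f"{path}:{line_no}: {exc}") from exc
    return edges


def write_ani_edges(edges: Iterable[AniEdge], path: str | Path) -> None:
    path = Path(path)
    rows = sorted(edges, key=lambda e: (e.query, e.reference))
    with path.open("w") as fh:
        fh.write("query\treference\tani\taf\n")
        for e in rows:
            fh.write(f"{e.query}\t{e.reference}\t{e.ani:.6g}\t{e.af:.6g}\n")


def read_taxonomy(path: str | Path) -> dict[Accession, str]:
    path = Path(path)
    taxonomy: dict[Accession, str] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["accession", "taxonomy"]:
            raise FormatError(f"{path}: unexpected header {header}")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{line_no}: expected 2 columns")
            acc = Accession.parse(parts[0])
            if acc in taxonomy:
                raise FormatError(f"{path}:{line_no}: duplicate accession {acc}")
            taxonomy[acc] = parts[1]
    return taxonomy


def write_taxonomy(taxonomy: dict[Accession, str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("accession\ttaxonomy\n")
        for acc in sorted(taxonomy):
            fh.write(f"{acc}\t{taxonomy[acc]}\n")


def read_sp_clusters(path: str | Path) -> list[SpeciesCluster]:
    path = Path(path)
    clusters: list[SpeciesCluster] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["representative", "species_label", "radius", "members", "retired"]
        if header[:5] != expected:
            raise FormatError(f"{path}: unexpected header {header}")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{line_no}: expected 5 columns")
            rep, label, radius_s, members_s, retired_s = parts
            members = {
                Accession.parse(m) for m in members_s.split(",") if m.strip()
            }
            clusters.append(
                SpeciesCluster(
                    representative=Accession.parse(rep),
                    species_label=label,
                    members=members,
                    radius=float(radius_s),
                    retired=_parse_bool(retired_s, line_no, "retired"),
                )
            )
    return clusters


def write_sp_clusters(clusters: Iterable[SpeciesCluster], path: str | Path) -> None:
    path = Path(path)
    rows = sorted(clusters, key=lambda c: c.representative)
    with path.open("w") as fh:
        fh.write("representative\tspecies_label\tradius\tmembers\tretired\n")
        for c in rows:
            members = ",".join(str(m) for m in sorted(c.members))
            fh.write(
                f"{c.representative}\t{c.species_label}\t{c.radius:.6g}\t"
                f"{members}\t{'t' if c.retired else 'f'}\n"
            )


def write_release(release: Release, out_dir: str | Path) -> dict[str, Path]:
    """Write a release as sp_clusters + taxonomy tables plus its identifier.

    The release must pass its invariants (a genome in two clusters, or a
    member without a taxonomy entry, is an integrity error).
    """
    release.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sp_clusters": out_dir / "sp_clusters.tsv",
        "taxonomy": out_dir / "taxonomy.tsv",
        "release_id": out_dir / "release_id.txt",
    }
    write_sp_clusters(release.clusters, paths["sp_clusters"])
    write_taxonomy(release.taxonomy, paths["taxonomy"])
    paths["release_id"].write_text(release.release_id + "\n")
    return paths


def read_release(in_dir: str | Path) -> Release:
    in_dir = Path(in_dir)
    release = Release(
        release_id=(in_dir / "release_id.txt").read_text().strip(),
        clusters=read_sp_clusters(in_dir / "sp_clusters.tsv"),
        taxonomy=read_taxonomy(in_dir / "taxonomy.tsv"),
    )
    release.validate()
    return release
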