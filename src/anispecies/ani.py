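"""Uniform source of pairwise ANI / alignment-fraction values.

Three routes feed the same in-memory structure (:class:`AniMatrix`):

* ingestion of external FastANI-style tabular output (see :mod:`.io`),
* a built-in fragment-based estimator over FASTA assemblies
  (:func:`fragment_ani`), suitable for end-to-end tests and small inputs,
* direct construction, e.g. by the synthetic-fixture generator.

Directional values are symmetrized with a max rule. A pair absent from the
matrix means "no detectable similarity" — it is never interpreted as 0% ANI.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
from Bio import SeqIO

from .model import Accession, AniEdge, ModelError

__all__ = [
    "AniMatrix",
    "symmetrize",
    "fragment_ani",
    "fragment_ani_seqs",
    "run_external_fastani",
    "ExternalToolError",
]


class ExternalToolError(RuntimeError):
    """An external ANI engine failed or is unavailable."""


def _key(a, b) -> tuple[str, str]:
    a, b = str(a), str(b)
    return (a, b) if a <= b else (b, a)


@dataclass
class AniMatrix:
    """Sparse symmetric map (accession, accession) -> (ani, af).

    Lookups are order-insensitive. A missing pair returns ``None`` (below
    detection); the identity pair always returns ``(100.0, 1.0)``.
    """

    pairs: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    policy: str = "max"

    def set(self, a, b, ani: float, af: float) -> None:
        if str(a) == str(b):
            return
        self.pairs[_key(a, b)] = (float(ani), float(af))

    def get(self, a, b) -> tuple[float, float] | None:
        if str(a) == str(b):
            return (100.0, 1.0)
        return self.pairs.get(_key(a, b))

    def ani(self, a, b) -> float | None:
        v = self.get(a, b)
        return None if v is None else v[0]

    def af(self, a, b) -> float | None:
        v = self.get(a, b)
        return None if v is None else v[1]

    def __contains__(self, pair) -> bool:
        a, b = pair
        return self.get(a, b) is not None

    def __len__(self) -> int:
        return len(self.pairs)

    def edges(self) -> list[AniEdge]:
        """Symmetrized pairs as (lexicographically ordered) edges, sorted."""
        out = []
        for (a, b), (ani, af) in sorted(self.pairs.items()):
            out.append(AniEdge(query=a, reference=b, ani=ani, af=af))
        return out


def symmetrize(edges: Iterable[AniEdge]) -> AniMatrix:
    """Collapse directional edges onto unordered pairs with a max rule.

    ANI and AF are maximized independently over the available directions.
    Duplicate rows for the same direction with conflicting values raise
    :class:`ModelError`; exact duplicates are tolerated.
    """
    seen_directed: dict[tuple[str, str], tuple[float, float]] = {}
    matrix = AniMatrix(policy="max")
    for e in edges:
        dkey = (str(e.query), str(e.reference))
        if dkey in seen_directed:
            if seen_directed[dkey] != (e.ani, e.af):
                raise ModelError(
                    f"conflicting duplicate ANI rows for {dkey[0]} -> {dkey[1]}: "
                    f"{seen_directed[dkey]} vs {(e.ani, e.af)}"
                )
            continue
        seen_directed[dkey] = (e.ani, e.af)
        if dkey[0] == dkey[1]:
            continue
        prev = matrix.get(e.query, e.reference)
        if prev is None:
            matrix.set(e.query, e.reference, e.ani, e.af)
        else:
            matrix.set(
                e.query, e.reference, max(prev[0], e.ani), max(prev[1], e.af)
            )
    return matrix


_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _load_concatenated(path: str | Path) -> str:
    """Concatenate all records of a (possibly multi-record) FASTA assembly."""
    seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ValueError(f"no sequence records in {path}")
    return "".join(seqs).upper()


def _accession_from_path(path: str | Path) -> str:
    name = Path(path).name
    for suffix in (".fna", ".fa", ".fasta", ".gz"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


def fragment_ani_seqs(
    query: str,
    reference: str,
    fragment_len: int = 3000,
    min_identity: float = 0.8,
) -> tuple[float, float]:
    """Fragment-based ANI/AF between two raw nucleotide sequences.

    The query is cut into non-overlapping fragments of ``fragment_len``;
    each fragment is aligned (infix, both orientations) against the
    reference with a banded edit-distance aligner and mapped if its best
    identity reaches ``min_identity``. Returns (ANI percent over mapped
    fragments, mapped/total fraction); ANI is 0 when nothing maps.
    Deterministic.
    """
    if len(query) < fragment_len:
        raise ValueError(
            f"query length {len(query)} shorter than one fragment "
            f"({fragment_len} nt); use a smaller fragment_len"
        )
    if not reference:
        raise ValueError("empty reference sequence")
    n_fragments = len(query) // fragment_len
    max_dist = int(fragment_len * (1.0 - min_identity))
    identities: list[float] = []
    rc_reference = _revcomp(reference)
    for i in range(n_fragments):
        frag = query[i * fragment_len : (i + 1) * fragment_len]
        best = None
        for target in (reference, rc_reference):
            res = edlib.align(frag, target, mode="HW", task="distance", k=max_dist)
            d = res["editDistance"]
            if d != -1 and (best is None or d < best):
                best = d
        if best is not None:
            identities.append(1.0 - best / fragment_len)
    if not identities:
        return 0.0, 0.0
    ani = 100.0 * sum(identities) / len(identities)
    af = len(identities) / n_fragments
    return ani, af


def fragment_ani(
    query_fasta: str | Path,
    reference_fasta: str | Path,
    fragment_len: int = 3000,
    min_identity: float = 0.8,
) -> AniEdge:
    """Built-in fragment-based ANI between two FASTA assemblies.

    Multi-record assemblies are concatenated before fragmenting. The result
    follows the FastANI contract (ANI = mean identity of mapped fragments,
    AF = mapped / total fragments) but is an independent estimator, not a
    FastANI clone.
    """
    q = _load_concatenated(query_fasta)
    r = _load_concatenated(reference_fasta)
    ani, af = fragment_ani_seqs(q, r, fragment_len=fragment_len, min_identity=min_identity)
    q_acc = _accession_from_path(query_fasta)
    r_acc = _accession_from_path(reference_fasta)
    if q_acc == r_acc:
        ani, af = 100.0, 1.0
    return AniEdge(query=q_acc, reference=r_acc, ani=ani, af=af)


def run_external_fastani(
    genome_paths: Sequence[str | Path],
    exe_path: str = "fastANI",
) -> list[AniEdge]:
    """Run an external FastANI executable many-to-many and parse its output.

    Optional route: the engine functions without the external tool. Raises
    :class:`ExternalToolError` when the executable is missing or fails.
    """
    from .io import read_fastani  # local import: io is format plumbing

    exe = shutil.which(exe_path)
    if exe is None:
        raise ExternalToolError(
            f"external tool unavailable: {exe_path!r} not found on PATH"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        listing = tmp / "genomes.txt"
        listing.write_text("\n".join(str(p) for p in genome_paths) + "\n")
        out = tmp / "fastani.tsv"
        proc = subprocess.run(
            [exe, "--ql", str(listing), "--rl", str(listing), "-o", str(out)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise ExternalToolError(
                f"{exe_path} exited with {proc.returncode}: {proc.stderr.strip()}"
            )
        return read_fastani(out)
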