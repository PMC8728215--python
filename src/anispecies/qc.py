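"""Quality-control gate applied to all genomes before clustering.

Assemblies of insufficient quality are removed from consideration entirely —
including genomes assembled from type material, unless the caller relaxes the
thresholds. Suppressed assemblies (withdrawn at the source archive) and
assemblies from large multi-isolate sequencing projects are excluded through
the same gate so the pipeline has a single removal point.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .model import GenomeRecord

__all__ = ["QcThresholds", "QcVerdict", "QcSummary", "passes_qc", "qc_summary"]


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds; defaults reproduce the published GTDB-style gate.

    ``min_quality`` bounds the composite CheckM quality
    (completeness − 5 × contamination). ``min_n50`` is only applied to
    records that carry an N50 value.
    """

    min_completeness: float = 50.0
    max_contamination: float = 10.0
    min_quality: float = 50.0
    max_contigs: int = 1000
    min_n50: int = 5000
    max_undetermined: int = 100_000
    exclude_suppressed: bool = True
    exclude_multi_isolate: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_completeness <= 100:
            raise ValueError("min_completeness outside [0, 100]")
        if self.max_contamination < 0:
            raise ValueError("max_contamination must be >= 0")


@dataclass(frozen=True)
class QcVerdict:
    accession: str
    passed: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.passed


def passes_qc(g: GenomeRecord, t: QcThresholds | None = None) -> QcVerdict:
    """Evaluate every criterion and return the verdict with all failure reasons."""
    t = t or QcThresholds()
    reasons: list[str] = []
    if t.exclude_suppressed and g.suppressed:
        reasons.append("suppressed at source")
    if t.exclude_multi_isolate and g.multi_isolate_project:
        reasons.append("large multi-isolate project")
    if g.completeness < t.min_completeness:
        reasons.append(f"completeness {g.completeness:g} < {t.min_completeness:g}")
    if g.contamination > t.max_contamination:
        reasons.append(f"contamination {g.contamination:g} > {t.max_contamination:g}")
    quality = g.completeness - 5.0 * g.contamination
    if quality < t.min_quality:
        reasons.append(
            f"quality (completeness - 5 x contamination) {quality:g} < {t.min_quality:g}"
        )
    if g.contig_count > t.max_contigs:
        reasons.append(f"contig count {g.contig_count} > {t.max_contigs}")
    if g.n50 is not None and g.n50 < t.min_n50:
        reasons.append(f"N50 {g.n50} < {t.min_n50}")
    if g.undetermined_bases > t.max_undetermined:
        reasons.append(
            f"undetermined bases {g.undetermined_bases} > {t.max_undetermined}"
        )
    return QcVerdict(str(g.accession), not reasons, tuple(reasons))


@dataclass
class QcSummary:
    total: int
    removed: int
    reasons: Counter = field(default_factory=Counter)
    verdicts: list[QcVerdict] = field(default_factory=list)

    @property
    def removed_pct(self) -> float:
        """Percentage removed, rounded to one decimal place."""
        if self.total == 0:
            return 0.0
        return round(self.removed / self.total * 100.0, 1)

    def headline(self) -> str:
        """Counts formatted as e.g. ``26407 (9.3%)``."""
        return f"{self.removed} ({self.removed_pct}%)"


def qc_summary(records: Iterable[GenomeRecord], t: QcThresholds | None = None) -> QcSummary:
    """Apply :func:`passes_qc` to every record and tabulate removals by reason."""
    t = t or QcThresholds()
    verdicts = [passes_qc(g, t) for g in records]
    reasons: Counter = Counter()
    for v in verdicts:
        for r in v.reasons:
            # histogram over criterion kinds, not the formatted values
            reasons[r.split(" ")[0] if not r.startswith(("suppressed", "large")) else r] += 1
    removed = sum(1 for v in verdicts if not v.passed)
    return QcSummary(total=len(verdicts), removed=removed, reasons=reasons, verdicts=verdicts)
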