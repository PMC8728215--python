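"""Human-readable and machine-readable renderings of update results."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .config import Config
from .updater import ChangeReport

__all__ = ["render_change_report", "change_report_dict", "RunManifest", "write_manifest"]


def _pct(part: int, whole: int) -> str:
    if whole == 0:
        return "0 (0.00%)"
    return f"{part} ({100.0 * part / whole:.2f}%)"


def change_report_dict(report: ChangeReport) -> dict:
    """Structured form of the release-to-release accounting."""
    prev_reps = report.prev_species_count
    assigned_total = report.assign_same + report.assign_diff + report.suppressed
    return {
        "releases": f"{report.prev_release_id} to {report.new_release_id}",
        "species_representatives": {
            "counts": f"{report.prev_species_count} to {report.cur_species_count}",
            "unchanged": report.reps_unchanged,
            "unchanged_pct": round(100.0 * report.reps_unchanged / prev_reps, 2)
            if prev_reps
            else 0.0,
            "changed": report.reps_changed,
            "changed_pct": round(100.0 * report.reps_changed / prev_reps, 2)
            if prev_reps
            else 0.0,
            "reasons": report.reasons(),
        },
        "new_species": {
            "count": report.new_species,
            "pct_increase": round(100.0 * report.new_species / prev_reps, 1)
            if prev_reps
            else 0.0,
        },
        "genome_cluster_assignment": {
            "counts": f"{report.prev_genome_count} to {report.cur_genome_count}",
            "same_cluster": report.assign_same,
            "different_cluster": report.assign_diff,
            "suppressed": report.suppressed,
            "total_tracked": assigned_total,
        },
        "qc_removed": report.qc_removed,
        "retired_species": list(report.retired),
        "frozen_species": list(report.frozen_species),
        "type_strain_conflicts": [
            {
                "species": c.species_label,
                "genomes": [str(g) for g in c.genomes],
                "min_pairwise_ani": c.min_pairwise_ani,
                "resolved": c.resolved,
            }
            for c in report.conflicts
        ],
    }


def render_change_report(report: ChangeReport) -> str:
    """Text table mirroring the release-notes layout, percentages to 2 dp."""
    prev_reps = report.prev_species_count
    tracked = report.assign_same + report.assign_diff + report.suppressed
    lines = [
        f"Release update: {report.prev_release_id} to {report.new_release_id}",
        "",
        f"Species representatives      {report.prev_species_count} to {report.cur_species_count}",
        f"  Unchanged                  {_pct(report.reps_unchanged, prev_reps)}",
        f"  Changed                    {_pct(report.reps_changed, prev_reps)}",
        f"New species                  {report.new_species}"
        + (
            f" ({100.0 * report.new_species / prev_reps:.1f}% increase)"
            if prev_reps
            else ""
        ),
        f"Genome cluster assignment    {report.prev_genome_count} to {report.cur_genome_count}",
        f"  Same cluster               {_pct(report.assign_same, tracked)}",
        f"  Different cluster          {_pct(report.assign_diff, tracked)}",
        f"  Suppressed                 {_pct(report.suppressed, tracked)}",
        f"Removed by quality control   {report.qc_removed}",
    ]
    reasons = report.reasons()
    if reasons:
        lines.append("Representative change reasons:")
        for reason in sorted(reasons):
            lines.append(f"  {reason:28s}{reasons[reason]}")
    if report.retired:
        lines.append("Retired species clusters: " + ", ".join(report.retired))
    if report.frozen_species:
        lines.append(
            "Frozen pending type-strain resolution: "
            + ", ".join(report.frozen_species)
        )
    return "\n".join(lines) + "\n"


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written into every output directory."""

    subcommand: str
    seed: int | None
    config_hash: str
    input_digests: dict[str, str] = field(default_factory=dict)
    tool_version: str = __version__
    timestamp: str = ""

    def to_dict(self) -> dict:
        return {
            "tool": "anispecies",
            "tool_version": self.tool_version,
            "subcommand": self.subcommand,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "input_digests": self.input_digests,
            "timestamp": self.timestamp,
        }


def write_manifest(
    out_dir: str | Path,
    subcommand: str,
    config: Config,
    inputs: Mapping[str, str | Path] | Sequence[str | Path] = (),
    seed: int | None = None,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not isinstance(inputs, Mapping):
        inputs = {Path(p).name: p for p in inputs}
    cfg_repr = repr(config).encode()
    manifest = RunManifest(
        subcommand=subcommand,
        seed=seed,
        config_hash=hashlib.sha256(cfg_repr).hexdigest()[:16],
        input_digests={
            name: _digest(Path(p)) for name, p in inputs.items() if Path(p).is_file()
        },
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n")
    return path
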