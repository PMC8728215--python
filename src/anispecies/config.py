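"""Run configuration: the numeric constants that govern clustering and updating.

All thresholds are expressed in the units used throughout the package: ANI
values in percent, alignment fractions in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

from .qc import QcThresholds

__all__ = ["Config", "load_config", "save_config"]


@dataclass(frozen=True)
class Config:
    """Engine configuration.

    ani_radius_default
        Default species circumscription radius (percent ANI).
    af_threshold
        Minimum alignment fraction for cluster membership. 0.65 by default;
        0.5 accommodates incomplete MAGs whose AF is artificially low.
    bas_replacement_margin
        A challenger replaces the current representative only if its Balanced
        ANI Score exceeds the incumbent's by at least this margin.
    type_conflict_ani
        Species whose type-strain genomes disagree below this pairwise ANI
        are flagged for manual resolution.
    fuzzy_ani / discrete_ani
        Species-discreteness verdicts: fuzzy if any interspecific ANI >=
        fuzzy_ani; discrete if none exceeds discrete_ani.
    subsample_per_species
        Cap on genomes per species examined in the discreteness analysis.
    radius_cap
        Upper guard on the circumscription radius so near-duplicate
        representatives cannot erase clusters.
    full_length_ssu
        Minimum 16S rRNA gene length (nt) counted as full length for the
        quality-score bonus.
    """

    ani_radius_default: float = 95.0
    af_threshold: float = 0.65
    bas_replacement_margin: float = 10.0
    type_conflict_ani: float = 99.0
    fuzzy_ani: float = 95.0
    discrete_ani: float = 94.0
    subsample_per_species: int = 150
    radius_cap: float = 97.0
    full_length_ssu: int = 1200
    rng_seed: int = 42
    qc: QcThresholds = field(default_factory=QcThresholds)

    def __post_init__(self) -> None:
        if not 0 < self.ani_radius_default <= 100:
            raise ValueError("ani_radius_default outside (0, 100]")
        if not 0 < self.af_threshold <= 1:
            raise ValueError("af_threshold outside (0, 1]")
        if not self.ani_radius_default <= self.radius_cap <= 100:
            raise ValueError("radius_cap must lie in [ani_radius_default, 100]")
        for name in ("type_conflict_ani", "fuzzy_ani", "discrete_ani"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} outside [0, 100]")

    def evolve(self, **changes) -> "Config":
        return replace(self, **changes)


def load_config(path: str | Path) -> Config:
    """Load a flat YAML document; keys mirror :class:`Config` fields.

    QC threshold keys live under a ``qc`` mapping. Unknown keys are an error.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    qc_data = data.pop("qc", {})
    known = set(Config.__dataclass_fields__) - {"qc"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    qc_known = set(QcThresholds.__dataclass_fields__)
    qc_unknown = set(qc_data) - qc_known
    if qc_unknown:
        raise ValueError(f"unknown qc config keys: {sorted(qc_unknown)}")
    return Config(qc=QcThresholds(**qc_data), **data)


def save_config(config: Config, path: str | Path) -> None:
    d = asdict(config)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
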