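"""Run configuration for the command-line pipeline.

A single YAML document drives all stages; every artifact a stage writes
carries the SHA-256 hash of the resolved configuration in a header comment
so a result can always be traced back to the exact settings that produced
it, and the resolved config file itself reruns to identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class RunConfig:
    # input files (stage-dependent; unused entries may stay None)
    census1: str | None = None
    census2: str | None = None
    species_table: str | None = None
    region_file: str | None = None        # GeoJSON study region
    partition_file: str | None = None     # GeoJSON fold partition
    # census schema
    schema: dict = field(default_factory=dict)
    dbh_unit: str = "cm"
    id_field: str = "stem_id"
    nominal_interval: float | None = None
    # modeling
    comp_dist: float = 7.5                # competitive radius, m
    comp_x_var: str = "basal_area"
    grouping: str = "sp"
    prior: dict = field(default_factory=dict)   # overrides: a0, b0, mu0, lambda0_scale
    # partition fallback when no file is given (rectangular grid)
    folds_nx: int = 2
    folds_ny: int = 2
    # synthetic-scene overrides for the simulate stage (extent, intensity, sigma, ...)
    sim: dict = field(default_factory=dict)
    # resampling
    n_perm: int = 49
    seed: int = 0
    # output
    out_dir: str = "."

    def __post_init__(self):
        if self.comp_dist <= 0:
            raise ValidationError("comp_dist must be > 0")
        if self.n_perm < 0:
            raise ValidationError("n_perm must be >= 0")
        if self.dbh_unit not in ("mm", "cm"):
            raise ValidationError("dbh_unit must be 'mm' or 'cm'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def write_csv(df, path: str | Path, config: RunConfig | None = None) -> None:
    """CSV with a `# config:` header comment carrying the config hash."""
    path = Path(path)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config: {config.digest()}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, comment="#")


def write_json(doc: dict | str, path: str | Path, config: RunConfig | None = None) -> None:
    if isinstance(doc, str):
        doc = json.loads(doc)
    if config is not None:
        doc = {"_config": config.digest(), **doc}
    Path(path).write_text(json.dumps(doc, indent=1))
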