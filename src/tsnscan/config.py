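"""Run configuration: defaults, validation, YAML round-trip.

Every threshold of the scan is a configurable default rather than a
hard-coded constant: top quantile q=0.001, clump r²=0.2 within a 500-kb
window (a 1-Mb block around each lead), EHH truncation 0.05, QC HWE floor
1e-10 and the HWE-deviation selection screen at 1e-6 with FST > 0.2, SV
divergence 0.20, gene flank 5 kb.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    """Everything a scan run needs: paths, populations, thresholds, seed."""

    vcf: str | None = None
    panel: str | None = None
    genes: str | None = None
    sv_table: str | None = None
    out_dir: str | None = None
    region: str | None = None

    target: str | None = None
    han: str | None = None          # reference used for FST/ΔDAF/XPEHH
    refs: list = field(default_factory=list)

    q: float = 0.001
    r2_max: float = 0.2
    clump_window: int = 500_000
    ehh_threshold: float = 0.05
    min_maf: float = 0.05
    ihs_bins: int = 50
    max_missing: float = 0.03
    hwe_floor: float = 1e-10
    drop_singletons: bool = True
    hwe_selection_cut: float = 1e-6
    fst_selection_cut: float = 0.2
    min_div: float = 0.20
    gene_flank: int = 5000
    window_size: int = 50_000
    window_step: int = 10_000
    null_reps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            ("q", self.q, 0.0, 1.0, False),
            ("r2_max", self.r2_max, 0.0, 1.0, True),
            ("ehh_threshold", self.ehh_threshold, 0.0, 1.0, False),
            ("min_maf", self.min_maf, 0.0, 0.5, True),
            ("max_missing", self.max_missing, 0.0, 1.0, True),
            ("hwe_floor", self.hwe_floor, 0.0, 1.0, True),
            ("hwe_selection_cut", self.hwe_selection_cut, 0.0, 1.0, True),
            ("fst_selection_cut", self.fst_selection_cut, -1.0, 1.0, True),
            ("min_div", self.min_div, 0.0, 1.0, True),
        ]
        for name, val, lo, hi, closed in checks:
            ok = (lo <= val <= hi) if closed else (lo < val < hi)
            if not ok:
                raise ConfigError(
                    f"{name}={val!r} outside its valid range "
                    f"{'[' if closed else '('}{lo}, {hi}{']' if closed else ')'}"
                )
        for name in ("clump_window", "gene_flank", "ihs_bins",
                     "window_size", "window_step"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.window_size < self.window_step:
            raise ConfigError("window_size must be >= window_step")

    def as_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)


_FIELD_NAMES = {f.name for f in fields(RunConfig)}


def parse_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file and/or explicit overrides.

    Overrides (e.g. command-line flags) take precedence over file values;
    unknown keys are rejected by name; defaults fill the rest.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
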