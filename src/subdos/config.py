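"""Run configuration, parameter presets and structured output.

A run is described by a flat key-value document (YAML) or CLI flags.
Defaults are the study's reference parameterization: a gene with four
775-nt regulatory domains and a 50-kb coding region, per-nucleotide
loss rates of 2.5e-8/generation for both mutation classes, a tight
heterodimer (K_eq = 1e10), per-domain totals of 2.5e-6 mol/mL for both
partners immediately after a whole-genome duplication, N_e = 1.4e5 and
fitness scalar w = 1.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import IO, List, Optional

import pandas as pd
import yaml

from .errors import ConfigurationError
from .fitness import ExpressionScenario, GeneArchitecture, Scenario, SelectionParams
from .markov import ModelSpec, Variant

__all__ = [
    "RunConfig",
    "PRESETS",
    "NE_SWEEP",
    "KEQ_SWEEP",
    "load_config",
    "write_results",
]

logger = logging.getLogger("subdos")

#: effective-population-size sweep used for the selection-efficacy analysis
NE_SWEEP = [1e2, 1e3, 1e4, 1e5, 1e6, 1e7]
#: binding-constant sweep used for the selection-strength analysis
KEQ_SWEEP = [1e4, 1e6, 1e9, 1e12]

_DEFAULT_TIMES = [float(t) for t in range(0, 5001, 50)]


@dataclass
class RunConfig:
    """Fully resolved parameters for one model run."""

    variant: str = "SUB_DOS"
    scenario: str = "WGD"
    z: int = 4
    l_c: float = 5.0e4
    l_r: float = 775.0
    u_b: float = 2.5e-8
    u_h: float = 2.5e-8
    w: float = 1.0
    n_e: float = 1.4e5
    keq: float = 1.0e10
    per_copy_concentration: float = 1.25e-6
    partner_total: float = 2.5e-6
    times: List[float] = field(default_factory=lambda: list(_DEFAULT_TIMES))
    output: Optional[str] = None
    format: str = "tsv"
    percent: bool = False
    log_level: str = "INFO"

    _FLOAT_FIELDS = (
        "l_c", "l_r", "u_b", "u_h", "w", "n_e", "keq",
        "per_copy_concentration", "partner_total",
    )

    def __post_init__(self) -> None:
        # YAML 1.1 reads exponent literals like "1.0e6" as strings;
        # coerce scalar fields so config files behave like flags
        for name in self._FLOAT_FIELDS:
            try:
                object.__setattr__(self, name, float(getattr(self, name)))
            except (TypeError, ValueError) as exc:
                raise ConfigurationError(f"{name} must be a number") from exc
        try:
            object.__setattr__(self, "z", int(self.z))
            object.__setattr__(
                self, "times", [float(t) for t in self.times]
            )
        except (TypeError, ValueError) as exc:
            raise ConfigurationError("z must be an integer and times numeric") from exc
        if self.variant not in Variant.__members__:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.scenario not in Scenario.__members__:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.format not in ("tsv", "csv", "json"):
            raise ConfigurationError(f"unknown output format {self.format!r}")

    def to_model_spec(self) -> ModelSpec:
        try:
            return ModelSpec(
                variant=Variant[self.variant],
                architecture=GeneArchitecture(
                    z=self.z, l_c=self.l_c, l_r=self.l_r, u_b=self.u_b, u_h=self.u_h
                ),
                selection=SelectionParams(w=self.w, n_e=self.n_e),
                scenario=ExpressionScenario(
                    scenario=Scenario[self.scenario],
                    per_copy_concentration=self.per_copy_concentration,
                    partner_total=self.partner_total,
                ),
                keq=self.keq,
            )
        except ValueError as exc:
            raise ConfigurationError(str(exc)) from exc

    def resolved(self) -> dict:
        return asdict(self)

    def dump(self, path: str | Path) -> None:
        """Write the fully resolved configuration back to YAML."""
        Path(path).write_text(yaml.safe_dump(self.resolved(), sort_keys=True))


# Presets bundle the parameter combinations behind the headline analyses.
# Sweep-style analyses (ne-sweep, keq-sweep) fix the shared values; the
# swept parameter is then varied over NE_SWEEP / KEQ_SWEEP by the caller.
PRESETS: dict[str, dict] = {
    "fig2": {"times": [float(t) for t in range(0, 5001, 50)]},
    "fig3a": {"times": [float(t) for t in range(0, 5001, 50)]},
    "fig3b": {
        "scenario": "SSD",
        "partner_total": 1.25e-6,
        "times": [float(t) for t in range(0, 5001, 50)],
    },
    "fig4": {"times": [float(t) for t in range(0, 2001, 20)]},
    "fig6a": {"n_e": 1.0e6, "times": [float(t) for t in range(0, 10001, 100)]},
    "table4": {"times": [400.0, 4.0e6]},
}


def load_config(
    path: str | Path | None = None,
    preset: str | None = None,
    **overrides,
) -> RunConfig:
    """Resolve defaults, preset, config file and explicit overrides, in
    that order of increasing precedence.

    Unknown keys anywhere are rejected with the offending key named;
    override values of None are ignored (unset CLI flags).
    """
    values: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigurationError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            )
        values.update(PRESETS[preset])

    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} is not a flat mapping")
        values.update(raw)

    values.update({k: v for k, v in overrides.items() if v is not None})

    known = set(RunConfig.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise ConfigurationError(f"unknown configuration key(s): {sorted(unknown)}")

    try:
        cfg = RunConfig(**values)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
    logger.info("resolved configuration: %s", cfg.resolved())
    return cfg


def _render_float(x: float) -> str:
    return format(x, ".6g")


def write_results(
    table: pd.DataFrame, format: str = "tsv", path: str | Path | None = None
) -> None:
    """Write a result table as TSV/CSV/JSON with 6-significant-digit floats.

    Column order is preserved from the DataFrame, which the producing
    operations build deterministically; the same inputs therefore give
    byte-identical output.
    """
    if table.empty:
        raise ConfigurationError("refusing to write an empty result table")
    handle: IO[str]
    close = False
    if path is None:
        handle = sys.stdout
    else:
        handle = open(path, "w")
        close = True
    try:
        if format in ("tsv", "csv"):
            sep = "\t" if format == "tsv" else ","
            table.to_csv(handle, sep=sep, index=False, float_format="%.6g")
        elif format == "json":
            records = []
            for _, row in table.iterrows():
                rec = {}
                for col, val in row.items():
                    if isinstance(val, float):
                        rec[col] = float(_render_float(val))
                    else:
                        rec[col] = val
                records.append(rec)
            json.dump(records, handle, indent=1)
            handle.write("\n")
        else:
            raise ConfigurationError(f"unknown output format {format!r}")
    finally:
        if close:
            handle.close()
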