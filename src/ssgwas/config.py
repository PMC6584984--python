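"""Flat key = value configuration files for analysis runs and simulations."""
from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .exceptions import InputError
from .simulate import SimConfig


@dataclass
class RunConfig:
    """Everything one analysis run needs besides the data files themselves."""

    pedigree: str = ""
    genotypes: str = ""
    phenotypes: str = ""
    genotype_dialect: str = "blupf90"
    map_file: str = ""
    trait: str = "y"
    animal_col: str = "animal"
    fixed_categorical: tuple[str, ...] = ("cg",)
    covariates: tuple[str, ...] = ()
    pe_col: str = ""  # grouping column for the permanent-environment effect
    sigma_u2: float = 0.48
    sigma_e2: float = 0.42
    sigma_pe2: float = 0.10
    alpha: float = 0.05
    maf_min: float = 0.01
    callrate_min: float = 0.9
    unknown_code: str = "0"
    write_plots: bool = False
    emmax_check: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise InputError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.sigma_u2 <= 0 or self.sigma_e2 <= 0:
            raise InputError("variance components must be positive")
        if self.pe_col and self.sigma_pe2 <= 0:
            raise InputError("sigma_pe2 must be positive when pe_col is set")


_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def _parse_flat(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for ln_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InputError(f"{path}:{ln_no}: expected 'key = value', got {line!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out


def _coerce(cls, raw: dict[str, str]):
    kwargs = {}
    by_name = {f.name: f for f in fields(cls)}
    for key, val in raw.items():
        if key not in by_name:
            raise InputError(f"unknown configuration key {key!r}")
        default = by_name[key].default
        if isinstance(default, bool):
            if val.lower() not in _BOOL:
                raise InputError(f"cannot parse boolean {key} = {val!r}")
            kwargs[key] = _BOOL[val.lower()]
        elif isinstance(default, int):
            kwargs[key] = int(val)
        elif isinstance(default, float) or default is None:
            kwargs[key] = float(val) if val.lower() not in ("none", "") else None
        elif isinstance(default, tuple):
            if key == "qtl":  # "index:effect" pairs, comma separated
                pairs = []
                for tok in filter(None, (t.strip() for t in val.split(","))):
                    j, eff = tok.split(":")
                    pairs.append((int(j), float(eff)))
                kwargs[key] = tuple(pairs)
            else:
                kwargs[key] = tuple(t.strip() for t in val.split(",") if t.strip())
        else:
            kwargs[key] = val
    return cls(**kwargs)


def read_run_config(path: str | Path, **overrides) -> RunConfig:
    raw = _parse_flat(path)
    raw.update({k: str(v) for k, v in overrides.items() if v is not None})
    return _coerce(RunConfig, raw)


def read_sim_config(path: str | Path, **overrides) -> SimConfig:
    raw = _parse_flat(path)
    raw.update({k: str(v) for k, v in overrides.items() if v is not None})
    return _coerce(SimConfig, raw)
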