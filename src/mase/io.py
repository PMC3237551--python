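"""Delimited-text readers/writers, fit-result JSON, and run configs.

Exchange series travel as tiny CSV/TSV tables with header
``t_seconds,R[,sigma][,censored]`` (delimiter auto-detected from the
header line).  Numeric columns are written with 17 significant digits
so a write/read round trip is bit-identical.  Trajectories export as
tidy long tables.  Fit results serialize to a small JSON object.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .kinetics import ExchangePoint
from .model import ExchangeResults
from .simulate import Trajectory

__all__ = [
    "ParseError",
    "read_series",
    "write_series",
    "write_trajectory",
    "write_fit_json",
    "RunConfig",
]

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no", ""}


class ParseError(ValueError):
    """Malformed series file; message names the offending line/column."""


def _parse_bool(text: str, line: int) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ParseError(f"line {line}, column censored: cannot parse {text!r} as boolean")


def _parse_float(text: str, line: int, column: str) -> float:
    try:
        value = float(text)
    except ValueError:
        raise ParseError(
            f"line {line}, column {column}: cannot parse {text!r} as a number"
        ) from None
    if not math.isfinite(value):
        raise ParseError(f"line {line}, column {column}: non-finite value {text!r}")
    return value


def read_series(path: Union[str, Path]) -> list[ExchangePoint]:
    """Read an exchange time series from delimited text.

    Requires columns ``t_seconds`` and ``R``; ``sigma`` and ``censored``
    are optional.  Comma or tab delimiting is auto-detected from the
    header line.  Rows come back ordered by time (duplicates allowed --
    they are replicates); any malformed row raises a
    :class:`ParseError` naming the line and column.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].strip():
        raise ParseError(f"{path}: empty file (expected a header line)")
    delim = "\t" if "\t" in lines[0] else ","
    header = [h.strip() for h in lines[0].split(delim)]
    for required in ("t_seconds", "R"):
        if required not in header:
            raise ParseError(f"{path}: missing required column {required!r}")
    col = {name: i for i, name in enumerate(header)}
    points: list[ExchangePoint] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split(delim)
        if len(fields) != len(header):
            raise ParseError(
                f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        t = _parse_float(fields[col["t_seconds"]], lineno, "t_seconds")
        if t < 0:
            raise ParseError(f"line {lineno}, column t_seconds: negative time {t!r}")
        R = _parse_float(fields[col["R"]], lineno, "R")
        if R < 0:
            raise ParseError(f"line {lineno}, column R: negative ratio {R!r}")
        sigma: Optional[float] = None
        if "sigma" in col and fields[col["sigma"]].strip() != "":
            sigma = _parse_float(fields[col["sigma"]], lineno, "sigma")
            if sigma <= 0:
                raise ParseError(
                    f"line {lineno}, column sigma: sigma must be positive when present"
                )
        censored = _parse_bool(fields[col["censored"]], lineno) if "censored" in col else False
        points.append(ExchangePoint(t=t, R=R, sigma=sigma, censored=censored))
    if not points:
        raise ParseError(f"{path}: no data rows")
    points.sort(key=lambda p: p.t)
    return points


def _fmt(value: float) -> str:
    return format(value, ".17g")


def write_series(
    points: Sequence[ExchangePoint],
    path: Union[str, Path],
    delimiter: str = ",",
) -> Path:
    """Write a series with 17-significant-digit numeric columns."""
    path = Path(path)
    rows = [delimiter.join(("t_seconds", "R", "sigma", "censored"))]
    for p in points:
        rows.append(
            delimiter.join(
                (
                    _fmt(p.t),
                    _fmt(p.R),
                    _fmt(p.sigma) if p.sigma is not None else "",
                    "1" if p.censored else "0",
                )
            )
        )
    path.write_text("\n".join(rows) + "\n")
    return path


def write_trajectory(traj: Trajectory, path: Union[str, Path], delimiter: str = ",") -> Path:
    """Export a trajectory as a tidy table (t_seconds, species, concentration)."""
    path = Path(path)
    traj.to_frame().to_csv(path, sep=delimiter, index=False, float_format="%.17g")
    return path


def write_fit_json(results: ExchangeResults, path: Union[str, Path]) -> Path:
    """Serialize the fit result fields a downstream consumer needs."""
    path = Path(path)
    payload = {
        "k_off_hat": results.k_off_hat,
        "ci_low": results.ci_low,
        "ci_high": results.ci_high,
        "rss": results.rss,
        "n_used": results.n_used,
        "converged": results.converged,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


@dataclass
class RunConfig:
    """One CLI run, fully serializable to readable YAML and back.

    ``params`` holds the command-specific flag values; the round trip
    ``RunConfig.from_yaml(cfg.to_yaml())`` is the identity.
    """

    command: str
    params: dict = field(default_factory=dict)
    seed: Optional[int] = None
    output: Optional[str] = None
    log_level: str = "INFO"

    def to_yaml(self, path: Optional[Union[str, Path]] = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: Union[str, Path]) -> "RunConfig":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            text = Path(source).read_text()
        else:
            text = str(source)
        data = yaml.safe_load(text)
        if not isinstance(data, dict) or "command" not in data:
            raise ValueError("config must be a mapping with a 'command' key")
        return cls(**data)
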