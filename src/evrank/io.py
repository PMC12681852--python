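"""File formats: matrix CSV, factor configuration YAML, table export.

Matrix files are plain UTF-8 CSV with a header row of factor names and the
first column holding alternative names. Factor configurations are YAML:

.. code-block:: yaml

    factors:
      - name: particle_recovery_pct
        direction: maximize        # maximize | minimize | shifted_minimize
        weight: 0.25               # optional; all-absent -> equal weights
        shift: 100                 # used by shifted_minimize only
        units: "%"

Values round-trip bit-exactly for decimals of <= 15 significant digits
(floats are serialized with Python's shortest-repr formatting).
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .exceptions import ConfigurationError, DataError
from .factors import DecisionMatrix, FactorSpec, build_decision_problem

__all__ = [
    "read_factor_config",
    "write_factor_config",
    "read_matrix",
    "write_matrix",
    "config_digest",
]


def read_factor_config(path) -> list[FactorSpec]:
    """Parse a YAML factor configuration into FactorSpecs."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(doc, dict) or "factors" not in doc:
        raise ConfigurationError(
            f"config {path} must be a mapping with a 'factors' list"
        )
    specs = []
    for i, entry in enumerate(doc["factors"]):
        if not isinstance(entry, dict) or "name" not in entry:
            raise ConfigurationError(
                f"config {path}: factor entry {i} needs at least a 'name'"
            )
        specs.append(
            FactorSpec(
                name=str(entry["name"]),
                direction=entry.get("direction", "maximize"),
                shift=float(entry.get("shift", 100.0)),
                weight=float(entry.get("weight", 0.0)),
                units=str(entry.get("units", "")),
            )
        )
    if not specs:
        raise ConfigurationError(f"config {path}: empty factor list")
    return specs


def write_factor_config(path, factors: Sequence[FactorSpec]) -> None:
    doc = {
        "factors": [
            {
                "name": f.name,
                "direction": f.direction.value,
                "weight": float(f.weight),
                "shift": float(f.shift),
                "units": f.units,
            }
            for f in factors
        ]
    }
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False), encoding="utf-8"
    )


def read_matrix(path, config_path, **kwargs) -> DecisionMatrix:
    """Read matrix CSV + config YAML into a validated DecisionMatrix.

    Extra keyword arguments (``weights``, ``auto_normalize_weights``) pass
    through to :func:`build_decision_problem`.
    """
    path = Path(path)
    specs = read_factor_config(config_path)
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except Exception as exc:  # parse failures carry pandas' line context
        raise DataError(f"cannot parse matrix {path}: {exc}") from exc
    return build_decision_problem(df, specs, **kwargs)


def write_matrix(path, m: DecisionMatrix) -> None:
    """Write the raw value table as CSV (shortest-repr floats)."""
    df = m.values.copy()
    df.index.name = "alternative"
    # shortest-repr floats so values round-trip bit-exactly
    df.to_csv(Path(path), encoding="utf-8",
              float_format=lambda x: repr(float(x)))


def config_digest(factors: Sequence[FactorSpec]) -> str:
    """Stable short digest of a factor configuration, for report metadata."""
    blob = ";".join(
        f"{f.name}|{f.direction.value}|{f.shift!r}|{f.weight!r}|{f.units}"
        for f in factors
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
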