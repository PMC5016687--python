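"""Titration CSV dialect, config documents, and structured reports.

Titration files are plain CSV with ``# key=value`` metadata header
lines followed by the two columns ``titrant_monomer_M, delta_r``:

    # probe_total_M=1e-08
    # replicate=1
    # effector=apo
    titrant_monomer_M,delta_r
    0.0,0.0
    ...

``probe_total_M`` is mandatory.  Reports are YAML key-value documents
embedding the package version and a hash of the configuration that
produced them; results go to files, logging to stderr, so commands
compose in pipes.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .titration import TitrationData

__all__ = ["read_titration", "write_titration", "write_report", "config_hash"]

_COLUMNS = ["titrant_monomer_M", "delta_r"]
_META_KEYS = {"probe_total_M", "replicate", "effector", "effector_concentration_M"}


class TitrationFormatError(ValueError):
    """Malformed titration CSV; the message names the offending line."""


def _parse_header(lines: list[str]) -> tuple[dict, int]:
    meta: dict[str, str] = {}
    n = 0
    for i, line in enumerate(lines, start=1):
        if not line.startswith("#"):
            break
        n += 1
        body = line[1:].strip()
        if "=" not in body:
            raise TitrationFormatError(f"line {i}: header line {line.strip()!r} is not 'key=value'")
        key, _, value = body.partition("=")
        key = key.strip()
        if key not in _META_KEYS:
            raise TitrationFormatError(f"line {i}: unknown header key {key!r}")
        meta[key] = value.strip()
    return meta, n


def read_titration(path: str | Path) -> TitrationData:
    """Parse one titration CSV into :class:`TitrationData`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    meta, n_header = _parse_header(lines)
    if "probe_total_M" not in meta:
        raise TitrationFormatError(f"{path.name}: missing required header key 'probe_total_M'")

    body = "\n".join(lines[n_header:])
    try:
        frame = pd.read_csv(_io.StringIO(body), float_precision="round_trip")
    except Exception as exc:
        raise TitrationFormatError(f"{path.name}: cannot parse CSV body: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise TitrationFormatError(
            f"{path.name}, line {n_header + 1}: missing column(s) {missing}; expected {_COLUMNS}"
        )
    if frame[_COLUMNS].isna().any().any():
        bad = int(frame[_COLUMNS].isna().any(axis=1).idxmax()) + n_header + 2
        raise TitrationFormatError(f"{path.name}: non-numeric or missing value near line {bad}")

    eff_conc = meta.get("effector_concentration_M")
    return TitrationData(
        probe_total=float(meta["probe_total_M"]),
        titrant_monomer_totals=frame["titrant_monomer_M"].to_numpy(dtype=float),
        delta_r=frame["delta_r"].to_numpy(dtype=float),
        replicate_id=meta.get("replicate"),
        effector_label=meta.get("effector"),
        effector_concentration=float(eff_conc) if eff_conc is not None else None,
    )


def write_titration(data: TitrationData, path: str | Path) -> Path:
    """Write a titration in the dialect read_titration parses (round-trips)."""
    path = Path(path)
    lines = [f"# probe_total_M={float(data.probe_total)!r}"]
    if data.replicate_id is not None:
        lines.append(f"# replicate={data.replicate_id}")
    if data.effector_label is not None:
        lines.append(f"# effector={data.effector_label}")
    if data.effector_concentration is not None:
        lines.append(f"# effector_concentration_M={float(data.effector_concentration)!r}")
    lines.append(",".join(_COLUMNS))
    # shortest round-trip float repr keeps the round trip bit-exact
    for x, y in zip(data.titrant_monomer_totals, data.delta_r):
        lines.append(f"{float(x)!r},{float(y)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(result: Mapping, path: str | Path, config: Mapping | None = None) -> Path:
    """Write a machine-readable YAML report with provenance fields."""
    path = Path(path)
    doc = {
        "anisofit_version": __version__,
        "config_hash": config_hash(config or {}),
        "result": _plain(result),
    }
    if config is not None:
        doc["config"] = _plain(config)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def _plain(obj):
    """Recursively convert numpy scalars/arrays for clean YAML output."""
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj
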