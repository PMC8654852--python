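"""Result serialization: tidy CSV tables plus a replayable JSON manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .strategies import behavioral_class, canonical_set, encode, names_for

__all__ = ["enumerate_table", "poly_table", "write_results", "config_hash"]


def enumerate_table() -> pd.DataFrame:
    """The canonical strategy table: code, bit string, class, catalog names."""
    rows = [
        {
            "code": encode(s),
            "bits": s.bitstring,
            "class": behavioral_class(s).value,
            "names": ";".join(names_for(s)),
        }
        for s in canonical_set()
    ]
    return pd.DataFrame(rows).sort_values("code", ignore_index=True)


def poly_table(params=None) -> pd.DataFrame:
    """Audit table of the monomorphic derivative cubic, one row per
    canonical strategy (ascending coefficients c0..c3)."""
    from .mean_field import ModelParams, monomorphic_poly

    params = ModelParams() if params is None else params
    rows = []
    for s in canonical_set():
        c0, c1, c2, c3 = monomorphic_poly(s, params)
        rows.append(
            {
                "code": encode(s),
                "bits": s.bitstring,
                "c0": c0,
                "c1": c1,
                "c2": c2,
                "c3": c3,
            }
        )
    return pd.DataFrame(rows)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def config_hash(config) -> str:
    """sha256 of the canonical JSON rendering of a configuration object."""
    payload = json.dumps(_jsonable(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()


def write_results(
    records,
    path: str | Path,
    fmt: str | None = None,
    *,
    config=None,
    seed: int | None = None,
    command: str | None = None,
) -> dict:
    """Write records (DataFrame or list of dicts) with a sidecar manifest.

    Column order is preserved as given (deterministic); the manifest JSON
    records the config hash, seed and package version so a run can be
    replayed from the manifest alone.
    """
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    fmt = fmt or (path.suffix.lstrip(".") or "csv")
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(df.to_json(orient="records", indent=1))
    else:
        raise ValueError(f"unsupported output format {fmt!r}")
    manifest = {
        "path": str(path),
        "format": fmt,
        "rows": int(len(df)),
        "columns": list(df.columns),
        "seed": seed,
        "config": _jsonable(config) if config is not None else None,
        "config_sha256": config_hash(config) if config is not None else None,
        "version": __version__,
        "command": command,
    }
    manifest_path = path.with_name(path.name + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
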