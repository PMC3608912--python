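"""Configuration, manifests and on-disk formats.

Conventions: volumes are NIfTI-1 (RAS+, mm units); event files are
tab-separated with onset/duration in seconds; trial tables are UTF-8 CSV
with categories as strings; fits and decoding results are JSON.  Every CLI
run writes a ``manifest.json`` recording the configuration hash, seeds and
package versions so outputs are attributable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG = {
    "experiment": "main_young",        # main_young | main_older | control
    "seed": 0,
    "stimulus": {},
    "design": {"reps": 16},
    "model": {},
    "mvpa": {"scheme": "all_levels", "select": 100, "alpha": 0.05},
    "searchlight": {"radius_mm": 9.0, "voxel_size_mm": [2.5, 2.5, 4.0],
                    "alpha": 0.05, "cluster_min": "auto"},
    "bootstrap": {"n_iter": 2000},
    "permutation": {"n_perm": 200},
    "paths": {},
}


def _check_keys(given: dict, allowed: dict, prefix: str = "") -> list[str]:
    unknown = []
    for k, v in given.items():
        if k not in allowed:
            unknown.append(prefix + k)
        elif isinstance(v, dict) and isinstance(allowed[k], dict):
            unknown += _check_keys(v, allowed[k], prefix + k + ".")
    return unknown


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a JSON config over defaults; unknown keys are a hard error."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))   # deep copy
    for source in (json.loads(Path(path).read_text()) if path else {},
                   overrides or {}):
        unknown = _check_keys(source, DEFAULT_CONFIG)
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
        for k, v in source.items():
            if isinstance(v, dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir, cfg: dict, extra: dict | None = None) -> Path:
    import glasslearn

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": cfg.get("seed"),
        "versions": {
            "glasslearn": glasslearn.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    manifest.update(extra or {})
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
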