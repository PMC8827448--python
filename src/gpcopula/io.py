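"""Dataset loading and model persistence.

Datasets are delimited tables (TSV/CSV) with an ``x`` column plus named
variable columns, or HDF5 files with ``/x`` and ``/Y`` datasets.  Fitted
models serialize to human-diffable JSON; loading reproduces log-densities
bit-identically (floats round-trip through ``repr``).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .families import make_family
from .gp import FitConfig, GPLatent, MixtureGPState
from .marginals import ConditionedDataset

__all__ = ["load_dataset", "save_vine", "load_vine", "config_hash"]

_FORMAT_VERSION = 1


def load_dataset(path) -> ConditionedDataset:
    """Load a ConditionedDataset from TSV/CSV (x column) or HDF5 (/x, /Y)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            x = np.asarray(f["x"])
            Y = np.asarray(f["Y"])
            names = [n.decode() if isinstance(n, bytes) else str(n) for n in f.attrs.get("names", [])]
        return ConditionedDataset(x, Y, names=list(names))
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if "x" not in df.columns:
        raise ValueError(f"{path} has no 'x' column")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in rows {rows[:10]}")
    ycols = [c for c in df.columns if c != "x"]
    return ConditionedDataset(df["x"].to_numpy(), df[ycols].to_numpy(), names=ycols)


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------
def _latent_to_dict(lat: GPLatent) -> dict:
    return {
        "G": lat.G,
        "mu": float(lat.mu),
        "log_ls": float(lat.log_ls),
        "log_scale": float(lat.log_scale),
        "m": lat.m.tolist(),
        "L_off": lat.L_off.tolist(),
        "L_log_diag": lat.L_log_diag.tolist(),
    }


def _latent_from_dict(d: dict) -> GPLatent:
    lat = GPLatent(d["G"], np.random.default_rng(0))
    lat.mu = d["mu"]
    lat.log_ls = d["log_ls"]
    lat.log_scale = d["log_scale"]
    lat.m = np.asarray(d["m"], dtype=float)
    lat.L_off = np.asarray(d["L_off"], dtype=float)
    lat.L_log_diag = np.asarray(d["L_log_diag"], dtype=float)
    lat._refresh_kernel()
    return lat


def _state_to_dict(state: MixtureGPState | None) -> dict | None:
    if state is None:
        return None
    return {
        "components": [c.key for c in state.components],
        "theta_latents": [_latent_to_dict(l) for l in state.theta_latents],
        "stick_latents": [_latent_to_dict(l) for l in state.stick_latents],
        "x_lo": state.x_lo,
        "x_hi": state.x_hi,
    }


def _state_from_dict(d: dict | None) -> MixtureGPState | None:
    if d is None:
        return None
    return MixtureGPState(
        [make_family(k) for k in d["components"]],
        [_latent_from_dict(l) for l in d["theta_latents"]],
        [_latent_from_dict(l) for l in d["stick_latents"]],
        d["x_lo"],
        d["x_hi"],
    )


def save_vine(results, path, extra: dict | None = None) -> None:
    """Serialize a fitted C-vine (or write ``extra`` provenance alongside)."""
    doc = {
        "format_version": _FORMAT_VERSION,
        "order": [int(v) for v in results.order],
        "edges": {
            f"{t},{j}": _state_to_dict(st) for (t, j), st in results.edges.items()
        },
        "waics": {f"{t},{j}": w for (t, j), w in results.waics.items()},
        "config": {k: getattr(results.config, k) for k in FitConfig.__dataclass_fields__},
    }
    if extra:
        doc["provenance"] = extra
    Path(path).write_text(json.dumps(doc))


def load_vine(path, model=None):
    """Load a serialized C-vine; ``model`` re-attaches the training data."""
    from .vine import CVine, CVineResults

    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('format_version')}")
    order = np.asarray(doc["order"], dtype=int)
    edges = {}
    waics = {}
    for key, st in doc["edges"].items():
        t, j = (int(v) for v in key.split(","))
        edges[(t, j)] = _state_from_dict(st)
        waics[(t, j)] = doc["waics"].get(key, 0.0)
    config = FitConfig.from_dict(doc["config"])
    if model is None:
        m = len(order)
        model = CVine(np.full((2, m), 0.5), np.zeros(2))
    return CVineResults(model, order, edges, waics, config)


def config_hash(config: FitConfig) -> str:
    doc = {k: getattr(config, k) for k in FitConfig.__dataclass_fields__}
    return hashlib.sha1(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:12]
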