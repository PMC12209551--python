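"""Dataset and fit-result I/O.

Datasets travel as a CSV table plus a *manifest*: a mapping that assigns
every non-id column a role among ``time``, ``status``, ``z_u``, ``z_p``,
``x_u``, ``x_p``.  The two penalized roles may alias the same columns
(the shared-penalized-block design).  Categorical covariate columns are
dummy-encoded deterministically (sorted level order, first level as
reference).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SurvivalDataset

__all__ = ["read_dataset", "write_dataset", "load_manifest"]

_ROLES = ("time", "status", "z_u", "z_p", "x_u", "x_p")


def load_manifest(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def _encode_block(df: pd.DataFrame, cols, name: str) -> np.ndarray:
    if not cols:
        return np.empty((len(df), 0))
    parts = []
    for col in cols:
        s = df[col]
        if s.dtype.kind in "ifub":
            vals = s.to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"column {col!r} in {name} contains non-finite values")
            parts.append(vals[:, None])
        else:
            levels = sorted(s.astype(str).unique())
            for level in levels[1:]:  # first level = reference
                parts.append((s.astype(str) == level).to_numpy(float)[:, None])
    return np.hstack(parts)


def read_dataset(csv_path, manifest: dict | str | Path) -> SurvivalDataset:
    """Read a survival table into a :class:`SurvivalDataset`.

    ``manifest`` maps roles to column names: ``time`` and ``status`` to a
    single column each, the four covariate roles to (possibly empty,
    possibly shared) column lists; an optional ``id`` column is ignored.
    """
    if not isinstance(manifest, dict):
        manifest = load_manifest(manifest)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    for role in ("time", "status"):
        if role not in manifest:
            raise ValueError(f"manifest is missing the {role!r} role")
    known = set()
    for role in _ROLES:
        spec = manifest.get(role, [])
        cols = [spec] if isinstance(spec, str) else list(spec)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"columns {missing} assigned to {role!r} are absent")
        known.update(cols)
    known.update([manifest.get("id")] if manifest.get("id") else [])
    unassigned = [c for c in df.columns if c not in known]
    if unassigned:
        raise ValueError(f"columns with no assigned role: {unassigned}")

    time = df[manifest["time"]].to_numpy(dtype=float)
    status = df[manifest["status"]].to_numpy()
    if np.any(time <= 0) or not np.all(np.isfinite(time)):
        bad = df[manifest["time"]][(time <= 0) | ~np.isfinite(time)]
        raise ValueError(
            f"non-positive or non-finite times in column {manifest['time']!r} "
            f"(rows {list(bad.index[:5])})"
        )
    if not np.isin(status, [0, 1]).all():
        raise ValueError(f"status column {manifest['status']!r} must be 0/1")

    def block(role):
        spec = manifest.get(role, [])
        cols = [spec] if isinstance(spec, str) else list(spec)
        return _encode_block(df, cols, role)

    return SurvivalDataset(
        time=time,
        event=status.astype(int),
        z_u=block("z_u"),
        z_p=block("z_p"),
        x_u=block("x_u"),
        x_p=block("x_p"),
    )


def write_dataset(
    dataset: SurvivalDataset,
    csv_path,
    sidecar_path=None,
    params=None,
    shared_penalized: bool = True,
):
    """Write a dataset to CSV (+ optional JSON sidecar with truth).

    Returns the manifest describing the written columns.  When the
    penalized incidence and latency blocks are identical the shared
    columns are written once and referenced by both roles.
    """
    cols = {"id": np.arange(dataset.n), "time": dataset.time, "status": dataset.event}
    manifest = {"id": "id", "time": "time", "status": "status"}
    for role, mat in (("z_u", dataset.z_u), ("x_u", dataset.x_u)):
        names = [f"{role}{j}" for j in range(mat.shape[1])]
        for name, col in zip(names, mat.T):
            cols[name] = col
        manifest[role] = names
    shared = shared_penalized and dataset.z_p.shape == dataset.x_p.shape and np.array_equal(
        dataset.z_p, dataset.x_p
    )
    if shared:
        names = [f"pen{j}" for j in range(dataset.p1p)]
        for name, col in zip(names, dataset.z_p.T):
            cols[name] = col
        manifest["z_p"] = names
        manifest["x_p"] = names
    else:
        for role, mat in (("z_p", dataset.z_p), ("x_p", dataset.x_p)):
            names = [f"{role}{j}" for j in range(mat.shape[1])]
            for name, col in zip(names, mat.T):
                cols[name] = col
            manifest[role] = names
    # %.17g keeps doubles exactly round-trippable through the CSV
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.17g")
    if sidecar_path is not None:
        side = {"manifest": manifest}
        if dataset.latent_cure is not None:
            side["latent_cure"] = dataset.latent_cure.tolist()
        if dataset.latent_frailty is not None:
            side["latent_frailty"] = dataset.latent_frailty.tolist()
        if params is not None:
            side["true_params"] = {
                "alpha": params.alpha,
                "gamma": params.gamma,
                "theta": params.theta,
                "b0": params.b0,
                "b_u": params.b_u.tolist(),
                "b_p": params.b_p.tolist(),
                "beta_u": params.beta_u.tolist(),
                "beta_p": params.beta_p.tolist(),
            }
        Path(sidecar_path).write_text(json.dumps(side))
    return manifest
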