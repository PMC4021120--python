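"""Plain-text readers/writers and run configuration.

Time series travel as CSV with the repetition time recorded in a leading
``# TR=<seconds>`` comment line; one column per voxel. Event tables are
tab-separated (see :mod:`nrffit.events`). Fit results serialize to JSON
with the config hash and seeds alongside, so a run is reproducible from
its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .vl import Posterior

__all__ = ["read_timeseries", "write_timeseries", "load_config",
           "config_hash", "posterior_to_dict", "save_posterior"]


def read_timeseries(path) -> tuple[np.ndarray, float]:
    """Read a CSV time-series file; returns ``(array of shape (T, V), TR)``.

    The TR must appear in a ``# TR=...`` comment line. Non-numeric entries
    and NaN rows are parse errors reported with their line number.
    """
    tr = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.upper().startswith("TR"):
                    try:
                        tr = float(body.split("=", 1)[1])
                    except (IndexError, ValueError) as exc:
                        raise ValueError(
                            f"{path}:{lineno}: malformed TR line") from exc
                continue
            parts = line.split(",")
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric entry") from exc
            if any(np.isnan(v) for v in vals):
                raise ValueError(f"{path}:{lineno}: NaN entry")
            rows.append(vals)
    if tr is None:
        raise ValueError(f"{path}: missing '# TR=' header")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows")
    return np.asarray(rows, dtype=float), tr


def write_timeseries(path, y: np.ndarray, tr: float) -> None:
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] == 1:
        y = y.T
    with open(path, "w") as fh:
        fh.write(f"# TR={tr}\n")
        for row in y:
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def config_hash(cfg: dict) -> str:
    """Stable hash of a (JSON-serializable) configuration mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def posterior_to_dict(post: Posterior, natural: dict | None = None,
                      config: dict | None = None) -> dict:
    out = {
        "mean": post.mean.tolist(),
        "sd": post.sd.tolist(),
        "cov": post.cov.tolist(),
        "names": list(post.names),
        "noise_log_precision": {"mean": post.m_lam, "var": post.s_lam},
        "free_energy": post.free_energy,
        "trace": [float(f) for f in post.trace],
        "converged": bool(post.converged),
        "status": post.status,
        "n_iter": int(post.n_iter),
    }
    if natural is not None:
        out["natural"] = {k: (v.tolist() if isinstance(v, np.ndarray)
                              else float(v)) for k, v in natural.items()}
    if config is not None:
        out["config"] = config
        out["config_hash"] = config_hash(config)
    return out


def save_posterior(path, post: Posterior, natural: dict | None = None,
                   config: dict | None = None) -> None:
    Path(path).write_text(json.dumps(
        posterior_to_dict(post, natural, config), indent=2))
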