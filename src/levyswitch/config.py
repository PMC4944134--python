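"""Run configuration, CSV persistence and reproducibility plumbing.

A ``RunConfig`` collects everything a solve or Monte Carlo run needs —
model rates, noise mix, intervals, resolutions, seed — and validates all
component invariants on load.  Output tables embed the producing
configuration as ``# key=value`` comment lines, so any result file can be
regenerated from its own header.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .analysis import intensities_from_rcf
from .domains import Domain1D
from .model import ModelParams
from .noise import NoiseSpec
from .solver import FieldSolution

__all__ = ["RunConfig", "load_config", "dump_config", "write_table", "DEFAULT_SEED"]

DEFAULT_SEED = 20160714  # fixed documented default so runs reproduce by default

_MODEL_KEYS = {"k_f", "K_d", "k_d", "R_bas"}
_NOISE_KEYS = {"sigma", "epsilon", "alpha", "lambda_rcf", "constrained"}
_TOP_KEYS = {
    "model",
    "noise",
    "domain",
    "target",
    "window",
    "J",
    "dt",
    "n_paths",
    "t_max",
    "seed",
    "outdir",
}


def _intervals(raw) -> Domain1D:
    """Parse [[a, b], ...] (JSON/TOML lists) or "a,b;c,d" strings."""
    if isinstance(raw, str):
        ivs = []
        for part in raw.split(";"):
            a, b = part.split(",")
            ivs.append((float(a), float(b)))
        return Domain1D(ivs)
    if raw and not isinstance(raw[0], (list, tuple)):
        raw = [raw]
    return Domain1D([(float(a), float(b)) for a, b in raw])


@dataclass(frozen=True)
class RunConfig:
    model: ModelParams
    noise: Optional[NoiseSpec] = None
    domain: Optional[Domain1D] = None
    target: Optional[Domain1D] = None
    window: Optional[Domain1D] = None
    J: int = 400
    dt: float = 1e-3
    n_paths: int = 10_000
    t_max: Optional[float] = None
    seed: int = DEFAULT_SEED
    outdir: str = "."


def _build(raw: dict, source: str) -> RunConfig:
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{source}: unknown keys {sorted(unknown)}")
    if "model" not in raw:
        raise ValueError(f"{source}: missing [model] section")
    mraw = dict(raw["model"])
    if set(mraw) - _MODEL_KEYS:
        raise ValueError(f"{source}: unknown model keys {sorted(set(mraw) - _MODEL_KEYS)}")
    model = ModelParams(**mraw)

    noise = None
    if "noise" in raw:
        nraw = dict(raw["noise"])
        if set(nraw) - _NOISE_KEYS:
            raise ValueError(
                f"{source}: unknown noise keys {sorted(set(nraw) - _NOISE_KEYS)}"
            )
        lam = nraw.pop("lambda_rcf", None)
        if lam is not None:
            if "sigma" in nraw or "epsilon" in nraw:
                raise ValueError(f"{source}: give either lambda_rcf or (sigma, epsilon)")
            sigma, epsilon = intensities_from_rcf(float(lam))
            nraw.update(sigma=sigma, epsilon=epsilon, constrained=True)
        noise = NoiseSpec(**nraw)

    kwargs: dict = {"model": model, "noise": noise}
    for key in ("domain", "target", "window"):
        if key in raw:
            kwargs[key] = _intervals(raw[key])
    for key in ("J", "dt", "n_paths", "t_max", "seed", "outdir"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a TOML or JSON run configuration."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        raw = tomllib.loads(path.read_text())
    elif path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
    else:
        raise ValueError(f"unsupported config extension {path.suffix!r} (TOML or JSON)")
    return _build(raw, str(path))


def dump_config(cfg: RunConfig, path) -> None:
    """Write a config back to JSON such that load(dump(cfg)) == cfg."""
    path = Path(path)
    raw: dict = {"model": dataclasses.asdict(cfg.model)}
    if cfg.noise is not None:
        raw["noise"] = {
            "sigma": cfg.noise.sigma,
            "epsilon": cfg.noise.epsilon,
            "alpha": cfg.noise.alpha,
            "constrained": cfg.noise.constrained,
        }
    for key in ("domain", "target", "window"):
        dom = getattr(cfg, key)
        if dom is not None:
            raw[key] = [list(iv) for iv in dom.intervals]
    raw.update(J=cfg.J, dt=cfg.dt, n_paths=cfg.n_paths, seed=cfg.seed, outdir=cfg.outdir)
    if cfg.t_max is not None:
        raw["t_max"] = cfg.t_max
    path.write_text(json.dumps(raw, indent=1))


def _config_comment_lines(meta: dict) -> list[str]:
    return [f"# {k}={v}" for k, v in meta.items()]


def write_table(table, path, meta: Optional[dict] = None) -> None:
    """Write a sweep table or field solution as CSV.

    A commented ``# key=value`` header block precedes the column headers;
    numbers carry 6 significant digits.  ``FieldSolution`` becomes columns
    (x, value); a sweep DataFrame keeps its own columns.
    """
    path = Path(path)
    if isinstance(table, FieldSolution):
        xs = np.concatenate(
            [table.interval_arrays(m)[0] for m in range(table.grid.n_intervals)]
        )
        vs = np.concatenate(
            [table.interval_arrays(m)[1] for m in range(table.grid.n_intervals)]
        )
        if table.kind == "fep":
            vs = np.clip(vs, 0.0, 1.0)
        df = pd.DataFrame({"x": xs, "value": vs})
    elif isinstance(table, pd.DataFrame):
        df = table
    else:
        raise TypeError(f"cannot serialise {type(table)!r}")
    lines = _config_comment_lines(meta or {})
    body = df.to_csv(index=False, float_format="%.6g")
    path.write_text("\n".join(lines + [body]) if lines else body)
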