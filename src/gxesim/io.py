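"""Readers/writers for CSV/JSON artefacts, config loading and provenance.

Matrices travel as labelled CSV (environment headers E1..Ep), tables as
tidy CSV, and every CLI run writes a RunManifest JSON recording the
resolved parameters, seed, package version and output digests. Floats
are written with 17 significant digits so round-trips are lossless.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .breeding import ProgrammeConfig, StageConfig
from .errors import ParameterError
from .tpe import CorrelationSpec, VarianceSpec

__all__ = [
    "RunManifest",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_table_csv",
    "load_config",
    "write_outputs",
    "get_logger",
]

FLOAT_FORMAT = "%.17g"

logger = logging.getLogger("gxesim")


def get_logger(level: str = "INFO") -> logging.Logger:
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level.upper())
    return logger


def write_matrix_csv(path, matrix: np.ndarray, labels=None, label_prefix: str = "E") -> Path:
    """Write a square (or rectangular) matrix as labelled CSV."""
    path = Path(path)
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if labels is None:
        labels = [f"{label_prefix}{j + 1}" for j in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, columns=labels)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_matrix_csv(path) -> np.ndarray:
    # round_trip parsing: the default pandas float parser can be 1 ulp off
    return pd.read_csv(path, float_precision="round_trip").to_numpy(dtype=float)


def write_table_csv(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


@dataclass
class RunManifest:
    """Provenance record for one CLI run; round-trips losslessly via JSON."""

    command: str
    parameters: dict
    seed: int | None
    package_version: str = ""
    timestamp: str = ""
    output_digests: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.package_version:
            from . import __version__

            self.package_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def add_output(self, path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.output_digests[path.name] = digest

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=_jsonify) + "\n")
        return path

    @classmethod
    def load(cls, path) -> "RunManifest":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# -- configuration ----------------------------------------------------------

def load_config(path) -> dict:
    """Load and validate a YAML parameter bundle.

    Recognised top-level sections: ``tpe`` (p, shape, scale, rho,
    epsilon, gamma_skew, k), ``met`` (p_m, v, r, mu, h2 or sigma2_eps),
    ``programme`` (ProgrammeConfig fields with a ``stages`` list).
    All domain-type constraints are enforced at load; violations raise
    ParameterError naming the field.
    """
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    bundle: dict = {"raw": raw}
    if "tpe" in raw:
        t = dict(raw["tpe"])
        p = int(t.pop("p"))
        var_spec = VarianceSpec(p=p, shape=float(t.pop("shape", 1.5)), scale=float(t.pop("scale", 1.0)))
        rho = float(t.pop("rho", 0.5))
        epsilon = t.pop("epsilon", None)
        epsilon = None if epsilon is None else float(epsilon)
        corr_spec = CorrelationSpec(
            p=p,
            rho=rho,
            epsilon=epsilon,
            gamma_skew=float(t.pop("gamma_skew", 0.0)),
            k=int(t.pop("k", 7)),
            enforce_rank=bool(t.pop("enforce_rank", epsilon is None or abs(epsilon - (1 - rho)) <= 1e-12)),
        )
        if t:
            raise ParameterError(f"unknown tpe fields: {sorted(t)}")
        bundle["variance_spec"] = var_spec
        bundle["correlation_spec"] = corr_spec
    if "met" in raw:
        m = dict(raw["met"])
        met = {
            "p_m": int(m.pop("p_m")),
            "v": int(m.pop("v")),
            "r": int(m.pop("r", 2)),
            "mu": float(m.pop("mu", 0.0)),
        }
        if "h2" in m:
            h2 = float(m.pop("h2"))
            if not 0.0 < h2 < 1.0:
                raise ParameterError(f"met.h2 must lie in (0, 1), got {h2}")
            met["h2"] = h2
        if "sigma2_eps" in m:
            met["sigma2_eps"] = float(m.pop("sigma2_eps"))
        if m:
            raise ParameterError(f"unknown met fields: {sorted(m)}")
        if min(met["p_m"], met["v"], met["r"]) < 1:
            raise ParameterError("met.p_m, met.v and met.r must all be >= 1")
        bundle["met"] = met
    if "programme" in raw:
        pr = dict(raw["programme"])
        stage_rows = pr.pop("stages", None)
        kwargs = {key: val for key, val in pr.items()}
        if stage_rows is not None:
            kwargs["stages"] = tuple(
                StageConfig(
                    name=str(s["name"]),
                    n_genotypes=int(s["n_genotypes"]),
                    n_envs=int(s["n_envs"]),
                    n_reps=int(s.get("n_reps", 1)),
                    error_variance=float(s.get("error_variance", 4.0)),
                )
                for s in stage_rows
            )
        bundle["programme"] = ProgrammeConfig(**kwargs)
    return bundle


def write_outputs(objects: dict, out_dir, command: str = "", parameters: dict | None = None, seed=None) -> RunManifest:
    """Write a named set of matrices/tables/dicts and a manifest.

    ``objects`` maps file stems to ndarray (-> labelled CSV), DataFrame
    (-> tidy CSV) or dict (-> JSON). Returns the saved manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(command=command, parameters=parameters or {}, seed=seed)
    for stem, obj in objects.items():
        if isinstance(obj, pd.DataFrame):
            path = write_table_csv(out_dir / f"{stem}.csv", obj)
        elif isinstance(obj, np.ndarray):
            path = write_matrix_csv(out_dir / f"{stem}.csv", obj)
        elif isinstance(obj, dict):
            path = out_dir / f"{stem}.json"
            path.write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")
        else:
            raise ParameterError(f"cannot serialise object of type {type(obj)} for {stem!r}")
        manifest.add_output(path)
    manifest.save(out_dir / "manifest.json")
    return manifest
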