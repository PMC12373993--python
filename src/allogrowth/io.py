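"""File formats and run configuration.

The interchange format is a plain CSV with one row per observation event and
the fixed header ``individual_id,scenario,time_days,length_mm,neonates``
(UTF-8, decimal point).  Outputs carry a run-metadata block as ``#``-prefixed
comment lines (inputs' checksums, configuration, seed, package version) that
readers skip.  A column-mapping hook lets differently-named deposits be
ingested without editing files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .gradient_fit import REQUIRED_COLUMNS, FitResult, GrowthDataset
from .growth_model import AllocationSchedule

__all__ = [
    "RunConfig",
    "read_growth_csv",
    "write_growth_csv",
    "write_fit_result",
    "read_fit_result",
    "metadata_block",
]

logger = logging.getLogger(__name__)

UM_PER_MM = 1000.0


@dataclasses.dataclass
class RunConfig:
    """Run configuration; flat key-value TOML files map onto these fields."""

    grid_step: float = 0.5          # dt (day)
    loess_span: float = 0.25
    loess_degree: int = 3
    lambda_min: float = 0.0
    lambda_max: float = 0.6
    lambda_step: float = 0.01
    bootstrap_B: int = 200
    seed: Optional[int] = None
    length_unit: str = "mm"         # "mm" or "um"
    k: float = 3.0                  # mass-length exponent

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.lambda_max < self.lambda_min or self.lambda_step <= 0:
            raise ValueError("empty lambda grid")
        if self.length_unit not in ("mm", "um"):
            raise ValueError("length_unit must be 'mm' or 'um'")

    @property
    def lambda_grid(self) -> tuple[float, float, float]:
        return (self.lambda_min, self.lambda_max, self.lambda_step)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            payload = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in payload.items() if k in known})


def metadata_block(seed=None, config: Optional[RunConfig] = None,
                   inputs: Optional[list] = None) -> list[str]:
    """Comment lines embedding provenance into text outputs."""
    from . import __version__
    lines = [f"# allogrowth {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append("# config: " + json.dumps(dataclasses.asdict(config)))
    for path in inputs or []:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        lines.append(f"# input: {Path(path).name} sha256:{digest}")
    return lines


def read_growth_csv(path, config: Optional[RunConfig] = None,
                    column_map: Optional[dict[str, str]] = None
                    ) -> GrowthDataset:
    """Read and validate a growth-records CSV.

    ``column_map`` renames foreign column names onto the package schema
    (e.g. ``{"id": "individual_id"}``) so deposited datasets with a
    different header can be ingested as-is.  With ``length_unit = "um"`` in
    the config, lengths are converted to millimetres on ingest.  Duplicate
    or non-increasing times per individual are errors naming the offending
    row; unknown columns raise a warning and are dropped.
    """
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=column_map)
    unknown = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown columns {unknown} in {path}")
        df = df.drop(columns=unknown)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if config is not None and config.length_unit == "um":
        df["length_mm"] = df["length_mm"] / UM_PER_MM
    # name offending rows (1-based, header = row 1) before the generic checks
    for ind, sub in df.groupby("individual_id", sort=False):
        t = sub["time_days"].to_numpy()
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            row = sub.index[bad[0] + 1] + 2
            kind = ("duplicate observation time"
                    if t[bad[0] + 1] == t[bad[0]] else "non-increasing time")
            raise ValueError(f"{path} row {row}: {kind} for individual "
                             f"{ind!r}")
    return GrowthDataset(df)


def write_growth_csv(dataset: GrowthDataset, path, seed=None,
                     config: Optional[RunConfig] = None) -> None:
    """Write a dataset with an embedded run-metadata comment block."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in metadata_block(seed=seed, config=config):
            fh.write(line + "\n")
        dataset.frame.to_csv(fh, index=False)


def _schedule_to_dict(sched: AllocationSchedule) -> dict:
    return {"times": sched.times.tolist(), "r": sched.r.tolist()}


def write_fit_result(fit: FitResult, path, seed=None,
                     config: Optional[RunConfig] = None) -> None:
    """Serialise a FitResult as structured text (JSON)."""
    payload = {
        "meta": metadata_block(seed=seed, config=config),
        "lambda_hat": fit.lambda_hat,
        "q_hat": fit.q_hat,
        "sigma_hat": fit.sigma_hat,
        "sse": fit.sse,
        "l0": fit.l0,
        "n_individuals": fit.n_individuals,
        "excluded": fit.excluded,
        "r_hat": {s: _schedule_to_dict(r) for s, r in fit.r_hat.items()},
        "ci": fit.ci,
        "ci_level": fit.ci_level,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n",
                          encoding="utf-8")


def read_fit_result(path) -> FitResult:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    r_hat = {s: AllocationSchedule(times=np.asarray(d["times"]),
                                   r=np.asarray(d["r"]))
             for s, d in payload["r_hat"].items()}
    ci = payload.get("ci")
    if ci is not None:
        ci = {k: tuple(v) for k, v in ci.items()}
    return FitResult(
        lambda_hat=payload["lambda_hat"], q_hat=payload["q_hat"],
        r_hat=r_hat, sigma_hat=payload["sigma_hat"], sse=payload["sse"],
        l0=payload["l0"], n_individuals=payload["n_individuals"],
        excluded=payload.get("excluded", []), ci=ci,
        ci_level=payload.get("ci_level"))
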