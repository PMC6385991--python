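"""Delimited-text readers/writers and run configuration.

Canonical dialect is tab-separated; comma-separated files are accepted on
read (sniffed from the header line).  Every file written by the package
carries a provenance header — comment lines with the package version, the
seed and a hash of the generating configuration — which readers skip.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kernels import MarkerMatrix
from .synthetic import SyntheticConfig, TruthRecord
from .tgblup import TGBLUPConfig
from .trial import OrdinalTrialTable

__all__ = [
    "read_phenotypes",
    "read_markers",
    "read_g1",
    "write_phenotypes",
    "write_markers",
    "write_truth",
    "provenance_header",
    "RunConfig",
]


def _sniff_sep(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: no data lines")


def provenance_header(config: dict | None = None, seed=None) -> str:
    """Comment block recording version, seed and a config hash."""
    blob = json.dumps(config or {}, sort_keys=True, default=str)
    digest = hashlib.sha1(blob.encode()).hexdigest()[:12]
    lines = [f"# ordinalgs v{__version__}", f"# config_sha1={digest}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config:
        lines.append(f"# config={blob}")
    return "\n".join(lines) + "\n"


def read_phenotypes(path) -> OrdinalTrialTable:
    """Read (env_id, line_id, trait, category) records.

    Categories are validated as integers and densely recoded to 1..C per
    trait (original labels retained in ``category_maps``); duplicate cells
    and unknown columns fail with the offending row.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    return OrdinalTrialTable(df)


def read_markers(path) -> MarkerMatrix:
    """Read a line × marker dosage matrix (first column ``line_id``).

    Missing values are rejected with their coordinates — marker imputation
    is out of scope and must happen upstream.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.columns[0] != "line_id":
        raise ValueError(f"{path}: first column must be 'line_id', got {df.columns[0]!r}")
    line_ids = df["line_id"].astype(str).tolist()
    body = df.drop(columns="line_id")
    values = body.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: missing/non-numeric value at line {line_ids[r]!r}, "
            f"marker {body.columns[c]!r}"
        )
    return MarkerMatrix(line_ids=line_ids, raw=values, marker_ids=list(body.columns))


def check_lines_covered(table: OrdinalTrialTable, markers: MarkerMatrix) -> None:
    """Every phenotyped line must be genotyped (extra genotypes are fine)."""
    missing = sorted(set(table.line_ids) - set(map(str, markers.line_ids)))
    if missing:
        raise ValueError(f"phenotyped line(s) absent from marker file: {missing}")


def read_g1(path, line_ids=None) -> np.ndarray:
    """Read a precomputed square GRM with a ``line_id`` index column."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#", index_col=0)
    G1 = df.to_numpy(dtype=float)
    if G1.shape[0] != G1.shape[1]:
        raise ValueError(f"{path}: GRM must be square, got {G1.shape}")
    ids = list(map(str, df.index))
    if line_ids is not None and ids != list(map(str, line_ids)):
        raise ValueError(f"{path}: GRM line ids do not match marker line ids")
    return G1


def _write(path, header: str, df: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def write_phenotypes(table: OrdinalTrialTable, path, config=None, seed=None) -> None:
    _write(path, provenance_header(config, seed), table.df)


def write_markers(markers: MarkerMatrix, path, config=None, seed=None) -> None:
    df = pd.DataFrame(markers.raw.astype(int), columns=markers.marker_ids)
    df.insert(0, "line_id", markers.line_ids)
    _write(path, provenance_header(config, seed), df)


def write_truth(truth: TruthRecord, path, config=None, seed=None) -> None:
    """Sidecar truth file: one row per grid cell with liability and probs."""
    cfg = truth.config
    ii, jj = np.meshgrid(np.arange(cfg.I), np.arange(cfg.J), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    df = pd.DataFrame(
        {
            "env_id": [cfg.env_ids[i] for i in ii],
            "line_id": [cfg.line_ids[j] for j in jj],
            "observed": truth.observed[ii, jj].astype(int),
            "liability": truth.liab_grid[ii, jj],
            "g": truth.g[jj],
            "gE": truth.gE[ii, jj],
            "category": truth.category_grid[ii, jj],
        }
    )
    for c in range(cfg.C):
        df[f"pi_{c+1}"] = truth.probs_grid[ii, jj, c]
    _write(path, provenance_header(config, seed), df)


@dataclass
class RunConfig:
    """End-to-end run configuration (YAML-loadable)."""

    phenotypes: str | None = None
    markers: str | None = None
    g1: str | None = None
    output_dir: str = "results"
    models: list = field(default_factory=lambda: ["TGBLUP", "MLP", "SVM"])
    variants: list = field(default_factory=lambda: ["I", "WI"])
    cv_k: int = 5
    seed: int = 0
    log_level: str = "INFO"
    synthetic: SyntheticConfig | None = None
    tgblup: TGBLUPConfig = field(default_factory=TGBLUPConfig)
    mlp_full_grid: bool = False
    svm_cost_grid: tuple = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0)
    svm_gamma_grid: tuple = (1e-4, 2e-4, 2.5e-4, 3e-4)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            for key in ("thresholds", "env_effects", "maf_range"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            raw["synthetic"] = SyntheticConfig(**syn)
        if "tgblup" in raw and raw["tgblup"] is not None:
            raw["tgblup"] = TGBLUPConfig(**raw["tgblup"])
        cfg = cls(**raw)
        for p in (cfg.phenotypes, cfg.markers, cfg.g1):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, (SyntheticConfig, TGBLUPConfig)):
                out[k] = v.__dict__
            else:
                out[k] = v
        return out
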