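"""Configuration, trace and report I/O.

Traces are two-column delimited text (time s, current) with a ``#``-prefixed
metadata header, readable with any plotting tool.  Datasets are a directory
of trace files plus a JSON manifest recording the generating truth.  Run
configurations are YAML with explicit units at the boundary: concentrations
in µM, rates in s⁻¹ and µM⁻¹s⁻¹, K_D reported in nM, ΔG in kJ/mol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .fitting import DEFAULT_TEMPERATURE, FitResult
from .model import RateParameters
from .protocols import CurrentTrace, DEFAULT_TAU_EXCHANGE
from .synthetic import RecoveryDataset

__all__ = [
    "RunConfig",
    "write_trace",
    "read_trace",
    "write_dataset",
    "read_dataset",
    "params_from_dict",
    "load_config",
    "save_config",
    "default_config",
    "fit_report_frame",
]


# ---------------------------------------------------------------------------
# traces


def write_trace(path: str | Path, trace: CurrentTrace) -> None:
    path = Path(path)
    header = "\n".join(
        f"# {key} = {json.dumps(value)}" for key, value in sorted(trace.metadata.items())
    )
    body = np.column_stack([trace.t, trace.I])
    with path.open("w") as fh:
        if header:
            fh.write(header + "\n")
        fh.write(f"# sampling_rate_hz = {trace.sampling_rate}\n")
        fh.write("# columns = time_s\tcurrent\n")
        np.savetxt(fh, body, fmt="%.12g", delimiter="\t")


def read_trace(path: str | Path) -> CurrentTrace:
    path = Path(path)
    metadata: dict[str, Any] = {}
    with path.open() as fh:
        rows = []
        for line in fh:
            if line.startswith("#"):
                if "=" in line:
                    key, _, raw = line[1:].partition("=")
                    key = key.strip()
                    raw = raw.strip()
                    if key == "columns":
                        continue
                    try:
                        metadata[key] = json.loads(raw)
                    except json.JSONDecodeError:
                        metadata[key] = raw
                continue
            if line.strip():
                rows.append([float(x) for x in line.split()])
    data = np.asarray(rows)
    sampling_rate = metadata.pop("sampling_rate_hz", 2000.0)
    return CurrentTrace(data[:, 0], data[:, 1], sampling_rate, metadata)


def write_dataset(dataset: RecoveryDataset, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, trace in enumerate(dataset.traces):
        p = directory / f"trace_{i:02d}.txt"
        write_trace(p, trace)
        paths.append(p)
    (directory / "manifest.json").write_text(json.dumps(dataset.manifest, indent=2))
    return paths


def read_dataset(directory: str | Path) -> tuple[list[CurrentTrace], dict]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    traces = [read_trace(p) for p in sorted(directory.glob("trace_*.txt"))]
    if not traces:
        raise FileNotFoundError(f"no trace files found under {directory}")
    return traces, manifest


# ---------------------------------------------------------------------------
# parameters and configuration


def params_from_dict(raw: Mapping[str, Any]) -> RateParameters:
    """Build RateParameters from a config mapping, naming any unknown key."""
    known = set(RateParameters._RATE_NAMES) | {"ties", "free"}
    unknown = set(raw) - known
    if unknown:
        raise KeyError(f"unknown rate-parameter keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = dict(raw)
    if "ties" in kwargs:
        kwargs["ties"] = tuple(tuple(g) for g in kwargs["ties"])
    if "free" in kwargs:
        kwargs["free"] = tuple(kwargs["free"])
    return RateParameters(**kwargs)


@dataclass
class RunConfig:
    """One reproducible run: parameters, protocol, fit options, outputs."""

    params: RateParameters
    protocol: dict = field(default_factory=dict)   # name + builder options
    fit: dict = field(default_factory=dict)        # temperature, starts, guess
    schild: dict = field(default_factory=dict)     # concentration grids
    seed: int = 0
    noise_sd: float = 0.02
    scale: float = 1.0
    tau_exchange: float = DEFAULT_TAU_EXCHANGE
    temperature: float = DEFAULT_TEMPERATURE
    output_dir: str = "p2x3kin_output"

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "protocol": dict(self.protocol),
            "fit": dict(self.fit),
            "schild": dict(self.schild),
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "scale": self.scale,
            "tau_exchange": self.tau_exchange,
            "temperature": self.temperature,
            "output_dir": self.output_dir,
        }


def default_config() -> RunConfig:
    """Wild-type defaults with the published TNP-ATP antagonist rates."""
    return RunConfig(
        params=RateParameters(),
        protocol={
            "name": "steady_state",
            "agonist_conc": 10.0,
            "antagonist_concs": [0.001, 0.003, 0.01, 0.03],
        },
        fit={"initial_guess": [1.0, 0.1], "n_starts": 3},
        schild={},
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} is not a mapping")
    try:
        params = params_from_dict(raw.get("params", {}))
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"invalid 'params' section in {path}: {exc}") from exc
    defaults = default_config()
    return RunConfig(
        params=params,
        protocol=raw.get("protocol", defaults.protocol),
        fit=raw.get("fit", defaults.fit),
        schild=raw.get("schild", {}),
        seed=int(raw.get("seed", 0)),
        noise_sd=float(raw.get("noise_sd", 0.02)),
        scale=float(raw.get("scale", 1.0)),
        tau_exchange=float(raw.get("tau_exchange", DEFAULT_TAU_EXCHANGE)),
        temperature=float(raw.get("temperature", DEFAULT_TEMPERATURE)),
        output_dir=str(raw.get("output_dir", "p2x3kin_output")),
    )


# ---------------------------------------------------------------------------
# reports


def fit_report_frame(
    fits: Sequence[FitResult],
    antagonists: Sequence[str] | None = None,
    variants: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tabulate fits in the conventional report shape.

    Columns: antagonist, variant, k1 (µM⁻¹s⁻¹), k_minus1 (s⁻¹), K_D ± SD
    (nM), ΔG ± SD (kJ/mol), n traces, converged.
    """
    rows = []
    for i, fit in enumerate(fits):
        rows.append({
            "antagonist": antagonists[i] if antagonists else "",
            "variant": variants[i] if variants else "wt",
            "k1_per_uM_s": fit.k1_hat,
            "k_minus1_per_s": fit.k_minus1_hat,
            "KD_nM": fit.KD,
            "sd_KD_nM": fit.sd_KD,
            "dG_kJ_mol": fit.dG,
            "sd_dG_kJ_mol": fit.sd_dG,
            "n": fit.n_traces,
            "converged": fit.converged,
        })
    return pd.DataFrame(rows)
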