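"""Reading and writing the package's plain-text table formats.

All tables are TSV.  Trajectory files may carry '#' comment lines in the
header echoing the scenario parameters and seeds; count tables and
insertion-call tables are plain TSV with a header row.  YAML configuration
files mirror :class:`~tedyn.params.SimParams` and
:class:`~tedyn.synth.GeneratorConfig` field for field.
"""

from __future__ import annotations

import sys
from pathlib import Path
from typing import List, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd
import yaml

from .engine import Trajectory
from .params import SimParams
from .synth import GeneratorConfig

__all__ = ["load_sim_config", "load_generator_config", "write_trajectories",
           "read_trajectories", "read_count_table", "write_count_table",
           "read_records", "write_records"]

PathLike = Union[str, Path]


def load_sim_config(path: PathLike) -> SimParams:
    """Load a simulation scenario from a YAML file mirroring SimParams."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimParams.from_dict(data)


def load_generator_config(path: PathLike) -> GeneratorConfig:
    """Load a synthetic-data generator config from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return GeneratorConfig.from_dict(data)


def write_trajectories(trajectories: Sequence[Trajectory], path: PathLike,
                       params: Optional[SimParams] = None) -> None:
    """Write replicate trajectories as TSV with a commented header.

    Columns: replicate, generation, mean_load, var_load, modifier_freq.
    When ``params`` is given, its fields (including the master seed) are
    echoed into '#' comment lines so a file is self-describing.
    """
    df = pd.concat([t.to_dataframe() for t in trajectories],
                   ignore_index=True)
    with open(path, "w") as fh:
        if params is not None:
            for key, value in params.to_dict().items():
                fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_trajectories(path: PathLike) -> List[Trajectory]:
    """Read a trajectory TSV (as written by :func:`write_trajectories`)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"replicate", "generation", "mean_load", "var_load",
                "modifier_freq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file misses columns: {sorted(missing)}")
    out = []
    for rep, g in df.groupby("replicate", sort=True):
        g = g.sort_values("generation")
        out.append(Trajectory(int(rep), g["generation"].to_numpy(),
                              g["mean_load"].to_numpy(),
                              g["var_load"].to_numpy(),
                              g["modifier_freq"].to_numpy()))
    return out


def read_count_table(path: PathLike) -> pd.DataFrame:
    """Read a per-sample count table (strain, mode, generation, coverage,
    count)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"strain", "mode", "generation", "coverage", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table misses columns: {sorted(missing)}")
    return df


def write_count_table(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_records(path: PathLike) -> pd.DataFrame:
    """Read a BED-like insertion-call table (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "start", "end", "family", "detector", "strain",
                "generation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"record table misses columns: {sorted(missing)}")
    return df


def write_records(records: pd.DataFrame, path: PathLike) -> None:
    records.to_csv(path, sep="\t", index=False)
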