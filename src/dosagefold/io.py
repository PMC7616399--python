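"""Plain-text readers/writers for all pipeline artifacts.

Feature tables are TSV (first columns ``sample_id``, ``strain``, ``ploidy``,
``replicate``, ``is_qc``, then one column per feature); flow and mass
observations are CSV; configs are YAML or JSON.  Every writer prepends a
``#`` metadata header recording the seed and a config hash so any
intermediate file identifies the run that produced it.  Readers validate
the schema and report offending row/column coordinates.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import FeatureTable, FlowObservation, MassObservation, PLOIDY_LEVELS
from .simulate import SimulationConfig

META_COLS = ["strain", "ploidy", "replicate", "is_qc"]


def config_hash(config: SimulationConfig | dict) -> str:
    d = config.to_dict() if isinstance(config, SimulationConfig) else dict(config)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _header(seed, chash) -> str:
    return f"# dosagefold seed={seed} config_hash={chash}\n"


def write_feature_table(
    table: FeatureTable, path, seed: int | None = None, chash: str = ""
) -> None:
    path = Path(path)
    frame = table.sample_meta[META_COLS].join(table.data)
    frame.index.name = "sample_id"
    with open(path, "w") as fh:
        fh.write(_header(seed if seed is not None else table.attrs.get("seed"), chash))
        fh.write(f"# platform={table.platform} scale={table.scale}\n")
        frame.to_csv(fh, sep="\t", float_format="%.17g")


def read_feature_table(path) -> FeatureTable:
    path = Path(path)
    platform, scale = "unknown", "raw"
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            if "platform=" in line:
                platform = line.split("platform=")[1].split()[0].strip()
            if "scale=" in line:
                scale = line.split("scale=")[1].split()[0].strip()
            continue
        body.append(line)
    frame = pd.read_csv(
        _io.StringIO("".join(body)),
        sep="\t",
        index_col="sample_id",
        float_precision="round_trip",
        dtype={"strain": str, "ploidy": str},
    )
    missing = [c for c in ("strain", "ploidy", "replicate") if c not in frame.columns]
    if missing:
        raise ValueError(f"feature table {path}: missing metadata columns {missing}")
    if "is_qc" not in frame.columns:
        frame["is_qc"] = False
    meta = frame[META_COLS].copy()
    meta["is_qc"] = meta["is_qc"].astype(bool)
    data = frame.drop(columns=META_COLS).astype(float)
    bad_ploidy = ~meta["ploidy"].isin(PLOIDY_LEVELS) & ~meta["is_qc"]
    if bad_ploidy.any():
        row = meta.index[bad_ploidy][0]
        raise ValueError(
            f"feature table {path}: row {row!r} has invalid ploidy "
            f"{meta.loc[row, 'ploidy']!r} (expected one of {PLOIDY_LEVELS})"
        )
    neg = data.lt(0) if scale == "raw" else data.lt(np.inf) & False
    if neg.any().any():
        col = neg.any().idxmax()
        row = neg[col].idxmax()
        raise ValueError(
            f"feature table {path}: negative abundance at row {row!r}, column {col!r}"
        )
    return FeatureTable(data, meta, platform, scale=scale)


def write_flow_observations(obs: list, path, seed=None, chash: str = "") -> None:
    frame = pd.DataFrame(
        [
            {
                "strain": o.strain,
                "rmass": o.rmass,
                "count_2C": o.count_2C,
                "count_4C": o.count_4C,
            }
            for o in obs
        ]
    )
    with open(path, "w") as fh:
        fh.write(_header(seed, chash))
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_flow_observations(path) -> list:
    frame = pd.read_csv(
        path, comment="#", float_precision="round_trip", dtype={"strain": str}
    )
    required = {"strain", "rmass", "count_2C", "count_4C"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"flow table {path}: missing columns {sorted(missing)}")
    return [
        FlowObservation(
            strain=str(r.strain),
            rmass=float(r.rmass),
            count_2C=int(r.count_2C),
            count_4C=int(r.count_4C),
        )
        for r in frame.itertuples()
    ]


def write_mass_observations(obs: list, path, seed=None, chash: str = "") -> None:
    frame = pd.DataFrame(
        [{"strain": o.strain, "ploidy": o.ploidy, "m": o.m, "dm": o.dm} for o in obs]
    )
    with open(path, "w") as fh:
        fh.write(_header(seed, chash))
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_mass_observations(path) -> list:
    frame = pd.read_csv(
        path,
        comment="#",
        float_precision="round_trip",
        dtype={"strain": str, "ploidy": str},
    )
    required = {"strain", "ploidy", "m", "dm"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"mass table {path}: missing columns {sorted(missing)}")
    return [
        MassObservation(
            strain=str(r.strain), ploidy=str(r.ploidy), m=float(r.m), dm=float(r.dm)
        )
        for r in frame.itertuples()
    ]


def write_config(config: SimulationConfig, path) -> None:
    path = Path(path)
    d = config.to_dict()
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(d, fh, sort_keys=True)
        else:
            json.dump(d, fh, indent=2, sort_keys=True)


def read_config(path) -> SimulationConfig:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            d = yaml.safe_load(fh)
        else:
            d = json.load(fh)
    return SimulationConfig.from_dict(d)


def write_draws(draws_by_name: dict, path) -> None:
    """Posterior draws as JSON: name -> flat list."""
    out = {k: np.asarray(v).ravel().tolist() for k, v in draws_by_name.items()}
    with open(path, "w") as fh:
        json.dump(out, fh)


def read_draws(path) -> dict:
    with open(path) as fh:
        return {k: np.asarray(v) for k, v in json.load(fh).items()}
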