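"""Configuration files, HDF5 persistence, and run manifests.

A model configuration is a YAML (or JSON) document with four optional
blocks::

    variant: ITWT
    lattice: {rows: 5, cols: 5}        # or {cells: 25}
    fixed:   {V: 4200.0, ...}          # fixed biophysical constants
    free:    {Nanog_NANOG: 125, ...}   # free-parameter values by alias
    flags:   {coop_power: false, ...}  # numerical-convention switches

Unknown keys anywhere are rejected; omitted values fall back to the MAP
defaults.  Ensembles are stored in HDF5 (``/grid`` stacked replicate arrays
plus ``/params`` and ``/meta`` attributes) and tidy summaries as CSV.  Every
run writes a JSON manifest capturing the full configuration, seed policy and
software version, which together with the code determines each output.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import GridSeries
from .lattice import Lattice, build_lattice, lattice_for_size
from .observables import FATES, fate_counts
from .params import FREE_PARAM_NAMES, VARIANTS, ParameterSet

__all__ = [
    "load_config",
    "dump_config",
    "RunManifest",
    "save_ensemble",
    "load_ensemble",
    "fate_table",
]

_FLAG_FIELDS = ("ku_rule", "rho_faces", "sequester_bound_tf",
                "dimer_ligand_count", "icd_split", "exogenous_target")
_FIXED_FIELDS = tuple(
    f.name for f in dataclasses.fields(ParameterSet)
    if f.name not in FREE_PARAM_NAMES and f.name not in _FLAG_FIELDS
)


def load_config(path) -> tuple[ParameterSet, Lattice, str]:
    """Load and validate a configuration file.

    Returns ``(params, lattice, variant)``.  Every offending key is listed
    in the raised error.
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError("configuration must be a mapping")
    errors = []
    unknown_top = set(doc) - {"variant", "lattice", "fixed", "free", "flags"}
    errors += [f"unknown top-level key: {k}" for k in sorted(unknown_top)]
    variant = doc.get("variant", "ITWT")
    if variant not in VARIANTS:
        errors.append(f"unknown variant: {variant}")
    kwargs = {}
    for block, allowed in (("fixed", _FIXED_FIELDS), ("free", FREE_PARAM_NAMES),
                           ("flags", _FLAG_FIELDS)):
        entries = doc.get(block, {}) or {}
        for k, v in entries.items():
            if k not in allowed:
                errors.append(f"unknown {block} key: {k}")
            else:
                kwargs[k] = v
    lat_spec = doc.get("lattice", {"rows": 5, "cols": 5}) or {}
    lattice = None
    if set(lat_spec) == {"rows", "cols"}:
        lattice = build_lattice(int(lat_spec["rows"]), int(lat_spec["cols"]))
    elif set(lat_spec) == {"cells"}:
        lattice = lattice_for_size(int(lat_spec["cells"]))
    else:
        errors.append("lattice block must give {rows, cols} or {cells}")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    try:
        params = ParameterSet(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
    return params, lattice, variant


def dump_config(params: ParameterSet, lattice: Lattice, variant: str,
                path=None) -> str:
    """Serialize a configuration; round-trips through :func:`load_config`."""
    doc = {
        "variant": variant,
        "lattice": {"rows": lattice.rows, "cols": lattice.cols},
        "fixed": {k: getattr(params, k) for k in _FIXED_FIELDS},
        "free": {k: getattr(params, k) for k in FREE_PARAM_NAMES},
        "flags": {k: getattr(params, k) for k in _FLAG_FIELDS},
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass
class RunManifest:
    """Reproducibility record written next to every output artifact."""

    command: str
    config: dict
    seed: int
    outputs: list
    version: str = __version__
    timestamp: str = ""

    def write(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["timestamp"] = doc["timestamp"] or time.strftime(
            "%Y-%m-%dT%H:%M:%S", time.gmtime())
        Path(path).write_text(json.dumps(doc, indent=2, default=str))


def save_ensemble(path, ensemble: Sequence[GridSeries],
                  params: ParameterSet, lattice: Lattice, variant: str,
                  base_seed: Optional[int] = None) -> None:
    """Persist an ensemble of grid series to HDF5.

    Layout: ``/grid`` is a (R, T, L, NSTATE) int32 dataset, ``/times`` the
    grid in seconds; the configuration snapshot lives in the ``/params``
    group as a YAML string attribute.
    """
    data = np.stack([s.data for s in ensemble])
    with h5py.File(path, "w") as f:
        f.create_dataset("grid", data=data, compression="gzip")
        f.create_dataset("times", data=ensemble[0].times)
        g = f.create_group("params")
        g.attrs["config_yaml"] = dump_config(params, lattice, variant)
        f.attrs["dt"] = ensemble[0].dt
        f.attrs["variant"] = variant
        f.attrs["version"] = __version__
        if base_seed is not None:
            f.attrs["base_seed"] = base_seed


def load_ensemble(path) -> tuple[list[GridSeries], ParameterSet, Lattice, str]:
    import io as _io
    import tempfile

    with h5py.File(path, "r") as f:
        data = f["grid"][...]
        times = f["times"][...]
        dt = float(f.attrs["dt"])
        variant = str(f.attrs["variant"])
        cfg_text = f["params"].attrs["config_yaml"]
    with tempfile.NamedTemporaryFile("w", suffix=".yaml", delete=False) as tmp:
        tmp.write(cfg_text)
        cfg_path = tmp.name
    params, lattice, _ = load_config(cfg_path)
    Path(cfg_path).unlink(missing_ok=True)
    ensemble = [GridSeries(dt, times, data[r], variant) for r in range(data.shape[0])]
    return ensemble, params, lattice, variant


def fate_table(ensemble: Sequence[GridSeries]) -> pd.DataFrame:
    """Tidy lineage-count table: (replicate, time_h, fate, count)."""
    rows = []
    for r, series in enumerate(ensemble):
        counts = fate_counts(series)
        for t_idx, t_h in enumerate(series.times_h):
            for f, name in enumerate(FATES):
                rows.append({"replicate": r, "time_h": float(t_h),
                             "fate": name, "count": int(counts[t_idx, f])})
    return pd.DataFrame(rows)
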