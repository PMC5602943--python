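"""Readers and writers for run artifacts.

Everything a run produces is plain text: the population time series and the
division/death event counts as CSV, field and agent-position snapshots as
CSV matrices (one file per field per snapshot step), and the classification
with its metrics as JSON.  An optional HDF5 container mirrors the snapshot
data for large runs.  Readers invert writers exactly for integer counts.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import SimulationResult
from .phenotype import ClassificationResult, PopulationTimeSeries

__all__ = [
    "write_timeseries", "read_timeseries",
    "write_events", "read_events",
    "write_snapshots", "write_result_json", "write_hdf5",
]

_TS_HEADER = ["step", "species", "count", "mean_generation"]


def write_timeseries(ts: PopulationTimeSeries, path: str | Path) -> None:
    """CSV with columns step, species, count, mean_generation."""
    ts.to_frame().to_csv(path, index=False, columns=_TS_HEADER)


def read_timeseries(path: str | Path) -> PopulationTimeSeries:
    """Read a time-series CSV; malformed rows are reported with their
    line number."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if header != _TS_HEADER:
            raise ValueError(f"{path}: line 1: expected header "
                             f"{','.join(_TS_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 fields, "
                                 f"got {len(row)}")
            try:
                rows.append((int(row[0]), row[1], int(row[2]),
                             float(row[3]) if row[3] != "" else np.nan))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: malformed row {row!r}") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    frame = pd.DataFrame(rows, columns=_TS_HEADER)
    return PopulationTimeSeries.from_frame(frame)


def write_events(result: SimulationResult, path: str | Path) -> None:
    """Divisions and deaths per species per recording interval."""
    ts = result.timeseries
    rows = []
    for si, name in enumerate(ts.species):
        div = np.diff(result.divisions[si], prepend=0)
        dea = np.diff(result.deaths[si], prepend=0)
        for step, d, x in zip(ts.steps, div, dea):
            rows.append((int(step), name, int(d), int(x)))
    pd.DataFrame(rows, columns=["step", "species", "divisions", "deaths"]
                 ).to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_snapshots(result: SimulationResult, outdir: str | Path) -> list[Path]:
    """One CSV matrix per field per snapshot step, plus agent positions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for step, snap in sorted(result.snapshots.items()):
        for name, values in snap.items():
            if name == "cells":
                path = outdir / f"snapshot_{step:06d}_cells.csv"
                pd.DataFrame({
                    "x": values["x"], "y": values["y"],
                    "species": [result.species_names[s]
                                for s in values["species"]],
                    "state": values["state"],
                }).to_csv(path, index=False)
            else:
                safe = name.replace(":", "_")
                path = outdir / f"snapshot_{step:06d}_{safe}.csv"
                np.savetxt(path, values, delimiter=",", fmt="%.10g")
            written.append(path)
    return written


def write_result_json(classification: ClassificationResult,
                      ts: PopulationTimeSeries, path: str | Path) -> None:
    """Label plus summary metrics, including the cutoffs used."""
    doc = classification.to_dict()
    doc["species"] = list(ts.species)
    doc["final_counts"] = {name: int(c)
                           for name, c in zip(ts.species, ts.counts[:, -1])}
    doc["generations_elapsed"] = float(ts.pooled_generation()[-1])
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def write_hdf5(result: SimulationResult, path: str | Path) -> None:
    """Snapshot fields as datasets ``/fields/<name>/<step>`` (optional)."""
    import h5py

    with h5py.File(path, "w") as h5:
        for step, snap in sorted(result.snapshots.items()):
            for name, values in snap.items():
                if name == "cells":
                    grp = h5.require_group(f"cells/{step}")
                    for key, arr in values.items():
                        grp.create_dataset(key, data=arr)
                else:
                    h5.create_dataset(f"fields/{name}/{step}", data=values)
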