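"""File formats: activity series, tables, and array containers.

Activity series are stored as delimited text with one column per region
(header row = region names) and one row per time sample, plus a mandatory
JSON sidecar ``<path>.json`` carrying dt/state/subject/session and the
region names. Floats are written with 17 significant digits so round
trips are bit-exact. Array stacks persist to NumPy ``.npz`` with an
embedded JSON header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .bands import BandDefinition
from .containers import BandPowerMatrix, BRALISeries, PeriodogramStack

FLOAT_FMT = "%.17g"


def write_brali(series: BRALISeries, path: str | Path,
                atlas: RegionAtlas | None = None) -> None:
    path = Path(path)
    if atlas is not None:
        if len(atlas) != series.n_regions:
            raise ValueError("atlas size does not match the series")
        names = atlas.names
    else:
        names = [f"r{i:03d}" for i in range(series.n_regions)]
    header = "\t".join(names)
    np.savetxt(path, series.values.T, fmt=FLOAT_FMT, delimiter="\t",
               header=header, comments="")
    meta = {
        "dt": series.dt,
        "state": series.state,
        "subject": series.subject,
        "session": series.session,
        "region_names": names,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2,
                                                    sort_keys=True))


def read_brali(path: str | Path,
               atlas: RegionAtlas | None = None) -> BRALISeries:
    path = Path(path)
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata {sidecar}")
    meta = json.loads(sidecar.read_text())
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
    if header != meta["region_names"]:
        raise ValueError("header region names do not match sidecar metadata")
    if atlas is not None:
        unknown = [h for h in header if h not in set(atlas.names)]
        if unknown or len(header) != len(atlas):
            raise ValueError(
                f"region-name mismatch against the atlas "
                f"(unknown: {unknown[:5]}, file has {len(header)} regions, "
                f"atlas has {len(atlas)})")
    values = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2).T
    if not np.all(np.isfinite(values)):
        raise ValueError("activity payload contains NaN or infinite values")
    return BRALISeries(values=values, dt=float(meta["dt"]),
                       state=meta["state"], subject=meta["subject"],
                       session=meta["session"])


def write_table(df: pd.DataFrame, path: str | Path,
                index: bool = False) -> None:
    """Deterministic delimited-text writer (fixed float format)."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def save_stack(stack: PeriodogramStack, path: str | Path,
               seed: int | None = None) -> None:
    header = {"window_length": stack.window_length, "dt": stack.dt,
              "state": stack.state, "seed": seed}
    np.savez(path, values=stack.values, freqs=stack.freqs,
             header=np.array(json.dumps(header, sort_keys=True)))


def load_stack(path: str | Path) -> PeriodogramStack:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        return PeriodogramStack(values=z["values"], freqs=z["freqs"],
                                window_length=int(header["window_length"]),
                                dt=float(header["dt"]),
                                state=header["state"])


def save_band_power(matrix: BandPowerMatrix, path: str | Path,
                    seed: int | None = None) -> None:
    b = matrix.band
    header = {"band": {"name": b.name, "nu_min": b.nu_min,
                       "nu_max": b.nu_max, "nu_peak": b.nu_peak},
              "normalized": matrix.normalized, "state": matrix.state,
              "seed": seed}
    np.savez(path, values=matrix.values,
             header=np.array(json.dumps(header, sort_keys=True)))


def load_band_power(path: str | Path) -> BandPowerMatrix:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        b = header["band"]
        return BandPowerMatrix(
            values=z["values"],
            band=BandDefinition(b["name"], b["nu_min"], b["nu_max"],
                                b["nu_peak"]),
            normalized=bool(header["normalized"]), state=header["state"])
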