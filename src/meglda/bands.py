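"""Frequency-band definitions for the spectral analysis.

Two band tables are shipped: the reference table (θ 3–7.5, α 7.5–12,
β 12–20, γ 25–40 Hz, with the θ/α/β peak positions) and a second table
with every edge scaled down by the subject-specific peak-alignment factor
(≈0.85) that compensates for a systematic downward offset of the θ-, α-
and β-peak frequencies between individuals. Oscillatory bands are treated
as closed intervals [ν_min, ν_max]; the DC "band" is the single zero-
frequency component.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

BAND_NAMES = ("theta", "alpha", "beta", "gamma", "DC")


@dataclass(frozen=True)
class BandDefinition:
    """One frequency band.

    ``nu_min``/``nu_max`` are the closed-interval edges in Hz; ``nu_peak``
    is the nominal peak frequency (absent for γ and DC). The DC band has no
    edges and denotes the zero-frequency periodogram value.
    """

    name: str
    nu_min: float | None = None
    nu_max: float | None = None
    nu_peak: float | None = None

    def __post_init__(self):
        if self.name not in BAND_NAMES:
            raise ValueError(f"unknown band name {self.name!r}")
        if self.is_dc:
            if self.nu_min is not None or self.nu_max is not None:
                raise ValueError("DC band has no edges")
        else:
            if self.nu_min is None or self.nu_max is None:
                raise ValueError(f"band {self.name!r} needs both edges")
            if not (0 < self.nu_min < self.nu_max):
                raise ValueError("band edges must satisfy 0 < nu_min < nu_max")

    @property
    def is_dc(self) -> bool:
        return self.name == "DC"

    @property
    def midpoint(self) -> float:
        if self.is_dc:
            return 0.0
        return 0.5 * (self.nu_min + self.nu_max)

    def scaled(self, factor: float) -> "BandDefinition":
        """Band with both edges (and the peak, if any) multiplied by factor."""
        if self.is_dc:
            return self
        peak = None if self.nu_peak is None else self.nu_peak * factor
        return replace(self, nu_min=self.nu_min * factor,
                       nu_max=self.nu_max * factor, nu_peak=peak)


DC_BAND = BandDefinition("DC")

#: Reference band table (subject 1 of the study conditions).
SUBJECT1_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 3.0, 7.5, 4.4),
    BandDefinition("alpha", 7.5, 12.0, 8.9),
    BandDefinition("beta", 12.0, 20.0, 13.5),
    BandDefinition("gamma", 25.0, 40.0, None),
)

#: Band table with every edge shifted down by the peak-alignment factor.
SUBJECT2_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 2.6, 6.4, 3.7),
    BandDefinition("alpha", 6.4, 10.2, 7.7),
    BandDefinition("beta", 10.2, 17.0, 11.2),
    BandDefinition("gamma", 21.3, 34.4, None),
)


def band_edge_ratio(bands_ref=SUBJECT1_BANDS, bands_other=SUBJECT2_BANDS) -> float:
    """Median ratio of corresponding distinct band edges (other / ref).

    Adjacent bands share edges; each distinct edge value is counted once.
    """
    ref, other = [], []
    seen = set()
    for br, bo in zip(bands_ref, bands_other):
        for er, eo in ((br.nu_min, bo.nu_min), (br.nu_max, bo.nu_max)):
            if er is None or er in seen:
                continue
            seen.add(er)
            ref.append(er)
            other.append(eo)
    return float(np.median(np.asarray(other) / np.asarray(ref)))


def bands_to_frame(bands) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "band": [b.name for b in bands],
            "nu_min": [b.nu_min for b in bands],
            "nu_max": [b.nu_max for b in bands],
            "nu_peak": [b.nu_peak for b in bands],
        }
    )


def save_bands(bands, path: str | Path) -> None:
    bands_to_frame(bands).to_csv(path, sep="\t", index=False)


def load_bands(path: str | Path) -> tuple[BandDefinition, ...]:
    df = pd.read_csv(path, sep="\t")

    def opt(x):
        return None if pd.isna(x) else float(x)

    return tuple(
        BandDefinition(str(n), opt(lo), opt(hi), opt(pk))
        for n, lo, hi, pk in zip(df["band"], df["nu_min"], df["nu_max"],
                                 df["nu_peak"])
    )
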