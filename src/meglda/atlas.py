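"""Brain-region atlas: parcel names, hemispheres and tissue classes.

The atlas fixes the row order of every matrix in the pipeline: region
``region_id`` is row ``region_id`` of the activity matrices, band-power
matrices and LDA separating vectors. The default construction mirrors a
combined cortical parcellation (74 regions per hemisphere) with 8 internal
(subcortical) structures per hemisphere plus the brainstem, for a total of
165 regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

HEMISPHERES = ("left", "right", "midline")
REGION_CLASSES = ("cortical", "internal", "brainstem")


@dataclass(frozen=True)
class Region:
    region_id: int
    name: str
    hemisphere: str
    region_class: str


class RegionAtlas:
    """Ordered collection of brain regions.

    Parameters
    ----------
    regions
        Regions with consecutive unique ids starting at 0.
    """

    def __init__(self, regions: Iterable[Region]):
        regions = list(regions)
        ids = [r.region_id for r in regions]
        if ids != list(range(len(regions))):
            raise ValueError("region ids must be consecutive starting at 0")
        names = [r.name for r in regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        for r in regions:
            if r.hemisphere not in HEMISPHERES:
                raise ValueError(f"unknown hemisphere {r.hemisphere!r}")
            if r.region_class not in REGION_CLASSES:
                raise ValueError(f"unknown region class {r.region_class!r}")
        self._regions = tuple(regions)

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self):
        return iter(self._regions)

    def __getitem__(self, region_id: int) -> Region:
        return self._regions[region_id]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self._regions]

    def ids_where(self, *, hemisphere: str | None = None,
                  region_class: str | Iterable[str] | None = None) -> list[int]:
        """Region ids matching the given hemisphere and/or class filters."""
        if isinstance(region_class, str):
            region_class = (region_class,)
        out = []
        for r in self._regions:
            if hemisphere is not None and r.hemisphere != hemisphere:
                continue
            if region_class is not None and r.region_class not in region_class:
                continue
            out.append(r.region_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [r.region_id for r in self._regions],
                "name": [r.name for r in self._regions],
                "hemisphere": [r.hemisphere for r in self._regions],
                "region_class": [r.region_class for r in self._regions],
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "RegionAtlas":
        df = pd.read_csv(path, sep="\t")
        return cls(
            Region(int(i), str(n), str(h), str(c))
            for i, n, h, c in zip(df["region_id"], df["name"],
                                  df["hemisphere"], df["region_class"])
        )


def make_atlas(n_cortical_per_hemi: int = 74, n_internal_per_hemi: int = 8,
               include_brainstem: bool = True) -> RegionAtlas:
    """Build a deterministic atlas.

    Row order is cortical-left, cortical-right, internal-left,
    internal-right, brainstem. With the defaults (74, 8, True) this yields
    the 165-region parcellation used throughout.
    """
    if n_cortical_per_hemi < 0 or n_internal_per_hemi < 0:
        raise ValueError("region counts must be non-negative")
    regions: list[Region] = []

    def add(name: str, hemi: str, cls: str) -> None:
        regions.append(Region(len(regions), name, hemi, cls))

    for hemi, tag in (("left", "lh"), ("right", "rh")):
        for i in range(n_cortical_per_hemi):
            add(f"ctx-{tag}-{i + 1:03d}", hemi, "cortical")
    for hemi, tag in (("left", "lh"), ("right", "rh")):
        for i in range(n_internal_per_hemi):
            add(f"sub-{tag}-{i + 1:02d}", hemi, "internal")
    if include_brainstem:
        add("brainstem", "midline", "brainstem")
    return RegionAtlas(regions)
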