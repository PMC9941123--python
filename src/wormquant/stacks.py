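"""Channel-paired z-stack containers and TIFF I/O.

One animal is imaged as four body-region z-stacks (head to tail), each
acquired in a green (reporter) and a red (autofluorescence) channel.  Arrays
use the 0-based ``(slice, row, col)`` convention; centroids are reported in
pixel units as floats.  Regions are treated as spatially disjoint body
segments — no stitching or overlap handling is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

N_REGIONS = 4


class StackFormatError(ValueError):
    """Raised when channel stacks violate the paired-acquisition contract."""


@dataclass
class StackPair:
    """Green + red 3-D intensity stacks for one body region of one animal."""

    green: np.ndarray
    red: np.ndarray
    pixel_size_um: float = 0.4
    slice_spacing_um: float = 3.0
    animal_id: str = "worm-0"
    region_index: int = 0
    day: int | None = None
    regime_id: str | None = None

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if self.green.ndim != 3 or self.red.ndim != 3:
            raise StackFormatError("channel stacks must be 3-D (slice, row, col)")
        if self.green.shape != self.red.shape:
            raise StackFormatError(
                f"green shape {self.green.shape} != red shape {self.red.shape}"
            )
        if not (0 <= self.region_index < N_REGIONS):
            raise ValueError(f"region_index must be in 0..{N_REGIONS - 1}")
        if self.pixel_size_um <= 0 or self.slice_spacing_um <= 0:
            raise ValueError("pixel geometry must be positive")
        if np.min(self.green) < 0 or np.min(self.red) < 0:
            raise StackFormatError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.green.shape


@dataclass
class WormImageSet:
    """The four region stacks belonging to one animal on one day."""

    animal_id: str
    day: int | None
    regime_id: str | None
    regions: tuple[StackPair, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        indices = sorted(p.region_index for p in self.regions)
        if indices != list(range(N_REGIONS)):
            missing = sorted(set(range(N_REGIONS)) - set(indices))
            dupes = sorted({i for i in indices if indices.count(i) > 1})
            parts = []
            if missing:
                parts.append(f"missing region(s) {missing}")
            if dupes:
                parts.append(f"duplicated region(s) {dupes}")
            if len(self.regions) != N_REGIONS:
                parts.append(f"got {len(self.regions)} regions, expected {N_REGIONS}")
            raise ValueError("invalid worm image set: " + "; ".join(parts))
        shapes = {p.shape for p in self.regions}
        if len(shapes) != 1:
            raise StackFormatError(f"regions differ in geometry: {sorted(shapes)}")
        if any(p.animal_id != self.animal_id for p in self.regions):
            raise ValueError("all regions must share animal_id")
        if any(p.day != self.day for p in self.regions):
            raise ValueError("all regions must share day")
        self.regions = tuple(sorted(self.regions, key=lambda p: p.region_index))


def write_stack_pair(pair: StackPair, green_path: str | Path, red_path: str | Path) -> None:
    """Write both channels as 16-bit multi-page TIFFs (one file per channel)."""
    for arr, path in ((pair.green, green_path), (pair.red, red_path)):
        data = np.asarray(arr)
        if data.dtype != np.uint16:
            data = np.clip(np.rint(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(Path(path), data)


def read_stack_pair(
    green_path: str | Path,
    red_path: str | Path,
    metadata: dict | None = None,
) -> StackPair:
    """Load a channel pair from two multi-page TIFFs, slice order = page order."""
    metadata = dict(metadata or {})
    try:
        green = tifffile.imread(Path(green_path))
        red = tifffile.imread(Path(red_path))
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise StackFormatError(f"cannot read TIFF stack: {exc}") from exc
    green = np.atleast_3d(green) if green.ndim < 3 else green
    red = np.atleast_3d(red) if red.ndim < 3 else red
    if green.shape != red.shape:
        raise StackFormatError(
            f"channel page mismatch: green {green.shape} vs red {red.shape} "
            f"({green_path} / {red_path})"
        )
    return StackPair(green=green, red=red, **metadata)


def assemble_worm(manifest: dict | str | Path, base_dir: str | Path | None = None) -> WormImageSet:
    """Assemble a :class:`WormImageSet` from a manifest.

    The manifest is either a dict or a path to a JSON file with the schema
    ``{animal_id, day, regime_id, pixel_size_um?, slice_spacing_um?,
    regions: [{index, green, red}]}``.
    """
    if not isinstance(manifest, dict):
        manifest_path = Path(manifest)
        base_dir = base_dir or manifest_path.parent
        manifest = json.loads(manifest_path.read_text())
    base = Path(base_dir) if base_dir is not None else Path(".")
    regions_spec: Sequence[dict] = manifest["regions"]
    if len(regions_spec) != N_REGIONS:
        indices = [r.get("index") for r in regions_spec]
        missing = sorted(set(range(N_REGIONS)) - set(indices))
        raise ValueError(
            f"manifest lists {len(regions_spec)} regions, expected {N_REGIONS}"
            + (f"; missing region(s) {missing}" if missing else "")
        )
    meta_common = {
        "animal_id": manifest["animal_id"],
        "day": manifest.get("day"),
        "regime_id": manifest.get("regime_id"),
    }
    for key in ("pixel_size_um", "slice_spacing_um"):
        if key in manifest:
            meta_common[key] = manifest[key]
    pairs = []
    for spec in regions_spec:
        meta = dict(meta_common, region_index=spec["index"])
        pairs.append(read_stack_pair(base / spec["green"], base / spec["red"], meta))
    return WormImageSet(
        animal_id=manifest["animal_id"],
        day=manifest.get("day"),
        regime_id=manifest.get("regime_id"),
        regions=tuple(pairs),
    )
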