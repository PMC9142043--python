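"""On-disk format for hyperspectral cubes and cohort manifests.

A cube is stored as a multi-page float32 TIFF (one page per spectral
channel, in axis order) plus a JSON sidecar ``<path>.json`` holding the
spectral axis, image metadata and the run-length-encoded saturation mask.
A cohort manifest is a CSV with header ``image_path,image_id,mouse_id,genotype``.

Writes are byte-stable: identical cubes produce identical files (no
timestamps or environment-dependent tags), so synthetic cohorts regenerate
bit-identically from a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .axis import SpectralAxis

__all__ = [
    "HyperCube",
    "CohortManifest",
    "ManifestRecord",
    "FormatError",
    "write_cube",
    "read_cube",
    "read_manifest",
    "write_manifest",
]

GENOTYPES = ("WT", "KO")


class FormatError(ValueError):
    """Raised when on-disk files are missing, inconsistent or invalid."""


@dataclass
class HyperCube:
    """One hyperspectral image: ``values[row, col, channel]`` plus metadata.

    ``sat_mask`` flags pixels excluded as oversaturated (True = excluded).
    ``meta`` carries image_id, mouse_id, genotype and the detector ceiling
    ``sat_value``.
    """

    values: np.ndarray
    axis: SpectralAxis
    sat_mask: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        # float64 stays float64 in memory; files are always float32
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.floating):
            self.values = self.values.astype(np.float32)
        if self.sat_mask is None:
            self.sat_mask = np.zeros(self.values.shape[:2], dtype=bool)
        else:
            self.sat_mask = np.asarray(self.sat_mask, dtype=bool)

    @property
    def shape(self):
        return self.values.shape

    def validate(self) -> None:
        if self.values.ndim != 3:
            raise FormatError(f"values must be 3-D, got shape {self.values.shape}")
        if self.values.shape[2] != self.axis.n_channels:
            raise FormatError(
                f"channel count {self.values.shape[2]} != axis length "
                f"{self.axis.n_channels}"
            )
        if self.sat_mask.shape != self.values.shape[:2]:
            raise FormatError("sat_mask shape does not match spatial shape")
        if np.any(self.values < 0):
            raise FormatError("negative intensities violate cube invariants")
        sat_value = self.meta.get("sat_value")
        if sat_value is not None and np.any(self.values > float(sat_value)):
            raise FormatError("intensities exceed sat_value")


@dataclass(frozen=True)
class ManifestRecord:
    image_path: str
    image_id: str
    mouse_id: str
    genotype: str


@dataclass
class CohortManifest:
    """Mapping of images to mice and genotypes (WT / KO)."""

    records: list[ManifestRecord]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.records:
            raise FormatError("manifest is empty")
        seen_ids: set[str] = set()
        mouse_geno: dict[str, str] = {}
        for i, r in enumerate(self.records):
            if r.genotype not in GENOTYPES:
                raise FormatError(
                    f"row {i} (image_id={r.image_id}): genotype {r.genotype!r} "
                    f"not in {GENOTYPES}"
                )
            if r.image_id in seen_ids:
                raise FormatError(f"row {i}: duplicate image_id {r.image_id!r}")
            seen_ids.add(r.image_id)
            prev = mouse_geno.setdefault(r.mouse_id, r.genotype)
            if prev != r.genotype:
                raise FormatError(
                    f"row {i}: mouse {r.mouse_id!r} listed as both {prev} and "
                    f"{r.genotype}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def mice(self) -> dict[str, str]:
        """mouse_id -> genotype."""
        return {r.mouse_id: r.genotype for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.image_path, r.image_id, r.mouse_id, r.genotype) for r in self.records],
            columns=["image_path", "image_id", "mouse_id", "genotype"],
        )


def _rle_encode(mask: np.ndarray) -> list[int]:
    # run lengths of the row-major flattened mask, alternating and starting
    # with a False run (possibly of length 0)
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return []
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    bounds = np.concatenate(([0], changes + 1, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def _rle_decode(runs: Sequence[int], shape: tuple[int, int]) -> np.ndarray:
    total = int(np.prod(shape))
    flat = np.zeros(total, dtype=bool)
    pos = 0
    value = False
    for run in runs:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    if pos != total:
        raise FormatError(f"sat_mask run lengths sum to {pos}, expected {total}")
    return flat.reshape(shape)


def write_cube(cube: HyperCube, path: str | Path) -> None:
    """Write a cube as multi-page float32 TIFF + JSON sidecar ``<path>.json``."""
    cube.validate()
    path = Path(path)
    pages = np.moveaxis(cube.values, 2, 0).astype(np.float32)  # (C, rows, cols)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "format_version": 1,
        "axis": cube.axis.to_dict(),
        "meta": cube.meta,
        "shape": [int(s) for s in cube.values.shape],
        "sat_mask_rle": _rle_encode(cube.sat_mask),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, sort_keys=True)
        fh.write("\n")


def read_cube(path: str | Path) -> HyperCube:
    """Read a cube written by :func:`write_cube`; validates all invariants."""
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    axis = SpectralAxis.from_dict(sidecar["axis"])
    pages = tifffile.imread(path)
    if pages.ndim == 2:  # single-channel cube
        pages = pages[None, :, :]
    if pages.shape[0] != axis.n_channels:
        raise FormatError(
            f"TIFF has {pages.shape[0]} pages but sidecar declares "
            f"{axis.n_channels} channels"
        )
    values = np.moveaxis(pages, 0, 2)
    mask = _rle_decode(sidecar["sat_mask_rle"], values.shape[:2])
    cube = HyperCube(values=values, axis=axis, sat_mask=mask, meta=sidecar["meta"])
    cube.validate()
    return cube


MANIFEST_COLUMNS = ["image_path", "image_id", "mouse_id", "genotype"]


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, index=False)


def read_manifest(path: str | Path) -> CohortManifest:
    """Parse and validate a cohort manifest CSV."""
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"manifest {path} is empty") from None
    if list(df.columns) != MANIFEST_COLUMNS:
        raise FormatError(
            f"manifest header must be {','.join(MANIFEST_COLUMNS)}, "
            f"got {','.join(df.columns)}"
        )
    if len(df) == 0:
        raise FormatError(f"manifest {path} has no records")
    records = [
        ManifestRecord(
            image_path=str(r.image_path),
            image_id=str(r.image_id),
            mouse_id=str(r.mouse_id),
            genotype=str(r.genotype),
        )
        for r in df.itertuples()
    ]
    return CohortManifest(records=records)
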