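"""On-disk scan layout: per-position multi-page TIFFs plus a manifest.

A scan directory contains one grayscale multi-page TIFF per light-sheet
position, named ``pos_0000.tif``, ``pos_0001.tif``, ..., a ``manifest.txt``
of plain ``key = value`` calibration lines, and (for simulated scans) a
``truth.csv`` ground-truth table.  GD maps and volumes are written as
32-bit float TIFFs before any 8-bit conversion so no precision is lost to
display scaling.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import tifffile

from .biospeckle import FrameStack
from .detect import DetectionResult, GDVolume
from .errors import ScanFormatError
from .simulate import AcquisitionConfig, VolumeScan

__all__ = [
    "MANIFEST_NAME",
    "TRUTH_NAME",
    "write_scan",
    "read_scan",
    "write_manifest",
    "read_manifest",
    "write_gd_tiff",
    "write_detections_csv",
    "write_report",
]

log = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.txt"
TRUTH_NAME = "truth.csv"


def write_manifest(path: Path, values: Dict[str, object]) -> None:
    lines = [f"{k} = {v}" for k, v in values.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: Path) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ScanFormatError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def write_scan(scan: VolumeScan, directory: str | Path) -> Path:
    """Write a scan to ``directory`` in the documented layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for stack in scan.stacks:
        tifffile.imwrite(
            directory / f"pos_{stack.position_index:04d}.tif",
            stack.frames,
            photometric="minisblack",
        )
    acq = scan.acquisition
    manifest = {
        "pixel_size_um": scan.pixel_size_um,
        "z_step_um": acq.z_increment_um,
        "frame_rate_hz": acq.frame_rate_hz,
        "frames_per_position": acq.frames_per_position,
        "n_positions": scan.n_positions,
        "sheet_thickness_um": acq.sheet_thickness_um,
        "settle_pause_s": acq.settle_pause_s,
        "exposure_scale": acq.exposure_scale,
        "bit_depth": acq.bit_depth,
        "read_noise_sd": acq.read_noise_sd,
        "seed": scan.truth.seed if scan.truth is not None else "",
    }
    write_manifest(directory / MANIFEST_NAME, manifest)
    if scan.truth is not None and scan.truth.nematodes:
        rows = []
        for i, nem in enumerate(scan.truth.nematodes):
            x, y, z = nem.centroid_um
            rows.append(
                {
                    "id": i,
                    "x_um": x,
                    "y_um": y,
                    "z_um": z,
                    "length_um": nem.length_um,
                    "width_um": nem.width_um,
                    "alive": int(nem.alive),
                    "decorrelation": nem.decorrelation,
                }
            )
        pd.DataFrame(rows).to_csv(directory / TRUTH_NAME, index=False)
    log.info("wrote scan with %d positions to %s", scan.n_positions, directory)
    return directory


def read_scan(
    directory: str | Path,
    *,
    pixel_size_um: Optional[float] = None,
    z_step_um: Optional[float] = None,
) -> VolumeScan:
    """Load a scan directory back into memory.

    Keyword overrides take precedence over manifest calibration (the
    override is logged).  Raises :class:`ScanFormatError` on a missing
    manifest, unreadable TIFFs, or stacks with inconsistent frame counts,
    shapes or bit depths, naming the offending file.
    """
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise ScanFormatError(f"missing manifest: {manifest_path}")
    manifest = read_manifest(manifest_path)

    pix = float(manifest.get("pixel_size_um", 16.0))
    z_step = float(manifest.get("z_step_um", 125.0))
    if pixel_size_um is not None:
        log.info("pixel size override: manifest %.4g um -> %.4g um", pix, pixel_size_um)
        pix = pixel_size_um
    if z_step_um is not None:
        log.info("z step override: manifest %.4g um -> %.4g um", z_step, z_step_um)
        z_step = z_step_um

    files = sorted(directory.glob("pos_*.tif"))
    if not files:
        raise ScanFormatError(f"no pos_*.tif stacks found in {directory}")
    stacks = []
    ref_shape = None
    ref_dtype = None
    for k, path in enumerate(files):
        try:
            frames = tifffile.imread(path)
        except Exception as exc:
            raise ScanFormatError(f"could not read {path.name}: {exc}") from exc
        if frames.ndim == 2:
            frames = frames[None]
        if ref_shape is None:
            ref_shape, ref_dtype = frames.shape, frames.dtype
        elif frames.shape != ref_shape:
            raise ScanFormatError(
                f"{path.name}: frame stack shape {frames.shape} differs from {ref_shape}"
            )
        elif frames.dtype != ref_dtype:
            raise ScanFormatError(
                f"{path.name}: bit depth {frames.dtype} differs from {ref_dtype}"
            )
        stacks.append(FrameStack(frames=frames, position_index=k, z_position_um=k * z_step))

    acq = AcquisitionConfig(
        frames_per_position=int(manifest.get("frames_per_position", ref_shape[0])),
        frame_rate_hz=float(manifest.get("frame_rate_hz", 10.0)),
        n_positions=len(stacks),
        z_increment_um=z_step,
        sheet_thickness_um=float(manifest.get("sheet_thickness_um", 1000.0)),
        settle_pause_s=float(manifest.get("settle_pause_s", 0.4)),
        exposure_scale=float(manifest.get("exposure_scale", 30.0)),
        bit_depth=int(manifest.get("bit_depth", 8 if ref_dtype == np.uint8 else 16)),
        read_noise_sd=float(manifest.get("read_noise_sd", 1.0)),
    )
    return VolumeScan(stacks=stacks, acquisition=acq, pixel_size_um=pix, truth=None)


def write_gd_tiff(data: np.ndarray | GDVolume, path: str | Path) -> Path:
    """Write a GD map or volume as 32-bit float TIFF."""
    arr = data.voxels if isinstance(data, GDVolume) else np.asarray(data)
    tifffile.imwrite(Path(path), arr.astype(np.float32), photometric="minisblack")
    return Path(path)


def write_detections_csv(result: DetectionResult, path: str | Path) -> Path:
    rows = [
        {
            "label": o.label,
            "x_um": o.centroid_um[0],
            "y_um": o.centroid_um[1],
            "z_um": o.centroid_um[2],
            "voxels": o.voxel_count,
            "peak_activity": o.peak_activity,
        }
        for o in result.objects
    ]
    df = pd.DataFrame(rows, columns=["label", "x_um", "y_um", "z_um", "voxels", "peak_activity"])
    df.to_csv(Path(path), index=False)
    return Path(path)


def write_report(values: Dict[str, object], path: str | Path) -> Path:
    """Plain-text key/value run report."""
    write_manifest(Path(path), values)
    return Path(path)
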