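"""Cine-sequence containers and file I/O.

A cine acquisition is a time-ordered stack of 2D frames at a fixed slice
position (~30 cardiac phases per cycle). Sequences travel as NIfTI volumes
(spatial axes first, time last, pixel spacing in the header zooms) with an
optional YAML sidecar carrying exam id and the cuff pressures recorded during
the exam. Masks use the same layout with integer 0/1 voxels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from PIL import Image

__all__ = [
    "CineSequence",
    "MaskSequence",
    "PressurePair",
    "load_sequence",
    "save_sequence",
    "load_mask_sequence",
    "save_mask_sequence",
    "save_frames_png",
]


@dataclass(frozen=True)
class PressurePair:
    """Systolic/diastolic cuff pressure in mmHg; systolic > diastolic > 0."""

    systolic: float
    diastolic: float

    def __post_init__(self) -> None:
        if not (self.systolic > self.diastolic > 0):
            raise ValueError(
                f"require systolic > diastolic > 0, got {self.systolic}/{self.diastolic} mmHg"
            )

    @property
    def pulse(self) -> float:
        """Pulse pressure (systolic minus diastolic), mmHg."""
        return self.systolic - self.diastolic


@dataclass
class CineSequence:
    """Time-ordered intensity frames with physical pixel spacing.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)``, any float/integer dtype, finite values.
    pixel_spacing
        ``(row, col)`` spacing in mm/px.
    frame_times
        Acquisition time of each frame in ms, length ``T``.
    exam_id
        Identifier tying frames, masks and pressures of one exam together.
    """

    frames: np.ndarray
    pixel_spacing: tuple[float, float]
    frame_times: np.ndarray | None = None
    exam_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError(f"frames must be (T,H,W) with T>=1, got {self.frames.shape}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite intensities")
        sr, sc = self.pixel_spacing
        if not (sr > 0 and sc > 0):
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing}")
        self.pixel_spacing = (float(sr), float(sc))
        if self.frame_times is None:
            self.frame_times = np.arange(self.frames.shape[0], dtype=float)
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.frames.shape[0],):
                raise ValueError("frame_times length must equal number of frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class MaskSequence:
    """Binary masks aligned frame-by-frame with a :class:`CineSequence`."""

    frames: np.ndarray
    pixel_spacing: tuple[float, float]
    exam_id: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(f"mask frames must be (T,H,W), got {frames.shape}")
        uniq = np.unique(frames)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {uniq[:5]}")
        self.frames = frames.astype(bool)
        sr, sc = self.pixel_spacing
        if not (sr > 0 and sc > 0):
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing}")
        self.pixel_spacing = (float(sr), float(sc))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".yaml")
    return path.with_suffix(".yaml")


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            return yaml.safe_load(fh) or {}
    return {}


def _natural_key(p: Path):
    return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", p.name)]


def _load_frame_dir(path: Path) -> np.ndarray:
    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}),
        key=_natural_key,
    )
    if not files:
        raise FileNotFoundError(f"no PNG/TIFF frames found in {path}")
    frames = []
    shape = None
    for f in files:
        arr = np.asarray(Image.open(f))
        if arr.ndim == 3:  # collapse RGB(A) exports
            arr = arr[..., 0]
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(
                f"inconsistent frame shapes: {f.name} is {arr.shape}, expected {shape}"
            )
        frames.append(arr)
    return np.stack(frames)


def load_sequence(path: str | Path) -> CineSequence:
    """Load a cine sequence from a NIfTI volume or a directory of 2D frames.

    The NIfTI volume is expected as ``(H, W, T)`` (spatial-first, the layout
    :func:`save_sequence` writes) and is returned time-first. Pixel spacing is
    taken from the NIfTI header zooms or, for frame directories, from a YAML
    sidecar with key ``pixel_spacing_mm``. A missing spacing is an error — it
    is never guessed.
    """
    path = Path(path)
    meta = _read_sidecar(path)
    if path.is_dir():
        frames = _load_frame_dir(path)
        if "pixel_spacing_mm" not in meta:
            sidecar = path / "sequence.yaml"
            if sidecar.exists():
                with open(sidecar) as fh:
                    meta = yaml.safe_load(fh) or {}
        if "pixel_spacing_mm" not in meta:
            raise ValueError(
                f"no pixel spacing for frame directory {path}: provide a YAML sidecar "
                "with key 'pixel_spacing_mm'"
            )
        spacing = meta["pixel_spacing_mm"]
        spacing = (float(spacing[0]), float(spacing[1])) if np.ndim(spacing) else (float(spacing),) * 2
    else:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 2:
            data = data[..., None]
        if data.ndim != 3:
            raise ValueError(f"expected a 3D cine volume, got shape {data.shape}")
        frames = np.moveaxis(data, -1, 0)
        zooms = img.header.get_zooms()
        spacing = (float(zooms[0]), float(zooms[1]))
        if spacing[0] <= 0 or spacing[1] <= 0:
            raise ValueError(f"non-positive pixel spacing in NIfTI header of {path}")
    frame_times = meta.get("frame_times_ms")
    if frame_times is not None:
        frame_times = np.asarray(frame_times, dtype=float)
    return CineSequence(
        frames=np.ascontiguousarray(frames),
        pixel_spacing=spacing,
        frame_times=frame_times,
        exam_id=str(meta.get("exam_id", path.stem.replace(".nii", ""))),
    )


def save_sequence(
    seq: CineSequence,
    path: str | Path,
    pressures: PressurePair | None = None,
) -> Path:
    """Write a sequence as NIfTI ``(H, W, T)`` plus a YAML sidecar.

    The sidecar records ``exam_id``, ``pixel_spacing_mm``, frame times and,
    when given, the exam pressures (``systolic_mmHg``/``diastolic_mmHg``).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.moveaxis(np.asarray(seq.frames, dtype=np.float32), 0, -1)
    sr, sc = seq.pixel_spacing
    affine = np.diag([sr, sc, 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sr, sc, 1.0))
    nib.save(img, str(path))
    meta = {
        "exam_id": seq.exam_id,
        "pixel_spacing_mm": [sr, sc],
        "frame_times_ms": [float(t) for t in seq.frame_times],
    }
    if pressures is not None:
        meta["systolic_mmHg"] = float(pressures.systolic)
        meta["diastolic_mmHg"] = float(pressures.diastolic)
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def load_pressures(path: str | Path) -> PressurePair:
    """Read the exam pressures from a sequence's YAML sidecar."""
    meta = _read_sidecar(Path(path))
    if "systolic_mmHg" not in meta or "diastolic_mmHg" not in meta:
        raise ValueError(f"no pressures recorded in sidecar of {path}")
    return PressurePair(float(meta["systolic_mmHg"]), float(meta["diastolic_mmHg"]))


def save_mask_sequence(masks: MaskSequence, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.moveaxis(masks.frames.astype(np.uint8), 0, -1)
    sr, sc = masks.pixel_spacing
    img = nib.Nifti1Image(data, np.diag([sr, sc, 1.0, 1.0]))
    img.header.set_zooms((sr, sc, 1.0))
    nib.save(img, str(path))
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(
            {"exam_id": masks.exam_id, "pixel_spacing_mm": [sr, sc]}, fh, sort_keys=False
        )
    return path


def load_mask_sequence(path: str | Path) -> MaskSequence:
    seq = load_sequence(path)
    return MaskSequence(
        frames=(seq.frames > 0.5).astype(np.uint8),
        pixel_spacing=seq.pixel_spacing,
        exam_id=seq.exam_id,
    )


def save_frames_png(frames: np.ndarray, directory: str | Path, prefix: str = "frame") -> list[Path]:
    """Export frames (or masks) as 8-bit per-frame PNGs ``prefix_000.png``..."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = np.asarray(frames)
    lo, hi = float(frames.min()), float(frames.max())
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    paths = []
    for i, frame in enumerate(frames):
        arr = ((frame - lo) * scale).astype(np.uint8)
        p = directory / f"{prefix}_{i:03d}.png"
        Image.fromarray(arr).save(p)
        paths.append(p)
    return paths
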