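"""Optional 4D-volume support: ROI-mean curve extraction from NIfTI data.

Multi-echo volumes follow the NIfTI-1 convention with echoes along the 4th
dimension; masks are byte volumes aligned to the spatial grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .curves import DecayCurve
from .schedule import AcquisitionSchedule

__all__ = ["RoiMask", "roi_mean_curve", "load_volume", "load_mask"]


@dataclass
class RoiMask:
    """Voxel indicator grid for one ROI, aligned to a volume's spatial dims."""

    data: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3-D volume")
        if not self.data.any():
            raise ValueError("mask is empty")


def roi_mean_curve(
    volume_4d: np.ndarray, mask: RoiMask, schedule: AcquisitionSchedule
) -> DecayCurve:
    """Mean in-mask magnitude signal per echo, ordered by the schedule."""
    vol = np.asarray(volume_4d, dtype=float)
    if vol.ndim != 4:
        raise ValueError("expected a 4-D multi-echo volume")
    if vol.shape[:3] != mask.data.shape:
        raise ValueError("mask shape does not match volume spatial dimensions")
    if vol.shape[3] != schedule.n_echoes:
        raise ValueError(
            f"volume has {vol.shape[3]} echoes but schedule has {schedule.n_echoes}"
        )
    signals = vol[mask.data, :].mean(axis=0)
    return DecayCurve(
        np.asarray(schedule.echo_times, dtype=float),
        signals,
        source_id=mask.label,
        run_labels=np.asarray(schedule.run_labels),
    )


def load_volume(path: str | Path) -> np.ndarray:
    """Load a 4D multi-echo NIfTI volume as a float array."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float)


def load_mask(path: str | Path, label: str = "") -> RoiMask:
    """Load a byte NIfTI ROI mask."""
    import nibabel as nib

    img = nib.load(str(path))
    return RoiMask(np.asarray(img.get_fdata()) > 0, label=label or Path(path).stem)
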