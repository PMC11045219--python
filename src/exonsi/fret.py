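"""Sensitized-emission FRET quantification from three-channel stacks.

A FRET acquisition yields a donor channel ID (donor excitation, donor
emission), an acceptor channel IA (acceptor excitation, acceptor
emission) and a transfer channel IF (donor excitation, acceptor
emission).  IF mixes true energy transfer with donor bleed-through
(fraction kD of ID) and acceptor cross-excitation (fraction kA of IA).
After calibrating kD on a donor-only control and kA on an acceptor-only
control, the per-pixel efficiency is

    F% = 100 * (IF - kD*ID - kA*IA) / IA

evaluated only where IA clears an intensity floor, since the formula
divides by IA and explodes at background pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import CalibrationError, DataError, ParameterError

#: fraction of the acceptor channel's peak intensity used as the default floor
DEFAULT_FLOOR_FRACTION = 0.05


@dataclass
class FretStack:
    """Registered ID/IA/IF channel images with optional correction factors."""

    donor: np.ndarray
    acceptor: np.ndarray
    transfer: np.ndarray
    kD: float | None = None
    kA: float | None = None

    def __post_init__(self) -> None:
        if not (self.donor.shape == self.acceptor.shape == self.transfer.shape):
            raise DataError("ID, IA and IF images must share one shape")
        if self.kD is not None and self.kD < 0:
            raise ParameterError("kD must be >= 0")
        if self.kA is not None and self.kA < 0:
            raise ParameterError("kA must be >= 0")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.donor.shape


@dataclass
class FretMap:
    """Per-pixel FRET efficiency in percent, defined where ``mask`` is true."""

    values: np.ndarray
    mask: np.ndarray


def _ratio_median(numerator: np.ndarray, denominator: np.ndarray,
                  mask: np.ndarray | None, what: str) -> float:
    valid = denominator > 0
    if mask is not None:
        valid &= mask.astype(bool)
    if not valid.any():
        raise CalibrationError(f"no valid pixels to calibrate {what}")
    return float(np.median(numerator[valid] / denominator[valid]))


def calibrate_kD(donor_only: FretStack, mask: np.ndarray | None = None) -> float:
    """Donor bleed-through: median IF/ID over a donor-only control.

    The median is robust to hot pixels and to the occasional zero-signal
    pixel escaping the mask.
    """
    return _ratio_median(donor_only.transfer, donor_only.donor, mask, "kD")


def calibrate_kA(acceptor_only: FretStack, mask: np.ndarray | None = None) -> float:
    """Acceptor cross-excitation: median IF/IA over an acceptor-only control."""
    return _ratio_median(acceptor_only.transfer, acceptor_only.acceptor, mask, "kA")


def fret_map(stack: FretStack, intensity_floor: float | None = None) -> FretMap:
    """Per-pixel FRET efficiency map.

    F% = 100 * (IF - kD*ID - kA*IA) / IA on pixels where IA exceeds
    ``intensity_floor`` (default: 5 percent of the IA maximum); all other
    pixels are masked out and carry NaN.
    """
    if stack.kD is None or stack.kA is None:
        raise ParameterError("stack must carry calibrated kD and kA")
    if intensity_floor is None:
        intensity_floor = DEFAULT_FLOOR_FRACTION * float(stack.acceptor.max())
    mask = stack.acceptor > intensity_floor
    values = np.full(stack.shape, np.nan)
    ia = stack.acceptor[mask]
    values[mask] = 100.0 * (stack.transfer[mask] - stack.kD * stack.donor[mask]
                            - stack.kA * ia) / ia
    return FretMap(values=values, mask=mask)


def roi_mean_fret(fmap: FretMap, roi: np.ndarray) -> tuple[float, int]:
    """Mean F% and pixel count over the valid pixels of a region of interest."""
    roi = roi.astype(bool)
    if roi.shape != fmap.values.shape:
        raise DataError("ROI shape differs from map shape")
    valid = roi & fmap.mask
    n = int(valid.sum())
    if n == 0:
        raise ParameterError("ROI does not intersect the valid-pixel mask")
    return float(fmap.values[valid].mean()), n


def roi_report(fmap: FretMap, rois: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-ROI mean efficiency table (roi, mean_f_percent, n_pixels)."""
    rows = []
    for name, roi in rois.items():
        mean, n = roi_mean_fret(fmap, roi)
        rows.append({"roi": name, "mean_f_percent": mean, "n_pixels": n})
    return pd.DataFrame(rows)


# -- TIFF I/O: multi-page stacks in (ID, IA, IF) page order ---------------

def write_stack(stack: FretStack, path: str | Path) -> None:
    pages = np.stack([stack.donor, stack.acceptor, stack.transfer]).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")


def read_stack(path: str | Path, kD: float | None = None,
               kA: float | None = None) -> FretStack:
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != 3:
        raise DataError(f"{path}: expected a 3-page stack (ID, IA, IF)")
    donor, acceptor, transfer = (pages[i].astype(float) for i in range(3))
    return FretStack(donor=donor, acceptor=acceptor, transfer=transfer,
                     kD=kD, kA=kA)


def write_map(fmap: FretMap, path: str | Path) -> None:
    tifffile.imwrite(path, fmap.values.astype(np.float32),
                     photometric="minisblack")
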