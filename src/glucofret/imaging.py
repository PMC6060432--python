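"""From two-channel movies to per-cell ratio traces.

The donor (CFP) and acceptor (YFP) emission channels of a FRET glucose
biosensor are acquired alternately every sampling interval.  This module
turns such a stack into per-cell ratio traces in three steps that mirror
standard practice for ratiometric time-lapse data:

1. :func:`register_stack` — translation-only registration of both
   channels against a reference frame, estimated on the summed-channel
   image by phase correlation with subpixel refinement.
2. :func:`ratio_stack` — pixelwise acceptor/donor ratio images, with
   pixels below a donor intensity floor masked out.
3. :func:`extract_trace` — unweighted mean of the defined ratio pixels
   over each cell's cytosolic ROI (soma with the nucleus excluded, since
   the sensor is largely absent from nuclei).

Ratio is computed pixelwise and then ROI-averaged (not as a ratio of
channel ROI means); the two differ in the presence of intensity
gradients and the pixelwise convention matches ratio-imaging practice
of dividing registered images before measurement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import tifffile
from skimage.draw import polygon as sk_polygon
from skimage.registration import phase_cross_correlation

__all__ = [
    "TwoChannelStack",
    "ShiftSeries",
    "RoiMask",
    "RatioTrace",
    "register_stack",
    "ratio_stack",
    "extract_trace",
    "rois_from_label_images",
    "rois_from_polygons",
    "traces_to_frame",
]


@dataclass
class TwoChannelStack:
    """Donor/acceptor frame series with acquisition timestamps.

    ``valid`` optionally marks pixels that are trustworthy (e.g. not
    filled in from outside the field of view after registration); when
    None every pixel is valid.
    """

    donor: np.ndarray  # (n, h, w), non-negative
    acceptor: np.ndarray  # (n, h, w)
    timestamps_s: np.ndarray  # (n,), strictly increasing
    valid: np.ndarray | None = None  # (n, h, w) bool

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.donor.ndim != 3 or self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor must be (n, h, w) with equal shapes")
        if len(self.timestamps_s) != self.donor.shape[0]:
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.nanmin(self.donor) < 0 or np.nanmin(self.acceptor) < 0:
            raise ValueError("intensities must be non-negative")
        if self.valid is not None and self.valid.shape != self.donor.shape:
            raise ValueError("valid mask must match frame shape")

    @property
    def n_frames(self) -> int:
        return self.donor.shape[0]

    # -- disk interchange ------------------------------------------------
    def save(self, directory: str | Path, prefix: str = "movie",
             sidecar_extra: dict | None = None) -> None:
        """Write ``<prefix>_donor.tif``, ``<prefix>_acceptor.tif`` and a
        JSON sidecar with timestamps (seconds) and any extra metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(directory / f"{prefix}_donor.tif",
                         self.donor.astype(np.float32))
        tifffile.imwrite(directory / f"{prefix}_acceptor.tif",
                         self.acceptor.astype(np.float32))
        sidecar = {"timestamps_s": self.timestamps_s.tolist()}
        if sidecar_extra:
            sidecar.update(sidecar_extra)
        (directory / f"{prefix}.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, directory: str | Path, prefix: str = "movie") -> "TwoChannelStack":
        directory = Path(directory)
        donor = tifffile.imread(directory / f"{prefix}_donor.tif").astype(float)
        acceptor = tifffile.imread(directory / f"{prefix}_acceptor.tif").astype(float)
        sidecar = json.loads((directory / f"{prefix}.json").read_text())
        return cls(donor=donor, acceptor=acceptor,
                   timestamps_s=np.asarray(sidecar["timestamps_s"], dtype=float))


@dataclass
class ShiftSeries:
    """Estimated per-frame translation of frame content relative to the
    reference frame, as (dx, dy) in pixels (x = column, y = row)."""

    shifts: np.ndarray  # (n, 2) columns (dx, dy), possibly fractional
    reference: int
    flagged: tuple[int, ...] = ()  # frames where estimation failed

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be (n, 2)")
        if not np.allclose(self.shifts[self.reference], 0.0):
            raise ValueError("reference frame must have zero shift")


@dataclass
class RoiMask:
    """Somatic ROI for one cell: soma and nucleus binary masks.

    The measured region is the cytosol, ``soma & ~nucleus``.
    """

    cell_id: str
    soma: np.ndarray
    nucleus: np.ndarray

    def __post_init__(self) -> None:
        self.soma = np.asarray(self.soma, dtype=bool)
        self.nucleus = np.asarray(self.nucleus, dtype=bool)
        if self.soma.shape != self.nucleus.shape:
            raise ValueError("soma and nucleus masks must have the same shape")
        if np.any(self.nucleus & ~self.soma):
            raise ValueError("nucleus must lie within the soma")
        if not np.any(self.cytosol):
            raise ValueError("cytosolic mask (soma minus nucleus) is empty")

    @property
    def cytosol(self) -> np.ndarray:
        return self.soma & ~self.nucleus


@dataclass
class RatioTrace:
    """Per-cell acceptor/donor (YFP/CFP) ratio over time, in minutes.

    NaN marks frames where no ratio pixel was defined in the ROI.
    """

    cell_id: str
    time_min: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.time_min.shape != self.R.shape:
            raise ValueError("time and ratio arrays must align")
        defined = self.R[np.isfinite(self.R)]
        if defined.size and np.any(defined <= 0):
            raise ValueError("ratio values must be positive where defined")


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def register_stack(
    stack: TwoChannelStack, reference: int = 0, upsample_factor: int = 20
) -> tuple[TwoChannelStack, ShiftSeries]:
    """Translation registration of both channels against ``reference``.

    The shift of each frame is estimated once on the donor+acceptor sum
    (channel-independent geometry, better SNR) by phase correlation with
    subpixel refinement, then applied identically to both channels with
    bilinear interpolation.  Pixels pulled in from outside the field are
    filled with the frame median and marked invalid so downstream ROI
    means exclude them.  An all-zero frame cannot be registered; it is
    flagged and inherits the previous frame's shift.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least two frames to register")
    if not 0 <= reference < stack.n_frames:
        raise ValueError("reference frame out of range")

    total = stack.donor + stack.acceptor
    ref_img = total[reference]
    if not np.any(ref_img):
        raise ValueError("reference frame is empty")

    n = stack.n_frames
    shifts = np.zeros((n, 2))  # (dx, dy) drift of content vs reference
    flagged: list[int] = []
    prev = np.zeros(2)
    for i in range(n):
        if i == reference:
            prev = shifts[i]
            continue
        frame = total[i]
        if not np.any(frame):
            shifts[i] = prev
            flagged.append(i)
            continue
        # returned (row, col) shift registers `frame` onto `ref_img`,
        # i.e. minus the content drift
        reg, _, _ = phase_cross_correlation(
            ref_img, frame, upsample_factor=upsample_factor, normalization=None
        )
        shifts[i] = (-reg[1], -reg[0])  # content drift as (dx, dy)
        prev = shifts[i]

    donor_al = np.empty_like(stack.donor)
    acceptor_al = np.empty_like(stack.acceptor)
    valid = np.ones(stack.donor.shape, dtype=bool)
    ones = np.ones(stack.donor.shape[1:])
    for i in range(n):
        dx, dy = shifts[i]
        if dx == 0 and dy == 0:
            donor_al[i] = stack.donor[i]
            acceptor_al[i] = stack.acceptor[i]
        else:
            corr = (-dy, -dx)  # undo the drift (row, col)
            donor_al[i] = ndi.shift(stack.donor[i], corr, order=1,
                                    mode="constant", cval=np.median(stack.donor[i]))
            acceptor_al[i] = ndi.shift(stack.acceptor[i], corr, order=1,
                                       mode="constant",
                                       cval=np.median(stack.acceptor[i]))
            cover = ndi.shift(ones, corr, order=1, mode="constant", cval=0.0)
            valid[i] = cover > 0.999
        if stack.valid is not None:
            valid[i] &= stack.valid[i]

    aligned = TwoChannelStack(
        donor=np.clip(donor_al, 0, None),
        acceptor=np.clip(acceptor_al, 0, None),
        timestamps_s=stack.timestamps_s.copy(),
        valid=valid,
    )
    return aligned, ShiftSeries(shifts=shifts, reference=reference,
                                flagged=tuple(flagged))


# ---------------------------------------------------------------------------
# ratio images and trace extraction
# ---------------------------------------------------------------------------

def ratio_stack(stack: TwoChannelStack, floor: float | None = None) -> np.ndarray:
    """Pixelwise acceptor/donor ratio images with dark pixels masked.

    A pixel is defined where the donor exceeds ``floor`` (and is marked
    valid); elsewhere the ratio is NaN.  By default the floor is 1% of
    each donor frame's 99th-percentile intensity.
    """
    if floor is not None and floor < 0:
        raise ValueError("floor must be non-negative")
    ratios = np.full(stack.donor.shape, np.nan)
    for i in range(stack.n_frames):
        d = stack.donor[i]
        fl = floor if floor is not None else 0.01 * np.percentile(d, 99)
        mask = d > fl
        if stack.valid is not None:
            mask &= stack.valid[i]
        ratios[i][mask] = stack.acceptor[i][mask] / d[mask]
    return ratios


def extract_trace(
    ratio_images: np.ndarray, roi: RoiMask, timestamps_s: np.ndarray
) -> RatioTrace:
    """Mean ratio over the cytosolic ROI at each time point.

    Frames with no defined cytosolic pixel yield NaN (missing, never
    interpolated).  Time is converted to minutes from the first frame.
    """
    cyto = roi.cytosol
    values = np.empty(ratio_images.shape[0])
    for i, img in enumerate(ratio_images):
        px = img[cyto]
        px = px[np.isfinite(px)]
        values[i] = px.mean() if px.size else np.nan
    t = np.asarray(timestamps_s, dtype=float) / 60.0
    return RatioTrace(cell_id=roi.cell_id, time_min=t, R=values)


# ---------------------------------------------------------------------------
# ROI input formats
# ---------------------------------------------------------------------------

def rois_from_label_images(
    soma_labels: np.ndarray, nucleus_labels: np.ndarray
) -> list[RoiMask]:
    """Build ROIs from label images (label k = cell k, 0 = background)."""
    soma_labels = np.asarray(soma_labels)
    nucleus_labels = np.asarray(nucleus_labels)
    rois = []
    for lab in sorted(set(np.unique(soma_labels)) - {0}):
        rois.append(
            RoiMask(
                cell_id=f"cell-{int(lab)}",
                soma=soma_labels == lab,
                nucleus=nucleus_labels == lab,
            )
        )
    return rois


def rois_from_polygons(spec: dict | str | Path, shape: tuple[int, int]) -> list[RoiMask]:
    """Build ROIs from a polygon JSON document.

    Expected structure::

        {"cells": [{"cell_id": "...",
                    "soma": [[x, y], ...],
                    "nucleus": [[x, y], ...]}, ...]}

    Coordinates are 0-based pixel centers, x = column, y = row.
    """
    if not isinstance(spec, dict):
        spec = json.loads(Path(spec).read_text())

    def rasterize(pts: Sequence[Sequence[float]]) -> np.ndarray:
        arr = np.asarray(pts, dtype=float)
        rr, cc = sk_polygon(arr[:, 1], arr[:, 0], shape=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask

    return [
        RoiMask(cell_id=str(c["cell_id"]), soma=rasterize(c["soma"]),
                nucleus=rasterize(c["nucleus"]))
        for c in spec["cells"]
    ]


def traces_to_frame(traces: Sequence[RatioTrace]) -> pd.DataFrame:
    """Long-form traces table (time_min, cell_id, value)."""
    parts = [
        pd.DataFrame({"time_min": tr.time_min, "cell_id": tr.cell_id, "value": tr.R})
        for tr in traces
    ]
    return pd.concat(parts, ignore_index=True)
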