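"""Multiplexed-core containers, TIFF I/O, and rolling-ball background
subtraction.

A core is stored as an ``H x W x C`` nonnegative array whose channel order
follows its :class:`~tmenet.panel.MarkerPanel`.  On disk, cores are
multipage TIFFs with one page per channel, in panel order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .panel import MarkerPanel, DEFAULT_PANEL

COVARIATE_COLUMNS = ("figo_stage", "grade", "age", "lvi",
                     "mmrp_deficient", "pole_mutated", "p53_abnormal")


@dataclass
class MultiplexedCore:
    """One multiplexed tissue core with its identity."""

    pixels: np.ndarray  # H x W x C, nonnegative
    core_id: str
    patient_id: str
    institution_id: str = "inst0"
    panel: MarkerPanel = field(default_factory=lambda: DEFAULT_PANEL)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3:
            raise ValueError("core pixels must be H x W x C")
        if self.pixels.shape[2] != self.panel.C:
            raise ValueError(
                f"core has {self.pixels.shape[2]} channels but panel "
                f"declares {self.panel.C}")

    @property
    def shape(self):
        return self.pixels.shape

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[:, :, self.panel.index(name)]


@dataclass
class PatientTable:
    """Patient-level labels, institution, core mapping, and covariates.

    ``label`` is 1 for recurrence.  Each patient contributes one or two
    cores; every core id maps to exactly one patient.
    """

    frame: pd.DataFrame
    max_cores: int = 2

    def __post_init__(self):
        df = self.frame
        required = {"patient_id", "label", "institution", "core_ids"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"patient table missing columns: {sorted(missing)}")
        if df["patient_id"].duplicated().any():
            raise ValueError("duplicate patient ids")
        all_cores = []
        for cids in df["core_ids"]:
            cids = self._split(cids)
            if not 1 <= len(cids) <= self.max_cores:
                raise ValueError(
                    f"each patient needs 1..{self.max_cores} cores, got {cids}")
            all_cores.extend(cids)
        if len(set(all_cores)) != len(all_cores):
            raise ValueError("a core is assigned to more than one patient")
        if not set(df["label"].unique()) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @staticmethod
    def _split(core_ids) -> list:
        if isinstance(core_ids, str):
            return [c for c in core_ids.split(";") if c]
        return list(core_ids)

    @property
    def patient_ids(self) -> list:
        return list(self.frame["patient_id"])

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    def cores_of(self, patient_id: str) -> list:
        row = self.frame.loc[self.frame["patient_id"] == patient_id]
        if row.empty:
            raise KeyError(f"unknown patient {patient_id}")
        return self._split(row["core_ids"].iloc[0])

    def covariates(self) -> pd.DataFrame:
        cols = [c for c in COVARIATE_COLUMNS if c in self.frame.columns]
        return self.frame.set_index("patient_id")[cols]

    def to_csv(self, path):
        df = self.frame.copy()
        df["core_ids"] = [";".join(self._split(c)) for c in df["core_ids"]]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, max_cores: int = 2) -> "PatientTable":
        df = pd.read_csv(path, dtype={"patient_id": str, "institution": str})
        return cls(df, max_cores=max_cores)


# ---------------------------------------------------------------------------
# TIFF round trip
# ---------------------------------------------------------------------------

def write_core(core: MultiplexedCore, path) -> Path:
    """Write a core as a multipage TIFF, one page per channel in panel order."""
    path = Path(path)
    pages = np.moveaxis(core.pixels, -1, 0)  # C x H x W
    tifffile.imwrite(path, pages, photometric="minisblack",
                     metadata={"axes": "CYX"})
    return path


def read_core(path, panel: MarkerPanel = DEFAULT_PANEL, *,
              core_id: str | None = None, patient_id: str = "",
              institution_id: str = "inst0") -> MultiplexedCore:
    """Read a multipage TIFF written with one page per channel."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface format problems clearly
        raise ValueError(f"{path} is not a readable TIFF: {exc}") from exc
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != panel.C:
        raise ValueError(
            f"{path}: expected {panel.C} channel pages, found {pages.shape[0]}")
    pixels = np.moveaxis(pages, 0, -1)
    return MultiplexedCore(pixels=pixels,
                           core_id=core_id or path.stem,
                           patient_id=patient_id,
                           institution_id=institution_id,
                           panel=panel)


# ---------------------------------------------------------------------------
# Rolling-ball background subtraction
# ---------------------------------------------------------------------------

def _ball_profile(radius: float) -> np.ndarray:
    """Height profile of a ball structuring element (NaN outside support)."""
    r = int(np.ceil(radius))
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = radius ** 2 - (x ** 2 + y ** 2)
    prof = np.full(d2.shape, -np.inf)
    inside = d2 >= 0
    prof[inside] = np.sqrt(d2[inside])
    return prof


def rolling_ball_background(image: np.ndarray, window: int = 50,
                            shrink: int | None = None) -> np.ndarray:
    """Estimate the background a ball of diameter ``window`` rolls under.

    The background is the grayscale opening of the image with a non-flat
    ball structuring element of radius ``window / 2`` — the classic
    rolling-ball estimator.  For large radii the image is optionally
    computed on a block-downsampled copy (block minimum, then bilinear
    enlargement), trading a small approximation for a large speedup; by
    default ``shrink`` is 4 once the radius exceeds 12 px, else 1 (exact).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("rolling ball operates on a single channel")
    h, w = image.shape
    if window < 3 or window >= min(h, w):
        raise ValueError(
            f"window must satisfy 3 <= window < min(H, W)={min(h, w)}, "
            f"got {window}")
    radius = window / 2.0
    if shrink is None:
        shrink = 4 if radius > 12 else 1
    if shrink > 1:
        hpad = (-h) % shrink
        wpad = (-w) % shrink
        padded = np.pad(image, ((0, hpad), (0, wpad)), mode="edge")
        small = padded.reshape(padded.shape[0] // shrink, shrink,
                               padded.shape[1] // shrink, shrink).min(axis=(1, 3))
        bg_small = rolling_ball_background(small, max(3, int(round(window / shrink))),
                                           shrink=1)
        zoom = (padded.shape[0] / bg_small.shape[0],
                padded.shape[1] / bg_small.shape[1])
        bg = ndimage.zoom(bg_small, zoom, order=1, mode="nearest")
        bg = bg[:h, :w]
        return np.minimum(bg, image)
    ball = _ball_profile(radius)
    footprint = np.isfinite(ball)
    structure = np.where(footprint, ball, 0.0)
    eroded = ndimage.grey_erosion(image, footprint=footprint,
                                  structure=structure, mode="nearest")
    opened = ndimage.grey_dilation(eroded, footprint=footprint,
                                   structure=structure, mode="nearest")
    return np.minimum(opened, image)


def rolling_ball_subtract(image: np.ndarray, window: int = 50,
                          shrink: int | None = None) -> np.ndarray:
    """Subtract the rolling-ball background; result is clipped at zero."""
    bg = rolling_ball_background(image, window=window, shrink=shrink)
    return np.clip(np.asarray(image, dtype=np.float64) - bg, 0.0, None)


def normalize_channels(cores: list, groupby: str = "institution") -> list:
    """Scale each channel to unit mean within a staining group.

    Marker intensities after unmixing are in arbitrary units and vary
    between staining batches mainly by per-channel multiplicative gain, so
    each institution's cores are divided channel-wise by the institution's
    mean channel intensity.  This cancels gain-only batch effects exactly
    while preserving within-institution contrast between patients.
    ``groupby`` may be ``"institution"`` or ``"cohort"`` (single group).
    """
    if groupby not in ("institution", "cohort"):
        raise ValueError("groupby must be 'institution' or 'cohort'")
    groups: dict = {}
    for core in cores:
        key = core.institution_id if groupby == "institution" else "all"
        groups.setdefault(key, []).append(core)
    out = []
    for members in groups.values():
        sums = np.zeros(members[0].panel.C, dtype=np.float64)
        count = 0
        for core in members:
            sums += core.pixels.reshape(-1, core.panel.C).sum(axis=0)
            count += core.pixels.shape[0] * core.pixels.shape[1]
        means = sums / count
        means = np.where(means > 0, means, 1.0)
        for core in members:
            out.append(MultiplexedCore(
                pixels=(core.pixels / means.astype(np.float32)),
                core_id=core.core_id, patient_id=core.patient_id,
                institution_id=core.institution_id, panel=core.panel))
    order = {c.core_id: i for i, c in enumerate(cores)}
    out.sort(key=lambda c: order[c.core_id])
    return out


def preprocess_core(core: MultiplexedCore, window: int = 50,
                    shrink: int | None = None) -> MultiplexedCore:
    """Apply rolling-ball subtraction to every channel (DAPI included)."""
    out = np.empty_like(core.pixels, dtype=np.float32)
    for c in range(core.panel.C):
        out[:, :, c] = rolling_ball_subtract(core.pixels[:, :, c],
                                             window=window, shrink=shrink)
    return MultiplexedCore(pixels=out, core_id=core.core_id,
                           patient_id=core.patient_id,
                           institution_id=core.institution_id,
                           panel=core.panel)
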