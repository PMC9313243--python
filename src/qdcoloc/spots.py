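"""Quantum-dot spot detection and sub-pixel centroid localization.

Diffraction-limited emitters are detected as local maxima of the
scale-normalized Laplacian-of-Gaussian response at the PSF scale, thresholded
in robust noise units (k x MAD of the response) and non-maximum-suppressed at
a minimum separation.  Candidates are then refined to sub-pixel positions by
a background-subtracted intensity-weighted centroid within a square window,
with the window-perimeter median as the local background estimate.

Coordinate convention: 0-based (row, col) = (y, x), pixel centers at integer
coordinates.  Detection is fully determined by the image and the recorded
parameters; candidate order is descending detection score with (y, x)
lexicographic tie-break.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max

__all__ = ["SpotSet", "detect_spots", "refine_centroids"]

COLUMNS = ["spot_id", "y_px", "x_px", "integrated_intensity",
           "detection_score", "flags"]


@dataclass
class SpotSet:
    """Detected spots with centroids, scores and full detection provenance."""

    spots: pd.DataFrame            # columns COLUMNS
    source_id: str = ""
    image_shape: tuple[int, int] | None = None
    detection_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.spots
        if len(df) and df["spot_id"].duplicated().any():
            raise ValueError("spot_ids must be pairwise distinct")
        if self.image_shape is not None and len(df):
            h, w = self.image_shape
            if ((df["y_px"] < 0) | (df["y_px"] > h - 1) |
                    (df["x_px"] < 0) | (df["x_px"] > w - 1)).any():
                raise ValueError("all centroids must lie inside the image frame")

    def __len__(self) -> int:
        return len(self.spots)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.spots.to_csv(path, index=False)
        sidecar = {"source_id": self.source_id,
                   "image_shape": list(self.image_shape or ()),
                   "detection_params": self.detection_params,
                   "coordinate_convention":
                       "0-based (row, col) = (y, x), pixel centers at integers"}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SpotSet":
        path = Path(path)
        df = pd.read_csv(path)
        if "flags" in df.columns:
            df["flags"] = df["flags"].fillna("")
        meta = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        shape = tuple(meta.get("image_shape") or ()) or None
        return cls(df, source_id=meta.get("source_id", ""),
                   image_shape=shape,
                   detection_params=meta.get("detection_params", {}))


def detect_spots(qd_channel: np.ndarray,
                 psf_sigma_px: float = 1.5,
                 detection_threshold: float = 5.0,
                 min_separation_px: float = 5.0,
                 threshold_mode: str = "robust",
                 source_id: str = "") -> SpotSet:
    """Detect candidate spots at integer positions.

    Parameters
    ----------
    detection_threshold
        In ``robust`` mode (default): multiples of the MAD-estimated noise
        sigma of the LoG response.  In ``absolute`` mode: a raw response
        threshold.
    min_separation_px
        Non-maximum suppression radius; of two closer peaks only the
        brighter survives.
    """
    img = np.asarray(qd_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")

    # scale-normalized LoG; negated so bright blobs give positive response.
    # The discrete LoG kernel leaves a small constant pedestal proportional
    # to the background level; subtracting the median removes it so scores
    # are zero on uniform background.
    response = -ndi.gaussian_laplace(img, psf_sigma_px) * psf_sigma_px ** 2
    response = response - np.median(response)

    if threshold_mode == "robust":
        mad = np.median(np.abs(response - np.median(response)))
        thr_abs = detection_threshold * 1.4826 * mad
        # noise-free images have zero MAD; keep the threshold strictly
        # positive so flat background plateaus are never "peaks"
        thr_abs = max(thr_abs, 1e-6 * max(float(np.abs(response).max()), 1.0))
    elif threshold_mode == "absolute":
        thr_abs = detection_threshold
    else:
        raise ValueError(f"unknown threshold_mode: {threshold_mode!r}")

    peaks = peak_local_max(response,
                           min_distance=max(1, int(np.ceil(min_separation_px))),
                           threshold_abs=thr_abs, exclude_border=False)
    scores = response[peaks[:, 0], peaks[:, 1]] if len(peaks) else np.empty(0)
    order = np.lexsort((peaks[:, 1] if len(peaks) else np.empty(0),
                        peaks[:, 0] if len(peaks) else np.empty(0),
                        -scores))
    peaks, scores = peaks[order], scores[order]

    df = pd.DataFrame({
        "spot_id": np.arange(len(peaks)),
        "y_px": peaks[:, 0].astype(float) if len(peaks) else pd.Series(dtype=float),
        "x_px": peaks[:, 1].astype(float) if len(peaks) else pd.Series(dtype=float),
        "integrated_intensity": np.full(len(peaks), np.nan),
        "detection_score": scores,
        "flags": [""] * len(peaks),
    })
    params = {"psf_sigma_px": psf_sigma_px,
              "detection_threshold": detection_threshold,
              "threshold_mode": threshold_mode,
              "min_separation_px": min_separation_px}
    return SpotSet(df, source_id=source_id, image_shape=img.shape,
                   detection_params=params)


def refine_centroids(qd_channel: np.ndarray, candidates: SpotSet,
                     window_radius_px: int = 5) -> SpotSet:
    """Refine candidate positions to sub-pixel centroids.

    For each candidate, a (2r+1)^2 window is extracted; the window-perimeter
    median is subtracted as local background; negative residuals are clipped
    to zero and the intensity-weighted centroid is taken.  Spots whose window
    exits the frame keep their integer position and carry a ``border`` flag;
    windows with non-positive net intensity keep the integer position with a
    ``low_intensity`` flag.
    """
    img = np.asarray(qd_channel, dtype=float)
    h, w = img.shape
    r = int(window_radius_px)
    rows = []
    for rec in candidates.spots.itertuples(index=False):
        y0, x0 = int(round(rec.y_px)), int(round(rec.x_px))
        flags = [f for f in str(rec.flags).split(";") if f]
        if y0 - r < 0 or y0 + r >= h or x0 - r < 0 or x0 + r >= w:
            flags.append("border")
            rows.append((rec.spot_id, float(y0), float(x0), np.nan,
                         rec.detection_score, ";".join(flags)))
            continue
        win = img[y0 - r:y0 + r + 1, x0 - r:x0 + r + 1]
        perimeter = np.concatenate([win[0, :], win[-1, :], win[1:-1, 0], win[1:-1, -1]])
        net = np.clip(win - np.median(perimeter), 0.0, None)
        total = net.sum()
        if total <= 0:
            flags.append("low_intensity")
            rows.append((rec.spot_id, float(y0), float(x0), 0.0,
                         rec.detection_score, ";".join(flags)))
            continue
        ys, xs = np.mgrid[y0 - r:y0 + r + 1, x0 - r:x0 + r + 1]
        yc = float((net * ys).sum() / total)
        xc = float((net * xs).sum() / total)
        rows.append((rec.spot_id, yc, xc, float(total),
                     rec.detection_score, ";".join(flags)))
    df = pd.DataFrame(rows, columns=COLUMNS)
    params = dict(candidates.detection_params)
    params["window_radius_px"] = r
    params["background_estimate"] = "window-perimeter median"
    return SpotSet(df, source_id=candidates.source_id,
                   image_shape=candidates.image_shape, detection_params=params)
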