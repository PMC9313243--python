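"""Synthetic root-tissue scenes with known ground truth.

Real micrographs of quantum-dot-labelled roots show elongated epidermal cell
files in a brightfield-like boundary channel and sparse diffraction-limited
emitters in the fluorescence channel.  This module emulates both channels from
explicit specs so that every downstream stage (boundary probability map, spot
detection, colocalization fraction) can be tested against known truth:

* an anisotropic nearest-seed tessellation stands in for the cell network —
  it preserves the one geometric property the colocalization statistic
  depends on (thin boundaries separating large cell interiors);
* emitters are rendered as pixel-integrated Gaussians (the standard
  diffraction-limited PSF approximation) with Poisson/Gaussian camera noise;
* a controllable fraction ``f_boundary`` of emitters is placed on boundary
  pixels — the ground-truth analogue of the measured boundary-colocalized
  fraction.

Coordinate convention used throughout the package: 0-based ``(row, col) =
(y, x)``, pixel centers at integer coordinates.

It also generates the tabular inputs of the statistics modules: multinomial
genotype segregation counts and long-format growth-assay tables.

Determinism: every generator is a pure function of its spec (including the
spec's seed).  Compound scenes split one top-level seed into per-operation
streams with :func:`split_seed`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from scipy.special import erf
from skimage.morphology import dilation, disk
from skimage.segmentation import find_boundaries

__all__ = [
    "CellNetworkSpec",
    "SpotPlacementSpec",
    "ImagingSpec",
    "SyntheticScene",
    "split_seed",
    "generate_cell_network",
    "place_spots",
    "render_qd_channel",
    "make_scene",
    "simulate_segregation_counts",
    "simulate_growth_table",
]


def split_seed(seed: int, stream: int) -> int:
    """Derive a per-operation seed from a top-level seed.

    Uses :class:`numpy.random.SeedSequence` with the stream index as spawn
    key, folded to a positive 31-bit integer so it can be stored in any spec.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=(int(stream),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellNetworkSpec:
    """Geometry of the simulated cell network.

    ``mean_cell_length``/``mean_cell_width`` (px) set the seed density of the
    tessellation; ``anisotropy`` >= 1 stretches cells along the root axis
    (image rows).  ``boundary_thickness_px`` is the rendered wall thickness.
    """

    image_height: int = 512
    image_width: int = 512
    mean_cell_length: float = 96.0
    mean_cell_width: float = 24.0
    boundary_thickness_px: int = 2
    anisotropy: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 64 or self.image_width < 64:
            raise ValueError("image dimensions must be >= 64 px each")
        if self.boundary_thickness_px < 1:
            raise ValueError("boundary_thickness_px must be >= 1")
        if self.anisotropy < 1:
            raise ValueError("anisotropy must be >= 1")
        if self.mean_cell_length <= 0 or self.mean_cell_width <= 0:
            raise ValueError("mean cell dimensions must be positive")


@dataclass(frozen=True)
class SpotPlacementSpec:
    """Ground-truth emitter placement.

    ``f_boundary`` is the fraction of spots placed on boundary pixels (the
    ground-truth colocalized fraction); boundary spots are jittered by at most
    ``boundary_jitter_px`` off the wall skeleton, interior spots are kept
    farther than twice that distance from any wall pixel.
    """

    n_spots: int = 50
    f_boundary: float = 0.8
    boundary_jitter_px: float = 1.0
    min_separation_px: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots < 1:
            raise ValueError("n_spots must be >= 1")
        if not 0.0 <= self.f_boundary <= 1.0:
            raise ValueError("f_boundary must lie in [0, 1]")
        if self.boundary_jitter_px < 0:
            raise ValueError("boundary_jitter_px must be >= 0")

    @property
    def n_boundary(self) -> int:
        """Boundary-labelled spot count: round half up of n_spots*f_boundary."""
        return int(np.floor(self.n_spots * self.f_boundary + 0.5))


NoiseModel = Literal["none", "poisson", "gaussian", "poisson+gaussian"]


@dataclass(frozen=True)
class ImagingSpec:
    """EMCCD-like rendering of the emitter channel.

    Each spot contributes ``spot_photon_mean`` photons integrated over a
    Gaussian PSF of width ``psf_sigma_px``; the camera adds a constant
    background, shot noise and/or Gaussian read noise, and digitizes to
    ``bit_depth`` bits.
    """

    psf_sigma_px: float = 1.5
    spot_photon_mean: float = 2000.0
    background_level: float = 100.0
    noise_model: NoiseModel = "poisson+gaussian"
    gaussian_noise_sd: float = 5.0
    bit_depth: Literal[8, 16] = 16
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")
        if self.noise_model not in ("none", "poisson", "gaussian", "poisson+gaussian"):
            raise ValueError(f"unknown noise_model: {self.noise_model!r}")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass
class SyntheticScene:
    """One simulated image pair with full ground truth."""

    boundary_mask: np.ndarray       # bool, dilated wall pixels
    boundary_channel: np.ndarray    # uint16 brightfield-like wall image
    qd_channel: np.ndarray          # uint8/uint16 emitter image
    spots_truth: pd.DataFrame       # spot_id, y_px, x_px, label
    network_spec: CellNetworkSpec
    placement_spec: SpotPlacementSpec
    imaging_spec: ImagingSpec

    @property
    def true_boundary_fraction(self) -> float:
        return float((self.spots_truth["label"] == "boundary").mean())

    def save(self, out_dir: str | Path, prefix: str = "scene") -> dict[str, Path]:
        """Write channels as grayscale TIFF, truth as CSV, specs as JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "boundary_channel": out / f"{prefix}_boundary.tif",
            "qd_channel": out / f"{prefix}_qd.tif",
            "boundary_mask": out / f"{prefix}_mask.tif",
            "spots_truth": out / f"{prefix}_spots_truth.csv",
            "scene_json": out / f"{prefix}.json",
        }
        tifffile.imwrite(paths["boundary_channel"], self.boundary_channel)
        tifffile.imwrite(paths["qd_channel"], self.qd_channel)
        tifffile.imwrite(paths["boundary_mask"], self.boundary_mask.astype(np.uint8))
        self.spots_truth.to_csv(paths["spots_truth"], index=False)
        specs = {
            "network": dataclasses.asdict(self.network_spec),
            "placement": dataclasses.asdict(self.placement_spec),
            "imaging": dataclasses.asdict(self.imaging_spec),
            "coordinate_convention": "0-based (row, col) = (y, x), pixel centers at integers",
        }
        paths["scene_json"].write_text(json.dumps(specs, indent=2))
        return paths


# ---------------------------------------------------------------------------
# cell network
# ---------------------------------------------------------------------------

def generate_cell_network(spec: CellNetworkSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate the wall mask and a brightfield-like boundary channel.

    Cells are the nearest-seed regions of uniformly scattered seed points
    under an anisotropic metric (rows compressed by ``anisotropy``), which
    yields elongated files along the root axis.  The wall mask is the region
    edge set dilated to ``boundary_thickness_px``; the boundary channel
    renders it as bright, slightly blurred lines over a noisy background.

    Returns
    -------
    (boundary_mask, boundary_channel)
        ``boundary_mask`` boolean, ``boundary_channel`` uint16.
    """
    h, w = spec.image_height, spec.image_width
    n_cells = int(round(h * w / (spec.mean_cell_length * spec.mean_cell_width)))
    if n_cells < 4:
        raise ValueError(
            f"image {h}x{w} px fits only {n_cells} cells of mean size "
            f"{spec.mean_cell_length}x{spec.mean_cell_width} px; need >= 4 — "
            "enlarge the image or shrink the cells"
        )
    rng = np.random.default_rng(spec.rng_seed)
    seeds = np.column_stack([rng.uniform(0, h, n_cells), rng.uniform(0, w, n_cells)])

    # anisotropic nearest-seed labels: compress the row axis before the query
    scaled_seeds = seeds / [spec.anisotropy, 1.0]
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([yy.ravel() / spec.anisotropy, xx.ravel()])
    _, lab = cKDTree(scaled_seeds).query(pix)
    labels = lab.reshape(h, w)

    skeleton = find_boundaries(labels, mode="thick")
    radius = spec.boundary_thickness_px // 2
    mask = dilation(skeleton, disk(radius)) if radius > 0 else skeleton

    background, amplitude, blur_sigma, noise_sd = 100.0, 120.0, 1.0, 6.0
    img = background + amplitude * ndi.gaussian_filter(mask.astype(float), blur_sigma)
    img = img + rng.normal(0.0, noise_sd, size=img.shape)
    channel = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return mask, channel


# ---------------------------------------------------------------------------
# spot placement
# ---------------------------------------------------------------------------

def place_spots(mask: np.ndarray, spec: SpotPlacementSpec) -> pd.DataFrame:
    """Place ground-truth spots on/off the wall mask.

    Exactly ``round-half-up(n_spots * f_boundary)`` spots are labelled
    ``boundary`` (each within ``boundary_jitter_px`` of a wall pixel); the
    rest are ``interior`` (farther than twice the jitter from any wall
    pixel).  All spots are strictly inside the frame and pairwise separated
    by at least ``min_separation_px``.
    """
    if not mask.any():
        raise ValueError("boundary mask is empty; cannot place boundary spots")
    h, w = mask.shape
    rng = np.random.default_rng(spec.rng_seed)
    n_b = spec.n_boundary
    n_i = spec.n_spots - n_b
    jitter = spec.boundary_jitter_px

    boundary_pixels = np.argwhere(mask)
    dist_to_wall = ndi.distance_transform_edt(~mask)
    interior_pixels = np.argwhere(dist_to_wall > 2.0 * jitter if jitter > 0
                                  else dist_to_wall > 0)
    if n_i > 0 and len(interior_pixels) == 0:
        raise ValueError("no interior pixels farther than 2x jitter from the wall")

    accepted: list[tuple[float, float, str]] = []

    def far_enough(y: float, x: float) -> bool:
        return all((y - ay) ** 2 + (x - ax) ** 2 >= spec.min_separation_px ** 2
                   for ay, ax, _ in accepted)

    max_tries = 200 * spec.n_spots
    tries = 0

    def draw(label: str) -> None:
        nonlocal tries
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"could not place {spec.n_spots} spots with "
                    f"min_separation_px={spec.min_separation_px} after "
                    f"{max_tries} attempts; relax min_separation_px or n_spots"
                )
            if label == "boundary":
                py, px_ = boundary_pixels[rng.integers(len(boundary_pixels))]
                if jitter > 0:    # uniform in a disc of radius <= jitter
                    r = jitter * np.sqrt(rng.uniform())
                    th = rng.uniform(0, 2 * np.pi)
                    y, x = py + r * np.sin(th), px_ + r * np.cos(th)
                else:
                    y, x = float(py), float(px_)
            else:
                py, px_ = interior_pixels[rng.integers(len(interior_pixels))]
                y, x = py + rng.uniform(-0.5, 0.5), px_ + rng.uniform(-0.5, 0.5)
            if not (0 < y < h - 1 and 0 < x < w - 1):
                continue
            if label == "interior" and dist_to_wall[int(round(y)), int(round(x))] <= 2.0 * jitter:
                continue
            if far_enough(y, x):
                accepted.append((y, x, label))
                return

    for _ in range(n_b):
        draw("boundary")
    for _ in range(n_i):
        draw("interior")

    df = pd.DataFrame(accepted, columns=["y_px", "x_px", "label"])
    df.insert(0, "spot_id", np.arange(len(df)))
    return df


# ---------------------------------------------------------------------------
# emitter rendering
# ---------------------------------------------------------------------------

def _integrated_gaussian_patch(y0: float, x0: float, sigma: float,
                               ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Unit-mass Gaussian integrated over unit pixels centred at (ys, xs)."""
    s = sigma * np.sqrt(2.0)
    fy = 0.5 * (erf((ys + 0.5 - y0) / s) - erf((ys - 0.5 - y0) / s))
    fx = 0.5 * (erf((xs + 0.5 - x0) / s) - erf((xs - 0.5 - x0) / s))
    return np.outer(fy, fx)


def render_qd_channel(spots_truth: pd.DataFrame, spec: ImagingSpec,
                      image_shape: tuple[int, int]) -> np.ndarray:
    """Render the emitter channel from ground-truth positions.

    Each spot is a pixel-integrated Gaussian of width ``psf_sigma_px``
    carrying ``spot_photon_mean`` photons, on a constant background, with
    the configured camera noise, digitized to ``bit_depth`` bits.
    """
    h, w = image_shape
    canvas = np.zeros((h, w), dtype=float)
    reach = int(np.ceil(4 * spec.psf_sigma_px)) + 1
    for y0, x0 in zip(spots_truth["y_px"], spots_truth["x_px"]):
        if not (0 <= y0 <= h - 1 and 0 <= x0 <= w - 1):
            raise ValueError(f"spot ({y0}, {x0}) outside frame {image_shape}")
        ylo, yhi = max(0, int(y0) - reach), min(h, int(y0) + reach + 1)
        xlo, xhi = max(0, int(x0) - reach), min(w, int(x0) + reach + 1)
        ys, xs = np.arange(ylo, yhi), np.arange(xlo, xhi)
        canvas[ylo:yhi, xlo:xhi] += spec.spot_photon_mean * _integrated_gaussian_patch(
            y0, x0, spec.psf_sigma_px, ys, xs)
    canvas += spec.background_level

    rng = np.random.default_rng(spec.rng_seed)
    if spec.noise_model in ("poisson", "poisson+gaussian"):
        canvas = rng.poisson(np.clip(canvas, 0, None)).astype(float)
    if spec.noise_model in ("gaussian", "poisson+gaussian") and spec.gaussian_noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.gaussian_noise_sd, size=canvas.shape)

    top = 2 ** spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    return np.clip(np.rint(canvas), 0, top).astype(dtype)


def make_scene(network_spec: CellNetworkSpec | None = None,
               placement_spec: SpotPlacementSpec | None = None,
               imaging_spec: ImagingSpec | None = None,
               seed: int | None = None) -> SyntheticScene:
    """Build a complete scene; if ``seed`` is given it overrides every spec
    seed via the documented per-operation splitting rule (streams 0/1/2 for
    network, placement, imaging)."""
    network_spec = network_spec or CellNetworkSpec()
    placement_spec = placement_spec or SpotPlacementSpec()
    imaging_spec = imaging_spec or ImagingSpec()
    if seed is not None:
        network_spec = dataclasses.replace(network_spec, rng_seed=split_seed(seed, 0))
        placement_spec = dataclasses.replace(placement_spec, rng_seed=split_seed(seed, 1))
        imaging_spec = dataclasses.replace(imaging_spec, rng_seed=split_seed(seed, 2))
    mask, boundary_channel = generate_cell_network(network_spec)
    spots = place_spots(mask, placement_spec)
    qd = render_qd_channel(spots, imaging_spec, mask.shape)
    return SyntheticScene(mask, boundary_channel, qd, spots,
                          network_spec, placement_spec, imaging_spec)


# ---------------------------------------------------------------------------
# tabular generators
# ---------------------------------------------------------------------------

def simulate_segregation_counts(n_plants: int,
                                probabilities: Sequence[float],
                                rng_seed: int = 0,
                                line_id: str = "sim") -> "pd.DataFrame":
    """Multinomial genotype counts (WT, heterozygous, homozygous).

    Returns a one-row DataFrame with columns line_id, wt, het, hom — the CSV
    layout the segregation module reads.
    """
    p = np.asarray(probabilities, dtype=float)
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("probabilities must sum to 1")
    rng = np.random.default_rng(rng_seed)
    counts = rng.multinomial(n_plants, p)
    return pd.DataFrame([{"line_id": line_id, "wt": counts[0],
                          "het": counts[1], "hom": counts[2]}])


def simulate_growth_table(treatment_effects: Mapping[str, float],
                          genotype_effects: Mapping[str, float] | None = None,
                          plates_per_treatment: int = 4,
                          seeds_per_plate: int = 10,
                          noise_sd: float = 1.0,
                          rng_seed: int = 0,
                          baseline: float = 10.0,
                          plate_sd: float = 0.0,
                          measure_name: str = "primary_root_length_mm") -> pd.DataFrame:
    """Long-format per-seedling growth table.

    value = baseline + treatment effect + genotype effect + plate random
    effect (sd ``plate_sd``) + residual (sd ``noise_sd``).  The design is a
    full treatment x genotype factorial with ``plates_per_treatment`` plates
    per cell — mirroring an assay with a fixed number of seeds started per
    plate and replicate plates per treatment.
    """
    if plates_per_treatment < 2:
        raise ValueError("need >= 2 plates per treatment")
    genotype_effects = genotype_effects or {"Col-0": 0.0}
    rng = np.random.default_rng(rng_seed)
    rows = []
    for treatment, t_eff in treatment_effects.items():
        for genotype, g_eff in genotype_effects.items():
            for p in range(plates_per_treatment):
                plate_id = f"{treatment}_{genotype}_p{p}"
                p_eff = rng.normal(0.0, plate_sd) if plate_sd > 0 else 0.0
                for s in range(seeds_per_plate):
                    noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                    rows.append({
                        "plate_id": plate_id,
                        "treatment": treatment,
                        "genotype": genotype,
                        "seedling_id": s,
                        "measure_name": measure_name,
                        "value": baseline + t_eff + g_eff + p_eff + noise,
                    })
    return pd.DataFrame(rows)
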