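"""Spot-level and auxiliary quantifications.

Difference-of-Gaussians MS2 spot localization with sub-voxel refinement;
mean histone intensity in a small pixel window around the spot (a chromatin
compaction proxy); spot mobility relative to the nucleus centroid; mean
nuclear factor levels; equivalent-ellipsoid nuclear axis lengths; and cell
shape / mesoderm-contact metrics on externally provided 2D label images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import regionprops


@dataclass(frozen=True)
class SpotParams:
    window_px: int = 5              # His2Av window side (odd)
    mobility_smooth: int = 8        # frames (2 min at 15 s/frame)
    dog_narrow: float = 0.36        # µm
    dog_wide: float = 0.9           # µm
    significance: float = 3.0       # DoG peak must exceed this x local SD

    def __post_init__(self) -> None:
        if self.window_px < 3 or self.window_px % 2 == 0:
            raise ValueError("window_px must be odd and >= 3")
        if self.mobility_smooth < 1:
            raise ValueError("mobility_smooth must be >= 1")
        if not self.dog_narrow < self.dog_wide:
            raise ValueError("dog_narrow must be smaller than dog_wide")


def detect_spot_dog(subvolume: np.ndarray, voxel_xy: float, voxel_z: float,
                    params: SpotParams = SpotParams()
                    ) -> tuple[float, float, float] | None:
    """Locate the MS2 punctum in a nucleus subvolume (z, y, x order in, µm
    (x, y, z) out).

    The subvolume is band-passed with a difference of Gaussians (sigmas in
    µm, scaled per axis by the voxel calibration); the global DoG maximum is
    refined to sub-voxel precision by the intensity-weighted centroid of its
    3x3x3 neighborhood.  None is returned when the peak does not rise above
    ``significance`` standard deviations of the DoG response (no detectable
    spot).  Adding a constant to the subvolume does not change the result.
    """
    vol = np.asarray(subvolume, dtype=np.float64)
    if vol.size == 0:
        raise ValueError("empty subvolume")
    sig_n = (params.dog_narrow / voxel_z, params.dog_narrow / voxel_xy,
             params.dog_narrow / voxel_xy)
    sig_w = (params.dog_wide / voxel_z, params.dog_wide / voxel_xy,
             params.dog_wide / voxel_xy)
    dog = (ndimage.gaussian_filter(vol, sig_n, mode="nearest")
           - ndimage.gaussian_filter(vol, sig_w, mode="nearest"))
    sd = dog.std()
    peak = dog.max()
    if sd == 0 or peak < params.significance * sd:
        return None
    cz, cy, cx = np.unravel_index(int(np.argmax(dog)), dog.shape)
    # sub-voxel: weighted centroid of the positive DoG in the 3x3x3 box
    z0, z1 = max(0, cz - 1), min(dog.shape[0], cz + 2)
    y0, y1 = max(0, cy - 1), min(dog.shape[1], cy + 2)
    x0, x1 = max(0, cx - 1), min(dog.shape[2], cx + 2)
    w = np.clip(dog[z0:z1, y0:y1, x0:x1], 0.0, None)
    if w.sum() > 0:
        zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
        cz = float((w * zz).sum() / w.sum())
        cy = float((w * yy).sum() / w.sum())
        cx = float((w * xx).sum() / w.sum())
    return ((cx + 0.5) * voxel_xy, (cy + 0.5) * voxel_xy,
            (cz + 0.5) * voxel_z)


def his_window_mean(plane: np.ndarray, spot_yx: tuple[int, int],
                    params: SpotParams = SpotParams()) -> float:
    """Mean histone intensity in the window_px x window_px window around the
    spot pixel; windows clipped at image borders average only valid pixels."""
    plane = np.asarray(plane, dtype=np.float64)
    r = params.window_px // 2
    y, x = int(spot_yx[0]), int(spot_yx[1])
    y0, y1 = max(0, y - r), min(plane.shape[0], y + r + 1)
    x0, x1 = max(0, x - r), min(plane.shape[1], x + r + 1)
    if y0 >= y1 or x0 >= x1:
        raise ValueError("spot window outside the image")
    return float(plane[y0:y1, x0:x1].mean())


def _rolling_median(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    return (pd.Series(x).rolling(width, center=True, min_periods=1)
            .median().to_numpy())


def spot_mobility(spot_positions: pd.DataFrame, centroids: pd.DataFrame,
                  frame_interval: float,
                  params: SpotParams = SpotParams()) -> pd.DataFrame:
    """Relative spot speed (µm/min) per frame.

    Inputs carry frame, x_um, y_um, z_um.  The speed at frame t is the
    Euclidean norm of the change of the spot − centroid offset vector from
    the previous observed frame, divided by the elapsed time; nuclear
    translation therefore cancels exactly.  Speeds are median-filtered over
    ``mobility_smooth`` frames.  Gaps: speeds are computed only across
    adjacent observed frames.
    """
    cols = ["frame", "x_um", "y_um", "z_um"]
    s = spot_positions[cols].sort_values("frame").reset_index(drop=True)
    c = centroids[cols].sort_values("frame").reset_index(drop=True)
    merged = s.merge(c, on="frame", suffixes=("_spot", "_nuc"))
    if len(merged) < 2:
        raise ValueError("spot mobility needs >= 2 frames with both positions")
    off = (merged[["x_um_spot", "y_um_spot", "z_um_spot"]].to_numpy()
           - merged[["x_um_nuc", "y_um_nuc", "z_um_nuc"]].to_numpy())
    frames = merged.frame.to_numpy()
    d = np.linalg.norm(np.diff(off, axis=0), axis=1)
    dt_min = np.diff(frames) * frame_interval / 60.0
    adjacent = np.diff(frames) == 1
    speed = np.where(adjacent, d / dt_min, np.nan)
    speed = _rolling_median(speed, params.mobility_smooth)
    return pd.DataFrame({"frame": frames[1:], "rel_speed": speed})


def nuclear_factor_levels(channel: np.ndarray, labels: np.ndarray,
                          tracks: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean intensity over each nucleus's voxels per frame.

    ``channel`` and ``labels`` are (T, Z, Y, X).  When a tracks table is
    given its (frame, label, track_id[, region]) mapping is used; otherwise
    raw labels are reported.  No bleaching normalization is applied.
    """
    rows = []
    for f in range(channel.shape[0]):
        ids = np.unique(labels[f])
        ids = ids[ids > 0]
        if len(ids) == 0:
            continue
        means = ndimage.mean(channel[f], labels[f], ids)
        for lab, m in zip(ids, means):
            rows.append((f, int(lab), float(m)))
    out = pd.DataFrame(rows, columns=["frame", "label", "mean_intensity"])
    if tracks is not None:
        keep = [c for c in ("frame", "label", "track_id", "region")
                if c in tracks.columns]
        out = out.merge(tracks[keep], on=["frame", "label"], how="left")
    return out


def region_curves(levels: pd.DataFrame) -> pd.DataFrame:
    """Per-region mean curve, weighting each nucleus equally (per-nucleus
    curves averaged, not voxels pooled)."""
    if "region" not in levels.columns:
        raise ValueError("levels table has no region column")
    return (levels.groupby(["region", "frame"])["mean_intensity"]
            .mean().reset_index())


def nuclear_axes(voxels_zyx: np.ndarray, voxel_xy: float, voxel_z: float
                 ) -> np.ndarray:
    """Equivalent-ellipsoid full axis lengths (µm), sorted descending.

    lengths = 2·sqrt(5·eigenvalues) of the covariance of the member voxels'
    physical coordinates — a uniform solid ellipsoid has variance a²/5 along
    a semi-axis a, so this recovers the full axis lengths exactly in the
    continuum limit.  A degenerate (coplanar) voxel set yields a zero third
    axis.
    """
    vox = np.asarray(voxels_zyx, dtype=np.float64)
    if vox.ndim != 2 or vox.shape[1] != 3 or len(vox) < 10:
        raise ValueError("need >= 10 voxel coordinates (z, y, x)")
    phys = (vox + 0.5) * np.array([voxel_z, voxel_xy, voxel_xy])
    cov = np.cov(phys.T, bias=True)
    lam = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    return np.sort(2.0 * np.sqrt(5.0 * lam))[::-1]


def cell_contact_length(label_image: np.ndarray, cell_id: int,
                        me_ids) -> int:
    """Pixels of contact between a cell and the mesoderm.

    Both the cell and every ME cell are thickened by 1 pixel (8-connected
    unit-square dilation); the contact length is the pixel count of the
    intersection of the thickened cell with the union of thickened ME cells.
    """
    lab = np.asarray(label_image)
    present = set(np.unique(lab))
    if cell_id not in present:
        raise ValueError(f"unknown cell id {cell_id}")
    me_ids = [int(i) for i in me_ids]
    missing = [i for i in me_ids if i not in present]
    if missing:
        raise ValueError(f"unknown ME ids {missing}")
    footprint = np.ones((3, 3), dtype=bool)
    cell = ndimage.binary_dilation(lab == cell_id, structure=footprint)
    me = np.zeros_like(cell)
    for i in me_ids:
        if i == cell_id:
            continue
        me |= ndimage.binary_dilation(lab == i, structure=footprint)
    return int(np.count_nonzero(cell & me))


def cell_shape_props(label_image: np.ndarray, voxel_xy: float | None = None
                     ) -> pd.DataFrame:
    """Per-cell pixel area (and µm² given the calibration) and eccentricity
    of the second-moment equivalent ellipse."""
    rows = []
    for rp in regionprops(np.asarray(label_image)):
        area_um2 = rp.area * voxel_xy ** 2 if voxel_xy else np.nan
        rows.append((rp.label, int(rp.area), area_um2,
                     float(rp.eccentricity)))
    return pd.DataFrame(rows, columns=["cell_id", "area_px", "area_um2",
                                       "eccentricity"])
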