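"""Per-nucleus fluorescence quantification from confocal stacks.

The measurement chain mirrors standard knockin-line quantification practice:
maximum-intensity projection of the z-stack, scalar background estimation
from non-nuclear pixels, Otsu-based segmentation with an area filter,
background-corrected integrated intensity per nucleus, and fold-change
summaries relative to the dormant (t = 0) state with replicate standard
errors.

Conventions (used everywhere): 0-based pixel coordinates in (row, col)
order; 8-connectivity for labeling; background is a scalar per image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import expand_labels, watershed

__all__ = [
    "NucleusRecord",
    "max_project",
    "estimate_background",
    "background_noise_sd",
    "segment_nuclei",
    "quantify_nuclei",
    "quantify_image",
    "track_nuclei",
    "compute_fold_change",
]

MIN_NUCLEI_PER_IMAGE = 30  # quantification guideline: >= 30 nuclei per image


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented nucleus in one channel, background-corrected."""

    nucleus_id: int
    centroid: tuple[float, float]          # (row, col), 0-based
    area: int                              # pixels
    channel: str
    integrated_intensity: float            # a.u., background-corrected
    censored: bool                         # below the detection floor
    gemma_id: str = ""
    time_h: float = 0.0


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection over z; 2-D input passes through.

    3-D input is interpreted as (z, row, col).  Idempotent.
    """
    a = np.asarray(stack, dtype=float)
    if a.ndim == 2:
        return a
    if a.ndim == 3:
        if a.shape[0] < 1:
            raise ValueError("empty stack")
        return a.max(axis=0)
    raise ValueError("stack must be 2-D or 3-D (z, row, col)")


def estimate_background(image: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Median intensity of non-nucleus pixels (scalar background).

    With an explicit nucleus ``mask`` (True = nucleus), the median is taken
    outside it; otherwise pixels below the Otsu threshold are treated as
    background.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if mask is None:
        if np.ptp(img) == 0:
            return float(img.flat[0])  # uniform image: everything is background
        bg = img[img < threshold_otsu(img)]
    else:
        bg = img[~np.asarray(mask, dtype=bool)]
    if bg.size == 0:
        raise ValueError("no background pixels available")
    return float(np.median(bg))


def background_noise_sd(image: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Robust (MAD-based) SD of non-nucleus pixels, for the detection floor."""
    img = np.asarray(image, dtype=float)
    if mask is None:
        bg = img[img < threshold_otsu(img)] if np.ptp(img) > 0 else img.ravel()
    else:
        bg = img[~np.asarray(mask, dtype=bool)]
    if bg.size == 0:
        raise ValueError("no background pixels available")
    mad = np.median(np.abs(bg - np.median(bg)))
    return float(1.4826 * mad)


def segment_nuclei(image: np.ndarray, min_area: int = 20, max_area: int = 10000,
                   smooth_sigma: float = 1.0, split_touching: bool = False,
                   expand_px: float = 0.0) -> np.ndarray:
    """Segment nuclei: Gaussian smooth, Otsu threshold, 8-connected components.

    Components outside [min_area, max_area] are discarded.  With
    ``split_touching`` a distance-transform watershed separates merged blobs.
    ``expand_px`` grows the final labels outward (without letting them merge)
    so that the dim Gaussian skirt of each nucleus is included when
    integrating intensity.  A blank image yields zero labels, not an error.
    """
    if min_area >= max_area:
        raise ValueError("min_area must be < max_area")
    img = np.asarray(image, dtype=float)
    smoothed = gaussian(img, sigma=smooth_sigma, preserve_range=True) if smooth_sigma > 0 else img
    if np.ptp(smoothed) == 0:
        return np.zeros(img.shape, dtype=int)
    binary = smoothed > threshold_otsu(smoothed)
    if split_touching:
        distance = ndi.distance_transform_edt(binary)
        peaks = peak_local_max(distance, labels=binary,
                               min_distance=max(int(np.sqrt(min_area / np.pi)), 3))
        markers = np.zeros(img.shape, dtype=int)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-distance, markers, mask=binary, connectivity=2)
    else:
        labels = cc_label(binary, connectivity=2)

    out = np.zeros_like(labels)
    next_id = 1
    for prop in regionprops(labels):
        if min_area <= prop.area <= max_area:
            out[labels == prop.label] = next_id
            next_id += 1
    if expand_px > 0 and next_id > 1:
        out = expand_labels(out, distance=expand_px)
    return out


def quantify_nuclei(projections: dict[str, np.ndarray], labels: np.ndarray,
                    background: dict[str, float],
                    noise_sd: dict[str, float] | None = None,
                    floor_sd: float = 3.0, gemma_id: str = "",
                    time_h: float = 0.0) -> pd.DataFrame:
    """Integrate background-corrected intensity per nucleus and channel.

    integrated_intensity = sum over the label's pixels of
    max(pixel - background, 0).  Detection is decided on the *unclipped*
    signed sum, which is zero-mean with SD ``noise_sd * sqrt(area)`` for a
    signal-free region (clipping adds a positive bias that would mask dim
    nuclei): a nucleus is flagged ``censored`` in a channel when that sum
    falls below ``floor_sd`` times this null SD — the detection floor for
    "nearly undetectable" signals.
    """
    labels = np.asarray(labels)
    rows = []
    for ch, proj in projections.items():
        proj = np.asarray(proj, dtype=float)
        if proj.shape != labels.shape:
            raise ValueError(f"channel {ch!r} shape {proj.shape} does not match labels {labels.shape}")
        bg = float(background[ch])
        sd = float(noise_sd[ch]) if noise_sd is not None else 0.0
        signed = proj - bg
        corrected = np.clip(signed, 0.0, None)
        for prop in regionprops(labels):
            pix = labels == prop.label
            total = float(corrected[pix].sum())
            floor = floor_sd * sd * np.sqrt(prop.area)
            rows.append({"gemma_id": gemma_id, "time_h": time_h,
                         "nucleus_id": int(prop.label),
                         "centroid_row": prop.centroid[0],
                         "centroid_col": prop.centroid[1],
                         "area_px": int(prop.area), "channel": ch,
                         "intensity": total,
                         "censored": bool(float(signed[pix].sum()) < floor)})
    columns = ["gemma_id", "time_h", "nucleus_id", "centroid_row", "centroid_col",
               "area_px", "channel", "intensity", "censored"]
    return pd.DataFrame(rows, columns=columns)


def quantify_image(stacks: dict[str, np.ndarray], min_area: int = 20,
                   max_area: int = 10000, smooth_sigma: float = 1.0,
                   floor_sd: float = 3.0, gemma_id: str = "",
                   time_h: float = 0.0) -> tuple[pd.DataFrame, np.ndarray]:
    """End-to-end quantification of one multi-channel stack.

    Projects each channel, segments on the channel sum, expands labels by
    the median equivalent nucleus radius (an Otsu mask stops partway down a
    nucleus's Gaussian intensity skirt; one extra radius captures the
    remaining integral), then estimates per-channel background from
    non-nucleus pixels and integrates.
    """
    projections = {ch: max_project(s) for ch, s in stacks.items()}
    composite = sum(projections.values())
    # detect on a log scale: nucleus brightness spans an order of magnitude,
    # and a linear Otsu threshold set by the bright nuclei can swallow dim ones
    labels = segment_nuclei(np.log1p(composite), min_area=min_area,
                            max_area=max_area, smooth_sigma=smooth_sigma)
    if labels.max() > 0:
        radii = [np.sqrt(p.area / np.pi) for p in regionprops(labels)]
        labels = expand_labels(labels, distance=2.0 * float(np.median(radii)))
    nucleus_mask = labels > 0
    background = {ch: estimate_background(p, mask=nucleus_mask)
                  for ch, p in projections.items()}
    noise_sd = {ch: background_noise_sd(p, mask=nucleus_mask)
                for ch, p in projections.items()}
    table = quantify_nuclei(projections, labels, background, noise_sd=noise_sd,
                            floor_sd=floor_sd, gemma_id=gemma_id, time_h=time_h)
    return table, labels


def track_nuclei(records_a: pd.DataFrame, records_b: pd.DataFrame,
                 max_displacement: float = 5.0) -> dict[int, int | None]:
    """Pair nuclei across two time points by mutual nearest centroids.

    Both inputs are quantification tables (one row per nucleus suffices; the
    first row per nucleus_id is used).  A pair forms only when each nucleus
    is the other's nearest neighbour and their distance is within
    ``max_displacement`` pixels; unmatched nuclei map to None.
    """
    a = records_a.drop_duplicates("nucleus_id")
    b = records_b.drop_duplicates("nucleus_id")
    ids_a = a["nucleus_id"].to_numpy()
    ids_b = b["nucleus_id"].to_numpy()
    if len(ids_a) == 0 or len(ids_b) == 0:
        return {int(i): None for i in ids_a}
    ca = a[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
    cb = b[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    nearest_b = d.argmin(axis=1)
    nearest_a = d.argmin(axis=0)
    pairing: dict[int, int | None] = {}
    for i, ia in enumerate(ids_a):
        j = nearest_b[i]
        mutual = nearest_a[j] == i and d[i, j] <= max_displacement
        pairing[int(ia)] = int(ids_b[j]) if mutual else None
    return pairing


def compute_fold_change(table: pd.DataFrame, group_cols: tuple[str, ...] = ("channel",),
                        replicate_col: str = "gemma_id", time_col: str = "time_h",
                        value_col: str = "intensity") -> pd.DataFrame:
    """Summarize per-nucleus tables into fold change relative to t = 0.

    Per image (replicate x time), nucleus intensities are averaged (the mean
    keeps the summary robust to nucleus-count differences between images);
    per replicate, FC(t) = mean(t) / mean(0); fc_mean and fc_se are the mean
    and standard error over replicates.  FC at time 0 is exactly 1 with zero
    SE by construction.  Images with fewer than 30 nuclei are flagged via
    ``low_n_warning`` and a warning.
    """
    group_cols = list(group_cols)
    per_image = (table.groupby(group_cols + [replicate_col, time_col])[value_col]
                 .agg(["mean", "count"]).reset_index()
                 .rename(columns={"mean": "image_mean", "count": "n_nuclei"}))
    out_rows = []
    for keys, grp in per_image.groupby(group_cols + [replicate_col]):
        grp = grp.sort_values(time_col)
        if 0.0 not in grp[time_col].values:
            raise ValueError(f"replicate {keys!r} has no t = 0 reference image")
        ref = float(grp.loc[grp[time_col] == 0.0, "image_mean"].iloc[0])
        if ref == 0:
            raise ValueError(f"replicate {keys!r} has zero mean intensity at t = 0")
        grp = grp.assign(fc=grp["image_mean"] / ref)
        out_rows.append(grp)
    per_rep = pd.concat(out_rows, ignore_index=True)

    def _summ(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        se = float(g["fc"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        min_nuclei = int(g["n_nuclei"].min())
        return pd.Series({"fc_mean": float(g["fc"].mean()), "fc_se": se,
                          "n_replicates": n,
                          "n_nuclei_per_image": min_nuclei,
                          "low_n_warning": min_nuclei < MIN_NUCLEI_PER_IMAGE})

    summary = (per_rep.groupby(group_cols + [time_col])
               .apply(_summ, include_groups=False).reset_index())
    if summary["low_n_warning"].any():
        warnings.warn("some images have fewer than 30 quantified nuclei", stacklevel=2)
    return summary
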