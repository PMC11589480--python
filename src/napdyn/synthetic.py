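"""Synthetic inputs with known ground truth for every pipeline stage.

The real study images fluorescent-protein knockins in Marchantia gemmae and
sequences germinating gemmae; neither microscope data nor the sequencing
archive is needed to exercise the pipeline.  Each generator here emulates one
input class — two-channel nuclei image stacks, auxin-induced decay traces,
replicate ARF fold-change time courses, and DESeq2-style expression tables —
and always returns its ground truth alongside the data.

Every generator is a pure function of its arguments including the seed:
identical calls are bitwise reproducible, and the ground truth never depends
on the seed (only noise realizations do).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import DecayTrace
from .params import load_arf_shapes

__all__ = [
    "SyntheticScene",
    "NoiseModel",
    "random_scene",
    "make_image_stack",
    "make_decay_trace",
    "make_arf_timecourse",
    "make_expression_table",
]


@dataclass(frozen=True)
class SyntheticScene:
    """Layout and ground truth of a synthetic two-channel nuclei image.

    ``true_intensity`` has shape (n_nuclei, n_channels) and holds the total
    integrated signal (photon-count scale, a.u.) each nucleus contributes to
    its channel.  Nuclei must be pairwise non-overlapping: centre distance
    greater than the sum of radii.
    """

    width: int
    height: int
    centroids: np.ndarray          # (n, 2) as (row, col), 0-based pixels
    radii: np.ndarray              # (n,) pixels
    true_intensity: np.ndarray     # (n, n_channels) a.u.
    background_level: float = 0.0  # a.u., uniform
    channel_names: tuple[str, ...] = ("mScarlet-I", "mNeonGreen")

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        r = np.atleast_1d(np.asarray(self.radii, dtype=float))
        ti = np.atleast_2d(np.asarray(self.true_intensity, dtype=float))
        if c.size == 0:
            c = c.reshape(0, 2)
            ti = ti.reshape(0, len(self.channel_names))
        object.__setattr__(self, "centroids", c)
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "true_intensity", ti)
        if c.shape[0] != r.shape[0] or ti.shape[0] != c.shape[0]:
            raise ValueError("centroids, radii and true_intensity disagree on nucleus count")
        if ti.shape[1] != len(self.channel_names):
            raise ValueError("true_intensity channel dimension does not match channel_names")
        if np.any(ti < 0) or self.background_level < 0 or np.any(r <= 0):
            raise ValueError("intensities and background must be >= 0 and radii > 0")
        # pairwise non-overlap: centre distance > sum of radii
        n = c.shape[0]
        if n > 1:
            d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
            rsum = r[:, None] + r[None, :]
            iu = np.triu_indices(n, k=1)
            if np.any(d[iu] <= rsum[iu]):
                raise ValueError("nuclei overlap: centre distance must exceed the sum of radii")

    @property
    def n_nuclei(self) -> int:
        return self.centroids.shape[0]


@dataclass(frozen=True)
class NoiseModel:
    """Camera-style noise: multiplicative lognormal, Poisson shot, Gaussian read.

    Stages apply in that order and are independently switchable; all
    parameters must be >= 0.  ``multiplicative_cv`` perturbs each nucleus's
    amplitude (per channel), emulating expression variability; shot noise
    acts on expected photon counts; read noise is additive per pixel.
    """

    read_noise_sd: float = 0.0
    shot_noise: bool = False
    multiplicative_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0 or self.multiplicative_cv < 0:
            raise ValueError("noise parameters must be >= 0")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multipliers with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def random_scene(n_nuclei: int = 10, width: int = 256, height: int = 256,
                 radius_range: tuple[float, float] = (5.0, 8.0),
                 intensity_range: tuple[float, float] = (8000.0, 30000.0),
                 background_level: float = 10.0,
                 channel_names: tuple[str, ...] = ("mScarlet-I", "mNeonGreen"),
                 seed: int = 0, max_tries: int = 10000) -> SyntheticScene:
    """Draw a non-overlapping scene by rejection sampling.

    Intensities are uniform per nucleus and channel on ``intensity_range``
    (photon-count scale: bright enough that integration error, not shot
    noise, limits recovery accuracy).
    """
    rng = np.random.default_rng(seed)
    margin = 3.0 * radius_range[1]
    centroids: list[np.ndarray] = []
    radii: list[float] = []
    tries = 0
    while len(centroids) < n_nuclei:
        if tries > max_tries:
            raise RuntimeError("could not place non-overlapping nuclei; lower n_nuclei or enlarge the image")
        tries += 1
        r = rng.uniform(*radius_range)
        c = rng.uniform([margin, margin], [height - margin, width - margin])
        # 3-sigma render supports reach 1.5 * radius; a 1.65 factor keeps
        # neighbouring blobs' rendered footprints disjoint with margin
        if all(np.linalg.norm(c - c0) > 1.65 * (r + r0) for c0, r0 in zip(centroids, radii)):
            centroids.append(c)
            radii.append(r)
    intensity = rng.uniform(*intensity_range, size=(n_nuclei, len(channel_names)))
    return SyntheticScene(width=width, height=height,
                          centroids=np.array(centroids).reshape(n_nuclei, 2),
                          radii=np.array(radii),
                          true_intensity=intensity,
                          background_level=background_level,
                          channel_names=channel_names)


def _gaussian_footprint(shape: tuple[int, int], centroid: np.ndarray, radius: float):
    """Discrete truncated Gaussian blob normalized to unit sum.

    sigma = radius / 2, truncated at 3 sigma; normalizing the discrete sum
    to exactly 1 makes the integrated-intensity oracle exact.
    """
    sigma = radius / 2.0
    cut = 3.0 * sigma
    r0 = max(int(np.floor(centroid[0] - cut)), 0)
    r1 = min(int(np.ceil(centroid[0] + cut)) + 1, shape[0])
    c0 = max(int(np.floor(centroid[1] - cut)), 0)
    c1 = min(int(np.ceil(centroid[1] + cut)) + 1, shape[1])
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    d2 = (rows - centroid[0]) ** 2 + (cols - centroid[1]) ** 2
    g = np.exp(-d2 / (2.0 * sigma * sigma))
    g[d2 > cut * cut] = 0.0
    g /= g.sum()
    return (slice(r0, r1), slice(c0, c1)), g


def make_image_stack(scene: SyntheticScene, noise: NoiseModel, n_z: int, seed: int
                     ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Render a scene into per-channel z-stacks plus a ground-truth table.

    Each nucleus is a truncated Gaussian blob (sigma = radius/2) placed
    entirely in one z-plane (round-robin over planes, deterministic in the
    scene alone), so a maximum-intensity projection over z retains each
    nucleus's full integrated signal on a uniform background.

    Returns
    -------
    stacks
        Mapping channel name -> float array of shape (n_z, height, width).
    truth
        One row per nucleus and channel: nucleus_id, centroid, radius,
        z_plane, the noise-free integrated ``true_intensity`` and the
        ``rendered_intensity`` actually placed in this realization (equal to
        ``true_intensity`` times the multiplicative noise draw).
    """
    if n_z < 1:
        raise ValueError("n_z must be >= 1")
    rng = np.random.default_rng(seed)
    shape = (scene.height, scene.width)
    stacks = {ch: np.full((n_z, *shape), float(scene.background_level))
              for ch in scene.channel_names}

    mult = _lognormal_factors(rng, noise.multiplicative_cv,
                              (scene.n_nuclei, len(scene.channel_names)))
    rows = []
    for i in range(scene.n_nuclei):
        z = i % n_z
        window, g = _gaussian_footprint(shape, scene.centroids[i], scene.radii[i])
        for j, ch in enumerate(scene.channel_names):
            stacks[ch][z][window] += scene.true_intensity[i, j] * mult[i, j] * g
            rows.append({"nucleus_id": i,
                         "centroid_row": scene.centroids[i, 0],
                         "centroid_col": scene.centroids[i, 1],
                         "radius_px": scene.radii[i],
                         "z_plane": z,
                         "channel": ch,
                         "true_intensity": scene.true_intensity[i, j],
                         "rendered_intensity": scene.true_intensity[i, j] * mult[i, j]})
    for ch in scene.channel_names:
        img = stacks[ch]
        if noise.shot_noise:
            img = rng.poisson(img).astype(float)
        if noise.read_noise_sd > 0:
            img = img + rng.normal(0.0, noise.read_noise_sd, size=img.shape)
        stacks[ch] = np.clip(img, 0.0, None)

    columns = ["nucleus_id", "centroid_row", "centroid_col", "radius_px",
               "z_plane", "channel", "true_intensity", "rendered_intensity"]
    truth = pd.DataFrame(rows, columns=columns)
    return stacks, truth


def make_decay_trace(half_life: float, duration: float, n_points: int,
                     noise_cv: float, plateau: float = 0.0, seed: int = 0,
                     label: str = "") -> DecayTrace:
    """Simulate a normalized fluorescence decay trace.

    The noise-free curve is ``(1 - plateau) * 2**(-t / half_life) + plateau``
    (value 1 at t = 0 by construction); each point is then perturbed by
    unit-mean multiplicative lognormal noise of the stated CV.  An infinite
    half-life gives the flat stabilized/bleaching control.
    """
    if not (half_life > 0):
        raise ValueError("half_life must be positive (np.inf for a flat control)")
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if not (0.0 <= plateau <= 1.0):
        raise ValueError("plateau must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_points)
    clean = plateau + (1.0 - plateau) * np.power(2.0, -t / half_life) \
        if np.isfinite(half_life) else np.ones_like(t)
    values = clean * _lognormal_factors(rng, noise_cv, t.shape)
    return DecayTrace(times=t, values=values, label=label)


def _decline_fc(shape, t: np.ndarray) -> np.ndarray:
    """Evaluate an exponential-to-plateau decline shape; fc(0) = 1."""
    if callable(shape):
        return np.asarray(shape(t), dtype=float)
    plateau, tau = float(shape["plateau"]), float(shape["tau_h"])
    return plateau + (1.0 - plateau) * np.exp(-t / tau)


def make_arf_timecourse(base_profiles: dict | None = None,
                        times: np.ndarray | list = (0.0, 4.0, 8.0, 12.0, 24.0),
                        n_replicates: int = 3, rep_cv: float = 0.1,
                        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate replicate per-ARF nuclear fold-change time courses.

    Fold change is relative to the dormant state, so FC(0) is exactly 1 for
    every replicate; later points carry multiplicative lognormal replicate
    noise of CV ``rep_cv``.  ``base_profiles`` maps ARF name to either a
    callable fc(t) or a ``{"plateau": p, "tau_h": tau}`` decline shape; the
    default is the packaged per-ARF shape file (ARF1 and ARF2 decline, ARF2
    faster and to near zero, ARF3 flat).

    Returns the long-format table (arf, replicate, time_h, fc) and the
    noise-free ground truth in the same format.
    """
    t = np.asarray(times, dtype=float)
    if t[0] != 0.0:
        raise ValueError("times must include 0 as the first point")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if base_profiles is None:
        base_profiles = load_arf_shapes()
    rng = np.random.default_rng(seed)
    obs_rows, truth_rows = [], []
    for arf in base_profiles:
        clean = _decline_fc(base_profiles[arf], t)
        for rep in range(1, n_replicates + 1):
            fc = clean * _lognormal_factors(rng, rep_cv, t.shape)
            fc[0] = 1.0  # FC at t=0 defines the reference: exactly 1
            for ti, (f, ftrue) in zip(t, zip(fc, clean)):
                obs_rows.append({"arf": arf, "replicate": rep, "time_h": ti, "fc": f})
                truth_rows.append({"arf": arf, "replicate": rep, "time_h": ti, "fc": ftrue})
    return pd.DataFrame(obs_rows), pd.DataFrame(truth_rows)


def make_expression_table(n_genes: int, n_de_up: int = 0, n_de_down: int = 0,
                          lfc_magnitude: float = 2.5, n_low_count: int = 0,
                          seed: int = 0, count_threshold: int = 45
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a DESeq2-results-style table with planted regulation classes.

    Exactly ``n_de_up``/``n_de_down`` genes satisfy the differential-
    expression rule (|log2FC| > 1 and padj < 0.05 — when ``lfc_magnitude``
    itself exceeds 1) among genes passing the total-count filter, and
    exactly ``n_low_count`` genes fall below the count threshold.  Low-count
    genes are given DE-like statistics so the count filter is load-bearing.

    Returns the table (gene_id, total_count, log2fc, padj) and a parallel
    ground-truth label Series: "up" | "down" | "low_count" | "null".
    """
    if n_de_up + n_de_down + n_low_count > n_genes:
        raise ValueError("planted classes exceed n_genes")
    rng = np.random.default_rng(seed)
    labels = np.array(["null"] * n_genes, dtype=object)
    labels[:n_de_up] = "up"
    labels[n_de_up:n_de_up + n_de_down] = "down"
    labels[n_de_up + n_de_down:n_de_up + n_de_down + n_low_count] = "low_count"
    rng.shuffle(labels)

    total_count = rng.integers(count_threshold, 5000, size=n_genes)
    log2fc = rng.normal(0.0, 0.3, size=n_genes).clip(-0.9, 0.9)
    padj = rng.uniform(0.1, 1.0, size=n_genes)

    for sign, cls in ((+1.0, "up"), (-1.0, "down")):
        idx = labels == cls
        k = idx.sum()
        log2fc[idx] = sign * lfc_magnitude * (1.0 + 0.2 * rng.random(k))
        padj[idx] = 10.0 ** -rng.uniform(3.0, 8.0, size=k)
    low = labels == "low_count"
    total_count[low] = rng.integers(0, count_threshold, size=low.sum())
    # DE-like stats on low-count genes: only the count filter removes them
    log2fc[low] = rng.choice([-1.0, 1.0], size=low.sum()) * lfc_magnitude * 1.1
    padj[low] = 1e-4

    table = pd.DataFrame({
        "gene_id": [f"Mp_g{i:05d}" for i in range(n_genes)],
        "total_count": total_count.astype(int),
        "log2fc": log2fc,
        "padj": padj,
    })
    return table, pd.Series(labels, index=table["gene_id"], name="truth")
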