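"""Seeded synthetic data with exact ground truth for every pipeline stage.

Cells are rendered as filled ellipses (actin/cytoskeleton channel), each
containing a smaller concentric ellipse (nucleus channel).  Ellipses carry
analytic ground truth for the two shape factors used downstream:

* nuclear circularity  C_N = 4*pi*A / P**2  (depends only on the axis ratio),
* cellular aspect ratio A_R = d_min / d_max.

Shape-factor targets are sampled from truncated normals whose *truncated*
mean is solved to equal the requested target, so sample means recover the
programmed values by construction.  Wound-healing series are textured cell
lawns flanking a smooth, rectangular cell-free gap that narrows at a fixed
edge velocity per side.  Marker tables (Western-blot band intensities and
qPCR Ct values) are generated so that noise-free tables round-trip exactly
through the quantification stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import ellipe
from scipy.stats import truncnorm

from .errors import PlacementError, ValidationError

PHENOTYPES = ("epithelial", "hybrid", "mesenchymal")

# Morphometry of untreated breast-cancer lines used as named presets:
# (A_R mean, A_R sd, C_N mean, C_N sd, cluster fraction).
PHENOTYPE_PRESETS: dict[str, tuple[float, float, float, float, float]] = {
    "epithelial": (0.707, 0.128, 0.808, 0.053, 0.7),
    "hybrid": (0.683, 0.170, 0.877, 0.046, 0.4),
    "mesenchymal": (0.240, 0.157, 0.735, 0.101, 0.0),
}

AR_CLIP = (0.05, 1.0)  # truncation interval for aspect-ratio sampling
CN_CLIP = (0.20, 1.0)  # truncation interval for circularity sampling

_BACKGROUND = 120.0
_CELL_LEVEL = 8000.0
_NUCLEUS_LEVEL = 12000.0


def ellipse_perimeter(a_semi: float, b_semi: float) -> float:
    """Exact perimeter of an ellipse with semi-axes ``a_semi >= b_semi``.

    Uses the complete elliptic integral of the second kind,
    P = 4 a E(m) with m = 1 - (b/a)^2.
    """
    if a_semi <= 0 or b_semi <= 0:
        raise ValidationError("ellipse semi-axes must be positive")
    a, b = max(a_semi, b_semi), min(a_semi, b_semi)
    return float(4.0 * a * ellipe(1.0 - (b / a) ** 2))


def ellipse_circularity(axis_ratio: float) -> float:
    """Circularity 4*pi*A/P^2 of an ellipse as a function of b/a alone."""
    if not 0 < axis_ratio <= 1:
        raise ValidationError("axis ratio must be in (0, 1]")
    a, b = 1.0, axis_ratio
    area = math.pi * a * b
    return 4.0 * math.pi * area / ellipse_perimeter(a, b) ** 2


def axis_ratio_for_circularity(c_n: float) -> float:
    """Invert :func:`ellipse_circularity` (monotone on (0, 1])."""
    if not 0 < c_n <= 1:
        raise ValidationError("circularity must be in (0, 1]")
    if c_n >= ellipse_circularity(1.0 - 1e-12):
        return 1.0
    return float(brentq(lambda q: ellipse_circularity(q) - c_n, 1e-4, 1.0))


def _targeted_truncnorm(mean: float, sd: float, low: float, high: float):
    """Truncated normal on [low, high] whose truncated mean equals ``mean``.

    The underlying location parameter is solved numerically; the returned
    frozen distribution therefore recovers ``mean`` in expectation even when
    mean +/- 3 sd leaves the interval (as it does for spindle-shaped cells).
    """
    if not low < mean <= high:
        raise ValidationError(
            f"target mean {mean} outside sampling interval ({low}, {high}]"
        )
    if sd < 0:
        raise ValidationError("target sd must be >= 0")
    if sd == 0:
        return None  # caller emits the constant

    def _mean_gap(mu: float) -> float:
        a, b = (low - mu) / sd, (high - mu) / sd
        return truncnorm.mean(a, b, loc=mu, scale=sd) - mean

    mu = brentq(_mean_gap, low - 8 * sd, high + 8 * sd)
    a, b = (low - mu) / sd, (high - mu) / sd
    return truncnorm(a, b, loc=mu, scale=sd)


def _sample_targeted(rng, n, mean, sd, low, high) -> np.ndarray:
    dist = _targeted_truncnorm(mean, sd, low, high)
    if dist is None:
        return np.full(n, mean)
    return dist.rvs(size=n, random_state=rng)


@dataclass(frozen=True)
class CellSceneSpec:
    """Parameters of one synthetic two-channel (nuclei + actin) scene."""

    n_cells: int
    phenotype: str = "epithelial"
    target_ar_mean: float | None = None
    target_ar_sd: float | None = None
    target_cn_mean: float | None = None
    target_cn_sd: float | None = None
    cluster_fraction: float | None = None
    image_size_px: tuple[int, int] = (1024, 1024)
    cell_radius_px: float = 28.0
    cell_radius_sd_px: float = 3.0
    nucleus_scale: float = 0.45
    noise_sd: float = 50.0
    seed: int = 0

    def resolved(self) -> "CellSceneSpec":
        """Fill target distribution fields from the phenotype preset."""
        if self.phenotype not in PHENOTYPES:
            raise ValidationError(f"unknown phenotype {self.phenotype!r}")
        ar_m, ar_s, cn_m, cn_s, cf = PHENOTYPE_PRESETS[self.phenotype]
        resolved = CellSceneSpec(
            n_cells=self.n_cells,
            phenotype=self.phenotype,
            target_ar_mean=self.target_ar_mean if self.target_ar_mean is not None else ar_m,
            target_ar_sd=self.target_ar_sd if self.target_ar_sd is not None else ar_s,
            target_cn_mean=self.target_cn_mean if self.target_cn_mean is not None else cn_m,
            target_cn_sd=self.target_cn_sd if self.target_cn_sd is not None else cn_s,
            cluster_fraction=self.cluster_fraction if self.cluster_fraction is not None else cf,
            image_size_px=tuple(self.image_size_px),
            cell_radius_px=self.cell_radius_px,
            cell_radius_sd_px=self.cell_radius_sd_px,
            nucleus_scale=self.nucleus_scale,
            noise_sd=self.noise_sd,
            seed=self.seed,
        )
        resolved.validate()
        return resolved

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if len(self.image_size_px) != 2 or min(self.image_size_px) < 32:
            raise ValidationError("image_size_px must be (height, width), each >= 32")
        for name, val, (lo, hi) in (
            ("target_ar_mean", self.target_ar_mean, AR_CLIP),
            ("target_cn_mean", self.target_cn_mean, CN_CLIP),
        ):
            if not lo < val <= hi:
                raise ValidationError(f"{name}={val} outside ({lo}, {hi}]")
        if self.target_ar_sd < 0 or self.target_cn_sd < 0:
            raise ValidationError("target sds must be >= 0")
        if not 0 <= self.cluster_fraction <= 1:
            raise ValidationError("cluster_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.cell_radius_px <= 2:
            raise ValidationError("cell_radius_px must exceed 2 px")


def generate_cell_scene(
    spec: CellSceneSpec, max_retries: int = 2000
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a two-channel scene and its analytic ground-truth table.

    Returns ``(nuclei_channel, actin_channel, ground_truth)`` where the
    channels are ``uint16`` arrays of ``spec.image_size_px`` and the table
    has one row per cell with true axes, areas, perimeters and shape factors.
    Identical specs (including seed) produce bit-identical outputs.
    """
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px

    n = spec.n_cells
    ar = _sample_targeted(rng, n, spec.target_ar_mean, spec.target_ar_sd, *AR_CLIP)
    cn = _sample_targeted(rng, n, spec.target_cn_mean, spec.target_cn_sd, *CN_CLIP)
    radii = np.clip(
        rng.normal(spec.cell_radius_px, spec.cell_radius_sd_px, n),
        4.0,
        None,
    )
    thetas = rng.uniform(0, math.pi, n)

    # equal-area parameterization: semi-axes a = r/sqrt(q), b = r*sqrt(q)
    a_cell = radii / np.sqrt(ar)
    b_cell = radii * np.sqrt(ar)
    bound = a_cell  # bounding radius per cell

    n_clustered = int(round(spec.cluster_fraction * n))
    centers, thetas = _place_cells(
        rng, h, w, a_cell, b_cell, thetas, n_clustered, max_retries
    )

    nuc_q = np.array([axis_ratio_for_circularity(c) for c in cn]) if n else np.empty(0)
    r_nuc = radii * spec.nucleus_scale
    a_nuc = r_nuc / np.sqrt(nuc_q)
    b_nuc = r_nuc * np.sqrt(nuc_q)

    actin = np.full((h, w), _BACKGROUND)
    nuclei = np.full((h, w), _BACKGROUND)
    from skimage.draw import ellipse as draw_ellipse

    rows = []
    for i in range(n):
        cy, cx = centers[i]
        rr, cc = draw_ellipse(cy, cx, a_cell[i], b_cell[i], shape=(h, w), rotation=thetas[i])
        actin[rr, cc] = _CELL_LEVEL
        rr, cc = draw_ellipse(cy, cx, a_nuc[i], b_nuc[i], shape=(h, w), rotation=thetas[i])
        nuclei[rr, cc] = _NUCLEUS_LEVEL
        rows.append(
            {
                "cell_id": i,
                "center_row": cy,
                "center_col": cx,
                "orientation_rad": thetas[i],
                "cell_dmax_px": 2 * a_cell[i],
                "cell_dmin_px": 2 * b_cell[i],
                "cell_ar_true": ar[i],
                "cell_area_px2": math.pi * a_cell[i] * b_cell[i],
                "nuc_dmax_px": 2 * a_nuc[i],
                "nuc_dmin_px": 2 * b_nuc[i],
                "nuc_area_px2": math.pi * a_nuc[i] * b_nuc[i],
                "nuc_perimeter_px": ellipse_perimeter(a_nuc[i], b_nuc[i]),
                "nuc_cn_true": cn[i],
                "clustered": i < n_clustered,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "center_row", "center_col", "orientation_rad",
            "cell_dmax_px", "cell_dmin_px", "cell_ar_true", "cell_area_px2",
            "nuc_dmax_px", "nuc_dmin_px", "nuc_area_px2", "nuc_perimeter_px",
            "nuc_cn_true", "clustered",
        ],
    )

    if spec.noise_sd > 0:
        nuclei = nuclei + rng.normal(0, spec.noise_sd, (h, w))
        actin = actin + rng.normal(0, spec.noise_sd, (h, w))
    nuclei = np.clip(nuclei, 0, 65535).astype(np.uint16)
    actin = np.clip(actin, 0, 65535).astype(np.uint16)
    return nuclei, actin, truth


def _place_cells(rng, h, w, a_cell, b_cell, thetas, n_clustered, max_retries):
    """Clustered near-contact placement + uniform non-overlapping singles.

    Overlap is checked against a rasterized occupancy bitmap with a 2 px
    clearance (a bounding-circle check would reject feasible layouts of
    spindle-shaped cells).  Cluster members are proposed at bounding-circle
    contact distance plus a 3 px gap from a random earlier member, which
    keeps clusters visually contiguous while guaranteeing disjoint masks.
    """
    from skimage.draw import ellipse as draw_ellipse

    n = len(a_cell)
    centers: list[tuple[float, float]] = []
    placed_thetas = np.array(thetas, float)
    occupancy = np.zeros((h, w), bool)
    # clearance must survive the segmentation's 1 px Gaussian smoothing
    margin = 4.0

    for i in range(n):
        a, b = a_cell[i], b_cell[i]
        placed = False
        for attempt in range(max_retries):
            # re-draw orientation on later attempts to ease dense packing
            th = thetas[i] if attempt == 0 else rng.uniform(0, math.pi)
            if 0 < i < n_clustered:
                j = int(rng.integers(0, i))
                ang = rng.uniform(0, 2 * math.pi)
                d = a + a_cell[j] + 3.0
                cy = centers[j][0] + d * math.sin(ang)
                cx = centers[j][1] + d * math.cos(ang)
            else:
                if h - 2 * (a + 2) <= 0 or w - 2 * (a + 2) <= 0:
                    raise PlacementError(
                        f"cell with bounding radius {a:.0f} px does not fit in "
                        f"a {h}x{w} image"
                    )
                cy = rng.uniform(a + 2, h - a - 2)
                cx = rng.uniform(a + 2, w - a - 2)
            if not (a + 2 <= cy <= h - a - 2 and a + 2 <= cx <= w - a - 2):
                continue
            rr, cc = draw_ellipse(cy, cx, a + margin, b + margin, rotation=th)
            if rr.min() < 0 or cc.min() < 0 or rr.max() >= h or cc.max() >= w:
                continue
            if occupancy[rr, cc].any():
                continue
            rr0, cc0 = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=th)
            occupancy[rr0, cc0] = True
            centers.append((cy, cx))
            placed_thetas[i] = th
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {i} of {n} after {max_retries} retries; "
                "increase image_size_px or reduce n_cells"
            )
    return centers, placed_thetas


@dataclass(frozen=True)
class WoundSpec:
    """Geometry and texture of a synthetic scratch-assay time series."""

    frame_size_px: tuple[int, int] = (400, 600)
    initial_gap_width_px: float = 280.0
    edge_velocity_px_per_h: float = 5.0
    timepoints_h: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0, 32.0)
    cell_texture_grain_px: float = 2.0
    texture_sd: float = 300.0
    lawn_level: float = 1000.0
    noise_sd: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.frame_size_px
        if min(h, w) < 16:
            raise ValidationError("frame_size_px too small")
        if not 0 < self.initial_gap_width_px < w:
            raise ValidationError("initial gap must be narrower than the frame")
        if self.edge_velocity_px_per_h < 0:
            raise ValidationError("edge velocity must be >= 0")
        t = np.asarray(self.timepoints_h, float)
        if t.size < 1 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValidationError("timepoints must start at 0 and strictly increase")
        if self.noise_sd < 0 or self.texture_sd < 0:
            raise ValidationError("noise/texture sds must be >= 0")


def generate_wound_series(spec: WoundSpec) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render scratch-assay frames plus a table of true gap areas.

    The gap is a centered vertical strip whose width shrinks by
    ``2 * edge_velocity * dt`` per interval (one front per side), floored at
    zero.  The lawn is smoothed speckle; the gap carries only sensor noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_size_px
    frames, rows = [], []
    for k, t in enumerate(spec.timepoints_h):
        width = max(0.0, spec.initial_gap_width_px - 2.0 * spec.edge_velocity_px_per_h * t)
        gap_px = int(round(width))
        tex = gaussian_filter(rng.normal(0, 1, (h, w)), spec.cell_texture_grain_px)
        tex = tex / max(tex.std(), 1e-12) * spec.texture_sd
        img = spec.lawn_level + tex
        c0 = (w - gap_px) // 2
        if gap_px > 0:
            img[:, c0 : c0 + gap_px] = spec.lawn_level
        if spec.noise_sd > 0:
            img = img + rng.normal(0, spec.noise_sd, (h, w))
        frames.append(np.clip(img, 0, 65535).astype(np.uint16))
        rows.append({"frame": k, "time_h": t, "true_gap_area_px2": float(gap_px) * h})
    return frames, pd.DataFrame(rows)


def generate_marker_intensities(
    true_folds: Mapping[str, tuple[float, float]],
    noise_cv: float = 0.0,
    seed: int = 0,
    control: str = "control",
    baselines: tuple[float, float, float] = (1200.0, 800.0, 1500.0),
) -> pd.DataFrame:
    """Band-intensity table (condition, cdh1, vim, gapdh) with programmed folds.

    ``true_folds`` maps condition -> (CDH1 fold, VIM fold) relative to the
    control condition, which is always emitted with folds (1, 1).  Noise is
    multiplicative lognormal with the given coefficient of variation and unit
    mean; with ``noise_cv=0`` downstream normalization + fold change recovers
    the programmed folds exactly.
    """
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    for cond, (fc, fv) in true_folds.items():
        if fc < 0 or fv < 0:
            raise ValidationError(f"negative fold for condition {cond!r}")
    c0, v0, g0 = baselines
    if min(c0, v0, g0) <= 0:
        raise ValidationError("baseline intensities must be positive")

    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(noise_cv**2))

    def noise():
        if noise_cv == 0:
            return 1.0
        return float(rng.lognormal(-(sigma**2) / 2.0, sigma))

    rows = [{"condition": control, "cdh1": c0 * noise(), "vim": v0 * noise(), "gapdh": g0 * noise()}]
    for cond, (fc, fv) in true_folds.items():
        if cond == control:
            continue
        rows.append(
            {
                "condition": cond,
                "cdh1": c0 * fc * noise(),
                "vim": v0 * fv * noise(),
                "gapdh": g0 * noise(),
            }
        )
    return pd.DataFrame(rows, columns=["condition", "cdh1", "vim", "gapdh"])


def generate_ct_table(
    true_delta_cts: Mapping[str, Mapping[str, float]],
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    housekeeper: str = "GAPDH",
    housekeeper_ct: float = 18.0,
) -> pd.DataFrame:
    """qPCR Ct table (sample, target, ct, housekeeper, housekeeper_ct).

    ``true_delta_cts`` maps sample -> {target: delta-Ct vs the housekeeper}.
    Additive Gaussian noise on each Ct; the noise-free table reproduces the
    programmed delta-Ct values exactly under ``relative_expression``.
    """
    if ct_noise_sd < 0:
        raise ValidationError("ct_noise_sd must be >= 0")
    if not housekeeper:
        raise ValidationError("housekeeper name must be provided")
    rng = np.random.default_rng(seed)

    def jitter():
        return float(rng.normal(0, ct_noise_sd)) if ct_noise_sd > 0 else 0.0

    rows = []
    for sample, targets in true_delta_cts.items():
        hk_ct = housekeeper_ct + jitter()
        for target, dct in targets.items():
            rows.append(
                {
                    "sample": sample,
                    "target": target,
                    "ct": hk_ct + float(dct) + jitter(),
                    "housekeeper": housekeeper,
                    "housekeeper_ct": hk_ct,
                }
            )
    return pd.DataFrame(rows, columns=["sample", "target", "ct", "housekeeper", "housekeeper_ct"])
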