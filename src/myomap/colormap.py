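"""Attenuation-normalized deviation maps of the left-ventricular myocardium.

On contrast-enhanced, ECG-gated arterial-phase CT angiography, ischemic or
infarcted myocardium is hypoattenuating relative to normally perfused muscle.
The deviation map makes this contrast explicit and comparable across scans:
for every voxel inside a myocardium mask, the mean myocardial attenuation is
subtracted, and the residual is divided by a quantile-trimmed ("robust")
measure of the intra-myocardial attenuation spread.

Because both the subtracted mean and the divisor are estimated from the same
myocardium, global shifts in absolute attenuation (tube voltage, contrast
timing) cancel out; the map is a *relative* quantity.  Trimming to the
central 10th-90th quantile range before computing the spread protects the
divisor from single-voxel outliers such as calcifications or beam-hardening
streaks.

Units: with ``normalizer="variance"`` the map carries units of HU^-1 (the
divisor is a variance, HU^2); with ``normalizer="sd"`` the map is the usual
dimensionless z-score.  The variance form is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "CTVolume",
    "ColormapParams",
    "DeviationMap",
    "RobustNorm",
    "LesionContrast",
    "robust_norm",
    "compute_deviation_map",
    "render_overlay",
    "lesion_contrast",
]

#: The two "yes"/"no" sides of a diverging overlay.  Negative deviations
#: (hypoattenuation, the finding of interest) render blue, positive red.
_BLUE = np.array([0.0, 0.0, 1.0])
_RED = np.array([1.0, 0.0, 0.0])


@dataclass
class CTVolume:
    """A 3-D CT attenuation volume in Hounsfield units.

    Parameters
    ----------
    data
        3-D array of attenuation values (HU).
    spacing
        Voxel edge lengths in mm per axis.
    affine
        Optional 4x4 voxel-to-world affine, carried through unchanged so
        that maps written back to disk stay aligned with the source scan.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite attenuation values")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid voxel spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass(frozen=True)
class ColormapParams:
    """Parameters of the deviation map.

    ``q_low``/``q_high`` bound the quantile trim applied before the spread
    is estimated (defaults: central 10th-90th quantile range).  The trim is
    inclusive of both quantile values, and quantiles are computed with the
    standard linear-interpolation definition.

    ``normalizer`` selects the divisor: the trimmed population ``variance``
    (default, map units HU^-1) or its square root ``sd`` (dimensionless).

    ``clip`` is the symmetric display clip used only by :func:`render_overlay`,
    in map units.  ``None`` defers to a default equivalent to +/-3 standard
    deviations regardless of normalizer.
    """

    q_low: float = 0.10
    q_high: float = 0.90
    normalizer: str = "variance"
    clip: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_low < self.q_high <= 1.0):
            raise ValueError(
                f"require 0 <= q_low < q_high <= 1, got ({self.q_low}, {self.q_high})"
            )
        if self.normalizer not in ("variance", "sd"):
            raise ValueError(f"normalizer must be 'variance' or 'sd', got {self.normalizer!r}")
        if self.clip is not None and self.clip <= 0:
            raise ValueError("clip must be positive")


class RobustNorm(NamedTuple):
    """Result of the quantile-trimmed spread estimate.

    ``degenerate`` is True when fewer than two values survived the trim, in
    which case ``value`` is reported as 0 and downstream maps fall back to
    all-zero output rather than dividing by an unusable estimate.
    """

    value: float
    degenerate: bool
    n_retained: int


@dataclass
class DeviationMap:
    """Per-voxel normalized attenuation deviation, defined inside a mask.

    Out-of-mask voxels carry NaN, deliberately distinct from 0 so that a
    renderer can tell "zero deviation" apart from "not myocardium".
    """

    data: np.ndarray
    mask: np.ndarray
    mu: float
    norm: RobustNorm
    params: ColormapParams
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    @property
    def in_mask(self) -> np.ndarray:
        """The map values inside the myocardium, as a flat array."""
        return self.data[self.mask]


class LesionContrast(NamedTuple):
    in_lesion: float
    remote: float
    separation: float


def robust_norm(values: Sequence[float] | np.ndarray, params: ColormapParams | None = None) -> RobustNorm:
    """Quantile-trimmed population variance (or SD) of a value collection.

    Values lying within the closed interval ``[Q(q_low), Q(q_high)]`` are
    retained; the population (divide-by-n) variance of the retained values
    is returned, or its square root under ``normalizer="sd"``.  With fewer
    than two retained values the estimate is degenerate and reported as 0.
    """
    params = params or ColormapParams()
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError(f"need at least 2 values, got {v.size}")
    lo, hi = np.quantile(v, [params.q_low, params.q_high])
    kept = v[(v >= lo) & (v <= hi)]
    if kept.size < 2:
        return RobustNorm(0.0, True, int(kept.size))
    var = float(kept.var())  # population variance, ddof=0
    value = var if params.normalizer == "variance" else float(np.sqrt(var))
    return RobustNorm(value, False, int(kept.size))


def compute_deviation_map(
    volume: CTVolume | np.ndarray,
    mask: np.ndarray,
    params: ColormapParams | None = None,
) -> DeviationMap:
    """Compute the normalized myocardial deviation map.

    For each voxel v inside the mask::

        map(v) = (HU(v) - mean_in_mask) / robust_norm(in_mask values)

    The subtracted mean is taken over *all* in-mask voxels (not only the
    trimmed subset), so the in-mask map mean is exactly zero.  If the robust
    norm is degenerate or zero (constant myocardium), the map is all zeros
    inside the mask and a warning is emitted; out-of-mask voxels are NaN.
    """
    params = params or ColormapParams()
    if not isinstance(volume, CTVolume):
        volume = CTVolume(np.asarray(volume))
    mask = np.asarray(mask).astype(bool)
    if mask.shape != volume.shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume shape {volume.shape}")
    if not mask.any():
        raise ValueError("mask is empty")

    vals = volume.data[mask].astype(float)
    # Anchor at the in-mask minimum before any reduction: the anchored
    # values are unchanged by a global HU shift (exactly so for integer
    # HU), which makes the map's shift invariance hold bit-for-bit rather
    # than only up to floating-point rounding of the mean.
    anchor = float(vals.min())
    w = vals - anchor
    mu_w = float(w.mean())
    mu = mu_w + anchor
    norm = robust_norm(w, params)

    out = np.full(volume.shape, np.nan, dtype=float)
    if norm.degenerate or norm.value == 0.0:
        warnings.warn(
            "degenerate robust norm (zero spread inside the mask); deviation map set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        out[mask] = 0.0
    else:
        out[mask] = (w - mu_w) / norm.value
    return DeviationMap(
        data=out,
        mask=mask,
        mu=mu,
        norm=norm,
        params=params,
        spacing=volume.spacing,
        affine=volume.affine,
    )


def default_clip(map_: DeviationMap) -> float:
    """Display clip equivalent to +/-3 SD of the trimmed attenuation values.

    Under sd normalization a deviation of 3 map units is 3 SDs; under
    variance normalization the same attenuation deviation is 3/SD map units.
    """
    if map_.params.normalizer == "sd":
        return 3.0
    if map_.norm.value <= 0:
        return 1.0
    return 3.0 / float(np.sqrt(map_.norm.value))


def render_overlay(
    volume: CTVolume | np.ndarray,
    map_: DeviationMap,
    slice_index: int,
    axis: int = 2,
    params: ColormapParams | None = None,
    window: tuple[float, float] = (-150.0, 450.0),
    alpha: float = 0.8,
) -> np.ndarray:
    """Render a grayscale CT slice with a signed blue/red deviation overlay.

    Negative deviations (hypoattenuation) are blue, positive red, zero is
    fully transparent; overlay opacity ramps linearly with |value| up to the
    symmetric clip.  Returns an (H, W, 3) float RGB array in [0, 1].
    """
    if not isinstance(volume, CTVolume):
        volume = CTVolume(np.asarray(volume))
    if volume.shape != map_.data.shape:
        raise ValueError("volume and map are on different grids")
    if not 0 <= axis <= 2:
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    if not 0 <= slice_index < volume.shape[axis]:
        raise ValueError(
            f"slice {slice_index} outside volume extent {volume.shape[axis]} on axis {axis}"
        )
    mask_slice = np.take(map_.mask, slice_index, axis=axis)
    if not mask_slice.any():
        raise ValueError(f"slice {slice_index} does not intersect the myocardium mask")

    params = params or map_.params
    clip = params.clip if params.clip is not None else default_clip(map_)

    ct = np.take(volume.data, slice_index, axis=axis).astype(float)
    lo, hi = window
    gray = np.clip((ct - lo) / (hi - lo), 0.0, 1.0)
    rgb = np.repeat(gray[..., None], 3, axis=-1)

    v = np.take(map_.data, slice_index, axis=axis)
    defined = np.isfinite(v)
    vv = np.where(defined, v, 0.0)
    a = np.where(defined, np.minimum(np.abs(vv) / clip, 1.0) * alpha, 0.0)[..., None]
    color = np.where(vv[..., None] > 0, _RED, _BLUE)
    return rgb * (1.0 - a) + color * a


def save_overlay(image: np.ndarray, path) -> None:
    """Write a rendered overlay to a PNG file."""
    import matplotlib.image

    matplotlib.image.imsave(path, np.clip(image, 0.0, 1.0))


def lesion_contrast(map_: DeviationMap, lesion_mask: np.ndarray) -> LesionContrast:
    """Mean map value inside a lesion vs. the remote (non-lesion) myocardium.

    ``separation = in_lesion - remote``; strongly negative separation means
    the map highlights the lesion as hypoattenuating, which is the behavior
    the overlay is designed to surface.
    """
    lesion_mask = np.asarray(lesion_mask).astype(bool)
    if lesion_mask.shape != map_.data.shape:
        raise ValueError("lesion mask is on a different grid than the map")
    if not lesion_mask.any():
        raise ValueError("lesion mask is empty")
    if np.any(lesion_mask & ~map_.mask):
        raise ValueError("lesion mask extends outside the myocardium mask")
    remote_mask = map_.mask & ~lesion_mask
    if not remote_mask.any():
        raise ValueError("no remote myocardium left outside the lesion")
    in_lesion = float(map_.data[lesion_mask].mean())
    remote = float(map_.data[remote_mask].mean())
    return LesionContrast(in_lesion, remote, in_lesion - remote)
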