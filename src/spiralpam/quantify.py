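"""Image-quality metrics and vessel morphometry.

Resolution follows the edge-spread-function route used for optical-resolution
photoacoustic systems: an edge profile is fitted to a scaled error function,
whose derivative is a Gaussian line-spread function; the lateral resolution
is that Gaussian's FWHM.  Axial resolution is the FWHM of a Gaussian fitted
to the Hilbert envelope of a point-target A-scan, converted to distance with
the one-way speed of sound.

Vessel morphometry on a binary vascular mask:

    VAD = vessel area / imaging area              (area density)
    VSD = skeleton length / imaging area          (skeleton density, 1/m)
    VDI = vessel area / skeleton length           (mean diameter, m)
    VCI = perimeter^2 / (4 pi area)               (complexity; 1 for a disc)

so VDI * VSD == VAD holds identically.  Vessels are split into macro/micro
populations at a local diameter of 100 um (twice the Euclidean distance
transform sampled on the skeleton, propagated to each vessel pixel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .acquisition import AScan, AcquisitionSettings
from .reconstruction import MapImage, envelope

__all__ = [
    "GAUSSIAN_FWHM",
    "ResolutionResult",
    "VesselMetrics",
    "FrameSeries",
    "lateral_resolution",
    "axial_resolution",
    "snr_db",
    "vessel_mask",
    "vessel_metrics",
    "skeleton_length",
    "diameter_split",
    "timeseries_quantify",
]

#: FWHM of a unit-sigma Gaussian, 2*sqrt(2*ln 2)
GAUSSIAN_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class ResolutionResult:
    """Gaussian-model resolution: fwhm = 2*sqrt(2 ln 2) * sigma."""

    fwhm: float  # m
    fit_sigma: float  # m (lateral) or s (axial, before conversion)
    fit_rmse: float  # relative to fitted amplitude
    kind: str  # "lateral" | "axial"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")


@dataclass(frozen=True)
class VesselMetrics:
    vad: float  # dimensionless fraction
    vsd: float  # 1/m
    vdi: float  # m
    vci: float  # dimensionless

    def to_dict(self) -> dict:
        return {"vad": self.vad, "vsd": self.vsd, "vdi": self.vdi, "vci": self.vci}


@dataclass
class FrameSeries:
    """Per-frame vessel density and in-mask amplitude change (dB vs baseline)."""

    times: np.ndarray
    vessel_density: np.ndarray
    mean_amplitude_db: np.ndarray
    macro_density: np.ndarray | None = None
    micro_density: np.ndarray | None = None


def _esf(x, amplitude, x0, sigma, offset):
    from scipy.special import erf

    return offset + 0.5 * amplitude * (1.0 + erf((x - x0) / (sigma * math.sqrt(2.0))))


def lateral_resolution(
    image: MapImage,
    edge_roi,
    pixel_size: float,
    profile_axis: int = 0,
    rmse_threshold: float = 0.15,
) -> ResolutionResult:
    """Lateral resolution from an edge region of a MAP image.

    ``edge_roi`` is a pair of slices selecting a region crossed by one
    straight edge perpendicular to ``profile_axis``.  Rows along the other
    axis are averaged into a single profile, fitted to a scaled-and-offset
    error-function ESF; the derived Gaussian LSF's FWHM is returned in
    meters.  Raises an unreliable-fit error when the relative fit RMSE
    exceeds ``rmse_threshold``.
    """
    region = np.asarray(image.data[tuple(edge_roi)], dtype=float)
    if region.ndim != 2 or min(region.shape) < 2:
        raise ValueError("edge_roi must select a 2-D region")
    profile = region.mean(axis=1 - profile_axis)
    x = np.arange(len(profile)) * pixel_size

    lo, hi = float(profile.min()), float(profile.max())
    rising = profile[-1] >= profile[0]
    if not rising:
        profile = profile[::-1]
    amp0 = hi - lo
    if amp0 <= 0:
        raise ValueError("edge ROI has no contrast")
    x0_guess = x[int(np.argmin(np.abs(profile - (lo + hi) / 2.0)))]
    p0 = [amp0, x0_guess, 2.0 * pixel_size, lo]
    popt, _ = curve_fit(_esf, x, profile, p0=p0, maxfev=20000)
    amplitude, _, sigma, _ = popt
    sigma = abs(float(sigma))
    rmse = float(np.sqrt(np.mean((_esf(x, *popt) - profile) ** 2)) / abs(amplitude))
    if rmse > rmse_threshold:
        raise ValueError(f"unreliable ESF fit: relative rmse {rmse:.3f}")
    return ResolutionResult(GAUSSIAN_FWHM * sigma, sigma, rmse, "lateral")


def axial_resolution(
    ascan: AScan, settings: AcquisitionSettings, rmse_threshold: float = 0.15
) -> ResolutionResult:
    """Axial resolution from a point-target A-scan.

    The Hilbert envelope is fitted to a Gaussian around its peak; the
    temporal FWHM is converted to meters with the one-way speed of sound.
    """
    env = envelope(ascan)
    fs = settings.sampling_rate
    t = np.arange(len(env)) / fs
    ipk = int(np.argmax(env))
    # fit window: samples above 10% of the peak around the maximum
    above = env >= 0.1 * env[ipk]
    left = ipk
    while left > 0 and above[left - 1]:
        left -= 1
    right = ipk
    while right < len(env) - 1 and above[right + 1]:
        right += 1
    sl = slice(left, right + 1)

    def gauss(tt, a, mu, sigma):
        return a * np.exp(-((tt - mu) ** 2) / (2.0 * sigma**2))

    sigma0 = max((right - left) / 4.0, 1.0) / fs
    popt, _ = curve_fit(
        gauss, t[sl], env[sl], p0=[env[ipk], t[ipk], sigma0], maxfev=20000
    )
    a, _, sigma_t = popt
    sigma_t = abs(float(sigma_t))
    rmse = float(np.sqrt(np.mean((gauss(t[sl], *popt) - env[sl]) ** 2)) / abs(a))
    if rmse > rmse_threshold:
        raise ValueError(f"unreliable envelope fit: relative rmse {rmse:.3f}")
    fwhm_m = GAUSSIAN_FWHM * sigma_t * settings.speed_of_sound
    return ResolutionResult(fwhm_m, sigma_t, rmse, "axial")


def snr_db(image, signal_roi, noise_roi) -> float:
    """20 log10(peak amplitude in signal ROI / noise std in noise ROI)."""
    data = image.data if isinstance(image, MapImage) else np.asarray(image, float)
    sig = np.max(np.abs(data[tuple(signal_roi)]))
    noise = float(np.std(data[tuple(noise_roi)]))
    if noise == 0:
        raise ValueError("noise ROI has zero standard deviation; SNR undefined")
    return 20.0 * math.log10(sig / noise)


def vessel_mask(image, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Binary vascular mask from an amplitude image."""
    data = image.data if isinstance(image, MapImage) else np.asarray(image, float)
    if method == "otsu":
        if np.ptp(data) == 0:
            raise ValueError("constant image: Otsu threshold undefined")
        threshold = threshold_otsu(data)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
    else:
        raise ValueError(f"unknown threshold method: {method!r}")
    return data >= threshold


def skeleton_length(skeleton: np.ndarray, pixel_size: float) -> float:
    """Total centerline length: 4-neighbor steps count 1, diagonals sqrt(2)."""
    sk = skeleton.astype(bool)
    n_h = int(np.sum(sk[:, 1:] & sk[:, :-1]))
    n_v = int(np.sum(sk[1:, :] & sk[:-1, :]))
    # a diagonal adjacency that shortcuts an existing L-path is not new length
    d1 = sk[1:, 1:] & sk[:-1, :-1] & ~(sk[1:, :-1] | sk[:-1, 1:])
    d2 = sk[1:, :-1] & sk[:-1, 1:] & ~(sk[1:, 1:] | sk[:-1, :-1])
    n_d = int(np.sum(d1)) + int(np.sum(d2))
    return (n_h + n_v + math.sqrt(2.0) * n_d) * pixel_size


def _perimeter(mask: np.ndarray, pixel_size: float) -> float:
    """Crofton-formula perimeter (4 directions).

    VCI is quadratic in perimeter, so estimator bias matters: a raw
    boundary-pixel count overestimates a circle by up to sqrt(2) and even a
    marching-squares contour polygon runs ~5% long (=> ~10% VCI error); the
    Crofton estimator is unbiased for smooth shapes to well under 1%.
    """
    return float(measure.perimeter_crofton(mask, directions=4)) * pixel_size


def vessel_metrics(mask: np.ndarray, pixel_size: float) -> VesselMetrics:
    """Morphometric indices of a binary vessel mask, in physical units.

    Skeleton by topological thinning; perimeter by the Crofton formula (see
    :func:`_perimeter`).  An empty mask returns VAD 0 with the remaining
    indices flagged as NaN.
    """
    mask = np.asarray(mask).astype(bool)
    total_area = mask.size * pixel_size**2
    area = float(mask.sum()) * pixel_size**2
    if area == 0:
        return VesselMetrics(0.0, math.nan, math.nan, math.nan)
    sk = skeletonize(mask)
    length = skeleton_length(sk, pixel_size)
    if length == 0:  # a blob so small its skeleton is a single point
        length = pixel_size
    perim = _perimeter(mask, pixel_size)
    return VesselMetrics(
        vad=area / total_area,
        vsd=length / total_area,
        vdi=area / length,
        vci=perim**2 / (4.0 * math.pi * area),
    )


def diameter_split(
    mask: np.ndarray, pixel_size: float, threshold_diameter: float = 100e-6
):
    """Partition vessel pixels into macro (>= threshold) and micro masks.

    The local diameter at each skeleton pixel is twice the Euclidean distance
    transform; every vessel pixel inherits the diameter of its nearest
    skeleton pixel.
    """
    mask = np.asarray(mask).astype(bool)
    macro = np.zeros_like(mask)
    micro = np.zeros_like(mask)
    if not mask.any():
        return macro, micro
    sk = skeletonize(mask)
    if not sk.any():
        sk = mask.copy()
    edt = ndimage.distance_transform_edt(mask) * pixel_size
    sk_pts = np.argwhere(sk)
    sk_diam = 2.0 * edt[sk]
    tree = cKDTree(sk_pts)
    vessel_pts = np.argwhere(mask)
    _, nearest = tree.query(vessel_pts)
    local = sk_diam[nearest]
    is_macro = local >= threshold_diameter
    macro[tuple(vessel_pts[is_macro].T)] = True
    micro[tuple(vessel_pts[~is_macro].T)] = True
    return macro, micro


def timeseries_quantify(
    frames,
    mask_method: str = "otsu",
    baseline_index: int = 0,
    times=None,
    pixel_size: float | None = None,
    split_threshold: float | None = None,
    fixed_threshold: float | None = None,
) -> FrameSeries:
    """Vessel density and amplitude change across a frame sequence.

    Per frame: the vascular mask's area fraction, and the mean in-mask
    amplitude expressed in dB (20 log10) relative to the baseline frame.
    With ``pixel_size`` and ``split_threshold`` given, densities are also
    reported for the macro/micro populations.
    """
    frames = list(frames)
    if times is None:
        times = np.arange(len(frames), dtype=float)
    times = np.asarray(times, dtype=float)

    density = np.empty(len(frames))
    amp = np.empty(len(frames))
    macro_d = np.empty(len(frames)) if split_threshold else None
    micro_d = np.empty(len(frames)) if split_threshold else None

    for i, frame in enumerate(frames):
        data = frame.data if isinstance(frame, MapImage) else np.asarray(frame, float)
        mask = vessel_mask(data, method=mask_method, threshold=fixed_threshold)
        density[i] = mask.mean()
        amp[i] = data[mask].mean() if mask.any() else 0.0
        if split_threshold:
            macro, micro = diameter_split(mask, pixel_size, split_threshold)
            macro_d[i] = macro.mean()
            micro_d[i] = micro.mean()

    base = amp[baseline_index]
    with np.errstate(divide="ignore"):
        amp_db = 20.0 * np.log10(np.where(amp > 0, amp / base, np.nan))
    amp_db[baseline_index] = 0.0
    return FrameSeries(times, density, amp_db, macro_d, micro_d)
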