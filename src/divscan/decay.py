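"""Divergence as a function of recombination distance from a focal locus.

Physical distance is converted to map distance with a constant genome-wide
rate (total map length / genome size); sites are pooled by unsigned
distance from the center of the functional interval, binned into
half-open 0.01-cM bins, and each bin's theta-hat is a ratio of sums over
its member sites.  Loess smoothing is presentational only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .divergence import SiteComponents
from .genotype_io import Region

__all__ = [
    "RecombinationModel",
    "DecayBin",
    "bp_to_cM",
    "locus_center",
    "distance_to_locus",
    "bin_decay",
    "loess_smooth",
    "fit_decay_scale",
]


@dataclass(frozen=True)
class RecombinationModel:
    """Constant-rate map: default 1430 cM over a 400-Mb genome."""

    map_length_cM: float = 1430.0
    genome_size_bp: float = 400e6

    def __post_init__(self) -> None:
        if self.map_length_cM <= 0 or self.genome_size_bp <= 0:
            raise ValueError("map length and genome size must be positive")

    @property
    def cM_per_bp(self) -> float:
        return self.map_length_cM / self.genome_size_bp


@dataclass
class DecayBin:
    bin_index: int
    cM_lo: float
    cM_hi: float
    theta: float  # NaN for empty bins
    n_positions: int
    sum_a: float = 0.0
    sum_den: float = 0.0


def bp_to_cM(distance_bp, model: RecombinationModel) -> np.ndarray | float:
    """Map distance for a physical distance (vectorized)."""
    d = np.asarray(distance_bp, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = d * model.cM_per_bp
    return float(out) if out.ndim == 0 else out


def locus_center(functional_region: Region) -> int:
    """Focal-locus coordinate: floor of the midpoint of the functional
    interval in the external 1-based convention."""
    return (functional_region.start1 + functional_region.end1) // 2


def distance_to_locus(
    position, functional_region: Region, model: RecombinationModel
) -> np.ndarray | float:
    """Unsigned map distance from position(s) to the locus center."""
    center = locus_center(functional_region)
    return bp_to_cM(np.abs(np.asarray(position, dtype=np.int64) - center), model)


def bin_decay(
    components: SiteComponents,
    distances_cM: np.ndarray,
    bin_width: float = 0.01,
) -> list[DecayBin]:
    """Assign sites to half-open distance bins and combine per bin.

    A site exactly at a bin edge falls in the upper bin
    (``floor(d / width)``).  Empty bins up to the farthest site are
    emitted with NaN theta so the bin set is exhaustive.
    """
    distances_cM = np.asarray(distances_cM, dtype=np.float64)
    if len(distances_cM) != components.n_sites:
        raise ValueError("need one distance per site")
    d = components.defined
    if not d.any():
        return []
    dist = distances_cM[d]
    a = np.nan_to_num(components.a[d])
    den = np.nan_to_num(components.den[d])
    idx = np.floor(dist / bin_width).astype(np.int64)
    n_bins = int(idx.max()) + 1
    sum_a = np.bincount(idx, weights=a, minlength=n_bins)
    sum_den = np.bincount(idx, weights=den, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    out = []
    for i in range(n_bins):
        theta = float("nan")
        if counts[i] > 0 and sum_den[i] != 0.0:
            theta = sum_a[i] / sum_den[i]
        out.append(
            DecayBin(
                bin_index=i,
                cM_lo=i * bin_width,
                cM_hi=(i + 1) * bin_width,
                theta=theta,
                n_positions=int(counts[i]),
                sum_a=float(sum_a[i]),
                sum_den=float(sum_den[i]),
            )
        )
    return out


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.3,
    degree: int = 2,
) -> np.ndarray:
    """Locally weighted polynomial regression (tricube weights).

    Evaluated at the input ``x``; NaN inputs are ignored for fitting and
    yield NaN outputs only where no fit is possible.  Purely
    presentational — never feeds back into estimates.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same shape")
    finite = np.isfinite(x) & np.isfinite(y)
    n_fin = int(finite.sum())
    q = max(int(np.ceil(span * n_fin)), degree + 1)
    if n_fin < max(4, degree + 2) or q > n_fin:
        raise ValueError(
            f"too few finite points ({n_fin}) for span={span}; increase span"
        )
    xf, yf = x[finite], y[finite]
    out = np.full_like(x, np.nan)
    powers = np.arange(degree + 1)
    for i in np.nonzero(np.isfinite(x))[0]:
        d = np.abs(xf - x[i])
        cut = np.partition(d, q - 1)[q - 1]
        if cut == 0:
            cut = np.finfo(float).tiny
        w = np.clip(1.0 - (d / cut) ** 3, 0.0, None) ** 3
        use = w > 0
        if use.sum() <= degree:
            # fall back to the q nearest points with uniform weight
            use = d <= cut
            w = np.where(use, 1.0, 0.0)
        X = (xf[use, None] - x[i]) ** powers[None, :]
        sw = np.sqrt(w[use])
        beta, *_ = np.linalg.lstsq(X * sw[:, None], yf[use] * sw, rcond=None)
        out[i] = beta[0]
    return out


def fit_decay_scale(
    cM: np.ndarray,
    theta: np.ndarray,
    p0: tuple[float, float, float] | None = None,
) -> tuple[float, float, float]:
    """Fit ``theta(d) = bg + amp * exp(-d / scale)`` to binned decay data.

    Returns ``(bg, amp, scale)``.  Used by the recovery checks; the
    analysis pipeline itself only bins and smooths.
    """
    from scipy.optimize import curve_fit

    cM = np.asarray(cM, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    ok = np.isfinite(cM) & np.isfinite(theta)
    if ok.sum() < 4:
        raise ValueError("too few finite bins to fit a decay scale")
    if p0 is None:
        bg0 = float(np.nanmedian(theta[ok][cM[ok] > np.nanmedian(cM[ok])]))
        amp0 = float(np.nanmax(theta[ok]) - bg0)
        p0 = (max(bg0, 1e-3), max(amp0, 1e-3), max(float(np.nanmedian(cM[ok])) / 2, 1e-3))

    def model(d, bg, amp, scale):
        return bg + amp * np.exp(-d / scale)

    popt, _ = curve_fit(
        model,
        cM[ok],
        theta[ok],
        p0=p0,
        bounds=([0.0, 0.0, 1e-6], [1.0, 1.0, np.inf]),
        maxfev=10_000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])
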