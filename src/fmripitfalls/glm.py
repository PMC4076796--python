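"""Minimal voxelwise general linear model for block-design BOLD series.

The model is the standard mass-univariate one: a boxcar of the experimental
condition is convolved with a canonical hemodynamic response function (HRF),
mean-centered, and regressed voxel-by-voxel against the time series with an
intercept.  The fit yields an effect-size map (beta, in signal units) and a
t-statistic map; the two deliberately live side by side because smoothing
moves them in opposite directions.

Not modeled: temporal autocorrelation (synthetic noise here is white by
construction), drift or nuisance regressors, multi-condition contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gamma as gamma_fn

from .grids import VoxelGrid

__all__ = ["DesignSpec", "GLMResult", "hrf", "build_design", "fit_glm"]

# Canonical double-gamma HRF constants: response peak 6 s, undershoot peak
# 16 s, unit dispersions, undershoot one sixth of the peak.
_PEAK_DELAY = 6.0
_UNDERSHOOT_DELAY = 16.0
_PEAK_DISP = 1.0
_UNDERSHOOT_DISP = 1.0
_UNDERSHOOT_RATIO = 1.0 / 6.0


@dataclass(frozen=True)
class DesignSpec:
    """A block (or event) design: stimulus onsets/durations on a scan grid.

    Parameters
    ----------
    onsets, durations : sequence of float, seconds
        Strictly increasing nonnegative onsets; each block must end within
        the acquisition and must not overlap the next.
    tr : float, seconds
        Repetition time between scans.
    n_scans : int
        Number of volumes acquired.
    """

    onsets: tuple[float, ...]
    durations: tuple[float, ...]
    tr: float
    n_scans: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "onsets", tuple(float(o) for o in self.onsets))
        object.__setattr__(self, "durations", tuple(float(d) for d in self.durations))
        if len(self.onsets) != len(self.durations):
            raise ValueError("onsets and durations must have equal length")
        if self.tr <= 0 or self.n_scans < 1:
            raise ValueError("tr must be > 0 and n_scans >= 1")
        total = self.tr * self.n_scans
        prev_end = -np.inf
        for onset, dur in zip(self.onsets, self.durations):
            if onset < 0 or dur < 0:
                raise ValueError("onsets and durations must be nonnegative")
            if onset <= prev_end - 1e-12 and prev_end > 0:
                raise ValueError(f"overlapping blocks: onset {onset} before previous block ends at {prev_end}")
            if onset + dur > total + 1e-9:
                raise ValueError(f"block at {onset}s ends after the acquisition ({total}s)")
            prev_end = onset + dur


def hrf(t: float | np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, zero for t <= 0.

    A positive gamma response peaking near 5 s minus a scaled gamma
    undershoot peaking near 15 s.  Amplitude is in arbitrary units; the
    response integrates to a positive value.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    def gpdf(x: np.ndarray, shape: float, scale: float) -> np.ndarray:
        return x ** (shape - 1) * np.exp(-x / scale) / (gamma_fn(shape) * scale**shape)

    out[pos] = gpdf(tp, _PEAK_DELAY / _PEAK_DISP, _PEAK_DISP) - _UNDERSHOOT_RATIO * gpdf(
        tp, _UNDERSHOOT_DELAY / _UNDERSHOOT_DISP, _UNDERSHOOT_DISP
    )
    return out


def build_design(design: DesignSpec, oversampling: int = 16) -> np.ndarray:
    """HRF-convolved, mean-centered task regressor sampled at the scan times.

    The condition boxcar is built on a fine grid (``tr / oversampling``),
    convolved with :func:`hrf`, sampled at t = 0, TR, 2*TR, ..., and
    mean-centered.  The implicit intercept column is added by
    :func:`fit_glm`; a design with no events yields the all-zero regressor.
    """
    dt = design.tr / oversampling
    n_fine = design.n_scans * oversampling
    t_fine = np.arange(n_fine) * dt
    boxcar = np.zeros(n_fine)
    for onset, dur in zip(design.onsets, design.durations):
        boxcar[(t_fine >= onset) & (t_fine < onset + dur)] = 1.0
    if not boxcar.any():
        return np.zeros(design.n_scans)
    kernel = hrf(np.arange(1, int(32.0 / dt) + 1) * dt) * dt
    conv = np.convolve(boxcar, kernel)[:n_fine]
    regressor = conv[::oversampling]
    return regressor - regressor.mean()


@dataclass
class GLMResult:
    """Per-voxel ordinary-least-squares fit of a single task regressor.

    ``beta`` is the effect size in signal units, ``tmap`` the t statistic
    ``beta / se(beta)`` with ``dof = n_scans - 2`` degrees of freedom, and
    ``sigma2`` the residual variance.  Voxels fit perfectly (zero residual
    variance) carry a +/-inf sentinel in ``tmap``.
    """

    beta: VoxelGrid
    tmap: VoxelGrid
    dof: int
    sigma2: VoxelGrid


def fit_glm(series: np.ndarray, regressor: np.ndarray, voxel_size=(3.0, 3.0, 3.0)) -> GLMResult:
    """Fit ``series[v, t] = intercept + beta[v] * regressor[t] + noise``.

    Parameters
    ----------
    series : ndarray, shape (x, y, z, t)
        BOLD time series, time last (NIfTI convention).
    regressor : ndarray, shape (t,)
        Mean-centered task regressor from :func:`build_design`.
    """
    series = np.asarray(series, dtype=float)
    regressor = np.asarray(regressor, dtype=float)
    if series.ndim != 4:
        raise ValueError(f"series must be 4-D (x, y, z, t), got ndim={series.ndim}")
    n = series.shape[-1]
    if regressor.shape != (n,):
        raise ValueError(f"regressor length {regressor.shape} does not match {n} scans")
    x = regressor - regressor.mean()
    sxx = float(x @ x)
    if sxx <= 1e-24:
        raise ValueError("degenerate regressor: zero variance after mean-centering")
    dof = n - 2
    if dof <= 0:
        raise ValueError(f"need more than 2 scans, got {n}")

    y = series.reshape(-1, n)
    ybar = y.mean(axis=1, keepdims=True)
    beta = ((y - ybar) @ x) / sxx
    resid = y - ybar - beta[:, None] * x[None, :]
    sigma2 = np.einsum("ij,ij->i", resid, resid) / dof
    sigma2 = np.maximum(sigma2, 0.0)
    # exact fits leave only round-off in the residuals: snap them to zero so
    # the t sentinel is +/-inf rather than an arbitrary huge number
    tss = np.einsum("ij,ij->i", y - ybar, y - ybar)
    sigma2[sigma2 * dof <= 1e-20 * tss] = 0.0
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    t = np.where((se == 0) & (beta == 0), 0.0, t)

    shape = series.shape[:3]
    return GLMResult(
        beta=VoxelGrid(beta.reshape(shape), voxel_size),
        tmap=VoxelGrid(t.reshape(shape), voxel_size, allow_nonfinite=True),
        dof=dof,
        sigma2=VoxelGrid(sigma2.reshape(shape), voxel_size),
    )
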