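"""Scalar field extraction from element histories.

Effective (von Mises) stress, effective strain, accumulated effective
plastic strain, logarithmic strain and linear-fit stiffness estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class ElementHistory:
    """Per-element time series of tensors and volume.

    ``stress``/``strain`` have shape (T, 3, 3); ``plastic_increments`` is the
    optional per-step plastic strain increment tensor (T, 3, 3).  Shell
    elements carry ``area`` and ``thickness`` instead of a solid ``volume``.
    """

    eid: int
    part: int
    tissue: str = "other"
    side: str = "na"
    volume: float | None = None
    area: float | None = None
    thickness: float | None = None
    times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    stress: np.ndarray = field(default_factory=lambda: np.zeros((0, 3, 3)))
    strain: np.ndarray = field(default_factory=lambda: np.zeros((0, 3, 3)))
    plastic_increments: np.ndarray | None = None
    volume_series: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("history times must be strictly increasing")

    def resolved_volume(self) -> float | None:
        """Volume used for failed-element bookkeeping.

        Shells use area * thickness; shells without a thickness cannot
        contribute and return None.
        """
        if self.volume is not None:
            return self.volume
        if self.area is not None and self.thickness is not None:
            return self.area * self.thickness
        return None


@dataclass(frozen=True)
class StiffnessFit:
    """Ordinary least-squares line through a stress-strain window."""

    strain_window: tuple[float, float]
    slope: float
    intercept: float
    r_squared: float


# ---------------------------------------------------------------------------


def _sym(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.shape[-2:] != (3, 3):
        raise ValueError("expected (..., 3, 3) tensors")
    if not np.allclose(t, np.swapaxes(t, -1, -2), atol=1e-8 * (1 + np.abs(t).max())):
        raise ValueError("tensor is not symmetric")
    return t


def effective_stress(sigma: np.ndarray) -> np.ndarray | float:
    """Von Mises stress sqrt(3 J2) of the deviator.

    Accepts a (..., 3, 3) tensor or a length-3 vector of principal values.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape[-2:] == (3, 3):
        sigma = _sym(sigma)
        tr = np.trace(sigma, axis1=-2, axis2=-1)
        dev = sigma - tr[..., None, None] / 3.0 * np.eye(3)
        j2 = 0.5 * np.sum(dev * dev, axis=(-2, -1))
        out = np.sqrt(3.0 * j2)
    elif sigma.shape[-1] == 3:
        s1, s2, s3 = sigma[..., 0], sigma[..., 1], sigma[..., 2]
        out = np.sqrt(0.5 * ((s1 - s2) ** 2 + (s1 - s3) ** 2 + (s2 - s3) ** 2))
    else:
        raise ValueError("expected a (...,3,3) tensor or (...,3) principal values")
    return float(out) if out.ndim == 0 else out


def effective_strain(eps: np.ndarray) -> np.ndarray | float:
    """Effective strain sqrt(2/3 * eps_ij eps_ij), full tensor contraction."""
    eps = _sym(eps)
    out = np.sqrt(2.0 / 3.0 * np.sum(eps * eps, axis=(-2, -1)))
    return float(out) if out.ndim == 0 else out


def effective_plastic_strain(history: ElementHistory) -> np.ndarray:
    """Accumulated effective plastic strain time series.

    Running sum of sqrt(2/3 deps_p : deps_p); identically zero (with a
    logged notice) when the history carries no plastic increments.
    """
    n = len(history.times)
    if history.plastic_increments is None:
        log.info("element %d has no plastic increments; series is zero", history.eid)
        return np.zeros(n)
    inc = _sym(history.plastic_increments)
    steps = np.sqrt(2.0 / 3.0 * np.sum(inc * inc, axis=(-2, -1)))
    return np.cumsum(steps)


def log_strain(F: np.ndarray) -> np.ndarray:
    """Spatial logarithmic (Hencky) strain sum ln(l_a) n_a x n_a.

    ``F`` may be a single 3x3 gradient or a batch (..., 3, 3).
    """
    F = np.asarray(F, dtype=float)
    if F.shape[-2:] != (3, 3):
        raise ValueError("deformation gradient must be (..., 3, 3)")
    B = F @ np.swapaxes(F, -1, -2)
    w, V = np.linalg.eigh(B)
    if np.any(w <= 0):
        raise ValueError("non-positive principal stretch")
    logl = 0.5 * np.log(w)
    return np.einsum("...a,...ia,...ja->...ij", logl, V, V)


def fit_young_modulus(
    stress: np.ndarray,
    strain: np.ndarray,
    window: tuple[float, float] | None = None,
    peak_fraction: float = 0.25,
) -> StiffnessFit:
    """Least-squares slope of effective stress vs effective strain.

    ``window`` is a (strain_lo, strain_hi) interval; when omitted, the
    contiguous run of samples around the stress peak where the stress is at
    least ``peak_fraction`` of its maximum is used (the timespan of highest
    loading).
    """
    stress = np.asarray(stress, dtype=float)
    strain = np.asarray(strain, dtype=float)
    if stress.shape != strain.shape or stress.ndim != 1:
        raise ValueError("stress and strain must be matching 1-d series")
    if window is None:
        mask = _auto_window(stress, peak_fraction)
    else:
        lo, hi = window
        mask = (strain >= lo) & (strain <= hi)
    if mask.sum() < 3:
        raise ValueError("need at least 3 samples inside the fit window")
    x, y = strain[mask], stress[mask]
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate window: zero strain variance")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    return StiffnessFit(
        strain_window=(float(x.min()), float(x.max())),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=min(1.0, r2),
    )


def moving_average(times: np.ndarray, values: np.ndarray,
                   window: float) -> np.ndarray:
    """Centred moving average over a time window (uniform sampling assumed).

    Used to suppress the discrete first-impact transient of penalty contact
    before peak extraction; window 0 returns the input unchanged.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if window <= 0 or len(times) < 2:
        return values
    n = max(1, int(round(window / (times[1] - times[0]))))
    if n <= 1:
        return values
    kernel = np.ones(n) / n
    if values.ndim == 1:
        return np.convolve(values, kernel, mode="same")
    return np.apply_along_axis(
        lambda col: np.convolve(col, kernel, mode="same"), 0, values)


def _auto_window(stress: np.ndarray, peak_fraction: float) -> np.ndarray:
    peak_i = int(np.argmax(stress))
    thr = peak_fraction * stress[peak_i]
    lo = peak_i
    while lo > 0 and stress[lo - 1] >= thr:
        lo -= 1
    hi = peak_i
    while hi < len(stress) - 1 and stress[hi + 1] >= thr:
        hi += 1
    mask = np.zeros(len(stress), dtype=bool)
    mask[lo : hi + 1] = True
    return mask
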