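"""Injury post-processing.

Threshold-based failed-element volume, the cumulative strain damage measure
(CSDM), peak contact-force extraction and pluggable force-to-probability
risk curves.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .metrics import (
    ElementHistory,
    effective_plastic_strain,
    effective_strain,
)

log = logging.getLogger(__name__)

FIELDS = ("effective_plastic_strain", "first_principal_strain", "effective_strain")


@dataclass
class RiskCurve:
    """Ordered (force, probability) points with linear interpolation."""

    forces: np.ndarray
    probabilities: np.ndarray
    label: str = "risk"

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.forces.ndim != 1 or self.forces.shape != self.probabilities.shape:
            raise ValueError("forces and probabilities must be matching 1-d arrays")
        if np.any(np.diff(self.forces) <= 0):
            raise ValueError("forces must be strictly increasing")
        if np.any(np.diff(self.probabilities) < 0):
            raise ValueError("probabilities must be non-decreasing")
        if np.any(self.probabilities < 0) or np.any(self.probabilities > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path, label: str | None = None) -> "RiskCurve":
        data = np.loadtxt(path, delimiter=",", ndmin=2)
        return cls(data[:, 0], data[:, 1], label=label or str(path))


@dataclass
class FailedVolumeSeries:
    """Once-failed-always-counted volume accumulation."""

    times: np.ndarray
    volume: np.ndarray
    part_volumes: dict[int, float]
    excluded: list[int] = field(default_factory=list)


@dataclass
class CsdmSeries:
    times: np.ndarray
    volume: np.ndarray
    fraction: np.ndarray
    group_volume: float


@dataclass
class InjuryReport:
    failed_volumes: dict[str, FailedVolumeSeries] = field(default_factory=dict)
    csdm: dict[str, CsdmSeries] = field(default_factory=dict)
    peak_force: tuple[float, float] | None = None  # (value, time)
    risks: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {"failed_volumes": {}, "csdm": {}, "risks": dict(self.risks)}
        for key, fv in self.failed_volumes.items():
            out["failed_volumes"][key] = {
                "times": fv.times.tolist(),
                "volume": fv.volume.tolist(),
                "part_volumes": {str(k): v for k, v in fv.part_volumes.items()},
                "excluded_elements": list(fv.excluded),
            }
        for key, cs in self.csdm.items():
            out["csdm"][key] = {
                "times": cs.times.tolist(),
                "volume": cs.volume.tolist(),
                "fraction": cs.fraction.tolist(),
                "group_volume": cs.group_volume,
            }
        if self.peak_force is not None:
            out["peak_force"] = {
                "value": self.peak_force[0],
                "time": self.peak_force[1],
            }
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------


def _field_series(history: ElementHistory, field_name: str) -> np.ndarray:
    if field_name == "effective_plastic_strain":
        return effective_plastic_strain(history)
    if field_name == "effective_strain":
        return np.atleast_1d(effective_strain(history.strain))
    if field_name == "first_principal_strain":
        return np.atleast_1d(first_principal_strain(history.strain))
    raise ValueError(f"unknown field {field_name!r}; choose from {FIELDS}")


def _common_times(histories: list[ElementHistory]) -> np.ndarray:
    times = histories[0].times
    for h in histories[1:]:
        if len(h.times) != len(times) or not np.allclose(h.times, times):
            raise ValueError("histories must share a common time grid")
    return times


def failed_element_volume(
    histories: list[ElementHistory],
    field_name: str,
    threshold: float,
    accumulate: bool = True,
) -> FailedVolumeSeries:
    """Volume of elements whose field strictly exceeds the threshold.

    With ``accumulate`` (the default) an element contributes its reference
    volume from the first exceedance onward; the instantaneous mode counts
    only currently exceeding elements.
    """
    if not histories:
        raise ValueError("no histories supplied")
    times = _common_times(histories)
    total = np.zeros(len(times))
    part_volumes: dict[int, float] = {}
    excluded: list[int] = []
    for h in histories:
        vol = h.resolved_volume()
        if vol is None:
            log.info("element %d lacks a volume (shell without thickness); skipped",
                     h.eid)
            excluded.append(h.eid)
            continue
        series = _field_series(h, field_name)
        over = series > threshold
        if accumulate:
            over = np.maximum.accumulate(over)
        total += vol * over
        if over[-1]:
            part_volumes[h.part] = part_volumes.get(h.part, 0.0) + vol
    return FailedVolumeSeries(times=times, volume=total,
                              part_volumes=part_volumes, excluded=excluded)


def csdm(
    histories: list[ElementHistory],
    threshold: float = 0.59,
    accumulate: bool = True,
) -> dict[str, CsdmSeries]:
    """Cumulative strain damage measure per (tissue, side) group.

    Accumulates the volume of elements whose effective strain ever exceeds
    the threshold; fractions are normalised by the group volume.
    """
    if not histories:
        raise ValueError("no histories supplied")
    times = _common_times(histories)
    groups: dict[str, list[ElementHistory]] = {}
    for h in histories:
        groups.setdefault(f"{h.tissue}/{h.side}", []).append(h)
    out: dict[str, CsdmSeries] = {}
    for key, members in sorted(groups.items()):
        vols = [m.resolved_volume() for m in members]
        usable = [(m, v) for m, v in zip(members, vols) if v is not None]
        group_volume = sum(v for _, v in usable)
        if group_volume == 0.0:
            log.info("CSDM group %s has no volume; empty series", key)
            out[key] = CsdmSeries(times, np.zeros(len(times)),
                                  np.zeros(len(times)), 0.0)
            continue
        vol_series = np.zeros(len(times))
        for m, v in usable:
            over = np.atleast_1d(effective_strain(m.strain)) > threshold
            if accumulate:
                over = np.maximum.accumulate(over)
            vol_series += v * over
        out[key] = CsdmSeries(times, vol_series, vol_series / group_volume,
                              group_volume)
    return out


def csdm_threshold_from_failure_stats(mean: float, sd: float) -> float:
    """Lower limit of the failure elongation: mean minus one s.d.

    Both arguments are strain fractions; the result is the CSDM threshold.
    """
    if sd < 0:
        raise ValueError("standard deviation must be non-negative")
    if mean <= sd:
        raise ValueError("mean must exceed the standard deviation "
                         "(threshold would be non-positive)")
    return mean - sd


def first_principal_strain(eps: np.ndarray) -> np.ndarray | float:
    """Largest eigenvalue of a symmetric strain tensor (batched)."""
    eps = np.asarray(eps, dtype=float)
    if eps.shape[-2:] != (3, 3):
        raise ValueError("expected (..., 3, 3) strain tensors")
    vals = np.linalg.eigvalsh(eps)
    out = vals[..., -1]
    return float(out) if out.ndim == 0 else out


def peak_force(times: np.ndarray, forces: np.ndarray) -> tuple[float, float]:
    """Maximum force magnitude and its first attainment time.

    ``forces`` may be scalar per sample or an (T, 3) resultant vector.
    """
    times = np.asarray(times, dtype=float)
    forces = np.asarray(forces, dtype=float)
    if len(times) == 0:
        raise ValueError("empty force series")
    mag = np.linalg.norm(forces, axis=-1) if forces.ndim == 2 else np.abs(forces)
    i = int(np.argmax(mag))  # argmax returns the first maximum
    return float(mag[i]), float(times[i])


def risk_lookup(curve: RiskCurve, force: float | np.ndarray) -> float | np.ndarray:
    """Probability at the given force, clamped to the end points."""
    out = np.interp(force, curve.forces, curve.probabilities)
    return float(out) if np.isscalar(force) else out
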