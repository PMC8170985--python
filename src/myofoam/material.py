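"""Hyperelastic compressible-foam constitutive model.

The strain energy is an Ogden-type functional of the principal stretches

    psi = sum_j (C_j / b_j) * (l1^b_j + l2^b_j + l3^b_j - 3
                               + (1/n) * (J^(-n*b_j) - 1))

with a volumetric penalty term controlled by the exponent ``n`` derived from
the Poisson ratio.  Principal Cauchy stresses follow from
``sigma_a = J^-1 * l_a * dpsi/dl_a`` and the full stress tensor from the
spectral decomposition of the left stretch.

The model is normally driven by an engineering stress-strain curve: the
constants ``C_j`` for a configurable exponent set are fitted by linear least
squares against the closed-form uniaxial nominal stress.  Strain-rate
dependent behaviour is supported through a table of curves keyed by strain
rate, interpolated linearly in log(rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

log = logging.getLogger(__name__)

DEFAULT_EXPONENTS = (1.0, 2.0, 4.0, -1.0, -2.0)


# ---------------------------------------------------------------------------
# penalty exponent


def penalty_exponent(nu: float, convention: str = "standard") -> float:
    """Volumetric penalty exponent ``n`` from the Poisson ratio.

    ``convention="standard"`` uses the compressible-foam relation
    ``n = nu / (1 - 2 nu)`` which yields lateral contraction
    ``l_lat = l_axial^-nu`` under uniaxial stress.  ``convention="paper"``
    uses the sign-flipped printed form ``n = nu / (2 nu - 1)``.
    """
    if not 0.0 <= nu < 0.5:
        raise ValueError(f"Poisson ratio must lie in [0, 0.5), got {nu}")
    if convention == "standard":
        return nu / (1.0 - 2.0 * nu)
    if convention == "paper":
        return nu / (2.0 * nu - 1.0) if nu != 0.0 else 0.0
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class MaterialConstants:
    """Constants of the foam material.

    ``bulk_modulus`` feeds only the wave speed (time step and contact
    stiffness); ``damping_mu`` and ``limit_stress`` are parsed and stored but
    have no constitutive effect.
    """

    density: float
    bulk_modulus: float
    shear_modulus: float
    poisson: float
    penalty_exp: float
    terms: tuple[tuple[float, float], ...]  # (C_j, b_j)
    damping_mu: float = 0.0
    limit_stress: float = 0.0
    fit_rms: float | None = None

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.bulk_modulus <= 0:
            raise ValueError("bulk modulus must be positive")
        if self.shear_modulus <= 0:
            raise ValueError("shear modulus must be positive")
        if not 0.0 <= self.poisson < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if len(self.terms) < 1:
            raise ValueError("at least one (C, b) term required")
        for _, b in self.terms:
            if not np.isfinite(b) or b == 0.0:
                raise ValueError("exponents b_j must be finite and nonzero")

    @property
    def wave_speed(self) -> float:
        """Dilatational wave speed sqrt((K + 4G/3) / rho)."""
        return float(
            np.sqrt((self.bulk_modulus + 4.0 * self.shear_modulus / 3.0) / self.density)
        )

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for c, _ in self.terms])

    @property
    def exponents(self) -> np.ndarray:
        return np.array([b for _, b in self.terms])


@dataclass
class LoadCurve:
    """Engineering stress-strain curve with an ordinate scale factor.

    The effective ordinate is ``stress * sfo``.  If the raw samples do not
    contain the origin it is prepended: zero stress at zero strain is an
    invariant of the material.
    """

    strain: np.ndarray
    stress: np.ndarray
    sfo: float = 1.0

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be matching 1-d arrays")
        if self.sfo <= 0:
            raise ValueError("SFO must be positive")
        if np.any(np.diff(self.strain) <= 0):
            raise ValueError("strain samples must be strictly increasing")
        if not np.any(np.isclose(self.strain, 0.0)):
            if self.strain[0] > 0.0:
                self.strain = np.concatenate([[0.0], self.strain])
                self.stress = np.concatenate([[0.0], self.stress])
            else:
                i = int(np.searchsorted(self.strain, 0.0))
                self.strain = np.insert(self.strain, i, 0.0)
                self.stress = np.insert(self.stress, i, 0.0)

    @property
    def scaled_stress(self) -> np.ndarray:
        return self.stress * self.sfo

    def interpolate(self, strain: np.ndarray | float) -> np.ndarray | float:
        """SFO-scaled ordinate at the given strain (linear, clamped)."""
        return np.interp(strain, self.strain, self.scaled_stress)


@dataclass
class RateTable:
    """Curves keyed by strain rate (strictly increasing, positive rates)."""

    entries: tuple[tuple[float, LoadCurve], ...]

    def __post_init__(self) -> None:
        self.entries = tuple(self.entries)
        if len(self.entries) < 2:
            raise ValueError("a rate table needs at least 2 entries")
        rates = np.array([r for r, _ in self.entries])
        if np.any(rates <= 0) or np.any(np.diff(rates) <= 0):
            raise ValueError("rates must be positive and strictly increasing")

    @property
    def rates(self) -> np.ndarray:
        return np.array([r for r, _ in self.entries])


def select_rate_curve(table: RateTable, rate: float) -> LoadCurve:
    """Curve at the given strain rate.

    Exact tabulated rates return that curve's scaled ordinates.  Between
    tabulated rates the ordinates are interpolated linearly in log(rate);
    outside the range the nearest curve is used.
    """
    if rate < 0:
        raise ValueError("strain rate must be non-negative")
    rates = table.rates
    curves = [c for _, c in table.entries]
    for r, c in table.entries:
        if rate == r:
            return LoadCurve(c.strain.copy(), c.scaled_stress, sfo=1.0)
    if rate <= rates[0]:
        c = curves[0]
        return LoadCurve(c.strain.copy(), c.scaled_stress, sfo=1.0)
    if rate >= rates[-1]:
        c = curves[-1]
        return LoadCurve(c.strain.copy(), c.scaled_stress, sfo=1.0)
    i = int(np.searchsorted(rates, rate)) - 1
    lo, hi = curves[i], curves[i + 1]
    w = (np.log(rate) - np.log(rates[i])) / (np.log(rates[i + 1]) - np.log(rates[i]))
    grid = np.union1d(lo.strain, hi.strain)
    lo_dom = (grid >= lo.strain[0]) & (grid <= lo.strain[-1])
    hi_dom = (grid >= hi.strain[0]) & (grid <= hi.strain[-1])
    grid = grid[lo_dom & hi_dom]
    y = (1.0 - w) * lo.interpolate(grid) + w * hi.interpolate(grid)
    return LoadCurve(grid, np.asarray(y), sfo=1.0)


@dataclass(frozen=True)
class DeformationState:
    """Kinematics at a material point derived from the deformation gradient.

    Principal directions are eigenvectors of the left stretch ``F F^T`` so
    that the assembled Cauchy stress lives in the spatial frame.
    """

    F: np.ndarray
    C: np.ndarray
    stretches: np.ndarray
    directions: np.ndarray  # columns are the orthonormal triad
    jacobian: float

    @classmethod
    def from_gradient(cls, F: np.ndarray) -> "DeformationState":
        F = np.asarray(F, dtype=float)
        if F.shape != (3, 3):
            raise ValueError("deformation gradient must be 3x3")
        J = float(np.linalg.det(F))
        if J <= 0.0:
            raise ValueError(f"non-positive Jacobian ({J:g}): deformation is invalid")
        C = F.T @ F
        B = F @ F.T
        w, V = np.linalg.eigh(B)
        lam = np.sqrt(np.maximum(w, 0.0))
        prod = float(np.prod(lam))
        if abs(prod - J) > 1e-10 * max(abs(J), 1.0):
            raise ValueError("principal stretches inconsistent with det F")
        return cls(F=F, C=C, stretches=lam, directions=V, jacobian=J)


# ---------------------------------------------------------------------------
# energy and stress


def _penalty(J: np.ndarray | float, b: np.ndarray, n: float) -> np.ndarray:
    """(1/n)(J^(-n b) - 1), with the analytic n->0 limit -b*ln(J)."""
    if n == 0.0:
        return -b * np.log(J)
    return (np.power(J, -n * b) - 1.0) / n


def hill_energy(state: DeformationState, mat: MaterialConstants) -> float:
    """Strain-energy density at the given deformation state."""
    lam = state.stretches
    if np.any(lam <= 0):
        raise ValueError("non-positive principal stretch")
    C = mat.coefficients
    b = mat.exponents
    bracket = (
        np.power(lam[0], b) + np.power(lam[1], b) + np.power(lam[2], b)
        - 3.0
        + _penalty(state.jacobian, b, mat.penalty_exp)
    )
    return float(np.sum(C / b * bracket))


def principal_stresses(state: DeformationState, mat: MaterialConstants) -> np.ndarray:
    """Principal Cauchy stresses sigma_a = J^-1 l_a dpsi/dl_a.

    Closed form: sigma_a = J^-1 * sum_j C_j (l_a^b_j - J^(-n b_j)).
    """
    lam = state.stretches
    if np.any(lam <= 0):
        raise ValueError("non-positive principal stretch")
    return principal_stress_values(lam, state.jacobian, mat.coefficients,
                                   mat.exponents, mat.penalty_exp)


def principal_stress_values(
    lam: np.ndarray,
    J: np.ndarray | float,
    C: np.ndarray,
    b: np.ndarray,
    n: float,
) -> np.ndarray:
    """Vectorised principal Cauchy stresses.

    ``lam`` has shape (..., 3), ``J`` shape (...), ``C``/``b`` shape (m,) or
    (..., m) for spatially varying coefficients.
    """
    lam = np.asarray(lam, dtype=float)
    J = np.asarray(J, dtype=float)
    lam_b = np.power(lam[..., None, :], np.asarray(b)[..., :, None])  # (..., m, 3)
    vol = np.power(J[..., None], -n * np.asarray(b))  # (..., m)
    contrib = np.asarray(C)[..., :, None] * (lam_b - vol[..., :, None])
    return contrib.sum(axis=-2) / J[..., None]


def assemble_cauchy_stress(sigma: Sequence[float], triad: np.ndarray) -> np.ndarray:
    """Full Cauchy stress from principal values and an orthonormal triad."""
    triad = np.asarray(triad, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if triad.shape != (3, 3):
        raise ValueError("triad must be 3x3 with principal directions as columns")
    if not np.allclose(triad.T @ triad, np.eye(3), atol=1e-8):
        raise ValueError("principal directions are not orthonormal")
    return (triad * sigma) @ triad.T


def cauchy_stress(state: DeformationState, mat: MaterialConstants) -> np.ndarray:
    """Symmetric Cauchy stress tensor in the spatial frame."""
    s = principal_stresses(state, mat)
    return assemble_cauchy_stress(s, state.directions)


# ---------------------------------------------------------------------------
# uniaxial response and curve fitting


def lateral_stretch(
    lam_axial: float, mat: MaterialConstants, numeric: bool = False
) -> float:
    """Lateral stretch under uniaxial stress (zero lateral Cauchy stress).

    With the standard penalty convention the closed form is
    ``l_lat = l_axial^-nu`` (independent of the exponent set).  Other penalty
    exponents fall back to root finding on the lateral equilibrium condition.
    """
    if lam_axial <= 0:
        raise ValueError("axial stretch must be positive")
    n_std = penalty_exponent(mat.poisson, "standard")
    if not numeric and abs(mat.penalty_exp - n_std) <= 1e-12 * max(1.0, abs(n_std)):
        return float(lam_axial ** (-mat.poisson))

    C = mat.coefficients
    b = mat.exponents
    n = mat.penalty_exp

    def lateral_stress(lam_lat: float) -> float:
        J = lam_axial * lam_lat**2
        return float(np.sum(C * (lam_lat**b - J ** (-n * b))))

    lo, hi = 1e-3, 1e3
    flo, fhi = lateral_stress(lo), lateral_stress(hi)
    if flo * fhi > 0:
        raise ValueError("no real lateral solution: invalid material constants")
    return float(brentq(lateral_stress, lo, hi, xtol=1e-14, rtol=1e-14))


def uniaxial_nominal_stress(
    lam_axial: np.ndarray | float, mat: MaterialConstants
) -> np.ndarray | float:
    """Engineering (nominal) stress under uniaxial loading.

    Under the standard convention this is
    ``sum_j C_j (l^(b_j - 1) - l^(-nu b_j - 1))``.
    """
    scalar = np.isscalar(lam_axial)
    lam = np.atleast_1d(np.asarray(lam_axial, dtype=float))
    if np.any(lam <= 0):
        raise ValueError("axial stretch must be positive")
    n_std = penalty_exponent(mat.poisson, "standard")
    if abs(mat.penalty_exp - n_std) <= 1e-12 * max(1.0, abs(n_std)):
        out = _nominal_closed_form(lam, mat.coefficients, mat.exponents, mat.poisson)
    else:
        out = np.empty_like(lam)
        for i, la in enumerate(lam):
            ll = lateral_stretch(float(la), mat)
            J = la * ll**2
            s = principal_stress_values(
                np.array([la, ll, ll]), J, mat.coefficients, mat.exponents,
                mat.penalty_exp,
            )
            out[i] = s[0] * J / la
    return float(out[0]) if scalar else out


def _nominal_closed_form(
    lam: np.ndarray, C: np.ndarray, b: np.ndarray, nu: float
) -> np.ndarray:
    lam = lam[..., None]
    return np.sum(C * (lam ** (b - 1.0) - lam ** (-nu * b - 1.0)), axis=-1)


def fit_constants_to_curve(
    curve: LoadCurve,
    nu: float,
    exponents: Sequence[float] = DEFAULT_EXPONENTS,
    density: float = 1000.0,
    bulk_modulus: float = 1e5,
    shear_modulus: float = 2e4,
    rms_limit: float = 0.05,
    allow_poor_fit: bool = False,
) -> MaterialConstants:
    """Least-squares fit of the coefficients ``C_j`` to an engineering curve.

    The design matrix is the closed-form uniaxial nominal stress, which is
    linear in the coefficients; the SFO-scaled ordinates are the target.
    Fits with RMS residual above ``rms_limit`` times the peak stress are
    rejected unless ``allow_poor_fit`` is set.
    """
    b = np.asarray(exponents, dtype=float)
    if len(np.unique(b)) != len(b):
        raise ValueError("duplicate exponents make the design rank-deficient")
    if len(curve.strain) < len(b):
        raise ValueError("need at least as many curve samples as exponents")
    lam = 1.0 + curve.strain
    if np.any(lam <= 0):
        raise ValueError("curve strains reach or cross -1 (non-positive stretch)")
    A = lam[:, None] ** (b - 1.0) - lam[:, None] ** (-nu * b - 1.0)
    y = curve.scaled_stress
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = A @ coef - y
    rms = float(np.sqrt(np.mean(resid**2)))
    peak = float(np.max(np.abs(y))) if np.any(y) else 1.0
    if rms > rms_limit * peak and not allow_poor_fit:
        raise ValueError(
            f"curve fit RMS {rms:g} exceeds {rms_limit:.0%} of peak stress {peak:g}; "
            "pass allow_poor_fit=True to override or change the exponent set"
        )
    return MaterialConstants(
        density=density,
        bulk_modulus=bulk_modulus,
        shear_modulus=shear_modulus,
        poisson=nu,
        penalty_exp=penalty_exponent(nu, "standard"),
        terms=tuple(zip(coef.tolist(), b.tolist())),
        fit_rms=rms,
    )


# ---------------------------------------------------------------------------
# runtime materials for the solver


@dataclass
class FoamMaterial:
    """Curve- or constants-driven foam material used by the solver.

    ``scale`` is a runtime ordinate multiplier (the SFO of the part): every
    stress output is exactly ``scale`` times the unscaled response.
    ``mass_scale`` multiplies the density used for inertia; it exists so that
    quasi-static fixtures can keep their dynamic trajectory independent of
    the stiffness scale.
    """

    constants: MaterialConstants
    scale: float = 1.0
    mass_scale: float = 1.0

    @classmethod
    def from_curve(
        cls,
        curve: LoadCurve,
        nu: float,
        sfo: float = 1.0,
        exponents: Sequence[float] = DEFAULT_EXPONENTS,
        **kwargs,
    ) -> "FoamMaterial":
        base = fit_constants_to_curve(curve, nu, exponents, **kwargs)
        return cls(constants=base, scale=sfo)

    @property
    def density(self) -> float:
        return self.constants.density * self.mass_scale

    @property
    def wave_speed(self) -> float:
        return float(
            np.sqrt(
                (self.constants.bulk_modulus + 4.0 * self.constants.shear_modulus / 3.0)
                / self.density
            )
        )

    def principal_stress(
        self, lam: np.ndarray, J: np.ndarray, rate: np.ndarray | None = None
    ) -> np.ndarray:
        del rate  # rate-independent
        s = principal_stress_values(
            lam, J, self.constants.coefficients, self.constants.exponents,
            self.constants.penalty_exp,
        )
        return s * self.scale


@dataclass
class RateDependentFoam:
    """Foam material with coefficients interpolated in log(strain rate).

    One coefficient set is fitted per tabulated rate using a shared exponent
    set; because the fit is linear in the ordinates, interpolating the fitted
    coefficients in log(rate) is identical to fitting the log-rate
    interpolated curve.
    """

    rates: np.ndarray
    coef_by_rate: np.ndarray  # (n_rates, m)
    exponents: np.ndarray
    constants: MaterialConstants  # density/K/G/nu carrier (coefs of lowest rate)
    scale: float = 1.0
    mass_scale: float = 1.0

    @classmethod
    def from_table(
        cls,
        table: RateTable,
        nu: float,
        sfo: float = 1.0,
        exponents: Sequence[float] = DEFAULT_EXPONENTS,
        **kwargs,
    ) -> "RateDependentFoam":
        fits = [
            fit_constants_to_curve(c, nu, exponents, **kwargs)
            for _, c in table.entries
        ]
        coefs = np.array([f.coefficients for f in fits])
        return cls(
            rates=table.rates,
            coef_by_rate=coefs,
            exponents=np.asarray(exponents, dtype=float),
            constants=fits[0],
            scale=sfo,
        )

    @property
    def density(self) -> float:
        return self.constants.density * self.mass_scale

    @property
    def wave_speed(self) -> float:
        return float(
            np.sqrt(
                (self.constants.bulk_modulus + 4.0 * self.constants.shear_modulus / 3.0)
                / self.density
            )
        )

    def coefficients_at(self, rate: np.ndarray) -> np.ndarray:
        """Per-element coefficient sets, clamped outside the tabulated range."""
        rate = np.clip(np.asarray(rate, dtype=float), self.rates[0], self.rates[-1])
        logr = np.log(rate)
        logt = np.log(self.rates)
        out = np.empty(rate.shape + (self.coef_by_rate.shape[1],))
        for j in range(self.coef_by_rate.shape[1]):
            out[..., j] = np.interp(logr, logt, self.coef_by_rate[:, j])
        return out

    def principal_stress(
        self, lam: np.ndarray, J: np.ndarray, rate: np.ndarray | None = None
    ) -> np.ndarray:
        if rate is None:
            rate = np.full(J.shape[:1] if J.ndim else (), self.rates[0])
        C = self.coefficients_at(rate)  # (E, m)
        if lam.ndim == 3:  # (E, gp, 3): broadcast coefficients over gauss points
            C = C[:, None, :]
        s = principal_stress_values(
            lam, J, C, self.exponents, self.constants.penalty_exp
        )
        return s * self.scale
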