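"""Continuous density-property surrogates fitted to homogenization sweeps.

The effective Young's modulus ratio ``E_bar/Es`` is modelled as a quadratic
in the relative density ``rho`` and the effective Poisson ratio
``nu_bar/nus`` as a cubic.  The fitted polynomials replace per-density
homogenization inside the optimizer, where element stiffnesses are evaluated
thousands of times.

Extrapolation is unsafe (the quadratic exceeds 1 well below full density),
so evaluation outside the fitted domain either clamps with a warning or
raises, per configuration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class UnderdeterminedFitError(ValueError):
    """Raised when fewer distinct densities than polynomial coefficients."""


#: Octet-truss coefficients reported in the graded-implant literature for a
#: titanium cell homogenized over rho in [0.1, 0.8]; handy as a sweep-free
#: default and as a cross-check for the package's own fits.
REFERENCE_E_COEFFS = (1.23, -0.2411, 0.03213)  # a2, a1, a0
REFERENCE_NU_COEFFS = (0.7165, -0.7995, -0.05101, 1.134)  # b3, b2, b1, b0


@dataclass
class SurrogateModel:
    """Polynomial surrogates ``E_bar(rho)`` and ``nu_bar(rho)``.

    ``e_coeffs = (a2, a1, a0)`` gives ``E_bar/Es = a2 rho^2 + a1 rho + a0``;
    ``nu_coeffs = (b3, b2, b1, b0)`` gives
    ``nu_bar/nus = b3 rho^3 + b2 rho^2 + b1 rho + b0``.
    """

    e_coeffs: tuple[float, float, float]
    nu_coeffs: tuple[float, float, float, float]
    r2_E: float = 1.0
    r2_nu: float = 1.0
    rho_domain: tuple[float, float] = (0.1, 0.8)
    Es: float = 110000.0  # MPa
    nus: float = 0.3
    clamp: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2_E <= 1.0 and 0.0 <= self.r2_nu <= 1.0):
            raise ValueError("R-squared values must lie in [0, 1]")
        lo, hi = self.rho_domain
        if not lo < hi:
            raise ValueError("rho_domain must be a non-empty interval")

    # -- evaluation ---------------------------------------------------------

    def _check_domain(self, rho):
        lo, hi = self.rho_domain
        rho = np.asarray(rho, dtype=float)
        if np.any(rho < lo - 1e-12) or np.any(rho > hi + 1e-12):
            if not self.clamp:
                raise ValueError(
                    f"density outside surrogate domain [{lo}, {hi}] with clamping disabled"
                )
            warnings.warn(
                f"density outside surrogate domain [{lo}, {hi}]; clamping",
                RuntimeWarning,
                stacklevel=3,
            )
        return np.clip(rho, lo, hi)

    def modulus(self, rho):
        """Effective Young's modulus, MPa."""
        rho = self._check_domain(rho)
        a2, a1, a0 = self.e_coeffs
        return (a2 * rho**2 + a1 * rho + a0) * self.Es

    def poisson(self, rho):
        """Effective Poisson ratio, dimensionless."""
        rho = self._check_domain(rho)
        b3, b2, b1, b0 = self.nu_coeffs
        return (b3 * rho**3 + b2 * rho**2 + b1 * rho + b0) * self.nus

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "e_coeffs": list(self.e_coeffs),
            "nu_coeffs": list(self.nu_coeffs),
            "r2_E": self.r2_E,
            "r2_nu": self.r2_nu,
            "rho_domain": list(self.rho_domain),
            "Es": self.Es,
            "nus": self.nus,
            "clamp": self.clamp,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SurrogateModel":
        payload = json.loads(Path(path).read_text())
        payload["e_coeffs"] = tuple(payload["e_coeffs"])
        payload["nu_coeffs"] = tuple(payload["nu_coeffs"])
        payload["rho_domain"] = tuple(payload["rho_domain"])
        return cls(**payload)

    @classmethod
    def with_reference_coefficients(
        cls, Es: float = 110000.0, nus: float = 0.3
    ) -> "SurrogateModel":
        return cls(
            e_coeffs=REFERENCE_E_COEFFS,
            nu_coeffs=REFERENCE_NU_COEFFS,
            Es=Es,
            nus=nus,
        )


def evaluate(model: SurrogateModel, rho):
    """``(E_bar MPa, nu_bar)`` at density ``rho`` (scalar or array)."""
    return model.modulus(rho), model.poisson(rho)


def _poly_fit(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[np.ndarray, float]:
    if len(np.unique(x)) < degree + 1:
        raise UnderdeterminedFitError(
            f"need at least {degree + 1} distinct densities for a degree-{degree} fit"
        )
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)  # ascending order
    resid = y - np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return coeffs[::-1], min(max(r2, 0.0), 1.0)  # descending order


def fit(
    sweep: pd.DataFrame | np.ndarray,
    *,
    Es: float = 110000.0,
    nus: float = 0.3,
) -> SurrogateModel:
    """Least-squares fit of the stated polynomial degrees to sweep samples.

    ``sweep`` holds columns/rows ``(rho, E_ratio, nu_ratio)`` with the
    property ratios relative to the solid constituent.  At least four
    distinct densities are required (the cubic needs them).
    """
    if isinstance(sweep, pd.DataFrame):
        rho = sweep.iloc[:, 0].to_numpy(float)
        e_ratio = sweep.iloc[:, 1].to_numpy(float)
        nu_ratio = sweep.iloc[:, 2].to_numpy(float)
    else:
        arr = np.asarray(sweep, dtype=float)
        rho, e_ratio, nu_ratio = arr[:, 0], arr[:, 1], arr[:, 2]
    e_coeffs, r2_E = _poly_fit(rho, e_ratio, 2)
    nu_coeffs, r2_nu = _poly_fit(rho, nu_ratio, 3)
    return SurrogateModel(
        e_coeffs=tuple(e_coeffs),
        nu_coeffs=tuple(nu_coeffs),
        r2_E=r2_E,
        r2_nu=r2_nu,
        rho_domain=(float(rho.min()), float(rho.max())),
        Es=Es,
        nus=nus,
    )


def fit_from_sweep_rows(
    rows: list[dict], *, Es: float = 110000.0, nus: float = 0.3
) -> SurrogateModel:
    """Fit directly from :func:`latticeimplant.homogenization.density_sweep` rows.

    The modulus ratio uses the axial engineering constant ``E1`` (the three
    axes agree for the cubic-symmetric octet) and the Poisson ratio ``nu12``.
    """
    table = np.array(
        [
            (row["rho"], row["constants"].E1 / Es, row["constants"].nu12 / nus)
            for row in rows
        ]
    )
    return fit(table, Es=Es, nus=nus)
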