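"""Steady-state spectrum operations and pH-titration fitting.

Covers the bench workflow around a purified retinal protein: locating the
absorption maximum with sub-grid precision, the A280/Apeak purity index, the
oxime-referenced extinction coefficient from a hydroxylamine-bleach
difference spectrum (the retinal oxime, eps = 33,600 M^-1 cm^-1, serves as
an internal standard: eps_Rh = eps_oxime * dA_Rh / dA_oxime), and double
Henderson-Hasselbalch fits to lambda_max(pH) titration curves with an acidic
(pK2) and a basic (pK1) transition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Spectrum",
    "BleachDifference",
    "TitrationFit",
    "OXIME_EPSILON",
    "find_lambda_max",
    "purity_index",
    "compute_extinction",
    "fit_titration",
]

#: Molar extinction of the retinal oxime bleach product, M^-1 cm^-1.
OXIME_EPSILON = 33_600.0


@dataclass
class Spectrum:
    """Absorbance vs wavelength on a strictly increasing grid."""

    wavelengths: np.ndarray  # nm
    absorbance: np.ndarray  # OD

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelength and absorbance axes must be equal-length 1-D")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def at(self, wavelength: float) -> float:
        """Absorbance linearly interpolated at one wavelength."""
        if not self.wavelengths[0] <= wavelength <= self.wavelengths[-1]:
            raise ValueError(f"{wavelength} nm outside the spectrum range")
        return float(np.interp(wavelength, self.wavelengths, self.absorbance))


@dataclass
class BleachDifference:
    """Difference spectrum (after - before) of a hydroxylamine bleach."""

    difference: Spectrum
    dA_rhodopsin: float  # |negative extremum|: bleached chromophore
    dA_oxime: float  # |positive extremum|: oxime product
    oxime_epsilon: float = OXIME_EPSILON

    def __post_init__(self) -> None:
        if not (self.dA_rhodopsin > 0 and self.dA_oxime > 0):
            raise ValueError("both difference extrema must be positive magnitudes")
        if not self.oxime_epsilon > 0:
            raise ValueError("oxime reference extinction must be positive")

    @classmethod
    def from_spectra(cls, before: Spectrum, after: Spectrum,
                     oxime_epsilon: float = OXIME_EPSILON) -> "BleachDifference":
        if before.wavelengths.shape != after.wavelengths.shape or np.any(
            before.wavelengths != after.wavelengths
        ):
            raise ValueError("before/after spectra must share the wavelength grid")
        diff = after.absorbance - before.absorbance
        return cls(
            Spectrum(before.wavelengths.copy(), diff),
            dA_rhodopsin=float(-diff.min()),
            dA_oxime=float(diff.max()),
            oxime_epsilon=oxime_epsilon,
        )


@dataclass
class TitrationFit:
    """Double (or single) Henderson-Hasselbalch parameters.

    ``pk_low`` is the acidic transition (pK2 convention), ``pk_high`` the
    basic one (pK1); plateaus are the asymptotic observables in the acid,
    intermediate and base regimes.
    """

    pk_low: float
    pk_high: float
    plateau_acid: float
    plateau_mid: float
    plateau_base: float
    fit_rms: float
    n_transitions: int = 2
    hill_low: float = 1.0
    hill_high: float = 1.0
    acid_plateau_extrapolated: bool = False


def find_lambda_max(s: Spectrum, window: float = 20.0, lambda_range=None) -> float:
    """Peak wavelength refined by a local quadratic fit around the grid maximum.

    ``window`` (nm) sets the neighbourhood used for the parabola;
    ``lambda_range = (lo, hi)`` restricts the search (e.g. to the visible
    chromophore band, away from the 280 nm protein peak).  Raises if the grid
    maximum sits at the searched range's edge (no interior peak).
    """
    if lambda_range is not None:
        lo, hi = lambda_range
        mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
        if mask.sum() < 5:
            raise ValueError("fewer than 5 points in the searched range")
        s = Spectrum(s.wavelengths[mask], s.absorbance[mask])
    i = int(np.argmax(s.absorbance))
    if i == 0 or i == s.wavelengths.size - 1:
        raise ValueError("maximum at spectrum edge: no interior peak")
    sel = np.abs(s.wavelengths - s.wavelengths[i]) <= window / 2.0
    if sel.sum() < 5:
        raise ValueError("fewer than 5 points in the refinement window")
    x, y = s.wavelengths[sel], s.absorbance[sel]
    c2, c1, _ = np.polyfit(x - s.wavelengths[i], y, 2)
    if c2 >= 0:  # degenerate curvature: fall back to the grid maximum
        return float(s.wavelengths[i])
    peak = float(s.wavelengths[i] - c1 / (2.0 * c2))
    return float(np.clip(peak, s.wavelengths[0], s.wavelengths[-1]))


def purity_index(s: Spectrum, chromophore_peak: float) -> float:
    """A(280 nm) / A(peak): the protein-to-chromophore purity factor (~1.3
    for a clean preparation once 280 nm scattering is included)."""
    a_peak = s.at(chromophore_peak)
    if a_peak <= 0:
        raise ValueError("non-positive absorbance at the chromophore peak")
    return s.at(280.0) / a_peak


def compute_extinction(bd: BleachDifference) -> float:
    """eps_rhodopsin = eps_oxime * dA(Rh) / dA(oxime), M^-1 cm^-1."""
    if bd.dA_oxime == 0:
        raise ValueError("zero oxime difference amplitude")
    return bd.oxime_epsilon * bd.dA_rhodopsin / bd.dA_oxime


# ---------------------------------------------------------------------------
# Titration fitting
# ---------------------------------------------------------------------------


def _hh_basis(pH, pks, hills):
    """Design matrix mapping (acid .. base plateaus) -> observable at each pH.

    Additive Henderson-Hasselbalch steps:
    value = p_base + sum_j (p_j - p_{j+1}) / (1 + 10**(h_j * (pH - pk_j)))
    with plateaus ordered acid-most first, so the coefficient of the acid-most
    plateau is f_0, of an interior plateau f_j - f_{j-1}, and of the base
    plateau 1 - f_{n-1}, where f_j is the acid-side fraction of transition j.
    """
    pH = np.asarray(pH, dtype=float)
    n = len(pks)  # transitions; n+1 plateaus
    f = [1.0 / (1.0 + 10.0 ** (h * (pH - pk))) for pk, h in zip(pks, hills)]
    cols = [f[0]]
    cols += [f[j] - f[j - 1] for j in range(1, n)]
    cols.append(1.0 - f[n - 1])
    return np.column_stack(cols)


def fit_titration(
    table,
    n_transitions: int = 2,
    free_hill: bool = False,
    value_column: str = "lambda_max_nm",
) -> TitrationFit:
    """Fit a single or double Henderson-Hasselbalch curve to a titration table.

    Parameters
    ----------
    table : DataFrame with columns ``pH`` and ``value_column``, or a
        ``(pH, values)`` pair of arrays.  The observable is typically the
        absorption maximum (nm) but any spectral observable works.
    n_transitions : 1 or 2
        One transition fits (pK, two plateaus); two fit (pK2 acidic, pK1
        basic, three plateaus).
    free_hill : bool
        Also fit Hill coefficients (default fixed at 1, pure
        Henderson-Hasselbalch behaviour).

    Plateaus are solved linearly at each trial pK set (the model is linear in
    them), so the nonlinear search runs only over the pKs (+ Hill slopes).
    An acid plateau extrapolated beyond the sampled pH range is flagged.
    """
    if n_transitions not in (1, 2):
        raise ValueError("n_transitions must be 1 or 2")
    if isinstance(table, pd.DataFrame):
        pH = table["pH"].to_numpy(dtype=float)
        y = table[value_column].to_numpy(dtype=float)
    else:
        pH, y = (np.asarray(a, dtype=float) for a in table)
    order = np.argsort(pH)
    pH, y = pH[order], y[order]
    n_params = 2 * n_transitions + 1 + (n_transitions if free_hill else 0)
    if pH.size < n_params:
        raise ValueError("fewer points than fit parameters")
    if np.ptp(y) == 0:
        raise ValueError("constant observable: nothing to fit")

    def unpack(x):
        pks = np.sort(x[:n_transitions])
        hills = np.abs(x[n_transitions:]) if free_hill else np.ones(n_transitions)
        return pks, hills

    def residual(x):
        pks, hills = unpack(x)
        basis = _hh_basis(pH, pks, hills)
        plateaus, *_ = np.linalg.lstsq(basis, y, rcond=None)
        return basis @ plateaus - y

    lo, hi = pH.min(), pH.max()
    if n_transitions == 1:
        starts = [[q] for q in np.quantile(pH, [0.25, 0.5, 0.75])]
    else:
        starts = [
            [lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo)],
            [lo + 0.35 * (hi - lo), hi - 0.35 * (hi - lo)],
            [lo + 0.1 * (hi - lo), hi - 0.45 * (hi - lo)],
        ]
    best = None
    for s0 in starts:
        x0 = np.array(s0 + ([1.0] * n_transitions if free_hill else []))
        sol = least_squares(residual, x0, method="lm", ftol=1e-12, xtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol

    pks, hills = unpack(best.x)
    basis = _hh_basis(pH, pks, hills)
    plateaus, *_ = np.linalg.lstsq(basis, y, rcond=None)
    resid = basis @ plateaus - y
    extrapolated = bool(pks[0] < lo + 0.5)
    if extrapolated:
        warnings.warn(
            "acidic transition midpoint near/below the sampled pH range; "
            "the acid plateau is an extrapolation",
            stacklevel=2,
        )
    if n_transitions == 1:
        return TitrationFit(
            pk_low=float(pks[0]), pk_high=float(pks[0]),
            plateau_acid=float(plateaus[0]), plateau_mid=float("nan"),
            plateau_base=float(plateaus[1]),
            fit_rms=float(np.sqrt(np.mean(resid**2))),
            n_transitions=1, hill_low=float(hills[0]), hill_high=float(hills[0]),
            acid_plateau_extrapolated=extrapolated,
        )
    return TitrationFit(
        pk_low=float(pks[0]), pk_high=float(pks[1]),
        plateau_acid=float(plateaus[0]), plateau_mid=float(plateaus[1]),
        plateau_base=float(plateaus[2]),
        fit_rms=float(np.sqrt(np.mean(resid**2))),
        n_transitions=2, hill_low=float(hills[0]), hill_high=float(hills[1]),
        acid_plateau_extrapolated=extrapolated,
    )
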