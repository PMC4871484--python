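"""First-order photocycle kinetics.

A photocycle is modelled as a set of named states (one ground state plus
photo-intermediates), each carrying an absorption band, coupled by first-order
rate constants.  Populations evolve as ``dc/dt = K c`` where ``K`` is the rate
matrix (column-conserving: off-diagonals are rate constants *into* a state,
each diagonal is minus its column sum).  The module solves this analytically
by eigen-decomposition, predicts the decay-associated spectra (DAS) a global
exponential fit would see, quantifies how a transient intermediate can remain
kinetically invisible when its formation and decay rates match, and models the
photostationary proton-pump current including the blue-light shunt through the
M intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "SpectralBand",
    "PhotocycleState",
    "PhotocycleScheme",
    "PopulationTrajectory",
    "e17r_scheme",
    "simulate_populations",
    "predict_das",
    "max_transient_occupancy",
    "steady_state_current",
    "DEFAULT_EXCITED_FRACTION",
    "DEFAULT_CONCENTRATION",
    "DEFAULT_PATHLENGTH",
]

# Scale factors shared with the synthetic-data generator: a typical detergent
# sample (ground-state A524 ~ 0.1 for a 1 cm cuvette) of which the flash
# excites 15%, giving bleach/DAS amplitudes of order 10 mOD.
DEFAULT_EXCITED_FRACTION = 0.15
DEFAULT_CONCENTRATION = 2.0e-6  # M
DEFAULT_PATHLENGTH = 1.0  # cm

# Relative tolerance below which two eigen-lifetimes are treated as one
# kinetic mode (exactly repeated eigenvalues of a diagonalizable matrix).
_EIGEN_MERGE_RTOL = 1e-9
_DIAG_COND_LIMIT = 1e10


@dataclass(frozen=True)
class SpectralBand:
    """Absorption band: a (possibly asymmetric) Gaussian in wavelength.

    Parameters
    ----------
    center : float
        Peak wavelength in nm.
    width : float
        Full width at half maximum in nm.
    peak_extinction : float
        Molar extinction at the peak, M^-1 cm^-1.
    skew : float
        Dimensionless asymmetry in (-1, 1); the red/blue half-widths are
        ``width * (1 +/- skew)`` (a bifurcated Gaussian, a standard
        lineshape for retinal-protein bands).  0 gives a symmetric band.
    """

    center: float
    width: float
    peak_extinction: float
    skew: float = 0.0

    def __post_init__(self) -> None:
        if not self.center > 0:
            raise ValueError("band center must be positive (nm)")
        if not self.width > 0:
            raise ValueError("band FWHM must be positive (nm)")
        if self.peak_extinction < 0:
            raise ValueError("peak extinction must be non-negative")
        if not -1 < self.skew < 1:
            raise ValueError("skew must lie in (-1, 1)")

    def extinction(self, wavelengths) -> np.ndarray:
        """Molar extinction evaluated at ``wavelengths`` (nm)."""
        wl = np.asarray(wavelengths, dtype=float)
        dx = wl - self.center
        half = np.where(dx >= 0, 1.0 + self.skew, 1.0 - self.skew) * self.width / 2.0
        sigma = half / np.sqrt(2.0 * np.log(2.0))
        return self.peak_extinction * np.exp(-0.5 * (dx / sigma) ** 2)


@dataclass(frozen=True)
class PhotocycleState:
    name: str
    band: SpectralBand
    is_ground: bool = False


@dataclass
class PhotocycleScheme:
    """States plus first-order rate matrix.

    ``rate_matrix[i, j]`` for ``i != j`` is the rate constant (s^-1) of the
    ``j -> i`` transition; diagonals are minus the column sums so that total
    population is conserved.  ``initial_populations`` are the fractions of the
    *excited* sub-ensemble at t = 0+ (the flash itself is not modelled; the
    first intermediate is formed within the instrument response).
    """

    states: list[PhotocycleState]
    rate_matrix: np.ndarray
    initial_populations: np.ndarray

    def __post_init__(self) -> None:
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        self.initial_populations = np.asarray(self.initial_populations, dtype=float)
        n = len(self.states)
        if self.rate_matrix.shape != (n, n):
            raise ValueError("rate matrix shape must match number of states")
        if self.initial_populations.shape != (n,):
            raise ValueError("initial populations must match number of states")
        off = self.rate_matrix.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rate constants must be >= 0")
        col = -off.sum(axis=0)
        if not np.allclose(np.diag(self.rate_matrix), col, rtol=1e-9, atol=1e-12):
            raise ValueError("rate matrix diagonal must equal minus its column sum")
        if not np.isclose(self.initial_populations.sum(), 1.0, atol=1e-9):
            raise ValueError("initial populations must sum to 1")
        if sum(s.is_ground for s in self.states) != 1:
            raise ValueError("exactly one state must be flagged as ground")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.states]

    @property
    def ground_index(self) -> int:
        return next(i for i, s in enumerate(self.states) if s.is_ground)

    def state_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no state named {name!r}") from None

    def delta_extinction(self, wavelengths) -> np.ndarray:
        """(n_states, n_wavelengths) matrix of eps_s(lambda) - eps_ground(lambda)."""
        eps_g = self.states[self.ground_index].band.extinction(wavelengths)
        return np.array([s.band.extinction(wavelengths) - eps_g for s in self.states])


@dataclass
class PopulationTrajectory:
    times: np.ndarray
    populations: np.ndarray  # (n_states, n_times)
    names: list[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.populations[self.names.index(name)]


# ---------------------------------------------------------------------------
# Default E17R scheme
# ---------------------------------------------------------------------------

E17R_LIFETIMES = (3.5e-6, 84e-6, 11e-3, 82e-3)  # s; tau_1 .. tau_4


def e17r_scheme(
    lifetimes: tuple[float, float, float, float] = E17R_LIFETIMES,
    m_branch_fraction: float = 0.1,
) -> PhotocycleScheme:
    """Default green-PR photocycle: four observed lifetimes plus a hidden M.

    The main path is a linear chain of red-shifted intermediates
    ``P1 -> P2 -> P3 -> P4 -> ground`` with the four rate constants equal to
    the reciprocal observed lifetimes (a sequential irreversible chain has a
    triangular rate matrix, so the eigen-lifetimes equal the step lifetimes
    exactly).  The blue-absorbing M state branches off P1 with a small
    fraction and decays at the *same* rate as the parallel 84 us step, so it
    contributes no fifth kinetic mode: the eigenvalue is repeated but the
    matrix remains diagonalizable (M and P2 are uncoupled), and M's transient
    occupancy stays small — kinetically invisible in the flash-photolysis
    data, yet present for blue-light excitation.
    """
    if not 0 <= m_branch_fraction < 1:
        raise ValueError("m_branch_fraction must lie in [0, 1)")
    k1, k2, k3, k4 = (1.0 / t for t in lifetimes)
    states = [
        PhotocycleState("P1", SpectralBand(560.0, 100.0, 52_000.0)),  # K-like
        PhotocycleState("P2", SpectralBand(600.0, 110.0, 42_000.0)),
        PhotocycleState("M", SpectralBand(400.0, 80.0, 25_000.0)),
        PhotocycleState("P3", SpectralBand(600.0, 110.0, 52_000.0)),  # O-like
        PhotocycleState("P4", SpectralBand(560.0, 100.0, 50_000.0)),
        PhotocycleState("ground", SpectralBand(524.0, 100.0, 50_000.0), is_ground=True),
    ]
    n = len(states)
    K = np.zeros((n, n))

    def edge(src: str, dst: str, k: float) -> None:
        i = [s.name for s in states].index(dst)
        j = [s.name for s in states].index(src)
        K[i, j] += k
        K[j, j] -= k

    edge("P1", "P2", (1.0 - m_branch_fraction) * k1)
    edge("P1", "M", m_branch_fraction * k1)
    edge("P2", "P3", k2)
    edge("M", "P3", k2)  # matched to the parallel decay: no extra mode
    edge("P3", "P4", k3)
    edge("P4", "ground", k4)
    c0 = np.zeros(n)
    c0[0] = 1.0
    return PhotocycleScheme(states, K, c0)


# ---------------------------------------------------------------------------
# Analytic propagation
# ---------------------------------------------------------------------------


def _eigen_system(scheme: PhotocycleScheme):
    """Eigen-decomposition of the rate matrix with diagonalizability check."""
    w, V = scipy.linalg.eig(scheme.rate_matrix)
    if np.linalg.cond(V) > _DIAG_COND_LIMIT:
        raise ValueError(
            "rate matrix is not diagonalizable (or nearly defective); "
            "perturb near-equal coupled rate constants slightly"
        )
    a = scipy.linalg.solve(V, scheme.initial_populations.astype(complex))
    return w, V, a


def simulate_populations(scheme: PhotocycleScheme, times) -> PopulationTrajectory:
    """Populations c(t) solving dc/dt = K c, analytically via eigenmodes."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    w, V, a = _eigen_system(scheme)
    c = (V @ (a[:, None] * np.exp(w[:, None] * times[None, :]))).real
    return PopulationTrajectory(times, c, scheme.names)


def predict_das(
    scheme: PhotocycleScheme,
    wavelengths,
    excited_fraction: float = DEFAULT_EXCITED_FRACTION,
    concentration: float = DEFAULT_CONCENTRATION,
    pathlength: float = DEFAULT_PATHLENGTH,
) -> tuple[np.ndarray, np.ndarray]:
    """Lifetimes and decay-associated spectra the scheme produces.

    DeltaA(lambda, t) = scale * sum_s Delta eps_s(lambda) c_s(t) is an exact
    sum of exponentials with rates given by the eigenvalues of K; the DAS of
    mode i is ``scale * sum_s Delta eps_s(lambda) V[s, i] a_i``.  The zero
    mode (stationary ground state) carries no amplitude because
    Delta eps_ground = 0.  Exactly repeated eigenvalues of a diagonalizable
    matrix are one kinetic mode: their DAS are summed.

    Returns ``(lifetimes ascending [s], das (n_modes, n_wavelengths) [OD])``.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    w, V, a = _eigen_system(scheme)
    if np.max(np.abs(w.imag)) > 1e-9 * max(np.max(np.abs(w.real)), 1.0):
        raise ValueError("oscillatory (complex) kinetic modes are not DAS-representable")
    w = w.real
    scale = excited_fraction * concentration * pathlength
    deps = scheme.delta_extinction(wavelengths)  # (n_states, n_wl)
    amps = scale * ((V * a[None, :]).real.T @ deps)  # (n_modes, n_wl)

    decaying = w < -1e-12 * np.max(np.abs(w))  # exclude the zero (stationary) mode
    rates = -w[decaying]
    amps = amps[decaying]
    order = np.argsort(-rates)  # ascending lifetime
    rates, amps = rates[order], amps[order]

    lifetimes: list[float] = []
    das_rows: list[np.ndarray] = []
    for r, row in zip(rates, amps):
        if lifetimes and abs(1.0 / r - lifetimes[-1]) <= _EIGEN_MERGE_RTOL * lifetimes[-1]:
            das_rows[-1] = das_rows[-1] + row
        else:
            lifetimes.append(1.0 / r)
            das_rows.append(row.copy())
    return np.array(lifetimes), np.array(das_rows)


def max_transient_occupancy(k_formation: float, k_decay: float) -> float:
    """Peak fractional population of B in A -> B -> C.

    Closed form ``(k1/k2)**(k2/(k2-k1))`` for distinct rates; the continuous
    limit for matched rates is 1/e — the kinetic-invisibility condition: an
    intermediate formed and consumed at similar rates never accumulates a
    distinct kinetic signature.
    """
    if not (k_formation > 0 and k_decay > 0):
        raise ValueError("both rate constants must be positive")
    if k_formation == k_decay:
        return float(np.exp(-1.0))
    r = k_formation / k_decay
    return float(r ** (k_decay / (k_decay - k_formation)))


def steady_state_current(
    scheme: PhotocycleScheme,
    green_rate: float,
    blue_rate: float,
    shunt_branch_ratio: float = 1.0,
    m_state: str = "M",
) -> float:
    """Relative photostationary pump current under green + blue illumination.

    Green light drives ground -> cycle entry at ``green_rate`` (s^-1,
    population-weighted over the scheme's t=0+ entry states).  Blue light
    excites the M intermediate, a fraction ``shunt_branch_ratio`` of which
    shunts straight back to the ground state, skipping the proton-release
    steps.  The photostationary populations are the null space of the
    augmented rate matrix; the pumped current is the flux into the ground
    state through the scheme's original edges (the shunt edge carries no
    pumped charge).  Returned normalized to the blue_rate = 0 current.
    """
    if green_rate < 0 or blue_rate < 0:
        raise ValueError("illumination rates must be >= 0")
    if not 0 <= shunt_branch_ratio <= 1:
        raise ValueError("shunt branch ratio must lie in [0, 1]")
    if green_rate == 0:
        raise ValueError("no excitation: green_rate must be positive for a steady state")
    g = scheme.ground_index
    m = scheme.state_index(m_state)

    def pump_flux(shunt: float) -> float:
        K = scheme.rate_matrix.copy()
        # ground -> entry states at green_rate, split like the t=0+ populations
        for j, frac in enumerate(scheme.initial_populations):
            if frac > 0:
                K[j, g] += green_rate * frac
                K[g, g] -= green_rate * frac
        K[g, m] += shunt
        K[m, m] -= shunt
        # photostationary state: null vector of K, normalized to sum 1
        _, _, vh = np.linalg.svd(K)
        c = vh[-1].real
        c = c / c.sum()
        if np.any(c < -1e-9):
            raise ValueError("no non-negative photostationary state found")
        # flux into ground via the ORIGINAL edges only
        orig = scheme.rate_matrix[g, :].copy()
        orig[g] = 0.0
        return float(orig @ c)

    ref = pump_flux(0.0)
    return pump_flux(blue_rate * shunt_branch_ratio) / ref
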