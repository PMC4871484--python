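"""Synthetic flash-photolysis, titration, bleach and sequence fixtures.

The generator emulates the acquisition geometry of a two-oscilloscope
flash-photolysis experiment on a green-tuned proteorhodopsin: 14 probe
wavelengths between 380 and 645 nm, 46,080 samples per oscilloscope at
200 ns/point (fast) and 20 us/point (slow), a 10 ns excitation flash at
503 nm, and independent Gaussian measurement noise.  The underlying signal is
the analytic bleach/absorption transient of a first-order photocycle scheme
(see :mod:`prflash.photocycle_model`): the first intermediate is fully formed
at the first sample (its formation lies below the time resolution).

Also generated here: lambda_max(pH) titration tables following a double
Henderson-Hasselbalch curve, hydroxylamine-bleach spectrum pairs for
extinction-coefficient round-trips, and synthetic proteorhodopsin-like toy
sequences with a known residue map (stand-ins for database accessions; no
real sequence data ships with the package).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .photocycle_model import (
    DEFAULT_CONCENTRATION,
    DEFAULT_EXCITED_FRACTION,
    DEFAULT_PATHLENGTH,
    PhotocycleScheme,
    SpectralBand,
    simulate_populations,
)

__all__ = [
    "PROBE_WAVELENGTHS",
    "AcquisitionConfig",
    "TraceSet",
    "make_photocycle_dataset",
    "noiseless_delta_absorbance",
    "make_titration_dataset",
    "double_henderson_hasselbalch",
    "make_bleach_pair",
    "make_toy_sequences",
    "TOY_ESR_ANNOTATIONS",
    "TOY_BPR_TUNING_POSITION",
]

#: Probe wavelengths (nm) of the monochromator/interference-filter set.
PROBE_WAVELENGTHS = (380, 400, 420, 440, 460, 480, 500, 517, 540, 562, 580, 600, 620, 645)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Two-oscilloscope acquisition geometry and noise model.

    Defaults are the experiment as run: 46,080 samples per oscilloscope
    (45 x 1024, the reading consistent with 880 log-reduced points), sampling
    at 200 ns and 20 us per point, excitation at 503 nm, and Gaussian noise
    of 0.3 mOD per sample.  ``fluence_mj_cm2`` is inert metadata.  Time zero
    is the flash; the first sample falls one sampling step after it.
    """

    probe_wavelengths: tuple = PROBE_WAVELENGTHS
    fast_dt: float = 200e-9
    slow_dt: float = 20e-6
    n_samples_per_scope: int = 46_080
    flash_time: float = 0.0
    flash_wavelength: float = 503.0
    noise_sd: float = 0.3e-3
    seed: int = 0
    excited_fraction: float = DEFAULT_EXCITED_FRACTION
    concentration: float = DEFAULT_CONCENTRATION
    pathlength: float = DEFAULT_PATHLENGTH
    fluence_mj_cm2: tuple = (5.0, 10.0)

    def __post_init__(self) -> None:
        wl = np.asarray(self.probe_wavelengths, dtype=float)
        if wl.size == 0:
            raise ValueError("probe wavelength list must not be empty")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("probe wavelengths must be strictly increasing")
        if not 0 < self.fast_dt < self.slow_dt:
            raise ValueError("require 0 < fast_dt < slow_dt")
        if self.n_samples_per_scope <= 0:
            raise ValueError("n_samples_per_scope must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["probe_wavelengths"] = list(self.probe_wavelengths)
        d["fluence_mj_cm2"] = list(self.fluence_mj_cm2)
        return d


@dataclass
class TraceSet:
    """DeltaA(lambda, t) on a uniform time base."""

    times: np.ndarray  # (n_times,) seconds, strictly increasing
    delta_A: np.ndarray  # (n_wavelengths, n_times) OD
    wavelengths: np.ndarray  # (n_wavelengths,) nm
    meta: AcquisitionConfig | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.delta_A = np.asarray(self.delta_A, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.delta_A.shape != (self.wavelengths.size, self.times.size):
            raise ValueError("delta_A shape must be (n_wavelengths, n_times)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def is_uniform(self) -> bool:
        dt = np.diff(self.times)
        return bool(dt.size == 0 or np.all(np.abs(dt - dt[0]) <= 1e-9 * dt[0]))


def noiseless_delta_absorbance(
    scheme: PhotocycleScheme,
    wavelengths,
    times,
    excited_fraction: float = DEFAULT_EXCITED_FRACTION,
    concentration: float = DEFAULT_CONCENTRATION,
    pathlength: float = DEFAULT_PATHLENGTH,
) -> np.ndarray:
    """Model DeltaA(lambda, t) = f * c0 * l * sum_s Delta eps_s(lambda) c_s(t)."""
    traj = simulate_populations(scheme, times)
    deps = scheme.delta_extinction(np.asarray(wavelengths, dtype=float))
    scale = excited_fraction * concentration * pathlength
    return scale * (deps.T @ traj.populations)


def make_photocycle_dataset(
    scheme: PhotocycleScheme, acq: AcquisitionConfig
) -> tuple[TraceSet, TraceSet]:
    """Simulate the fast- and slow-oscilloscope trace sets of one experiment.

    Both oscilloscopes digitize the same underlying transient; each records
    ``n_samples_per_scope`` samples starting one sampling step after the
    flash, with independent Gaussian noise of sd ``acq.noise_sd`` added per
    sample.  Deterministic for a given ``acq.seed``.
    """
    if not np.any(np.delete(scheme.initial_populations, scheme.ground_index) > 0):
        raise ValueError("scheme has no excited state populated at t = 0+")
    wl = np.asarray(acq.probe_wavelengths, dtype=float)
    rng = np.random.default_rng(acq.seed)
    out = []
    for dt in (acq.fast_dt, acq.slow_dt):
        t = acq.flash_time + dt * np.arange(1, acq.n_samples_per_scope + 1)
        dA = noiseless_delta_absorbance(
            scheme, wl, t - acq.flash_time,
            acq.excited_fraction, acq.concentration, acq.pathlength,
        )
        if acq.noise_sd > 0:
            dA = dA + rng.normal(0.0, acq.noise_sd, size=dA.shape)
        out.append(TraceSet(t, dA, wl, acq))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# pH titration
# ---------------------------------------------------------------------------


def double_henderson_hasselbalch(
    pH, pk_low: float, pk_high: float, plateau_acid: float,
    plateau_mid: float, plateau_base: float,
) -> np.ndarray:
    """lambda_max(pH) with two protonation transitions (Hill coefficient 1).

    lambda = base + (mid - base) / (1 + 10**(pH - pk_high))
                  + (acid - mid) / (1 + 10**(pH - pk_low))
    """
    pH = np.asarray(pH, dtype=float)
    return (
        plateau_base
        + (plateau_mid - plateau_base) / (1.0 + 10.0 ** (pH - pk_high))
        + (plateau_acid - plateau_mid) / (1.0 + 10.0 ** (pH - pk_low))
    )


def make_titration_dataset(
    pk_low: float = 3.0,
    pk_high: float = 10.0,
    plateaus: tuple[float, float, float] = (535.0, 525.0, 517.0),
    pH_grid=None,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic lambda_max(pH) titration table.

    ``plateaus`` are (acid, mid, base) in nm, ordered for the red shift on
    acidification seen for green proteorhodopsins (535 / 525 / 517 nm by
    default, transitions at pK ~3 and ~10).  Returns a DataFrame with columns
    ``pH`` and ``lambda_max_nm``; ``df.attrs["overlapping_pks"]`` flags pK
    separations below 0.5 units (transitions no longer resolvable).
    """
    if not pk_low < pk_high:
        raise ValueError("pk_low must be below pk_high")
    acid, mid, base = plateaus
    if not acid > mid > base:
        raise ValueError("plateaus must decrease (acid > mid > base) for a red shift on acidification")
    if pH_grid is None:
        pH_grid = np.linspace(2.0, 11.0, 25)
    pH = np.atleast_1d(np.asarray(pH_grid, dtype=float))
    lam = double_henderson_hasselbalch(pH, pk_low, pk_high, acid, mid, base)
    if noise_sd > 0:
        lam = lam + np.random.default_rng(seed).normal(0.0, noise_sd, size=lam.shape)
    df = pd.DataFrame({"pH": pH, "lambda_max_nm": lam})
    overlapping = abs(pk_high - pk_low) < 0.5
    df.attrs["overlapping_pks"] = bool(overlapping)
    if overlapping:
        warnings.warn("pK values closer than 0.5 units: transitions overlap", stacklevel=2)
    return df


# ---------------------------------------------------------------------------
# Hydroxylamine bleach pair
# ---------------------------------------------------------------------------


def make_bleach_pair(
    rhodopsin_band: SpectralBand,
    oxime_band: SpectralBand,
    concentration: float,
    pathlength: float = 1.0,
    wavelengths=None,
):
    """Spectra of a sample before and after hydroxylamine bleaching.

    Before: the rhodopsin chromophore band; after: the retinal-oxime band of
    the same chromophore pool, both scaled by concentration * pathlength.
    Returns ``(before, after)`` as :class:`prflash.spectral_analysis.Spectrum`.
    """
    from .spectral_analysis import Spectrum  # local import avoids a cycle

    if not concentration > 0:
        raise ValueError("concentration must be positive")
    if not pathlength > 0:
        raise ValueError("pathlength must be positive")
    if wavelengths is None:
        wavelengths = np.arange(250.0, 701.0)
    wl = np.asarray(wavelengths, dtype=float)
    scale = concentration * pathlength
    return (
        Spectrum(wl, scale * rhodopsin_band.extinction(wl)),
        Spectrum(wl, scale * oxime_band.extinction(wl)),
    )


# ---------------------------------------------------------------------------
# Toy sequences (synthetic stand-ins for database accessions)
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: 1-based key-residue positions of the synthetic ESR-like reference.
TOY_ESR_ANNOTATIONS = {
    "acceptor": 85,      # D
    "donor": 96,         # K
    "his_partner": 57,   # H
    "schiff_lysine": 232,  # K
    "tuning_switch": 93,   # L (green)
}

#: 1-based tuning-switch position of the synthetic BPR-like reference.
TOY_BPR_TUNING_POSITION = 106


def make_toy_sequences(seed: int = 0) -> dict:
    """Synthetic proteorhodopsin-like sequences with a known residue map.

    Builds a 250-residue ESR-like annotated reference (D85, K96, H57, K232,
    L93), an E17R-like query derived from it by one N-terminal insertion and
    a 7-residue loop deletion plus scattered substitutions — so its mapped
    positions are D86, K97, H58, K226 and the tuning leucine sits at 94 — a
    BPR-like blue reference whose tuning position 106 carries Q, and an
    unalignable poly-alanine control.  All sequences are synthetic stand-ins;
    no database sequence is reproduced.
    """
    from .sequence_tools import SequenceRecord  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    esr = [_AA[i] for i in rng.integers(0, len(_AA), size=250)]
    for name, pos in TOY_ESR_ANNOTATIONS.items():
        esr[pos - 1] = {"acceptor": "D", "donor": "K", "his_partner": "H",
                        "schiff_lysine": "K", "tuning_switch": "L"}[name]

    # E17R-like: +1 insertion at the N-terminus region (before residue 10),
    # -7 deletion in the E-F loop region (residues 150-156), ~8% substitutions.
    e17 = esr.copy()
    protected = {p - 1 for p in TOY_ESR_ANNOTATIONS.values()}
    for i in sorted(rng.choice(250, size=20, replace=False)):
        if i not in protected and not 149 <= i <= 155:
            e17[i] = _AA[int(rng.integers(0, len(_AA)))]
    del e17[149:156]
    e17.insert(9, "G")

    # BPR-like: a third homolog; 13 extra N-terminal residues place the
    # tuning switch at 106 (ESR numbering 93 + 13), carrying Q (blue).
    bpr = list("".join(_AA[i] for i in rng.integers(0, len(_AA), size=13))) + esr.copy()
    bpr[TOY_BPR_TUNING_POSITION - 1] = "Q"
    bpr[76 - 1] = "H"  # his partner at 76 in BPR numbering
    for i in sorted(rng.choice(len(bpr), size=60, replace=False)):
        if i not in {TOY_BPR_TUNING_POSITION - 1, 76 - 1}:
            bpr[i] = _AA[int(rng.integers(0, len(_AA)))]

    return {
        "esr_like": SequenceRecord("synthetic-ESR-like", "".join(esr)),
        "e17r_like": SequenceRecord("synthetic-E17R-like", "".join(e17)),
        "bpr_like": SequenceRecord("synthetic-BPR-like", "".join(bpr)),
        "polyA": SequenceRecord("synthetic-polyA", "A" * 120),
    }
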