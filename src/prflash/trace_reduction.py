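"""Logarithmic block-averaging of oscilloscope traces and timebase merging.

Raw transient-absorbance traces are recorded on a uniform time base but span
many decades of kinetics, so they are reduced century by century: the n-th
century consumes ``points_per_century * 2**(n-1)`` consecutive raw samples and
emits ``points_per_century`` block means of block size ``2**(n-1)``.  With the
default 100 points per century, a 46,080-sample trace reduces to 880 points
(eight full centuries of 100 plus 80 blocks of 256 from the partial ninth;
the incomplete tail block is discarded).  Each reduced timestamp is the
arithmetic mean of its block's sample times.  The reduced fast and slow
oscilloscope traces are then merged by keeping every fast point and appending
the slow points whose block-center time strictly exceeds the last fast time —
880 + 880 points merge into 1520 covering up to ~1 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import TraceSet

__all__ = ["ReducedTraceSet", "reduce_log_blocks", "merge_traces", "century_blocks"]


@dataclass
class ReducedTraceSet:
    """DeltaA(lambda, t) on a strictly increasing, non-uniform time base."""

    times: np.ndarray  # (n_reduced,) block-center seconds
    delta_A: np.ndarray  # (n_wavelengths, n_reduced)
    wavelengths: np.ndarray  # nm
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.delta_A = np.asarray(self.delta_A, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.delta_A.shape != (self.wavelengths.size, self.times.size):
            raise ValueError("delta_A shape must be (n_wavelengths, n_times)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def block_sizes(self) -> np.ndarray:
        """Per-point source block size, if reduction provenance is recorded."""
        if "block_sizes" in self.provenance:
            return np.asarray(self.provenance["block_sizes"], dtype=int)
        sizes = []
        for bs, nb in self.provenance.get("centuries", []):
            sizes.extend([bs] * nb)
        return np.asarray(sizes, dtype=int)


def century_blocks(n_raw: int, points_per_century: int = 100) -> list[tuple[int, int]]:
    """Block scheme for a raw length: list of (block_size, n_blocks) per century.

    Century n uses block size 2**(n-1) and emits at most ``points_per_century``
    block means; the final partial century emits only its full blocks.
    """
    if n_raw <= 0:
        raise ValueError("empty trace")
    if points_per_century <= 0:
        raise ValueError("points_per_century must be positive")
    scheme = []
    i, century = 0, 1
    while i < n_raw:
        bs = 2 ** (century - 1)
        n_blocks = min(points_per_century, (n_raw - i) // bs)
        if n_blocks > 0:
            scheme.append((bs, n_blocks))
        i += min(points_per_century * bs, n_raw - i)
        century += 1
    return scheme


def reduce_log_blocks(raw: TraceSet, points_per_century: int = 100) -> ReducedTraceSet:
    """Logarithmically block-average a uniformly sampled trace set.

    Every wavelength column is averaged identically; reduced values are exact
    arithmetic means of their source blocks and reduced times the means of the
    member sample times.
    """
    if raw.times.size == 0:
        raise ValueError("empty trace")
    if not raw.is_uniform:
        raise ValueError("raw trace must have a uniform time base")
    scheme = century_blocks(raw.times.size, points_per_century)

    times, cols = [], []
    i = 0
    for bs, nb in scheme:
        n = bs * nb
        times.append(raw.times[i : i + n].reshape(nb, bs).mean(axis=1))
        cols.append(raw.delta_A[:, i : i + n].reshape(-1, nb, bs).mean(axis=2))
        # the century consumed points_per_century * bs raw samples (or all
        # remaining); the incomplete tail block, if any, is discarded
        i += min(points_per_century * bs, raw.times.size - i)
    dt = float(raw.times[1] - raw.times[0]) if raw.times.size > 1 else None
    return ReducedTraceSet(
        np.concatenate(times),
        np.concatenate(cols, axis=1),
        raw.wavelengths.copy(),
        provenance={
            "source_dt": dt,
            "n_raw": int(raw.times.size),
            "points_per_century": int(points_per_century),
            "centuries": scheme,
        },
    )


def merge_traces(fast: ReducedTraceSet, slow: ReducedTraceSet) -> ReducedTraceSet:
    """Merge reduced fast and slow timebases into one logarithmic dataset.

    Keeps all fast points and the slow points whose block-center time strictly
    exceeds the last fast time.
    """
    if fast.wavelengths.shape != slow.wavelengths.shape or np.any(
        fast.wavelengths != slow.wavelengths
    ):
        raise ValueError("fast and slow trace sets must share the wavelength axis")
    if not fast.times[-1] < slow.times[-1]:
        raise ValueError("fast trace must end before the slow trace does")
    keep = slow.times > fast.times[-1]
    return ReducedTraceSet(
        np.concatenate([fast.times, slow.times[keep]]),
        np.concatenate([fast.delta_A, slow.delta_A[:, keep]], axis=1),
        fast.wavelengths.copy(),
        provenance={
            "merged": True,
            "fast": fast.provenance,
            "slow": slow.provenance,
            "n_fast": int(fast.times.size),
            "n_slow_kept": int(keep.sum()),
            "block_sizes": np.concatenate(
                [fast.block_sizes, slow.block_sizes[keep]]
            ).tolist()
            if fast.block_sizes.size and slow.block_sizes.size
            else [],
        },
    )
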