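"""Sample entropy of within-cycle joint-angle series.

SampEn(N, m, T) is the negative natural log of the conditional probability
that two subsequences similar for m points (Chebyshev distance <= T) remain
similar at m + 1 points, self-matches excluded.  Lower values mean more
self-similar (more regular) signals.  Following the standard
Richman-Moorman counting, both template lengths use the N - m subsequences
starting at the first N - m points, so the ratio is a true conditional
probability.

Each series is standardized to zero mean and unit (population) variance
first, and the tolerance is T = r * SD of the input; together these make
the statistic exactly invariant under affine maps a*x + b (a != 0).  The
defaults m = 2, r = 0.2 are the usual choice for per-cycle gait data.

Two implementations are provided: :func:`sampen` (vectorized) and
:func:`sampen_bruteforce` (a deliberately plain O(N^2) nested-loop
transcription of the six-step definition, kept as an independent reference
for validation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import DataError, UndefinedEntropyError, ZeroVarianceError
from .gait_geometry import ANGLE_NAMES, AngleCurves

__all__ = ["SampEnResult", "standardize", "sampen", "sampen_bruteforce",
           "sampen_per_cycle"]


@dataclass(frozen=True)
class SampEnResult:
    """Sample entropy with the template-match counts behind it."""

    value: float          # nats; may be +inf when no matches survive at m+1
    m: int
    r: float
    T: float              # absolute tolerance on the standardized series
    N: int
    matches_m: int        # B: similar unordered template pairs at length m
    matches_m1: int       # A: similar unordered template pairs at length m+1

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.value)


def standardize(series: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance (population SD) copy of ``series``."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise DataError("standardize: need a 1-D series of length >= 2")
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise ZeroVarianceError("constant series cannot be standardized")
    return (x - x.mean()) / sd


def sampen(series: np.ndarray, m: int = 2, r: float = 0.2) -> SampEnResult:
    """Sample entropy of a series, tolerance T = r * SD.

    The series is standardized internally (so T = r afterwards).  Raises
    :class:`UndefinedEntropyError` when no template pair matches at length m;
    returns ``value = +inf`` (flagged, never silent) when matches exist at m
    but none survive at m + 1.
    """
    x = standardize(series)
    N = len(x)
    if N <= m + 1:
        raise DataError(f"sampen: need N > m + 1, got N={N}, m={m}")
    n_templates = N - m
    # embed: row i = x[i : i + m + 1]; rows are the first N - m start points
    emb = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_templates]
    # pairwise Chebyshev distances at lengths m and m + 1
    d_m = np.zeros((n_templates, n_templates))
    for k in range(m):
        d_m = np.maximum(d_m, np.abs(emb[:, None, k] - emb[None, :, k]))
    d_m1 = np.maximum(d_m, np.abs(emb[:, None, m] - emb[None, :, m]))
    iu = np.triu_indices(n_templates, k=1)    # unordered pairs, no self-match
    B = int(np.count_nonzero(d_m[iu] <= r))
    A = int(np.count_nonzero(d_m1[iu] <= r))
    if B == 0:
        raise UndefinedEntropyError("no template matches at length m")
    value = math.inf if A == 0 else -math.log(A / B)
    return SampEnResult(value=value, m=m, r=r, T=r, N=N,
                        matches_m=B, matches_m1=A)


def sampen_bruteforce(series: np.ndarray, m: int = 2, r: float = 0.2
                      ) -> SampEnResult:
    """Plain nested-loop sample entropy; the validation reference.

    Transcribes the six-step definition directly: build the N - m
    subsequences of length m, count per-template similar vectors under the
    Chebyshev criterion without self-matches, average the match
    probabilities, repeat at m + 1, and take -ln of the ratio.  Kept free of
    vectorized shortcuts on purpose.
    """
    x = list(standardize(series))
    N = len(x)
    if N <= m + 1:
        raise DataError(f"sampen: need N > m + 1, got N={N}, m={m}")
    n_templates = N - m

    def count_similar(length: int) -> int:
        total = 0
        for i in range(n_templates):
            for j in range(n_templates):
                if j == i:
                    continue
                d = 0.0
                for k in range(length):
                    diff = abs(x[i + k] - x[j + k])
                    if diff > d:
                        d = diff
                if d <= r:
                    total += 1
        return total

    # ordered counts are twice the unordered ones; the ratio is unchanged
    B2 = count_similar(m)
    A2 = count_similar(m + 1)
    if B2 == 0:
        raise UndefinedEntropyError("no template matches at length m")
    value = math.inf if A2 == 0 else -math.log(A2 / B2)
    return SampEnResult(value=value, m=m, r=r, T=r, N=N,
                        matches_m=B2 // 2, matches_m1=A2 // 2)


def sampen_per_cycle(curves: AngleCurves, m: int = 2, r: float = 0.2,
                     use_resampled: bool = True
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cycle and summary sample entropy for every angle.

    ``use_resampled`` selects the K-point per-cycle curves (the default
    representation) rather than the raw within-cycle frames.  Undefined
    cycles (constant or match-free) are excluded from the mean and counted;
    an angle with no defined cycle reports NaN, never zero.

    Returns ``(per_cycle, summary)``: ``per_cycle`` is cycles x angles with
    NaN where undefined; ``summary`` has one row per angle with columns
    ``mean_sampen``, ``n_cycles``, ``n_undefined``.
    """
    if curves.cycle_index is None:
        raise DataError("sampen_per_cycle: curves carry no cycle index")
    n_cycles = curves.cycle_index.n_cycles
    if n_cycles < 1:
        raise DataError("sampen_per_cycle: no cycles")
    names = [n for n in ANGLE_NAMES if n in curves.angles]
    table = np.full((n_cycles, len(names)), np.nan)
    for a, name in enumerate(names):
        for c in range(n_cycles):
            if use_resampled:
                if curves.phi is None:
                    raise DataError("sampen_per_cycle: curves not resampled")
                seg = curves.phi[name][c]
            else:
                start, end = curves.cycle_index.cycles[c]
                seg = curves.angles[name][start:end]
            try:
                res = sampen(seg, m=m, r=r)
            except (ZeroVarianceError, UndefinedEntropyError, DataError):
                continue
            if not res.is_infinite:
                table[c, a] = res.value
    per_cycle = pd.DataFrame(table, columns=names)
    summary = pd.DataFrame({
        "mean_sampen": per_cycle.mean(axis=0, skipna=True),
        "n_cycles": n_cycles,
        "n_undefined": per_cycle.isna().sum(axis=0),
    })
    summary.index.name = "angle"
    return per_cycle, summary
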