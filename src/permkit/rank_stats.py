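"""Tie-corrected Spearman rank correlation, implemented from scratch.

The coefficient is the Pearson correlation of midranks rather than the
``6 sum d^2 / (n (n^2 - 1))`` shortcut, because clearance data contain
tied zeros (censored drugs all enter as 0) and the shortcut is biased
under ties.

Two-sided p-values come from the permutation distribution of rs: exact
enumeration of all n! permutations for n <= 8, seeded Monte-Carlo
permutation sampling otherwise (with the add-one correction
``(count + 1) / (B + 1)``), and a Student-t approximation available as
an explicit opt-in. Permutations at least as extreme as the observed
|rs| are counted as extreme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np

from .datamodel_io import ValidationError

#: Largest n for which the exact permutation distribution is enumerated
#: by default (8! = 40,320 permutations).
EXACT_N_MAX = 8
#: Default number of Monte-Carlo permutations.
DEFAULT_N_PERM = 100_000
#: Ties with the observed statistic are resolved as extreme within this
#: absolute slack, so exact enumeration is robust to float round-off.
_TIE_EPS = 1e-12


class UndefinedCorrelationError(ValueError):
    """Raised when a rank correlation is undefined (zero rank variance)."""


@dataclass(frozen=True)
class CorrelationResult:
    """A Spearman correlation with its two-sided p-value."""

    rs: float
    p_value: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.rs <= 1.0 + 1e-12):
            raise ValidationError(f"rs out of [-1, 1]: {self.rs!r}")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value out of [0, 1]: {self.p_value!r}")
        if self.n < 3:
            raise ValidationError(f"n must be >= 3, got {self.n!r}")


def midranks(values: Sequence[float]) -> list[float]:
    """Average (mid) ranks, 1-based; tied groups share their mean rank.

    The ranks always sum to n (n + 1) / 2.
    """
    n = len(values)
    if n == 0:
        raise ValidationError("midranks requires at least one value")
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j + 2) / 2.0  # mean of 1-based ranks i+1 .. j+1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _standardized_ranks(values: Sequence[float]) -> np.ndarray:
    """Midranks centered and scaled to unit L2 norm; error on zero variance."""
    r = np.asarray(midranks(values), dtype=float)
    r -= r.mean()
    norm = math.sqrt(float(np.dot(r, r)))
    if norm == 0.0:
        raise UndefinedCorrelationError(
            "rank correlation undefined: a vector has zero rank variance"
        )
    return r / norm


def _check_pair(x: Sequence[float], y: Sequence[float]) -> int:
    if len(x) != len(y):
        raise ValidationError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValidationError(f"need n >= 3 observations, got {len(x)}")
    return len(x)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected Spearman coefficient (Pearson on midranks)."""
    _check_pair(x, y)
    rx = _standardized_ranks(x)
    ry = _standardized_ranks(y)
    return float(np.clip(np.dot(rx, ry), -1.0, 1.0))


def spearman_test(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman correlation with a two-sided permutation p-value.

    ``method`` is one of:

    * ``"auto"`` — exact enumeration for n <= 8, Monte-Carlo otherwise;
    * ``"exact"`` — full enumeration of all n! permutations;
    * ``"permutation"`` — seeded Monte-Carlo with ``n_perm`` draws and
      the add-one correction (count + 1) / (n_perm + 1);
    * ``"t_approx"`` — Student-t approximation with n - 2 degrees of
      freedom (opt-in; anti-conservative at small n with ties).
    """
    n = _check_pair(x, y)
    rx = _standardized_ranks(x)
    ry = _standardized_ranks(y)
    rs = float(np.clip(np.dot(rx, ry), -1.0, 1.0))
    if method == "auto":
        method = "exact" if n <= EXACT_N_MAX else "permutation"
    if method == "exact":
        p = _exact_p(rx, ry, abs(rs))
    elif method == "permutation":
        p = _mc_p(rx, ry, abs(rs), n_perm, seed)
    elif method == "t_approx":
        p = _t_approx_p(rs, n)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return CorrelationResult(rs=rs, p_value=p, n=n, method=method)


def _exact_p(rx: np.ndarray, ry: np.ndarray, abs_rs: float) -> float:
    n = len(rx)
    total = 0
    extreme = 0
    for perm in permutations(range(n)):
        stat = abs(float(np.dot(rx, ry[list(perm)])))
        total += 1
        if stat >= abs_rs - _TIE_EPS:
            extreme += 1
    return extreme / total


def _mc_p(
    rx: np.ndarray, ry: np.ndarray, abs_rs: float, n_perm: int, seed: int
) -> float:
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm!r}")
    rng = np.random.default_rng(seed)
    n = len(rx)
    # vectorized: one matrix of permuted standardized ranks per batch
    count = 0
    done = 0
    batch = 20_000
    while done < n_perm:
        b = min(batch, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        stats = np.abs(ry[idx] @ rx)
        count += int(np.sum(stats >= abs_rs - _TIE_EPS))
        done += b
    return (count + 1) / (n_perm + 1)


def _t_approx_p(rs: float, n: int) -> float:
    from scipy.stats import t as t_dist

    if abs(rs) >= 1.0:
        return 0.0
    t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
    return float(2.0 * t_dist.sf(abs(t), df=n - 2))
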