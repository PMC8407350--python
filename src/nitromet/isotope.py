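"""Mass-isotopomer arithmetic for 13C tracer data.

Covers the enrichment formula e = (1/N) sum_i i*M_i, natural-abundance
correction by inverting the binomial convolution operator, tracer
normalization, and headspace 12C/13C fractions.  Only carbon isotopes
are corrected (metabolites measured in negative mode; carbon dominates
the correction); O/N/H/S corrections are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.stats import binom

#: natural 13C abundance
NATURAL_P13 = 0.0107

MID_TOL = 1e-6


@dataclass
class MID:
    """Mass-isotopomer distribution M0..MN of an N-carbon metabolite."""

    metabolite: str
    n_carbons: int
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.n_carbons < 1:
            raise ValueError("n_carbons must be a positive integer")
        if self.fractions.shape != (self.n_carbons + 1,):
            raise ValueError(
                f"MID for {self.metabolite!r}: expected {self.n_carbons + 1} "
                f"fractions, got {self.fractions.shape}"
            )
        if np.any(self.fractions < -MID_TOL):
            raise ValueError(f"MID for {self.metabolite!r}: negative fraction")

    @property
    def normalized(self) -> bool:
        return abs(self.fractions.sum() - 1.0) <= MID_TOL


@dataclass
class EnrichmentSeries:
    """Time course of 13C enrichment for one metabolite pool."""

    metabolite: str
    times_min: np.ndarray
    enrichment: np.ndarray
    tracer_normalized: bool = False

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.enrichment = np.asarray(self.enrichment, dtype=float)
        if self.times_min.shape != self.enrichment.shape:
            raise ValueError("times and values must align")
        if not self.tracer_normalized and (
            np.any(self.enrichment < -MID_TOL)
            or np.any(self.enrichment > 1 + MID_TOL)
        ):
            raise ValueError("raw enrichment values must lie in [0, 1]")


def enrichment(mid: MID) -> float:
    """Mean fraction of labeled carbons, (1/N) sum_{i=1..N} i*M_i."""
    if not mid.normalized:
        raise ValueError(
            f"MID for {mid.metabolite!r} is not normalized "
            f"(sum {mid.fractions.sum():.6f})"
        )
    i = np.arange(mid.n_carbons + 1)
    return float((i * mid.fractions).sum() / mid.n_carbons)


def forward_operator(n_carbons: int, p13: float) -> np.ndarray:
    """(N+1)x(N+1) natural-abundance convolution: column j is the
    observed distribution of a molecule with exactly j labeled carbons,
    the remaining N-j carbons labeled binomially at p13."""
    if not 0 <= p13 < 1:
        raise ValueError("p13 must lie in [0, 1)")
    N = n_carbons
    M = np.zeros((N + 1, N + 1))
    for j in range(N + 1):
        k = np.arange(N - j + 1)
        M[j : N + 1, j] = binom.pmf(k, N - j, p13)
    return M


def natural_abundance_matrix(n_carbons: int, p13: float = NATURAL_P13) -> np.ndarray:
    """Correction operator: the inverse of the forward convolution.

    Applying it to a measured MID removes natural-abundance 13C.  Raises
    for an ill-conditioned operator (p13 approaching 1).
    """
    M = forward_operator(n_carbons, p13)
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"correction operator ill-conditioned (cond={cond:.2e})")
    return np.linalg.inv(M)


@dataclass
class CorrectionStats:
    clipped: int = 0   # number of negative fractions set to zero


def correct_natural_abundance(
    mid: MID, p13: float = NATURAL_P13, stats: CorrectionStats = None
) -> MID:
    """Invert the natural-abundance convolution, clip small negative
    fractions to zero and renormalize (counted, not silent)."""
    x = natural_abundance_matrix(mid.n_carbons, p13) @ mid.fractions
    neg = x < 0
    if neg.any():
        if stats is not None:
            stats.clipped += int(neg.sum())
        else:
            warnings.warn(
                f"{neg.sum()} negative corrected fraction(s) clipped for "
                f"{mid.metabolite}",
                stacklevel=2,
            )
        x = np.clip(x, 0.0, None)
    total = x.sum()
    if total <= 0:
        raise ValueError("corrected MID sums to zero")
    return MID(mid.metabolite, mid.n_carbons, x / total)


def normalize_to_tracer(e: float, tracer_fraction: float) -> float:
    """Enrichment normalized to a tracer 13C fraction of 1.

    Values exceeding 1 after normalization are reported as-is with a
    warning (flagged, never silently clipped).
    """
    if tracer_fraction <= 0 or tracer_fraction > 1:
        raise ValueError("tracer fraction must lie in (0, 1]")
    out = e / tracer_fraction
    if out > 1 + MID_TOL:
        warnings.warn(
            f"normalized enrichment {out:.4f} exceeds 1 (tracer fraction "
            f"{tracer_fraction}); reported unclipped",
            stacklevel=2,
        )
    return out


def headspace_fraction(signal_12: float, signal_13: float) -> float:
    """13C fraction from 12CO2/13CO2 ion intensities."""
    if signal_12 < 0 or signal_13 < 0:
        raise ValueError("signals must be non-negative")
    total = signal_12 + signal_13
    if total == 0:
        raise ValueError("both signals zero")
    return signal_13 / total


def binomial_mid(metabolite: str, n_carbons: int, e: float) -> MID:
    """MID of a metabolite whose carbons are labeled independently at
    enrichment ``e`` (the approximation used by the simulator)."""
    k = np.arange(n_carbons + 1)
    return MID(metabolite, n_carbons, binom.pmf(k, n_carbons, min(max(e, 0.0), 1.0)))
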