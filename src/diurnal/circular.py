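"""Circular arithmetic on acrophases measured in hours on a period-T clock.

Phase shifts, the mean resultant vector, the Rayleigh uniformity test and
wedge (angular-bin) histograms. Negative signed differences are phase
advances, positive ones delays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass
class CircularSummary:
    """Mean resultant vector and Rayleigh statistic of a set of phases."""

    n: int
    mean_direction: float  # hours in [0, T); nan when R == 0
    resultant_length_R: float
    rayleigh_Z: float
    rayleigh_p: float


def signed_phase_difference(phi_a: float, phi_b: float, period: float = 24.0) -> float:
    """Signed circular difference ``phi_b - phi_a`` mapped into (-T/2, T/2].

    Negative values are advances of B relative to A, positive values
    delays; the antipodal boundary maps to +T/2 so the difference is
    single-valued.
    """
    if period <= 0:
        raise ValidationError(f"period must be positive, got {period}")
    if not (np.isfinite(phi_a) and np.isfinite(phi_b)):
        raise ValidationError("phases must be finite")
    d = float(np.mod(phi_b - phi_a, period))
    if d > period / 2:
        d -= period
    return d


def circular_mean_vector(hours, period: float = 24.0) -> CircularSummary:
    """Mean resultant vector of phases/shifts given in hours.

    Angles are ``2*pi*h/T``; R is the mean resultant length, the mean
    direction its argument converted back to hours. The Rayleigh statistic
    Z = n*R^2 and its p-value are attached (p = 1 for n < 2 or R = 0).
    """
    h = np.asarray(hours, dtype=float)
    if h.size == 0:
        raise ValidationError("circular_mean_vector requires at least one phase")
    if period <= 0:
        raise ValidationError(f"period must be positive, got {period}")
    theta = 2.0 * np.pi * h / period
    resultant = np.exp(1j * theta).sum()
    r = float(np.abs(resultant) / h.size)
    r = min(r, 1.0)
    if r < 1e-15:
        mean_direction = float("nan")
    else:
        mean_direction = float(np.mod(np.angle(resultant) * period / (2 * np.pi), period))
    z = h.size * r * r
    p = _rayleigh_p(z, h.size) if h.size >= 2 else 1.0
    return CircularSummary(
        n=int(h.size),
        mean_direction=mean_direction,
        resultant_length_R=r,
        rayleigh_Z=float(z),
        rayleigh_p=float(p),
    )


def _rayleigh_p(z: float, n: int) -> float:
    # Series approximation of the Rayleigh null tail; clipped to (0, 1].
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return float(np.clip(p, np.finfo(float).tiny, 1.0))


def rayleigh_test(hours, period: float = 24.0) -> tuple[float, float]:
    """Rayleigh test of circular uniformity; returns ``(Z, p)``."""
    h = np.asarray(hours, dtype=float)
    if h.size < 2:
        raise ValidationError("rayleigh_test requires n >= 2")
    summary = circular_mean_vector(h, period)
    return summary.rayleigh_Z, summary.rayleigh_p


def wedge_histogram(hours, period: float = 24.0, wedge_width: float = 20.0):
    """Bin shifts/phases into angular wedges of ``wedge_width`` degrees.

    Hours map to degrees ``h*360/T`` reduced to [0, 360); wedge ``i``
    covers the half-open interval ``[i*width, (i+1)*width)``. Returns
    ``(edges_deg, counts)`` with ``len(counts) == 360/width``.
    """
    if wedge_width <= 0 or 360.0 % wedge_width != 0:
        raise ValidationError(f"wedge width {wedge_width} does not divide 360")
    h = np.asarray(hours, dtype=float)
    n_wedges = int(round(360.0 / wedge_width))
    degrees = np.mod(h * 360.0 / period, 360.0)
    idx = np.floor(degrees / wedge_width).astype(int)
    idx = np.clip(idx, 0, n_wedges - 1)  # guard float roundoff at 360
    counts = np.bincount(idx, minlength=n_wedges)
    edges = np.arange(n_wedges) * wedge_width
    return edges, counts
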