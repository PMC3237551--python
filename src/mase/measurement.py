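"""Synthetic quantitative-proteomics readout of exchange ratios.

A real exchange experiment measures R(t) as an isotope abundance ratio
computed from the selected-ion chromatograms of the several peptides
that a protein yields after digestion.  This module emulates that
readout so the estimator can be exercised end to end without
instrument data: at each requested time point it draws per-peptide
ratios as multiplicative (log-normal) deviates around the true curve
value and summarizes them robustly, the way ratio quantification
pipelines summarize peptide-level ratios into a protein-level ratio.

What is emulated: peptide-to-peptide scatter of a ratio measurement
(coefficient of variation ``cv``), the number of quantifiable peptides
per protein, and a lower detection floor below which a ratio cannot be
called.  What is not: spectra, chromatographic interference,
identification error, or incomplete metabolic-label incorporation --
all of which act upstream of the ratio abstraction this package works
in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .kinetics import ExchangePoint, peak_sensitivity_kt, predict_R

__all__ = ["NoiseModel", "sample_series", "default_design"]

#: Consistency factor making the median absolute deviation estimate the
#: standard deviation of a normal sample.
_MAD_SCALE = 1.4826


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description of a single protein-ratio readout.

    Parameters
    ----------
    cv
        Coefficient of variation of one peptide-level ratio measurement
        (dimensionless).  Default 0.15, typical of metabolic-labeling
        ratio quantification.
    n_peptides
        Peptides quantified per protein; the reported R is their median.
    floor
        Optional lower detection limit on R; reported values below it
        are flagged censored (never silently dropped).
    seed
        Seed for the generator; identical seeds reproduce the series.
    """

    cv: float = 0.15
    n_peptides: int = 5
    floor: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cv) and self.cv >= 0.0):
            raise ValueError("cv must be finite and >= 0")
        if int(self.n_peptides) != self.n_peptides or self.n_peptides < 1:
            raise ValueError("n_peptides must be an integer >= 1")
        object.__setattr__(self, "n_peptides", int(self.n_peptides))
        if self.floor is not None and not (0.0 <= self.floor < 1.0):
            raise ValueError("floor must satisfy 0 <= floor < 1")

    @property
    def sigma_log(self) -> float:
        """Log-scale standard deviation giving the requested CV."""
        return math.sqrt(math.log1p(self.cv * self.cv))


def sample_series(
    k_off: float,
    t_points: Sequence[float],
    noise: NoiseModel,
) -> list[ExchangePoint]:
    """Draw one noisy exchange time series around the true progress curve.

    For each time point, ``n_peptides`` log-normal multiplicative
    deviates are drawn around ``predict_R(k_off, t)`` (median equal to
    the true value); the reported R is their median and the reported
    sigma their scaled median absolute deviation.  Points where the true
    ratio is exactly 0 (t = 0) pass through noiselessly as R = 0 with no
    sigma.  Reported values below ``noise.floor`` are kept but flagged
    censored.
    """
    t_points = np.asarray(t_points, dtype=float)
    if t_points.ndim != 1 or t_points.size == 0:
        raise ValueError("t_points must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(t_points)) or np.any(t_points < 0):
        raise ValueError("t_points must be finite and >= 0")
    rng = np.random.default_rng(noise.seed)
    sigma_log = noise.sigma_log
    out: list[ExchangePoint] = []
    for t in t_points:
        mu = predict_R(k_off, float(t))
        if mu == 0.0:
            out.append(ExchangePoint(t=float(t), R=0.0, sigma=None, censored=False))
            continue
        draws = mu * np.exp(sigma_log * rng.standard_normal(noise.n_peptides))
        r = float(np.median(draws))
        s = _MAD_SCALE * float(np.median(np.abs(draws - r)))
        censored = noise.floor is not None and r < noise.floor
        out.append(
            ExchangePoint(
                t=float(t),
                R=r,
                sigma=s if s > 0.0 else None,
                censored=censored,
            )
        )
    return out


def default_design(
    k_off_prior_low: float,
    k_off_prior_high: float,
    n_points: int,
    horizon: float = 28800.0,
) -> np.ndarray:
    """Sampling times covering the informative region of the curve.

    Given an order-of-magnitude prior ``[low, high]`` on k_off, returns
    ``n_points`` times: t = 0 (anchoring R = 0) plus ``n_points - 1``
    log-spaced points between 0.1/high (earliest time the fastest
    plausible complex shows measurable exchange) and 3/low (late plateau
    of the slowest), capped at ``horizon`` (default 8 h).  The log-spaced
    point nearest to the maximal-sensitivity time
    ``1.5434 / sqrt(low * high)`` is snapped onto it, so every design
    contains a sample where dR/dk_off for the prior's central rate
    peaks.
    """
    low = float(k_off_prior_low)
    high = float(k_off_prior_high)
    if not (0.0 < low <= high) or not math.isfinite(high):
        raise ValueError("need 0 < k_off_prior_low <= k_off_prior_high, finite")
    if int(n_points) != n_points or n_points < 3:
        raise ValueError("n_points must be an integer >= 3")
    n_points = int(n_points)
    if not (math.isfinite(horizon) and horizon > 0):
        raise ValueError("horizon must be finite and > 0")
    t_lo = 0.1 / high
    t_hi = min(3.0 / low, horizon)
    if t_lo > horizon:
        raise ValueError(
            f"horizon {horizon:g} s is shorter than the earliest informative "
            f"time 0.1/k_off_prior_high = {t_lo:g} s"
        )
    if t_hi <= t_lo:
        t_hi = horizon
    pts = np.geomspace(t_lo, t_hi, n_points - 1)
    t_star = peak_sensitivity_kt() / math.sqrt(low * high)
    if t_lo <= t_star <= min(3.0 / low, horizon):
        idx = int(np.argmin(np.abs(np.log(pts) - math.log(t_star))))
        pts[idx] = t_star
    pts = np.unique(pts)
    return np.concatenate(([0.0], np.sort(pts)))
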