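"""Summary statistics: integration-frequency profiles, soft-site
enhancement, exponential enhancement fits, contact-probability and size
scaling exponents, and the analytic re-integration distance predictor.

The scaling observables connect polymer state to re-integration range: a
chain of length L has size R ~ L^nu and the contact probability of two loci
at genomic separation s scales as P_c(s) ~ s^(-3 nu), with nu = 1/3 for
collapsed globules, 1/2 for ideal chains and ~3/5 for self-avoiding walks.
A cut-and-paste element that excises and re-integrates through 3D contact
therefore lands at distance s with probability proportional to s^(-3 nu):
open chromatin favours short-range, collapsed chromatin long-range re-entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .integration import ExperimentResult
from .sampler import EnsembleSample


@dataclass
class FrequencyProfile:
    """Per-locus integration fractions over an ensemble of replicates."""

    freqs: np.ndarray
    n_events: int
    se: np.ndarray
    counts: Optional[np.ndarray] = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.freqs.ndim != 1 or self.se.shape != self.freqs.shape:
            raise ValueError("freqs and se must be 1-D arrays of equal size")
        if np.any(self.freqs < 0):
            raise ValueError("frequencies must be non-negative")
        if abs(self.freqs.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")

    @property
    def n_loci(self) -> int:
        return self.freqs.size


def frequency_profile(result: ExperimentResult) -> FrequencyProfile:
    """Pooled per-locus counts over unflagged replicates, normalised by the
    total number of accepted events, with binomial standard errors."""
    loci = np.array([e.locus for e in result.ok_events], dtype=int)
    if loci.size == 0:
        raise ValueError("no accepted integration events to profile")
    n_loci = result.spec.n_loci
    counts = np.bincount(loci, minlength=n_loci).astype(float)
    freqs = counts / loci.size
    se = np.sqrt(freqs * (1.0 - freqs) / loci.size)
    return FrequencyProfile(freqs=freqs, n_events=int(loci.size), se=se,
                            counts=counts)


@dataclass
class EnhancementEstimate:
    value: float
    se: float
    n_soft: int
    n_events: int


def soft_site_enhancement(profile: FrequencyProfile,
                          soft_indices: Sequence[int],
                          n_insertable: Optional[int] = None
                          ) -> EnhancementEstimate:
    """Summed soft-locus frequency over the uniform-random expectation n/N.

    ``n`` is the number of designated soft loci and ``N`` the number of
    insertable loci (defaults to the profile length). Unity means the soft
    sites capture exactly their random share of events.
    """
    soft = np.asarray(sorted(set(int(i) for i in soft_indices)), dtype=int)
    if soft.size == 0:
        raise ValueError("soft_indices must be non-empty")
    if soft.min() < 0 or soft.max() >= profile.n_loci:
        raise ValueError("soft_indices out of profile range")
    n_tot = n_insertable if n_insertable is not None else profile.n_loci
    expected = soft.size / n_tot
    p_soft = float(profile.freqs[soft].sum())
    se_p = np.sqrt(p_soft * (1.0 - p_soft) / profile.n_events) \
        if profile.n_events > 0 else float("nan")
    return EnhancementEstimate(value=p_soft / expected,
                               se=float(se_p / expected),
                               n_soft=int(soft.size),
                               n_events=profile.n_events)


def uniformity_test(profile: FrequencyProfile,
                    loci: Optional[Sequence[int]] = None
                    ) -> Tuple[float, float]:
    """Chi-squared goodness of fit of the event counts against a uniform
    distribution over ``loci`` (default: all profile loci). Returns
    (statistic, p-value)."""
    if profile.counts is None:
        raise ValueError("profile carries no raw counts")
    counts = profile.counts if loci is None \
        else profile.counts[np.asarray(loci, dtype=int)]
    chi2, p = stats.chisquare(counts)
    return float(chi2), float(p)


@dataclass
class ExponentialFit:
    """Log-linear fit of enhancement against rigidity drop (l_p - l_f)."""

    rate_per_bp: float
    rate_se: float
    intercept: float
    residuals: np.ndarray
    r_squared: float
    faster_than_exponential: bool


def fit_enhancement_exponential(lf_values: Sequence[float],
                                enhancements: Sequence[float],
                                lp_bp: float = 150.0) -> ExponentialFit:
    """Least-squares line on log(enhancement) vs (l_p - l_f).

    A single exponential is the expectation for a Metropolis rule whose
    energy barrier falls linearly with the soft-site stiffness; the fit
    flags the most-softened point when it lies clearly above the line, the
    departure signature at strong softening.
    """
    lf = np.asarray(lf_values, dtype=float)
    enh = np.asarray(enhancements, dtype=float)
    if lf.shape != enh.shape or lf.ndim != 1:
        raise ValueError("lf_values and enhancements must be 1-D and matched")
    if lf.size < 3:
        raise ValueError("at least 3 (l_f, enhancement) points are required")
    if np.any(enh <= 0):
        raise ValueError("enhancements must be positive")
    if np.any(lf <= 0) or np.any(lf > lp_bp):
        raise ValueError("lf_values must lie in (0, lp_bp]")
    x = lp_bp - lf
    y = np.log(enh)
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    residuals = y - fitted
    rmse = float(np.sqrt(np.mean(residuals ** 2)))
    i_max = int(np.argmax(x))
    others = np.delete(residuals, i_max)
    rmse_others = float(np.sqrt(np.mean(others ** 2))) if others.size else 0.0
    faster = bool(residuals[i_max] > 2.0 * max(rmse_others, 1e-12)) \
        and residuals[i_max] > 0
    return ExponentialFit(rate_per_bp=float(res.slope),
                          rate_se=float(res.stderr),
                          intercept=float(res.intercept),
                          residuals=residuals,
                          r_squared=float(res.rvalue ** 2),
                          faster_than_exponential=faster)


@dataclass
class ScalingCurve:
    """(separation, contact probability) or (length, size) pairs, with an
    optionally attached fitted exponent."""

    abscissa: np.ndarray
    ordinate: np.ndarray
    ordinate_se: Optional[np.ndarray] = None
    fitted_exponent: Optional[float] = None
    exponent_se: Optional[float] = None
    fit_window: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.ordinate = np.asarray(self.ordinate, dtype=float)
        if self.abscissa.shape != self.ordinate.shape:
            raise ValueError("abscissa and ordinate must match")
        if np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa must be strictly increasing")


def contact_probability(ensemble: EnsembleSample, cutoff: float,
                        min_frames: int = 1) -> ScalingCurve:
    """P_c(s): fraction of bead pairs (i, i+s) within ``cutoff`` bead
    diameters, averaged over beads and frames."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if ensemble.n_frames < min_frames:
        raise ValueError(
            f"need at least {min_frames} frames, got {ensemble.n_frames}")
    coords = ensemble.coords_array()
    n = coords.shape[1]
    s_vals = np.arange(1, n)
    pc = np.empty(s_vals.size)
    for k, s in enumerate(s_vals):
        d = np.linalg.norm(coords[:, s:, :] - coords[:, :-s, :], axis=2)
        pc[k] = np.mean(d < cutoff)
    return ScalingCurve(abscissa=s_vals.astype(float), ordinate=pc)


def asymptotic_contact_window(cutoff: float, n_beads: int
                              ) -> Tuple[float, float]:
    """Fit window over which P_c(s) is in its asymptotic power-law regime.

    For an ideal chain the contact probability is known in closed form,
    P_c(s) = gammainc(3/2, 3 c^2 / (2 s)) for cutoff c, and its local
    log-slope approaches -3/2 as -3/2 (1 - 0.4 x) with x = 3 c^2 / (2 s).
    Requiring x <= 0.1 (slope within ~4% of the asymptote) gives a lower
    edge s >= 15 c^2; fitting below it measures the crossover, not the
    exponent. The upper edge L/4 keeps clear of chain-end depletion in
    self-avoiding and collapsed states.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    lo = max(4, int(np.ceil(15.0 * cutoff * cutoff)))
    hi = max(lo + 4, n_beads // 4)
    return (float(lo), float(hi))


@dataclass
class ExponentFit:
    nu: float
    se: float
    slope: float
    slope_se: float
    window: Tuple[float, float]
    n_points: int


def fit_scaling_exponent(curve: ScalingCurve, mode: str,
                         window: Optional[Tuple[float, float]] = None
                         ) -> ExponentFit:
    """Flory exponent nu from a log-log fit.

    mode='contact': slope of log P_c vs log s equals -3 nu.
    mode='size':    slope of log R vs log L equals nu directly.
    """
    if mode not in ("contact", "size"):
        raise ValueError("mode must be 'contact' or 'size'")
    x = curve.abscissa
    y = curve.ordinate
    if window is None:
        window = curve.fit_window
    if window is None:
        window = (x.min(), x.max())
    lo, hi = window
    mask = (x >= lo) & (x <= hi) & (y > 0)
    if mask.sum() < 4:
        raise ValueError(
            f"fit window {window} holds {int(mask.sum())} usable points; "
            "at least 4 are required")
    lx = np.log(x[mask])
    ly = np.log(y[mask])
    if np.ptp(lx) < 1e-12:
        raise ValueError("degenerate fit window (no abscissa spread)")
    (slope, _), cov = np.polyfit(lx, ly, 1, cov=True)
    slope_se = float(np.sqrt(cov[0, 0]))
    if mode == "contact":
        nu, se = -slope / 3.0, slope_se / 3.0
    else:
        nu, se = slope, slope_se
    return ExponentFit(nu=float(nu), se=float(se), slope=float(slope),
                       slope_se=slope_se, window=(float(lo), float(hi)),
                       n_points=int(mask.sum()))


def reintegration_distance_pdf(nu: float, s_min: int, s_max: int
                               ) -> Tuple[np.ndarray, np.ndarray]:
    """Normalised re-integration distance law p(s) propto s^(-3 nu) over
    integer genomic separations s in [s_min, s_max]."""
    if nu <= 0:
        raise ValueError(f"nu must be positive, got {nu}")
    if not (0 < s_min < s_max):
        raise ValueError(
            f"require 0 < s_min < s_max, got ({s_min}, {s_max})")
    s = np.arange(int(s_min), int(s_max) + 1, dtype=float)
    w = s ** (-3.0 * nu)
    return s, w / w.sum()


def distribution_median(s: np.ndarray, p: np.ndarray) -> float:
    """Median of a discrete distribution given support and probabilities."""
    cdf = np.cumsum(p)
    return float(s[np.searchsorted(cdf, 0.5)])
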