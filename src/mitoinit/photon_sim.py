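"""Synthetic two-color confocal photon traces with known ground truth.

The simulator emulates freely diffusing, fluorophore-labeled molecules
transiting a confocal detection volume in the single-molecule regime
(occupancy ``N <= 0.01``), producing binned photon-count traces for a red
(Cy5, ribosome) and a green (Cy3, mRNA) detection channel. Diffusion is
modeled in time only: each transit is a Poisson-process arrival with an
exponentially distributed duration and a Gaussian temporal intensity
profile; the confocal geometry is folded into the brightness and transit
time parameters. This is sufficient for burst statistics and FCS-style
autocorrelation checks, and deliberately omits sub-bin photon arrival
times, 3-D Brownian dynamics and triplet kinetics.

Incomplete labeling, multi-dye red labeling (an average of six Cy5 dyes
per ribosome), per-transit photobleaching, channel crosstalk and Poisson
background are all modeled so that detection losses can be configured to
match a measured positive control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import curve_fit
from scipy.special import erf

from .errors import (
    FitFailureError,
    InvalidConfigError,
    InvalidMixError,
    UndefinedACFError,
)

__all__ = [
    "ConfocalSimConfig",
    "Species",
    "SpeciesMix",
    "Transit",
    "PhotonTrace",
    "simulate_trace",
    "autocorrelation",
    "fit_diffusion_time",
    "analytic_acf",
    "expected_mean_counts",
    "PROFILE_WIDTH_FACTOR",
    "SINGLE_MOLECULE_OCCUPANCY",
]

#: Width of the Gaussian temporal intensity profile of a transit, as a
#: fraction of the transit duration (sigma = factor * duration).
PROFILE_WIDTH_FACTOR = 0.25

#: Occupancy above which chance coincidence is no longer negligible.
SINGLE_MOLECULE_OCCUPANCY = 0.01


@dataclass(frozen=True)
class ConfocalSimConfig:
    """Parameters of the confocal trace simulator.

    Parameters
    ----------
    duration : float
        Total acquisition time in seconds.
    bin_width : float
        Width of a counting bin in seconds.
    occupancy : float
        Expected number of molecules in the detection volume, summed over
        the species mixture. The single-molecule regime, in which chance
        coincidence is negligible, is ``occupancy <= 0.01``; larger values
        trigger a warning, not an error.
    mean_transit_time : float
        Mean dwell time of a molecule in the detection volume, seconds.
    brightness_red, brightness_green : float
        Expected detected photons per dye per bin for a molecule at the
        focus center.
    n_dyes_red : int
        Number of red dyes per red-labeled molecule (six Cy5 dyes per
        ribosome on average).
    labeling_efficiency_green : float
        Probability that a green-labeled species actually carries a green
        dye.
    labeling_efficiency_red : float
        Probability that a red-labeled species carries its red dye stack
        at all; lumps together incomplete labeling, complete bleaching
        and dissociation losses on the red side.
    background_rate_red, background_rate_green : float
        Uncorrelated background in counts per second.
    crosstalk_green_to_red : float
        Fraction of the green molecular signal leaking into the red
        detection channel.
    bleach_prob_per_transit : float
        Per-dye probability of being dark for a given transit (applied as
        binomial thinning of the red dye stack).
    seed : int
        Seed of the simulation; identical (config, mix, seed) reproduces
        the trace bit for bit.
    """

    duration: float
    bin_width: float = 1e-3
    occupancy: float = 0.01
    mean_transit_time: float = 2e-3
    brightness_red: float = 8.0
    brightness_green: float = 25.0
    n_dyes_red: int = 6
    labeling_efficiency_green: float = 1.0
    labeling_efficiency_red: float = 1.0
    background_rate_red: float = 1000.0
    background_rate_green: float = 1000.0
    crosstalk_green_to_red: float = 0.02
    bleach_prob_per_transit: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise InvalidConfigError(f"duration must be > 0, got {self.duration}")
        if not self.bin_width > 0:
            raise InvalidConfigError(f"bin_width must be > 0, got {self.bin_width}")
        if not self.mean_transit_time > 0:
            raise InvalidConfigError(
                f"mean_transit_time must be > 0, got {self.mean_transit_time}"
            )
        if self.occupancy < 0:
            raise InvalidConfigError(f"occupancy must be >= 0, got {self.occupancy}")
        if self.occupancy > SINGLE_MOLECULE_OCCUPANCY:
            warnings.warn(
                f"occupancy {self.occupancy} exceeds the single-molecule regime "
                f"(N <= {SINGLE_MOLECULE_OCCUPANCY}); chance coincidence will not "
                "be negligible",
                stacklevel=3,
            )
        for name in ("brightness_red", "brightness_green"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if int(self.n_dyes_red) != self.n_dyes_red or self.n_dyes_red < 1:
            raise InvalidConfigError("n_dyes_red must be a positive integer")
        for name in ("labeling_efficiency_green", "labeling_efficiency_red",
                     "bleach_prob_per_transit"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.crosstalk_green_to_red < 1.0:
            raise InvalidConfigError(
                f"crosstalk_green_to_red must be in [0, 1), got "
                f"{self.crosstalk_green_to_red}"
            )
        for name in ("background_rate_red", "background_rate_green"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_width))


@dataclass(frozen=True)
class Species:
    """One molecular species of the mixture."""

    label: str
    fraction: float
    carries_red: bool = False
    carries_green: bool = False


@dataclass(frozen=True)
class SpeciesMix:
    """Composition of the sample: positive control, negative control or
    exchange-experiment mixtures are all encoded as species fractions."""

    species: tuple[Species, ...]

    def __init__(self, species: Sequence[Species]):
        object.__setattr__(self, "species", tuple(species))
        if not self.species:
            raise InvalidMixError("mix must contain at least one species")
        total = sum(s.fraction for s in self.species)
        if abs(total - 1.0) > 1e-9:
            raise InvalidMixError(
                f"species fractions must sum to 1 (got {total!r})"
            )
        for s in self.species:
            if not 0.0 <= s.fraction <= 1.0:
                raise InvalidMixError(
                    f"species {s.label!r} fraction {s.fraction} outside [0, 1]"
                )

    @classmethod
    def positive_control(cls) -> "SpeciesMix":
        """Every complex double-labeled (ribosome-bound mRNA)."""
        return cls([Species("complex", 1.0, carries_red=True, carries_green=True)])

    @classmethod
    def negative_control(cls) -> "SpeciesMix":
        """Independently diffusing red-only and green-only molecules."""
        return cls([
            Species("ribosome", 0.5, carries_red=True),
            Species("mrna", 0.5, carries_green=True),
        ])

    @classmethod
    def exchange_experiment(cls, labeled_bound_fraction: float) -> "SpeciesMix":
        """mRNA-bound complexes of which ``labeled_bound_fraction`` carry a
        red-labeled large subunit; the rest kept their unlabeled subunit."""
        if not 0.0 <= labeled_bound_fraction <= 1.0:
            raise InvalidMixError("labeled_bound_fraction must be in [0, 1]")
        return cls([
            Species("complex-labeled-LSU", labeled_bound_fraction,
                    carries_red=True, carries_green=True),
            Species("complex-unlabeled-LSU", 1.0 - labeled_bound_fraction,
                    carries_green=True),
        ])


class Transit(NamedTuple):
    """Ground-truth record of one molecule crossing the detection volume."""

    label: str
    start_bin: int
    end_bin: int


@dataclass
class PhotonTrace:
    """Two aligned binned photon-count channels.

    ``counts_red``/``counts_green`` are photons per bin; ``transit_log``
    carries the simulator's ground truth and is absent for traces read
    from a file.
    """

    bin_width: float
    counts_red: np.ndarray
    counts_green: np.ndarray
    transit_log: list[Transit] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts_red = np.asarray(self.counts_red, dtype=np.int64)
        self.counts_green = np.asarray(self.counts_green, dtype=np.int64)
        if self.counts_red.shape != self.counts_green.shape:
            raise InvalidConfigError("channels must have equal length")
        if self.counts_red.ndim != 1:
            raise InvalidConfigError("counts must be one-dimensional")
        if (self.counts_red < 0).any() or (self.counts_green < 0).any():
            raise InvalidConfigError("photon counts must be non-negative")
        if self.transit_log is not None:
            n = len(self.counts_red)
            for t in self.transit_log:
                if not (0 <= t.start_bin < t.end_bin <= n):
                    raise InvalidConfigError(
                        f"transit {t} outside trace of {n} bins"
                    )

    @property
    def n_bins(self) -> int:
        return int(len(self.counts_red))

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    def channel(self, name: str) -> np.ndarray:
        if name == "red":
            return self.counts_red
        if name == "green":
            return self.counts_green
        raise InvalidConfigError(f"channel must be 'red' or 'green', got {name!r}")


def _transit_profile(start: float, dur: float, cfg: ConfocalSimConfig,
                     intensity: np.ndarray, scale: float) -> None:
    """Add one transit's expected photons per bin to the accumulator.

    The intensity is a Gaussian of the time in the volume (peak ``scale``
    photons per bin at the focus center), truncated to the transit
    interval; each bin receives the exact integral of that profile over
    the bin, so binning introduces no discretization bias.
    """
    bw = cfg.bin_width
    n = len(intensity)
    b0 = max(int(math.floor(start / bw)), 0)
    b1 = min(int(math.ceil((start + dur) / bw)), n)
    if b1 <= b0:
        return
    sigma = PROFILE_WIDTH_FACTOR * dur
    mid = start + dur / 2.0
    edges = np.arange(b0, b1 + 1) * bw
    # clip bin edges to the transit window, then integrate the Gaussian
    z = (np.clip(edges, start, start + dur) - mid) / (sigma * math.sqrt(2.0))
    cdf = erf(z)
    intensity[b0:b1] += (scale * sigma * math.sqrt(math.pi / 2.0) / bw
                         * np.diff(cdf))


def simulate_trace(config: ConfocalSimConfig, mix: SpeciesMix) -> PhotonTrace:
    """Simulate a two-channel photon-count trace for a species mixture.

    Transits of each species arrive as a Poisson process with rate
    ``occupancy * fraction / mean_transit_time``; each transit has an
    exponential duration and a Gaussian temporal intensity profile.
    Photons per bin are Poisson with mean = profile x brightness x number
    of active dyes, plus channel-independent Poisson background; a
    configurable fraction of the green molecular signal leaks into the
    red channel. Random streams are separated by purpose (arrivals,
    labeling, photons) so changing one parameter perturbs only its own
    stream.
    """
    n_bins = config.n_bins
    if n_bins <= 0:
        raise InvalidConfigError("duration shorter than one bin")

    ss = np.random.SeedSequence(config.seed)
    rng_arrivals, rng_labels, rng_photons = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )

    mean_red = np.zeros(n_bins)
    mean_green = np.zeros(n_bins)
    transit_log: list[Transit] = []

    for sp in mix.species:
        rate = config.occupancy * sp.fraction / config.mean_transit_time
        n_transits = rng_arrivals.poisson(rate * config.duration)
        if n_transits == 0:
            continue
        starts = np.sort(rng_arrivals.uniform(0.0, config.duration, n_transits))
        durs = rng_arrivals.exponential(config.mean_transit_time, n_transits)

        if sp.carries_green:
            green_on = (rng_labels.random(n_transits)
                        < config.labeling_efficiency_green)
        else:
            green_on = np.zeros(n_transits, dtype=bool)
        if sp.carries_red:
            labeled = (rng_labels.random(n_transits)
                       < config.labeling_efficiency_red)
            n_active = rng_labels.binomial(
                config.n_dyes_red, 1.0 - config.bleach_prob_per_transit,
                n_transits)
            n_active = np.where(labeled, n_active, 0)
        else:
            n_active = np.zeros(n_transits, dtype=np.int64)

        for i in range(n_transits):
            t0, dur = float(starts[i]), float(durs[i])
            if green_on[i]:
                _transit_profile(t0, dur, config, mean_green,
                                 config.brightness_green)
            if n_active[i] > 0:
                _transit_profile(t0, dur, config, mean_red,
                                 config.brightness_red * int(n_active[i]))
            b0 = max(int(math.floor(t0 / config.bin_width)), 0)
            b1 = min(int(math.ceil((t0 + dur) / config.bin_width)), n_bins)
            if b1 > b0:
                transit_log.append(Transit(sp.label, b0, b1))

    mean_red = mean_red + config.crosstalk_green_to_red * mean_green
    mean_red += config.background_rate_red * config.bin_width
    mean_green = mean_green + config.background_rate_green * config.bin_width

    counts_red = rng_photons.poisson(mean_red)
    counts_green = rng_photons.poisson(mean_green)
    transit_log.sort(key=lambda t: (t.start_bin, t.end_bin, t.label))
    return PhotonTrace(config.bin_width, counts_red, counts_green, transit_log)


def expected_mean_counts(config: ConfocalSimConfig,
                         mix: SpeciesMix) -> tuple[float, float]:
    """Analytic expectation of the per-bin mean counts in each channel.

    The Gaussian profile of a transit of duration ``T`` integrates to
    ``c T sqrt(2 pi) erf(1 / (2 sqrt(2) c))`` photons-at-peak-equivalents
    (``c`` the profile width factor); the exponential duration average
    cancels the transit rate's ``1 / mean_transit_time``, leaving a mean
    occupancy-proportional signal. Used as the closed-form oracle for the
    simulator's photon budget.
    """
    c = PROFILE_WIDTH_FACTOR
    k = c * math.sqrt(2.0 * math.pi) * erf(1.0 / (2.0 * math.sqrt(2.0) * c))
    red_sig = 0.0
    green_sig = 0.0
    for sp in mix.species:
        if sp.carries_green:
            green_sig += (config.occupancy * sp.fraction * k
                          * config.brightness_green
                          * config.labeling_efficiency_green)
        if sp.carries_red:
            mean_dyes = (config.labeling_efficiency_red * config.n_dyes_red
                         * (1.0 - config.bleach_prob_per_transit))
            red_sig += (config.occupancy * sp.fraction * k
                        * config.brightness_red * mean_dyes)
    red = (red_sig + config.crosstalk_green_to_red * green_sig
           + config.background_rate_red * config.bin_width)
    green = green_sig + config.background_rate_green * config.bin_width
    return red, green


def autocorrelation(trace: PhotonTrace, channel: str,
                    max_lag: int) -> np.ndarray:
    """Normalized intensity autocorrelation G(tau) of one channel.

    ``G(tau) = <dF(t) dF(t+tau)> / <F>^2`` over all valid bin pairs, for
    lags ``1..max_lag`` (the zero-lag point is shot-noise dominated and
    excluded). Returns an array of shape ``(max_lag, 2)`` with columns
    (lag in seconds, G).
    """
    f = trace.channel(channel).astype(np.float64)
    n = len(f)
    if max_lag >= n:
        raise InvalidConfigError(f"max_lag {max_lag} must be < trace length {n}")
    if max_lag < 1:
        raise InvalidConfigError("max_lag must be >= 1")
    mean = f.mean()
    if mean == 0.0:
        raise UndefinedACFError("constant-zero channel has no autocorrelation")
    d = f - mean
    out = np.empty((max_lag, 2))
    for k in range(1, max_lag + 1):
        out[k - 1, 0] = k * trace.bin_width
        out[k - 1, 1] = np.dot(d[:-k], d[k:]) / (n - k) / mean**2
    return out


def _hyperbola(tau, amplitude, tau_d):
    return amplitude / (1.0 + tau / tau_d)


def fit_diffusion_time(acf: np.ndarray | Sequence[tuple[float, float]]
                       ) -> tuple[float, float]:
    """Least-squares fit of ``G(tau) = A / (1 + tau / tau_D)``.

    The 2-D Gaussian-volume approximation of the FCS diffusion curve;
    returns ``(tau_D, amplitude)``.
    """
    arr = np.asarray(acf, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 5:
        raise InvalidConfigError("acf must be >= 5 (lag, G) points")
    tau, g = arr[:, 0], arr[:, 1]
    head = g[: max(len(g) // 4, 1)].mean()
    tail = g[-max(len(g) // 4, 1):].mean()
    if not head > 0 or head <= tail:
        raise FitFailureError(
            f"ACF does not decay (head mean {head:.3g}, tail mean {tail:.3g}); "
            "cannot fit a diffusion time"
        )
    p0 = (float(g[0]), float(tau[min(np.searchsorted(-g, -g[0] / 2), len(tau) - 1)]))
    try:
        popt, _ = curve_fit(_hyperbola, tau, g, p0=p0, maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise FitFailureError(f"diffusion fit failed to converge: {exc}") from exc
    amplitude, tau_d = float(popt[0]), float(popt[1])
    if tau_d <= 0 or amplitude <= 0:
        raise FitFailureError(
            f"diffusion fit returned non-physical parameters "
            f"(A={amplitude:.3g}, tau_D={tau_d:.3g})"
        )
    return tau_d, amplitude


def analytic_acf(mean_transit_time: float, lags: Sequence[float],
                 profile_width_factor: float = PROFILE_WIDTH_FACTOR
                 ) -> np.ndarray:
    """Model autocorrelation of the transit process, up to amplitude.

    For a transit of duration ``T`` with Gaussian profile ``sigma = c T``,
    the lag-``tau`` self-correlation integrates in closed form to
    ``exp(-tau^2 / (4 sigma^2)) * sigma * sqrt(pi) * erf((T - tau) / (2 sigma))``;
    the exponential duration distribution is integrated numerically.
    Serves as the ground-truth curve for FCS recovery tests: fitting it
    with :func:`fit_diffusion_time` on the same lag grid as a simulated
    trace defines the diffusion time the simulator encodes.
    """
    c = profile_width_factor
    mu = mean_transit_time

    def integrand(T: float, tau: float) -> float:
        s = c * T
        return (math.exp(-T / mu) / mu
                * math.exp(-tau * tau / (4.0 * s * s))
                * s * math.sqrt(math.pi) * erf((T - tau) / (2.0 * s)))

    out = np.empty((len(lags), 2))
    for i, tau in enumerate(lags):
        val = quad(integrand, max(tau, 1e-12), 50.0 * mu,
                   args=(float(tau),), limit=200)[0]
        out[i] = (tau, val)
    return out
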