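"""FRET-efficiency traces, photobleach windowing and histogram fitting.

A single-molecule FRET trace reports the proximity ratio

    E = I_A / (I_D + I_A)

computed frame by frame from background-subtracted donor (Cy3) and acceptor
(Cy5) intensities.  For the human telomeric G-quadruplex construct analysed
here the folded conformers sit at E ~ 0.70 (parallel) and E ~ 0.59
(anti-parallel/hybrid), the unfolded hairpin-free strand below E = 0.45, and
molecules without an active acceptor appear at E ~ 0.12 from donor leakage
into the acceptor channel.  No gamma-factor or leakage correction is applied:
event thresholds operate on the raw proximity ratio, and the donor-only
population is modelled as a histogram component rather than subtracted.

The usable part of a trace runs from the start of recording until the first
photobleach (donor or acceptor) or the end of the movie, whichever comes
first; :func:`detect_observation_window` finds that boundary from the
intensities alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityTrace",
    "FretTrace",
    "GaussianComponent",
    "HistogramModel",
    "MixtureFitError",
    "compute_fret",
    "detect_observation_window",
    "fret_trace",
    "build_fret_histogram",
    "histogram_from_samples",
    "fit_gaussian_mixture",
]

#: Histogram support; wider than [0, 1] so uncorrected ratios near the edges
#: and future non-clamped inputs keep their tails.
HISTOGRAM_RANGE = (-0.2, 1.2)


@dataclass
class IntensityTrace:
    """One molecule's donor/acceptor intensity time series.

    Intensities are in camera counts (background-subtracted values may be
    negative); ``frame_interval`` is in seconds.
    """

    molecule_id: str
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.ndim != 1 or self.acceptor.ndim != 1:
            raise ValueError("donor and acceptor must be 1-D arrays")
        if self.donor.size != self.acceptor.size or self.donor.size < 1:
            raise ValueError(
                f"trace {self.molecule_id!r}: donor and acceptor must have equal "
                f"length >= 1 (got {self.donor.size} and {self.acceptor.size})"
            )
        if not (np.isfinite(self.frame_interval) and self.frame_interval > 0):
            raise ValueError(f"frame_interval must be positive, got {self.frame_interval}")

    @property
    def n_frames(self) -> int:
        return int(self.donor.size)

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


@dataclass
class FretTrace:
    """Per-frame FRET efficiencies plus the valid (pre-photobleach) window.

    ``efret`` holds NaN on frames where the total intensity is non-positive
    (undefined ratio).  ``observation_end_frame`` is exclusive; frames at or
    beyond it are ignored by event detection and histograms.
    """

    molecule_id: str
    efret: np.ndarray
    frame_interval: float
    observation_end_frame: int

    def __post_init__(self) -> None:
        self.efret = np.asarray(self.efret, dtype=float)
        if not 0 <= self.observation_end_frame <= self.efret.size:
            raise ValueError(
                f"observation_end_frame {self.observation_end_frame} outside "
                f"[0, {self.efret.size}] for molecule {self.molecule_id!r}"
            )
        defined = self.efret[np.isfinite(self.efret)]
        if defined.size and (defined.min() < 0 or defined.max() > 1):
            raise ValueError(f"efret outside [0, 1] for molecule {self.molecule_id!r}")

    @property
    def observation_time(self) -> float:
        """Seconds of usable recording, ``observation_end_frame * frame_interval``."""
        return self.observation_end_frame * self.frame_interval

    def windowed(self) -> np.ndarray:
        """Efficiencies inside the observation window (NaN = undefined)."""
        return self.efret[: self.observation_end_frame]


def compute_fret(trace: IntensityTrace) -> FretTrace:
    """Convert intensities to the raw proximity ratio, frame by frame.

    Negative (over-subtracted) intensities are clamped to zero before the
    ratio.  Frames with non-positive total intensity are undefined (NaN).
    The returned window spans the whole trace; combine with
    :func:`detect_observation_window` (or use :func:`fret_trace`) to bound it
    at photobleaching.
    """
    d = np.maximum(trace.donor, 0.0)
    a = np.maximum(trace.acceptor, 0.0)
    total = d + a
    efret = np.full(trace.n_frames, np.nan)
    ok = total > 0
    np.divide(a, total, out=efret, where=ok)
    if not ok.any():
        logger.warning(
            "trace %s: all frames have non-positive total intensity; "
            "no FRET defined (trace should be excluded)",
            trace.molecule_id,
        )
    return FretTrace(
        molecule_id=trace.molecule_id,
        efret=efret,
        frame_interval=trace.frame_interval,
        observation_end_frame=trace.n_frames,
    )


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Trailing running median; early frames repeat the first full-window value.

    NaN entries are ignored inside a window (all-NaN windows give NaN).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    w = max(1, min(window, n))
    sw = np.lib.stride_tricks.sliding_window_view(x, w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(sw, axis=1)
    out = np.empty(n)
    out[w - 1 :] = med
    out[: w - 1] = med[0]
    return out


def detect_observation_window(
    trace: IntensityTrace,
    drop_fraction: float = 0.5,
    window: int = 5,
    acceptor_efret_cut: float = 0.2,
) -> int:
    """Find the exclusive end frame of the usable observation window.

    Two bleaching signatures end a trace:

    * donor bleach -- the trailing running median (over ``window`` frames) of
      the total intensity falls below ``drop_fraction`` times its initial
      value (both dyes go dark, the ratio becomes meaningless);
    * acceptor bleach -- the total is sustained but the efficiency collapses
      to the donor-leakage level; detected as the earliest frame from which
      at least 90% of running-median efficiencies stay below
      ``acceptor_efret_cut`` through the end of the (donor-bounded) trace,
      for at least ``window`` frames.  The permanence requirement
      distinguishes bleaching from genuine unfolded dwells, which refold;
      the 90% tolerance keeps rare noise excursions from hiding a bleach.

    Returns the earlier of the two boundaries, or the trace length if neither
    fires.  Always returns an index (never raises).  Donor-only molecules
    (efficiency at the leakage level throughout) get an empty window, which
    downstream analysis treats as exclusion.
    """
    total = trace.donor + trace.acceptor
    n = trace.n_frames
    w = max(1, min(window, n))
    med_total = _running_median(total, w)
    initial = float(np.median(total[:w]))
    below = med_total < drop_fraction * initial
    if below.any():
        # trailing median at i covers frames [i-w+1, i]; centre the estimate
        donor_end = max(0, int(np.argmax(below)) - w // 2)
    else:
        donor_end = n
    if donor_end == 0:
        return 0

    efret = compute_fret(trace).efret[:donor_end]
    med_e = _running_median(efret, w)
    with np.errstate(invalid="ignore"):
        low = med_e < acceptor_efret_cut  # NaN compares False
    end = donor_end
    # suffix fraction of low medians, scanning from the end
    suffix_low = np.cumsum(low[::-1])[::-1]
    tail_len = donor_end - np.arange(donor_end)
    candidates = low & (suffix_low >= 0.9 * tail_len) & (tail_len >= w)
    if candidates.any():
        end = max(0, int(np.argmax(candidates)) - w // 2)
    return end


def fret_trace(
    trace: IntensityTrace,
    drop_fraction: float = 0.5,
    window: int = 5,
    acceptor_efret_cut: float = 0.2,
) -> FretTrace:
    """Proximity-ratio trace with the photobleach-bounded observation window."""
    ft = compute_fret(trace)
    end = detect_observation_window(
        trace,
        drop_fraction=drop_fraction,
        window=window,
        acceptor_efret_cut=acceptor_efret_cut,
    )
    return replace(ft, observation_end_frame=end)


@dataclass
class GaussianComponent:
    """One Gaussian peak of a FRET histogram fit (weight = area fraction)."""

    mean: float
    sd: float
    weight: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"component sd must be > 0, got {self.sd}")


@dataclass
class HistogramModel:
    """Binned molecule-frame FRET counts, optionally with fitted components."""

    bin_edges: np.ndarray
    counts: np.ndarray
    components: list[GaussianComponent] | None = None
    fit_residual: float | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be non-negative")

    @property
    def n_components(self) -> int:
        return 0 if self.components is None else len(self.components)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def histogram_from_samples(samples: Sequence[float], bin_width: float = 0.02) -> HistogramModel:
    """Bin raw efficiency samples on the fixed grid spanning [-0.2, 1.2]."""
    samples = np.asarray(samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if samples.size == 0:
        raise ValueError("no defined efficiency samples to histogram")
    lo, hi = HISTOGRAM_RANGE
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(samples, bins=edges)
    return HistogramModel(bin_edges=edges, counts=counts.astype(float))


def build_fret_histogram(
    fret_traces: Sequence[FretTrace],
    first_k_frames: int = 15,
    bin_width: float = 0.02,
) -> HistogramModel:
    """Pool the first frames of every molecule into a FRET histogram.

    For each molecule the defined efficiencies among its first
    ``min(first_k_frames, observation_end_frame)`` frames are pooled, the
    short-movie practice used to snapshot the folded-state distribution
    before enzyme activity redistributes it.
    """
    if first_k_frames < 1:
        raise ValueError("first_k_frames must be >= 1")
    pooled: list[np.ndarray] = []
    for ft in fret_traces:
        seg = ft.efret[: min(first_k_frames, ft.observation_end_frame)]
        pooled.append(seg[np.isfinite(seg)])
    values = np.concatenate(pooled) if pooled else np.empty(0)
    if values.size == 0:
        raise ValueError("no defined efficiency frames in any trace")
    return histogram_from_samples(values, bin_width=bin_width)


class MixtureFitError(RuntimeError):
    """Raised when the Gaussian-sum least-squares fit fails to converge."""

    def __init__(self, message: str, residual_norm: float, init_means: Sequence[float]):
        super().__init__(
            f"{message} (residual norm at initialization {residual_norm:.4g}, "
            f"init_means={list(init_means)})"
        )
        self.residual_norm = residual_norm
        self.init_means = list(init_means)


def _gaussian_sum(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for i in range(0, len(params), 3):
        a, m, s = params[i : i + 3]
        y = y + a * np.exp(-0.5 * ((x - m) / s) ** 2)
    return y


def fit_gaussian_mixture(
    hist: HistogramModel,
    n_components: int,
    init_means: Sequence[float],
    init_sd: float | None = None,
) -> HistogramModel:
    """Least-squares fit of a sum of Gaussians to binned counts.

    This is the conventional presentation-style fit of smFRET histograms
    (individual peaks plus their cumulative curve), not an EM mixture on raw
    samples: the data are counts on a fixed grid and the fit is deterministic
    given ``init_means``.  To dodge local minima when neighbouring peaks
    overlap, the optimiser is started from a fixed ladder of initial widths
    (0.02, 0.03, 0.05 when ``init_sd`` is not given) and the lowest-residual
    solution is kept -- still fully deterministic.  Components are returned
    sorted by mean, with weights as area fractions summing to 1.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if len(init_means) != n_components:
        raise ValueError("init_means must have length n_components")
    x = hist.bin_centers
    y = hist.counts.astype(float)
    if not (y > 0).any():
        raise ValueError("histogram is empty; nothing to fit")

    lo, hi = HISTOGRAM_RANGE
    lower = [0.0, lo, 1e-3] * n_components
    upper = [np.inf, hi, 2.0] * n_components
    init_sds = (init_sd,) if init_sd is not None else (0.02, 0.03, 0.05)
    best: np.ndarray | None = None
    best_resid = np.inf
    last_error: Exception | None = None
    for s0 in init_sds:
        p0: list[float] = []
        for m in init_means:
            amp = float(
                max(y[int(np.argmin(np.abs(x - m)))], y.max() / (2 * n_components), 1.0)
            )
            p0.extend([amp, float(m), float(s0)])
        try:
            popt, _ = curve_fit(
                _gaussian_sum, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
            )
        except (RuntimeError, ValueError) as exc:
            last_error = exc
            continue
        resid = float(np.linalg.norm(y - _gaussian_sum(x, *popt)))
        if resid < best_resid:
            best, best_resid = popt, resid
    if best is None:
        resid0 = float(np.linalg.norm(y))
        raise MixtureFitError(str(last_error), resid0, init_means) from last_error
    popt = best

    comps = []
    for i in range(n_components):
        a, m, s = popt[3 * i : 3 * i + 3]
        comps.append(GaussianComponent(mean=float(m), sd=float(s), weight=float(a * s)))
    total_weight = sum(c.weight for c in comps)
    if total_weight > 0:
        for c in comps:
            c.weight /= total_weight
    comps.sort(key=lambda c: c.mean)
    residual = float(np.linalg.norm(y - _gaussian_sum(x, *popt)))
    return HistogramModel(
        bin_edges=hist.bin_edges.copy(),
        counts=hist.counts.copy(),
        components=comps,
        fit_residual=residual,
    )
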