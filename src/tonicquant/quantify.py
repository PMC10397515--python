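"""Tonic current quantification from voltage-clamp traces.

The procedure mirrors standard practice for tonic GABA-A current
measurement: within each pharmacological phase (before / after drug
application), pick 5-s epochs with as little spontaneous synaptic
activity as possible, build an all-point histogram of every sample in
the epoch, and fit a Gaussian to the histogram while excluding the
skewed tail contributed by sIPSCs — the fit window runs from two bins
beyond the peak on the event-tail side across the entire event-free
side. The Gaussian mean estimates the holding current of the epoch; the
per-phase holding current is the arithmetic mean over three epochs, and
the tonic current is the difference between the pre- and post-drug
holding currents (reported as a magnitude with the signed value
retained). Dividing by cell capacitance gives the current density in
pA/pF.

Because sIPSCs are inward (negative) deflections, the naive segment
mean is biased negative by the events; the constrained Gaussian fit is
robust to this contamination, which is the entire point of the
procedure.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, optimize

from .errors import FitError, InsufficientDataError, ValidationError
from .traceio import CurrentTrace

__all__ = [
    "QuantParams",
    "Segment",
    "EpochSelection",
    "AllPointHistogram",
    "GaussianFit",
    "TonicResult",
    "detect_events",
    "select_epochs",
    "all_point_histogram",
    "fit_gaussian_constrained",
    "holding_current",
    "tonic_current",
    "quantify_trace",
]

Phase = Literal["pre", "post"]
TailSide = Literal["negative", "positive"]


@dataclass(frozen=True)
class QuantParams:
    """Analysis settings for the tonic quantification pipeline.

    Attributes
    ----------
    bin_width_pa
        All-point histogram bin width; 0.5 pA resolves few-pA shifts
        while keeping hundreds of counts in central bins of a 50,000-
        sample epoch.
    threshold_sd, min_width_ms
        Event-screening criterion: an epoch sample run is an "obvious"
        event when the high-pass residual deviates inward beyond
        ``threshold_sd`` robust noise SDs for at least ``min_width_ms``.
    epoch_len_s, n_per_phase
        Three 5-s epochs per phase, per the standard procedure.
    post_delay_s
        Dead time after drug application before post epochs may start,
        so the wash-in is essentially complete (>=98% at four wash-in
        time constants of the simulator default).
    tail_side, peak_offset_bins
        Side of the histogram carrying the sIPSC tail (negative for
        inward events) and how many bins past the peak toward that side
        remain inside the fit window.
    """

    bin_width_pa: float = 0.5
    threshold_sd: float = 3.0
    min_width_ms: float = 2.0
    detrend_window_s: float = 0.5
    epoch_len_s: float = 5.0
    n_per_phase: int = 3
    post_delay_s: float = 120.0
    tail_side: TailSide = "negative"
    peak_offset_bins: int = 2
    weighted_fit: bool = False


@dataclass(frozen=True)
class Segment:
    start_index: int
    length_samples: int
    phase: Phase
    clean: bool
    event_density: float  # events / s overlapping the window

    @property
    def stop_index(self) -> int:
        return self.start_index + self.length_samples


@dataclass
class EpochSelection:
    segments: list[Segment]
    epoch_len_s: float
    n_per_phase: int

    def for_phase(self, phase: Phase) -> list[Segment]:
        return [s for s in self.segments if s.phase == phase]


@dataclass
class AllPointHistogram:
    """Histogram of every sample in a segment; uniform bins in pA."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_samples: int
    degenerate: bool = False

    @property
    def mode_bin(self) -> int:
        return int(np.argmax(self.counts))

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class GaussianFit:
    mu_pa: float
    sigma_pa: float
    amplitude: float
    fit_window: tuple[int, int]  # [first_bin, last_bin] inclusive
    residual_norm: float
    converged: bool


@dataclass
class TonicResult:
    """Per-cell tonic current quantification."""

    cell_id: str
    i_hold_pre_pa: float
    i_hold_post_pa: float
    tonic_current_pa: float            # magnitude |pre - post|
    tonic_signed_pa: float             # i_post - i_pre (antagonist: > 0)
    current_density_pa_per_pf: float | None
    mode: Literal["antagonist", "agonist"]
    capacitance_pf: float | None = None
    per_segment_mus: dict = field(default_factory=dict)
    group_label: str = ""
    condition: str = ""
    all_clean: bool = True

    def as_row(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "group_label": self.group_label,
            "condition": self.condition,
            "mode": self.mode,
            "i_hold_pre_pa": self.i_hold_pre_pa,
            "i_hold_post_pa": self.i_hold_post_pa,
            "tonic_current_pa": self.tonic_current_pa,
            "tonic_signed_pa": self.tonic_signed_pa,
            "current_density_pa_per_pf": self.current_density_pa_per_pf,
            "capacitance_pf": self.capacitance_pf,
            "n_segments_pre": len(self.per_segment_mus.get("pre", [])),
            "n_segments_post": len(self.per_segment_mus.get("post", [])),
            "all_clean": self.all_clean,
        }


def detect_events(
    trace: CurrentTrace,
    threshold_sd: float = 3.0,
    min_width_ms: float = 2.0,
    detrend_window_s: float = 0.5,
) -> np.ndarray:
    """Locate inward synaptic events as (start, stop) sample intervals.

    The trace is detrended by subtracting a moving-average baseline
    (window ``detrend_window_s``), which removes the holding current and
    the slow drug wash-in ramp. The noise SD of the residual is
    estimated robustly (scaled median absolute deviation) so the events
    themselves do not inflate it; samples deviating inward (negative)
    beyond ``threshold_sd * SD`` for at least ``min_width_ms`` form an
    event interval.

    Returns an integer array of shape (n_events, 2) with half-open
    [start, stop) sample indices.
    """
    fs = trace.sampling_rate_hz
    if trace.duration_s < 1.0:
        raise ValidationError("trace: must be at least 1 s for event detection")
    win = int(round(detrend_window_s * fs)) | 1
    if trace.n_samples <= win:
        raise ValidationError(
            "trace: shorter than the detrending window"
        )
    x = trace.samples
    baseline = ndimage.uniform_filter1d(x, size=win, mode="nearest")
    resid = x - baseline
    mad = np.median(np.abs(resid - np.median(resid)))
    sigma = max(1.4826 * mad, 1e-12)
    below = resid < -threshold_sd * sigma
    if not below.any():
        return np.empty((0, 2), dtype=np.int64)
    # run-length extraction of contiguous True stretches
    d = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if below[0]:
        starts = np.concatenate(([0], starts))
    if below[-1]:
        stops = np.concatenate((stops, [below.size]))
    min_len = max(1, int(round(min_width_ms / 1000.0 * fs)))
    keep = (stops - starts) >= min_len
    return np.stack([starts[keep], stops[keep]], axis=1)


def _window_event_counts(
    starts: np.ndarray, stops: np.ndarray, win_starts: np.ndarray, win_len: int
) -> np.ndarray:
    """Number of event intervals overlapping each candidate window."""
    if starts.size == 0:
        return np.zeros(win_starts.size, dtype=np.int64)
    # event overlaps [i, i+L) iff start < i+L and stop > i
    n_start_before_end = np.searchsorted(starts, win_starts + win_len, side="left")
    n_stop_before = np.searchsorted(stops, win_starts, side="right")
    return n_start_before_end - n_stop_before


def select_epochs(
    trace: CurrentTrace,
    events: np.ndarray,
    epoch_len_s: float = 5.0,
    n_per_phase: int = 3,
    post_delay_s: float = 120.0,
) -> EpochSelection:
    """Choose event-free epochs in each phase, or the least-contaminated.

    Windows are scanned exhaustively at every sample start within each
    phase ([0, t_drug) before the drug; [t_drug + post_delay_s, end)
    after). Event-free windows are preferred and taken earliest-first
    without overlap; when fewer than ``n_per_phase`` event-free windows
    exist, the selection falls back to the lowest-event-density windows
    (ties broken by earlier start), flags them ``clean=False`` and warns.
    """
    if trace.t_drug_s is None:
        raise ValidationError("t_drug_s: required for epoch selection")
    fs = trace.sampling_rate_hz
    L = int(round(epoch_len_s * fs))
    events = np.asarray(events, dtype=np.int64).reshape(-1, 2)
    ev_starts = events[:, 0]
    ev_stops = events[:, 1]

    t_drug_idx = int(round(trace.t_drug_s * fs))
    post_from = int(round((trace.t_drug_s + post_delay_s) * fs))
    phases: list[tuple[Phase, int, int]] = [
        ("pre", 0, t_drug_idx),
        ("post", post_from, trace.n_samples),
    ]

    chosen: list[Segment] = []
    any_dirty = False
    for phase, lo, hi in phases:
        usable = hi - lo
        if usable < n_per_phase * L:
            raise InsufficientDataError(
                f"{phase} phase: {usable / fs:.1f} s usable, "
                f"needs {n_per_phase * epoch_len_s:.1f} s"
            )
        win_starts = np.arange(lo, hi - L + 1, dtype=np.int64)
        counts = _window_event_counts(ev_starts, ev_stops, win_starts, L)
        order = np.lexsort((win_starts, counts))  # by count, then earliest
        picked: list[tuple[int, int]] = []
        taken: list[tuple[int, int]] = []

        def _capacity(intervals: list[tuple[int, int]]) -> int:
            # windows of length L that still fit in the free gaps
            cap, prev = 0, lo
            for b, e in sorted(intervals):
                cap += (b - prev) // L
                prev = max(prev, e)
            return cap + (hi - prev) // L

        for idx in order:
            s = int(win_starts[idx])
            if any(s < e and s + L > b for b, e in taken):
                continue
            # accept only if the remaining epochs can still be placed
            needed = n_per_phase - len(picked) - 1
            if _capacity(taken + [(s, s + L)]) < needed:
                continue
            picked.append((s, int(counts[idx])))
            taken.append((s, s + L))
            if len(picked) == n_per_phase:
                break
        if len(picked) < n_per_phase:
            raise InsufficientDataError(
                f"{phase} phase: cannot place {n_per_phase} non-overlapping epochs"
            )
        picked.sort()
        for s, c in picked:
            clean = c == 0
            any_dirty |= not clean
            chosen.append(
                Segment(
                    start_index=s,
                    length_samples=L,
                    phase=phase,
                    clean=clean,
                    event_density=c / epoch_len_s,
                )
            )
    if any_dirty:
        warnings.warn(
            "fewer event-free epochs than requested; using lowest-density "
            "windows (clean=False)",
            stacklevel=2,
        )
    return EpochSelection(segments=chosen, epoch_len_s=epoch_len_s,
                          n_per_phase=n_per_phase)


def all_point_histogram(
    trace: CurrentTrace | np.ndarray,
    segment: Segment | tuple[int, int] | None = None,
    bin_width_pa: float = 0.5,
) -> AllPointHistogram:
    """All-point histogram of a segment with edges on the pA grid.

    Bin edges are aligned to integer multiples of ``bin_width_pa`` and
    span the segment's range; the counts sum to the segment length. A
    zero-variance segment yields a single-bin histogram flagged
    degenerate.
    """
    if not bin_width_pa > 0:
        raise ValidationError("bin_width_pa: must be > 0")
    x = trace.samples if isinstance(trace, CurrentTrace) else np.asarray(trace)
    if segment is not None:
        if isinstance(segment, Segment):
            x = x[segment.start_index:segment.stop_index]
        else:
            start, length = segment
            x = x[start:start + length]
    if x.size == 0:
        raise ValidationError("segment: empty")
    w = bin_width_pa
    lo = np.floor(x.min() / w) * w
    hi = np.ceil(x.max() / w) * w
    if hi <= x.max():
        hi += w
    if hi <= lo:  # constant segment on a grid point
        hi = lo + w
    edges = lo + w * np.arange(round((hi - lo) / w) + 1)
    counts, _ = np.histogram(x, bins=edges)
    return AllPointHistogram(
        bin_edges=edges,
        counts=counts.astype(np.int64),
        n_samples=int(x.size),
        degenerate=edges.size == 2,
    )


def _gauss(x: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_gaussian_constrained(
    hist: AllPointHistogram,
    tail_side: TailSide = "negative",
    peak_offset_bins: int = 2,
    weighted: bool = False,
) -> GaussianFit:
    """Least-squares Gaussian fit excluding the sIPSC tail.

    The fitted window runs from ``peak_offset_bins`` past the mode bin
    toward the tail side through the far edge of the opposite side: the
    peak and two bins into the tail are kept, deeper tail bins —
    the skewed sIPSC contribution — are excluded. Initial values come
    from the mode bin (mu), the half-width at half-maximum (sigma) and
    the mode count (amplitude). A failed optimization returns
    ``converged=False`` with the initial values rather than garbage.
    """
    if hist.degenerate:
        raise FitError("histogram is degenerate (single bin); cannot fit")
    if tail_side not in ("negative", "positive"):
        raise ValidationError(f"tail_side: unknown side {tail_side!r}")
    mode = hist.mode_bin
    nbins = hist.counts.size
    if tail_side == "negative":
        first, last = max(0, mode - peak_offset_bins), nbins - 1
    else:
        first, last = 0, min(nbins - 1, mode + peak_offset_bins)
    if last - first + 1 < 3:
        raise FitError("fewer than 3 fittable bins in the constrained window")

    centers = hist.centers()[first:last + 1]
    counts = hist.counts[first:last + 1].astype(np.float64)
    w = hist.bin_width

    amp0 = float(hist.counts[mode])
    mu0 = float(hist.centers()[mode])
    half = amp0 / 2.0
    above = np.flatnonzero(hist.counts >= half)
    sigma0 = max(w, (above[-1] - above[0] + 1) * w / 2.355) if above.size else w

    sigma_weights = None
    if weighted:
        sigma_weights = np.sqrt(np.maximum(counts, 1.0))  # Poisson
    try:
        popt, _ = optimize.curve_fit(
            _gauss, centers, counts,
            p0=(amp0, mu0, sigma0),
            sigma=sigma_weights,
            bounds=((0.0, centers[0] - 10 * sigma0, w / 100.0),
                    (np.inf, centers[-1] + 10 * sigma0, np.inf)),
            maxfev=10_000,
        )
        amp, mu, sigma = map(float, popt)
        converged = np.isfinite(mu) and np.isfinite(sigma) and sigma > 0
    except (RuntimeError, ValueError):
        amp, mu, sigma = amp0, mu0, sigma0
        converged = False
    resid = counts - _gauss(centers, amp, mu, sigma)
    return GaussianFit(
        mu_pa=mu,
        sigma_pa=sigma,
        amplitude=amp,
        fit_window=(first, last),
        residual_norm=float(np.linalg.norm(resid)),
        converged=converged,
    )


def holding_current(
    trace: CurrentTrace,
    selection: EpochSelection,
    phase: Phase,
    params: QuantParams = QuantParams(),
) -> tuple[float, list[float]]:
    """Phase holding current: mean of the per-epoch Gaussian peak values.

    Each epoch's all-point histogram is fitted with the constrained
    Gaussian; the fitted means are averaged arithmetically. A
    non-converged fit raises :class:`FitError` carrying the epoch index.
    """
    segments = selection.for_phase(phase)
    if not segments:
        raise ValidationError(f"phase: no segments selected for {phase!r}")
    mus: list[float] = []
    for i, seg in enumerate(segments):
        hist = all_point_histogram(trace, seg, params.bin_width_pa)
        fit = fit_gaussian_constrained(
            hist, params.tail_side, params.peak_offset_bins,
            weighted=params.weighted_fit,
        )
        if not fit.converged:
            raise FitError(
                f"{phase} segment {i}: Gaussian fit did not converge",
                segment_index=i,
            )
        mus.append(fit.mu_pa)
    return float(np.mean(mus)), mus


def tonic_current(
    i_pre: float,
    i_post: float,
    mode: Literal["antagonist", "agonist"],
    capacitance_pf: float | None = None,
    cell_id: str = "",
) -> TonicResult:
    """Tonic current from the pre/post holding currents.

    The magnitude |i_pre - i_post| is the reported tonic current; the
    signed change i_post - i_pre is retained (positive for an
    antagonist unmasking an inward standing current, negative for an
    agonist inducing one). Current density is magnitude / capacitance
    when the capacitance is known.
    """
    if not (np.isfinite(i_pre) and np.isfinite(i_post)):
        raise ValidationError("holding currents: must be finite")
    if mode not in ("antagonist", "agonist"):
        raise ValidationError(f"mode: unknown mode {mode!r}")
    if capacitance_pf is not None and not capacitance_pf > 0:
        raise ValidationError("capacitance_pf: must be > 0 when given")
    signed = i_post - i_pre
    magnitude = abs(signed)
    density = None if capacitance_pf is None else magnitude / capacitance_pf
    return TonicResult(
        cell_id=cell_id,
        i_hold_pre_pa=i_pre,
        i_hold_post_pa=i_post,
        tonic_current_pa=magnitude,
        tonic_signed_pa=signed,
        current_density_pa_per_pf=density,
        mode=mode,
        capacitance_pf=capacitance_pf,
    )


def quantify_trace(
    trace: CurrentTrace,
    mode: Literal["antagonist", "agonist"],
    params: QuantParams = QuantParams(),
) -> TonicResult:
    """Full per-cell pipeline: screen events, select epochs, fit, subtract."""
    events = detect_events(
        trace, params.threshold_sd, params.min_width_ms, params.detrend_window_s
    )
    selection = select_epochs(
        trace, events, params.epoch_len_s, params.n_per_phase, params.post_delay_s
    )
    i_pre, mus_pre = holding_current(trace, selection, "pre", params)
    i_post, mus_post = holding_current(trace, selection, "post", params)
    result = tonic_current(
        i_pre, i_post, mode, trace.capacitance_pf, trace.cell_id
    )
    result.per_segment_mus = {"pre": mus_pre, "post": mus_post}
    result.group_label = trace.group_label
    result.condition = trace.condition
    result.all_clean = all(s.clean for s in selection.segments)
    return result
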