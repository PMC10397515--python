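"""Synthetic voltage-clamp traces with known tonic shifts.

The simulator emulates a whole-cell recording of a hippocampal
interneuron held at -70 mV with a high-Cl internal solution: a stationary
holding current, Gaussian recording noise low-pass filtered as by a 4 kHz
hardware filter, spontaneous IPSCs arriving as a Poisson process with
lognormal amplitudes and bi-exponential (fast rise / slower decay)
kinetics, and a drug-induced sustained baseline shift that washes in
exponentially. Inward currents are negative throughout; sIPSCs are
inward deflections. The realized event times/amplitudes and the true
pre/post holding currents are returned as ground truth so downstream
estimators can be scored exactly.

Two pharmacological conditions are covered by the same machinery:

* antagonist (SR95531): ``tonic_shift_pa > 0`` (block of a standing
  inward current makes the holding current less negative) and
  ``post_drug_event_scale = 0`` (sIPSCs abolished);
* agonist (THIP): ``tonic_shift_pa < 0`` (an additional inward tonic
  current) with events unchanged.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _signal

from .errors import ValidationError
from .traceio import CurrentTrace, StepResponse

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_trace",
    "simulate_cohort",
    "simulate_step_response",
    "ipsc_kernel",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated recording.

    Defaults describe a plausible hippocampal interneuron recording; the
    sampling rate and filter corner follow the emulated acquisition chain
    (10 kHz sampling, 4 kHz low-pass). Event kinetics default to fast
    GABA-A synaptic kinetics (1 ms rise, 10 ms decay).
    """

    duration_s: float = 180.0
    sampling_rate_hz: float = 10_000.0
    i_hold_pa: float = -50.0          # inward-negative holding current
    noise_sd_pa: float = 3.0          # white-noise SD before the low-pass
    event_rate_hz: float = 2.0        # Poisson sIPSC arrival rate
    event_amp_mean_pa: float = 30.0   # mean peak magnitude (applied negative)
    event_amp_cv: float = 0.5         # lognormal coefficient of variation
    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 10.0
    tonic_shift_pa: float = 0.0       # signed steady-state shift after drug
    t_drug_s: float | None = None
    washin_tau_s: float = 30.0        # exponential wash-in time constant
    post_drug_event_scale: float = 1.0
    filter_cutoff_hz: float = 4000.0
    v_hold_mv: float = -70.0
    capacitance_pf: float | None = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("duration_s", self.duration_s > 0),
            ("sampling_rate_hz", self.sampling_rate_hz > 0),
            ("noise_sd_pa", self.noise_sd_pa >= 0),
            ("event_rate_hz", self.event_rate_hz >= 0),
            ("event_amp_mean_pa", self.event_amp_mean_pa > 0),
            ("event_amp_cv", self.event_amp_cv >= 0),
            ("tau_rise_ms", self.tau_rise_ms > 0),
            ("tau_decay_ms", self.tau_decay_ms > self.tau_rise_ms),
            ("washin_tau_s", self.washin_tau_s >= 0),
            ("post_drug_event_scale", self.post_drug_event_scale >= 0),
            ("filter_cutoff_hz", self.filter_cutoff_hz > 0),
            ("capacitance_pf",
             self.capacitance_pf is None or self.capacitance_pf > 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ValidationError(f"{name}: invalid value {getattr(self, name)!r}")
        if self.t_drug_s is not None and not (0 <= self.t_drug_s <= self.duration_s):
            raise ValidationError(
                f"t_drug_s: must lie in [0, duration_s], got {self.t_drug_s!r}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


@dataclass
class GroundTruth:
    """The realized truth behind one simulated trace."""

    event_times_s: np.ndarray
    event_amps_pa: np.ndarray
    i_hold_pre_pa: float
    i_hold_post_pa: float
    tonic_shift_pa: float
    capacitance_pf: float | None

    def __post_init__(self) -> None:
        self.event_times_s = np.asarray(self.event_times_s, dtype=np.float64)
        self.event_amps_pa = np.asarray(self.event_amps_pa, dtype=np.float64)
        if self.event_times_s.size != self.event_amps_pa.size:
            raise ValidationError("event lists: times and amplitudes differ in length")


def ipsc_kernel(
    tau_rise_ms: float,
    tau_decay_ms: float,
    sampling_rate_hz: float,
    n_decay_constants: float = 10.0,
) -> np.ndarray:
    """Difference-of-exponentials sIPSC kernel, peak-normalized to 1.

    k(t) = c * (exp(-t/tau_d) - exp(-t/tau_r)) with c chosen so
    max k = 1; the kernel is truncated after ``n_decay_constants`` decay
    time constants. Returned positive; the simulator applies it with a
    negative (inward) sign.
    """
    if not tau_decay_ms > tau_rise_ms > 0:
        raise ValidationError("tau_decay_ms must exceed tau_rise_ms > 0")
    tr = tau_rise_ms / 1000.0
    td = tau_decay_ms / 1000.0
    n = max(2, int(round(n_decay_constants * td * sampling_rate_hz)))
    t = np.arange(n) / sampling_rate_hz
    k = np.exp(-t / td) - np.exp(-t / tr)
    # analytic peak time: t* = ln(td/tr) * tr*td/(td-tr)
    t_peak = np.log(td / tr) * tr * td / (td - tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    return k / peak


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and CV."""
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _washin_profile(config: SimConfig, t: np.ndarray) -> np.ndarray:
    """Fractional wash-in (0 before drug, ->1 at steady state)."""
    frac = np.zeros(t.size, dtype=np.float64)
    if config.t_drug_s is None or config.tonic_shift_pa == 0.0:
        return frac
    i0 = int(np.searchsorted(t, config.t_drug_s))
    if config.washin_tau_s == 0:
        frac[i0:] = 1.0
    else:
        frac[i0:] = -np.expm1(
            -(t[i0:] - config.t_drug_s) / config.washin_tau_s
        )
    return frac


def _draw_events(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson event times over the trace, with the post-drug rate scaled."""
    t_switch = config.t_drug_s if config.t_drug_s is not None else config.duration_s
    segments = [
        (0.0, t_switch, config.event_rate_hz),
        (t_switch, config.duration_s,
         config.event_rate_hz * config.post_drug_event_scale),
    ]
    times = []
    for lo, hi, rate in segments:
        span = hi - lo
        if span <= 0 or rate <= 0:
            continue
        n = rng.poisson(rate * span)
        times.append(lo + rng.random(n) * span)
    times = np.sort(np.concatenate(times)) if times else np.empty(0)
    mu, sigma = _lognormal_params(config.event_amp_mean_pa, config.event_amp_cv)
    if config.event_amp_cv == 0:
        amps = np.full(times.size, config.event_amp_mean_pa)
    else:
        amps = rng.lognormal(mu, sigma, size=times.size)
    return times, amps


def _filtered_noise(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Gaussian white noise through a 2nd-order Butterworth low-pass.

    The low-pass stands in for the acquisition chain's 4 kHz Bessel
    filter; ``noise_sd_pa`` is the SD of the white noise before
    filtering. A cutoff at or above Nyquist disables the filter.
    """
    white = rng.normal(0.0, config.noise_sd_pa, size=n)
    nyq = config.sampling_rate_hz / 2.0
    if config.filter_cutoff_hz >= nyq:
        return white
    sos = _signal.butter(2, config.filter_cutoff_hz / nyq, output="sos")
    return _signal.sosfilt(sos, white)


def simulate_trace(config: SimConfig) -> tuple[CurrentTrace, GroundTruth]:
    """Simulate one voltage-clamp current trace with ground truth.

    The trace is the sum of the holding current, the washed-in tonic
    shift, the superimposed inward event kernels, and filtered Gaussian
    noise. Identical config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    fs = config.sampling_rate_hz
    t = np.arange(n) / fs

    trace = np.full(n, config.i_hold_pa, dtype=np.float64)
    trace += config.tonic_shift_pa * _washin_profile(config, t)

    times, amps = _draw_events(config, rng)
    if times.size:
        kernel = ipsc_kernel(config.tau_rise_ms, config.tau_decay_ms, fs)
        for t0, amp in zip(times, amps):
            i0 = int(round(t0 * fs))
            if i0 >= n:
                continue
            seg = min(kernel.size, n - i0)
            trace[i0:i0 + seg] -= amp * kernel[:seg]

    if config.noise_sd_pa > 0:
        trace += _filtered_noise(config, n, rng)

    ct = CurrentTrace(
        samples=trace,
        sampling_rate_hz=fs,
        t_drug_s=config.t_drug_s,
        capacitance_pf=config.capacitance_pf,
    )
    gt = GroundTruth(
        event_times_s=times,
        event_amps_pa=amps,
        i_hold_pre_pa=config.i_hold_pa,
        i_hold_post_pa=config.i_hold_pa + config.tonic_shift_pa,
        tonic_shift_pa=config.tonic_shift_pa,
        capacitance_pf=config.capacitance_pf,
    )
    return ct, gt


# Fields whose magnitude is sign-constrained: cohort draws preserve the
# template's sign and disperse the magnitude.
_MAGNITUDE_FIELDS = {
    "i_hold_pa", "noise_sd_pa", "event_rate_hz", "event_amp_mean_pa",
    "tonic_shift_pa", "capacitance_pf",
}


def _draw_field(
    template_value: float, sd: float, family: str, rng: np.random.Generator,
    magnitude: bool,
) -> float:
    if sd == 0:
        return template_value
    if family == "normal":
        value = rng.normal(template_value, sd)
        if magnitude and template_value != 0 and np.sign(value) != np.sign(template_value):
            value = 0.0 if template_value == 0 else np.sign(template_value) * 1e-9
        return float(value)
    if family == "lognormal":
        mag = abs(template_value)
        if mag == 0:
            raise ValidationError(
                "between_cell_sd: lognormal dispersion needs a nonzero template value"
            )
        mu, sigma = _lognormal_params(mag, sd / mag)
        return float(np.sign(template_value) * rng.lognormal(mu, sigma))
    raise ValidationError(f"family: unknown dispersion family {family!r}")


def simulate_cohort(
    n_cells: int,
    config_template: SimConfig,
    between_cell_sd: Mapping[str, float] | None = None,
    seed: int = 0,
    family: str = "normal",
    cell_id_prefix: str = "cell",
) -> list[tuple[CurrentTrace, GroundTruth]]:
    """Simulate ``n_cells`` independent recordings around a template.

    ``between_cell_sd`` maps SimConfig field names to between-cell
    standard deviations; listed fields are redrawn per cell around the
    template value (``family="normal"``, clipped at sign constraints, or
    ``family="lognormal"``, moment-matched on the magnitude with the
    template's sign restored — the natural choice for strictly signed
    quantities such as tonic shifts). Per-cell seeds are derived from
    ``seed`` so the cohort is reproducible as a whole.
    """
    if n_cells < 1:
        raise ValidationError("n_cells: must be >= 1")
    between_cell_sd = dict(between_cell_sd or {})
    valid = {f.name for f in dataclasses.fields(SimConfig)}
    for name, sd in between_cell_sd.items():
        if name not in valid:
            raise ValidationError(f"between_cell_sd: unknown field {name!r}")
        if sd < 0:
            raise ValidationError(f"between_cell_sd[{name!r}]: must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_cells):
        overrides: dict = {}
        for name, sd in between_cell_sd.items():
            overrides[name] = _draw_field(
                getattr(config_template, name), sd, family, rng,
                magnitude=name in _MAGNITUDE_FIELDS,
            )
        overrides["seed"] = int(rng.integers(0, 2**31 - 1))
        cfg = replace(config_template, **overrides)
        trace, truth = simulate_trace(cfg)
        trace.cell_id = f"{cell_id_prefix}{i:02d}"
        out.append((trace, truth))
    return out


def simulate_step_response(
    r_input_mohm: float,
    tau_membrane_ms: float,
    i_step_pa: float,
    config: SimConfig,
    pulse_start_s: float = 0.2,
    pulse_duration_s: float = 1.0,
    noise_sd_mv: float = 0.0,
) -> StepResponse:
    """Simulate an RC voltage response to a square current step.

    The membrane is a single RC compartment: during the pulse the
    voltage relaxes exponentially toward baseline + i_step * R (with
    1 pA x 1 MOhm = 1e-3 mV), and back to baseline afterwards. The
    protocol default is the 1-s, -10 pA hyperpolarizing pulse; voltage
    noise is white with SD ``noise_sd_mv``.
    """
    if not r_input_mohm > 0:
        raise ValidationError("r_input_mohm: must be > 0")
    if not tau_membrane_ms > 0:
        raise ValidationError("tau_membrane_ms: must be > 0")
    if pulse_start_s + pulse_duration_s > config.duration_s:
        raise ValidationError("pulse window: pulse does not fit within the trace")
    fs = config.sampling_rate_hz
    n = config.n_samples
    t = np.arange(n) / fs
    tau = tau_membrane_ms / 1000.0
    dv = i_step_pa * r_input_mohm * 1e-3  # pA * MOhm = 1e-3 mV
    v = np.full(n, config.v_hold_mv, dtype=np.float64)
    during = (t >= pulse_start_s) & (t < pulse_start_s + pulse_duration_s)
    v[during] += dv * -np.expm1(-(t[during] - pulse_start_s) / tau)
    after = t >= pulse_start_s + pulse_duration_s
    if after.any():
        v_end = dv * -np.expm1(-pulse_duration_s / tau)
        v[after] += v_end * np.exp(
            -(t[after] - (pulse_start_s + pulse_duration_s)) / tau
        )
    if noise_sd_mv > 0:
        rng = np.random.default_rng(config.seed)
        v += rng.normal(0.0, noise_sd_mv, size=n)
    return StepResponse(
        voltage_samples=v,
        sampling_rate_hz=fs,
        i_step_pa=i_step_pa,
        pulse_start_s=pulse_start_s,
        pulse_duration_s=pulse_duration_s,
    )
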