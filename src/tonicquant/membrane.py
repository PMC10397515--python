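"""Passive membrane properties from current-step responses.

Input resistance follows the steady-state protocol: the voltage
deflection is the mean of the last 100 ms of a 1-s current pulse minus
the mean of the 100 ms immediately preceding pulse onset, divided by the
injected current. Unit algebra: with dV in mV and dI in pA,

    R = dV / dI  [mV/pA] = dV/dI * 1e-3 V / 1e-12 A = dV/dI * 1e9 Ohm
      = dV/dI * 1000 MOhm,

so a -1.0 mV response to a -10 pA pulse is 100 MOhm.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .traceio import StepResponse

__all__ = ["PassiveProps", "input_resistance"]

_WINDOW_S = 0.1  # 100-ms averaging windows for baseline and steady state


@dataclass(frozen=True)
class PassiveProps:
    r_input_mohm: float
    v_baseline_mv: float
    v_steady_mv: float
    i_step_pa: float


def input_resistance(step: StepResponse) -> PassiveProps:
    """Input resistance from a square-pulse voltage response.

    Baseline is the mean of the 100 ms immediately before pulse onset;
    steady state is the mean of the last 100 ms of the pulse. Requires
    at least 100 ms of pre-pulse baseline and a pulse longer than
    100 ms; the pulse current must be nonzero.
    """
    fs = step.sampling_rate_hz
    nwin = int(round(_WINDOW_S * fs))
    if nwin < 1:
        raise ValidationError("sampling_rate_hz: too low for a 100-ms window")
    if step.i_step_pa == 0:
        raise ValidationError("i_step_pa: must be nonzero")
    on = int(round(step.pulse_start_s * fs))
    off = int(round((step.pulse_start_s + step.pulse_duration_s) * fs))
    if on < nwin:
        raise ValidationError(
            "pulse_start_s: needs >= 100 ms of pre-pulse baseline"
        )
    if off - on < nwin:
        raise ValidationError("pulse_duration_s: pulse shorter than 100 ms")
    v = step.voltage_samples
    v_base = float(np.mean(v[on - nwin:on]))
    v_steady = float(np.mean(v[off - nwin:off]))
    r = (v_steady - v_base) / step.i_step_pa * 1000.0  # mV/pA -> MOhm
    return PassiveProps(
        r_input_mohm=r,
        v_baseline_mv=v_base,
        v_steady_mv=v_steady,
        i_step_pa=step.i_step_pa,
    )
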