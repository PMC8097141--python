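"""Quantification of the three cellular "building block" features.

Each protocol starts the cell from rest, (v_r, u=0), and applies current
steps:

* **Rheobase (Rheo)** — constant currents from -25 to 25 pA in 0.5 pA
  increments; the smallest current eliciting a spike within the first
  500 ms is the rheobase.
* **Post-inhibitory rebound (PIR)** — 1 s hyperpolarizing steps from 0
  to -25 pA in 0.5 pA increments, released to zero current; the first
  step whose release elicits a spike (absent at the previous, less
  negative step) is the PIR value.
* **Spike-frequency adaptation (SFA)** — 1 s steps from 0 to 98 pA in
  2 pA increments; per step, the initial frequency is the inverse first
  interspike interval and the final frequency the inverse last one.
  Straight lines are fitted to both frequency-vs-current relations and
  SFA is the difference of their slopes (initial minus final, Hz/pA):
  the larger the value, the stronger the adaptation.

Sweep resolutions and ranges are fixed by the protocol definitions;
auxiliary choices the protocols leave open (rebound detection window,
minimum spike count for the f-I fits) are exposed as keyword arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import _first_spike_step, integrate_single
from .cell import DEFAULT_DT, CellParams

__all__ = [
    "FeatureTriplet",
    "FICurveFit",
    "quantify_rheobase",
    "quantify_pir",
    "quantify_sfa",
    "quantify_features",
    "RHEO_SWEEP_PA",
    "PIR_SWEEP_PA",
    "SFA_SWEEP_PA",
]

#: Rheobase sweep grid (pA): -25 to 25 in 0.5 pA increments, ascending.
RHEO_SWEEP_PA = np.round(np.arange(-25.0, 25.0 + 0.25, 0.5), 1)
#: Hyperpolarizing step grid (pA): 0 down to -25 in 0.5 pA increments.
PIR_SWEEP_PA = np.round(-np.arange(0.0, 25.0 + 0.25, 0.5), 1)
#: f-I step grid (pA): 0 to 98 inclusive in 2 pA increments.
SFA_SWEEP_PA = np.arange(0.0, 98.0 + 1.0, 2.0)


@dataclass(frozen=True)
class FeatureTriplet:
    """Quantified (SFA, Rheo, PIR) phenotype of one model cell.

    ``None`` encodes "no qualifying current found in the sweep range"
    (or, for SFA, too few spiking steps to fit the two lines).
    """

    sfa: float | None
    rheo: float | None
    pir: float | None

    def is_complete(self) -> bool:
        return None not in (self.sfa, self.rheo, self.pir)

    def as_tuple(self) -> tuple:
        return (self.sfa, self.rheo, self.pir)


@dataclass(frozen=True)
class FICurveFit:
    """f-I data and line fits underlying one SFA quantification.

    ``currents`` holds the qualifying step amplitudes (pA); the two
    frequency arrays (Hz) are aligned with it.  ``sfa`` is
    ``init_slope - final_slope``; ``None`` with ``reason`` set when
    fewer than two steps qualify.
    """

    currents: np.ndarray
    init_freq: np.ndarray
    final_freq: np.ndarray
    init_slope: float | None
    final_slope: float | None
    sfa: float | None
    reason: str | None = None


def _check(params: CellParams) -> None:
    if not isinstance(params, CellParams):
        raise TypeError("params must be a CellParams")


def quantify_rheobase(params: CellParams, *, dt: float = DEFAULT_DT,
                      window_ms: float = 500.0) -> float | None:
    """Minimal sweep current (pA) eliciting a spike within ``window_ms``.

    Sweeps ascending from -25 pA so the first qualifying value is the
    minimal one; returns ``None`` if no sweep current elicits a spike.
    """
    _check(params)
    n_steps = int(round(window_ms / dt))
    for I in RHEO_SWEEP_PA:
        step = _first_spike_step(
            params.C_m, params.v_r, params.v_t, params.v_peak,
            params.a, params.b, params.c, params.d,
            params.k_low, params.k_high,
            params.v_r, 0.0, I, dt, n_steps)
        if step > 0:
            return float(I)
    return None


def quantify_pir(params: CellParams, *, dt: float = DEFAULT_DT,
                 step_ms: float = 1000.0,
                 rebound_window_ms: float = 500.0) -> float | None:
    """First hyperpolarizing step (pA) whose release elicits a rebound spike.

    Each 1 s step starts from rest and is released to zero current; a
    rebound spike is one occurring within ``rebound_window_ms`` after
    step offset.  The value returned is the first (least negative) step
    at which a rebound spike appears while the previous step showed
    none; ``None`` if no step in the sweep elicits one.
    """
    _check(params)
    n_step = int(round(step_ms / dt))
    n_post = int(round(rebound_window_ms / dt))
    I = np.empty(n_step + n_post)
    prev_rebound = False
    for amp in PIR_SWEEP_PA:
        I[:n_step] = amp
        I[n_step:] = 0.0
        _, _, spikes = integrate_single(
            params.C_m, params.v_r, params.v_t, params.v_peak,
            params.a, params.b, params.c, params.d,
            params.k_low, params.k_high,
            params.v_r, 0.0, I, dt)
        rebound = bool(np.any(spikes > step_ms))
        if rebound and not prev_rebound and amp < 0.0:
            return float(amp)
        prev_rebound = rebound
    return None


def quantify_sfa(params: CellParams, *, dt: float = DEFAULT_DT,
                 step_ms: float = 1000.0,
                 min_spikes: int = 3) -> FICurveFit:
    """Fit the initial and final f-I lines and return their slope difference.

    Only steps eliciting at least ``min_spikes`` spikes contribute (with
    exactly two spikes the initial and final interspike intervals
    coincide and carry no adaptation contrast); both lines are fitted
    over the same qualifying set so the slopes are comparable.
    """
    _check(params)
    n_steps = int(round(step_ms / dt))
    I = np.empty(n_steps)
    cur, fi, ff = [], [], []
    for amp in SFA_SWEEP_PA:
        I[:] = amp
        _, _, spikes = integrate_single(
            params.C_m, params.v_r, params.v_t, params.v_peak,
            params.a, params.b, params.c, params.d,
            params.k_low, params.k_high,
            params.v_r, 0.0, I, dt)
        if len(spikes) < min_spikes:
            continue
        cur.append(amp)
        fi.append(1000.0 / (spikes[1] - spikes[0]))
        ff.append(1000.0 / (spikes[-1] - spikes[-2]))
    cur = np.asarray(cur)
    fi = np.asarray(fi)
    ff = np.asarray(ff)
    if len(cur) < 2:
        return FICurveFit(cur, fi, ff, None, None, None,
                          reason="fewer than 2 qualifying currents")
    init_slope = float(np.polyfit(cur, fi, 1)[0])
    final_slope = float(np.polyfit(cur, ff, 1)[0])
    return FICurveFit(cur, fi, ff, init_slope, final_slope,
                      float(init_slope - final_slope))


def quantify_features(params: CellParams, *,
                      dt: float = DEFAULT_DT) -> FeatureTriplet:
    """Run all three protocols and return the (SFA, Rheo, PIR) triplet."""
    sfa = quantify_sfa(params, dt=dt).sfa
    rheo = quantify_rheobase(params, dt=dt)
    pir = quantify_pir(params, dt=dt)
    return FeatureTriplet(sfa=sfa, rheo=rheo, pir=pir)


def feature_row(model_id, params: CellParams,
                triplet: FeatureTriplet) -> dict:
    """One phenotyping-report row (None serializes to an empty CSV field)."""
    return {
        "model_id": model_id,
        "a": params.a, "b": params.b, "d": params.d, "k_low": params.k_low,
        "sfa": triplet.sfa, "rheo": triplet.rheo, "pir": triplet.pir,
    }
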