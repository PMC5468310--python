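"""Voltage-dependent gating kinetics.

Gates are described declaratively (in the channel parameter file) by a small
algebra of rate/steady-state/time-constant forms common to Hodgkin-Huxley
style hippocampal models:

rate forms (ms^-1):
  trap:      a*(v - vhalf) / (1 - exp(-(v - vhalf)/k))   (linoid, opening)
  trap_neg:  a*(vhalf - v) / (1 - exp((v - vhalf)/k))    (linoid, closing)
  exp:       a*exp((v - vhalf)/k)

steady-state forms (dimensionless, in [0, 1]):
  boltzmann:   1 / (1 + exp((v - vhalf)/k))
  bg:          1 / (1 + exp(zeta*c*(v - vhalf)))         (thermodynamic form,
               c = F/(R*T) per mV; optional voltage-dependent zeta)
  rate_ratio:  alpha / (alpha + beta)

time-constant forms (ms, floored at ``min``):
  inverse_rate_sum:  1 / (q*(alpha + beta))
  bg:                beta_bg / (a0*(1 + alpha_bg))
  linear:            slope*(v - v0)
  constant:          value

All evaluators are vectorized over the voltage array; the solver consumes
them through lookup tables on a fine voltage grid.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .errors import ParameterError

FARADAY = 9.648e4      # C/mol
GAS_CONSTANT = 8.315   # J/(mol K)


def thermo_slope(temperature_c: float) -> float:
    """F/(R*T) in 1/mV."""
    return 1e-3 * FARADAY / (GAS_CONSTANT * (273.16 + temperature_c))


def _trap(v: np.ndarray, a: float, vhalf: float, k: float) -> np.ndarray:
    """a*(v-vhalf)/(1-exp(-(v-vhalf)/k)); continuous (-> a*k) at v = vhalf."""
    x = (v - vhalf) / k
    with np.errstate(over="ignore"):
        den = -np.expm1(-x)
    out = np.where(np.abs(x) < 1e-6, a * k * (1.0 + x / 2.0),
                   a * (v - vhalf) / np.where(den == 0, 1.0, den))
    return out


def _rate(v: np.ndarray, spec: Mapping, c: float) -> np.ndarray:
    form = spec["form"]
    if form == "trap":
        return _trap(v, spec["a"], spec["vhalf"], spec["k"])
    if form == "trap_neg":
        return _trap(-v, spec["a"], -spec["vhalf"], spec["k"])
    if form == "exp":
        return spec["a"] * np.exp((v - spec["vhalf"]) / spec["k"])
    raise ParameterError(f"unknown rate form {form!r}")


def _zeta_eff(v: np.ndarray, spec: Mapping) -> np.ndarray:
    zeta = np.full_like(v, float(spec["zeta"]))
    mod = spec.get("zeta_mod")
    if mod:
        zeta = zeta + mod["pw"] / (1.0 + np.exp((v - mod["tq"]) / mod["qq"]))
    return zeta


def _bg_alpha(v: np.ndarray, spec: Mapping, c: float) -> np.ndarray:
    return np.exp(_zeta_eff(v, spec) * c * (v - spec["vhalf"]))


@dataclass(frozen=True)
class GateSpec:
    """One gating variable: steady state, time constant, exponent."""

    name: str
    exponent: int
    inf: Mapping
    tau: Mapping
    alpha: Optional[Mapping] = None
    beta: Optional[Mapping] = None

    def __post_init__(self):
        if self.exponent < 1:
            raise ParameterError(f"gate {self.name!r}: exponent must be >= 1")

    def evaluate(self, v: np.ndarray, temperature_c: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (inf, tau) over the voltage array."""
        v = np.asarray(v, dtype=float)
        c = thermo_slope(temperature_c)
        alpha = _rate(v, self.alpha, c) if self.alpha else None
        beta = _rate(v, self.beta, c) if self.beta else None

        iform = self.inf["form"]
        if iform == "boltzmann":
            inf = 1.0 / (1.0 + np.exp((v - self.inf["vhalf"]) / self.inf["k"]))
        elif iform == "bg":
            inf = 1.0 / (1.0 + _bg_alpha(v, self.inf, c))
        elif iform == "rate_ratio":
            if alpha is None or beta is None:
                raise ParameterError(f"gate {self.name!r}: rate_ratio needs alpha and beta")
            inf = alpha / (alpha + beta)
        else:
            raise ParameterError(f"unknown inf form {iform!r}")

        tform = self.tau["form"]
        floor = float(self.tau.get("min", 0.0))
        if tform == "inverse_rate_sum":
            if alpha is None or beta is None:
                raise ParameterError(f"gate {self.name!r}: inverse_rate_sum needs rates")
            q = float(self.tau.get("q", 1.0))
            tau = 1.0 / (q * (alpha + beta))
        elif tform == "bg":
            a = _bg_alpha(v, self.tau, c)
            b = np.exp(_zeta_eff(v, self.tau) * float(self.tau["gm"]) * c
                       * (v - self.tau["vhalf"]))
            tau = b / (float(self.tau["a0"]) * (1.0 + a))
        elif tform == "linear":
            tau = self.tau["slope"] * (v - self.tau["v0"])
        elif tform == "constant":
            tau = np.full_like(v, float(self.tau["value"]))
        else:
            raise ParameterError(f"unknown tau form {tform!r}")
        tau = np.maximum(tau, floor if floor > 0 else np.finfo(float).tiny)
        if np.any(~np.isfinite(inf)) or np.any(~np.isfinite(tau)):
            raise ParameterError(f"gate {self.name!r}: non-finite kinetics")
        if np.any(inf < -1e-12) or np.any(inf > 1 + 1e-12):
            raise ParameterError(f"gate {self.name!r}: steady state outside [0, 1]")
        if np.any(tau <= 0):
            raise ParameterError(f"gate {self.name!r}: non-positive time constant")
        return np.clip(inf, 0.0, 1.0), tau

    @classmethod
    def from_dict(cls, d: Mapping) -> "GateSpec":
        return cls(name=d["name"], exponent=int(d.get("exponent", 1)),
                   inf=d["inf"], tau=d["tau"],
                   alpha=d.get("alpha"), beta=d.get("beta"))


#: default voltage grid for kinetics tables (mV)
TABLE_V_MIN, TABLE_V_MAX, TABLE_DV = -150.0, 100.0, 0.05


def table_grid() -> np.ndarray:
    n = int(round((TABLE_V_MAX - TABLE_V_MIN) / TABLE_DV)) + 1
    return TABLE_V_MIN + TABLE_DV * np.arange(n)
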