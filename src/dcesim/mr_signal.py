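"""MR signal <-> T1 <-> gadolinium concentration conversion.

Implements the signal chain used to turn dynamic ROI signal series into
concentration curves: spoiled gradient-echo (SPGR) signal models for the
linear-ordered arterial readout and the saturation-prepared, centric-ordered
tissue readout; numerical inversion of signal to T1; the fast-exchange
relaxivity relation ``[Gd] = (1/r) (1/T1 - 1/T1_0)``; proton-density
normalization; and hematocrit correction of whole-blood concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AcquisitionSettings",
    "RelaxationState",
    "AIF_SETTINGS",
    "TISSUE_SETTINGS",
    "PD_SETTINGS",
    "DEFAULT_RELAXIVITY",
    "DEFAULT_HEMATOCRIT",
    "InversionRangeError",
    "spgr_signal",
    "signal_to_t1",
    "gd_concentration",
    "t1_from_concentration",
    "hematocrit_correct",
    "pd_normalize",
    "estimate_m0",
    "signal_series_to_concentration",
]

DEFAULT_RELAXIVITY = 4.2   # gadolinium relaxivity r1 (1/s/mM) at 3 T
DEFAULT_HEMATOCRIT = 0.45


@dataclass(frozen=True)
class AcquisitionSettings:
    """Readout settings of one SPGR acquisition mode.

    ``ordering`` selects the signal law: a ``linear`` readout (or zero
    ``sat_delay_ms``) uses the SPGR steady state; a ``centric`` readout with
    a saturation delay tau uses saturation recovery, since the center of
    k-space is acquired first and its signal is set by the recovery since
    the preceding saturation pulse.
    """

    tr_ms: float = 10.0
    te_ms: float = 4.0
    flip_deg: float = 15.0
    sat_delay_ms: float = 0.0
    tfe_factor: int = 80
    ordering: str = "linear"

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if not (0.0 < self.flip_deg < 90.0):
            raise ValueError("flip_deg must lie in (0, 90)")
        if self.sat_delay_ms < 0:
            raise ValueError("sat_delay_ms must be non-negative")
        if self.tfe_factor < 1:
            raise ValueError("tfe_factor must be at least 1")
        if self.ordering not in ("linear", "centric"):
            raise ValueError("ordering must be 'linear' or 'centric'")


# Dynamic protocol defaults: fast low-flip linear readout for the arterial
# slice, saturation-prepared centric readout for the tissue slice, and a
# long-TR low-flip proton-density reference.
AIF_SETTINGS = AcquisitionSettings(tr_ms=10.0, te_ms=4.0, flip_deg=15.0,
                                   sat_delay_ms=0.0, ordering="linear")
TISSUE_SETTINGS = AcquisitionSettings(tr_ms=10.0, te_ms=4.0, flip_deg=25.0,
                                      sat_delay_ms=800.0, ordering="centric")
PD_SETTINGS = AcquisitionSettings(tr_ms=300.0, te_ms=2.3, flip_deg=4.0,
                                  sat_delay_ms=0.0, ordering="linear")


@dataclass(frozen=True)
class RelaxationState:
    """Longitudinal relaxation state of one ROI or vial.

    ``t1`` and ``t1_0`` are the current and pre-contrast T1 (seconds);
    ``m0`` is the equilibrium signal scale in arbitrary units.
    """

    t1: float
    t1_0: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t1_0 <= 0:
            raise ValueError("t1 and t1_0 must be positive")


class InversionRangeError(ValueError):
    """Signal lies outside the range attainable by the forward model."""

    def __init__(self, signal: float, lo: float, hi: float):
        self.attainable_range = (lo, hi)
        super().__init__(
            f"signal {signal:g} outside attainable range [{lo:g}, {hi:g}]")


def _signal(t1_s, m0, settings: AcquisitionSettings):
    """Vectorized signal law for the given settings (T1 in seconds)."""
    t1_s = np.asarray(t1_s, dtype=float)
    alpha = math.radians(settings.flip_deg)
    if settings.ordering == "centric" and settings.sat_delay_ms > 0:
        tau_s = settings.sat_delay_ms / 1000.0
        return m0 * math.sin(alpha) * -np.expm1(-tau_s / t1_s)
    e = np.exp(-settings.tr_ms / 1000.0 / t1_s)
    return m0 * math.sin(alpha) * (1.0 - e) / (1.0 - math.cos(alpha) * e)


def spgr_signal(state: RelaxationState, settings: AcquisitionSettings) -> float:
    """Signal (a.u.) of one readout for the given relaxation state.

    Strictly decreasing in T1 for moderate flip angles, which is what makes
    the numeric inversion in :func:`signal_to_t1` well posed.
    """
    return float(_signal(state.t1, state.m0, settings))


def signal_to_t1(signal: float, m0: float, settings: AcquisitionSettings,
                 bracket: tuple[float, float] = (0.01, 10.0)) -> float:
    """Invert the signal law to T1 (seconds) by bracketed root finding.

    Raises :class:`InversionRangeError` when the signal is not attainable
    for any T1 in ``bracket``.
    """
    lo_t1, hi_t1 = bracket
    s_hi = float(_signal(lo_t1, m0, settings))   # short T1 -> bright
    s_lo = float(_signal(hi_t1, m0, settings))   # long T1 -> dark
    if not (s_lo <= signal <= s_hi):
        raise InversionRangeError(signal, s_lo, s_hi)
    f = lambda t1: float(_signal(t1, m0, settings)) - signal
    return float(brentq(f, lo_t1, hi_t1, xtol=1e-12, rtol=1e-14))


def gd_concentration(t1: float, t1_0: float,
                     relaxivity: float = DEFAULT_RELAXIVITY) -> float:
    """Gadolinium concentration (mM) from current and baseline T1 (s)."""
    if t1 <= 0 or t1_0 <= 0 or relaxivity <= 0:
        raise ValueError("t1, t1_0 and relaxivity must be positive")
    return (1.0 / relaxivity) * (1.0 / t1 - 1.0 / t1_0)


def t1_from_concentration(conc: float, t1_0: float,
                          relaxivity: float = DEFAULT_RELAXIVITY) -> float:
    """Algebraic inverse of :func:`gd_concentration` (seconds)."""
    return 1.0 / (1.0 / t1_0 + relaxivity * conc)


def hematocrit_correct(blood_conc, hct: float = DEFAULT_HEMATOCRIT):
    """Whole-blood to plasma concentration: divide by (1 - Hct)."""
    if not (0.0 <= hct < 1.0):
        raise ValueError(f"hematocrit must lie in [0, 1), got {hct}")
    return np.asarray(blood_conc, dtype=float) / (1.0 - hct) \
        if np.ndim(blood_conc) else blood_conc / (1.0 - hct)


def pd_normalize(dynamic_signal, pd_signal: float):
    """Divide a dynamic signal series by its proton-density reference."""
    if pd_signal <= 0:
        raise ValueError("pd_signal must be positive")
    return np.asarray(dynamic_signal, dtype=float) / pd_signal


def estimate_m0(pre_contrast_signal: float, t1_0: float,
                settings: AcquisitionSettings) -> float:
    """Equilibrium scale m0 from the mean pre-contrast signal at known T1_0."""
    unit = float(_signal(t1_0, 1.0, settings))
    return pre_contrast_signal / unit


def signal_series_to_concentration(
    signals, pd_signal: float, settings: AcquisitionSettings, t1_0: float,
    n_precontrast: int = 3, relaxivity: float = DEFAULT_RELAXIVITY,
) -> np.ndarray:
    """Full ROI pipeline: signal series -> concentration series (mM).

    Normalizes by the proton-density signal, estimates m0 from the first
    ``n_precontrast`` frames (acquired before contrast influx, so their T1
    is the supplied baseline ``t1_0``), inverts each frame to T1 and
    applies the relaxivity relation.
    """
    norm = pd_normalize(signals, pd_signal)
    if n_precontrast < 1 or n_precontrast > norm.size:
        raise ValueError("n_precontrast must be in [1, len(signals)]")
    m0 = estimate_m0(float(np.mean(norm[:n_precontrast])), t1_0, settings)
    t1 = np.array([signal_to_t1(float(s), m0, settings) for s in norm])
    return np.array([gd_concentration(x, t1_0, relaxivity) for x in t1])
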