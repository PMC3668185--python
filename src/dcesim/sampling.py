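"""Interleave timing and STR/DTR temporal under-sampling.

The dual-resolution sequence alternates one single-shot arterial (AIF)
image with one segment of an n-segment tissue image. With segment duration
``TR x TFE`` this gives an AIF frame every ``2 x segment_time`` and a full
tissue image every ``2 n x segment_time``; relative to acquiring the tissue
image single-shot in the same alternating scheme, the AIF rate is
``(n + 1) / 2`` times faster.

Under-sampling of the simulated curves is a pure decimation: samples are
the native grid points nearest to ``t0 + shift + k dt``; nothing is
interpolated, so every under-sampled value exists in the source curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetic_models import ConcentrationCurve

__all__ = [
    "SequenceTiming",
    "SamplingScheme",
    "interleave_timing",
    "undersample",
    "apply_scheme",
    "scheme_sample_table",
]

N_SHIFTS = 6  # sub-interval temporal registrations per scheme


@dataclass(frozen=True)
class SequenceTiming:
    """Interleave arithmetic of the dual-resolution sequence."""

    tr_ms: float
    tfe_factor: int
    n_segments: int

    def __post_init__(self) -> None:
        if self.tr_ms <= 0 or self.tfe_factor < 1 or self.n_segments < 1:
            raise ValueError("tr_ms, tfe_factor and n_segments must be positive")

    @property
    def segment_time_s(self) -> float:
        """Duration of one shot/segment: TR x TFE factor (s)."""
        return self.tr_ms / 1000.0 * self.tfe_factor

    @property
    def aif_dt_s(self) -> float:
        """AIF frame interval: one AIF shot alternating with one segment."""
        return 2.0 * self.segment_time_s

    @property
    def tissue_dt_s(self) -> float:
        """Full tissue image interval: n segments, each paired with an AIF shot."""
        return 2.0 * self.n_segments * self.segment_time_s

    @property
    def speedup_vs_single_shot(self) -> float:
        """AIF rate gain over a single-shot tissue image: (n + 1) / 2."""
        return (self.n_segments + 1) / 2.0


def interleave_timing(tr_ms: float, tfe_factor: int, n_segments: int) -> SequenceTiming:
    """Build the sequence timing model from its three inputs."""
    return SequenceTiming(tr_ms=tr_ms, tfe_factor=tfe_factor, n_segments=n_segments)


@dataclass(frozen=True)
class SamplingScheme:
    """One STR or DTR under-sampling condition.

    STR ("same time resolution") decimates AIF and tissue at the same rate
    with the same grid shift, emulating an AIF read off the slow tissue
    frames. DTR ("different time resolution") decimates only the tissue
    curve; the AIF keeps its fast grid (shift 0).
    """

    kind: str                 # "STR" | "DTR"
    tissue_dt: float          # s
    aif_dt: float             # s
    shift_index: int = 0      # 0 .. N_SHIFTS-1

    def __post_init__(self) -> None:
        if self.kind not in ("STR", "DTR"):
            raise ValueError("kind must be 'STR' or 'DTR'")
        if self.tissue_dt <= 0 or self.aif_dt <= 0:
            raise ValueError("sampling intervals must be positive")
        if self.kind == "STR" and self.aif_dt != self.tissue_dt:
            raise ValueError("STR requires aif_dt == tissue_dt")
        if self.kind == "DTR" and self.aif_dt > self.tissue_dt:
            raise ValueError("DTR requires aif_dt <= tissue_dt")
        if not (0 <= self.shift_index < N_SHIFTS):
            raise ValueError(f"shift_index must be in [0, {N_SHIFTS})")

    @property
    def shift_offset(self) -> float:
        """Temporal registration offset: shift_index x tissue_dt / 6 (s)."""
        return self.shift_index * self.tissue_dt / N_SHIFTS


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def undersample(curve: ConcentrationCurve, dt: float,
                shift_index: int = 0, n_shifts: int = N_SHIFTS) -> ConcentrationCurve:
    """Decimate a curve to interval ``dt`` with a sub-interval grid shift.

    The shift is ``shift_index x dt / n_shifts``; each requested time is
    mapped to the nearest native sample (round half up), and samples past
    the end of the curve are dropped. ``dt`` below the native interval is
    rejected.
    """
    if dt < curve.dt * (1 - 1e-9):
        raise ValueError(
            f"requested interval {dt} s is finer than the native {curve.dt} s grid")
    step = _round_half_up(dt / curve.dt)
    shift = shift_index * dt / n_shifts
    start = _round_half_up(shift / curve.dt)
    idx = np.arange(start, curve.n, step)
    if idx.size < 2:
        raise ValueError("under-sampled curve would have fewer than 2 samples")
    return ConcentrationCurve(t0=curve.t0 + start * curve.dt,
                              dt=step * curve.dt, values=curve.values[idx])


def apply_scheme(aif: ConcentrationCurve, tissue: ConcentrationCurve,
                 scheme: SamplingScheme) -> tuple[ConcentrationCurve, ConcentrationCurve]:
    """Apply an STR or DTR scheme to an AIF/tissue curve pair.

    Both curves must share the native grid. STR shifts both combs together;
    DTR shifts only the tissue comb and keeps the dense AIF at shift 0.
    """
    if aif.t0 != tissue.t0 or aif.dt != tissue.dt or aif.n != tissue.n:
        raise ValueError("AIF and tissue curves must share the native grid")
    tissue_s = undersample(tissue, scheme.tissue_dt, scheme.shift_index)
    if scheme.kind == "STR":
        aif_s = undersample(aif, scheme.tissue_dt, scheme.shift_index)
    else:
        aif_s = undersample(aif, scheme.aif_dt, 0)
    return aif_s, tissue_s


def scheme_sample_table(aif: ConcentrationCurve, tissue: ConcentrationCurve,
                        scheme: SamplingScheme) -> pd.DataFrame:
    """Audit table of the sample times a scheme selects."""
    aif_s, tissue_s = apply_scheme(aif, tissue, scheme)
    rows = []
    for role, c in (("aif", aif_s), ("tissue", tissue_s)):
        for t in c.times:
            rows.append({"scheme": scheme.kind, "tissue_dt": scheme.tissue_dt,
                         "aif_dt": scheme.aif_dt, "shift": scheme.shift_offset,
                         "role": role, "sample_time_s": t})
    return pd.DataFrame(rows)
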