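"""Synthetic stand-ins for scanner data.

Two generators make the signal-conversion and fitting pipeline testable
end-to-end without any acquisition: a multi-vial gadolinium dilution
phantom (signal per readout mode at known concentration), and a dynamic
carotid-style study (arterial, vessel-wall and muscle ROI signal series on
the interleaved dual-resolution grids, with the ground truth serialized
alongside). All randomness is seeded; the default noise level is zero so
closed-loop recovery is exact up to solver and sampling error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetic_models import (AIFModelSpec, ConcentrationCurve, KineticParams,
                             generate_aif, tofts_forward)
from .mr_signal import (AIF_SETTINGS, PD_SETTINGS, TISSUE_SETTINGS,
                        DEFAULT_HEMATOCRIT, DEFAULT_RELAXIVITY,
                        AcquisitionSettings, _signal, hematocrit_correct,
                        signal_series_to_concentration, t1_from_concentration)
from .sampling import SequenceTiming, interleave_timing, undersample
from .estimation import FitResult, fit_modified_tofts

__all__ = ["PhantomSpec", "SyntheticStudySpec", "generate_phantom",
           "generate_dynamic_study", "analyze_dynamic_study", "DynamicStudy"]


@dataclass(frozen=True)
class PhantomSpec:
    """Multi-vial Gd dilution phantom.

    Ten saline vials spanning 0-5 mM by default; per-vial T1 follows the
    relaxivity relation 1/T1 = 1/T1_base + r C.
    """

    concentrations: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 5.0, 10), 4))
    t1_base: float = 2.5          # diluent T1 (s)
    relaxivity: float = DEFAULT_RELAXIVITY
    noise_sd: float = 0.0         # additive signal noise (a.u.)
    m0: float = 1.0
    seed: int = 0


def generate_phantom(
    spec: PhantomSpec,
    settings_pairs: dict[str, AcquisitionSettings] | None = None,
) -> pd.DataFrame:
    """Vial table: concentration, T1, and signal per acquisition mode.

    ``settings_pairs`` maps a column name to the readout settings used for
    it; the default emulates the dynamic protocol's fast linear AIF mode,
    the saturation-prepared tissue mode, and the proton-density reference.
    """
    if settings_pairs is None:
        settings_pairs = {"signal_aif_mode": AIF_SETTINGS,
                          "signal_tissue_mode": TISSUE_SETTINGS,
                          "signal_pd": PD_SETTINGS}
    rng = np.random.default_rng(spec.seed)
    rows = []
    for vial, conc in enumerate(spec.concentrations):
        t1 = t1_from_concentration(conc, spec.t1_base, spec.relaxivity)
        row = {"vial": vial, "concentration_mM": conc, "t1_s": t1}
        for col, settings in settings_pairs.items():
            s = float(_signal(t1, spec.m0, settings))
            if spec.noise_sd > 0:
                s += rng.normal(0.0, spec.noise_sd)
            row[col] = s
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Dynamic carotid-style study specification.

    Ground-truth kinetics default to reported vessel-wall and skeletal-
    muscle magnitudes. Contrast injection starts after the configured
    number of pre-contrast tissue frames (default 3, i.e. 19.2 s on the
    default timing), which fixes the bolus arrival of the model AIF.
    """

    aif_spec: AIFModelSpec = field(default_factory=AIFModelSpec)
    wall_params: KineticParams = field(
        default_factory=lambda: KineticParams(vp=0.02, ktrans=0.27, ve=0.53))
    muscle_params: KineticParams = field(
        default_factory=lambda: KineticParams(vp=0.0, ktrans=0.09, ve=0.27))
    t1_0_blood: float = 1.65      # pre-contrast blood T1 at 3 T (s)
    t1_0_wall: float = 1.2
    t1_0_muscle: float = 1.4
    hematocrit: float = DEFAULT_HEMATOCRIT
    relaxivity: float = DEFAULT_RELAXIVITY
    timing: SequenceTiming = field(
        default_factory=lambda: interleave_timing(10.0, 80, 4))
    n_precontrast: int = 3
    native_dt: float = 0.1
    duration: float = 300.0
    m0: dict[str, float] = field(
        default_factory=lambda: {"aif": 1.0, "wall": 1.0, "muscle": 1.0})
    noise_sd_frac: float = 0.0    # signal noise SD as fraction of pre-contrast signal
    seed: int = 0


@dataclass(frozen=True)
class DynamicStudy:
    """Output of :func:`generate_dynamic_study`."""

    aif_signal: pd.DataFrame       # time_s, signal
    wall_signal: pd.DataFrame
    muscle_signal: pd.DataFrame
    pd_signals: dict[str, float]   # proton-density reference per ROI
    truth: dict                    # ground-truth record

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.aif_signal.to_csv(out / "aif_signal.csv", index=False)
        self.wall_signal.to_csv(out / "wall_signal.csv", index=False)
        self.muscle_signal.to_csv(out / "muscle_signal.csv", index=False)
        (out / "ground_truth.json").write_text(json.dumps(
            {"pd_signals": self.pd_signals, **self.truth}, indent=2))


def _conc_to_signal(curve: ConcentrationCurve, t1_0: float, relaxivity: float,
                    m0: float, settings: AcquisitionSettings) -> np.ndarray:
    t1 = 1.0 / (1.0 / t1_0 + relaxivity * curve.values)
    return np.asarray(_signal(t1, m0, settings), dtype=float)


def generate_dynamic_study(spec: SyntheticStudySpec) -> DynamicStudy:
    """Forward-simulate the dynamic study down to ROI signal series.

    Plasma concentration follows the model AIF (bolus arriving after the
    pre-contrast frames); tissue concentrations follow the modified
    Tofts-Kermode model. Blood concentration is plasma scaled by
    ``(1 - Hct)``; concentrations map to T1 through the relaxivity
    relation and to signal through the per-ROI readout settings, then the
    curves are decimated onto the interleaved AIF and tissue grids.
    """
    arrival = spec.n_precontrast * spec.timing.tissue_dt_s
    aif_model = spec.aif_spec.with_arrival(arrival)
    plasma = generate_aif(aif_model, t0=0.0, dt=spec.native_dt,
                          duration=spec.duration)
    rng = np.random.default_rng(spec.seed)

    def noisy(sig: np.ndarray) -> np.ndarray:
        if spec.noise_sd_frac > 0:
            sd = spec.noise_sd_frac * sig[0]
            sig = sig + rng.normal(0.0, sd, size=sig.shape)
        return sig

    # Arterial ROI sees whole-blood concentration with the fast linear readout.
    blood = ConcentrationCurve(plasma.t0, plasma.dt,
                               plasma.values * (1.0 - spec.hematocrit))
    aif_sampled = undersample(blood, spec.timing.aif_dt_s)
    aif_sig = noisy(_conc_to_signal(aif_sampled, spec.t1_0_blood,
                                    spec.relaxivity, spec.m0["aif"],
                                    AIF_SETTINGS))

    tables = {}
    for roi, params, t1_0 in (("wall", spec.wall_params, spec.t1_0_wall),
                              ("muscle", spec.muscle_params, spec.t1_0_muscle)):
        ct = tofts_forward(plasma, params)
        ct_sampled = undersample(ct, spec.timing.tissue_dt_s)
        sig = noisy(_conc_to_signal(ct_sampled, t1_0, spec.relaxivity,
                                    spec.m0[roi], TISSUE_SETTINGS))
        tables[roi] = pd.DataFrame({"time_s": ct_sampled.times, "signal": sig})

    pd_signals = {
        "aif": float(_signal(spec.t1_0_blood, spec.m0["aif"], PD_SETTINGS)),
        "wall": float(_signal(spec.t1_0_wall, spec.m0["wall"], PD_SETTINGS)),
        "muscle": float(_signal(spec.t1_0_muscle, spec.m0["muscle"],
                                PD_SETTINGS)),
    }
    truth = {
        "wall": asdict(spec.wall_params),
        "muscle": asdict(spec.muscle_params),
        "t1_0": {"aif": spec.t1_0_blood, "wall": spec.t1_0_wall,
                 "muscle": spec.t1_0_muscle},
        "hematocrit": spec.hematocrit,
        "relaxivity": spec.relaxivity,
        "bolus_arrival_s": arrival,
        "seed": spec.seed,
    }
    return DynamicStudy(
        aif_signal=pd.DataFrame({"time_s": aif_sampled.times,
                                 "signal": aif_sig}),
        wall_signal=tables["wall"],
        muscle_signal=tables["muscle"],
        pd_signals=pd_signals,
        truth=truth,
    )


def analyze_dynamic_study(study: DynamicStudy,
                          n_precontrast: int = 3) -> dict[str, FitResult]:
    """Run the full ROI analysis pipeline on a generated study.

    Normalization -> T1 inversion -> relaxivity relation -> hematocrit
    correction of the arterial curve -> modified Tofts-Kermode fit, using
    only the signal tables, the proton-density references and the acquisition
    metadata in the sidecar (baseline T1, hematocrit, relaxivity).
    Returns one :class:`~dcesim.estimation.FitResult` per tissue ROI.
    """
    t1_0 = study.truth["t1_0"]
    r = study.truth["relaxivity"]
    blood = signal_series_to_concentration(
        study.aif_signal["signal"].to_numpy(), study.pd_signals["aif"],
        AIF_SETTINGS, t1_0["aif"], n_precontrast, r)
    plasma = hematocrit_correct(blood, study.truth["hematocrit"])
    t_aif = study.aif_signal["time_s"].to_numpy()
    aif = ConcentrationCurve(t0=float(t_aif[0]),
                             dt=float(t_aif[1] - t_aif[0]), values=plasma)
    results = {}
    for roi, table in (("wall", study.wall_signal),
                       ("muscle", study.muscle_signal)):
        conc = signal_series_to_concentration(
            table["signal"].to_numpy(), study.pd_signals[roi],
            TISSUE_SETTINGS, t1_0[roi], n_precontrast, r)
        t = table["time_s"].to_numpy()
        tissue = ConcentrationCurve(t0=float(t[0]), dt=float(t[1] - t[0]),
                                    values=conc)
        results[roi] = fit_modified_tofts(aif, tissue)
    return results
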