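# dcesim

Simulation and fitting toolkit for **dual-temporal-resolution dynamic
contrast-enhanced (DCE) MRI** of the vessel wall.

Quantifying plaque microvasculature with DCE-MRI requires sampling two very
different signals at once: the arterial input function (AIF), which peaks
and decays within seconds, and the slowly enhancing vessel wall, which
needs high spatial resolution and can only be refreshed every several
seconds. An interleaved acquisition alternates one fast low-resolution AIF
frame with one segment of an *n*-segment tissue image, so the AIF is
sampled every `2·TR·TFE` seconds while a full tissue image completes every
`2n·TR·TFE` seconds — `(n+1)/2` times faster AIF sampling than a
single-shot dual acquisition.

`dcesim` is aimed at sequence developers and perfusion modelers who want to
ask, before touching a scanner: *how much do kinetic-parameter estimates
degrade when the AIF is read off the slow tissue frames ("same time
resolution", STR), and how much is rescued by a fast interleaved AIF
("different time resolution", DTR)?* It provides:

- the modified Tofts–Kermode forward model
  `C_t = v_p·C_p + K^trans (C_p ⊛ e^{−k_ep t})`, with an exact
  recursive exponential-kernel convolution, and a population-average model
  AIF (bi-Gaussian + sigmoid-modulated washout);
- STR/DTR decimation with six sub-interval grid shifts emulating variable
  bolus/acquisition registration, plus the interleave timing model;
- non-linear least-squares recovery of (v_p, K^trans, v_e) — k_ep =
  K^trans/v_e derived — and median error/spread summaries over a 150-set
  parameter grid;
- the MR signal layer for in-vivo-style analysis: SPGR steady-state and
  saturation-recovery signal laws, signal→T1 inversion, the relaxivity
  relation `[Gd] = (1/r)(1/T1 − 1/T1_0)`, proton-density normalization and
  hematocrit correction;
- synthetic generators (Gd vial phantom, dynamic carotid-style ROI study)
  so the whole pipeline runs end-to-end with no scanner data.

## Worked example

Run the reduced experiment from the shell:

```bash
$ dcesim simulate --preset smoke --out smoke_out --no-plots
running 432 fits (8 parameter sets, 9 scheme cells, 6 shifts) ...
wrote smoke_out/raw_fits.csv
wrote smoke_out/error_summary.csv
worst-cell medians by scheme (%):
        median_rel_error_pct  median_rel_sd_pct
scheme
DTR                 0.023123           0.029862
STR               362.798016         262.498468
```

Reading: with a fast AIF (DTR), the worst median error/spread of any
parameter at any tissue rate stays in the hundredths of a percent, while
sampling the AIF at the tissue rate (STR) destroys the estimates at coarse
rates — here up to a few hundred percent at the 51.2 s tissue interval.
`--preset full` runs the complete study grid (150 parameter sets, tissue
rates 1.6–51.2 s, 16,200 fits, roughly two minutes) and `--plots` writes
four-panel log-scale figures of the medians per parameter.

The same from Python:

```python
from dcesim import (ExperimentConfig, run_experiment, interleave_timing)

print(interleave_timing(10.0, 80, 4).aif_dt_s)      # 1.6 (s)
result = run_experiment(ExperimentConfig.smoke())
print(result.summary.head())
```

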