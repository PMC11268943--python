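# oxycpap

Closed-loop simulation of a blower-based neonatal CPAP device with an
integrated pressure-swing-adsorption (PSA) oxygen concentrator, including
the power-minimizing FiO2 control-allocation algorithm and the in-vitro
validation protocol that measures FiO2 delivery accuracy (Bland-Altman
agreement) and compressor power drain.

## What is in here

| Module | Purpose |
| --- | --- |
| `oxycpap.plant` | Physical simulation: radial blower with servo lag, single-limb circuit with a power-law intentional leak, oxygen injection node with a well-mixed proximal dead space, and an active RC test lung driven by synthetic infant breath tracings. |
| `oxycpap.estimator` | Airway pressure/flow estimation from blower-side sensors only (tube-drop and leak-model corrections), plus the windowed mean-inspiratory-flow statistic the allocator consumes. |
| `oxycpap.control` | PID blower-speed controller (derivative on measurement, clamped integrator) regulating estimated airway pressure to the CPAP setpoint. |
| `oxycpap.concentrator` | Synthetic static ground-truth surfaces of the concentrator — flow, purity and power as functions of compressor speed (CS) and solenoid-valve duty (SV) — the 90-point characterization experiment, ordinary-least-squares fitting of the two bivariate-quadratic inverse models, and the reservoir low-pass filter. |
| `oxycpap.allocation` | The FiO2 control allocator: samples candidate purities, sizes each candidate's flow from the gas-blending mass balance, maps candidates through the fitted inverse models, and picks the feasible command with the lowest compressor speed. Includes a lookup-table compiler and an exhaustive brute-force oracle for verification. |
| `oxycpap.loop` | Closed-loop wiring of all of the above (500 Hz plant, 100 Hz PID, 1 Hz allocator). |
| `oxycpap.protocol` | The validation grid (CPAP 3/5/8/10 cmH2O x FiO2 25–70% x minute ventilation 800/1000/1500 ml/min), Bland-Altman agreement statistics, and the power-saving report. |
| `oxycpap.configio`, `oxycpap.cli` | JSON configuration with field-level validation and the command-line interface. |

## CLI

```bash
oxycpap characterize --out-dir out          # sample the concentrator grid
oxycpap fit --table out/characterization.csv --out-dir out
oxycpap allocate --fio2 0.45 --v-awo 0.8    # one allocation query
oxycpap simulate --cpap 5 --fio2 0.40 --mv 1000 --out-dir out
oxycpap validate --out-dir out              # full grid + all reports
oxycpap validate --fast --out-dir out       # CI profile (dt 5 ms)
oxycpap report --records out/records.csv --out-dir out
```

All commands accept `--config <file.json>`; see
`oxycpap.configio.dump_default_config` for the full schema with defaults.
Outputs are plain CSV/JSON artifacts (`records.csv`, `bland_altman.json`,
`power_report.csv`, `run_log.csv`).

## Notes on the synthetic concentrator

The real device's characterization data are not public, so the ground-truth
surfaces are synthetic, calibrated to the published anchors: compressor
power affine from 65 W (CS 20%) to 146 W (CS 100%), a ~93% purity ceiling,
a 130 W standard mode, the four monotone characterization trends (flow
rises with valve duty and speed; purity falls with duty and rises with
speed), and feasibility of the full validation grid up to 70% FiO2. Small
smooth perturbations keep the inverse characteristics from being exactly
polynomial, so the quadratic inverse-model fits carry a realistic residual
that the allocation tolerances must absorb.
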