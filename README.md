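# smds — single-molecule microfluidic diffusional sizing

`smds` is an analysis toolkit for single-molecule microfluidic diffusional
sizing (smMDS): measuring the hydrodynamic radius R_H of proteins and protein
assemblies in free solution by watching them diffuse. A fluorescent analyte
stream is flow-focused between two buffer streams in a laminar-flow
microchannel (25 µm × 225 µm observation channel, ~1:8 sample:buffer ratio);
a confocal spot scanned across the channel at several downstream crossings
records either intensity (continuous scans, nM concentrations) or individual
molecule transits counted digitally from photon bursts (step scans, down to
fM). The transverse spreading at each crossing encodes the diffusion
coefficient D, and

    R_H = k_B T / (6 π η D)

converts it to a calibration-free hydrodynamic radius. Because detection is
at the single-molecule level, subpopulations of a heterogeneous sample —
oligomeric states, rare fibrils in a monomer background, nanoscale
condensate clusters — can be gated and sized independently.

The package covers the full chain:

| module | what it does |
| --- | --- |
| `smds.physics` | Stokes–Einstein conversions, R_H–M_W scaling laws |
| `smds.chip` | chip geometry/flow model; advection–diffusion solver that simulates the basis profiles used for calibration-free fitting |
| `smds.bursts` | Lee-filtered IPT_max/N_min burst search on photon timestamp traces (16-ps ticks) |
| `smds.profiles` | diffusion profiles from continuous (intensity) or step (molecule-count) scans |
| `smds.fitting` | global least-squares fit of profiles against the simulated basis: R_H, global ± range, per-crossing local errors |
| `smds.oligomers` | burst-brightness deconvolution (skew-normal monomer + tied Gaussian n-mers), species gating, bootstrap abundance CIs, N_min threshold sweeps |
| `smds.clusters` | fibril/bulk trace splitting, >k·σ nanocluster event detection, Fick-law sizing, flux → concentration → volume fraction |
| `smds.isotherm` | exact two-site mass-balance binding isotherm and K_d fitting |
| `smds.synthetic` | ground-truth generator (photon traces, brightness samples, cluster event clouds) so every stage has an oracle |
| `smds.cli` / `smds.io` | `smds` command-line pipeline, delimited-text + JSON formats, provenance records |

## Worked example

Size a 3.73-nm protein from a simulated single-molecule step scan
(~5,000 counted molecules across four channel crossings):

```python
import numpy as np
from smds import chip, physics, synthetic
from smds.bursts import BurstSearchParams
from smds.profiles import profile_from_step
from smds.fitting import global_fit

geom, flow, cond = chip.ChipGeometry(), chip.FlowSettings(100.0), physics.SolventConditions()
basis = chip.simulate_basis(geom, flow, cond, np.geomspace(0.5, 300, 45),
                            chip.SolverOptions(n_transverse=101, n_depth=9))

acq = synthetic.AcquisitionSpec(seed=5, dwell_s=2.0, n_steps_per_crossing=60,
                                background_rate_khz=1.0)
pos, bounds = synthetic.step_positions(geom, 60)
conc = synthetic.concentration_for_total_counts(
    5000, synthetic.SpeciesSpec(3.73, 1e-12), geom, flow, acq, basis, pos, bounds)
traces, man = synthetic.generate_step_scan(
    [synthetic.SpeciesSpec(3.73, conc)], geom, flow, cond, acq, basis)

profile = profile_from_step(traces, BurstSearchParams(),
                            [tuple(b) for b in man["crossing_boundaries"]])
fit = global_fit(profile, basis)
print(f"R_H = {fit.r_h_nm:.2f} +/- {fit.r_h_error_nm:.2f} nm "
      f"(D = {fit.d_m2_s:.3g} m^2/s, {int(profile.total)} molecules)")
```

Output:

```
R_H = 3.63 +/- 0.11 nm (D = 6.77e-11 m^2/s, 5097 molecules)
```

The burst search found ~5,000 single-molecule transits, the digital
count-vs-position profile was fitted globally against the simulated basis,
and the recovered radius agrees with the 3.73-nm ground truth within its
~3% statistical range. The same `global_fit` call also reports per-crossing
local radius errors (deviation of each crossing's own best radius from the
global one); the inlet crossing at zero residence time carries no size
information and is reported as undefined.

The same machinery runs from the shell:

```bash
smds simulate-basis --config run.yaml --out basis/
smds generate --config run.yaml --basis basis/ --out scan/
smds profile  --traces scan/traces.csv --boundaries 0:225,275:500,550:775,825:1050 --out prof.csv
smds fit      --profile prof.csv --basis basis/ --out report.json
```

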