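# fretmask

Dynamic binary-mask analysis of two-channel FRET time-lapse stacks, with a
synthetic dilating-vessel phantom for end-to-end validation.

## The problem

Ratiometric FRET biosensors (donor/CFP over acceptor/YFP emission) report
intracellular signaling — here modeled on a cGMP sensor whose CFP/YFP ratio
rises from 0.8 to 1.2 as cGMP saturates the binding sites (EC50 500 nM, a
50% ΔR/R at saturation). In tissue that moves — most drastically, blood
vessels that dilate — a fixed ROI drawn around the structure acquires a
changing proportion of dim background. The resulting intensity drops in
*both* channels dwarf the few-percent FRET signal, and conventional
background subtraction does not remove them.

The dynamic binary mask sidesteps the artifact: every frame of one channel
is thresholded, pixels at or above the threshold keep the value 1 and
pixels below become an **excluded marker (IEEE NaN — deliberately not
zero)**. Multiplying the same mask into both channels leaves stacks in
which only the bright structure carries numbers. ROI means, ΔR/R traces,
pixel-wise ratio maps and kymographs then skip excluded pixels entirely, so
an ROI may contain arbitrary amounts of background without affecting either
the trace or its noise, and vessel diameter can be read off a mask
kymograph by counting excluded lumen pixels between the wall bands.

## What's in the package

| Module | Contents |
| --- | --- |
| `fretmask.sensor` | Two-state FRET sensor photophysics: Hill binding, channel emissions, bleed-through/direct-excitation crosstalk, titration (EC50) fitting |
| `fretmask.phantom` | Synthetic dilating-vessel phantom: cGMP pulses, diameter coupling, Poisson/read noise, bleaching, jitter, channel misalignment, ground truth |
| `fretmask.stacks` | Two-channel TIFF I/O, polygon ROIs, channel alignment, binning, background subtraction, ΔX/X baseline normalization |
| `fretmask.segmentation` | Pooled exact-Otsu or manual thresholds, the dynamic binary mask, NaN-aware ROI traces and ratio maps |
| `fretmask.kymograph` | Scan-line reslicing and run-counting diameter estimation |
| `fretmask.pipeline` | YAML-configured end-to-end runs, segmentation-vs-subtraction comparison, output bundles |
| `fretmask.cli` | `fretmask simulate / analyze / kymo / compare` |

## Worked example

A vessel whose wall cGMP rises to 5 µM while the vessel dilates by 30%,
imaged with shot noise — then analyzed blind to the ground truth:

```python
import numpy as np
import fretmask as fm

cfg = fm.PhantomConfig(
    n_frames=80, seed=11,
    pulses=(fm.Pulse(start_frame=30, c_max_nM=5000.0,
                     tau_on_s=10.0, tau_off_s=60.0, duration_s=120.0),),
    coupling=fm.Coupling(g_max=0.3, k_dil_nM=500.0, hill=2.0))
stack, truth = fm.simulate_timelapse(cfg)

analysis = fm.AnalysisConfig(baseline_frames=(0, 30),
                             scan_line=(10, 32, 70, 32))
roi = fm.RoiPolygon.rectangle(18, 8, 62, 56, "vessel")
bundle = fm.run_analysis(analysis, stack=stack, rois={"vessel": roi})

tr = bundle["modes"]["segmentation"]["vessel"]
peak = int(np.nanargmax(tr.drr))
print(f"threshold      : {bundle['diagnostics']['threshold']:.1f}")
print(f"baseline ratio : {np.nanmean(tr.ratio[:30]):.4f}")
print(f"peak dR/R      : {np.nanmax(tr.drr):.4f} at frame {peak} "
      f"(truth {truth.true_ratio.max()/truth.true_ratio[0]-1:.4f})")
print(f"peak dilation  : {np.nanmax(tr.dd_d):.4f} "
      f"(truth {truth.diameter_px.max()/20-1:.4f})")
```

Output:

```
threshold      : 428.8
baseline ratio : 0.8002
peak dR/R      : 0.5013 at frame 38 (truth 0.4941)
peak dilation  : 0.3000 (truth 0.2970)
```

The same run from the command line:

```sh
fretmask simulate --config phantom.yaml --out sim/
fretmask analyze  --config analysis.yaml --out results/
fretmask kymo --cfp sim/cfp.tif --yfp sim/yfp.tif --line 10,32,70,32 \
              --baseline 0,30 --out diameter.csv
```

`analyze` writes per-ROI trace CSVs, the 1/NaN mask, segmented channel and
pixel-ratio stacks (float32 TIFF), the kymograph, a diagnostics JSON and a
config echo for provenance. Exit codes: 0 success, 2 configuration error,
3 data error.

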