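# helixafm

Quantitative analysis of high-speed AFM (HS-AFM) movies of actin
filaments, built for studying cofilin-induced conformational changes:
crossover-peak tracking, half-helical pitch and height statistics with a
paracrystal-calibrated measurement-error decomposition, cofilin-cluster
delimitation and directional growth counting, and severing-site
classification — plus a calibrated synthetic movie generator so every
stage can be validated against known ground truth.

## Who it is for

HS-AFM lets you watch single actin filaments at ~2 frames/s with
nanometre height resolution. The two strands of the actin double helix
cross over every half helix (~36.8 nm when bare), and the crossover
points appear as height maxima along the filament. Cofilin binding
supertwists the helix — clusters of bound cofilin are ~2 nm taller and
~27% shorter in pitch — and the supertwist propagates asymmetrically
into the bare zone on the pointed-end side of a cluster. This package
turns raw height maps into those numbers.

Core quantities, in the field's notation:

- half-helical pitch `p` = arc distance between consecutive crossover
  peaks along the traced backbone; peak height `h` = apparent filament
  thickness at the crossover.
- variance decomposition `σ_true = sqrt(σ_obs² − σ_err²)`, with `σ_err`
  calibrated on actin paracrystals (zero structural twist variation).
- supertwist ratio `p_bare / p_cofilactin` and percent shortening
  `100·(1 − p_cofilactin / p_bare)`.
- cluster growth events (one per half helix gained per frame) with a
  pointed-end fraction and Clopper–Pearson 95% CI.
- severing sites classified as far bare / neighbor bare / cluster end /
  cluster interior relative to the decorated runs.

## Worked example

Simulate a movie of filaments carrying one cofilin cluster each, analyze
it with the ground-truth sidecar supplying polarity, and summarize:

```sh
helixafm simulate --preset cluster --seed 2 --out sim/ \
    --n-filaments 6 --n-half-helices 12 --n-frames 2
helixafm analyze --input sim/movie.tif --out run/ \
    --polarity pointed_at_start --truth sim/ground_truth.json
helixafm summarize --analysis run/ --out summary/
```

which prints (seed 2):

```
"per_state": {
 "bare":      {"n": 96, "pitch_mean_nm": 36.0, "pitch_sd_nm": 4.5,
               "height_mean_nm": 8.9, "pitch_sd_true_nm": 3.3},
 "decorated": {"n": 48, "pitch_mean_nm": 27.5, "pitch_sd_nm": 3.0,
               "height_mean_nm": 10.3, "pitch_sd_true_nm": 0.3}
},
"supertwist": {"ratio": 1.31, "percent_shortening": 24},
"height_difference_nm": 1.4
```

Read: 96 bare and 48 cofilin-decorated half helices were measured; the
decorated pitch (27.5 nm) is ~24% shorter and the decorated crossovers
are ~1.4 nm taller, and subtracting the 3.0 nm measurement-error
calibration from the observed bare pitch SD leaves ~3.3 nm of true
structural variation. (Small-sample values — note how unstable the
decorated `sd_true` is at n = 48; at the full reproduction scale of
~2000 half helices the means converge to 36.8/26.9 nm, ratio 1.37, 27%,
+2.0 nm.)

The same machinery is available as a library:

```python
import numpy as np
from helixafm import (GeneratorConfig, build_filament_model, render_frame,
                      trace_backbone, detect_peaks_along_trace, half_pitches,
                      summarize, subtract_measurement_variance)

cfg = GeneratorConfig()
model = build_filament_model(cfg, n_half_helices=20, rng=np.random.default_rng(1))
frame = render_frame(model, cfg)
trace = trace_backbone(frame, seed_point_nm=(model.total_arc_nm / 2, 18.0))
peaks = detect_peaks_along_trace(frame, trace)
pitches = [hh.pitch_nm for hh in half_pitches(peaks)]
print(summarize(pitches).mean)                        # ~36.8
print(subtract_measurement_variance(4.3, 3.0).sd_true)  # 3.08... -> 3.1
```

Real movies are read with `helixafm.io.read_movie` (multi-page float
TIFF in nm, or a directory of TIFFs with a `metadata.json`); the pixel
size is never guessed — pass `--pixel-size` if it is not embedded.

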