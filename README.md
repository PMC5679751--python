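# gastrotrack

Quantification tools for zebrafish gastrulation imaging: cell-position
normalization onto the embryo axes from stained snapshots, and trajectory
metrics from time-lapse cell tracks, together with a synthetic-embryo
simulator that makes the whole pipeline testable without microscopy data.

## Who this is for

During gastrulation, internalized mesendodermal cells migrate from the
margin toward the animal pole. Comparing genotypes (e.g. wild type against
a signaling mutant with impaired animal-ward migration) requires
quantitative readouts from two kinds of data:

* **snapshots** — in situ stained embryos in lateral view, where each
  marker-positive cell's position is normalized to *percent embryo height*
  along the animal–vegetal (AV) axis (vegetal pole = 0%, animal pole =
  100%), restricted to a lateral window (cells on or within 10% of the
  embryo width from the center of the lateral side), and summarized as cell
  counts, pooled position distributions and per-embryo leading-edge
  heights;
* **time-lapse tracks** — per-cell trajectories (TrackMate XML or plain
  CSV), aligned at the onset of internalization, binned into four equal
  time windows (segments with < 5 points per window dropped, first window
  excluded), and summarized per cell and window by

  - path length `L = Σᵢ |xᵢ₊₁ − xᵢ|` (µm),
  - net displacement `D = |x_last − x_first|` (µm),
  - straightness `D / L ∈ [0, 1]`,
  - speed `L / (t_last − t_first)` (µm/min),

  plus a displacement-weighted **rose histogram**: each per-frame step adds
  its magnitude to the angular bin of its direction in the anatomical
  compass frame (dorsal 0°, animal 90°, ventral 180°, vegetal 270°), with
  bin weights normalized to proportions.

Proliferation is scored from track-splitting events in observation windows
(percent proliferation = 100 × divisions / cells present at window start,
averaged over windows per embryo), and group differences use the unpaired
two-tailed t-test.

The simulator generates biased-random-walk trajectories
(`step = drift·Δt + N(0, σ²I)`) with genotype presets, division/death
events at per-window probabilities, and closed-form expectations (the step
magnitude is Rice-distributed) used as oracles in the tests.

## Worked example

```python
import numpy as np
from gastrotrack import params_for, simulate_tracks, compute_window_metrics, expected_speed
from gastrotrack.trajectory_metrics import bin_into_windows, rose_histogram
from gastrotrack.embryo_geometry import DirectionConvention

conv = DirectionConvention()
for gt in ("wildtype", "mutant"):
    p = params_for(gt, n_cells=100, seed=1)
    ts = simulate_tracks(p, genotype=gt)
    m = compute_window_metrics(ts, 4)          # windows 2-4, >=5 points each
    segs = [s for s in bin_into_windows(ts, 4) if s.window_index > 0]
    rose = rose_histogram(segs, ts.geometry, conv)
    print(f"{gt}: n_tracks={len(ts.tracks)}  "
          f"mean speed={np.mean([x.speed for x in m]):.3f} um/min "
          f"(expected {expected_speed(p):.3f})  "
          f"straightness={np.mean([x.straightness for x in m]):.3f}  "
          f"animal-bin proportion={rose.proportion_toward('animal', conv):.3f}")
```

prints

```
wildtype: n_tracks=144  mean speed=1.000 um/min (expected 1.006)  straightness=0.439  animal-bin proportion=0.253
mutant: n_tracks=130  mean speed=0.747 um/min (expected 0.757)  straightness=0.247  animal-bin proportion=0.161
```

The wild-type cohort moves faster, straighter and with a larger share of
its total displacement in the animal-pole bin than the mutant cohort —
the genotype contrast the metrics are designed to detect. The measured
mean speeds sit next to the analytic Rice-mean expectations, and track
counts exceed the 100 starting cells because divisions split tracks.

The same analyses are available from the shell:

```bash
gastrotrack simulate --preset wildtype --seed 1 -o runs/wt
gastrotrack track-metrics --tracks runs/wt/tracks.csv -o runs/wt/metrics
gastrotrack proliferation --tracks runs/wt/tracks.csv --frame-spans 30,30,30 -o runs/wt/prolif
gastrotrack positions --cells cells.csv --landmarks landmarks.csv -o runs/pos
```

Each run writes a `manifest.json` with the resolved configuration and seed.

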