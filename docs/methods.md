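# Methods

## Coordinate frame

An embryo in lateral view is described by landmarks: animal pole, vegetal
pole, a dorsal reference point, and measured height (animal–vegetal
extent) and width (lateral extent). The lateral view is treated as a flat
2D plane — positions are what measurements on maximum-intensity
projections deliver, with no spherical correction. Percent embryo height
is the linear projection of a point onto the AV segment, scaled to
vegetal = 0% and animal = 100%; by construction it is invariant under
rigid transforms applied jointly to landmarks and cells, and the poles map
exactly to 0 and 100. Points projecting outside the segment by more than
a tolerance (default 1% of height, absorbing landmark click error) are
rejected; inside the tolerance they are clipped to [0, 100].

The lateral offset of a cell is its signed perpendicular distance from the
AV axis, in units of embryo width, positive toward dorsal. The center of
the lateral side sits 90° from dorsal around the embryo; its projection
into the lateral view is the center of the bounding ellipse, i.e. the
midpoint of the AV segment, which is the default when it is not annotated
explicitly. Lateral offset is straight-line image distance, not arc
length along the embryo surface.

Movement angles use a configurable compass convention, by default
dorsal = 0°, animal = 90°, ventral = 180°, vegetal = 270°,
counter-clockwise. Numeric angles are a choice of this package; only the
four cardinal anatomical labels and their 90° spacing are fixed.

## Trajectory metrics

Tracks are aligned so internalization onset is t = 0 (earlier points keep
negative times and never enter window statistics). The observation span
[0, T], with T the last timestamp present, is cut into equal windows
(default four); windows are half-open [start, end) with the final window
closed at T, so every point lands in exactly one window. Segments with
fewer than 5 points in a window are dropped, and the first window is
excluded from aggregates by default — both filters are parameters, not
constants.

Per segment: path length is the sum of per-frame Euclidean step
magnitudes; net displacement the first-to-last chord; straightness
net/path, the standard [0, 1]-bounded directionality ratio (1 = straight,
0 = closed loop); speed path/elapsed-time. The reciprocal path/net
convention is available behind a `reciprocal` flag for comparison with
sources that divide the other way — the bounded index is the default
because it is the conventional migration statistic. A segment that never
moves has undefined straightness and is marked missing rather than given
a value.

Rose histograms are displacement-weighted: every positive-magnitude step
adds its magnitude to the bin of its movement angle; zero-magnitude steps
have no direction and are skipped (their weight is zero anyway). Default
8 bins, centered on the four cardinal directions and the diagonals so
that exactly-animal motion falls in the middle of a bin; weights are
additive across arbitrary partitions of the step set before
normalization, and proportions sum to 1.

## Snapshot analyses

Lateral selection keeps cells with |lateral offset| ≤ 0.10 of embryo
width (closed boundary: "on or within"). The per-embryo lateral cell
count is the endoderm cell-number proxy. Position distributions pool
selected cells across embryos (not embryo averages) and normalize to
proportions; the default bin width is 5% of embryo height. The leading
edge is the mean percent height of the k most animally positioned cells,
default k = 1 (the single front cell), and the per-embryo value is what
enters group comparisons. Group comparison is the unpaired two-tailed
Student's t-test (equal variances); Welch's form is behind a flag.
Identical constant groups return t = 0, p = 1; otherwise zero pooled
variance is an error.

## Proliferation and death

Observation windows are configured as frame spans (defaults 20, 54, 20
frames — acquisition-driven, not biological). Percent proliferation of a
window is 100 × splitting events / cells present at the window start; a
division is one event regardless of daughter count, and a cell entering
mid-window from a division counts in the starting population of the next
window only ("present at the beginning" is read literally). The
per-embryo value is the unweighted mean over windows. Deaths are
summarized as a count and a fraction of tracked cells.

## Synthetic embryos

The simulator is a drift + isotropic-Gaussian random walk in the 2D
lateral plane: each frame a cell moves `drift·Δt + N(0, σ²I)`, with the
drift vector expressed in the anatomical frame. There are no cell–cell
interactions, no epiboly surface flow and no confinement to the embryo
outline (snapshot conversion clips out-of-range cells with a warning);
this is the minimal model whose summary statistics the pipeline's metrics
measure, chosen deliberately so that every metric has a closed-form or
symmetry-based oracle. Passing tests therefore demonstrate correctness of
the computations, not realism of embryonic mechanics: real trajectories
have persistence, neighbor coupling and stage-dependent drift that this
generator does not emulate.

Defaults: 180 min duration (≈50% → 85% epiboly) at 2-min frames (the
acquisitions used ≤ 3 min); embryo 600 µm × 600 µm; cells start in a
5–20% height band near the margin, centered laterally. The wild-type
preset uses animal drift 0.4 µm/min with step noise σ = 1.5 µm; the
mutant preset reduces drift to 0.1 µm/min and scales noise by 0.8, and
raises the per-window death probability to 0.06 — fixed test fixtures
encoding the qualitative genotype contrast (reduced animal-ward
migration, slower cells, more death), not estimates of real kinetics.

Division and death are scheduled per event window (default 3 equal
windows): a cell present at a window start divides with probability 0.05
and dies with probability 0.02 per window, the event placed at a
uniformly chosen frame within the window (the earlier event wins if both
fire). Daughters start one noise step from the split position and become
eligible for events at the next window start, mirroring how the
proliferation counter attributes cells to windows; the per-window
division probability is therefore recovered unbiasedly by the pipeline.
Because death competes with division inside a window, recovery checks run
with death disabled to isolate the estimator (with default death rates
the censoring bias is ~0.0005, far below Monte-Carlo error at the sizes
used).

The expected pipeline speed has a closed form: step magnitudes are
Rice(ν = |drift|·Δt, σ) distributed, so mean speed is the Rice mean over
Δt, reducing to |drift| as σ → 0 and to the Rayleigh mean σ√(π/2)/Δt at
zero drift. All runs are reproducible from a single seed; draws are made
in a fixed order over a FIFO lineage queue.

## Numerical choices and problem sizes

Times are minutes, lengths µm throughout; TrackMate spot times are
converted from the file's declared units, and merges (two incoming edges
at a spot) are rejected since the biology has divisions only. CSV output
uses 6 significant digits; the write∘read round trip is the identity at
that precision. Window assignment uses floor division of timestamps, so
boundary points go to the later window.

Validation sizes are chosen to give tight Monte-Carlo error at
interactive runtimes: oracle equivalence on 100 random tracks at 1e-9;
speed recovery with 300 cells against the Rice mean at 3 MC-SE; division
probability with 60-cell embryos × 500 replicates at 2 MC-SE;
directional monotonicity over an animal-drift grid 0–0.5 µm/min at 150
cells per point with a shared seed; genotype separation at n = 200 (3σ on
snapshot mean height); t-test calibration with 10,000 null replicates at
α = 0.05 ± 0.01.

## Known limitations

2D lateral-view geometry only; no spherical coordinates, no 3D metrics,
no mean-squared-displacement or persistence-time modelling. The TrackMate
reader targets the stable spot/edge core and ignores features, filters
and views. The simulator's step model is memoryless between frames;
straightness values it produces are those of a biased random walk, not of
persistent crawling cells.
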