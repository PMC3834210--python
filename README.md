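# anechoid

Extraction of time-shiftable movement primitives from multichannel
kinematic trajectories by **anechoic demixing**, with the model-selection
machinery to decide how many primitives the data support, a
correlation-matrix PCA baseline for comparison, gait-event/reach-timing
measures, and a ground-truth synthetic-data generator that makes the whole
pipeline testable offline.

## The problem

Whole-body movements such as reaching for a target while walking combine
a *rhythmic* component (locomotion) and a *discrete* component (the
reach).  Across joints and trials the same underlying waveforms recur —
scaled differently and, crucially, **shifted in time**: the left hip
repeats the right hip's trajectory half a gait cycle later, and the reach
starts at a different phase in every trial.  Instantaneous mixing models
(PCA, ICA, NMF) cannot absorb those shifts and need many components to
approximate such data.  The anechoic mixing model makes the shift explicit:

    x_i(t) = Σ_j  a_ij · s_j(t − τ_ij) + ε_i(t)

— every channel `i` receives each source `s_j` with its own amplitude
`a_ij` **and its own time delay** `τ_ij`.  The fitting algorithm (FADA,
Fourier-based anechoic demixing) exploits the band-limitedness of
movement data: signals are represented by truncated Fourier series, where
a delay is a per-harmonic phase rotation and hence a continuous,
differentiable parameter.  Fitting alternates non-negative factorization
of the coefficient magnitudes, least-squares phase and source updates, and
per-channel delay estimation by frequency-domain cross-correlation, with
25 random restarts.  Model order is chosen with the variance-accounted-for
(VAF) curve and a regression scree test; see `docs/methods.md` for the
full account.

Audience: movement scientists and biosignal methodologists who want a
shift-invariant decomposition with reproducible model selection, and
anyone who needs a tested reference implementation of anechoic demixing
for band-limited signals.

## Worked example

```python
import anechoid as an

# synthetic walk-and-reach study: 2 ground-truth sources, 10 trials x 6
# joint-angle channels x 350 samples, 5 % noise, known weights and delays
cfg = an.gait_reach_config(n_trials=10, noise_level=0.05, seed=0)
ts, truth = an.make_mixture_dataset(cfg)

curve = an.vaf_sweep(ts, range(1, 6), {"n_restarts": 25, "seed": 1})
print("VAF:", [round(v, 2) for v in curve.vaf])
print("selected N =", an.scree_select(curve))

model = curve.fit_refs[1]                      # the N = 2 fit
al = an.align_sources(model.source_matrix(), truth.sources)
print("source recovery:", [round(float(abs(c)), 4) for c in al.correlations])

pca = an.pca_vaf_sweep(ts, range(1, 6))
print("PCA VAF:", [round(v, 2) for v in pca.vaf], "| PCA scree:", an.scree_select(pca))
```

prints

```
VAF: [93.77, 99.73, 99.72, 99.73, 99.73]
selected N = 2
source recovery: [1.0, 1.0]
PCA VAF: [36.49, 71.86, 94.45, 98.36, 99.34] | PCA scree: None
```

Reading: the anechoic model saturates at two sources — the scree test
picks N = 2, the two recovered waveforms correlate > 0.999 with the
generator's hidden sources, and 99.7 % VAF is the ceiling set by the 5 %
noise.  PCA, blind to the per-channel delays, climbs gradually and still
has no elbow at five components (`None`), reproducing the qualitative gap
between the two model classes on delay-rich data.

The same pipeline is scriptable from the shell:

```sh
anechoid simulate --template gait-reach --trials 40 --noise 0.05 --seed 1 --out data/
anechoid select --in data/ --n-max 5 --restarts 25 --seed 1 --out report.json
anechoid fit --in data/ --n-sources 2 --seed 1 --out model.json
```

## Layout

| module | contents |
| --- | --- |
| `anechoid.io` | `TrajectorySet` container, CSV/JSON on-disk format, resample-and-smooth preprocessing |
| `anechoid.fourier` | truncated Fourier series, evaluation, circular delay operator |
| `anechoid.fada` | the anechoic demixing estimator and `AnechoicModel` |
| `anechoid.selection` | VAF, VAF sweeps, regression scree test, by-trial cross-validation, source alignment |
| `anechoid.pca` | correlation-matrix PCA baseline |
| `anechoid.events` | foot-event detection, gait-cycle/stance metrics, reach timing |
| `anechoid.simulate` | ground-truth mixture generator and gait marker fixture |
| `anechoid.cli` | `anechoid` command-line interface |
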