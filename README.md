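# synapse-capture

Quantitative analysis of **antigen capture in the B-cell immune synapse**
on supported lipid bilayers.

B cells acquire antigen by physically pulling it out of the membrane of an
antigen-presenting cell. Model experiments replace that cell with a glass-
supported planar lipid bilayer (PLB) carrying DNA-tethered hapten antigens:
a fluid DOPC bilayer lets antigens diffuse freely, a gel-phase DPPC bilayer
nearly immobilizes them. When the B cell ruptures the DNA tether by force,
a quenched Atto647N fluorophore lights up ("unquenching"), so every
extraction event appears as a new fluorescent spot in a live movie.

This package implements the full quantitative pipeline around that assay,
plus a synthetic-data generator that stands in for raw microscopy data:

| module | what it does |
| --- | --- |
| `synapse_capture.membrane` | closed-form membrane physics: surface viscosity η_m = η_mb·h and the diffusion prediction D = k_B·T·λ/(4π·η_m·R) |
| `synapse_capture.simulate` | generators for Brownian/fractional-Brownian tracks, FRAP curves, TIRF-style movies, extraction experiments, calcium traces, translocation images — all with ground truth |
| `synapse_capture.spt` | spot detection, trajectory linking, MSD, diffusion coefficient D and anomalous exponent α |
| `synapse_capture.frap` | FRAP normalization and mobile-fraction / half-time fitting |
| `synapse_capture.synapse` | cell segmentation, three concentric equal-width zones (recomputed per frame), unquenching-event detection, cluster and efficiency quantification, affinity discrimination |
| `synapse_capture.signaling` | calcium dF/F summaries, four-pattern classification, nuclear-to-cytoplasmic translocation scoring |
| `synapse_capture.stats` | SuperPlots-style experiment-mean aggregation, paired t tests, Pearson correlations, pipeline orchestration |

## Worked example

Predict how fast a DNA-tethered antigen diffuses on each bilayer, then
check the estimate by simulating single-particle tracking and refitting:

```python
from synapse_capture import membrane, simulate, spt

for spec in (membrane.DOPC, membrane.DPPC):
    print(spec.name, round(membrane.predict_diffusion_coefficient(spec), 3), "um^2/s")

tracks, truth = simulate.simulate_brownian_tracks(
    D=1.9, n_tracks=500, n_steps=100, dt=0.01, seed=1)
fits = spt.fit_tracks(tracks)
print("recovered D:", round(fits["D_um2_s"].mean(), 3), "um^2/s")
print("recovered alpha:", round(fits["alpha"].mean(), 3))
```

prints

```
DOPC 1.949 um^2/s
DPPC 0.055 um^2/s
recovered D: 1.855 um^2/s
recovered alpha: 0.98
```

The closed-form predictions (1.95 and 0.055 µm²/s) sit within a few
percent of the measured diffusion constants on the two bilayers (1.9 and
0.057 µm²/s), a 35-fold surface-viscosity contrast mapping onto a ~35-fold
mobility change. The refit of the simulated ensemble recovers the input D
within ~2 % and the Brownian exponent α ≈ 1 (the small negative bias is
the usual log–log finite-track effect).

The same pattern — simulate with known truth, analyze, compare — runs end
to end for FRAP, extraction movies, calcium traces and translocation
images; see `tests/` for executable examples of each.

A thin CLI wraps the library:

```sh
synapse-capture physics --eta-m 8.4e-11
synapse-capture simulate --kind extraction --seed 1 --out scratch/demo
synapse-capture report --config run.yaml --out report/
```

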