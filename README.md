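# fermsense

**Weighted-ensemble Gaussian-process soft sensor for batch fermentation
monitoring.**

Key biochemical parameters of a fermentation — biomass concentration
*X* (g/L), substrate concentration *S* (g/L) and relative product
activity *P* — can usually only be measured by slow offline assays,
while temperature, pH, dissolved oxygen and agitation are logged
continuously. A *soft sensor* estimates the former from the latter.
Batch fermentations are, however, multi-stage processes (lag /
exponential growth / stationary phase), and a single regression model
fitted to a whole campaign must compromise across regimes with very
different dynamics and noise.

`fermsense` implements a local-modelling pipeline for this problem:

1. **Variable selection.** Auxiliary channels whose grey-relational
   degree with the target exceeds 0.7 become model inputs.
2. **Partitioning (ADPC).** Adaptive density-peak clustering splits the
   training rows into local sample subsets. Each point gets a local
   density ρ_i = Σ_{j≠i} exp(−(d_ij/d_c)²) and a distance δ_i to the
   nearest denser point; the decision parameter D_i = ρ_i·lg δ̃_i is
   sorted descending and the relative-drop statistic
   γ*_i = (γ_{i−1}−γ_i)/(γ_i−γ_{i+1}) locates the boundary between
   cluster centers and the noise tail, so the number of clusters is not
   a user input.
3. **Sub-models (ISOA-GPR).** One Gaussian-process regression per
   subset (RBF kernel, exact Cholesky inference); the three log
   hyperparameters (ℓ, σ_f², σ_n²) are tuned by an improved seagull
   optimization algorithm whose migration weight follows the tangent
   schedule A(t) = −f_c·tan(t/T·π/4 − π/4).
4. **Gating and fusion.** Each subset is summarised by an
   entropy-weighted grey centroid Z_m = w ⊙ Z*. At prediction time the
   grey-relational degree ω_i between the test sample and each Z_m
   selects the sub-models with ω_i ≥ ω* = 0.7 (falling back to the
   single best), and their predictive means are fused as
   ŷ = Σ_i (ω_i/Σω)·ŷ_i — a convex combination.

Because real fermentation campaign data of this kind are proprietary,
the package ships a kinetic batch simulator (logistic growth with Monod
substrate limitation, Luedeking–Piret product formation, state-driven
environmental channels, batch-to-batch parameter jitter, constant-CV
assay noise and sampling-time jitter) that reproduces the benchmark
shape used throughout: 15 batches × 60 time points, the first 12
batches (720 rows) for training and the last 3 (180 rows) for testing.

## Worked example

```python
from fermsense import (
    generate_dataset, split_by_batch,
    WeightedEnsembleSoftSensor, GlobalGPRSoftSensor,
)

ds = generate_dataset(seed=0)              # 15 batches x 60 points
train, test = split_by_batch(ds, 12)       # 720 / 180 rows

res = WeightedEnsembleSoftSensor(train, target="X").fit(seed=0)
print(res.summary())

report = res.evaluate(test)
print(f"ensemble: rmse={report.rmse:.3f}  max|err|={report.max_abs_error:.3f}")

glo = GlobalGPRSoftSensor(train, target="X").fit(seed=0)
g = glo.evaluate(test)
print(f"global:   rmse={g.rmse:.3f}  max|err|={g.max_abs_error:.3f}")
```

prints

```
Weighted-ensemble GPR soft sensor
=================================
target: X    train rows: 720    seed: 0
aux selection (grey degree > 0.7): temperature=0.709, agitation=0.729, time_index=0.775
sub-models: 2    gating threshold omega* = 0.7    tuned by ISOA/nlml (pop 12, 30 iter)
------------------------------------------------------------------------------
 sub   rows  lengthscale  signal_var  noise_var    criterion
   1    350       0.4208       1.407      0.164       178.54
   2    370        5.566       13.43     0.6263       462.21
------------------------------------------------------------------------------
fit time: 5.8 s
ensemble: rmse=0.631  max|err|=2.104
global:   rmse=0.571  max|err|=2.094
```

The summary shows the selected inputs with their grey degrees, the two
regimes ADPC found (exponential growth vs stationary phase, 350 and 370
training rows) and the per-regime kernel hyperparameters — note the
short length-scale / low noise of the growth-phase model against the
long length-scale / higher noise of the stationary one. On this seed
the ensemble tracks the global baseline closely but does not beat it;
`docs/methods.md` explains when and why the two models differ and the
known limitations of the grey-relational gate.

The same pipeline is available from a shell:

```bash
fermsense simulate --out data.csv --batches 15 --points 60 --seed 7
fermsense fit --data data.csv --target P --out model.json --seed 7
fermsense predict --model model.json --data data.csv --out pred.csv
fermsense evaluate --model model.json --data data.csv --report report.json
fermsense baseline-compare --seed 7        # ensemble vs single-global table
```

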