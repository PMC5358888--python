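# rbcforecast

Quantitative forecasting of metabolite concentration time courses in stored
red blood cells (RBCs) from a small panel of extracellular biomarkers.

During refrigerated storage, RBC metabolism decays in a characteristic
multi-phase "storage lesion" spanning roughly 45 days. A handful of
extracellular metabolites (glucose, lactate, hypoxanthine, malate, xanthine,
…) track this decay closely. `rbcforecast` asks the quantitative question:
given only the measured time courses of five such biomarkers in a blood bag,
how well can the concentration profiles of the *other* metabolites be
predicted — and is that prediction genuinely better than a naive statistical
null?

The package is aimed at metabolomics and transfusion-medicine researchers who
have replicate-resolved concentration tables (blood bags sampled repeatedly
over storage) and want a validated, fully reproducible biomarker-to-metabolome
forecasting workflow.

## The model

Each target metabolite `y` is described by an Output-Error (OE) model of the
biomarker inputs `u_i`:

    y(t) = Σᵢ [Bᵢ(q) / Fᵢ(q)] uᵢ(t − nk) + e(t)
    B(q) = b₁ + b₂ q⁻¹ + … + b_nb q^−(nb−1)
    F(q) = 1 + f₁ q⁻¹ + … + f_nf q^−nf

with `q⁻¹` the one-sample delay operator. The selected configuration uses
`n = 5` biomarker inputs with `nb = 1`, `nf = 0`, `nk = 0` — a static linear
mixing, estimated per blood bag by closed-form least squares. Simulation
supports `nf > 0`; estimation is deliberately restricted to the FIR family
(`nf = 0`), where least squares is exact.

The workflow, per target metabolite:

1. **Split** the replicates (blood bags) into equal training and testing
   halves at random.
2. **Train an ensemble**: one OE model per training replicate.
3. **Predict** each test replicate's profile from its biomarkers alone, taking
   the per-time-point **median** of the ensemble members as the consensus.
4. **Score** with the symmetric mean absolute percentage error over the n
   time points, `SMAPE = (1/n) Σₜ |yₜ − ŷₜ| / (yₜ + ŷₜ)` ∈ [0, 1].
5. **Benchmark** against 10,000 naive random walks per metabolite (zero-mean
   Gaussian steps with the step size estimated from the testing replicates,
   started from measured starting values). The empirical p-value is the
   fraction of walks with lower SMAPE; a metabolite is predictable
   (significant) when p < 0.05.

Biomarker panels themselves are chosen by exhaustive subset search (all
C(8,5) = 56 five-of-eight combinations) under leave-one-replicate-out
cross-validation on the training half.

Because raw storage-study datasets are not bundled, the package ships a
synthetic-data generator (`rbcforecast.synthgen`) that emulates the
statistical shape of a 20-bag, 96-metabolite, 45-day study — three-phase
biomarker decay/accumulation, multiplicative blood-bag effects, proportional
measurement noise, linearly mixed signal targets with known coefficients,
pure-noise targets, and an optional mid-storage (day 31) dispersion artifact —
so every stage runs offline with ground truth available for validation.

## Worked example

Run the full pipeline on a default synthetic study (96 metabolites, 5
biomarkers, 20 bags, 14 sampling days, 10,000 walks per metabolite):

```sh
rbcforecast run --seed 1 --n-walks 10000 --outdir runs/demo
```

which prints:

```
rbcforecast run summary (runs/demo)
  metabolites: 96  time points: 14
  biomarker panel: BM01, BM02, BM03, BM04, BM05
  ensembles trained: 91 (10 members each)
  global median SMAPE: 0.0218 ± 0.0119 (sd of per-metabolite means)
  significant vs 10000 random walks: 85/91 (93.4%)
  train/test divergence flagged: 0.0% of cells
```

Reading the numbers: 91 non-biomarker metabolites each get a 10-member
ensemble; the median per-metabolite prediction error is ≈ 2.2% SMAPE; 85 of
the 91 metabolites (all 85 biomarker-driven targets, none of the 6 planted
pure-noise targets) are predicted significantly better than their random-walk
null; and no (metabolite, time point) cell shows a training/testing
divergence flag (Welch t-test, BH-FDR < 0.05 *and* > 20% mean difference).

The run directory contains every stage's output: `dataset.csv`,
`ground_truth.csv`, `anomaly_flags.csv`, `predictions.csv`,
`evaluation_summary.csv`, `divergence.csv`, `benchmark.csv`, serialized
models under `models/`, and the machine-readable `summary.json`. The same
workflow runs on real data via `rbcforecast benchmark <data.csv>
--biomarkers glc,lac,…` with the tidy CSV dialect described in
`docs/methods.md`.

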