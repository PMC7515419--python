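# bmecv

Bayesian/Maximum-Entropy (BME) reweighting of conformational ensembles
against averaged observables (NMR chemical shifts), with selection of the
confidence hyperparameter θ by interleaved train/validation
cross-validation, Wasserstein distribution diagnostics, secondary
chemical-shift preprocessing, and a seeded synthetic helix–coil benchmark
generator.

## What it does

Given per-frame calculated observables `s_ji` and target averages `y_i`
with uncertainties `σ_i`, BME minimizes

```
L(w) = (m/2) χ²_red(w) − θ S_rel(w)
```

over frame weights `w` on the simplex, balancing fit quality against the
Kullback–Leibler deviation from the prior (uniform) weights. The solution
has the exponential form `w_j ∝ w0_j exp(−Σ_i λ_i s_ji)`; the package
solves the convex dual in the m-dimensional λ space with a damped Newton
iteration, so N (frames) can be much larger than m (observables).

θ is chosen by a validation scan: odd frames are fit over a descending
log-spaced θ grid (warm-started), the λ are transferred to the even
frames, and θ* is the grid point minimizing the validation χ²
(`min_chi2_v`; an advisory `d_tv_elbow` rule locates the curvature knee of
the train/validation Wasserstein distance). The full ensemble is then
re-fit at θ*. Diagnostics include the entropy-based effective sample size
N_eff = exp(S_rel), λ RMS, a Wald–Wolfowitz runs test on residuals, and a
lag-1 frame-autocorrelation report.

The `synthetic` module builds seeded benchmark cases: a ground-truth
helix/coil ensemble scored with forward model A (whose column means are
the targets) and a mismatched prior ensemble scored with forward model B
(A plus conformation-dependent systematic offsets plus extra noise),
standing in for pairs of force-field ensembles scored with independent
shift predictors.

Note on the coil reference: secondary shifts subtract a random-coil
reference computed **per residue position** by default (average shift over
coil-assigned frames at that position, prior weights); `pool_residues=True`
collapses it to one value per atom kind.

## CLI

```
bmecv generate --config config.yaml --seed 1 --out case/
bmecv scan --calc case/prior_cs.tsv --targets case/targets.tsv \
           --target-calc case/target_cs.tsv \
           --theta-grid 100,0.001,30 --out scan/
bmecv fit  --calc case/prior_cs.tsv --targets case/targets.tsv \
           --theta 1.27 --out fit/
bmecv analyze --case case/ --weights fit/weights.tsv --out analysis/
```

`scan --secondary-cs --ss ... [--target-ss ...]` converts observables and
targets to secondary shifts before fitting. All file formats are plain
TSV (see module docstrings in `bmecv.ensemble`); every command writes a
`manifest.json` with seeds, input digests and the tool version.

## Acceptance

Release acceptance is property- and benchmark-based (dual/primal oracle
equivalence, stationarity, θ limits, scan monotonicity, overfitting
detection, helicity recovery, predictor-error and secondary-shift
experiments, Wasserstein and runs-test oracles); it lives in
`tests/test_acceptance.py`. The report script,

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs an end-to-end self-check and writes the (empty) numeric-target
report — there are no recomputable headline numbers, since the reference
quantities derive from unreleased MD trajectories.
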