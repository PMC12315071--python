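# hetstab

Does fine-scale substrate heterogeneity stabilise rocky-shore communities
over multiple years — and through which causal pathways?  `hetstab` is a
reusable analysis pipeline for paired-tile intertidal experiments: flat
versus pitted settlement tiles deployed in pairs at stations along an
emersion-stress gradient and surveyed seasonally by point-count image
subsampling.  It is aimed at community ecologists who want to go beyond
"does heterogeneity affect stability?" to "through which counteracting
mechanisms?".

The pipeline chains five analysis stages, each usable on its own:

1. **Synthetic community generator** — tile designs and percent-cover time
   series from a configurable ground-truth causal model (refugia,
   richness-mediated asynchrony, dominant suppression, consumer
   suppression), so every downstream stage can be validated against a
   known answer without any field data.
2. **Survey metrics** — per-tile, time-averaged species richness, Pielou
   evenness `J = H'/ln S`, and functional-group covers.
3. **Stability decomposition** — five per-tile metrics computed from
   linearly detrended cover series:
   - temporal stability `TS = mu_T / sigma_T` (inverse CV of total cover),
   - population stability `PS = sum(mu_i) / sum(sigma_i)`,
   - synchrony `phi = sigma_T^2 / (sum sigma_i)^2` (Loreau–de Mazancourt),
     with asynchrony `1 - phi`,
   - statistical averaging `SA = sum(sigma_i) / sqrt(sum sigma_i^2)`,
   - compositional stability `CS = 1 -` mean consecutive Bray–Curtis
     dissimilarity.

   Because the same detrended residuals enter every term, the
   decomposition identity `TS = PS * phi^(-1/2)` holds exactly.
4. **Mixed-effects models** — each tile-level response regressed on
   z-scored heterogeneity × emersion ratio with random intercepts for
   transect and station-in-transect (REML; Satterthwaite t tests, verified
   against lme4/lmerTest; Nakagawa marginal/conditional R²).
5. **Multigroup piecewise SEM and cascades** — a declarative causal DAG is
   fitted as a set of component mixed models; Shipley's union basis set
   yields d-separation claims combined into Fisher's
   `C = -2 Σ ln p ~ chi²(2k)`; paths are freed across shore zones when
   their edge × zone interaction is significant; and net heterogeneity
   effects are computed by summing products of significant standardised
   path coefficients along causal chains, with cluster-bootstrap
   uncertainty (stations resampled, tile pairs kept intact).

## Worked example

```bash
hetstab run --config configs/default.yaml --seed 42 --out out/
```

with `configs/default.yaml` containing:

```yaml
scenario: counteracting
n_boot: 300
seed: 42
```

prints:

```
hetstab 0.1.0 run
config hash: d9e93ca600bf   seed: 42
tiles: 70   censuses: 11   taxa: 20
Fisher's C = 259.91  df = 54  p = 0.0000
significant heterogeneity -> temporal-stability chains: 8
net heterogeneity -> temporal stability (high): -0.092 [-0.630, +0.134]
net heterogeneity -> temporal stability (low): +0.713 [-0.519, +2.314]
net heterogeneity -> temporal stability (mid): +0.223 [-0.143, +0.739]
```

Reading this: 70 tiles were simulated under the counteracting-pathways
scenario and pushed through metrics, stability decomposition, mixed
models, the multigroup SEM and the cascade computation.  Eight
significant heterogeneity-origin chains reach temporal stability across
the three shore zones (refugia, richness → asynchrony, dominant
suppression, consumer suppression), yet in every zone the bootstrap
interval for the net effect covers zero: the positive and negative
cascades cancel.  Fisher's C rejects here because the generator's
community dynamics are richer than the 11-node analysis DAG — on data
simulated from the DAG itself, C is close to its nominal distribution
(see `tests/test_acceptance.py`).

Intermediate tables (`design.csv`, `covers.csv`, `analysis_table.csv`,
`lmm_coefficients.csv`, `sem_edges.csv`, `sem_claims.csv`, `chains.csv`,
`cascades.csv`) are plain CSV with a one-line `#` header carrying the
config hash and seed, so any stage can be re-run on field data instead:
point `mode: csv` at your own `design.csv`/`covers.csv` with the same
columns.

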