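# sbspca

Stratified-bootstrap sparse PCA for unsupervised time-trend and
spill-marker screening in LC-HRMS non-target feature tables.

Non-target screening (NTS) of wastewater produces feature tables —
samples x (m/z, retention time) intensities — with hundreds to
thousands of features and no labels. The analytical question is which
features carry *temporally structured* signals: gradual trends,
periodic fluctuation, and especially spill events (left-sided, wide,
short-lived, right-sided or episodic exposure windows). Classical PCA
spreads loading weight across everything; this package implements a
sparsity- and stability-based alternative for analysts who need a
short, defensible candidate list from a time-ordered feature table.

## Method

Given an autoscaled matrix **X** (n time points x p features), sparse
components come from the regression formulation of PCA: alternate

1. **b**_j = argmin ‖X **a**_j − X **b**‖² + λ‖**b**‖² + λ₁‖**b**‖₁,
   with λ₁ chosen so **b**_j has exactly k = round((1−s)·p) non-zeros
   (s = targeted sparsity, λ = ridge penalty);
2. **A** ← polar factor of (XᵀX)**B** (orthonormal helper update),

then report unit-norm loadings **B**, scores **T** = X**B**, and
QR-adjusted explained variance R²ₐₐ/tr(XᵀX) per component.

Stability selection (SBS-SPCA) wraps this fit in a stratified
bootstrap: rows are resampled with replacement inside consecutive
5-point temporal strata, each replicate is re-autoscaled and fitted for
every configuration of a sparsity x ridge grid (default
{0.6,0.7,0.8,0.9} x {0.1,1,10,100}, 500 replicates, 10 components =
80,000 fits), replicate components are aligned to a full-data reference
by maximal-|cosine| matching, and each feature's **selection
frequency** per aligned component is recorded. Significance comes from
a permutation test (features permuted independently across time; null
frequencies pooled; p = (1+#{null ≥ obs})/(1+N)). Robust markers
combine frequency > 0.70 with p < 0.05. Downstream utilities choose
consensus penalties, fit the final fixed model with 99% score control
limits and top-10 loading rankings, compare peak tables from different
extraction tools by Procrustes dissimilarity, and aggregate candidates
that at least two tools support in the same component.

A seeded synthetic generator emulates the study designs (52 consecutive
daily samples with nine spiked spill-type targets, or 53 replicate
injections with eight trend-type targets) over a log-normal AR(1)
background with sensitivity drift, internal-standard channels,
non-detects and spiky artifacts, plus distorted "tool variant" tables —
so the whole pipeline is testable without any data download.

## Worked example

```python
import sbspca

table, registry = sbspca.generate_dataset(sbspca.GeneratorConfig(seed=1), "II")
Z, filtered, _, _ = sbspca.preprocess(
    table, sbspca.PreprocessParams(is_ids=[f"IS{i+1:02d}" for i in range(5)])
)
plan = sbspca.BootstrapPlan(n_reps=50, n_components=3,
                            grid=((0.6, 1.0), (0.7, 1.0)), seed=1)
stab = sbspca.run_sbs_grid(Z, plan, feature_ids=filtered.feature_ids)
for e in registry.entries:
    i = filtered.feature_ids.index(e.feature_id)
    print(e.feature_id, round(stab.freq[0, :3, i].max(), 2))
```

prints (seed 1, sparsity 0.6 / ridge 1):

```
T01_spill_left 0.9
T02_spill_left 0.94
T03_spill_wide 0.86
T04_spill_wide 0.86
T05_spill_short 0.62
T06_spill_short 0.7
T07_spill_short 0.56
T08_spill_right 0.72
T09_episodic 0.62
```

The persistent spills (left-sided, wide) are selected in ~86-94% of
bootstrap replicates within the first three components, while
short-lived and episodic spikes are markedly less stable — the
behaviour that motivates stability-based prioritization over a single
fit. `examples/` contains one narrative script per capability
(simulation, preprocessing + PCA, sparse PCA with control limits,
stability selection with p-values, Procrustes table comparison,
cross-tool prioritization), and the `sbspca` CLI exposes the same
stages as subcommands (`sbspca simulate --seed 1 --out run/ ...`).

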