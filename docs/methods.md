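# Methods

## Problem setting

Bulk RNA-seq studies of a progressive condition frequently observe only the
two ends of the process: control animals ("SN") and fully treated/affected
animals ("CN"), with no intermediate tissue collection. This package
simulates the unobserved intermediate transcriptome states with a generative
model, analyses the simulated time course with weighted co-expression
network methods, ties the resulting modules back to a behavioral trait
measured only in the real animals, and re-tests every gene for differential
expression *along* the simulated course, rescuing genes whose expression
rises and falls between the endpoints and is therefore invisible to an
endpoint-only comparison.

## Pipeline

1. **Normalization and augmentation** (`data_io`). Counts are converted to
   log2 CPM with a 0.5 pseudocount, `log2((c + 0.5)/(lib + 1) * 1e6)`;
   pre-normalized log-scale matrices are accepted verbatim. Because the real
   sample count is small, training data are expanded 10-fold per group with
   convex combinations `a*x_i + (1-a)*x_j` of random within-group pairs,
   `a ~ U(0,1)` (mixup-style). Augmentation is interpolation-only: every
   synthetic sample lies inside the per-gene min/max envelope of its group.
   The exact recipe behind "linear augmentation" is under-specified in the
   literature this follows; within-group random-pair mixing is the natural
   reading that preserves group identity, and is our choice.

2. **Adversarial training** (`gan`). A Wasserstein GAN with gradient penalty:
   critic loss `E[D(fake)] - E[D(real)] + lambda * E[(||grad_x D(x_hat)|| - 1)^2]`
   with `x_hat` sampled uniformly on segments between real and fake batch
   rows, generator loss `-E[D(fake)]`, `lambda = 10`, five critic updates per
   generator update, RMSprop for both players. Generator and critic are
   small fully connected leaky-ReLU networks implemented directly on NumPy;
   all gradients, including the forward-over-reverse pass that
   differentiates the gradient penalty with respect to the critic
   parameters, are derived analytically and verified against finite
   differences in the test suite. Training standardizes each gene to zero
   mean / unit variance (the inverse transform is stored with every
   checkpoint), which decouples the learning-rate scale from the absolute
   expression level.

   Desk-scale defaults: latent dimension 32, hidden widths (128, 128),
   batch 64, 2000 generator steps, RMSprop learning rate 1e-3, and 10
   generator checkpoints evenly spaced over the second half of training.
   The learning rate is deliberately larger than the 5e-5 used in
   multi-thousand-epoch WGAN training schedules: with a 2000-step budget the
   RMSprop-normalized parameter displacement must still reach O(1). All of
   this is exposed in `GanConfig`.

3. **Resembled fakes and latent interpolation** (`trajectory`). For each
   real sample and each checkpoint, 35,000 latent vectors are drawn from
   N(0, I); the 10 whose decoded profiles correlate best with the target are
   averaged into `z_bar`, requiring every selected correlation and the
   correlation of `G(z_bar)` itself to reach 0.95. If the draw fails, the
   pool is redrawn with a new derived seed, up to 20 retries, after which
   the failure (with the best correlation attained) aborts the run. For
   every control x treated pair the latent segment
   `z_i = z_SN + (z_CN - z_SN) * i/100, i = 1..99` is decoded, giving a
   101-timestep trajectory whose endpoints are the two resembled fakes.
   Trajectories are averaged over all pairs within a checkpoint, and the
   10 checkpoint-level averages form the repeat axis of the trajectory
   stack; their mean is the averaged profile all later stages use. Averaging
   over pairs before checkpoints is a memory-layout choice only — means
   commute — but the checkpoint-level slices are also the replica unit of
   the serial test below, which is a genuine modelling choice (the
   alternative, per-pair replicas, is available via `keep_pairs`).

   Large decoding batches run in float32 (the rounding, ~1e-7 relative, is
   far below the data's noise scale and an order of magnitude faster here);
   training and all gradient math stay in float64. One consequence is that a
   profile decoded alone and the same profile decoded inside a batch can
   differ in the last float bits (BLAS blocking), so equality tests compare
   at 1e-6, not bitwise.

4. **Network construction** (`wgcna`). On the timestep x gene averaged
   profile: soft-thresholded correlation adjacency, topological overlap
   matrix `w_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 - a_ij)`, average-linkage
   clustering of `1 - TOM`, static cut at 0.8 of the maximum merge height,
   minimum module size 10 (desk scale), modules renumbered by size. The
   soft-threshold power is the smallest beta in 1..20 whose scale-free fit
   index (R^2 of the log-log degree distribution, signed against positive
   slopes) reaches 0.8; when no beta qualifies — simulated trajectories are
   smooth and strongly modular, so they often do not — the power maximising
   the index is used, floored at 6. The default network is **signed**,
   `a = ((1+r)/2)^beta`: trajectory archetypes that mirror each other
   (monotonically rising vs falling) are distinct biology and an unsigned
   network would merge them by construction. The unsigned variant `|r|^beta`
   is one config switch away.

5. **Module-trait alignment** (`wgcna.module_trait_alignment`). Module
   eigengenes (unit-variance first principal components of the standardized
   module block) are recomputed **in the real samples**, where the
   behavioral trait exists; the sign is linked to the simulated-profile
   eigengene through the correlation of the two loading vectors. A module
   passes when the Pearson correlation with the trait has `p < 0.05` (exact
   t transform, no multiple-testing correction, matching the stated
   criteria; BH is available) and `|r| > 0.5`.

6. **Temporal network** (`temporal`). Each module is aligned to the argmax
   timestep of its simulated eigengene (ties to the earliest timestep, so a
   constant eigengene lands at t=0 — a documented artifact), staged
   early/mid/late with boundaries 10 and 90 on the 0..100 scale (invented,
   configurable), and connected to other modules by the Pearson correlation
   of eigengene time profiles at |r| >= 0.5. Within a stage, modules are
   split into two pattern groups by average-linkage clustering of `1 - r`.
   An alternative alignment to the peak of |first difference| (where a
   module changes fastest) is available for the monotone modules for which
   the peak rule is uninformative.

7. **Serial and rescued differential expression** (`rdeg`). Treating the
   checkpoint-level trajectories as replicas, every timestep t >= 1 is
   tested against t = 0 with a paired moderated t: gene-wise variances are
   shrunk as `s2_post = (d0*s0^2 + d*s^2)/(d0 + d)` where the prior `(d0,
   s0^2)` is estimated from all genes by matching the mean and variance of
   `log s^2` (digamma/trigamma moment equations — verified to reproduce
   limma's `eBayes` prior and p-values to machine precision on a frozen
   two-group dataset). Pairing is used because repeats share a checkpoint;
   an unpaired mode exists and makes the two-timestep special case
   identical to the conventional endpoint test. A gene is a serial hit at t
   when `|log2FC| >= 0.2` and `p <= 0.05`; thresholds follow the stated
   criteria and are uncorrected across genes and timesteps (the per-timestep
   size is calibrated; the any-timestep union rate is reported, not
   controlled). `rescued = serial hit AND not significant at the endpoints`.

8. **Enrichment** (`enrichment`). Upper-tail hypergeometric test of module
   genes against flat GMT gene sets, universe = all genes in the analysed
   matrix. Odds ratios use a Haldane +0.5 correction when a 2x2 cell is
   empty. The per-module primary term is the most significant term with
   `p < 0.05` among terms of effective size <= 50; the size cutoff is
   interpreted as a *maximum* (favouring specific terms), switchable to a
   minimum. Ontology structure (term ancestry, conditional tests) is out of
   scope: collections are flat sets.

## Synthetic study conditions

`synth.make_synthetic` emulates the two-endpoint design: 300 genes, five
planted modules of 50 genes (the rest background), 12 samples per group.
Gene `g` in module `m` of sample `s` is
`baseline_g + loading_g * A_m(s) + N(0, 0.25^2)`, with per-gene baselines
U(4, 12) (log2 CPM scale), loadings U(0.7, 1.3), and module activity
`A_m(s) = archetype_m(t_s) + N(0, 0.3^2)` where `t_s` is 0 (SN) or 100 (CN).
Archetypes: linear rise to the 2.0 log2-unit effect size (carries the
trait), linear fall, Gaussian bumps centred at t=40 and t=60 (sd 15 — their
endpoint fold change is ~0, their peak fold change is the full effect; these
are the genes only the serial test can find), and flat. The treated-sample
trait is the trait module's activity plus N(0, 0.1^2), clipped at zero;
controls are zero. A negative-binomial count mode (dispersion 10, library
~3e6) feeds the log-CPM path end to end. `truth_stack` generates
trajectory-driven repeat x timestep x gene data directly from the planted
archetypes, bypassing the generative model, to validate the network and
serial-testing stages against known truth.

What the fixture does *not* emulate: empirical count-depth heterogeneity,
gene-gene correlation outside planted modules, batch structure, and
non-Gaussian biological variability. Passing tests therefore demonstrate
correctness of the machinery and recoverability under the planted model,
not performance on any particular real dataset.

## Numerical and design notes

- Every stage derives its RNG streams from one global seed via
  `SeedSequence`; reruns are bitwise reproducible (up to the float32 batch
  note above).
- Module recovery is scored by adjusted Rand index over the genes planted in
  modules, with detected "unassigned" as its own cluster. Background genes
  are excluded — the method never claims to partition noise — and planted
  *flat* modules are retained: a time-course detector must leave them
  unassigned, and the score reflects that.
- Genes with zero variance over the trajectory are dropped from network
  construction with a warning and reported as unassigned.
- Degenerate inputs: a single-gene module's eigengene is the standardized
  gene; a zero-variance trait or target vector raises instead of emitting
  NaN correlations; non-finite training losses abort with diagnostics.
- Per-region studies run the pipeline once per region label; cross-region
  aggregation is a report-level join.

## Problem sizes

Defaults throughout are desk scale, chosen so the full study (augment,
train 2000 generator steps, 240 resembled fakes at 35,000 candidates each,
2.4 million decoded intermediate profiles, network + alignment + serial
testing) completes in a few minutes on one CPU core. All sizes are config
fields; nothing in the code assumes the defaults.

## Known limitations

- The static dendrogram cut is simpler than hybrid dynamic tree cutting;
  on data with nested module structure it will merge or shred modules that
  adaptive cutting would resolve.
- The scale-free criterion rarely holds on smooth simulated trajectories;
  the fallback power is a heuristic, as is any soft-threshold choice.
- Peak alignment is uninformative for monotone modules (they pin to the
  endpoints); the differential-alignment mode mitigates but does not remove
  this.
- The serial test's replicas are model snapshots, not biological samples;
  its p-values quantify reproducibility across generator checkpoints and
  should be read as screening statistics, not population inference.
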