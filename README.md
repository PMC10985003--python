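# methplier

Knowledge-constrained matrix factorization for DNA methylation arrays,
with probe-to-transcript PCA compression and transfer decomposition of
new cohorts against a frozen latent matrix.

## Who this is for

Methylation cohorts preprocessed with different pipelines (Genome
Studio, SWAN, BMIQ, PBC, ...) or measured on different platforms (HM450
arrays vs. WGBS/RRBS) have systematically different beta-value
distributions, which frustrates cross-dataset comparison and
meta-analysis. This package lets you train a biologically labelled
latent space once on a large reference cohort, then express any new
cohort — array or lifted-over bisulfite data — as loadings in that same
space, where pipeline and platform bias is attenuated and group
structure is preserved.

## The model

Probe betas are first compressed per transcript: probes within 1500 bp
of the TSS are decomposed by PCA across samples, and the leading
principal-component scores covering >= 80% of variance become the
transcript's features. The compressed matrix **D** (features x samples)
is then factorized under a gene-set prior **C** (binary features x
sets):

```
min  ||D − ZB||²_F + λ₁||Z − CU||²_F + λ₂||B||²_F + λ₃||U||_L1
s.t. U ≥ 0,  Z ≥ 0
```

**Z** (features x k) holds the latent variables (LVs), **B** (k x
samples) the per-sample loadings, and **U** (sets x k) sparsely couples
each LV to at most `max_path = 10` gene sets, so LVs come with readable
biological labels. The U penalty is an elastic net with L1 fraction 0.9;
λ₃ is adapted until at least 70% of LVs carry a prior association. A new
cohort **D'** is decomposed with **Z** frozen:
`B' = (ZᵀZ + λ₂I)⁻¹ZᵀD'`.

Downstream utilities cover the standard loading-matrix analyses: Ward
hierarchical clustering, Hartigan–Wong k-means, UMAP embedding, per-LV
Welch t tests with Benjamini–Hochberg FDR, two-group log-rank tests, and
per-probe differential-methylation calling, plus an exact-coordinate
liftover from per-CpG bisulfite calls to array probes.

## Worked example

Everything can be exercised on synthetic data with a planted ground
truth — no downloads needed:

```python
import methplier as mp

manifest = mp.simulate_manifest(n_genes=120, seed=17)
beta, gene_sets, truth = mp.simulate_plier_dataset(manifest, seed=17)

probe_map = mp.select_region_probes(manifest, mode="tss_window", window_bp=1500)
gene_map = manifest.drop_duplicates("transcript_id").set_index("transcript_id")["gene"]
cmodel, scores = mp.fit_compression(beta, probe_map, cum_threshold=0.8,
                                    transcript_gene_map=gene_map)
print(f"{beta.shape[0]} probes -> {cmodel.n_features} features "
      f"over {len(cmodel.transcripts)} transcripts")

K = mp.build_feature_knowledge(gene_sets, scores.feature_gene, min_genes=10)
D = mp.align_to_knowledge(scores, K)
model = mp.fit(D, K, mp.PlierConfig(k=6, seed=17))
print(f"converged={model.converged} after {model.n_iter} iterations; "
      f"{model.prior_associated_fraction():.0%} of LVs carry a gene set")

loadings = mp.transfer_loadings(D, model)
diff = mp.differential_lv(loadings, truth.groups)
print(diff.head(3).round(4))
```

prints

```
720 probes -> 167 features over 120 transcripts
converged=True after 45 iterations; 100% of LVs carry a gene set
     mean_A  mean_B       t    p    q
LV
LV4  0.2645 -0.2645  9.4956  0.0  0.0
LV1  0.2136 -0.2136  8.4794  0.0  0.0
LV2 -0.1780  0.1780 -4.6198  0.0  0.0
```

The 720 simulated probes compress to 167 transcript-level PC features;
the factorization converges in 45 of the 350 allowed iterations with
every LV tied to at least one gene set; and the Welch tests on the
transfer loadings flag the LVs that the simulation actually shifted
between the two sample groups (here LV4, LV1 and LV2 head the table at
q ≈ 0, i.e. far below an FDR of 0.05).

The same stages are available from the shell:

```sh
methplier simulate --preset default --seed 17 --out fixtures/
methplier compress --beta fixtures/beta.tsv --manifest fixtures/manifest.tsv \
    --mode tss_window --window 1500 --cum-var 0.8 --out cmodel/
methplier fit --data cmodel/scores.tsv --gmt fixtures/gene_sets.gmt \
    --feature-genes cmodel/feature_gene.tsv --k 6 --seed 17 --out model/
methplier transfer --data cmodel/scores.tsv --model model/ --out B_new.tsv
```

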