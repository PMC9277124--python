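# mmconn — multimodal brain-network group analysis

`mmconn` is a reusable, tested implementation of the graph-theoretic
connectome comparison widely used in clinical neuroimaging: build
functional and structural brain networks per subject, binarize them over a
threshold sweep, compute global and nodal network properties with
random-graph normalization, probe resilience under node attack, and compare
a patient group against controls with permutation statistics, FDR
correction and clinical-score correlation.  It is aimed at researchers who
have already extracted per-region signals from imaging data (or want to
study the analysis itself on simulated cohorts) and need the downstream
network statistics to be reproducible and unit-tested.

## The analysis

**Inputs.** Per subject: a regions × timepoints matrix of mean ROI time
series (functional arm) and/or an FA-weighted symmetric connectivity matrix
from tractography (structural arm, FA = fractional anisotropy ∈ [0, 1)),
plus a manifest CSV (`subject_id, group, hamd, ts_path, fa_path`) with
`group ∈ {patient, control}` and a HAMD-like clinical score.

**Networks.** Functional connectivity is the pairwise Pearson correlation
of region time series, Fisher-Z transformed (z = atanh r).  Undirected
binary networks are formed either by *sparsity* thresholding — keep the
K = round(s·N(N−1)/2) strongest positive weights, swept over
s = 26%–50% in 1% steps — or by an absolute FA cutoff, swept over
0.20–0.42 in 0.02 steps.

**Graph properties.** For a binary graph G with distances d(i,j):

- clustering coefficient C (mean of 2Tᵢ/kᵢ(kᵢ−1)), characteristic path
  length L (mean d over connected pairs);
- global efficiency E_glob = ⟨1/d(i,j)⟩ over all pairs, local efficiency
  E_loc (mean efficiency of neighbor subgraphs), nodal efficiency
  E_nod(i) = (1/(N−1)) Σ_j 1/d(i,j);
- normalized indices γ = C/⟨C_null⟩, λ = L/⟨L_null⟩ and small-worldness
  σ = γ/λ, where the null is an ensemble of degree-preserving
  double-edge-swap randomizations of G.

**Resilience.** Nodes are deleted one at a time — in descending betweenness
order computed once on the intact graph (targeted attack) or in random
order averaged over replicates (random attack) — while recording global
efficiency with a fixed denominator; curves are summarized by their
normalized area under the curve (AUC).

**Inference.** Group differences (patient mean − control mean) are tested
with label-permutation tests, p = (#{|perm| ≥ |obs|}+1)/(n_perm+1)
(5,000 permutations by default), Benjamini–Hochberg FDR-corrected across
the thresholds of each metric and across regions for nodal tests
(q = 0.05).  Nodal efficiency of flagged regions is correlated with the
clinical score within the patient group (Pearson r, t-distributed p).

**Synthetic cohorts.** Because such studies rarely deposit raw MRI,
`mmconn.synthdata` generates seeded cohorts (default 42 patients / 38
controls, 246 regions, 230 timepoints) from a Watts–Strogatz small-world
backbone, with planted, recoverable group effects: attenuated connectivity
on edges incident to hub regions (functional), FA shifts on affected edges
(structural), and a clinical score linear in a designated region's nodal
efficiency.  Ground truth is written alongside the data, so every pipeline
stage can be validated by planted-effect recovery.

## Worked example

```python
from mmconn import RunConfig, run_pipeline

# 60-region reduced profile: synthetic 42/38 cohort, 1,000 permutations
res = run_pipeline(RunConfig.reduced("out/demo", seed=42))

comp = res.comparisons
lam = comp[(comp.modality == "functional") & (comp.metric == "lambda")]
print("lambda flagged at", int(lam.significant.sum()), "of 25 sparsity thresholds")
print(lam[lam.threshold.isin([0.26, 0.38, 0.50])]
      [["threshold", "patient_mean", "control_mean", "p_perm", "p_fdr"]])
```

prints (about a minute on one core):

```
lambda flagged at 22 of 25 sparsity thresholds
 threshold  patient_mean  control_mean   p_perm    p_fdr
      0.26      1.011663      1.056367 0.000999 0.001249
      0.38      1.014622      1.007066 0.000999 0.001249
      0.50      1.000323      1.000000 0.000999 0.001249
```

i.e. the planted hub lesion shifts the normalized path length λ of the
patient group across most of the sweep (lower than controls at the
strictest thresholds, higher from mid-sweep up), and the permutation tests
flag it after FDR correction.  The nodal table ranks regions by p with
group means ± SD per region, and the attack stage shows the lesioned
patients' networks collapsing faster under targeted attack:

```
region  patient_mean  patient_sd  control_mean  control_sd   p_perm
   R00      0.582002    0.026867      0.614407    0.033909 0.000999
   R03      0.602737    0.024988      0.647487    0.049742 0.000999
targeted-attack AUC, patient minus control: -0.0332 (p=0.000999)
```

The same run writes `metrics_global.tsv`, `metrics_nodal.tsv`,
`comparisons.tsv`, `nodal_comparisons.tsv`, `attack_*.tsv`,
`correlations.tsv` and `summary.json` under `out/demo/`.

From the shell, the same pipeline (and its individual stages) is exposed as
a CLI:

```bash
mmconn simulate --reduced --seed 42 --out out/cohort
mmconn run-all  --reduced --seed 42 --out out/demo
mmconn run-all  --manifest out/cohort/manifest.csv --reduced --seed 42 --out out/demo2
```

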