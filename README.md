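# richconn

Rich-club organization analysis of structural brain connectomes, built for
group studies that contrast patient populations (here: major depressive
disorder with vs. without suicidal ideation vs. controls) on diffusion-MRI
structural networks. The package takes per-subject weighted connectivity
matrices (streamline counts over an AAL-style 90-region parcellation) and
runs the complete analysis chain a connectome study needs:

1. **Network construction** — streamline-count filtering (> 3), sparsity
   thresholding across a sweep (0.05–0.20, step 0.01), metric integration
   over the sweep.
2. **Graph metrics** — clustering C, path length L, small-worldness
   σ = (C/C_rand)/(L/L_rand), global/local efficiency, modularity Q, and
   nodal degree (Dc), efficiency (Ne), betweenness (Bc), plus a hemispheric
   asymmetry index (X_L − X_R)/(X_L + X_R).
3. **Rich club** — Φ(k) = E_{>k} / [N_{>k}(N_{>k}−1)/2], normalized by
   degree-preserving (Maslov–Sneppen) rewired nulls:
   Φ_norm(k) = Φ(k)/⟨Φ_rand(k)⟩, with permutation p per degree level;
   hub identification on 80%-occurrence group-average networks; and the
   rich / feeder / local edge decomposition with sweep-integrated class
   strengths.
4. **Inference** — covariate-adjusted permutation tests (10,000 default)
   with Bonferroni control over nodes (0.05/90), partial correlations with
   symptom scores, and the network-based statistic (NBS): per-edge t maps,
   supra-threshold components, family-wise p from the permutation
   distribution of the largest component.
5. **Circuits** — mapping differential edges onto six depression-related
   circuits (DMN, salience, negative/positive affect, attention, cognitive
   control) defined over AAL labels.
6. **Classification** — t-filter + min-max + RBF-SVM under leave-one-out
   cross-validation with ROC/AUC and label-permutation significance.

Because clinical DTI cohorts of this kind are not publicly deposited, the
package includes a first-class synthetic-cohort generator
(`richconn.synthetic`) that plants a known rich club (11 hubs: bilateral
putamen, precuneus, thalamus, insula, caudate + left ACC) and
feeder/local-restricted group effects, so every stage of the pipeline is
validated against ground truth. See `docs/methods.md` for the full model
description and its limitations.

## Worked example

The numbered drivers under `analysis/` run a complete simulated study
(three groups, 90 nodes, one shared seed in `analysis/study_config.py`):

```bash
python analysis/01_simulate_cohort.py
python analysis/03_richclub_decomposition.py
```

which prints (abridged):

```
common hubs across groups (9): ACG.L, CAU.R, INS.L, INS.R, PCUN.L, PUT.L, PUT.R, THA.L, THA.R
  CN: Phi_norm > 1 (p < 0.05) for K in [11, 28]
  MDDNSI: Phi_norm > 1 (p < 0.05) for K in [7, 26]
  MDDSI: Phi_norm > 1 (p < 0.05) for K in [11, 27]

sweep-integrated connection strengths (group means):
edge_class  feeder   local    rich
group
CN          3795.3  3647.7  1273.0
MDDNSI      3302.0  3302.2  1339.1
MDDSI       2919.8  3134.3  1315.2
```

Nine of the eleven planted hubs survive the per-group-intersection at this
reduced cohort size; all three groups show a significant rich-club regime
(Φ_norm > 1), and the integrated feeder/local strengths — the classes the
generator weakens in the patient groups — drop monotonically from CN to
MDDNSI to MDDSI while rich-club strength is preserved. The inference and
classification drivers continue the story:

```bash
python analysis/04_group_inference.py   # NBS: CN vs MDDSI -> one 220-edge
                                        # component, p_fwe = 0.0005
python analysis/06_classification.py
```

```
best connection class per contrast:
  CN_vs_MDDNSI: feeder_connections (AUC 0.985)
  CN_vs_MDDSI: feeder_connections (AUC 1.000)
  MDDNSI_vs_MDDSI: feeder_connections (AUC 1.000)
```

Feeder connections discriminate best in every pairwise contrast — the
qualitative signature the analysis is designed to detect.

The same pipeline runs on real data by pointing a `RunConfig` (or the
`richconn` CLI) at a cohort manifest:

```bash
richconn all --manifest cohort/manifest.tsv --node-table cohort/nodes.tsv \
         --out-dir results/real --seed 7
```

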