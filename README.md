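# dtafusion

Drug–target affinity (DTA) regression with structure-aware graph encoders
and early fusion.

Screening campaigns need continuous binding-strength estimates — pKd values
or KIBA scores — for drug–kinase pairs long before crystal structures or
assay panels exist. `dtafusion` predicts the affinity `A = F_θ(P, D)` of a
small molecule `D` against a protein target `P` from structure-aware graph
representations of both sides:

* the **drug** is a heavy-atom molecular graph encoded twice — by a top-S
  sparse self-attention encoder whose logits carry three structural biases
  (learnable degree-centrality embeddings, per-shortest-path-distance-bucket
  scalars, and bond features averaged along each atom pair's shortest path),
  interleaved with convolution + ELU + strided-max-pool distillation blocks;
  and by a permutation-invariant GCN encoder
  (`H_i = ReLU(D̃^{-1/2}(A+I)D̃^{-1/2} H_{i-1} W)`) with residual blocks and
  global max pooling that yields a drug super-node vector `x_d`;
* the **protein** is a residue contact graph (non-adjacent residues closer
  than 8 Å, plus backbone edges) whose nodes concatenate per-residue
  sequence embeddings, one-hot 8-state secondary structure and relative
  solvent accessibility;
* **early fusion** stacks `x_d` as a super node onto the residue graph with
  cross edges to every residue, refines the heterograph jointly with GCN +
  residual blocks, separates drug and protein rows by a node mask, and a
  fully connected head emits the scalar affinity.

Training minimises MSE with Adam; evaluation reports MSE, RMSE, Pearson,
Spearman, concordance index (ties count 0.5) and r². Everything runs on a
built-in NumPy reverse-mode autodiff engine — no GPU framework required —
and a synthetic-data module generates valid molecules, plausible protein
records and planted-signal labels so the whole pipeline is testable offline.

## Worked example

```python
from dtafusion import AffinityModel, Hyperparameters, FixtureSpec, gen_dataset

# 50 synthetic pairs (10 drugs x 5 proteins), label noise sigma = 0.1
table = gen_dataset(FixtureSpec(n_drugs=10, n_proteins=5, noise_sigma=0.1, seed=11))
hp = Hyperparameters(epochs=300, lr=0.001, seed=1)
results = AffinityModel(table, hp=hp).fit()
print(results.summary("test"))
```

```
Drug-Target Affinity Regression Results
===============================================
No. pairs (total)                            50
No. pairs (test)                              8
Epochs run                                  300
Final train MSE                          0.0367
Seed                                          1
Hidden / d_model                       256 / 32
-----------------------------------------------
MSE                                      0.0592
RMSE                                     0.2432
PEARSON                                  0.9930
SPEARMAN                                 0.9940
CI                                       0.9821
R2                                       0.9187
===============================================
```

The model is trained on the 42 non-test pairs (a seeded six-part split
reserves 8 pairs as the independent test set) and drives the training MSE
close to the σ² = 0.01 noise floor; on the held-out pairs the planted
descriptor signal — which includes a drug×protein interaction term that
neither branch alone can fit — is recovered with near-perfect ranking
(CI 0.98) and r² ≈ 0.92. `results.evaluate("test")` returns the same
numbers as a `MetricReport`; `results.predict("test")` yields per-pair
`(drug_id, protein_id, y_true, y_pred)` rows.

The same workflow is scriptable from the shell:

```sh
dtafusion synth --n-drugs 10 --n-prots 5 --seed 11 --out data/
dtafusion train --data data/ --out run/ --epochs 300
dtafusion evaluate --pred run/predictions.tsv
```

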