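# ecmc — consensus/disagreement kernel decomposition for multi-view clustering

Multi-omics studies routinely measure the same patients through several
*views* — mRNA expression, DNA methylation, miRNA expression — and ask for a
single clustering of the patients (e.g. cancer subtypes). Each view carries
some clustering signal shared with the other views and some structure of its
own; when the view-specific structure is strong, naive integration (summing
kernels, concatenating features) clusters the noise. This package implements
two Hilbert–Schmidt-Independence-Criterion (HSIC) based kernel models that
separate the two:

- **CMC** (consensus multi-view clustering) reconstructs one unit-trace PSD
  kernel `K_i` per view by maximizing

  `Σ_i tr(W_i H K_i H) + λ Σ_{i≠j} tr(K_i H K_j H)`,

  preserving each input kernel `W_i` while pushing the reconstructions to
  agree across views (`H = I − ee'/n` is the centering matrix; `tr(K H L H)`
  is the empirical HSIC agreement between kernels).

- **ECMC** (enhanced CMC) decomposes each view's reconstructed kernel into a
  consensus part `C_i` and a disagreement part `D_i`, maximizing

  `Σ_i tr(W_i H (C_i + D_i) H) + α Σ_{i≠j} tr(C_i H C_j H) − β Σ_{i,j} tr(C_i H D_j H)`

  subject to `C_i, D_i ⪰ 0`, `tr(C_i) = tr(D_i) = 1`. The disagreement parts
  soak up view-specific structure and are discarded; clustering runs on the
  summed consensus `Σ_i C_i` only.

Both models are fitted by alternating block updates, each of which is an
exact solve of `max tr(MC)` over the unit-trace PSD simplex (the top
eigenprojector of `M`). Downstream, the package provides normalized spectral
clustering with replicated k-means, evaluation metrics (NMI, clustering
accuracy with optimal label matching, silhouette), per-view consensus
scores, and the two synthetic two-view generators used to validate the
method, all behind a library API and a `ecmc` command-line tool.

## Worked example

```python
import ecmc

# two-view dataset with a planted 50/50 clustering and a strong
# view-specific disagreement block (scale t = 2)
data = ecmc.simulate1(t=2.0, seed=3)

fit = ecmc.ecmc_fit(data.views, alpha=1.0, beta=1000.0)
consensus = ecmc.combine_consensus(fit.C_list)
clust = ecmc.spectral_cluster(consensus, k=2, n_replicates=100, seed=3)
report = ecmc.evaluate_replicates(clust.replicate_labels, data.truth)
print(f"NMI {report.nmi_mean:.3f} +/- {report.nmi_se:.3f}, "
      f"ACC {report.acc_mean:.3f}")
print("consensus scores:", [round(s, 3) for s in fit.consensus_scores])
```

prints

```
NMI 1.000 +/- 0.000, ACC 1.000
consensus scores: [0.239, 0.226]
```

(plus a `RuntimeWarning` that the iterates were still drifting at the
iteration cap — at strong independence pressure the rank-one blocks rotate
along a flat ridge after the objective has settled; see `docs/methods.md`.)

At t = 2 each raw kernel is dominated by the disagreement block — spectral
clustering on the raw kernels alone misplaces roughly half the samples —
yet the consensus decomposition recovers the planted clustering exactly.
The consensus scores (fraction of each input kernel's centered signal
absorbed by the consensus part) are low, correctly reporting that most of
the raw kernel energy was view-specific and discarded.

The same pipeline from the shell:

```bash
ecmc simulate --family sim1 --t 2 --seed 3 --out sim/
ecmc grid --views sim/view1.tsv --views sim/view2.tsv \
     --truth sim/truth.tsv --k 2 --seed 3 --out run/
cat run/best.json
```

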