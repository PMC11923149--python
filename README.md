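# pocketec

Enzyme function prediction from 3D structure, using only the region around a
binding site.

Enzymes are annotated with Enzyme Commission (EC) numbers — four hierarchical
levels `main.sub.subsub.designation`, e.g. `2.7.10.1` for a receptor
protein-tyrosine kinase (a transferase `2`, transferring
phosphorus-containing groups `2.7`, as a protein-tyrosine kinase `2.7.10`).
Fold-based prediction leaks: enzymes with near-identical folds can catalyze
different reactions, and sequence-cluster-respecting ("fold") splits expose
this.  `pocketec` instead classifies a *localized 3D descriptor* — the *n*
closest residues or heavy atoms around a binding-site center, or everything
within a radius *r* — with geometry-aware message-passing networks:

- **distances**: continuous-filter convolutions,
  x_i ← x_i + f(Σ_j x_j ∘ W(d_ij)), with filters generated from a Gaussian
  radial basis expansion e_k(d) = exp(−γ (d − μ_k)²);
- **distances + angles**: directional message passing over per-edge messages
  m_ji, modulated by a spherical Fourier–Bessel basis of the pair
  (d_kj, α_(kj,ji)) for every edge pair (k→j, j→i).

Nodes are typed by amino acid (residue resolution, at Cα positions) or by
chemical environment in a force-field-style 31-class heavy-atom vocabulary
(atom resolution), so one element can occupy several classes.  Both networks
are invariant to rigid motions and node permutation by construction.  The
package also provides fold-bias-free data splitting, binding-site ingestion
(pocket-prediction tables, homolog-ligand transfer, random-center controls),
class-imbalance-aware training (weighted cross-entropy
l_n = −Σ_c ω_c y_{n,c} log softmax_c(x_n), oversampling), protein-centric
F-score / per-class AUPR evaluation, structure-perturbation benchmarking
(alanine scans, coordinate translation), and a softmask node-importance
explainer optimizing l(y, ŷ) + β₁·mean(F) + β₂·mean(H(F)) with
H = −F log(F+c) − (1−F) log(1−F+c).

It is aimed at structural bioinformaticians who want to train, probe, or
extend localized structure-based function classifiers without GPU
infrastructure: the networks run on a compact NumPy automatic-differentiation
engine shipped with the package.

## Worked example

Train on synthetic planted-motif enzymes: helical chains in which a local
residue motif near the binding-site center determines the class.  The fold
split holds out whole sequence lineages, so the classifier must learn the
motif, not the background.

```python
from pocketec import GraphNetClassifier, build_pocket_graph, default_scheme, make_dataset
from pocketec.datasplit import fold_split

scheme = default_scheme()
ds = make_dataset(n_per_class=12, seed=0)

graphs = {s.source_id: build_pocket_graph(s, site, scheme, cut_mode="count", cut_param=12)
          for s, site, _ in ds.items}
split = fold_split(ds.clustering, ds.labels, seed=0)
part = {p: split.partition(p) for p in ("train", "val", "test")}
X = {p: [graphs[i] for i in part[p]] for p in part}
y = {p: [str(ds.labels[i]) for i in part[p]] for p in part}

clf = GraphNetClassifier(embedding_dim=32, n_filters=32, n_interactions=2,
                         n_rbf=24, max_epochs=60, patience=60, random_state=0)
clf.fit(X["train"], y["train"], X_val=X["val"], y_val=y["val"])

print("classes:", clf.classes_.tolist())
print(f"train accuracy: {clf.score(X['train'], y['train']):.3f}")
print(f"test accuracy:  {clf.score(X['test'], y['test']):.3f}")
for label, conf in clf.predict_with_confidence(X["test"][:3]):
    print(f"predicted EC {label}  (confidence {conf:.2f})")
```

Output:

```
classes: ['1.1.1.1', '2.7.10.1', '3.4.21.4', '4.2.1.11']
train accuracy: 1.000
test accuracy:  0.750
predicted EC 1.1.1.1  (confidence 1.00)
predicted EC 4.2.1.11  (confidence 0.53)
predicted EC 3.4.21.4  (confidence 0.96)
```

The train accuracy of 1.000 shows the network fits the pockets it has seen;
the test accuracy of 0.750 (chance = 0.25) is measured on sequence lineages
never seen in training, so it reflects what the model learned about the
site-local signal rather than memorized backgrounds.  At this miniature size
(12 structures per class) generalization is noisy; the standard benchmark in
`pocketec.benchmark` (40 per class) reaches held-out accuracies of 0.8–1.0.
Per-class confidences come from the softmax; coarser EC levels follow by
truncation, e.g. `label.truncate(2)` → `2.7`.

The same workflow runs from the shell:

```bash
pocketec fixtures --out data --n-per-class 12 --seed 0
pocketec split --clusters data/clusters.tsv --labels data/labels.csv --out split.csv
pocketec train --pdb-dir data --sites data/sites.csv --labels data/labels.csv \
               --split split.csv --cut-param 12 --out model.npz
pocketec predict --checkpoint model.npz --pdb data/SYN_0_000.pdb --center 1.1 0.3 45.2
pocketec explain --checkpoint model.npz --pdb data/SYN_0_000.pdb \
                 --center 1.1 0.3 45.2 --out importance.csv
```

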