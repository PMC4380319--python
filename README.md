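# varinterp

Interpretable prediction of neutral vs disease-associated human missense
variants.

Most variant-effect predictors are accurate but opaque. `varinterp`
takes the opposite trade: **linear** support-vector classifiers, trained
separately on subsets of variants sharing the same reference amino acid,
so that the learned feature weights themselves are the result — a
per-substitution map of what makes a variant dangerous. It is aimed at
researchers who have labeled variant catalogues, protein sequences and
alignments, and who want to know *why* a class of variants is predicted
deleterious, not only a score.

## The model

Each variant `(protein, position, ref → mut)` is encoded by five
sequence-derived feature blocks: the substitution itself (−1 at ref, +1
at mut), amino-acid counts in a 19-residue window, MSA conservation
(f_ref, f_mut, alignment depth, column occupancy), minimal
physicochemical distances between the mutant and the residues observed
in the MSA column (19 amino-acid scales), and Pfam family/domain/clan
membership. Only substitutions reachable by a single nucleotide change
in the codon are modelled — 150 of the 380 ordered pairs under the
standard genetic code.

Variants are split into 18 subsets by reference amino acid (W, Y and F
merged). Per subset, a linear SVM (C = 0.1) with Platt-calibrated
probability output is trained on standardized features; its weight
vector is recovered from the dual solution

    w = Σᵢ αᵢ yᵢ Φ(vᵢ),    yᵢ ∈ {−1, +1},

standardized, and arranged into subset × feature heat maps. Positive
weights are disease-predictive, negative neutral-predictive. The pooled
ensemble (C_S) is evaluated by stratified 10-fold cross-validation,
combining all out-of-fold probabilities into one ROC; a single whole-set
classifier (C_E) is the comparison. A substitution-count log-odds
matrix provides a model-free cross-check of the substitution weights.

Because real variant catalogues are large downloads with external tool
dependencies (alignments, Pfam scans), the package ships a synthetic
study generator with *planted*, tunable feature–label structure and a
computable Bayes-optimal AUC, so the entire pipeline is testable and
parameter recovery is measurable offline.

## Worked example

```python
import numpy as np
from varinterp import GeneratorConfig, TrainingConfig, simulate, models, interpret, oracle_auc

cfg = GeneratorConfig(n_variants=6000, seed=4)
dataset = simulate.generate(cfg)
print(f"variants: {len(dataset.variants)}  disease fraction: "
      f"{np.mean([v.label for v in dataset.variants]):.3f}")
print(f"Bayes-optimal AUC for this configuration: {oracle_auc(cfg):.3f}")

data, _ = models.build_subset_data(dataset.variants, dataset.resources())
result = models.cross_validate(data, TrainingConfig(seed=4))
print(f"pooled 10-fold AUC (C_S): {result.pooled_auc:.3f}")

trained = models.train_all_subsets(data, TrainingConfig(seed=4))
ranking = interpret.ensemble_mean_weights(interpret.weight_table(trained))
print("strongest ensemble weights:")
for key, w in ranking.abs().sort_values(ascending=False).head(5).items():
    print(f"  {key[0]:12s} {key[1]:10s} {ranking[key]:+.2f}")
```

prints

```
variants: 6000  disease fraction: 0.127
Bayes-optimal AUC for this configuration: 0.965
pooled 10-fold AUC (C_S): 0.909
strongest ensemble weights:
  conservation f_ref      +3.01
  physchem     scale_3    +2.32
  domain       domain     +1.96
  substitution P          +1.54
  surrounding  #C         +1.49
```

The generator planted exactly one disease effect per feature category
(high reference-amino-acid conservation, large physicochemical distance
on scale 3, Pfam-domain membership, substitution to proline, cysteines
in the window). The trained ensemble reaches 94% of the Bayes bound and
its five strongest standardized weights are precisely the five planted
features, all with the correct (positive = disease) sign — the weights
mean what they claim to mean.

The same pipeline is available from the shell:

```bash
varinterp simulate --out study --seed 4 --n-variants 6000
varinterp filter   --variants study/variants.tsv --fasta study/proteins.fasta --out filtered
varinterp crossval --variants filtered/filtered.tsv --fasta study/proteins.fasta \
                   --msa-dir study/msa --pfam study/pfam.tsv --out cv --seed 4
varinterp interpret --variants filtered/filtered.tsv --fasta study/proteins.fasta \
                    --msa-dir study/msa --pfam study/pfam.tsv --out maps --seed 4
```

`crossval` writes per-subset and pooled AUCs plus the ROC curve;
`interpret` writes per-category weight tables (TSV + heat map) and the
log-odds substitution matrix; `train`/`predict` save and apply a
plain-text model bundle. Every output directory gets a
`run_manifest.json` with the seed and input checksums.

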