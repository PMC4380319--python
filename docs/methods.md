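# Methods

`varinterp` re-implements an interpretable predictor for human missense
variants: linear maximum-margin classifiers, trained separately per
reference amino acid, whose feature weights expose what distinguishes
neutral from disease-associated substitutions. This note records the
model, the numerical conventions, the design choices made where the
design was genuinely open, and what the synthetic benchmark does and does
not demonstrate.

## Variant model and features

A variant is an amino-acid substitution `(protein, position, ref, mut)`
with a binary label (0 neutral, 1 disease-associated). Five feature
blocks encode each variant (66 columns with the default 19-scale set):

1. **Substitution** (20): one column per amino acid; −1 at the reference,
   +1 at the mutant, 0 elsewhere. Rows always sum to zero.
2. **Surrounding sequence** (20): counts of each amino acid in a
   19-residue window centred on the position, truncated at sequence ends.
   The substituted residue itself is counted by default
   (`WindowSpec(include_center=False)` flips this; the window is odd and
   centred, so 9 residues each side).
3. **Conservation** (4): from the MSA column at the position — frequency
   of the reference and of the mutant amino acid, the number of aligned
   proteins, and the number of non-gap residues in the column. The two
   count features exist because the two frequencies are uninformative
   when few homologs are available. Frequencies are over non-gap
   residues (`Resources(conservation_denominator="n_proteins")` divides
   by alignment depth instead); an empty column yields frequencies 0.
   The query sequence is part of the column multiset, so a position with
   no homologs has f_ref = 1 rather than 0 — absence of homologs is not
   evidence of non-conservation.
4. **Physicochemical conservation** (K = 19): per amino-acid scale, the
   minimal absolute scale difference between the mutant and any residue
   observed in the column (reference included). Zero whenever the mutant
   itself is observed; zero, with no extra flag column, for an empty
   column — the conservation count features already encode that the
   column carries no information.
5. **Domain** (3): binary membership of the position in a Pfam family,
   domain, or clan annotation interval.

The packaged scale set mirrors the shape of the VARIMAX-factored AAindex
scales conventionally used for this feature type but is a synthetic
stand-in (see `varinterp/scales.py`): scales 1, 2, 3, 4, 7 and 8 are
standardized versions of published hydropathy, helix-propensity, residue
mass, composition, isoelectric-point and sheet-propensity scales —
matching the properties conventionally associated with those indices —
and the remaining 13 are fixed pseudorandom scales orthogonalised
against the rest. Any user table of the same shape can be substituted.

## Genetic-code reachability

Only substitutions attainable by a single nucleotide change in some codon
of the reference are considered: 150 of the 380 ordered amino-acid pairs
under the standard code. Stop codons are excluded on both sides; the
matrix is symmetric with an unused diagonal. The DNA alphabet (T) is
canonical internally; readers accept U. Reachability drives both the
dataset filter and constant-column removal: for a serine-reference
subset, the serine column (constant −1) and the columns of the seven
unreachable mutants D, E, H, K, M, Q, V (constant 0) are dropped.

## Dataset construction

The filtering pipeline runs in a fixed order: (1) variants present in
both classes keep the disease label and leave the neutral set; (2)
synonymous records, exact duplicates, start-codon variants (position 1 in
protein coordinates) and records with non-standard letters are dropped;
(3) substitutions needing more than one codon mutation are dropped; (4)
variants whose protein is unknown or whose reference mismatches the
sequence are dropped; (5) variants sharing an identical 19-residue window
and the same substitution are collapsed — these are taken to be one DNA
mutation mapped to several proteins, so one canonical record survives
(smallest protein id, then position); `keep_one=False` /
`--drop-all-window-dups` removes whole groups instead. Window
comparison is across both labels. A `FilterReport` reconciles every
record (`input == output + Σ removed`), and the pipeline is idempotent.

## Classifiers and evaluation

Subsets: variants grouped by reference amino acid; tryptophan, tyrosine
and phenylalanine are merged into one `WYF` subset (18 keys total).
`min_size` (default 500) only warns — merging is a judgment call, not a
threshold rule. Each subset gets a support-vector machine (scikit-learn's
libsvm binding), linear kernel with C = 0.1 by default; an RBF kernel
(C = 1.0, γ = 0.01) is available for the performance comparison but has
no interpretable weight vector. Features are standardized to zero mean
and unit variance using the population (n) standard deviation —
constant columns must be removed first — and both the constant-column
list and the scaler are fitted on training rows only, inside each CV
fold, then applied verbatim to test rows (leak-free convention; the
evaluation does not offer a full-set-fitting mode).

Probability outputs come from Platt sigmoid calibration fitted on 5-fold
cross-validated decision values (`CalibratedClassifierCV`,
`ensemble=False`), so P(disease) = σ(−(a·f + b)) with f the decision
value. Calibration makes scores of different subset classifiers
comparable, which the pooled evaluation needs.

Evaluation is stratified 10-fold cross-validation per subset, seeded; a
subset's fold count drops to its minority-class size when that is below
10, and subsets with fewer than 3 minority members are flagged
untrainable and excluded. Two protocols:

- **C_S**: out-of-fold calibrated probabilities of all subset
  classifiers pooled into one ROC; the area under it is the score.
- **C_E**: one classifier on all variants; the score is the mean AUC of
  the ten folds. Calibration is skipped here — the sigmoid is monotone,
  so per-fold AUC is identical and training is ~6× faster.

C_S and C_E fold partitions are generated independently from the same
seed. Per-subset fold seeds are derived deterministically from the
configured seed, so reruns reproduce fold assignments exactly.

### A bias of pooled calibrated probabilities

With no signal at all, the pooled C_S AUC sits slightly *above* 0.5 at
small subset sizes (~+0.05 at ~110 variants/subset, ~+0.015 at ~1,100):
each subset's calibration centres its outputs on the subset's realized
class rate, so random between-subset base-rate differences leak into the
pooled ranking, and positives are by construction more frequent in
subsets with higher realized rates. The null benchmark is therefore run
at the headline study size (n = 20,000), where the artifact is
negligible. At real-catalogue scale (10⁵ variants) it is irrelevant, but
pooled-AUC comparisons on small subset ensembles should keep it in mind.

## Weight interpretation

For a linear model the weight vector is recovered from the dual solution,
`w = Σ αᵢ yᵢ Φ(vᵢ)` over support vectors, and checked against the
solver's primal coefficients (agreement to 1e−6 relative, typically
exact). Positive weights are disease-predictive, negative
neutral-predictive. For cross-subset comparison each classifier's weight
vector is standardized to zero mean, unit population sd over its
*retained* features; features dropped as constant appear as masked cells
and never enter the row statistics. Weight tables are ordered either by
a fixed amino-acid property grouping (charged, polar, small, hydrophobic,
aromatic: `DEKRHNQSTGACVILMPFYW`, an editable constant) or by
complete-linkage hierarchical clustering with Euclidean distance, masked
cells imputed as 0 for the distance computation only.

Row standardization has a consequence for ensemble-level summaries: every
row ends up with unit sd, so a subset whose classifier learned nothing
still contributes unit-scale weights (noise), and collinear feature pairs
(n_proteins/n_residues) can carry large cancelling weights.
`ensemble_mean_weights` therefore aggregates *signed* standardized
weights across subset rows — consistent signal survives, row-local noise
cancels — and ranking by its absolute value is what the recovery
benchmark uses.

The model-free cross-check is a substitution log-odds matrix: for each
reachable (ref, mut), `log[(d+c)/(D+380c)] − log[(n+c)/(N+380c)]` with
disease/neutral counts d, n, class totals D, N and pseudocount c
(default 0.5, Haldane–Anscombe; c = 0 reproduces raw ratios with ±inf at
zero counts). Class-total normalisation makes the matrix insensitive to
class imbalance; positive cells mark disease-enriched substitutions; the
230 unreachable cells are masked. Swapping labels negates the matrix
exactly.

## Synthetic data generator

The generator emulates the inputs of a real study: i.i.d. uniform-
composition proteins (default 40 proteins of 200–400 residues), MSAs from
a copy-with-probability model (per-column conservation α ~ U(0.1, 0.95),
homolog gap probability 0.1, depth 5–50), Pfam-like interval annotations
covering ~30% of residues, and variants drawn only among reachable
substitutions at positions ≥ 2 whose reference matches the sequence — so
generated datasets pass the filtering pipeline untouched. Labels follow
a logistic model over the *true* feature values, z-scored across the
generated set so each planted β is a per-sd log-odds effect; the
intercept is solved (Brent) so the expected disease fraction matches the
configured class balance (default 0.125, the disease fraction of real
variant catalogues). Defaults plant one effect per category:
substitution→P +1.0, #C in the window +1.0, f_ref +2.5, scale_3 distance
+1.5, domain membership +1.0 — sizes chosen so each category is
individually discriminative, as in real data, and the combined Bayes
AUC is ≈ 0.96. `subset_heterogeneity = h` multiplies each effect by a
per-subset factor 1 + h·U(−1, 1) (h = 2 allows sign flips), creating
structure a single linear model cannot represent but the subset ensemble
can. `oracle_auc` Monte-Carlo estimates the Bayes-optimal AUC (score =
true P(disease), labels redrawn), which calibrates what a trained
pipeline can be expected to reach.

What the generator does **not** emulate: phylogenetic correlation in
MSAs, realistic domain architectures, natural amino-acid composition
(uniform by default; a composition table can be supplied through a custom
config), linkage between variants in the same gene, or annotation biases
between classes. Passing benchmarks therefore demonstrates correctness
of the machinery and recoverability of planted structure — not
performance on real catalogues.

## Benchmark problem sizes

Chosen so the full suite runs in minutes on one CPU: headline pooled-AUC
experiment n = 20,000 (oracle ≈ 0.965, pooled C_S AUC ≈ 0.948); null
baseline n = 20,000; planted-feature recovery 20 replicates × 5
categories at n = 6,000 each, one effect planted per replicate (planting
all five at once makes within-category top-1 recovery ill-posed, because
physicochemical and conservation features genuinely depend on mutant
identity and so correlate across categories); C_S vs C_E comparison 10
seeds at n = 4,000 with heterogeneity 2.0 (observed C_S ≈ 0.93 vs C_E ≈
0.86). `scripts/acceptance.py` recomputes all of these from scratch.

## Known limitations

- RBF models cannot be serialized to the text bundle format and have no
  weight interpretation; they exist only for the performance comparison.
- Per-variant prediction rebuilds features one variant at a time; bulk
  scoring should go through `assemble` + `SubsetModel.predict_proba`.
- The libsvm solver's O(n²)-ish scaling makes whole-set (C_E) training
  the bottleneck above ~50k variants.
- Platt calibration is fitted within each training fold on 5 internal
  folds; very small subsets (minority < ~10) get coarse calibration.
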