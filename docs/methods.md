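# Methods

## Encoding

Sequences are embedded positionally with the published BLOSUM62 log-odds
matrix (raw integers, no rescaling — a forest is invariant to monotone
per-feature scaling). The alphabet order is fixed to
`ARNDCQEGHILKMFPSTWYV` and documented in `encoding.py`; position *j* of a
sequence occupies feature block `20j..20j+19`. Padding is on the right
(positions past the end of the sequence) and is exactly zero — padding is
absence of a residue, not a gap character with scores. Flattening order is
frozen so serialized models remain valid across versions.

Dimensional identities asserted in code: 20·19 + 20·11 = 600 (pair mode)
and 600 + 20·34 = 1280 (pmhc mode).

Records containing any non-standard residue (X, B, Z, U, `*`) are
rejected at validation rather than imputed: every accepted record has a
well-defined encoding. HLA names are normalized to two-field (protein)
resolution — synonymous and non-coding suffixes cannot change the
pseudo-sequence.

### Pseudo-sequence

The compact MHC representation is the 34 residues of the mature class-I
heavy chain at the peptide-contact positions shipped in
`data/class1_contact_positions.txt` (the NetMHCpan-style position list).
Real allele sequences are supplied by the user as FASTA keyed by allele
name; the bundled lookup panel
(`data/synthetic_class1_pseudosequences.tsv`) is **synthetic** — generated
stand-in chains for tests and examples, not IMGT/HLA-derived sequences —
and is labelled as such in the file and in
`encoding.bundled_synthetic_pseudo_map`.

## Classifier

`RandomForestClassifier` with 300 trees, unlimited depth, √p features per
split, uniform class weights, `n_jobs=1`. The tree count trades accuracy
against fit time and is overridable everywhere (`--n-trees`); depth is
left unlimited because the positional-motif signal is conjunctive (peptide
k-mer AND CDR3β k-mer) and shallow trees truncate it. Class-ratio control
belongs to the sampling step, not to class weights, so that the ratio is
an explicit, reportable property of the training set. Ties at the
probability threshold classify as binding (`≥`), fixed and tested.
Training is byte-reproducible: a fixed seed fully determines the forest.

Model files are joblib archives with an embedded metadata block (mode,
tree count, seed, class counts, format version); loading rejects files
from a newer format version and corrupt/truncated files.

The model-comparison harness runs stratified k-fold cross-validation
(folds stratified on the binary label; peptide-disjoint evaluation is a
separate, deliberate splitter in `curation`) and reports mean validation
accuracy, mean AUC and mean fit time per candidate family.

## Curation

* Duplicate key: `(cdr3b, peptide)` without MHC, `(cdr3b, peptide, hla)`
  with MHC; dedup keeps one record per (key, label) and concatenates
  source tags.
* Conflicts (a key observed with both labels) are removed entirely, both
  sides — keeping either would inject label noise and no tiebreak is
  defensible.
* Subset construction deals each peptide's records round-robin across
  subsets with proportional allocation (Bresenham-style quota per
  peptide), so every subset approximates the global peptide spectrum;
  records beyond `n_subsets × target` stay unassigned, mirroring
  collections larger than the subsets they feed. Duplicate keys are a
  contract violation here (they would break subset disjointness).
* Negative sampling keeps all binding pairs and draws non-binding pairs
  uniformly without replacement to exactly `ratio ×` the binding count
  (everything, when the pool is smaller).
* The unseen-peptide splitter partitions *peptides*, stratified over the
  four peptide categories (binding-only / non-binding-only / mix /
  generated wild-type) at the requested train fraction; every observation
  follows its peptide. Wild-type negatives are random (TCR, self-peptide)
  pairs under the self-tolerance assumption, tagged
  `generated-wildtype` so evaluation can exclude them.

## Evaluation

AUC is the trapezoidal area under the ROC curve, which equals the
tie-aware Mann–Whitney statistic; a brute-force pairwise comparison serves
as the oracle in the test suite (agreement to 1e-12 up to n = 200). A
stratum containing a single truth class reports threshold metrics with AUC
marked unavailable (`None`), never zero-filled. Per-stratum confusion
counts are conserved: they sum to the pooled counts by construction and by
test.

## Peptide analysis

* **Dominant set**: peptides ranked by false-positive count; the dominant
  set is the smallest prefix reaching a cumulative FP share (default
  0.95), or an explicit top-n. An evaluated set with zero FPs yields an
  empty, flagged table.
* **Ratio titration** rebuilds the training set per target
  binding:non-binding quotient by downsampling one class of the chosen
  peptides only; the other peptides' records are bit-identical across
  ratios (asserted). Upsampling with replacement is deliberately avoided —
  duplicated training rows would leak into held-out folds of any
  downstream CV.
* **Levenshtein similarity** is `1 − d/max(|a|,|b|)` with unit-cost edit
  distance (computed by edlib; a textbook DP is the test oracle).
* **Clustering** is a seeded PAM-style medoid partitioner on the pairwise
  similarity matrix (assignment ties break toward the lowest-index medoid;
  an emptied cluster retains its medoid), chosen because medoids are
  required as interpretable representatives and no k-medoids
  implementation exists in the dependency set.
* **Similarity bins**: training peptides are binned by similarity to a
  representative (default width 0.1 over [0,1], top bin closed); each
  non-empty bin's (binding, non-binding, mix) peptide-category proportions
  are compared with the representative's predicted-label proportion vector
  by RMSE over the three components. A "mix" peptide is one observed with
  both labels; a representative called both ways is itself "mix". Empty
  bins are omitted, not zero-filled.

## Synthetic data

The generator emulates the *structure* of public TCR–peptide collections,
not their biology: uniform residue draws over uniform valid lengths
(CDR3β 8–19, peptide 8–11), a default binding prevalence of 3.27%
(the reference collection's prevalence), and optional injected dominant
peptides (high-frequency, ~50% label noise) as a positive control for the
error analyses.

Binding truth is a planted k-mer compatibility rule: peptide 3-mer at
anchor position 3 → allowed CDR3β 3-mer at anchor position 4 (0-based).
Fixed anchor windows are the analogue of anchor-residue contacts in real
pMHC–TCR interfaces and make the rule learnable from positional
encodings; binding pairs are constructed by motif implantation, and
accidental rule firings in free draws keep their rule label, so the
exported rule reproduces noise-free labels exactly. Label noise flips the
rule label independently per record.

What this does **not** emulate: V(D)J recombination statistics, amino-acid
composition biases, peptide processing/presentation, shared motifs across
related epitopes, or HLA restriction (synthetic HLA chains are random).
Passing tests therefore demonstrate that the pipeline recovers a planted
positional signal under realistic imbalance — not field performance on
real repertoires.

## Problem sizes and numerical choices

The acceptance study uses a 12 000-pair repertoire (≈390 binding) sampled
to 1:10, a 70/30 stratified held-out split, and 300 trees — large enough
that the held-out AUC estimate is stable to ±0.01 across seeds, small
enough to run in seconds. The permutation null retrains on shuffled labels
and lands at AUC 0.5 within sampling noise. The dominant-peptide control
injects one epitope at 400 pairs with 50% label noise into a 6000-pair
repertoire; its FP rank is 1 in every seed tried.

Degenerate inputs are contracts, not silent behavior: empty evaluation
sets, single-class training data, thresholds outside (0,1), ratios ≤ 0,
subset requests exceeding the record pool, and truncated heavy chains all
raise with specific messages.

## Known limitations

* Real pseudo-sequence lookups require user-supplied FASTA; only the
  synthetic panel is bundled.
* `ratio_titration` cannot reach ratios requiring upsampling.
* The medoid partitioner is O(n²) in distinct peptides; it targets the
  hundreds-to-thousands range of real peptide vocabularies.
* Prediction tables for external tools are consumed as-is; no
  re-implementation or retraining of neural baselines is included.
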