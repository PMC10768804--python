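# Methods

This note documents the models, the numerical choices, and the synthetic
data the package is validated against, including what passing tests do —
and do not — establish about behavior on real data.

## Contrastive 3D pretraining

Two encoders are trained jointly on molecules with conformers:

* **2D encoder** — principal neighborhood aggregation (PNA). Each layer
  computes edge messages `m_uv = ReLU(W [h_u ; e_uv])`, aggregates
  incoming messages per node with four aggregators (mean, max, min,
  standard deviation), rescales the concatenated aggregate with three
  degree-dependent scalers — identity, amplification
  `log(deg+1)/log(δ+1)`, and attenuation, its inverse, where δ is the
  mean node degree of the pretraining set — and updates
  `h_v ← ReLU(W' [h_v ; agg])`. The graph readout concatenates min, max,
  mean, and sum over nodes. Nodes without neighbors (single-atom
  molecules) receive a zero aggregate, and the attenuation scaler is
  defined as 0 there to avoid a 0/0.
* **3D encoder** — message passing over all atom pairs where the only
  geometric input is the interatomic distance, expanded in 16 Gaussian
  radial basis functions spanning 0–8 Å (width = center spacing), for
  3 rounds with mean aggregation. Because no coordinates enter except
  through pairwise distances, invariance to global rotation, translation,
  and reflection holds by construction, and the tests assert it to
  1e-10.

The loss is NT-Xent over cosine similarities with temperature τ
(default 0.1). The implemented denominator runs over *other* molecules
only — the positive pair is excluded — which makes the loss `ln(N−1)`
when all embeddings coincide and allows negative values. The canonical
convention (positives included in the denominator) is available via
`include_positives_in_denominator=True`; the exclusive form is the
default because it is the form the fusion model's pretraining
contract is written against. Closed-form values (0 at N=2, ln 2 at N=3,
−1 for the orthogonal two-molecule case) and brute-force double-loop
equality to 1e-6 are pinned in tests.

Pretraining runs full-batch with Adam (lr 1e-3 default). The number of
conformers per molecule is truncated to the minimum count present so the
batch is rectangular; the fixture generator attaches 2 conformers per
molecule, a deliberately small number that keeps desk-scale pretraining
in seconds while still exercising the multi-conformer sum in the loss.

**Freezing.** For fine-tuning, the first ⌊fraction · n_layers⌋ PNA
message-passing layers (counted from the input; the admissible range is
[0, 0.95]) can be flagged frozen; optimizers skip flagged parameters,
so frozen values are bitwise unchanged after any number of steps.

## Fusion model

* Compound branch: per-atom PNA features are keys/values; one learnable
  embedding row per set Morgan-fingerprint bit (radius 2, 2048 bits by
  default) forms the query sequence. A lookup table rather than a dense
  MLP is used because the fingerprint is extremely sparse. Attended
  queries are mean-pooled into `x_comp`.
* Protein branch: the one-hot atom matrix **A** (atom-name block of 38
  standard heavy-atom names, amino-acid block of 21, element block of 5,
  each with an "other" slot so every block row-sums to 1) passes through
  a 3-layer 1D CNN (kernel 7, ReLU, max-pool 4); the Fourier-mapped
  distance map γ(D) (default F=4, so 2F+1 = 9 channels; channel 0 is the
  raw distance) passes through a 3-layer 2D CNN (kernel 3, ReLU,
  max-pool 2). The printed Fourier form scales *amplitudes* by 2^−k; an
  argument-scaled variant (genuinely higher frequencies) exists behind
  `scale_argument=True` but is off by default — the printed formula wins.
  Each pooled row of the 2D map, flattened across channels, is one
  query; pooled 1D-tower positions are keys/values.
* Cross-attention is `softmax(QKᵀ/√(C/h))·V` per head with heads
  concatenated, plus a residual on the projected-query path and layer
  norm (standard stabilization; the raw form is exposed separately and
  is what the hand-computed attention tests address). Padded keys are
  excluded with an additive −1e9 mask.
* Variable protein size is handled by truncation/zero-padding to
  `max_residues` / `max_atoms` with explicit masks. Activations are
  re-masked after every convolution so padding cannot leak into valid
  positions through the kernel support; a test asserts that appending
  extra masked rows leaves `x_prot` unchanged to 1e-9. Defaults
  (64 residues / 256 atoms) suit the synthetic fixtures; real predicted
  structures need larger values, set in config.
* Head: `z = ReLU(w_zᵀ[x_comp; x_prot] + b_z)`, `ŷ = w_oᵀz + b_o`,
  with a logistic output for classification. Objectives: MSE
  (regression) or BCE (classification). Training is mini-batch Adam
  (defaults lr 1e-4, batch 32, 50 epochs) with early stopping on an
  internal validation split (10%, patience 5) and restoration of the
  best state.

All networks run in float64 on a small reverse-mode autodiff engine
(`cpifusion.autodiff`); every operation's gradient is checked against
central finite differences in the test suite. Max/min gradients split
equally across ties (a subgradient choice that only matters on
measure-zero inputs).

## Cluster cross-validation

* Butina clustering: neighbors are pairs at Tanimoto *distance* strictly
  below the cutoff (default 0.6, i.e. similarity above 0.4); candidates
  are processed in order of decreasing neighbor count with index
  tie-break, each unassigned candidate seeding a cluster that claims its
  unassigned neighbors. The implementation is cross-checked against
  RDKit's reference on random instances.
* Protein clustering: k-means (seeded k-means++, scikit-learn) on
  L2-normalized 3-mer composition vectors over a 21-letter alphabet
  (20 standard amino acids plus one slot for anything else; 21³ = 9261
  dimensions). K defaults to ⌈√n_proteins⌉.
* Protein similarity for the hard-pair threshold: global alignment
  (match +1, mismatch 0, linear gap −1, Biopython PairwiseAligner)
  normalized by the longer sequence length and clipped to [0, 1]. This
  is one reasonable identity definition among several; it is
  configurable in spirit (descriptor cosine is a drop-in alternative)
  and its absolute scale interacts with the 0.3 threshold, so the audit
  reports the realized maxima rather than trusting the rule.
* Fold construction assigns whole clusters to folds by greedy size
  balancing (largest first, lowest-index fold on ties). For the pair
  settings, compound clusters and protein clusters are partitioned
  independently; the fold-f test set is the interactions whose compound
  fold *and* protein fold are both f, and the training set avoids both,
  so neither entity type ever crosses the boundary. A consequence worth
  knowing: interactions whose two fold labels disagree are tested in no
  fold (they would leak one side if used); the fold *assignment* still
  partitions the dataset. `novel_hard_pair` additionally removes
  training interactions whose compound Tanimoto OR protein similarity
  to any test item exceeds the threshold (default 0.3); `cross_domain`
  trains on the lexicographically first dataset tag and applies the same
  removal. The audit computes exhaustive maxima over train × test pairs.

## Screening metrics

EF at fraction f ranks by descending score (stable index tie-break),
takes the top ⌈fN⌉, and reports the active rate there over the overall
rate. BEDROC uses the exponential rank weighting
S = Σ_{i∈pos} e^(−α·rᵢ/N), min–max normalized with the exact discrete
extremes (all positives first / last), which maps perfect ranking to
exactly 1 and worst to exactly 0 and agrees with RDKit's implementation
to machine precision. α = 80.5 concentrates ~80% of the weight in the
top 2%. The C-index credits prediction ties 0.5 (Harrell convention);
a strict mode gives ties no credit, matching the literal indicator
definition, which is internally tie-ambiguous. Spearman uses the
rank-difference formula with average ranks under ties; with ties it is
the formula's value, not the Pearson correlation of ranks. Activity
labeling for classification sets: IC50 < 100 nM positive, > 10,000 nM
negative, everything between excluded.

The random-guessing reference simulates Uniform(0,1) scores at a given
positive/negative composition and averages EF and BEDROC over
repetitions (three by default, matching the reporting convention of the
screening experiment it calibrates).

## Synthetic fixtures and what they show

Molecules come from a 90-entry library (6 ring scaffolds × 15
substituents), all valid drug-like SMILES, embedded with ETKDG (2
conformers each, seeded). The library spans ≥ 3 Butina clusters at
cutoff 0.6 and contains close analog pairs, which is what makes the
leakage-audit contrast (cluster split vs random K-fold) meaningful.
Proteins are ideal α-helices — rise 1.5 Å, 100° twist, radius 2.3 Å,
four heavy backbone atoms per residue, random sequence of length 20–40 —
serialized as valid PDB (coordinates round to 3 decimals there; the
in-memory structure keeps exact values, so the distance-map Toeplitz
property holds to 1e-6 while the PDB round-trip agrees to 5e-3).

Interaction labels are a planted linear signal:
w · [one-hot Butina cluster of the compound ; 4-channel amino-acid
composition summary of the protein] + N(0, 0.1²), with cluster weights
drawn N(0, 0.7²) and composition weights N(0, 8²) (composition fractions
are O(0.1), so both terms contribute O(1) label variance). The default
study condition is 50 compounds × 10 proteins with 200 sampled
interactions. Ridge regression on the generating features reaches
R² > 0.9 at this noise level and collapses below 0.1 under label
permutation; the end-to-end check trains the full model on one
novel-compound fold and requires test MSE below the best constant
predictor, with a label-shuffled control that must not beat it. Under a
novel-compound split the cluster component of the signal is
unlearnable by construction, so what the passing test shows is that the
model recovers the protein-side signal and generalizable fingerprint
structure — not that it would rank real binding affinities. The
fixtures share no physics with real CPI data: no binding geometry, no
affinity scale, no label noise structure. They validate code paths,
contracts, and statistical behavior only.

## Problem sizes and determinism

Desk-scale defaults throughout: pretraining on ≤ 50 molecules for tens
of epochs, fine-tuning on ≤ 200 interactions with hidden widths 8–16,
protein maxima 48–64 residues. Every stochastic stage (model init, data
generation, conformer embedding, k-means, shuffling) takes an explicit
seed, and reruns with the same seed are bit-reproducible; tests pin this.

## Known limitations

* No mmCIF input; PDB ATOM records only, hydrogens ignored.
* The exact Butina cutoff and the protein similarity definition used
  with the 0.3 threshold are field-convention choices, not uniquely
  determined; both are parameters.
* The interaction step is concatenation + MLP only (the cross-attention
  interaction variant is deliberately out of scope).
* Fine-tuning processes samples one at a time inside a batch
  (gradient accumulation), which is simple and exact but leaves
  throughput on the table; at fixture scale this is immaterial.
* Per-target metric aggregation reports MSE only for targets whose
  label vector is constant (C-index and Spearman are undefined there).
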