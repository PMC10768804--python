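# cpifusion

Compound–protein interaction (CPI) prediction for drug discovery, built
around three ideas:

1. **3D-aware compound encoding.** A principal-neighborhood-aggregation
   (PNA) graph encoder over the 2D bond graph is pretrained contrastively
   against a rigid-motion-invariant 3D encoder of molecular conformers,
   so the graph encoder absorbs geometric information it can later use
   without any 3D input. The objective is a normalized
   temperature-scaled cross-entropy (NT-Xent) over cosine similarities:

   L = −(1/N) Σᵢ log [ Σⱼ exp(sim(z²ᴰᵢ, z³ᴰᵢⱼ)/τ) / Σ_{k≠i} Σⱼ exp(sim(z²ᴰᵢ, z³ᴰₖⱼ)/τ) ]

   for N molecules with c conformers each.

2. **Atomic-resolution protein features from predicted structures.**
   Instead of treating the protein as a character string, the model
   consumes a PDB structure (e.g. a single-sequence folding-model
   output): a one-hot atom matrix **A** (atom name × amino acid ×
   element) processed by a 1D CNN — the "what" — and the Cα–Cα distance
   map **D** lifted by a Fourier feature mapping
   γ(d) = [d, sin(d)/2⁰, cos(d)/2⁰, …, sin(d)/2^{F−1}, cos(d)/2^{F−1}]
   and processed by a 2D CNN — the "where". The two streams are fused by
   multi-head cross-attention (queries from "where", keys/values from
   "what"), mirrored on the compound side with Morgan-fingerprint lookup
   embeddings as queries over per-atom PNA features. The pooled vectors
   x_comp and x_prot are concatenated into a two-layer MLP head (MSE
   loss for affinity regression, BCE for active/decoy classification).

3. **Leakage-controlled evaluation.** Instead of random K-fold splits —
   which let near-duplicate compounds and homologous proteins straddle
   the train/test boundary — folds are built from Butina (sphere
   exclusion, Tanimoto) clusters of compounds and k-means clusters of
   protein 3-mer composition vectors, with settings `novel_compound`,
   `novel_protein`, `novel_pair`, `novel_hard_pair` (extra removal of
   training items above a 0.3 train-vs-test similarity threshold), and
   `cross_domain`. Every split carries an exhaustive leakage audit.

Evaluation metrics include MSE, concordance index, Spearman ρ
(ρ = 1 − 6Σd²/(n(n²−1))), enrichment factor, and BEDROC (exponential
rank weighting, α = 80.5).

The package is desk-scale by design: every component is exercised end to
end on synthetic fixtures (library-derived drug-like molecules with ETKDG
conformers, ideal α-helix proteins, and interaction labels with a
planted, recoverable linear signal). The neural components run on a
compact numpy reverse-mode autodiff engine included in the package, so
there is no GPU or deep-learning-framework dependency.

## Worked example

```bash
cpifusion make-fixtures --out data --n-compounds 25 --n-proteins 6 \
    --n-interactions 100 --seed 3
# wrote 100 interactions, 25 compounds, 6 proteins to data

cat > run.yaml <<'YAML'
paths: {data: data, output: output}
model: {hidden_dim: 16, n_pna_layers: 2, fp_bits: 512, attn_dim: 16,
        n_heads: 2, conv1d_channels: 8, conv2d_channels: 4, head_hidden: 16,
        fourier_F: 2, max_residues: 48, max_atoms: 192}
training: {pretrain_epochs: 5, epochs: 25, batch_size: 16, lr: 0.003, patience: 8}
split: {setting: novel_compound, n_folds: 2}
seed: 1
YAML
cpifusion run-all --config run.yaml
```

prints (about 15 s on one CPU):

```
pipeline complete; metrics at output/metrics.json
{
 "mse": 1.282840429284191,
 "c_index": 0.6282828282828283,
 "spearman": 0.3173237323732373,
 ...
}
```

Here `mse` is the pooled squared error of held-out predictions across
the two novel-compound folds (labels are in the fixture's latent-signal
units), `c_index` the fraction of test pairs ranked concordantly with
their labels (0.5 = chance), and `spearman` the rank correlation between
predictions and labels. Even this small run learns a real ordering
signal on compounds from clusters never seen in training (CI 0.63,
ρ 0.32); absolute calibration at this scale still trails a constant
predictor on one fold, and the larger 50-compound × 10-protein
configuration exercised by the test suite beats the constant baseline
outright. `output/split.json` records the leakage audit and
`output/predictions_fold*.tsv` the per-pair predictions.

Library use mirrors the CLI: `cpifusion.fixtures` generates data,
`cpifusion.pretrain.pretrain` trains the contrastive encoders,
`cpifusion.split.make_split` builds audited folds,
`cpifusion.model.train` fine-tunes the fusion network, and
`cpifusion.metrics` scores predictions.

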