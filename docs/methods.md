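# Methods

## Model

The phenome is a binary incidence matrix X ∈ {0,1}^{M×N}: M drugs, N
phenotype terms partitioned into side-effect and indication columns.
Each drug is treated as a bag of count-1 tokens — one token per present
phenotype — and modeled with latent Dirichlet allocation: topic mixtures
θ_d ~ Dirichlet(α·1_K) per drug, phenotype distributions φ_t ~
Dirichlet(β·1_N) per topic, tokens drawn topic-first. The quantity the
pipeline consumes is the mixture marginal p(ph|d) = Σ_t θ_{dt} φ_{t,ph}.

Multiplicity is deliberately absent: the matrix is 0/1, so a phenotype
contributes at most one token to its drug's document. The generative
multinomial is therefore an approximation to presence/absence data; it
is adopted because the latent paths it induces (drug → topic →
phenotype) are the object of interest, not the token counts.

## Inference

Collapsed Gibbs sampling with θ and φ integrated out; the conditional
for token i is p(z_i=k) ∝ (n_dk+α)(n_kw+β)/(n_k+Nβ). Estimates are
Rao-Blackwellised plug-ins (n_dk+α)/(n_d+Kα) and (n_kw+β)/(n_k+Nβ)
averaged over post-burn-in samples at a fixed lag. Randomness comes from
an explicit splitmix64-seeded xorshift64* generator inside the kernel,
so a (corpus, config, seed) triple is bit-reproducible across platforms;
the kernels are numba-compiled.

Defaults: α = 50/K, β = 0.01, 2,000 iterations, 500 burn-in, lag 10 —
the conventional Gibbs-LDA settings. All are exposed in `LDAConfig`.
Note that 50/K is a *prior mass* of 50 tokens: on corpora whose
documents carry only tens of tokens (all the built-in fixtures) it
swamps the data, and a weakly informative α of around 0.1–0.3 is the
appropriate setting; the tests use exactly that for the block and
generative fixtures.

Topic labels are not identifiable. Sample averaging is safe in practice
because chains on structured data do not traverse label modes, but every
cross-model comparison (tests, diagnostics) first applies
best-permutation matching (`match_topics`, Hungarian algorithm on L1 row
distance). On tiny corpora the chain *does* mix across modes, which is
precisely why its averages converge to the exact label-symmetric
posterior means computed by enumeration — the basis of the
sampler-correctness tests.

An optional fold-in mode infers a single document's mixture against
fixed φ (used by `PhenomeLDA.transform` and the fast recovery mode).

## Scoring and decision criteria

`mixture_scores` computes Σ_t θ_{·t} φ_{t·} by explicit accumulation in
topic order rather than BLAS matmul. The cost is negligible at these
shapes and the summation order becomes part of the contract: the result
is bit-identical to a naive double-loop summation, which makes exact
(not tolerance-based) verification possible.

p(i|d) is the drug's row restricted to indication columns, renormalized
to sum 1 (rank-preserving; zero-mass rows are flagged and excluded). The
two acceptance rules are:

- above chance: p(i|d) > q with q = N_known/(|D|·|I|). The inequality is
  strict — boundary cases are rejected. N_known counts *all* known
  drug–indication 1-cells, including those of single-drug indications
  (for the SIDER-scale counts, 12,066 vs 11,183 both round to q = 0.005,
  so the distinction is immaterial at three decimals; the count used is
  recorded in `DecisionCriteria`).
- within IS: rank ≤ IS(drug) among all |I| indications, ranked by
  descending p(i|d) with ties broken by the canonical column order
  (stable sort). IS(drug) is the drug's known-indication count in the
  unperturbed matrix; drugs with none fall back to `default_is = 13`,
  the average indication count of the SIDER-scale phenome.

## Leave-one-out recovery

Every known pair whose indication is held by ≥ 2 drugs is eligible
(masking a single-drug indication would delete the term from the data
set). For each masked pair the cell is set to 0, the model refitted with
a per-pair derived seed (`SeedSequence`-based, < 2^31), the masked
indication rescored and ranked, and the cell restored; the matrix is
checksummed before and after, and a violated restore is an error, not a
warning. IS and q always come from the unperturbed matrix. The fast
`foldin` mode fits one model on the unperturbed matrix and folds only
the perturbed document into its fixed topics — recorded in the report,
appropriate for large matrices or trend checks.

Summary: success rate s = n_recovered/n_above_chance (undefined, never
0, when nothing clears chance), a p(i|d) histogram at bin width 0.005
(aligned with the chance threshold), and success rates stratified by IS
and by incremental low-IS removal.

## Repositioning queries

- `suggest_indications`: drugs with ≥ 1 known indication; 0-cells
  passing both criteria, ranked among all indications (known ones occupy
  their ranks, so a drug's IS is partly "used up" by what it already
  treats — intentional conservatism).
- `retrieve_indications`: drugs with no recorded indications; top
  `default_is` above-chance indications.
- `query_drugs`: reverse query. With a uniform drug prior, p(d|i) ∝
  p(i|d), so per-drug renormalized scores are compared across drugs; k is
  the number of drugs already holding the indication and candidates are
  the top-k not among them. The caveat — per-drug renormalization makes
  cross-drug comparison prior-dependent — is inherent to the design and
  documented here rather than hidden.

## Topic-number selection

The criterion is held-out perplexity exp(−Σ log p(ph|d)/n) on a
deterministic 90/10 per-document token split (every 10th token in
canonical order held out — reproducible without a second RNG stream).
Replicate fits per K use derived seeds; scores are averaged; ties go to
the smaller K. The selection objective is pluggable
(`register_criterion`), so an alternative information-loss criterion can
be swapped in without touching the search; held-out perplexity is the
package's default because it is principled, standard, and needs no
quantities beyond the model itself.

## Synthetic data

`generate_lda_phenome` draws from the generative process above and
binarizes (raw counts are kept for diagnostics). Defaults — 200 drugs,
700 side-effect + 300 indication terms, K = 5, α = 0.3, β = 0.05, 50
tokens/drug — are sized so that each drug holds only a few percent of
the indication vocabulary. That sparsity is the regime the method
actually targets: the chance threshold q ≈ 0.03 sits well below typical
within-topic p(i|d), as it does on the real phenome (q = 0.005), so the
above-chance criterion is informative. A denser toy (e.g. tens of
indications) inverts that relation and silently disables the first
criterion. Planted held-outs are known links from the top quartile
(configurable) of generative p(i|d), flipped to 0 — recoverable in
principle by construction.

`make_block_fixture` plants topics as noisy block-diagonal structure
(drugs of block b carry block b's phenotypes; independent Bernoulli bit
flips). It is dense by design, so on it q is large and only the rank/IS
criterion is exercised; it serves identifiability and ranking tests, not
threshold tests.

What the generators do *not* emulate: SIDER's heavy-tailed term
frequencies, MedDRA term correlations, label-extraction noise, and the
scale (996×6,776). Passing tests therefore demonstrate correctness of
the machinery and recoverability under the model's own assumptions — not
performance on real label data.

## Problem sizes and numerical choices

Test and example runs use the compact fixtures above (60–200 drugs,
90–1,000 phenotypes, 50–120 masked pairs, 800–21,000 sampler
iterations), chosen so the full posterior-enumeration and
permutation-matching oracles stay exact while every pipeline stage runs
at realistic sparsity. Normalization contracts are enforced at 1e-9.
Model serialization writes 17 significant digits and reparses with
round-trip float precision, so save/load is bit-identical. All derived
seeds stay below 2^31.

## Known limitations

- Gibbs estimates on multimodal posteriors depend on the seed; only
  small corpora mix fully. Confirmed behavior, not a defect: fits are
  reproducible bit-for-bit given the seed.
- The per-pair full-refit recovery is O(pairs × fit); at SIDER scale the
  fold-in mode or per-pair parallelism is required.
- `retrieve_indications` inherits the IS = 13 fallback; for phenomes
  with very different indication densities the default should be reset
  from the data.
- No hyperparameter learning (α, β fixed per run) and no nonparametric
  K.
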