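# phenolda

Phenome-guided drug repositioning with a latent variable model.

A drug's observed phenome — the side effects it elicits together with the
indications it treats — carries more information than any single
drug–drug similarity. `phenolda` models a binary drug × phenotype
incidence matrix (SIDER-style: rows are drugs, columns are MedDRA-style
side-effect and indication terms) with latent Dirichlet allocation,
treating each drug as a *document* and each phenotype as a *word*. The
latent topics link drugs to phenotypes they were never observed with,
which is exactly what a repositioning screen needs.

## The model

With per-drug topic mixtures θ (rows p(t|d) ~ Dirichlet(α)) and per-topic
phenotype distributions φ (rows p(ph|t) ~ Dirichlet(β)), fitted here by
collapsed Gibbs sampling, the drug→phenotype path probability is

    p(ph|d) = Σ_t p(t|d) · p(ph|t)

Restricting a drug's row to the indication columns and renormalizing
gives p(i|d). A candidate (drug, indication) pair is proposed only if it
passes **two decision criteria**:

1. **above chance** — p(i|d) > q, where q = N/(|D|·|I|) is the
   probability of drawing one of the N known drug–indication pairs
   uniformly from all drug × indication cells;
2. **within the indication space (IS)** — the indication ranks within the
   top IS positions among all |I| indications for that drug, IS being the
   drug's count of known indications (a configurable fallback, 13 by
   default, covers drugs with none).

The model validates itself by a leave-one-out experiment: every known
pair whose indication is held by ≥ 2 drugs is switched to 0 one at a
time, the model is refitted, and the masked indication is rescored. The
success rate s = n_recovered / n_above_chance summarizes how often an
above-chance prediction also lands within the IS.

## Worked example

No external download is needed: the package ships a generator that
samples a phenome from the model's own generative process, with known
θ/φ and planted held-out links.

```python
import numpy as np
from phenolda import (
    SyntheticSpec, generate_lda_phenome, to_corpus, LDAConfig, fit_lda,
    phenotype_probabilities, indication_probabilities, DecisionCriteria,
    suggest_indications, enumerate_maskable_pairs, run_recovery,
)

truth = generate_lda_phenome(SyntheticSpec(seed=0))
matrix = truth.matrix
config = LDAConfig(n_topics=5, alpha=0.3, beta=0.05, seed=0)
model = fit_lda(to_corpus(matrix), config)
criteria = DecisionCriteria.from_matrix(matrix)

pid = indication_probabilities(phenotype_probabilities(model), matrix)
suggestions = suggest_indications(matrix, pid, criteria)

eligible = [p for p in enumerate_maskable_pairs(matrix) if p.eligible]
rng = np.random.default_rng(0)
sample = [eligible[i] for i in sorted(rng.choice(len(eligible), 100, replace=False))]
report = run_recovery(matrix, config, pairs=sample, seed=0, mode="foldin")
```

which prints (via the obvious `print` statements):

```
200 drugs x 1000 phenotypes (700 side effects + 300 indications)
known drug-indication pairs: 2061
random chance q = 0.0343
suggested novel pairs: 427 across 182 drugs
e.g. drug00000 -> ind00267  p=0.064  rank 3 of 300 (IS=13)
masked-pair recovery: 32/100 above chance, 32 also within IS -> s = 100%
```

Reading this: the synthetic phenome has 2,061 known links, so drawing one
at random from the 200×300 indication cells succeeds with probability
q = 0.034. The fitted model proposes 427 new links that are both above
that chance level and ranked inside their drug's indication space; for
the first one, the indication ranks 3rd of 300 for its drug. Masking 100
known links one at a time and rescoring them, 32 come back above chance
and all 32 also fall within their drug's IS (s = 100%).

The same pipeline runs from the shell:

```sh
phenolda simulate --seed 0 --out sim/
phenolda select-topics --data sim/ --grid 2,5,8 --replicates 3 --seed 0
phenolda recover --data sim/ --pairs sample:100 --topics 5 --alpha 0.3 --beta 0.05 --seed 0
phenolda suggest --data sim/ --topics 5 --alpha 0.3 --beta 0.05 --seed 0 --out suggestions.tsv
phenolda query --data sim/ --topics 5 --alpha 0.3 --beta 0.05 --indication ind00267
```

`phenolda convert --table assoc.tsv --out dir/` builds the matrix
directory from a real long-format association table (column mapping is
configurable, so any SIDER release layout can be adapted).

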