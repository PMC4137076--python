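"""Synthetic drug–phenome matrices with known latent structure.

Two generators: :func:`generate_lda_phenome` samples from the topic model's
own generative process (Dirichlet topic mixtures, Dirichlet phenotype
distributions, multinomial token draws, then binarization) and plants
held-out high-probability indication links for recovery experiments;
:func:`make_block_fixture` builds a noisy block-diagonal incidence whose
blocks act as planted topics.  A third helper builds a drug/phenotype
matrix with the summary counts of the public SIDER phenome (996 drugs,
4,500 side-effect and 2,276 indication terms, 12,066 known
drug–indication pairs of which 883 indications are held by a single
drug) for accounting-level checks; its cell layout is synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PhenomeMatrix
from .scoring import mixture_scores

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_lda_phenome",
    "make_block_fixture",
    "make_sider_like_mock",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative conditions for a phenome draw.

    Defaults emulate a compact phenome in the regime the method targets:
    200 drugs over 700 side-effect and 300 indication terms, five latent
    topics, sparse topics (beta = 0.05) and moderately mixed drugs
    (alpha = 0.3), 50 token draws per drug.  The vocabulary is sized so
    each drug holds only a few percent of the indications, keeping the
    random-chance level q well below typical within-topic p(i|d) — the
    sparsity that makes the above-chance criterion informative on the real
    phenome.
    """

    n_drugs: int = 200
    n_side_effects: int = 700
    n_indications: int = 300
    n_topics: int = 5
    alpha: float = 0.3
    beta: float = 0.05
    tokens_per_drug: int = 50
    n_planted: int = 20
    planted_quantile: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_side_effects", "n_indications", "n_topics"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.tokens_per_drug < 1:
            raise ValueError("tokens_per_drug must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.n_planted < 0:
            raise ValueError("n_planted must be >= 0")
        if not (0 <= self.planted_quantile < 1):
            raise ValueError("planted_quantile must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """A generated matrix together with the latent truth that produced it."""

    matrix: PhenomeMatrix
    theta: np.ndarray  # (M, K) generative p(t|d)
    phi: np.ndarray  # (K, N_ph) generative p(ph|t), matrix column order
    counts: np.ndarray  # raw token counts before binarization
    planted: list[tuple[str, str]] = field(default_factory=list)


def _phenotype_names(n_side_effects: int, n_indications: int) -> tuple[list[str], np.ndarray]:
    side = [f"se{j:05d}" for j in range(n_side_effects)]
    ind = [f"ind{j:05d}" for j in range(n_indications)]
    names = side + ind
    is_ind = np.zeros(len(names), dtype=bool)
    is_ind[n_side_effects:] = True
    return names, is_ind


def generate_lda_phenome(spec: SyntheticSpec) -> SyntheticTruth:
    """Sample a binary phenome from the generative topic process.

    φ rows ~ Dirichlet(β·1), θ rows ~ Dirichlet(α·1); each drug draws
    ``tokens_per_drug`` phenotype tokens topic-first, and the incidence is
    the binarized count matrix.  ``n_planted`` known indication links whose
    generative p(i|d) lies above the ``planted_quantile`` of all known
    indication links are then flipped to 0 and reported as planted
    held-outs.  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_ph = spec.n_side_effects + spec.n_indications
    phi = rng.dirichlet(np.full(n_ph, spec.beta), size=spec.n_topics)
    theta = rng.dirichlet(np.full(spec.n_topics, spec.alpha), size=spec.n_drugs)
    counts = np.zeros((spec.n_drugs, n_ph), dtype=np.int64)
    for d in range(spec.n_drugs):
        topic_counts = rng.multinomial(spec.tokens_per_drug, theta[d])
        for t, c in enumerate(topic_counts):
            if c:
                counts[d] += rng.multinomial(c, phi[t])
    X = (counts > 0).astype(np.uint8)
    names, is_ind = _phenotype_names(spec.n_side_effects, spec.n_indications)
    drugs = [f"drug{d:05d}" for d in range(spec.n_drugs)]
    matrix = PhenomeMatrix(drugs, names, is_ind, X)

    planted: list[tuple[str, str]] = []
    if spec.n_planted:
        gen_p = mixture_scores(theta, phi)  # generative p(ph|d)
        ind_cols = matrix.indication_columns
        rows, cols = np.nonzero(X[:, ind_cols])
        if len(rows) == 0:
            raise ValueError("no known indication links to plant held-outs from")
        link_p = gen_p[rows, ind_cols[cols]]
        cut = np.quantile(link_p, spec.planted_quantile)
        top = np.flatnonzero(link_p >= cut)
        if len(top) < spec.n_planted:
            raise ValueError(
                f"requested {spec.n_planted} planted links but only {len(top)} "
                f"known links lie above the {spec.planted_quantile} quantile"
            )
        pick = rng.choice(top, size=spec.n_planted, replace=False)
        for r in pick:
            d, j = int(rows[r]), int(ind_cols[cols[r]])
            X[d, j] = 0
            planted.append((drugs[d], names[j]))
    return SyntheticTruth(
        matrix=matrix, theta=theta, phi=phi, counts=counts, planted=planted
    )


def make_block_fixture(
    n_blocks: int = 3,
    drugs_per_block: int = 20,
    phenos_per_block: int = 30,
    indication_fraction: float = 0.3,
    noise_rate: float = 0.05,
    seed: int = 0,
) -> SyntheticTruth:
    """Noisy block-diagonal phenome: block b's drugs carry block b's phenotypes.

    Each block contributes ``round(phenos_per_block * indication_fraction)``
    indication columns (the rest are side effects); every cell is then
    flipped independently with probability ``noise_rate``.  The block
    identity of each drug is the planted topic, recorded in ``theta``
    (one-hot) and ``phi`` (uniform over the block's phenotypes).
    """
    if n_blocks < 1 or drugs_per_block < 1 or phenos_per_block < 1:
        raise ValueError("counts must be positive")
    if not (0 <= noise_rate < 0.5):
        raise ValueError("noise_rate must lie in [0, 0.5)")
    if not (0 <= indication_fraction <= 1):
        raise ValueError("indication_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_ind_per_block = round(phenos_per_block * indication_fraction)
    n_se_per_block = phenos_per_block - n_ind_per_block

    side_names: list[str] = []
    ind_names: list[str] = []
    block_cols: list[list[str]] = []
    for b in range(n_blocks):
        se = [f"se_b{b}_{j:03d}" for j in range(n_se_per_block)]
        ind = [f"ind_b{b}_{j:03d}" for j in range(n_ind_per_block)]
        side_names.extend(se)
        ind_names.extend(ind)
        block_cols.append(se + ind)
    names = sorted(side_names) + sorted(ind_names)
    is_ind = np.array([n.startswith("ind_") for n in names], dtype=bool)
    col_of = {n: j for j, n in enumerate(names)}

    drugs = [f"drug_b{b}_{i:03d}" for b in range(n_blocks) for i in range(drugs_per_block)]
    M, N = len(drugs), len(names)
    X = np.zeros((M, N), dtype=np.uint8)
    theta = np.zeros((M, n_blocks))
    phi = np.zeros((n_blocks, N))
    for b in range(n_blocks):
        cols = np.array([col_of[n] for n in block_cols[b]])
        phi[b, cols] = 1.0 / len(cols)
        for i in range(drugs_per_block):
            d = b * drugs_per_block + i
            X[d, cols] = 1
            theta[d, b] = 1.0
    if noise_rate > 0:
        flips = rng.random((M, N)) < noise_rate
        X = np.where(flips, 1 - X, X).astype(np.uint8)
    # drug list is already lexicographic by construction
    matrix = PhenomeMatrix(drugs, names, is_ind, X)
    counts = X.astype(np.int64)
    return SyntheticTruth(matrix=matrix, theta=theta, phi=phi, counts=counts, planted=[])


def make_sider_like_mock(
    n_drugs: int = 996,
    n_side_effects: int = 4500,
    n_indications: int = 2276,
    n_known_pairs: int = 12066,
    n_single_drug_indications: int = 883,
    seed: int = 0,
) -> PhenomeMatrix:
    """Synthetic matrix reproducing the SIDER phenome's summary counts.

    Deterministic layout: the first ``n_single_drug_indications`` indication
    columns receive exactly one 1-cell each; the remaining known pairs are
    spread round-robin over the other indication columns so every one of
    them is held by at least two drugs.  A thin band of side-effect 1-cells
    keeps every drug's document non-empty.  Only the counts are meaningful;
    the cell layout is synthetic.
    """
    n_multi = n_indications - n_single_drug_indications
    n_rest = n_known_pairs - n_single_drug_indications
    if n_multi <= 0 or n_rest < 2 * n_multi:
        raise ValueError("counts do not admit >=2 drugs per non-singleton indication")
    rng = np.random.default_rng(seed)
    names, is_ind = _phenotype_names(n_side_effects, n_indications)
    drugs = [f"drug{d:05d}" for d in range(n_drugs)]
    X = np.zeros((n_drugs, n_side_effects + n_indications), dtype=np.uint8)
    # a couple of side effects per drug so no document is empty
    for d in range(n_drugs):
        X[d, (2 * d) % n_side_effects] = 1
        X[d, (2 * d + 1) % n_side_effects] = 1
    # singleton indications: one holder each
    for j in range(n_single_drug_indications):
        X[j % n_drugs, n_side_effects + j] = 1
    # remaining known pairs round-robin over the other indications
    base = n_side_effects + n_single_drug_indications
    per_col = n_rest // n_multi
    extra = n_rest - per_col * n_multi
    row = rng.integers(0, n_drugs)
    for jj in range(n_multi):
        m = per_col + (1 if jj < extra else 0)
        for r in range(m):
            X[(row + r) % n_drugs, base + jj] = 1
        row = (row + m) % n_drugs
    matrix = PhenomeMatrix(drugs, names, is_ind, X)
    if matrix.n_known_pairs != n_known_pairs:
        raise AssertionError("mock construction failed to place the declared counts")
    return matrix
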