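"""Latent Dirichlet allocation over the drug phenome.

Drugs are documents and phenotypes are words.  The model estimates the
per-drug topic mixture θ (rows p(t|d)) and the per-topic phenotype
distribution φ (rows p(ph|t)) by collapsed Gibbs sampling; posterior means
are averaged over post-burn-in samples.  The estimator follows the
scikit-learn protocol (``fit`` / ``transform`` / ``get_params``), and the
module-level :func:`fit_lda` is a thin wrapper returning an
:class:`LDAModel` record.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator

from ._sampler import gibbs_fit, gibbs_foldin
from .io import Corpus

__all__ = [
    "LDAConfig",
    "LDAModel",
    "PhenomeLDA",
    "fit_lda",
    "heldout_perplexity",
    "match_topics",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class LDAConfig:
    """Sampler configuration.

    ``alpha=None`` resolves to the conventional symmetric 50/K; ``beta``
    defaults to 0.01.  ``burn_in`` iterations are discarded, then one sample
    is kept every ``sample_lag`` iterations.
    """

    n_topics: int
    alpha: float | None = None
    beta: float = 0.01
    n_iterations: int = 2000
    burn_in: int = 500
    sample_lag: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.sample_lag < 1:
            raise ValueError("sample_lag must be >= 1")

    @property
    def effective_alpha(self) -> float:
        return 50.0 / self.n_topics if self.alpha is None else self.alpha


@dataclass
class LDAModel:
    """A fitted topic model tied to a corpus' drug/phenotype indexing."""

    theta: np.ndarray  # (M, K) rows p(t|d)
    phi: np.ndarray  # (K, N_ph) rows p(ph|t)
    config: LDAConfig
    drug_ids: list[str]
    vocabulary: list[str]

    @property
    def n_topics(self) -> int:
        return self.phi.shape[0]

    def validate(self, atol: float = 1e-9) -> None:
        if (self.theta < 0).any() or (self.phi < 0).any():
            raise ValueError("theta/phi must be non-negative")
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=atol):
            raise ValueError("theta rows must sum to 1")
        if not np.allclose(self.phi.sum(axis=1), 1.0, atol=atol):
            raise ValueError("phi rows must sum to 1")


class PhenomeLDA(BaseEstimator):
    """Collapsed-Gibbs LDA estimator over a binary incidence (or count) matrix.

    Parameters mirror :class:`LDAConfig`; ``random_state`` seeds the
    sampler's own deterministic generator, so identical inputs and seed give
    bit-identical fits.

    Attributes (after ``fit``)
    --------------------------
    theta_ : ndarray of shape (n_documents, n_topics)
        Posterior-mean document–topic mixtures, rows sum to 1.
    components_ : ndarray of shape (n_topics, n_features)
        Posterior-mean topic–word distributions, rows sum to 1.
    n_post_samples_ : int
        Number of post-burn-in samples averaged.
    """

    def __init__(
        self,
        n_topics: int = 10,
        alpha: float | None = None,
        beta: float = 0.01,
        n_iterations: int = 2000,
        burn_in: int = 500,
        sample_lag: int = 10,
        random_state: int = 0,
    ):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.sample_lag = sample_lag
        self.random_state = random_state

    # -- helpers --------------------------------------------------------
    def _config(self) -> LDAConfig:
        return LDAConfig(
            n_topics=self.n_topics,
            alpha=self.alpha,
            beta=self.beta,
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            sample_lag=self.sample_lag,
            seed=self.random_state,
        )

    @staticmethod
    def _tokens_from_X(X) -> tuple[np.ndarray, np.ndarray, int, int]:
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be a 2-d count matrix")
        if (X < 0).any():
            raise ValueError("X must be non-negative counts")
        docs, words = [], []
        Xi = X.astype(np.int64)
        for d in range(Xi.shape[0]):
            for w in np.flatnonzero(Xi[d]):
                c = Xi[d, w]
                docs.extend([d] * c)
                words.extend([w] * c)
        return (
            np.asarray(docs, np.int64),
            np.asarray(words, np.int64),
            Xi.shape[0],
            Xi.shape[1],
        )

    # -- estimator API --------------------------------------------------
    def fit(self, X, y=None):
        """Fit on a documents × vocabulary count matrix or a :class:`Corpus`."""
        cfg = self._config()
        if isinstance(X, Corpus):
            doc_ids, word_ids = X.token_arrays()
            n_docs, n_words = X.n_documents, X.vocab_size
        else:
            doc_ids, word_ids, n_docs, n_words = self._tokens_from_X(X)
        if n_docs == 0 or len(doc_ids) == 0:
            raise ValueError("cannot fit LDA on an empty corpus")
        if cfg.n_topics > len(doc_ids):
            warnings.warn(
                f"n_topics={cfg.n_topics} exceeds the total token count "
                f"({len(doc_ids)}); surplus topics will stay near-empty",
                stacklevel=2,
            )
        theta, phi, n_samples = gibbs_fit(
            doc_ids,
            word_ids,
            n_docs,
            n_words,
            cfg.n_topics,
            cfg.effective_alpha,
            cfg.beta,
            cfg.n_iterations,
            cfg.burn_in,
            cfg.sample_lag,
            cfg.seed,
        )
        self.theta_ = theta
        self.components_ = phi
        self.n_post_samples_ = int(n_samples)
        self.n_features_in_ = n_words
        return self

    def transform(self, X):
        """Fold new documents into the fitted topics; returns doc–topic rows."""
        if not hasattr(self, "components_"):
            raise AttributeError("PhenomeLDA instance is not fitted yet")
        cfg = self._config()
        if isinstance(X, Corpus):
            docs = X.documents
            if X.vocab_size != self.n_features_in_:
                raise ValueError("corpus vocabulary size differs from the fit")
        else:
            doc_ids, word_ids, n_docs, n_words = self._tokens_from_X(X)
            if n_words != self.n_features_in_:
                raise ValueError("X has a different vocabulary size than the fit")
            docs = [word_ids[doc_ids == d] for d in range(n_docs)]
        out = np.empty((len(docs), cfg.n_topics))
        for i, doc in enumerate(docs):
            out[i] = gibbs_foldin(
                np.asarray(doc, np.int64),
                self.components_,
                cfg.effective_alpha,
                cfg.n_iterations,
                cfg.burn_in,
                cfg.sample_lag,
                cfg.seed + i,
            )
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X, y).theta_

    def to_model(self, drug_ids: list[str], vocabulary: list[str]) -> LDAModel:
        if not hasattr(self, "components_"):
            raise AttributeError("PhenomeLDA instance is not fitted yet")
        return LDAModel(self.theta_, self.components_, self._config(), list(drug_ids), list(vocabulary))


def fit_lda(corpus: Corpus, config: LDAConfig) -> LDAModel:
    """Fit the topic model on a phenome corpus (wrapper over :class:`PhenomeLDA`)."""
    est = PhenomeLDA(
        n_topics=config.n_topics,
        alpha=config.alpha,
        beta=config.beta,
        n_iterations=config.n_iterations,
        burn_in=config.burn_in,
        sample_lag=config.sample_lag,
        random_state=config.seed,
    ).fit(corpus)
    model = est.to_model(corpus.doc_ids, corpus.vocabulary)
    model.validate()
    return model


def heldout_perplexity(model: LDAModel, corpus: Corpus) -> float:
    """Perplexity of held-out tokens under the drug-wise mixture p(ph|d).

    ``corpus`` documents must align positionally with the model's drugs;
    p(ph|d) = Σ_t p(t|d) p(ph|t).  Lower is better; a uniform model over V
    terms scores exactly V.
    """
    if corpus.n_documents != model.theta.shape[0]:
        raise ValueError("corpus documents do not align with the model's drugs")
    vocab_index = {t: j for j, t in enumerate(model.vocabulary)}
    log_sum = 0.0
    n_tok = 0
    for d, doc in enumerate(corpus.documents):
        if len(doc) == 0:
            continue
        p_row = model.theta[d] @ model.phi
        for w in doc:
            term = corpus.vocabulary[int(w)]
            j = vocab_index.get(term)
            if j is None:
                raise ValueError(f"token {term!r} outside the model vocabulary")
            log_sum += float(np.log(p_row[j]))
            n_tok += 1
    if n_tok == 0:
        raise ValueError("corpus contains no tokens")
    return float(np.exp(-log_sum / n_tok))


def match_topics(phi_ref: np.ndarray, phi_est: np.ndarray) -> np.ndarray:
    """Best-permutation topic matching (Hungarian, L1 row distance).

    Returns the permutation ``perm`` such that ``phi_est[perm[k]]`` matches
    ``phi_ref[k]``.  Used in tests and diagnostics; topic labels are not
    identifiable, so all cross-model comparisons go through this.
    """
    if phi_ref.shape != phi_est.shape:
        raise ValueError("shape mismatch")
    K = phi_ref.shape[0]
    cost = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            cost[a, b] = np.abs(phi_ref[a] - phi_est[b]).sum()
    _, perm = linear_sum_assignment(cost)
    return perm


# -- serialization ------------------------------------------------------

def save_model(model: LDAModel, out_dir: str | Path) -> None:
    """Write theta/phi as headed TSVs plus a config sidecar.

    Floats are written at 17 significant digits, which round-trips float64
    exactly, so a reload restores bit-identical matrices.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    topics = [f"topic_{k}" for k in range(model.n_topics)]
    th = pd.DataFrame(model.theta, index=model.drug_ids, columns=topics)
    th.index.name = "drug_id"
    th.to_csv(out / "theta.tsv", sep="\t", float_format="%.17g")
    ph = pd.DataFrame(model.phi, index=topics, columns=model.vocabulary)
    ph.index.name = "topic"
    ph.to_csv(out / "phi.tsv", sep="\t", float_format="%.17g")
    cfg = asdict(model.config)
    (out / "model.meta.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))


def load_model(in_dir: str | Path) -> LDAModel:
    src = Path(in_dir)
    cfg = LDAConfig(**yaml.safe_load((src / "model.meta.yaml").read_text()))
    th = pd.read_csv(src / "theta.tsv", sep="\t", index_col=0, float_precision="round_trip")
    ph = pd.read_csv(src / "phi.tsv", sep="\t", index_col=0, float_precision="round_trip")
    return LDAModel(
        theta=th.to_numpy(dtype=np.float64),
        phi=ph.to_numpy(dtype=np.float64),
        config=cfg,
        drug_ids=[str(i) for i in th.index],
        vocabulary=[str(c) for c in ph.columns],
    )
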