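"""Choosing the number of topics K.

For each candidate K the model is fitted ``replicates`` times on the 90% of
tokens kept by a deterministic per-document split (every 10th token held
out), scored on the held-out tokens, and the criterion values averaged; the
arg-min K wins, ties going to the smaller K.  The default criterion is
held-out perplexity; alternative information criteria can be registered as
plugins under a name and selected with ``criterion="plugin:<name>"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .io import Corpus
from .lda import LDAConfig, LDAModel, fit_lda, heldout_perplexity
from .recovery import derive_seed

__all__ = [
    "SelectionResult",
    "select_topics",
    "split_corpus",
    "register_criterion",
]

# criterion(model, train_corpus, heldout_corpus) -> score (lower is better)
CriterionFn = Callable[[LDAModel, Corpus, Corpus], float]
_CRITERIA: dict[str, CriterionFn] = {}


def register_criterion(name: str, fn: CriterionFn) -> None:
    """Register an information criterion under ``plugin:<name>``."""
    _CRITERIA[name] = fn


@dataclass
class SelectionResult:
    grid: list[int]
    scores: list[float]  # mean criterion per K, aligned with grid
    sds: list[float]
    chosen_k: int
    replicates: int
    seeds: list[list[int]]  # seeds used, per K then per replicate
    criterion: str


def split_corpus(corpus: Corpus, period: int = 10) -> tuple[Corpus, Corpus]:
    """Deterministic per-document token split: every ``period``-th token held out.

    Tokens are taken in each document's stored (canonical) order; documents
    shorter than ``period`` contribute no held-out tokens.
    """
    if period < 2:
        raise ValueError("period must be >= 2")
    train_docs, held_docs = [], []
    for doc in corpus.documents:
        mask = (np.arange(len(doc)) + 1) % period == 0
        train_docs.append(doc[~mask])
        held_docs.append(doc[mask])
    train = Corpus(train_docs, list(corpus.vocabulary), list(corpus.doc_ids))
    held = Corpus(held_docs, list(corpus.vocabulary), list(corpus.doc_ids))
    return train, held


def select_topics(
    corpus: Corpus,
    grid: list[int],
    criterion: str = "heldout_perplexity",
    replicates: int = 3,
    seed: int = 0,
    base_config: LDAConfig | None = None,
) -> SelectionResult:
    """Fit every K in ``grid`` and return the criterion-minimizing one.

    Deterministic given (grid, replicates, seed): replicate seeds are
    derived from the master seed, and the held-out tokens are never shown
    to the fit.
    """
    if not grid:
        raise ValueError("empty candidate grid")
    if any(k < 1 for k in grid):
        raise ValueError("all K candidates must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if corpus.n_tokens == 0:
        raise ValueError("empty corpus")
    if criterion == "heldout_perplexity":
        crit_fn: CriterionFn = lambda m, tr, he: heldout_perplexity(m, he)
    elif criterion.startswith("plugin:"):
        name = criterion.split(":", 1)[1]
        if name not in _CRITERIA:
            raise ValueError(f"no criterion registered under {name!r}")
        crit_fn = _CRITERIA[name]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    train, held = split_corpus(corpus)
    if held.n_tokens == 0:
        raise ValueError("held-out split is empty; documents are too short")

    base = base_config or LDAConfig(n_topics=1)
    means: list[float] = []
    sds: list[float] = []
    seeds: list[list[int]] = []
    for ki, k in enumerate(grid):
        vals = []
        k_seeds = []
        for rep in range(replicates):
            s = derive_seed(seed, ki, rep)
            k_seeds.append(s)
            cfg = LDAConfig(
                n_topics=k,
                alpha=base.alpha,
                beta=base.beta,
                n_iterations=base.n_iterations,
                burn_in=base.burn_in,
                sample_lag=base.sample_lag,
                seed=s,
            )
            model = fit_lda(train, cfg)
            vals.append(float(crit_fn(model, train, held)))
        means.append(float(np.mean(vals)))
        sds.append(float(np.std(vals)))
        seeds.append(k_seeds)
    if not all(np.isfinite(means)):
        raise RuntimeError("criterion produced a non-finite score")
    # arg-min with ties toward the smaller K
    best_k = None
    best_score = np.inf
    for k, score in sorted(zip(grid, means)):
        if score < best_score:
            best_score = score
            best_k = k
    return SelectionResult(
        grid=list(grid),
        scores=means,
        sds=sds,
        chosen_k=int(best_k),
        replicates=replicates,
        seeds=seeds,
        criterion=criterion,
    )
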