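"""Applying the unperturbed model + criteria to propose repositioning links.

Three query modes: (a) ``suggest_indications`` emits novel (0-cell)
drug–indication pairs passing both criteria for drugs that have at least
one known indication; (b) ``retrieve_indications`` handles drugs with no
recorded indications, returning their top-``default_is`` above-chance
indications; (c) ``query_drugs`` reverses the question, ranking drugs for
one indication under a uniform drug prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PhenomeMatrix
from .scoring import DecisionCriteria, IndicationProbabilities, rank_and_decide

__all__ = [
    "Suggestion",
    "DrugQueryResult",
    "suggest_indications",
    "retrieve_indications",
    "query_drugs",
    "suggestions_to_frame",
]


@dataclass(frozen=True)
class Suggestion:
    drug: str
    indication: str
    probability: float
    rank: int
    is_used: int  # the IS bound the rank was checked against
    novel: bool  # pair absent (0-cell) in the source matrix


@dataclass
class DrugQueryResult:
    indication: str
    drugs: list[str]  # all rankable drugs, descending score
    scores: list[float]
    k: int  # number of drugs known to hold the indication (>= 1)
    candidates: list[str]  # top-k drugs not already associated


def _check_alignment(pid: IndicationProbabilities, matrix: PhenomeMatrix) -> None:
    if pid.drugs != list(matrix.drugs) or pid.indications != matrix.indication_ids:
        raise ValueError("indication probabilities do not index the given matrix")


def suggest_indications(
    matrix: PhenomeMatrix,
    pid: IndicationProbabilities,
    criteria: DecisionCriteria,
) -> list[Suggestion]:
    """Novel indications passing both criteria, for drugs with known indications.

    Ranking is over ALL indications (known ones included, so a drug's known
    indications occupy ranks inside its IS); only 0-cells are emitted.
    Output is sorted by drug, then rank — fully deterministic.
    """
    _check_alignment(pid, matrix)
    ind_cols = matrix.indication_columns
    out: list[Suggestion] = []
    for i, drug in enumerate(matrix.drugs):
        if drug in pid.excluded_drugs:
            continue
        known = matrix.X[i, ind_cols].astype(bool)
        if not known.any():
            continue  # handled by retrieve_indications
        preds = rank_and_decide(pid, criteria, drug)
        is_d = criteria.indication_space(drug)
        for j, pred in enumerate(preds):
            if known[j]:
                continue
            if pred.above_chance and pred.within_is:
                out.append(
                    Suggestion(
                        drug=drug,
                        indication=pred.indication,
                        probability=pred.probability,
                        rank=pred.rank,
                        is_used=is_d,
                        novel=True,
                    )
                )
    out.sort(key=lambda s: (s.drug, s.rank))
    return out


def retrieve_indications(
    matrix: PhenomeMatrix,
    pid: IndicationProbabilities,
    criteria: DecisionCriteria,
    drug: str,
) -> list[Suggestion]:
    """Top ``default_is`` above-chance indications for a drug with none recorded."""
    _check_alignment(pid, matrix)
    i = matrix.drug_index(drug)
    if matrix.X[i, matrix.indication_columns].any():
        raise ValueError(
            f"drug {drug!r} has known indications; use suggest_indications"
        )
    preds = rank_and_decide(pid, criteria, drug)
    preds.sort(key=lambda p: p.rank)
    out = [
        Suggestion(
            drug=drug,
            indication=p.indication,
            probability=p.probability,
            rank=p.rank,
            is_used=criteria.default_is,
            novel=True,
        )
        for p in preds
        if p.rank <= criteria.default_is and p.above_chance
    ]
    return out


def query_drugs(
    matrix: PhenomeMatrix,
    pid: IndicationProbabilities,
    indication: str,
) -> DrugQueryResult:
    """Rank drugs for one indication by p(i|d) under a uniform drug prior.

    With p(d) uniform, p(d|i) ∝ p(i|d), so the per-drug renormalized scores
    are compared directly across drugs.  k is the number of drugs already
    holding the indication (floored at 1); candidates are top-k drugs not
    among them.
    """
    _check_alignment(pid, matrix)
    if indication not in pid.indications:
        raise KeyError(f"unknown indication {indication!r}")
    j = pid.indications.index(indication)
    col = matrix.indication_columns[j]
    holders = {matrix.drugs[i] for i in np.flatnonzero(matrix.X[:, col])}
    rankable = [
        (d, float(pid.values[i, j]))
        for i, d in enumerate(matrix.drugs)
        if d not in pid.excluded_drugs
    ]
    order = sorted(range(len(rankable)), key=lambda r: (-rankable[r][1], rankable[r][0]))
    drugs = [rankable[r][0] for r in order]
    scores = [rankable[r][1] for r in order]
    k = max(len(holders), 1)
    candidates = [d for d in drugs[:k] if d not in holders]
    return DrugQueryResult(
        indication=indication, drugs=drugs, scores=scores, k=k, candidates=candidates
    )


def suggestions_to_frame(suggestions: list[Suggestion]) -> pd.DataFrame:
    """TSV-ready table: drug, indication, probability, rank, IS."""
    return pd.DataFrame(
        [
            {
                "drug_id": s.drug,
                "term_id": s.indication,
                "probability": s.probability,
                "rank": s.rank,
                "indication_space": s.is_used,
            }
            for s in suggestions
        ],
        columns=["drug_id", "term_id", "probability", "rank", "indication_space"],
    )
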