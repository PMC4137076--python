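"""From a fitted topic model to ranked drug–indication decisions.

The drug→phenotype path probability is the topic mixture
p(ph|d) = Σ_t p(t|d) p(ph|t).  Restricting a drug's row to the indication
columns and renormalizing gives p(i|d), which is compared against two
criteria: (1) it must exceed the random-chance level q — the probability of
drawing a known drug–indication pair uniformly from all drug × indication
cells — and (2) its rank among all indications must fall within the drug's
indication space IS (its count of known indications; drugs with none use a
configurable fallback, 13 by default, the mean IS of the SIDER-scale
phenome).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import PhenomeMatrix
from .lda import LDAModel

__all__ = [
    "PhenotypeProbabilities",
    "IndicationProbabilities",
    "DecisionCriteria",
    "RankedPrediction",
    "phenotype_probabilities",
    "indication_probabilities",
    "random_chance",
    "rank_and_decide",
    "mixture_scores",
]

DEFAULT_INDICATION_SPACE = 13


def mixture_scores(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Σ_t θ[:, t] φ[t, :] accumulated in fixed topic order.

    Equivalent to ``theta @ phi`` but with a pinned summation order, so the
    result is bit-identical to a plain double-loop summation over topics.
    """
    theta = np.asarray(theta, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    if theta.ndim == 1:
        theta = theta[None, :]
    if theta.shape[1] != phi.shape[0]:
        raise ValueError(
            f"topic dimension mismatch: theta has {theta.shape[1]}, phi has {phi.shape[0]}"
        )
    out = np.zeros((theta.shape[0], phi.shape[1]), dtype=np.float64)
    for t in range(phi.shape[0]):
        out += theta[:, t, None] * phi[None, t, :]
    return out


@dataclass
class PhenotypeProbabilities:
    """p(ph|d) for every drug row and phenotype column of the source matrix."""

    values: np.ndarray  # (M, N_ph)
    drugs: list[str]
    phenotypes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.drugs), len(self.phenotypes)):
            raise ValueError("probability matrix shape mismatch")


@dataclass
class IndicationProbabilities:
    """Per-drug renormalized p(i|d) over the indication columns only.

    Drugs whose indication-column mass is zero cannot be renormalized; they
    are listed in ``excluded_drugs`` and must be skipped by ranking code.
    """

    values: np.ndarray  # (M, |I|)
    drugs: list[str]
    indications: list[str]
    excluded_drugs: list[str] = field(default_factory=list)

    def drug_row(self, drug_id: str) -> np.ndarray:
        try:
            i = self.drugs.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug {drug_id!r}") from None
        if drug_id in self.excluded_drugs:
            raise ValueError(f"drug {drug_id!r} has zero indication mass and was excluded")
        return self.values[i]


@dataclass
class DecisionCriteria:
    """The two-part acceptance rule: above chance, and within the drug's IS."""

    q: float
    n_known_pairs: int
    per_drug_is: dict[str, int]
    default_is: int = DEFAULT_INDICATION_SPACE

    def __post_init__(self) -> None:
        if not (0 < self.q <= 1):
            raise ValueError("q must lie in (0, 1]")
        if self.default_is < 1:
            raise ValueError("default_is must be >= 1")
        if any(v < 0 for v in self.per_drug_is.values()):
            raise ValueError("per-drug IS counts must be >= 0")

    def indication_space(self, drug_id: str) -> int:
        """IS of a drug; the fallback applies when it has no known indications."""
        n = self.per_drug_is.get(drug_id, 0)
        return n if n > 0 else self.default_is

    @classmethod
    def from_matrix(
        cls,
        matrix: PhenomeMatrix,
        default_is: int = DEFAULT_INDICATION_SPACE,
    ) -> "DecisionCriteria":
        ind = matrix.is_indication
        per_drug = {
            d: int(matrix.X[i, ind].sum()) for i, d in enumerate(matrix.drugs)
        }
        n_known = matrix.n_known_pairs
        return cls(
            q=random_chance(n_known, matrix.n_drugs, matrix.n_indications),
            n_known_pairs=n_known,
            per_drug_is=per_drug,
            default_is=default_is,
        )


@dataclass(frozen=True)
class RankedPrediction:
    drug: str
    indication: str
    probability: float
    rank: int  # 1 = highest p(i|d) for this drug
    above_chance: bool  # strictly p > q
    within_is: bool  # rank <= IS(drug)


def phenotype_probabilities(model: LDAModel) -> PhenotypeProbabilities:
    """p(ph|d) = Σ_t p(t|d)·p(ph|t) for every drug (the θ·φ mixture)."""
    if model.theta.shape[1] != model.phi.shape[0]:
        raise ValueError("theta/phi topic dimensions disagree")
    return PhenotypeProbabilities(
        mixture_scores(model.theta, model.phi), list(model.drug_ids), list(model.vocabulary)
    )


def indication_probabilities(
    pphd: PhenotypeProbabilities, matrix: PhenomeMatrix
) -> IndicationProbabilities:
    """Restrict p(ph|d) to indication columns and renormalize each row to 1.

    Renormalization preserves the within-drug order of indications.  Rows
    with zero indication mass are flagged and excluded, with a warning.
    """
    if pphd.phenotypes != list(matrix.phenotypes) or pphd.drugs != list(matrix.drugs):
        raise ValueError("probability matrix does not index the given phenome matrix")
    cols = matrix.indication_columns
    sub = pphd.values[:, cols].copy()
    mass = sub.sum(axis=1)
    excluded = [matrix.drugs[i] for i in np.flatnonzero(mass == 0)]
    if excluded:
        warnings.warn(
            f"{len(excluded)} drug(s) with zero indication-column mass excluded "
            f"from ranking: {excluded[:5]}",
            stacklevel=2,
        )
    safe = np.where(mass == 0, 1.0, mass)
    sub /= safe[:, None]
    return IndicationProbabilities(
        sub, list(matrix.drugs), [matrix.phenotypes[j] for j in cols], excluded
    )


def random_chance(n_known_pairs: int, n_drugs: int, n_indications: int) -> float:
    """q = N_known / (|D|·|I|): chance of drawing a known pair uniformly."""
    if n_drugs <= 0 or n_indications <= 0:
        raise ValueError("drug and indication counts must be positive")
    if n_known_pairs <= 0:
        raise ValueError("n_known_pairs must be positive")
    if n_known_pairs > n_drugs * n_indications:
        raise ValueError("more known pairs than matrix cells")
    return n_known_pairs / (n_drugs * n_indications)


def rank_and_decide(
    pid: IndicationProbabilities,
    criteria: DecisionCriteria,
    drug: str,
) -> list[RankedPrediction]:
    """Rank all indications for one drug and evaluate both criteria.

    Ranks are 1..|I| by descending p(i|d); ties keep the canonical column
    order (stable sort).  ``above_chance`` is the strict comparison p > q;
    boundary cases are rejected.
    """
    row = pid.drug_row(drug)
    order = np.argsort(-row, kind="stable")
    is_d = criteria.indication_space(drug)
    out: list[RankedPrediction] = []
    ranks = np.empty(len(row), dtype=np.int64)
    ranks[order] = np.arange(1, len(row) + 1)
    for j, term in enumerate(pid.indications):
        p = float(row[j])
        r = int(ranks[j])
        out.append(
            RankedPrediction(
                drug=drug,
                indication=term,
                probability=p,
                rank=r,
                above_chance=p > criteria.q,
                within_is=r <= is_d,
            )
        )
    return out
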