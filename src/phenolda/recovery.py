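"""Leave-one-out masked-indication recovery.

Each known drug–indication 1-cell (except those whose indication is held by
a single drug, which masking would erase from the data set entirely) is
switched to 0 one at a time; the model is refitted on the perturbed matrix
and asked to rank the masked indication among all indications for that
drug.  A masked pair counts as recovered when its renormalized probability
exceeds random chance AND its rank falls within the drug's indication
space, both computed against the UNPERTURBED matrix's bookkeeping.  The
success rate s = n_recovered / n_above_chance summarizes the run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import PhenomeMatrix, to_corpus
from .lda import LDAConfig, LDAModel, PhenomeLDA, fit_lda
from .scoring import (
    DecisionCriteria,
    mixture_scores,
)

__all__ = [
    "MaskablePair",
    "PairOutcome",
    "RecoveryReport",
    "enumerate_maskable_pairs",
    "run_recovery",
    "summarize_recovery",
    "success_rate",
    "derive_seed",
]


def derive_seed(*parts: int) -> int:
    """Stable sub-stream seed below 2**31 from integer key parts."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class MaskablePair:
    drug: str
    indication: str
    eligible: bool  # indication held by >= 2 drugs


@dataclass(frozen=True)
class PairOutcome:
    drug: str
    indication: str
    probability: float
    rank: int
    above_chance: bool
    within_is: bool


@dataclass
class RecoveryReport:
    outcomes: list[PairOutcome]
    mode: str
    seed: int
    criteria: DecisionCriteria

    @property
    def n_tested(self) -> int:
        return len(self.outcomes)

    @property
    def n_above_chance(self) -> int:
        return sum(o.above_chance for o in self.outcomes)

    @property
    def n_recovered(self) -> int:
        return sum(o.above_chance and o.within_is for o in self.outcomes)

    @property
    def s(self) -> float | None:
        """Success rate n_recovered / n_above_chance; None when undefined."""
        return success_rate(self.n_recovered, self.n_above_chance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([o.__dict__ for o in self.outcomes])


def success_rate(n_recovered: int, n_above_chance: int) -> float | None:
    """s = n_recovered / n_above_chance; undefined (None) on an empty denominator."""
    if n_above_chance == 0:
        return None
    if not (0 <= n_recovered <= n_above_chance):
        raise ValueError("need 0 <= n_recovered <= n_above_chance")
    return n_recovered / n_above_chance


def enumerate_maskable_pairs(matrix: PhenomeMatrix) -> list[MaskablePair]:
    """All known drug–indication pairs, flagged maskable when the indication
    is held by at least two drugs.  Deterministic row-major order."""
    cols = matrix.indication_columns
    col_sums = matrix.X[:, cols].sum(axis=0)
    pairs: list[MaskablePair] = []
    for i, drug in enumerate(matrix.drugs):
        hits = np.flatnonzero(matrix.X[i, cols])
        for h in hits:
            pairs.append(
                MaskablePair(
                    drug=drug,
                    indication=matrix.phenotypes[cols[h]],
                    eligible=bool(col_sums[h] >= 2),
                )
            )
    return pairs


def _masked_indication_outcome(
    theta_row: np.ndarray,
    phi: np.ndarray,
    ind_cols: np.ndarray,
    target_pos: int,
    drug: str,
    indication: str,
    criteria: DecisionCriteria,
) -> PairOutcome:
    p_row = mixture_scores(theta_row, phi)[0]
    sub = p_row[ind_cols]
    mass = sub.sum()
    if mass <= 0:
        raise ValueError(f"drug {drug!r} has zero indication mass after masking")
    sub = sub / mass
    order = np.argsort(-sub, kind="stable")
    ranks = np.empty(len(sub), dtype=np.int64)
    ranks[order] = np.arange(1, len(sub) + 1)
    p = float(sub[target_pos])
    rank = int(ranks[target_pos])
    return PairOutcome(
        drug=drug,
        indication=indication,
        probability=p,
        rank=rank,
        above_chance=p > criteria.q,
        within_is=rank <= criteria.indication_space(drug),
    )


def run_recovery(
    matrix: PhenomeMatrix,
    lda_config: LDAConfig,
    criteria: DecisionCriteria | None = None,
    pairs: list[MaskablePair] | None = None,
    seed: int = 0,
    mode: str = "refit",
) -> RecoveryReport:
    """Mask each pair, rescore it, restore the cell.

    ``mode="refit"`` refits the full model on the perturbed matrix with a
    per-pair derived seed (faithful but costly); ``mode="foldin"`` fits one
    model on the unperturbed matrix and folds only the perturbed drug
    document into its fixed topics (fast approximation).  The decision
    criteria — q and each drug's IS — always come from the unperturbed
    matrix.  The input matrix is bit-identical before and after the run.
    """
    if mode not in ("refit", "foldin"):
        raise ValueError("mode must be 'refit' or 'foldin'")
    if criteria is None:
        criteria = DecisionCriteria.from_matrix(matrix)
    all_pairs = enumerate_maskable_pairs(matrix)
    eligible = {(p.drug, p.indication) for p in all_pairs if p.eligible}
    if pairs is None:
        pairs = [p for p in all_pairs if p.eligible]
    else:
        for p in pairs:
            if (p.drug, p.indication) not in eligible:
                raise ValueError(
                    f"pair ({p.drug!r}, {p.indication!r}) is not maskable "
                    "(unknown, or its indication is held by a single drug)"
                )

    checksum_before = matrix.checksum()
    ind_cols = matrix.indication_columns
    col_pos = {matrix.phenotypes[c]: k for k, c in enumerate(ind_cols)}

    base_model: LDAModel | None = None
    base_est: PhenomeLDA | None = None
    if mode == "foldin":
        cfg0 = replace(lda_config, seed=derive_seed(seed, 0))
        base_est = PhenomeLDA(
            n_topics=cfg0.n_topics,
            alpha=cfg0.alpha,
            beta=cfg0.beta,
            n_iterations=cfg0.n_iterations,
            burn_in=cfg0.burn_in,
            sample_lag=cfg0.sample_lag,
            random_state=cfg0.seed,
        ).fit(to_corpus(matrix))

    outcomes: list[PairOutcome] = []
    try:
        for idx, pair in enumerate(pairs):
            d = matrix.drug_index(pair.drug)
            j = matrix.term_index(pair.indication)
            assert matrix.X[d, j] == 1
            matrix.X[d, j] = 0
            pair_seed = derive_seed(seed, idx + 1)
            try:
                if mode == "refit":
                    cfg = replace(lda_config, seed=pair_seed)
                    model = fit_lda(to_corpus(matrix), cfg)
                    theta_row = model.theta[d]
                    phi = model.phi
                else:
                    from ._sampler import gibbs_foldin

                    doc = np.flatnonzero(matrix.X[d]).astype(np.int64)
                    theta_row = gibbs_foldin(
                        doc,
                        base_est.components_,
                        lda_config.effective_alpha,
                        lda_config.n_iterations,
                        lda_config.burn_in,
                        lda_config.sample_lag,
                        pair_seed,
                    )
                    phi = base_est.components_
            finally:
                matrix.X[d, j] = 1
            outcomes.append(
                _masked_indication_outcome(
                    np.asarray(theta_row),
                    phi,
                    ind_cols,
                    col_pos[pair.indication],
                    pair.drug,
                    pair.indication,
                    criteria,
                )
            )
    finally:
        if matrix.checksum() != checksum_before:
            raise RuntimeError("mask-and-restore violated: matrix changed")
    return RecoveryReport(outcomes=outcomes, mode=mode, seed=seed, criteria=criteria)


def summarize_recovery(
    report: RecoveryReport, bin_width: float = 0.005
) -> dict:
    """Aggregate a recovery run.

    Returns the success rate s, a histogram of per-pair p(i|d) at the given
    bin width (with the count of pairs above q), the success rate stratified
    by IS, and the cumulative success rate after incrementally dropping
    drugs below an IS cutoff.
    """
    if report.n_tested == 0:
        raise ValueError("empty recovery report")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    probs = np.array([o.probability for o in report.outcomes])
    n_bins = int(np.ceil(max(probs.max(), bin_width) / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(probs, bins=edges)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )

    frame = report.to_frame()
    frame["is_"] = [report.criteria.indication_space(o.drug) for o in report.outcomes]

    def _rate(g: pd.DataFrame) -> float | None:
        return success_rate(
            int((g.above_chance & g.within_is).sum()), int(g.above_chance.sum())
        )

    levels = sorted(frame["is_"].unique())
    by_is = pd.DataFrame(
        {
            "is_": levels,
            "success_rate": [_rate(frame[frame["is_"] == v]) for v in levels],
        }
    )
    cutoffs = levels
    cumulative = pd.DataFrame(
        {
            "min_is": cutoffs,
            "success_rate": [_rate(frame[frame["is_"] >= c]) for c in cutoffs],
            "n_pairs": [int((frame["is_"] >= c).sum()) for c in cutoffs],
        }
    )
    return {
        "n_tested": report.n_tested,
        "n_above_chance": report.n_above_chance,
        "n_recovered": report.n_recovered,
        "s": report.s,
        "histogram": hist,
        "n_above_q": int((probs > report.criteria.q).sum()),
        "success_by_is": by_is,
        "success_by_min_is": cumulative,
    }
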