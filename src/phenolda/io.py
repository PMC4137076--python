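"""Reading drug–phenotype association tables and building the phenome matrix.

The input is a long-format table in the style of SIDER: one row per
(drug, phenotype term) association, each term labelled as a side effect or
an indication.  The working representation is a binary drug × phenotype
incidence matrix whose columns are partitioned into side-effect and
indication columns, plus a token "corpus" view in which each drug is a
document and each present phenotype contributes one token.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SIDE_EFFECT = "side_effect"
INDICATION = "indication"

__all__ = [
    "SIDE_EFFECT",
    "INDICATION",
    "PhenomeRecord",
    "PhenomeMatrix",
    "Corpus",
    "TableDialect",
    "read_phenome_table",
    "build_matrix",
    "to_corpus",
    "write_matrix",
    "load_matrix",
]


@dataclass(frozen=True)
class PhenomeRecord:
    """One drug–phenotype association row.

    ``term_class`` is either ``"side_effect"`` or ``"indication"``; term ids
    are opaque (MedDRA-style codes or free labels) and are never parsed.
    """

    drug_id: str
    term_id: str
    term_name: str
    term_class: str

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValueError("drug_id must be non-empty")
        if not self.term_id:
            raise ValueError("term_id must be non-empty")
        if self.term_class not in (SIDE_EFFECT, INDICATION):
            raise ValueError(
                f"term_class must be {SIDE_EFFECT!r} or {INDICATION!r}, "
                f"got {self.term_class!r}"
            )


@dataclass
class PhenomeMatrix:
    """Binary drug × phenotype incidence matrix with a column partition.

    Rows are drugs, columns are phenotype terms; ``is_indication[j]`` marks
    column ``j`` as an indication (otherwise a side effect).  Column order is
    canonical: side-effect columns first, then indication columns, each block
    sorted lexicographically by term id.  Drug rows are sorted
    lexicographically by drug id.
    """

    drugs: list[str]
    phenotypes: list[str]
    is_indication: np.ndarray  # bool, length N_ph
    X: np.ndarray  # uint8, shape (M, N_ph), entries in {0, 1}

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=np.uint8)
        self.is_indication = np.asarray(self.is_indication, dtype=bool)
        if self.X.shape != (len(self.drugs), len(self.phenotypes)):
            raise ValueError("matrix shape does not match drug/phenotype lists")
        if self.is_indication.shape != (len(self.phenotypes),):
            raise ValueError("is_indication length does not match phenotypes")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")
        if len(set(self.drugs)) != len(self.drugs):
            raise ValueError("duplicate drug identifiers")
        if len(set(self.phenotypes)) != len(self.phenotypes):
            raise ValueError("duplicate phenotype identifiers")

    # -- derived counts -------------------------------------------------
    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotypes)

    @property
    def n_indications(self) -> int:
        return int(self.is_indication.sum())

    @property
    def n_side_effects(self) -> int:
        return self.n_phenotypes - self.n_indications

    @property
    def n_known_pairs(self) -> int:
        """Number of 1-cells in indication columns (known drug–indication pairs)."""
        return int(self.X[:, self.is_indication].sum())

    @property
    def n_unknown_pairs(self) -> int:
        """Number of 0-cells in indication columns (candidate pairs)."""
        return self.n_drugs * self.n_indications - self.n_known_pairs

    @property
    def indication_columns(self) -> np.ndarray:
        return np.flatnonzero(self.is_indication)

    @property
    def side_effect_columns(self) -> np.ndarray:
        return np.flatnonzero(~self.is_indication)

    @property
    def indication_ids(self) -> list[str]:
        return [self.phenotypes[j] for j in self.indication_columns]

    def drug_index(self, drug_id: str) -> int:
        try:
            return self.drugs.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug {drug_id!r}") from None

    def term_index(self, term_id: str) -> int:
        try:
            return self.phenotypes.index(term_id)
        except ValueError:
            raise KeyError(f"unknown phenotype term {term_id!r}") from None

    def known_indications(self, drug_id: str) -> int:
        """Count of known indications of ``drug_id`` (its indication space)."""
        return int(self.X[self.drug_index(drug_id), self.is_indication].sum())

    def checksum(self) -> bytes:
        import hashlib

        h = hashlib.sha256()
        h.update(self.X.tobytes())
        h.update("\x00".join(self.drugs).encode())
        h.update("\x00".join(self.phenotypes).encode())
        h.update(self.is_indication.tobytes())
        return h.digest()

    def copy(self) -> "PhenomeMatrix":
        return PhenomeMatrix(
            list(self.drugs), list(self.phenotypes), self.is_indication.copy(), self.X.copy()
        )


@dataclass
class Corpus:
    """Token view of a phenome matrix: one document of count-1 tokens per drug."""

    documents: list[np.ndarray]  # int64 token ids into ``vocabulary``
    vocabulary: list[str]
    doc_ids: list[str]

    def __post_init__(self) -> None:
        self.documents = [np.asarray(d, dtype=np.int64) for d in self.documents]
        if len(self.documents) != len(self.doc_ids):
            raise ValueError("documents and doc_ids differ in length")

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_tokens(self) -> int:
        return int(sum(len(d) for d in self.documents))

    @property
    def vocab_size(self) -> int:
        return len(self.vocabulary)

    def token_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to parallel (doc index, word index) arrays, document order."""
        if self.n_tokens == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        doc_ids = np.concatenate(
            [np.full(len(d), i, dtype=np.int64) for i, d in enumerate(self.documents)]
        )
        word_ids = np.concatenate(self.documents) if self.documents else np.empty(0, np.int64)
        return doc_ids, word_ids


@dataclass
class TableDialect:
    """Column mapping for a long-format association table.

    Column selectors are header names, or 0-based positions when
    ``has_header`` is false.  ``class_values`` maps raw class labels
    (matched case-insensitively after stripping) onto the two canonical
    classes.
    """

    drug_column: str | int = "drug_id"
    term_id_column: str | int = "term_id"
    term_name_column: str | int | None = "term_name"
    class_column: str | int = "term_class"
    class_values: dict[str, str] = field(default_factory=dict)
    has_header: bool = True

    def class_map(self) -> dict[str, str]:
        mapping = {
            "side_effect": SIDE_EFFECT,
            "side effect": SIDE_EFFECT,
            "se": SIDE_EFFECT,
            "adverse": SIDE_EFFECT,
            "indication": INDICATION,
            "ind": INDICATION,
        }
        for raw, canon in self.class_values.items():
            canon_l = canon.strip().lower()
            if canon_l not in (SIDE_EFFECT, INDICATION):
                raise ValueError(f"class_values target {canon!r} is not a phenotype class")
            mapping[raw.strip().lower()] = canon_l
        return mapping


def read_phenome_table(
    path: str | Path, dialect: TableDialect | None = None
) -> list[PhenomeRecord]:
    """Read a long-format drug–phenotype TSV into records.

    One record per data row; duplicates are preserved at this stage (they are
    collapsed by :func:`build_matrix`).  Rows with an empty drug or term id
    are reported with a warning and dropped; an unmappable class label is an
    error.  An empty table yields an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or TableDialect()
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        header=0 if dialect.has_header else None,
        encoding="utf-8",
    )
    if frame.empty:
        warnings.warn(f"{path}: table has no data rows", stacklevel=2)
        return []

    def col(selector: str | int) -> pd.Series:
        if isinstance(selector, int):
            return frame.iloc[:, selector]
        if selector not in frame.columns:
            raise ValueError(f"{path}: column {selector!r} not found in header")
        return frame[selector]

    drugs = col(dialect.drug_column).str.strip()
    terms = col(dialect.term_id_column).str.strip()
    names = (
        col(dialect.term_name_column).str.strip()
        if dialect.term_name_column is not None
        else terms
    )
    raw_classes = col(dialect.class_column).str.strip()
    class_map = dialect.class_map()

    records: list[PhenomeRecord] = []
    bad_rows: list[int] = []
    for i in range(len(frame)):
        drug, term, name, raw = drugs.iat[i], terms.iat[i], names.iat[i], raw_classes.iat[i]
        if not drug or not term:
            bad_rows.append(i)
            continue
        cls = class_map.get(raw.lower())
        if cls is None:
            raise ValueError(
                f"{path}: row {i}: term_class {raw!r} not mappable to "
                f"{SIDE_EFFECT!r}/{INDICATION!r}"
            )
        records.append(PhenomeRecord(drug, term, name, cls))
    if bad_rows:
        warnings.warn(
            f"{path}: {len(bad_rows)} row(s) with empty drug/term id dropped "
            f"(rows {bad_rows[:10]}{'...' if len(bad_rows) > 10 else ''})",
            stacklevel=2,
        )
    return records


def build_matrix(records: list[PhenomeRecord]) -> PhenomeMatrix:
    """Deduplicate records into a canonical binary incidence matrix.

    Column order is side effects then indications, lexicographic within each
    class; drug rows are lexicographic.  The result is therefore invariant to
    the order of ``records``.  A term id appearing under both classes is an
    error.
    """
    if not records:
        raise ValueError("cannot build a matrix from zero records")
    term_class: dict[str, str] = {}
    for r in records:
        prev = term_class.setdefault(r.term_id, r.term_class)
        if prev != r.term_class:
            raise ValueError(
                f"term {r.term_id!r} appears as both {prev!r} and {r.term_class!r}"
            )
    side_effects = sorted(t for t, c in term_class.items() if c == SIDE_EFFECT)
    indications = sorted(t for t, c in term_class.items() if c == INDICATION)
    phenotypes = side_effects + indications
    drugs = sorted({r.drug_id for r in records})
    col = {t: j for j, t in enumerate(phenotypes)}
    row = {d: i for i, d in enumerate(drugs)}
    X = np.zeros((len(drugs), len(phenotypes)), dtype=np.uint8)
    for r in records:
        X[row[r.drug_id], col[r.term_id]] = 1
    is_indication = np.zeros(len(phenotypes), dtype=bool)
    is_indication[len(side_effects):] = True
    return PhenomeMatrix(drugs, phenotypes, is_indication, X)


def to_corpus(matrix: PhenomeMatrix) -> Corpus:
    """Binary rows become documents: one count-1 token per present phenotype.

    An all-zero drug row yields an empty document (permitted, with a
    warning).  ``to_corpus`` round-trips: rebuilding the incidence from the
    documents reproduces the matrix exactly.
    """
    documents = [np.flatnonzero(row).astype(np.int64) for row in matrix.X]
    empty = [matrix.drugs[i] for i, d in enumerate(documents) if len(d) == 0]
    if empty:
        warnings.warn(
            f"{len(empty)} drug(s) with no phenotypes yield empty documents: "
            f"{empty[:5]}{'...' if len(empty) > 5 else ''}",
            stacklevel=2,
        )
    return Corpus(documents, list(matrix.phenotypes), list(matrix.drugs))


# -- serialization ------------------------------------------------------

def write_matrix(matrix: PhenomeMatrix, out_dir: str | Path) -> None:
    """Write dense 0/1 TSV, sparse triplet TSV and a metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dense = pd.DataFrame(matrix.X, index=matrix.drugs, columns=matrix.phenotypes)
    dense.index.name = "drug_id"
    dense.to_csv(out / "matrix.tsv", sep="\t")
    rows, cols = np.nonzero(matrix.X)
    trip = pd.DataFrame(
        {
            "drug_id": [matrix.drugs[i] for i in rows],
            "term_id": [matrix.phenotypes[j] for j in cols],
            "value": 1,
        }
    )
    trip.to_csv(out / "matrix.triplets.tsv", sep="\t", index=False)
    meta = {
        "drugs": list(matrix.drugs),
        "phenotypes": list(matrix.phenotypes),
        "classes": [
            INDICATION if b else SIDE_EFFECT for b in matrix.is_indication.tolist()
        ],
    }
    (out / "matrix.meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def load_matrix(in_dir: str | Path) -> PhenomeMatrix:
    """Load a matrix written by :func:`write_matrix`."""
    src = Path(in_dir)
    meta = yaml.safe_load((src / "matrix.meta.yaml").read_text())
    dense = pd.read_csv(src / "matrix.tsv", sep="\t", index_col=0, dtype=str)
    drugs = list(meta["drugs"])
    phenotypes = list(meta["phenotypes"])
    X = dense.loc[drugs, phenotypes].to_numpy(dtype=np.uint8)
    is_indication = np.array([c == INDICATION for c in meta["classes"]], dtype=bool)
    return PhenomeMatrix(drugs, phenotypes, is_indication, X)
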