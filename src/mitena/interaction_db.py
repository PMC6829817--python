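"""Load, validate, index, filter, and synthesise miRNA-target interaction tables.

An :class:`InteractionDB` is the statistical universe for every downstream
analysis: its size ``universe_M`` is the *M* of the hypergeometric test.
Two kinds of tables are supported:

* *predicted* interactions (TargetScan-style), carrying a real-valued ranking
  score where more negative means stronger predicted repression (the
  context++ convention);
* *validated* interactions (miRTarBase-style), carrying an evidence category
  (``strong`` for e.g. luciferase assay / western blot, ``weak`` for e.g.
  CLIP-derived support).

miRNA identifiers are matched case-sensitively (miRBase IDs are
case-meaningful: ``hsa-miR-…`` vs ``hsa-mir-…``); gene symbols are upper-cased
on load because symbols in the wild vary in case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCES = ("predicted", "validated")
EVIDENCE_LEVELS = ("strong", "weak", "none")

#: Canonical internal column order; ``write_interactions`` emits exactly these.
CANONICAL_COLUMNS = ["mirna_id", "gene_symbol", "species", "source", "evidence", "score", "family"]


class FormatError(ValueError):
    """The input table does not match the declared dialect."""


class EmptyInputError(ValueError):
    """The input file or list contains no usable rows."""


class LookupError_(KeyError):
    """An identifier is absent from the database."""


@dataclass(frozen=True)
class Dialect:
    """Column-mapping configuration for a delimited interaction table.

    ``score_col`` applies to predicted tables, ``evidence_col`` to validated
    ones; either may be ``None`` when the table lacks that column.
    """

    mirna_col: str
    gene_col: str
    score_col: str | None = None
    evidence_col: str | None = None
    family_col: str | None = None
    species: str = "hsa"


#: TargetScan 7.2 default predicted-target file headers.
TARGETSCAN_DIALECT = Dialect(
    mirna_col="miRNA",
    gene_col="Gene Symbol",
    score_col="Cumulative weighted context++ score",
    family_col="miR Family",
)

#: miRTarBase 7.0 spreadsheet headers.
MIRTARBASE_DIALECT = Dialect(
    mirna_col="miRNA",
    gene_col="Target Gene",
    evidence_col="Support Type",
)

#: Canonical internal dialect (what ``write_interactions`` produces).
CANONICAL_DIALECT = Dialect(
    mirna_col="mirna_id",
    gene_col="gene_symbol",
    score_col="score",
    evidence_col="evidence",
    family_col="family",
)


def classify_evidence(support_type: str) -> str:
    """Map a miRTarBase "Support Type" string onto the two-level evidence model.

    Strings containing ``(Weak)`` — e.g. ``Functional MTI (Weak)`` — are
    ``weak``; every other non-empty string is ``strong``.
    """
    if "(weak)" in str(support_type).strip().lower():
        return "weak"
    return "strong"


@dataclass
class InteractionDB:
    """Indexed bipartite table of miRNA-target interactions.

    ``records`` holds one row per deduplicated (miRNA, gene) pair with the
    canonical columns.  ``universe_M`` is the number of interactions, i.e. the
    urn size of the over-representation test.
    """

    records: pd.DataFrame
    source: str
    species: str = "hsa"
    _by_mirna: dict[str, pd.DataFrame] | None = field(default=None, repr=False, compare=False)
    _by_gene: dict[str, pd.DataFrame] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"records missing canonical columns: {missing}")

    # -- indices -----------------------------------------------------------

    @property
    def universe_M(self) -> int:
        return len(self.records)

    @property
    def index_by_mirna(self) -> dict[str, pd.DataFrame]:
        if self._by_mirna is None:
            self._by_mirna = {m: g for m, g in self.records.groupby("mirna_id", sort=False)}
        return self._by_mirna

    @property
    def index_by_gene(self) -> dict[str, pd.DataFrame]:
        if self._by_gene is None:
            self._by_gene = {g: d for g, d in self.records.groupby("gene_symbol", sort=False)}
        return self._by_gene

    @property
    def mirnas(self) -> list[str]:
        return list(self.records["mirna_id"].unique())

    @property
    def genes(self) -> list[str]:
        return list(self.records["gene_symbol"].unique())

    def targets_of(self, mirna_id: str) -> set[str]:
        if mirna_id not in self.index_by_mirna:
            raise LookupError_(f"unknown miRNA identifier: {mirna_id!r}")
        return set(self.index_by_mirna[mirna_id]["gene_symbol"])

    def mirnas_targeting(self, gene_symbol: str) -> set[str]:
        gene_symbol = gene_symbol.upper()
        if gene_symbol not in self.index_by_gene:
            raise LookupError_(f"unknown gene symbol: {gene_symbol!r}")
        return set(self.index_by_gene[gene_symbol]["mirna_id"])


def _canonicalise(df: pd.DataFrame, source: str) -> pd.DataFrame:
    """Normalise identifiers and dedup (miRNA, gene) pairs.

    Predicted tables keep the best (most negative) score per pair; validated
    tables keep the strongest evidence and record the pre-dedup support-row
    count in ``n_support`` (used as the validated rank surrogate).
    """
    df = df.copy()
    df["mirna_id"] = df["mirna_id"].astype(str).str.strip()
    df["gene_symbol"] = df["gene_symbol"].astype(str).str.strip().str.upper()
    bad = (df["mirna_id"] == "") | (df["gene_symbol"] == "")
    n_bad = int(bad.sum())
    if n_bad:
        df = df[~bad]
    if source == "predicted":
        df["evidence"] = "none"
        df = df.sort_values(["mirna_id", "gene_symbol", "score"], kind="mergesort")
        deduped = df.drop_duplicates(["mirna_id", "gene_symbol"], keep="first")
        deduped = deduped.assign(n_support=1)
    else:
        df["score"] = np.nan
        # strong < weak lexically sorts strong first, keeping the strongest
        df = df.sort_values(["mirna_id", "gene_symbol", "evidence"], kind="mergesort")
        counts = df.groupby(["mirna_id", "gene_symbol"], sort=False).size().rename("n_support")
        deduped = df.drop_duplicates(["mirna_id", "gene_symbol"], keep="first")
        deduped = deduped.merge(counts, left_on=["mirna_id", "gene_symbol"], right_index=True)
    deduped = deduped.sort_values(["mirna_id", "gene_symbol"], kind="mergesort").reset_index(drop=True)
    deduped.attrs["rows_dropped"] = n_bad
    return deduped


def load_interactions(path, source: str, dialect: Dialect | None = None, delimiter: str | None = None) -> InteractionDB:
    """Read a delimited interaction table into a deduplicated, indexed DB.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    source
        ``"predicted"`` (scored) or ``"validated"`` (evidence-categorised).
    dialect
        Column mapping; defaults to :data:`TARGETSCAN_DIALECT` for predicted
        and :data:`MIRTARBASE_DIALECT` for validated tables.
    delimiter
        Field delimiter; sniffed from the header line (tab vs comma) when
        ``None``.

    Duplicate (miRNA, gene) pairs are collapsed keeping the best score
    (predicted) or the strongest evidence (validated).  A load report (rows
    read / dropped / duplicates collapsed) goes to the module logger.
    """
    if source not in SOURCES:
        raise ValueError(f"source must be one of {SOURCES}, got {source!r}")
    if dialect is None:
        dialect = TARGETSCAN_DIALECT if source == "predicted" else MIRTARBASE_DIALECT

    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        if not header.strip():
            raise EmptyInputError(f"{path}: empty input file")
        delimiter = "\t" if header.count("\t") >= header.count(",") else ","

    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    if raw.empty:
        raise EmptyInputError(f"{path}: no data rows")

    needed = {"mirna_id": dialect.mirna_col, "gene_symbol": dialect.gene_col}
    for canonical, col in needed.items():
        if col not in raw.columns:
            raise FormatError(f"{path}: missing mapped column {col!r} (for {canonical})")

    df = pd.DataFrame({
        "mirna_id": raw[dialect.mirna_col],
        "gene_symbol": raw[dialect.gene_col],
    })
    df["species"] = dialect.species
    df["source"] = source
    if source == "predicted":
        if dialect.score_col is not None:
            if dialect.score_col not in raw.columns:
                raise FormatError(f"{path}: missing mapped column {dialect.score_col!r} (for score)")
            df["score"] = pd.to_numeric(raw[dialect.score_col], errors="coerce")
        else:
            df["score"] = np.nan
        df["evidence"] = "none"
    else:
        if dialect.evidence_col is not None:
            if dialect.evidence_col not in raw.columns:
                raise FormatError(f"{path}: missing mapped column {dialect.evidence_col!r} (for evidence)")
            df["evidence"] = raw[dialect.evidence_col].map(classify_evidence)
        else:
            df["evidence"] = "strong"
        df["score"] = np.nan
    if dialect.family_col is not None and dialect.family_col in raw.columns:
        df["family"] = raw[dialect.family_col]
    else:
        df["family"] = ""

    n_read = len(df)
    deduped = _canonicalise(df, source)
    n_dropped = deduped.attrs.get("rows_dropped", 0)
    n_collapsed = n_read - n_dropped - len(deduped)
    logger.info(
        "loaded %s: %d rows read, %d dropped (empty identifiers), %d duplicates collapsed, universe_M=%d",
        path, n_read, n_dropped, n_collapsed, len(deduped),
    )
    return InteractionDB(records=deduped[CANONICAL_COLUMNS + ["n_support"]], source=source, species=dialect.species)


def write_interactions(db: InteractionDB, path) -> None:
    """Write the canonical deduplicated table as TSV (round-trips with
    :func:`load_interactions` under :data:`CANONICAL_DIALECT`)."""
    db.records[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False)


def filter_by_evidence(db: InteractionDB, mode: str) -> InteractionDB:
    """Restrict a validated DB to an evidence category.

    ``mode`` is ``strong``, ``weak`` or ``strong_and_weak``; ``universe_M`` is
    recomputed.  An empty result (e.g. ``weak`` on an all-strong DB) is a
    valid empty DB, not an error.
    """
    if db.source != "validated":
        raise ValueError("evidence filtering applies only to validated interaction DBs")
    if mode == "strong_and_weak":
        keep = db.records["evidence"].isin(["strong", "weak"])
    elif mode in ("strong", "weak"):
        keep = db.records["evidence"] == mode
    else:
        raise ValueError(f"unknown evidence mode {mode!r}")
    return InteractionDB(records=db.records[keep].reset_index(drop=True), source=db.source, species=db.species)


def top_targets(db: InteractionDB, mirna_id: str, k: int) -> list[str]:
    """Return the miRNA's top ``min(k, K)`` target genes, deterministically.

    Predicted DBs rank by ascending score (most negative context++ first);
    validated DBs rank by descending pre-dedup support-row count.  Ties break
    lexicographically by gene symbol, so the order is stable across runs.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if mirna_id not in db.index_by_mirna:
        raise LookupError_(f"unknown miRNA identifier: {mirna_id!r}")
    recs = db.index_by_mirna[mirna_id]
    if db.source == "predicted":
        ordered = recs.sort_values(["score", "gene_symbol"], kind="mergesort")
    else:
        ordered = recs.sort_values(["n_support", "gene_symbol"], ascending=[False, True], kind="mergesort")
    return list(ordered["gene_symbol"].head(k))


def _sample_bounded_power_law(rng: np.random.Generator, exponent: float, kmin: int, kmax: int, n: int) -> np.ndarray:
    """Draw n integers from P(k) ∝ k^-exponent on [kmin, kmax]."""
    ks = np.arange(kmin, kmax + 1)
    pmf = ks.astype(float) ** (-exponent)
    pmf /= pmf.sum()
    return rng.choice(ks, size=n, p=pmf)


def bounded_power_law_mle(counts, kmin: int, kmax: int) -> float:
    """Maximum-likelihood exponent of a bounded discrete power law.

    Grid-refined MLE of γ in P(k) ∝ k^-γ on [kmin, kmax] given observed
    counts; used to verify the synthetic generator's degree law.
    """
    counts = np.asarray(counts, dtype=float)
    ks = np.arange(kmin, kmax + 1, dtype=float)
    logk = np.log(ks)
    sum_log = np.log(counts).sum()
    n = len(counts)

    def nll(gamma: float) -> float:
        logz = np.log(np.exp(-gamma * logk).sum())
        return gamma * sum_log + n * logz

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(nll, bounds=(0.1, 6.0), method="bounded")
    return float(res.x)


def generate_synthetic_db(
    n_mirnas: int,
    n_genes: int,
    exponent: float = 1.8,
    min_targets: int = 20,
    max_targets: int = 2000,
    seed: int = 0,
    species: str = "hsa",
) -> InteractionDB:
    """Synthesise a predicted-style interaction DB with heavy-tailed degrees.

    Each synthetic miRNA's target count is drawn from a bounded discrete
    power law P(k) ∝ k^-exponent on [min_targets, max_targets]; its targets
    are sampled without replacement from ``n_genes`` synthetic gene symbols
    and given i.i.d. negative scores (stronger predicted repression = more
    negative, mimicking context++ scores).  Reproducible given ``seed``; no
    duplicate (miRNA, gene) pairs by construction.
    """
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    if not (1 <= min_targets <= max_targets):
        raise ValueError("need 1 <= min_targets <= max_targets")
    if n_genes < max_targets:
        raise ValueError(
            f"n_genes ({n_genes}) must be >= max_targets ({max_targets}): "
            "a miRNA cannot target more genes than exist"
        )
    rng = np.random.default_rng(seed)
    genes = np.array([f"GENE{i:05d}" for i in range(n_genes)])
    mirnas = [f"syn-miR-{i + 1}-5p" for i in range(n_mirnas)]
    degrees = _sample_bounded_power_law(rng, exponent, min_targets, max_targets, n_mirnas)
    frames = []
    for mirna, deg in zip(mirnas, degrees):
        targets = rng.choice(genes, size=int(deg), replace=False)
        scores = -rng.exponential(scale=0.3, size=int(deg))
        frames.append(pd.DataFrame({
            "mirna_id": mirna,
            "gene_symbol": targets,
            "species": species,
            "source": "predicted",
            "evidence": "none",
            "score": scores,
            "family": "",
        }))
    records = pd.concat(frames, ignore_index=True)
    records = records.sort_values(["mirna_id", "gene_symbol"], kind="mergesort").reset_index(drop=True)
    records["n_support"] = 1
    return InteractionDB(records=records, source="predicted", species=species)
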