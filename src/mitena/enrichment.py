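"""Hypergeometric over-representation of miRNA-target interactions.

Given an interaction database (the urn) and an input list of genes or mature
miRNAs, each candidate item on the opposite side of the bipartite table is
tested for over-representation of its interactions within the input list:

    p = 1 - sum_{i=0}^{X-1} C(K, i) C(M-K, N-i) / C(M, N)

i.e. the upper-tail probability P(count >= X) of a hypergeometric draw, where

* M — size of the universe (total interactions in the DB),
* N — length of the (deduplicated) input list,
* K — number of interactions the candidate item has in the DB,
* X — how many of those interactions fall inside the input list.

This "interaction universe" convention mixes interaction counts with list
lengths; it is the tool's native urn and the default here.  An alternative
self-consistent entity universe (M = distinct genes in the DB, K = distinct
targets of the miRNA) is available via ``universe="entities"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from mitena.interaction_db import InteractionDB

GENES_IN = "genes_in__mirnas_out"
MIRNAS_IN = "mirnas_in__genes_out"

#: Tool-wide defaults ("default parameters"): FDR threshold and minimum overlap.
DEFAULT_FDR = 0.05
DEFAULT_MIN_OVERLAP = 1


def _log_binom(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_pvalue(M: int, K: int, N: int, X: int) -> float:
    """Upper-tail hypergeometric probability P(count >= X).

    Computed by summing the hypergeometric pmf over the upper tail in
    log space (log-binomials via ``gammaln``), which is stable for M up to
    ~1e6.  The lower tail is summed instead whenever it is the shorter one,
    and the complement taken, so neither tail's length hurts accuracy.

    Raises ``ValueError`` unless 0 <= K <= M, 0 <= N <= M and
    0 <= X <= min(K, N).
    """
    for name, v in (("M", M), ("K", K), ("N", N), ("X", X)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    M, K, N, X = int(M), int(K), int(N), int(X)
    if K > M or N > M:
        raise ValueError(f"need K <= M and N <= M (got M={M}, K={K}, N={N})")
    if X > min(K, N):
        raise ValueError(f"X ({X}) exceeds min(K, N) = {min(K, N)}")
    if X == 0:
        return 1.0
    hi = min(K, N)
    denom = _log_binom(M, N)
    # sum the upper tail directly: subtracting the lower tail from 1 would
    # amplify the ~1e-9 absolute error of large-argument log-binomials into
    # percent-level relative error whenever the tail probability is tiny
    i_values = np.arange(X, hi + 1)
    logs = _log_binom(K, i_values) + _log_binom(M - K, N - i_values) - denom
    m = logs.max()
    p = float(np.exp(m) * np.exp(logs - m).sum())
    return float(min(max(p, 0.0), 1.0))


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving.

    Values are clipped to 1; an input outside [0, 1] raises ``ValueError``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    """Enrichment table plus the input identifiers the DB did not contain."""

    rows: pd.DataFrame
    unmatched: list[str]
    direction: str
    universe: str
    M: int
    N: int

    def __len__(self) -> int:
        return len(self.rows)


RESULT_COLUMNS = ["item", "M", "N", "K", "X", "p_value", "fdr", "overlap"]


def enrich(db: InteractionDB, input_list, direction: str, universe: str = "interactions") -> EnrichmentResult:
    """Test every candidate item for over-representation in the input list.

    Parameters
    ----------
    db
        The interaction universe.
    input_list
        Gene symbols (``direction=genes_in__mirnas_out``) or mature miRNA IDs
        (``direction=mirnas_in__genes_out``), deduplicated after identifier
        normalisation; must be non-empty.
    direction
        Which side of the bipartite table the input sits on.  With genes in,
        miRNAs come out, and vice versa.
    universe
        ``"interactions"`` (native convention: M = total interactions) or
        ``"entities"`` (M = distinct items on the input's side of the DB).

    Returns one row per candidate with X >= 1, sorted by p-value then item.
    The BH adjustment runs over *all* candidates with K >= 1 in the DB (not
    only the overlapping ones), which is the conservative choice; rows with
    X = 0 are then dropped from the report.  Input identifiers absent from
    the DB are returned in ``unmatched`` rather than silently discarded.
    """
    if direction not in (GENES_IN, MIRNAS_IN):
        raise ValueError(f"unknown direction {direction!r}")
    if universe not in ("interactions", "entities"):
        raise ValueError(f"unknown universe mode {universe!r}")

    if direction == GENES_IN:
        normalise = lambda s: str(s).strip().upper()
        known = db.index_by_gene
        candidates = db.index_by_mirna
        partner_col = "gene_symbol"
    else:
        normalise = lambda s: str(s).strip()
        known = db.index_by_mirna
        candidates = db.index_by_gene
        partner_col = "mirna_id"

    seen: dict[str, None] = {}
    for ident in input_list:
        ident = normalise(ident)
        if ident:
            seen.setdefault(ident)
    deduped = list(seen)
    if not deduped:
        raise ValueError("input list is empty after deduplication")
    matched = [i for i in deduped if i in known]
    unmatched = [i for i in deduped if i not in known]
    matched_set = set(matched)

    N = len(deduped)
    if universe == "interactions":
        M = db.universe_M
    else:
        M = len(known)
        N = len(matched)  # entity urn: only identifiers that exist in it

    items, Ks, Xs, overlaps = [], [], [], []
    for item, recs in candidates.items():
        partners = recs[partner_col]
        if universe == "interactions":
            K = len(recs)
        else:
            K = partners.nunique()
        hit = sorted(set(partners) & matched_set)
        items.append(item)
        Ks.append(K)
        Xs.append(len(hit))
        overlaps.append(hit)

    p = np.array([hypergeom_pvalue(M, k, N, x) for k, x in zip(Ks, Xs)])
    fdr = adjust_fdr(p) if len(p) else np.array([])
    rows = pd.DataFrame({
        "item": items,
        "M": M,
        "N": N,
        "K": Ks,
        "X": Xs,
        "p_value": p,
        "fdr": fdr,
        "overlap": overlaps,
    })
    rows = rows[rows["X"] >= 1]
    rows = rows.sort_values(["p_value", "item"], kind="mergesort").reset_index(drop=True)
    return EnrichmentResult(rows=rows, unmatched=unmatched, direction=direction, universe=universe, M=M, N=N)


def filter_results(rows: pd.DataFrame, threshold: float = DEFAULT_FDR, on: str = "fdr",
                   min_overlap: int = DEFAULT_MIN_OVERLAP) -> pd.DataFrame:
    """Keep rows with ``on``-metric <= threshold and X >= min_overlap.

    ``threshold`` must lie in (0, 1]; ``on`` is ``"p_value"`` or ``"fdr"``.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if on not in ("p_value", "fdr"):
        raise ValueError(f"filter metric must be 'p_value' or 'fdr', got {on!r}")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    keep = (rows[on] <= threshold) & (rows["X"] >= min_overlap)
    return rows[keep].reset_index(drop=True)


def write_results(result: EnrichmentResult, path) -> None:
    """Write the enrichment table as tab-delimited text (overlap ';'-joined)."""
    out = result.rows.copy()
    out["overlap"] = out["overlap"].map(";".join)
    out[RESULT_COLUMNS].to_csv(path, sep="\t", index=False)
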