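"""Simulation-based evaluation of miRNA-activity detection.

The benchmark plants miRNA activity into a synthetic expression matrix and
asks whether the over-representation pipeline recovers the active miRNAs:

* Every gene in the interaction DB gets i.i.d. standard-normal expression
  across samples, E(g, s) ~ N(0, 1).
* A set of active miRNAs is chosen; the j-th represses its top
  ``target_counts[j]`` targets (100, 200, … under the default budgets).
* In half of the samples (the *affected* ones) each repressed target's value
  is reduced by α + ε with ε ~ N(0, 1), i.e.
  E(g, s) = N(0, 1) − (α + N(0, 1)): expectation −α, variance 2.
* The activity level α sweeps a grid (0.3 … 1.0 in steps of 0.05 by
  default); at each α a differential input gene list is derived (one-sided
  Welch t-test, affected < unaffected, BH FDR ≤ 0.05), fed to the
  enrichment with default filtering, and every DB miRNA is called
  detected or not.  The per-α (FPR, TPR) points trace a ROC curve whose
  trapezoidal area summarises detection power.

A companion precision harness feeds a list of representative proteins
(e.g. tissue-high proteins) to the enrichment and scores how many of the
detected miRNAs belong to an independently defined representative set:
PPV = TP / (TP + FP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mitena.enrichment import (
    DEFAULT_FDR,
    DEFAULT_MIN_OVERLAP,
    GENES_IN,
    adjust_fdr,
    enrich,
    filter_results,
)
from mitena.interaction_db import InteractionDB, top_targets

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.30, 1.0001, 0.05), 2))
DEFAULT_TARGET_COUNTS = tuple(range(100, 1001, 100))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the planted-activity benchmark.

    Defaults are the reference conditions: 100 samples, 50 of them affected,
    10 active miRNAs with budgets 100..1000, α from 0.3 to 1.0 in 0.05 steps.
    """

    n_samples: int = 100
    n_affected: int = 50
    n_active: int = 10
    target_counts: tuple[int, ...] = DEFAULT_TARGET_COUNTS
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_affected > self.n_samples:
            raise ValueError("n_affected cannot exceed n_samples")
        if len(self.target_counts) != self.n_active:
            raise ValueError("target_counts must list one budget per active miRNA")
        if any(a <= 0 for a in self.alpha_grid):
            raise ValueError("all activity levels must be positive")


def scaled_config(n_active: int = 5, seed: int = 0, **overrides) -> SimulationConfig:
    """Reference conditions scaled to fewer active miRNAs (budgets 100·j)."""
    kw = dict(
        n_active=n_active,
        target_counts=tuple(100 * j for j in range(1, n_active + 1)),
        seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclass
class SimulatedDataset:
    """Expression matrix with the planted ground truth."""

    expression: pd.DataFrame  # genes × samples
    active_mirnas: list[str]
    affected_samples: list[str]
    alpha: float
    repressed_genes: set[str] = field(default_factory=set)

    @property
    def unaffected_samples(self) -> list[str]:
        return [s for s in self.expression.columns if s not in set(self.affected_samples)]


def eligible_mirnas(db: InteractionDB, min_targets: int) -> list[str]:
    """miRNAs with at least ``min_targets`` targets in the DB (a budget of
    "top K targets" presupposes K targets exist)."""
    sizes = db.records.groupby("mirna_id", sort=False).size()
    return sorted(sizes[sizes >= min_targets].index)


def simulate_expression(
    config: SimulationConfig,
    db: InteractionDB,
    alpha: float,
    seed: int | None = None,
    active_mirnas: list[str] | None = None,
) -> SimulatedDataset:
    """Draw one simulated dataset at activity level ``alpha``.

    Baseline expression is i.i.d. N(0, 1) over (DB genes) × samples.  Active
    miRNAs are chosen uniformly at random among those with at least
    ``max(target_counts)`` targets unless given explicitly; the j-th
    represses its top ``target_counts[j]`` targets in every affected sample
    by α + N(0, 1).  A gene targeted by several active miRNAs is repressed
    once.  Fully reproducible given the seed.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    max_budget = max(config.target_counts)
    if active_mirnas is None:
        pool = eligible_mirnas(db, max_budget)
        if len(pool) < config.n_active:
            raise ValueError(
                f"only {len(pool)} miRNAs have >= {max_budget} targets; "
                f"need {config.n_active} active miRNAs"
            )
        active_mirnas = list(rng.choice(pool, size=config.n_active, replace=False))
    else:
        active_mirnas = list(active_mirnas)
        if len(active_mirnas) != config.n_active:
            raise ValueError("active_mirnas length must equal n_active")

    genes = db.genes
    samples = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    E = rng.standard_normal((len(genes), config.n_samples))
    affected_idx = rng.choice(config.n_samples, size=config.n_affected, replace=False)
    affected_idx.sort()

    gene_pos = {g: i for i, g in enumerate(genes)}
    repressed: set[str] = set()
    for mirna, budget in zip(active_mirnas, config.target_counts):
        repressed.update(top_targets(db, mirna, budget))
    rep_rows = np.array(sorted(gene_pos[g] for g in repressed))
    if len(rep_rows):
        eps = rng.standard_normal((len(rep_rows), config.n_affected))
        E[np.ix_(rep_rows, affected_idx)] -= alpha + eps

    expr = pd.DataFrame(E, index=genes, columns=samples)
    return SimulatedDataset(
        expression=expr,
        active_mirnas=active_mirnas,
        affected_samples=[samples[i] for i in affected_idx],
        alpha=alpha,
        repressed_genes=repressed,
    )


def derive_input_list(dataset: SimulatedDataset, fdr_threshold: float = 0.05) -> list[str]:
    """Differential gene list: one-sided Welch t-test per gene.

    Tests affected < unaffected (miRNA repression reduces expression) and
    returns genes passing BH FDR ≤ ``fdr_threshold``.  Deterministic given
    the dataset.
    """
    aff = dataset.affected_samples
    unaff = dataset.unaffected_samples
    if len(aff) < 2 or len(unaff) < 2:
        raise ValueError("both sample groups need >= 2 members for a two-sample test")
    A = dataset.expression[aff].to_numpy()
    U = dataset.expression[unaff].to_numpy()
    res = stats.ttest_ind(A, U, axis=1, equal_var=False, alternative="less")
    q = adjust_fdr(res.pvalue)
    genes = dataset.expression.index.to_numpy()
    return list(genes[q <= fdr_threshold])


@dataclass
class EvaluationResult:
    """ROC over the α-sweep: one (FPR, TPR) operating point per α."""

    points: list[tuple[float, float, float]]  # (alpha, fpr, tpr)
    auc: float
    detected: dict[float, set[str]]
    active_mirnas: list[str]


def roc_auc(points) -> float:
    """Trapezoidal area under the staircase through the sorted unique
    (FPR, TPR) points, anchored at (0, 0) and (1, 1)."""
    pts = sorted({(float(f), float(t)) for _, f, t in points} | {(0.0, 0.0), (1.0, 1.0)})
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    return float(np.trapezoid(tpr, fpr))


def evaluate_detection(
    db: InteractionDB,
    config: SimulationConfig,
    fdr_threshold: float = DEFAULT_FDR,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> EvaluationResult:
    """Sweep the α-grid and score detection of the planted miRNAs.

    The active set is drawn once from the master seed and held fixed across
    the sweep (the same miRNAs act at every level); each α level then gets
    fresh, independently seeded noise.  At each α: simulate, derive the
    differential gene list, run the gene-list enrichment under default
    filtering, and call every DB miRNA detected or not.  TPR is the detected
    fraction of active miRNAs, FPR the detected fraction of inactive ones;
    the AUC comes from :func:`roc_auc`.
    """
    master = np.random.SeedSequence(config.seed)
    pick_rng = np.random.default_rng(master.spawn(1)[0])
    pool = eligible_mirnas(db, max(config.target_counts))
    if len(pool) < config.n_active:
        raise ValueError(
            f"only {len(pool)} miRNAs have >= {max(config.target_counts)} targets; "
            f"need {config.n_active}"
        )
    active = list(pick_rng.choice(pool, size=config.n_active, replace=False))
    active_set = set(active)
    all_mirnas = set(db.mirnas)
    inactive = all_mirnas - active_set

    points = []
    detected_by_alpha: dict[float, set[str]] = {}
    for i, alpha in enumerate(config.alpha_grid):
        # fixed per-α offset from the master seed: independent noise per level
        alpha_seed = np.random.SeedSequence([config.seed, 1000 + i])
        sim_seed = alpha_seed.generate_state(1)[0] % (2**31)
        ds = simulate_expression(config, db, alpha=alpha, seed=int(sim_seed), active_mirnas=active)
        gene_list = derive_input_list(ds)
        if not gene_list:
            detected: set[str] = set()
        else:
            result = enrich(db, gene_list, direction=GENES_IN)
            kept = filter_results(result.rows, threshold=fdr_threshold, on="fdr",
                                  min_overlap=min_overlap)
            detected = set(kept["item"])
        detected_by_alpha[float(alpha)] = detected
        tpr = len(detected & active_set) / len(active_set)
        fpr = len(detected & inactive) / len(inactive) if inactive else 0.0
        points.append((float(alpha), fpr, tpr))
        logger.info("alpha=%.2f: |input|=%d, detected=%d, TPR=%.2f, FPR=%.3f",
                    alpha, len(gene_list), len(detected), tpr, fpr)

    return EvaluationResult(points=points, auc=roc_auc(points),
                            detected=detected_by_alpha, active_mirnas=active)


# -- tissue-representativeness precision harness ---------------------------

def average_repeat_measurements(profile: pd.DataFrame, id_col: str = "mirna",
                                value_col: str = "expression") -> pd.Series:
    """Average repeat measurements of the same miRNA into one value each."""
    return profile.groupby(id_col)[value_col].mean()


def select_representative_mirnas(profile: pd.Series, percentile: float = 75.0) -> set[str]:
    """miRNAs whose expression is strictly greater than the given percentile
    of the profile's value distribution (linear-interpolation quantile).

    With all values equal, nothing exceeds the percentile and the result is
    empty.  ``profile`` maps miRNA id → expression, repeats already averaged.
    """
    if len(profile) == 0:
        raise ValueError("empty expression profile")
    cut = np.percentile(profile.to_numpy(dtype=float), percentile)
    return set(profile.index[profile.to_numpy(dtype=float) > cut])


@dataclass
class PPVResult:
    """Precision of detected miRNAs against a representative reference set.

    ``ppv`` is ``None`` (undefined) when nothing was detected.
    """

    tp: int
    fp: int
    ppv: float | None
    detected: set[str] = field(default_factory=set)

    @property
    def defined(self) -> bool:
        return self.ppv is not None


def ppv_evaluation(
    representative_proteins,
    representative_mirnas,
    db: InteractionDB,
    fdr_threshold: float = DEFAULT_FDR,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> PPVResult:
    """Precision of the gene-list enrichment against a reference miRNA set.

    Runs the enrichment with default filtering on the representative
    proteins; among detected miRNAs, those in ``representative_mirnas``
    count as true positives and the rest as false positives;
    PPV = TP / (TP + FP), 1 in a perfect test.
    """
    proteins = list(representative_proteins)
    reference = set(representative_mirnas)
    if not proteins or not reference:
        raise ValueError("both input sets must be non-empty")
    result = enrich(db, proteins, direction=GENES_IN)
    kept = filter_results(result.rows, threshold=fdr_threshold, on="fdr", min_overlap=min_overlap)
    detected = set(kept["item"])
    tp = len(detected & reference)
    fp = len(detected - reference)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    return PPVResult(tp=tp, fp=fp, ppv=ppv, detected=detected)
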