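"""Ranking, pooled ROC analysis and stratified reports.

Candidate targets are ranked per drug by descending similarity. The ROC
analysis is pooled (micro-averaged): every scored (drug, gene) cell of the
similarity matrix is one instance, cells listed in the evaluation set are
positives, every other scored cell is treated as a negative
(unlabeled-as-negative — no negative sampling). The curve is swept over
descending score thresholds with tied scores processed as one block, which
makes the trapezoid-rule AUC identical to the Mann-Whitney U statistic with
ties counted 1/2.

Confidence intervals use a normal approximation with a maximum-variance
bound: sigma^2 = AUC(1-AUC)/min(m, n) for m positives and n negatives, so
the interval is AUC +/- z * sigma, clipped to [0, 1]. A Hanley-McNeil
variance is available behind the same switch for comparison.

Stratified analyses restrict the candidate space: for protein families the
gene columns are restricted to family members (every drug kept), for drug
categories the drug rows are restricted (every gene kept); groups must have
strictly more than ``min_positives`` positive pairs to be reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .corpus import EvaluationSet
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

VARIANCE_FORMULAS = ("max_variance", "hanley_mcneil")


@dataclass
class ROCResult:
    """ROC curve, AUC and its normal-approximation confidence interval."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    m: int          # positives
    n: int          # negatives
    ci: tuple[float, float]
    label: str = ""

    def to_points_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr,
                             "threshold": self.thresholds})

    def summary_row(self) -> dict:
        return {"label": self.label, "auc": self.auc, "ci_lower": self.ci[0],
                "ci_upper": self.ci[1], "m": self.m, "n": self.n}


@dataclass
class StratifiedReport:
    """Per-group ROC results for one grouping kind; may be empty if no
    group passes the minimum-positives rule."""

    kind: str                       # protein_family | drug_category
    min_positives: int
    groups: dict[str, ROCResult] = field(default_factory=dict)
    skipped: dict[str, int] = field(default_factory=dict)  # group -> positives

    @property
    def empty(self) -> bool:
        return not self.groups

    def to_frame(self) -> pd.DataFrame:
        rows = [r.summary_row() | {"group": g} for g, r in self.groups.items()]
        cols = ["group", "auc", "ci_lower", "ci_upper", "m", "n"]
        return pd.DataFrame(rows, columns=cols + ["label"])[cols]


def rank_targets(matrix: SimilarityMatrix, drug: str) -> pd.DataFrame:
    """Rank candidate genes for one drug by descending similarity.

    Ties share the mean of their rank span (mid-rank); the listing order is
    deterministic via a secondary sort on gene ID. Returns a DataFrame with
    columns ``gene_id, score, rank``.
    """
    scores = matrix.drug_row(drug)
    ranks = rankdata(-scores, method="average")
    order = np.lexsort((np.array(matrix.genes, dtype=object), -scores))
    return pd.DataFrame({
        "gene_id": [matrix.genes[i] for i in order],
        "score": scores[order],
        "rank": ranks[order],
    })


def _positive_mask(matrix: SimilarityMatrix, eval_set: EvaluationSet
                   ) -> np.ndarray:
    drug_index = {d: i for i, d in enumerate(matrix.drugs)}
    gene_index = {g: j for j, g in enumerate(matrix.genes)}
    mask = np.zeros(matrix.scores.shape, dtype=bool)
    n_outside = 0
    for d, g in eval_set.pair_set():
        if d in drug_index and g in gene_index:
            mask[drug_index[d], gene_index[g]] = True
        else:
            n_outside += 1
    if n_outside:
        logger.info("%d evaluation pair(s) fall outside the scored matrix "
                    "and are excluded", n_outside)
    return mask


def auc_ci(auc_value: float, m: int, n: int, *, level: float = 0.95,
           variance_formula: str = "max_variance") -> tuple[float, float]:
    """Normal-approximation confidence interval for an AUC.

    ``max_variance`` (default) uses the distribution-free bound
    sigma^2 = AUC(1-AUC)/min(m, n); ``hanley_mcneil`` uses the
    exponential-model variance of Hanley & McNeil (1982). Bounds are
    clipped to [0, 1]; the interval degenerates to a point at AUC 0 or 1.
    """
    if m < 1 or n < 1:
        raise ValueError("confidence interval requires m >= 1 and n >= 1")
    if not 0.0 <= auc_value <= 1.0:
        raise ValueError(f"AUC outside [0, 1]: {auc_value}")
    if variance_formula == "max_variance":
        var = auc_value * (1.0 - auc_value) / min(m, n)
    elif variance_formula == "hanley_mcneil":
        q1 = auc_value / (2.0 - auc_value)
        q2 = 2.0 * auc_value**2 / (1.0 + auc_value)
        var = (auc_value * (1 - auc_value) + (m - 1) * (q1 - auc_value**2)
               + (n - 1) * (q2 - auc_value**2)) / (m * n)
    else:
        raise ValueError(f"unknown variance formula {variance_formula!r}; "
                         f"choose from {VARIANCE_FORMULAS}")
    z = float(norm.ppf(0.5 + level / 2.0))
    half = z * np.sqrt(max(var, 0.0))
    return (max(0.0, auc_value - half), min(1.0, auc_value + half))


def roc(matrix: SimilarityMatrix, eval_set: EvaluationSet, *,
        level: float = 0.95, variance_formula: str = "max_variance",
        label: str = "") -> ROCResult:
    """Pooled ROC over all scored (drug, gene) cells.

    Pairs in ``eval_set`` (intersected with the matrix) are positives, all
    other scored cells negatives. AUC is the trapezoid-rule area of the
    tie-blocked threshold sweep, equal to the Mann-Whitney U statistic over
    positive/negative score pairs with ties counted 1/2.
    """
    mask = _positive_mask(matrix, eval_set)
    y_true = mask.ravel()
    y_score = matrix.scores.ravel()
    m = int(y_true.sum())
    n = int(y_true.size - m)
    if m == 0 or n == 0:
        raise ValueError(
            f"evaluation set {eval_set.source or label or '<unnamed>'!r}: "
            f"{m} positive(s) and {n} negative(s) after intersection with the "
            "matrix; ROC undefined")
    fpr, tpr, thresholds = _roc_curve(y_true, y_score, drop_intermediate=False)
    auc_value = float(_trapezoid_auc(fpr, tpr))
    ci = auc_ci(auc_value, m, n, level=level, variance_formula=variance_formula)
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc_value,
                     m=m, n=n, ci=ci, label=label or eval_set.source)


def _subset_matrix(matrix: SimilarityMatrix, *, drugs: list[str] | None = None,
                   genes: list[str] | None = None) -> SimilarityMatrix:
    d_idx = ([matrix.drugs.index(d) for d in drugs] if drugs is not None
             else list(range(len(matrix.drugs))))
    g_idx = ([matrix.genes.index(g) for g in genes] if genes is not None
             else list(range(len(matrix.genes))))
    return SimilarityMatrix(
        drugs=[matrix.drugs[i] for i in d_idx],
        genes=[matrix.genes[j] for j in g_idx],
        scores=matrix.scores[np.ix_(d_idx, g_idx)], measure=matrix.measure)


def stratified_roc(matrix: SimilarityMatrix, eval_set: EvaluationSet,
                   grouping, *, kind: str, min_positives: int = 5,
                   level: float = 0.95,
                   variance_formula: str = "max_variance") -> StratifiedReport:
    """Per-group ROC analysis by protein family or drug category.

    ``grouping`` is a TSV path or DataFrame with columns
    ``entity_id, group``. For ``kind="protein_family"`` the candidate genes
    are restricted to each family's members (all drugs kept); for
    ``kind="drug_category"`` the drugs are restricted (all genes kept).
    Groups with at most ``min_positives`` positives in their restricted
    matrix are skipped and recorded; an empty report (no group passes) is
    returned as such, not raised.
    """
    if kind not in ("protein_family", "drug_category"):
        raise ValueError(f"unknown grouping kind {kind!r}")
    if not isinstance(grouping, pd.DataFrame):
        grouping = pd.read_csv(grouping, sep="\t", dtype=str)
    if not {"entity_id", "group"} <= set(grouping.columns):
        raise ValueError("grouping table needs columns (entity_id, group)")
    report = StratifiedReport(kind=kind, min_positives=min_positives)
    scored = set(matrix.genes if kind == "protein_family" else matrix.drugs)
    for group, sub in grouping.groupby("group", sort=True):
        members = sorted(set(sub["entity_id"]) & scored)
        if not members:
            continue
        if kind == "protein_family":
            sub_matrix = _subset_matrix(matrix, genes=members)
        else:
            sub_matrix = _subset_matrix(matrix, drugs=members)
        n_pos = int(_positive_mask(sub_matrix, eval_set).sum())
        if n_pos <= min_positives:
            report.skipped[group] = n_pos
            logger.info("group %r skipped: %d positive(s), need > %d",
                        group, n_pos, min_positives)
            continue
        report.groups[group] = roc(sub_matrix, eval_set, level=level,
                                   variance_formula=variance_formula,
                                   label=group)
    return report


def plot_roc(results, path) -> None:
    """Plot one or more ROC curves to an image file (SVG/PNG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(results, ROCResult):
        results = [results]
    fig, ax = plt.subplots(figsize=(5, 5))
    for r in results:
        ax.plot(r.fpr, r.tpr,
                label=f"{r.label or 'ROC'} (AUC={r.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("False-positive rate")
    ax.set_ylabel("True-positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
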