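"""Validation-based tuning and evaluation.

Quantitative imputations are scored by Pearson correlation with observed
trait values; binary-risk imputations by the AUC of the continuous
imputed score against observed status.  Two correlated AUCs on the same
samples are compared with DeLong's paired test.  Tuning is retrospective:
the mixing weight omega is grid-searched and the transfer method's epoch
is chosen as the argmax of the per-epoch validation metric (early
stopping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .genodata import AlignmentError, GenotypeMatrix
from .impute import DEFAULT_RIDGE, gram_solve


@dataclass
class TuningResult:
    grid: list[tuple[float, float]]  # (parameter value, validation metric)
    selected: float
    metric_name: str  # pearson | auc

    def __post_init__(self) -> None:
        best = max(m for _, m in self.grid)
        sel = dict(self.grid)[self.selected]
        if not np.isclose(sel, best):
            raise ValueError("selected parameter does not attain the grid maximum")


def pearson_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation; errors on constant input."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for constant input")
    ac = a - a.mean()
    bc = b - b.mean()
    return float(ac @ bc / np.sqrt((ac @ ac) * (bc @ bc)))


def _split_classes(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("AUC undefined with a single class")
    return cases, controls


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(case score > control score) + half-credit ties."""
    cases, controls = _split_classes(scores, labels)
    n1, n0 = len(cases), len(controls)
    ranks = sps.rankdata(np.concatenate([cases, controls]))
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> list[tuple[float, float]]:
    """(fpr, tpr) points from a descending threshold sweep over unique scores."""
    cases, controls = _split_classes(scores, labels)
    n1, n0 = len(cases), len(controls)
    points = [(0.0, 0.0)]
    for thr in np.unique(np.concatenate([cases, controls]))[::-1]:
        tpr = float((cases >= thr).sum() / n1)
        fpr = float((controls >= thr).sum() / n0)
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def _placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components: per-case and per-control placements."""
    n1, n0 = len(cases), len(controls)
    all_ranks = sps.rankdata(np.concatenate([cases, controls]))
    case_ranks = sps.rankdata(cases)
    control_ranks = sps.rankdata(controls)
    v10 = (all_ranks[:n1] - case_ranks) / n0          # per case
    v01 = 1.0 - (all_ranks[n1:] - control_ranks) / n1  # per control
    return v10, v01


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, float]:
    """DeLong's paired test for two correlated AUCs on the same samples.

    Returns (auc_a, auc_b, z, two-sided p).  Identical score vectors give
    z = 0, p = 1 by convention; a zero-variance difference with unequal
    AUCs is an error.
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    if scores_a.shape != scores_b.shape:
        raise ValueError("score vectors must cover the same samples")
    labels = np.asarray(labels)
    ca, na = _split_classes(scores_a, labels)
    cb, nb = _split_classes(scores_b, labels)
    auc_a = float(np.mean((ca[:, None] > na).astype(float) + 0.5 * (ca[:, None] == na)))
    auc_b = float(np.mean((cb[:, None] > nb).astype(float) + 0.5 * (cb[:, None] == nb)))
    if np.array_equal(scores_a, scores_b):
        return auc_a, auc_b, 0.0, 1.0
    v10a, v01a = _placements(ca, na)
    v10b, v01b = _placements(cb, nb)
    n1, n0 = len(ca), len(na)
    s10 = np.cov(np.vstack([v10a, v10b]))  # 2x2 over cases
    s01 = np.cov(np.vstack([v01a, v01b]))  # 2x2 over controls
    cov = s10 / n1 + s01 / n0
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        if np.isclose(auc_a, auc_b):
            return auc_a, auc_b, 0.0, 1.0
        raise ValueError("degenerate zero variance with unequal AUCs")
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return auc_a, auc_b, float(z), max(p, np.nextafter(0, 1))


DEFAULT_OMEGA_GRID = np.round(np.arange(0.0, 1.0001, 0.01), 2)


def metric_for(y_obs: np.ndarray, binary: bool):
    """Validation metric closed over the observed trait: AUC or Pearson r."""
    y_obs = np.asarray(y_obs, dtype=np.float64)
    if binary:
        return "auc", lambda yhat: auc(yhat, y_obs)
    return "pearson", lambda yhat: pearson_corr(yhat, y_obs)


def tune_omega(
    x1: GenotypeMatrix,
    beta1: np.ndarray,
    x2: GenotypeMatrix,
    beta2: np.ndarray,
    y_obs: np.ndarray,
    binary: bool = False,
    grid=DEFAULT_OMEGA_GRID,
    ridge_lambda: float = DEFAULT_RIDGE,
) -> TuningResult:
    """Grid-search omega for the combined method on a validation cohort.

    The two Gram matrices are built once and re-blended per grid point, so
    the sweep costs one n2 x n2 solve per omega; each point is numerically
    identical to a fresh combined_impute call.
    """
    if x1.sample_ids != x2.sample_ids:
        raise AlignmentError("validation genotype panels are not sample-aligned")
    grid = list(grid)
    if not grid:
        raise ValueError("empty omega grid")
    n = x1.n_samples
    a, b = x1.dosages, x2.dosages
    g1, g2 = a @ a.T, b @ b.T
    r1, r2 = a @ np.asarray(beta1, float), b @ np.asarray(beta2, float)
    name, metric = metric_for(y_obs, binary)
    rows = []
    for w in grid:
        yhat = (n - 1) * gram_solve(w * g1 + (1 - w) * g2, w * r1 + (1 - w) * r2, ridge_lambda)
        rows.append((float(w), metric(yhat)))
    return TuningResult(grid=rows, selected=select_argmax(rows), metric_name=name)


def select_argmax(rows: list[tuple[float, float]]) -> float:
    """Parameter attaining the maximum metric; ties go to the smaller value."""
    best = max(m for _, m in rows)
    return min(v for v, m in rows if m == best)


def select_omega(grid_metrics: list[tuple[float, float]], binary: bool = False) -> TuningResult:
    """Wrap precomputed (omega, metric) pairs as a TuningResult."""
    if not grid_metrics:
        raise ValueError("empty omega grid")
    return TuningResult(
        grid=list(grid_metrics),
        selected=select_argmax(list(grid_metrics)),
        metric_name="auc" if binary else "pearson",
    )


def select_epochs(trajectory: list[dict], metric_name: str = "pearson") -> TuningResult:
    """Early stopping: the epoch whose validation metric is maximal.

    Ties break toward the earliest epoch; no unimodal shape is assumed.
    """
    if not trajectory:
        raise ValueError("empty trajectory")
    if any("metric" not in t for t in trajectory):
        raise ValueError("trajectory lacks per-epoch validation metrics")
    rows = [(float(t["epoch"]), float(t["metric"])) for t in trajectory]
    best = max(m for _, m in rows)
    selected = min(e for e, m in rows if m == best)
    return TuningResult(grid=rows, selected=selected, metric_name=metric_name)
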