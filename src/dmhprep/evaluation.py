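"""Method comparison: T.stat, ROC/AUC, and the 5 x 4 preprocessing grid.

Performance of a preprocessing pipeline is measured by how well the
resulting methylation scores separate known methylated genes (positive
controls) from housekeeping genes (negative controls):

T.stat
    Welch two-sample statistic,
    (mean_m - mean_hk) / sqrt(var_m / N_m + var_hk / N_hk),
    sample variances with denominator n - 1.
AUC
    Area under the ROC staircase obtained by sweeping the score cutoff
    C0 = 0..N (a gene is called methylated when its score >= C0), with
    the point (0, 0) appended and trapezoidal integration over points
    ordered by increasing false-positive rate.

``run_method_grid`` executes all 20 combinations of the five background
corrections and four normalizations, scores the islands of both control
gene groups under each, and tabulates both statistics at every p-value
threshold, together with the per-factor means (each normalization
averaged over the background methods and vice versa).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DMHError, InputError
from .background import BACKGROUND_METHODS, DEFAULT_OFFSET, correct_background
from .io import ProbeAnnotation, TwoColorArray
from .normalization import (
    DEFAULT_DEGREE,
    DEFAULT_SPAN,
    NORMALIZATION_METHODS,
    compute_ma,
    normalize,
    stack_m_values,
)
from .restriction import ControlProbeSet
from .scoring import DEFAULT_TAU, DEFAULT_THRESHOLDS, score_islands

logger = logging.getLogger(__name__)


def t_statistic(scores_m, scores_hk, pooled: bool = False) -> float:
    """Separation of methylated-gene vs housekeeping-gene score means.

    Welch form by default; ``pooled=True`` uses the pooled-variance
    two-sample denominator instead.  Both groups must be non-empty with
    non-zero combined variance.
    """
    m = np.asarray(scores_m, dtype=float)
    h = np.asarray(scores_hk, dtype=float)
    if m.size == 0 or h.size == 0:
        raise InputError("both score groups must be non-empty")
    var_m = m.var(ddof=1) if m.size > 1 else 0.0
    var_h = h.var(ddof=1) if h.size > 1 else 0.0
    if pooled:
        df = m.size + h.size - 2
        if df <= 0:
            raise InputError("pooled t needs at least 3 scores in total")
        sp2 = ((m.size - 1) * var_m + (h.size - 1) * var_h) / df
        denom2 = sp2 * (1.0 / m.size + 1.0 / h.size)
    else:
        denom2 = var_m / m.size + var_h / h.size
    if denom2 <= 0:
        raise InputError("undefined statistic: zero variance in both score groups")
    return float((m.mean() - h.mean()) / np.sqrt(denom2))


def roc_curve(scores_m, scores_hk, n_max: int) -> pd.DataFrame:
    """ROC points for cutoffs C0 = 0..n_max plus the appended (0, 0).

    TPR(C0) = fraction of methylated genes with score >= C0, FPR(C0)
    likewise for housekeeping genes.  Returned ordered by increasing
    FPR (ties by increasing TPR).
    """
    m = np.asarray(scores_m)
    h = np.asarray(scores_hk)
    if m.size == 0 or h.size == 0:
        raise InputError("both score groups must be non-empty")
    for name, s in (("methylated", m), ("housekeeping", h)):
        if ((s < 0) | (s > n_max)).any() or not np.allclose(s, np.round(s)):
            raise InputError(f"{name} scores must be integers in [0, {n_max}]")
    cutoffs = np.arange(0, n_max + 2)  # n_max + 1 yields the (0, 0) point
    tpr = np.array([(m >= c).mean() for c in cutoffs])
    fpr = np.array([(h >= c).mean() for c in cutoffs])
    pts = pd.DataFrame({"C0": cutoffs, "fpr": fpr, "tpr": tpr})
    return pts.sort_values(["fpr", "tpr"], kind="stable").reset_index(drop=True)


def roc_auc(scores_m, scores_hk, n_max: int) -> float:
    """Trapezoidal area under the ROC staircase of :func:`roc_curve`."""
    pts = roc_curve(scores_m, scores_hk, n_max)
    return float(np.trapezoid(pts["tpr"].to_numpy(), pts["fpr"].to_numpy()))


@dataclasses.dataclass
class EvaluationGrid:
    """Result of :func:`run_method_grid`.

    ``results``: one row per (background, normalization, p0) with
    T_stat, AUC and group sizes.  ``failures`` maps a failed
    (background, normalization) cell to the reason it was skipped.
    """

    results: pd.DataFrame
    failures: dict

    def per_factor_means(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Marginal means: each normalization averaged over background
        methods, and each background method averaged over
        normalizations, at every threshold."""
        by_norm = (
            self.results.groupby(["normalization", "p0"], as_index=False)[["T_stat", "AUC"]]
            .mean()
        )
        by_bg = (
            self.results.groupby(["background", "p0"], as_index=False)[["T_stat", "AUC"]]
            .mean()
        )
        return by_norm, by_bg


def preprocess_arrays(
    arrays: Sequence[TwoColorArray],
    background: str,
    normalization: str,
    controls: ControlProbeSet | None = None,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    offset_k: float = DEFAULT_OFFSET,
    edwards_d: float | None = None,
) -> pd.DataFrame:
    """One full preprocessing pipeline; returns the probes x arrays
    matrix of normalized M values."""
    normalized = []
    for arr in arrays:
        corrected = correct_background(arr, background, d=edwards_d, k=offset_k)
        ma = compute_ma(corrected)
        normalized.append(normalize(ma, normalization, controls=controls, span=span, degree=degree))
    return stack_m_values(normalized)


def run_method_grid(
    arrays: Sequence[TwoColorArray],
    annotation: ProbeAnnotation,
    controls: ControlProbeSet,
    methylated_islands: Sequence[str],
    housekeeping_islands: Sequence[str],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    tau: float = DEFAULT_TAU,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    offset_k: float = DEFAULT_OFFSET,
    backgrounds: Sequence[str] = BACKGROUND_METHODS,
    normalizations: Sequence[str] = NORMALIZATION_METHODS,
) -> EvaluationGrid:
    """Run every background x normalization pipeline and evaluate it.

    Scoring runs only on the islands of the two control-gene groups.  A
    cell whose pipeline or scoring fails is logged and skipped; the rest
    of the grid continues.
    """
    methylated_islands = list(methylated_islands)
    housekeeping_islands = list(housekeeping_islands)
    overlap = set(methylated_islands) & set(housekeeping_islands)
    if overlap:
        raise InputError(f"islands in both control groups: {sorted(overlap)[:3]}...")
    island_of_probe = {
        probe: island
        for probe, island in zip(annotation.data["probe_id"], annotation.data["island_id"])
        if island is not None
    }
    wanted = methylated_islands + housekeeping_islands
    rows = []
    failures: dict = {}
    # background corrections are independent of the normalization choice;
    # compute the M/A values once per background method.  normexp_offset
    # reuses the normexp fit (it only adds the offset k).
    normexp_cache: list | None = None
    for bg in backgrounds:
        try:
            if bg in ("normexp", "normexp50", "normexp_offset"):
                if normexp_cache is None:
                    normexp_cache = [correct_background(arr, "normexp") for arr in arrays]
                corrected = normexp_cache
                if bg != "normexp":
                    corrected = [
                        dataclasses.replace(
                            c, R=c.R + offset_k, G=c.G + offset_k,
                            method_id="normexp_offset", offset_k=offset_k,
                        )
                        for c in normexp_cache
                    ]
            else:
                corrected = [correct_background(arr, bg, k=offset_k) for arr in arrays]
            mas = [compute_ma(c) for c in corrected]
        except DMHError as exc:
            for norm in normalizations:
                failures[(bg, norm)] = f"background correction failed: {exc}"
                logger.warning("grid cell (%s, %s) skipped: %s", bg, norm, exc)
            continue
        for norm in normalizations:
            try:
                normalized = [
                    normalize(ma, norm, controls=controls, span=span, degree=degree) for ma in mas
                ]
                m_values = stack_m_values(normalized)
                table, _fits, skipped = score_islands(
                    m_values, island_of_probe, islands=wanted, tau=tau, thresholds=thresholds
                )
                score_of = table.data.set_index(["island_id", "p0"])["score"]
                for p0 in thresholds:
                    sm = [score_of.get((i, p0)) for i in methylated_islands]
                    sh = [score_of.get((i, p0)) for i in housekeeping_islands]
                    sm = [s for s in sm if s is not None]
                    sh = [s for s in sh if s is not None]
                    rows.append(
                        {
                            "background": bg,
                            "normalization": norm,
                            "p0": p0,
                            "T_stat": t_statistic(sm, sh),
                            "AUC": roc_auc(sm, sh, table.n_arrays),
                            "N_m": len(sm),
                            "N_HK": len(sh),
                        }
                    )
            except DMHError as exc:
                failures[(bg, norm)] = str(exc)
                logger.warning("grid cell (%s, %s) skipped: %s", bg, norm, exc)
    results = pd.DataFrame(
        rows, columns=["background", "normalization", "p0", "T_stat", "AUC", "N_m", "N_HK"]
    )
    return EvaluationGrid(results=results, failures=failures)
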