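"""Per-CpG-island quantile-regression methylation scoring.

For one island with probes p = 1..P measured on arrays a = 1..N, the
normalized log-ratios are modelled at the tau = 0.75 quantile as

    M_ap = array_a + probe_p + error_ap,

array and probe both fixed effects, errors independent and distribution
free with tau-quantile zero.  There is no intercept and the probe
effects are constrained to sum to zero, so ``array_a`` is directly the
island-level 75 %-quantile methylation signal of array a.  The check
loss sum_ap rho_tau(M_ap - array_a - probe_p) is minimized exactly via a
linear-programming formulation.

Each array gets a one-sided p-value for H1: array_a > 0 (Wald test with
kernel-estimated sparsity, Student-t reference).  The methylation score
of an island at threshold p0 is the number of arrays with p-value below
p0; it ranges from 0 to N.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats

from .exceptions import FitError, InputError

DEFAULT_TAU = 0.75
#: p-value thresholds used for the score sweep.
DEFAULT_THRESHOLDS = (0.05, 0.04, 0.03, 0.02, 0.01)
#: Reliability floor: islands with fewer probes are skipped.
MIN_PROBES = 3
MIN_ARRAYS = 2
#: Minimum fraction of non-missing cells in an island block.
MIN_COMPLETE = 0.8


def check_loss(residuals, tau: float) -> float:
    """Quantile-regression check loss sum_i rho_tau(r_i)."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(r * (tau - (r < 0))))


def _design_matrix(arr_idx: np.ndarray, probe_idx: np.ndarray, n_arrays: int, n_probes: int):
    """Sparse design: one column per array, plus P-1 sum-zero probe
    columns (the last probe is minus the sum of the others)."""
    n = arr_idx.size
    rows, cols, vals = [], [], []
    rows.extend(range(n))
    cols.extend(arr_idx)
    vals.extend([1.0] * n)
    for i in range(n):
        p = probe_idx[i]
        if p < n_probes - 1:
            rows.append(i)
            cols.append(n_arrays + p)
            vals.append(1.0)
        else:
            for j in range(n_probes - 1):
                rows.append(i)
                cols.append(n_arrays + j)
                vals.append(-1.0)
    k = n_arrays + n_probes - 1
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, k))


def _solve_quantile_lp(X: sparse.csr_matrix, y: np.ndarray, tau: float) -> np.ndarray:
    """Exact check-loss minimizer via the standard LP formulation:
    minimize tau 1'u+ + (1-tau) 1'u-  s.t.  X b + u+ - u- = y."""
    n, k = X.shape
    c = np.concatenate([np.zeros(k), np.full(n, tau), np.full(n, 1.0 - tau)])
    A_eq = sparse.hstack([X, sparse.identity(n), -sparse.identity(n)], format="csr")
    bounds = [(None, None)] * k + [(0, None)] * (2 * n)
    res = optimize.linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - HiGHS is reliable on feasible LPs
        raise FitError(f"quantile LP failed: {res.message}")
    return res.x[:k]


def _hall_sheather_bandwidth(n: int, tau: float, alpha: float = 0.05) -> float:
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_t = stats.norm.ppf(tau)
    f_t = stats.norm.pdf(z_t)
    return n ** (-1.0 / 3.0) * z_a ** (2.0 / 3.0) * (
        1.5 * f_t**2 / (2.0 * z_t**2 + 1.0)
    ) ** (1.0 / 3.0)


def _sparsity(residuals: np.ndarray, tau: float, n_params: int) -> tuple[float, float]:
    """Kernel (difference-quotient) estimate of the sparsity
    1 / f(F^-1(tau)) from the residual empirical quantile function,
    Hall-Sheather bandwidth.  Returns ``(sparsity, df_eff)``.

    The LP drives ``n_params`` residuals to exact zero; these carry no
    information about the error density and are dropped first.

    ``df_eff`` is a Satterthwaite-style effective degrees of freedom for
    the sparsity estimate itself: the difference quotient
    (Q(hi) - Q(lo)) / (hi - lo) is a ratio of order statistics whose
    asymptotic variance (binomial quantile theory, density locally
    approximated by the quotient) gives cv^2 = v / (n (hi - lo)^2) with
    v = hi(1-hi) + lo(1-lo) - 2 lo(1-hi); matching a chi distribution
    yields df_eff = 1 / (2 cv^2).  Using a Student-t reference with this
    df accounts for the sparsity-estimation error that a plain normal
    reference ignores.
    """
    r = np.sort(residuals)
    nz = np.abs(r) > 1e-9 * max(1.0, float(np.abs(r).max()))
    if nz.sum() >= 10:
        r = r[nz]
    n = r.size
    h = _hall_sheather_bandwidth(n, tau)
    lo = max(tau - h, 1.0 / (n + 1))
    hi = min(tau + h, n / (n + 1.0))
    q_hi = np.quantile(r, hi)
    q_lo = np.quantile(r, lo)
    s = (q_hi - q_lo) / (hi - lo)
    v = hi * (1 - hi) + lo * (1 - lo) - 2 * lo * (1 - hi)
    cv2 = v / (n * (hi - lo) ** 2)
    df_eff = max(1.0 / (2.0 * cv2), 2.5)
    return max(s, 1e-12), df_eff


@dataclasses.dataclass
class IslandQuantileResults:
    """Fit of the island quantile-regression model.

    ``array_coefs`` are the per-array 75 %-quantile signals (M units),
    ``p_values`` the per-array one-sided p-values for H1: array_a > 0,
    ``probe_effects`` the sum-zero per-probe effects.
    """

    island_id: str | None
    tau: float
    array_ids: np.ndarray
    probe_ids: np.ndarray
    array_coefs: np.ndarray
    probe_effects: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    n_obs: int
    loss: float
    sparsity: float

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.array_coefs, index=self.array_ids, name="array")

    def summary(self) -> pd.DataFrame:
        """Per-array coefficient table."""
        return pd.DataFrame(
            {
                "coef": self.array_coefs,
                "std_err": self.std_errors,
                "p_value": self.p_values,
            },
            index=pd.Index(self.array_ids, name="array_id"),
        )


#: Spec-facing alias: the fit object doubles as the island model fit.
IslandModelFit = IslandQuantileResults


class IslandQuantileModel:
    """Fixed-effects quantile regression for one CpG island.

    Parameters
    ----------
    m_block:
        DataFrame of normalized M values, probes (rows) x arrays
        (columns); NaN marks missing cells.
    tau:
        Quantile level (default 0.75).
    island_id:
        Optional label carried into the results.
    """

    def __init__(self, m_block: pd.DataFrame, tau: float = DEFAULT_TAU, island_id: str | None = None):
        if not 0 < tau < 1:
            raise InputError(f"tau must be in (0, 1), got {tau}")
        self.m_block = m_block
        self.tau = tau
        self.island_id = island_id
        P, N = m_block.shape
        if P < MIN_PROBES:
            raise FitError(f"island {island_id!r}: needs >= {MIN_PROBES} probes, got {P}")
        if N < MIN_ARRAYS:
            raise FitError(f"island {island_id!r}: needs >= {MIN_ARRAYS} arrays, got {N}")
        frac = float(np.isfinite(m_block.to_numpy(dtype=float)).mean())
        if frac < MIN_COMPLETE:
            raise FitError(
                f"island {island_id!r}: only {frac:.0%} of cells non-missing (need >= {MIN_COMPLETE:.0%})"
            )

    def fit(self, alternative: str = "greater") -> IslandQuantileResults:
        """Minimize the check loss exactly and compute per-array Wald
        p-values (``alternative``: "greater" or "two-sided")."""
        if alternative not in ("greater", "two-sided"):
            raise InputError(f"alternative must be 'greater' or 'two-sided', got {alternative!r}")
        y_mat = self.m_block.to_numpy(dtype=float)
        P, N = y_mat.shape
        probe_idx_full, arr_idx_full = np.meshgrid(np.arange(P), np.arange(N), indexing="ij")
        present = np.isfinite(y_mat)
        # arrays with no data at all get p-value 1 and are excluded from the fit
        array_has_data = present.any(axis=0)
        mask = present & array_has_data[np.newaxis, :]
        y = y_mat[mask]
        arr_idx = arr_idx_full[mask]
        probe_idx = probe_idx_full[mask]
        live = np.flatnonzero(array_has_data)
        arr_pos = np.searchsorted(live, arr_idx)  # re-index live arrays 0..n_live-1
        n_live = live.size
        X = _design_matrix(arr_pos, probe_idx, n_live, P)
        beta = _solve_quantile_lp(X, y, self.tau)
        resid = y - X @ beta
        n, k = X.shape
        s, df_eff = _sparsity(resid, self.tau, k)
        xtx = (X.T @ X).toarray()
        cov = self.tau * (1.0 - self.tau) * s**2 * np.linalg.pinv(xtx)
        se_live = np.sqrt(np.clip(np.diag(cov)[:n_live], 0.0, None))
        df = max(min(n - k, df_eff), 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se_live > 0, beta[:n_live] / se_live, np.inf * np.sign(beta[:n_live]))
        if alternative == "greater":
            p_live = stats.t.sf(tvals, df)
        else:
            p_live = 2.0 * stats.t.sf(np.abs(tvals), df)
        p_live = np.where(np.isnan(p_live), 1.0, p_live)

        array_coefs = np.full(N, np.nan)
        std_errors = np.full(N, np.nan)
        p_values = np.ones(N)
        array_coefs[live] = beta[:n_live]
        std_errors[live] = se_live
        p_values[live] = p_live
        probe_effects = np.concatenate([beta[n_live:], [-beta[n_live:].sum()]])
        return IslandQuantileResults(
            island_id=self.island_id,
            tau=self.tau,
            array_ids=np.asarray(self.m_block.columns),
            probe_ids=np.asarray(self.m_block.index),
            array_coefs=array_coefs,
            probe_effects=probe_effects,
            std_errors=std_errors,
            p_values=p_values,
            n_obs=n,
            loss=check_loss(resid, self.tau),
            sparsity=s,
        )


def fit_island_quantile_model(
    m_block: pd.DataFrame,
    tau: float = DEFAULT_TAU,
    island_id: str | None = None,
    alternative: str = "greater",
) -> IslandQuantileResults:
    """Convenience wrapper: build an :class:`IslandQuantileModel` and fit it."""
    return IslandQuantileModel(m_block, tau=tau, island_id=island_id).fit(alternative)


@dataclasses.dataclass
class MethylationScoreTable:
    """Long-format score table: one row per (island, threshold).

    ``data`` columns: island_id, p0, score.  Scores are integer counts in
    [0, n_arrays].
    """

    data: pd.DataFrame
    n_arrays: int

    def pivot(self) -> pd.DataFrame:
        return self.data.pivot(index="island_id", columns="p0", values="score")


def methylation_scores(
    fits: Iterable[IslandQuantileResults],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    n_arrays: int | None = None,
) -> MethylationScoreTable:
    """Count, per island and threshold p0, the arrays with p-value < p0."""
    thresholds = list(thresholds)
    if any(not 0 < p0 < 1 for p0 in thresholds):
        raise InputError(f"thresholds must lie in (0, 1), got {thresholds}")
    rows = []
    n_max = 0
    for fit in fits:
        n_max = max(n_max, len(fit.p_values))
        for p0 in thresholds:
            rows.append(
                {
                    "island_id": fit.island_id,
                    "p0": p0,
                    "score": int(np.sum(fit.p_values < p0)),
                }
            )
    data = pd.DataFrame(rows, columns=["island_id", "p0", "score"])
    return MethylationScoreTable(data=data, n_arrays=n_arrays if n_arrays is not None else n_max)


def score_islands(
    m_values: pd.DataFrame,
    island_of_probe: Mapping,
    islands: Sequence[str] | None = None,
    tau: float = DEFAULT_TAU,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    alternative: str = "greater",
) -> tuple[MethylationScoreTable, dict, dict]:
    """Fit the island model across a whole M matrix and tabulate scores.

    ``m_values`` is probes x arrays; ``island_of_probe`` maps probe_id ->
    island_id (probes absent from the mapping are ignored).  Islands
    failing the reliability preconditions (fewer than 3 probes, too much
    missingness) are skipped and reported in the returned ``skipped``
    mapping island_id -> reason.
    """
    groups: dict = {}
    for probe_id in m_values.index:
        island = island_of_probe.get(probe_id)
        if island is not None:
            groups.setdefault(island, []).append(probe_id)
    if islands is not None:
        groups = {i: groups.get(i, []) for i in islands}
    fits: dict = {}
    skipped: dict = {}
    for island, probes in groups.items():
        block = m_values.loc[probes]
        try:
            fits[island] = fit_island_quantile_model(
                block, tau=tau, island_id=island, alternative=alternative
            )
        except FitError as exc:
            skipped[island] = str(exc)
    table = methylation_scores(fits.values(), thresholds, n_arrays=m_values.shape[1])
    return table, fits, skipped


# ---------------------------------------------------------------------------
# control-gene selection filters
# ---------------------------------------------------------------------------

REASON_NOT_IN_TABLE = "not-in-table"
REASON_NO_ISLAND = "no-island"
REASON_MULTI_ISLAND = "multi-island"
REASON_TOO_FEW_PROBES = "too-few-probes"
REASON_NO_PROMOTER = "no-promoter-probe"
REASON_SCORE_TOO_HIGH = "score-above-half"


def build_gene_table(
    annotation,
    gene_islands: Mapping[str, Sequence[str]],
    primary_island: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One row per (gene, island): gene, island_id, n_probes,
    n_promoter_probes, is_primary.

    ``gene_islands`` maps each gene to the CpG islands associated with
    it; probe counts and promoter flags come from the annotation.
    """
    primary_island = primary_island or {}
    d = annotation.data
    island_rows = d[d["island_id"].notna()]
    n_probes = island_rows.groupby("island_id").size()
    n_prom = island_rows.groupby("island_id")["in_promoter"].sum()
    rows = []
    for gene, islands in gene_islands.items():
        for island in islands:
            rows.append(
                {
                    "gene": gene,
                    "island_id": island,
                    "n_probes": int(n_probes.get(island, 0)),
                    "n_promoter_probes": int(n_prom.get(island, 0)),
                    "is_primary": primary_island.get(gene) == island,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "island_id", "n_probes", "n_promoter_probes", "is_primary"])


def select_housekeeping_genes(
    gene_table: pd.DataFrame,
    scores: pd.DataFrame,
    candidates: Sequence[str] | None = None,
) -> tuple[list, dict]:
    """Select negative-control (assumed-unmethylated) genes.

    A gene is kept iff (1) exactly one CpG island is associated with it;
    (2) that island has >= 3 probes, at least one in the promoter region;
    and (3) its methylation score is <= N/2 under *every* supplied
    preprocessing method and dataset.  ``scores`` is long format with
    columns island_id, score, n_arrays (one row per island x method x
    dataset x threshold).  Returns (kept genes, excluded gene -> reason).
    """
    for col in ("island_id", "score", "n_arrays"):
        if col not in scores.columns:
            raise InputError(f"scores table missing column {col!r}")
    genes = list(candidates) if candidates is not None else list(dict.fromkeys(gene_table["gene"]))
    by_gene = dict(tuple(gene_table.groupby("gene")))
    excess = scores["score"] - scores["n_arrays"] / 2.0
    max_excess = excess.groupby(scores["island_id"]).max()
    kept: list = []
    excluded: dict = {}
    for gene in genes:
        rows = by_gene.get(gene)
        if rows is None or rows.empty:
            excluded[gene] = REASON_NOT_IN_TABLE
            continue
        if len(rows) != 1:
            excluded[gene] = REASON_MULTI_ISLAND
            continue
        row = rows.iloc[0]
        if row["n_probes"] < MIN_PROBES:
            excluded[gene] = REASON_TOO_FEW_PROBES
            continue
        if row["n_promoter_probes"] < 1:
            excluded[gene] = REASON_NO_PROMOTER
            continue
        if max_excess.get(row["island_id"], np.inf) > 0:
            excluded[gene] = REASON_SCORE_TOO_HIGH
            continue
        kept.append(gene)
    return kept, excluded


def filter_candidate_methylated_genes(
    candidates: Sequence[str], gene_table: pd.DataFrame
) -> tuple[list, dict]:
    """Filter positive-control (known methylated) candidate genes.

    A candidate is excluded iff (1) it has no associated CpG island on
    the array; (2) its island has fewer than 3 probes; (3) its island
    does not cover the promoter / first-exon region; or (4) several
    islands map to it and none is designated primary.
    """
    by_gene = dict(tuple(gene_table.groupby("gene")))
    kept: list = []
    excluded: dict = {}
    for gene in candidates:
        rows = by_gene.get(gene)
        if rows is None or rows.empty:
            excluded[gene] = REASON_NO_ISLAND
            continue
        if len(rows) > 1:
            primary = rows[rows["is_primary"]]
            if len(primary) != 1:
                excluded[gene] = REASON_MULTI_ISLAND
                continue
            rows = primary
        row = rows.iloc[0]
        if row["n_probes"] < MIN_PROBES:
            excluded[gene] = REASON_TOO_FEW_PROBES
            continue
        if row["n_promoter_probes"] < 1:
            excluded[gene] = REASON_NO_PROMOTER
            continue
        kept.append(gene)
    return kept, excluded
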