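"""Cohort-level statistics for the T1rho glioma study design.

The analysis pools measurements across weeks 2-4 (weeks in which tumours
are present and mice survive), then compares groups and ROIs with
two-sided Mann-Whitney U tests.  Multiple testing over the four spin-lock
amplitudes within a comparison family is controlled with the
Benjamini-Hochberg step-up procedure at FDR 5%; the six dispersion-ratio
comparisons are not independent (each FSL enters three ratios), so they
use a Bonferroni threshold of alpha/6 ~ 0.0083 instead.  A per-mouse
linear trend of brain T1rho over study week (with a t-test of zero slope,
BH-corrected across FSLs) screens for age effects in the naive group.

Mann-Whitney p-values are exact (full null distribution) whenever the
pooled sample is small (n1 + n2 <= 20) and tie-free, otherwise the normal
approximation with tie and continuity corrections is used; the mode is
recorded in every outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, InvalidParameterError

EXACT_N_CUTOFF = 20
DEFAULT_FDR = 0.05
MEASUREMENT_COLUMNS = ["mouse", "group", "week", "fsl", "roi", "metric", "value"]
POOLED_WEEKS = (2, 3, 4)


# ---------------------------------------------------------------------------
# measurement table
# ---------------------------------------------------------------------------

def validate_measurement_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format measurement table invariants."""
    missing = set(MEASUREMENT_COLUMNS) - set(table.columns)
    if missing:
        raise InvalidParameterError(f"measurement table missing columns {missing}")
    key = ["mouse", "week", "fsl", "roi", "metric"]
    if table.duplicated(subset=key).any():
        raise InvalidParameterError("duplicate (mouse, week, fsl, roi, metric) keys")
    g1_tumour = (table["group"] == 1) & (table["roi"] == "tumour")
    if g1_tumour.any():
        raise InvalidParameterError("naive group cannot have tumour rows")
    return table


def merge_weeks(table: pd.DataFrame,
                weeks: Iterable[int] = POOLED_WEEKS) -> pd.DataFrame:
    """Pool measurements across the given study weeks.

    Returns the rows restricted to ``weeks`` (a copy; the input table is
    unmodified).  Downstream comparisons then treat all remaining rows of
    a (group, fsl, roi, metric) cell as one sample.
    """
    return table[table["week"].isin(set(weeks))].copy()


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestOutcome:
    """A two-sided Mann-Whitney U comparison."""

    comparison: str
    u_statistic: float
    p_value: float
    n1: int
    n2: int
    mode: str  # "exact" or "asymptotic"
    family: str = ""


@dataclass(frozen=True)
class TrendOutcome:
    """OLS slope of T1rho against study week with a t-test of slope = 0."""

    mouse: str
    fsl_hz: float
    slope_ms_per_week: float
    slope_p: float
    n_weeks: int


def mann_whitney(x: Sequence[float], y: Sequence[float], mode: str = "auto",
                 comparison: str = "", family: str = "") -> TestOutcome:
    """Two-sided Mann-Whitney U test.

    ``mode="auto"`` selects the exact null distribution when
    ``n1 + n2 <= 20`` and the pooled sample is tie-free, else the normal
    approximation with tie and continuity corrections.  Exact mode with
    ties falls back to the approximation (the exact distribution assumes
    continuous data).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    if mode not in ("auto", "exact", "asymptotic"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (mode == "exact") or (
        mode == "auto" and pooled.size <= EXACT_N_CUTOFF)
    if has_ties:
        use_exact = False
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestOutcome(comparison=comparison, u_statistic=float(res.statistic),
                       p_value=float(res.pvalue), n1=x.size, n2=y.size,
                       mode=method, family=family)


def bh_adjust(p_values: Sequence[float], fdr: float = DEFAULT_FDR,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    if not 0 < fdr < 1:
        raise InvalidParameterError("FDR must lie in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return reject, p_adj


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    if m < 1:
        raise InvalidParameterError("m must be at least 1")
    return alpha / m


def age_trend_test(weeks: Sequence[float], values: Sequence[float],
                   mouse: str = "", fsl_hz: float = 0.0) -> TrendOutcome:
    """OLS slope of T1rho vs week, with a two-sided t-test of zero slope.

    Degenerate cases: constant values give slope 0 and p = 1; an exactly
    collinear (zero-residual) non-constant fit gives p = 0.
    """
    w = np.asarray(list(weeks), dtype=float)
    v = np.asarray(list(values), dtype=float)
    if w.size != v.size or w.size < 3:
        raise InsufficientDataError("need at least 3 (week, value) points")
    if np.unique(w).size < 2:
        raise InsufficientDataError("weeks are all identical")
    if np.allclose(v, v[0]):
        return TrendOutcome(mouse, fsl_hz, 0.0, 1.0, w.size)
    res = sps.linregress(w, v)
    resid = v - (res.intercept + res.slope * w)
    if np.allclose(resid, 0.0, atol=1e-12 * max(1.0, float(np.abs(v).max()))):
        return TrendOutcome(mouse, fsl_hz, float(res.slope), 0.0, w.size)
    return TrendOutcome(mouse, fsl_hz, float(res.slope), float(res.pvalue),
                        w.size)


def age_trend_analysis(table: pd.DataFrame, group: int = 1,
                       fdr: float = DEFAULT_FDR) -> pd.DataFrame:
    """Per-mouse brain-T1rho week trends with BH correction across FSLs."""
    sub = table[(table["group"] == group) & (table["roi"] == "brain")
                & (table["metric"] == "t1rho")]
    rows = []
    for mouse, by_mouse in sub.groupby("mouse"):
        outcomes = []
        for fsl, cell in by_mouse.groupby("fsl"):
            cell = cell.sort_values("week")
            if cell.shape[0] < 3:
                continue
            outcomes.append(age_trend_test(cell["week"], cell["value"],
                                           mouse=str(mouse), fsl_hz=float(fsl)))
        if not outcomes:
            continue
        reject, p_adj = bh_adjust([o.slope_p for o in outcomes], fdr)
        for o, rej, pa in zip(outcomes, reject, p_adj):
            rows.append(dict(mouse=o.mouse, fsl=o.fsl_hz,
                             slope_ms_per_week=o.slope_ms_per_week,
                             p=o.slope_p, p_adjusted=pa, significant=bool(rej),
                             n_weeks=o.n_weeks))
    return pd.DataFrame(rows, columns=["mouse", "fsl", "slope_ms_per_week",
                                       "p", "p_adjusted", "significant",
                                       "n_weeks"])


# ---------------------------------------------------------------------------
# the comparison battery
# ---------------------------------------------------------------------------

def _cell_values(table: pd.DataFrame, *, group: int, roi: str | None,
                 metric: str, fsl) -> np.ndarray:
    m = ((table["group"] == group) & (table["metric"] == metric)
         & (table["_fsl_key"] == fsl))
    if roi is not None:
        m &= table["roi"] == roi
    return np.sort(table.loc[m, "value"].to_numpy(dtype=float))


def _with_fsl_key(table: pd.DataFrame) -> pd.DataFrame:
    """Normalise the fsl column: numeric for single-FSL metrics, the
    "low-high" string for dispersion pairs (robust to CSV round trips)."""
    numeric = pd.to_numeric(table["fsl"], errors="coerce")
    key = numeric.astype(object)
    key[numeric.isna()] = table.loc[numeric.isna(), "fsl"].astype(str)
    return table.assign(_fsl_key=key)


def run_group_comparisons(table: pd.DataFrame, fdr: float = DEFAULT_FDR,
                          dispersion_alpha: float = 0.05,
                          ) -> dict[str, pd.DataFrame]:
    """Run the full comparison battery on a pooled measurement table.

    Families (BH-corrected across the FSLs within each family):

    * tumour vs brain T1rho, within group 2 and within group 3;
    * tumour T1rho, group 2 vs group 3;
    * brain T1rho, groups 1 vs 2, 1 vs 3 and 2 vs 3;
    * delta-T1rho, group 2 vs group 3;

    plus tumour dispersion ratios group 2 vs 3 at the six FSL pairs with a
    Bonferroni threshold of ``dispersion_alpha / 6``.

    Missing cells yield a "no comparison possible" row rather than an
    exception.  Row order of the input table does not affect the result.
    Returns ``{"t1rho_delta": ..., "dispersion": ...}`` data frames.
    """
    table = _with_fsl_key(table)
    fsls = sorted(set(table.loc[table["metric"] == "t1rho", "_fsl_key"]))
    families: list[tuple[str, str, dict]] = [
        ("tumour_vs_brain_G2", "t1rho",
         dict(a=dict(group=2, roi="tumour"), b=dict(group=2, roi="brain"))),
        ("tumour_vs_brain_G3", "t1rho",
         dict(a=dict(group=3, roi="tumour"), b=dict(group=3, roi="brain"))),
        ("tumour_G2_vs_G3", "t1rho",
         dict(a=dict(group=2, roi="tumour"), b=dict(group=3, roi="tumour"))),
        ("brain_G1_vs_G2", "t1rho",
         dict(a=dict(group=1, roi="brain"), b=dict(group=2, roi="brain"))),
        ("brain_G1_vs_G3", "t1rho",
         dict(a=dict(group=1, roi="brain"), b=dict(group=3, roi="brain"))),
        ("brain_G2_vs_G3", "t1rho",
         dict(a=dict(group=2, roi="brain"), b=dict(group=3, roi="brain"))),
        ("delta_G2_vs_G3", "delta",
         dict(a=dict(group=2, roi="tumour"), b=dict(group=3, roi="tumour"))),
    ]
    rows = []
    for family, metric, sides in families:
        outcomes: list[TestOutcome | None] = []
        for fsl in fsls:
            xa = _cell_values(table, metric=metric, fsl=fsl, **sides["a"])
            xb = _cell_values(table, metric=metric, fsl=fsl, **sides["b"])
            if xa.size == 0 or xb.size == 0:
                outcomes.append(None)
            else:
                outcomes.append(mann_whitney(xa, xb, comparison=family,
                                             family=family))
        done = [o for o in outcomes if o is not None]
        if done:
            reject, p_adj = bh_adjust([o.p_value for o in done], fdr)
        adj_iter = iter(zip(reject, p_adj)) if done else iter(())
        for fsl, o in zip(fsls, outcomes):
            if o is None:
                rows.append(dict(family=family, comparison=family, fsl=fsl,
                                 n1=0, n2=0, u=np.nan, p=np.nan,
                                 p_adjusted=np.nan, significant=False,
                                 mode="", note="no comparison possible"))
            else:
                rej, pa = next(adj_iter)
                rows.append(dict(family=family, comparison=family, fsl=fsl,
                                 n1=o.n1, n2=o.n2, u=o.u_statistic,
                                 p=o.p_value, p_adjusted=pa,
                                 significant=bool(rej), mode=o.mode, note=""))
    t1rho_delta = pd.DataFrame(rows)

    disp = table[table["metric"] == "dispersion_ratio"]
    pairs = sorted(set(disp["_fsl_key"].astype(str)),
                   key=lambda p: tuple(float(v) for v in p.split("-")))
    disp_rows = []
    outcomes = []
    for pair in pairs:
        xa = _cell_values(disp, group=2, roi="tumour",
                          metric="dispersion_ratio", fsl=pair)
        xb = _cell_values(disp, group=3, roi="tumour",
                          metric="dispersion_ratio", fsl=pair)
        outcomes.append(None if xa.size == 0 or xb.size == 0 else
                        mann_whitney(xa, xb, comparison=f"dispersion_{pair}",
                                     family="dispersion_G2_vs_G3"))
    m = sum(o is not None for o in outcomes)
    thr = bonferroni_threshold(dispersion_alpha, m) if m else np.nan
    for pair, o in zip(pairs, outcomes):
        if o is None:
            disp_rows.append(dict(family="dispersion_G2_vs_G3", fsl_pair=pair,
                                  n1=0, n2=0, u=np.nan, p=np.nan,
                                  threshold=thr, significant=False, mode="",
                                  note="no comparison possible"))
        else:
            disp_rows.append(dict(family="dispersion_G2_vs_G3", fsl_pair=pair,
                                  n1=o.n1, n2=o.n2, u=o.u_statistic,
                                  p=o.p_value, threshold=thr,
                                  significant=bool(o.p_value < thr),
                                  mode=o.mode, note=""))
    dispersion = pd.DataFrame(
        disp_rows, columns=["family", "fsl_pair", "n1", "n2", "u", "p",
                            "threshold", "significant", "mode", "note"])
    return {"t1rho_delta": t1rho_delta, "dispersion": dispersion}
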