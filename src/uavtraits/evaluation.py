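"""Accuracy metrics and significance testing for retrieval comparison.

Accuracy is summarised per method x trait x group (date, nitrogen level
or pooled) by R^2, RMSE and the range-normalised RMSE

    NRMSE% = 100 * RMSE / (max(observed) - min(observed)).

Method differences are tested with the Friedman rank test over blocks of
per-plot absolute errors, followed by pairwise post-hoc z-tests on mean
rank differences with the Bergmann-Hommel exhaustive-set p-value
adjustment (exact for up to four methods, Holm fallback beyond); nitrogen
effects on a designated method pair use the paired t-test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Metrics",
    "EvaluationReport",
    "metrics",
    "friedman_test",
    "pairwise_posthoc",
    "paired_ttest",
    "compare_report",
]

TRAITS = ("lai", "fcover", "ccc")


@dataclass
class Metrics:
    """Agreement summary between observed and predicted values."""

    r2: float
    rmse: float
    nrmse_pct: float
    n: int
    range_used: float


def metrics(observed, predicted, r2_mode: str = "pearson") -> Metrics:
    """R^2, RMSE and range-normalised RMSE of a prediction set.

    ``r2_mode="pearson"`` (default) squares the Pearson correlation, the
    convention of retrieval scatter plots; ``"explained"`` computes
    1 - SS_res/SS_tot instead.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D")
    if obs.size < 2:
        raise ValueError("need at least 2 points")
    rng = float(obs.max() - obs.min())
    if rng <= 0:
        raise ValueError("observed range is zero: NRMSE undefined")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if r2_mode == "pearson":
        if np.std(pred) == 0 or np.std(obs) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    elif r2_mode == "explained":
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        r2 = 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot
    else:
        raise ValueError(f"unknown r2_mode {r2_mode!r}")
    return Metrics(r2=r2, rmse=rmse, nrmse_pct=100.0 * rmse / rng,
                   n=obs.size, range_used=rng)


def _block_ranks(errors: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, errors)


def friedman_test(errors) -> tuple:
    """Friedman rank test over a blocks x methods error matrix.

    Uses mid-ranks for ties and the standard tie correction; returns the
    chi-squared statistic and its p-value with k-1 degrees of freedom.
    """
    E = np.asarray(errors, dtype=float)
    if E.ndim != 2 or E.shape[0] < 2 or E.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 blocks and >= 2 methods")
    n, k = E.shape
    R = _block_ranks(E)
    col_sums = R.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(col_sums ** 2) - 3.0 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_term = 0.0
    for row in E:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts ** 3 - counts))
    denom = 1.0 - tie_term / (n * k * (k ** 2 - 1))
    if denom <= 0:
        return 0.0, 1.0
    chi2 /= denom
    p = float(stats.chi2.sf(chi2, k - 1))
    return float(chi2), p


def _set_partitions(items: list):
    """All partitions of a small set (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _exhaustive_sets(k: int) -> list:
    """Exhaustive hypothesis sets of the k(k-1)/2 pairwise equalities.

    A set of pairwise hypotheses is exhaustive when some partition of the
    methods into equal-mean blocks makes exactly those hypotheses true:
    the union of within-block pairs over all partitions.
    """
    sets = set()
    for part in _set_partitions(list(range(k))):
        pairs = frozenset(
            pair
            for block in part
            for pair in itertools.combinations(sorted(block), 2)
        )
        if pairs:
            sets.add(pairs)
    return [sorted(s) for s in sets]


def pairwise_posthoc(
    errors,
    procedure: str = "bergmann_hommel",
    fallback: bool = True,
) -> pd.DataFrame:
    """Post-hoc pairwise comparisons after a Friedman test.

    The z-statistic of a method pair is the mean-rank difference scaled
    by sqrt(k(k+1)/(6n)).  ``bergmann_hommel`` applies the exhaustive-set
    adjustment APV_ij = max{ |E| * min_{uv in E} p_uv : E exhaustive,
    ij in E }, exact for k <= 4; for larger k it falls back to Holm when
    ``fallback`` is set and raises otherwise.
    """
    E = np.asarray(errors, dtype=float)
    n, k = E.shape
    if k < 2:
        raise ValueError("need >= 2 methods")
    if procedure not in ("bergmann_hommel", "holm"):
        raise ValueError(f"unknown procedure {procedure!r}")
    mean_ranks = _block_ranks(E).mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pairs = list(itertools.combinations(range(k), 2))
    z = {p: (mean_ranks[p[0]] - mean_ranks[p[1]]) / se for p in pairs}
    raw = {p: float(2.0 * stats.norm.sf(abs(z[p]))) for p in pairs}

    use_bh = procedure == "bergmann_hommel"
    if use_bh and k > 4:
        if not fallback:
            raise ValueError(
                "Bergmann-Hommel exhaustive sets are enumerated only for "
                "k <= 4; pass fallback=True to use Holm instead"
            )
        use_bh = False

    if use_bh:
        adjusted = {}
        for p in pairs:
            apv = raw[p]
            for ex in _exhaustive_sets(k):
                if tuple(p) in [tuple(e) for e in ex]:
                    apv = max(apv, len(ex) * min(raw[tuple(e)] for e in ex))
            adjusted[p] = min(1.0, apv)
    else:  # Holm step-down
        order = sorted(pairs, key=lambda p: raw[p])
        m = len(pairs)
        adjusted = {}
        running = 0.0
        for i, p in enumerate(order):
            running = max(running, (m - i) * raw[p])
            adjusted[p] = min(1.0, running)

    return pd.DataFrame(
        [{
            "method_i": p[0], "method_j": p[1], "z": z[p],
            "p_raw": raw[p], "p_adjusted": adjusted[p],
        } for p in pairs]
    )


def paired_ttest(a, b) -> tuple:
    """Two-sided paired t-test; returns (t, p) with n-1 degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    d = a - b
    if np.var(d, ddof=1) == 0:
        raise ValueError("zero variance of paired differences: t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EvaluationReport:
    """Per-cell accuracy table plus significance-test results."""

    metrics: pd.DataFrame    # method, variable, group_type, group, r2, ...
    friedman: pd.DataFrame   # variable, statistic, p, methods
    posthoc: pd.DataFrame    # variable, method_i, method_j, z, p_raw, p_adjusted
    ttests: pd.DataFrame     # variable, method_a, method_b, t, p


def compare_report(
    predictions: pd.DataFrame,
    measurements: pd.DataFrame,
    groupings: tuple = ("pooled", "date"),
    ttest_pairs: tuple = (("lut_std", "lut_reg"),),
    targets: tuple = TRAITS,
) -> EvaluationReport:
    """Build the full method x trait x group comparison report.

    ``predictions`` holds one row per (method, plot_id) with predicted
    trait columns; ``measurements`` one row per plot_id with measured
    traits and ``date``/``nitrogen`` metadata.  Metrics are computed per
    grouping cell (the NRMSE range is the observed range *within* the
    cell, recorded in ``range_used``); the Friedman test compares >= 3
    methods on pooled per-plot absolute errors, and the paired t-test is
    run for the designated method pairs.
    """
    methods = list(predictions["method"].unique())
    merged = predictions.merge(
        measurements, on="plot_id", suffixes=("_pred", "_obs")
    )
    rows = []
    for method in methods:
        sub_m = merged[merged["method"] == method]
        for trait in targets:
            cells = []
            if "pooled" in groupings:
                cells.append(("pooled", "all", sub_m))
            if "date" in groupings:
                cells.extend(
                    ("date", d, g) for d, g in sub_m.groupby("date")
                )
            if "nitrogen" in groupings and "nitrogen" in sub_m.columns:
                cells.extend(
                    ("nitrogen", nl, g) for nl, g in sub_m.groupby("nitrogen")
                )
            for gtype, gname, cell in cells:
                obs = cell[f"{trait}_obs"].to_numpy()
                pred = cell[f"{trait}_pred"].to_numpy()
                if len(obs) < 2 or np.ptp(obs) == 0:
                    warnings.warn(
                        f"group {gname} skipped for {method}/{trait}: "
                        "too few points or zero range",
                        stacklevel=2,
                    )
                    continue
                sc = metrics(obs, pred)
                rows.append({
                    "method": method, "variable": trait,
                    "group_type": gtype, "group": gname,
                    "r2": sc.r2, "rmse": sc.rmse,
                    "nrmse_pct": sc.nrmse_pct, "n": sc.n,
                    "range_used": sc.range_used,
                })
    metrics_df = pd.DataFrame(rows)

    fried_rows, post_rows = [], []
    if len(methods) >= 3:
        for trait in targets:
            errs = []
            for method in methods:
                sub = merged[merged["method"] == method].sort_values("plot_id")
                errs.append(
                    np.abs(sub[f"{trait}_pred"].to_numpy()
                           - sub[f"{trait}_obs"].to_numpy())
                )
            E = np.column_stack(errs)
            chi2, p = friedman_test(E)
            fried_rows.append({
                "variable": trait, "statistic": chi2, "p": p,
                "methods": ",".join(methods),
            })
            ph = pairwise_posthoc(E)
            ph["method_i"] = ph["method_i"].map(dict(enumerate(methods)))
            ph["method_j"] = ph["method_j"].map(dict(enumerate(methods)))
            ph.insert(0, "variable", trait)
            post_rows.append(ph)

    tt_rows = []
    for ma, mb in ttest_pairs:
        if ma not in methods or mb not in methods:
            continue
        for trait in targets:
            sa = merged[merged["method"] == ma].sort_values("plot_id")
            sb = merged[merged["method"] == mb].sort_values("plot_id")
            ea = np.abs(sa[f"{trait}_pred"].to_numpy()
                        - sa[f"{trait}_obs"].to_numpy())
            eb = np.abs(sb[f"{trait}_pred"].to_numpy()
                        - sb[f"{trait}_obs"].to_numpy())
            try:
                t, p = paired_ttest(ea, eb)
            except ValueError:
                continue
            tt_rows.append({"variable": trait, "method_a": ma,
                            "method_b": mb, "t": t, "p": p})

    return EvaluationReport(
        metrics=metrics_df,
        friedman=pd.DataFrame(fried_rows),
        posthoc=(pd.concat(post_rows, ignore_index=True)
                 if post_rows else pd.DataFrame()),
        ttests=pd.DataFrame(tt_rows),
    )
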