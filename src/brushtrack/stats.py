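"""The inferential layer: nonparametric comparisons and equivalence checks.

All group data are summarized as median (min; max).  Independent groups are
compared with the Mann-Whitney U test, paired data with the Wilcoxon
signed-rank test, correlations use Spearman's rho, and families of p values
(the 18 per-area VO-vs-MT duration comparisons) are adjusted by the
Bonferroni-Holm step-down procedure.  The tracker-effect sub-study uses a
two-sided 90% confidence interval of the mean paired difference, declared
equivalent when it lies entirely within +/-8 s (the two-one-sided-tests
duality at level 5%).

Exact small-sample null distributions are used where tractable (U when the
smaller group has <= 8 observations, signed-rank for n <= 25, both only
without ties); otherwise the tie-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .areas import ALL_AREAS
from .errors import DegenerateDataError, UndefinedResultError

ALPHA_DEFAULT = 0.05
EQUIVALENCE_MARGIN_S = 8.0


def median_min_max(values) -> tuple[float, float, float]:
    v = np.asarray(list(values), dtype=float)
    return float(np.median(v)), float(v.min()), float(v.max())


def format_mmm(values) -> str:
    """Render a sample the way results tables print it: median (min; max)."""
    m, lo, hi = median_min_max(values)
    return f"{m:.2f} ({lo:.2f}; {hi:.2f})"


@dataclass
class ComparisonResult:
    """Outcome of one two-sample or paired comparison."""

    label: str
    statistic: float
    p_value: float
    summary_a: tuple  # (median, min, max)
    summary_b: tuple
    n_a: int
    n_b: int
    method: str
    p_adjusted: float | None = None

    def significant(self, alpha: float = ALPHA_DEFAULT) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        return p < alpha


@dataclass(frozen=True)
class EquivalenceResult:
    """t-based two-sided CI of a mean paired difference vs an equivalence
    margin; ``equivalent`` iff the CI lies inside [-margin, +margin]."""

    mean_difference_s: float
    ci90_low_s: float
    ci90_high_s: float
    margin_s: float
    equivalent: bool
    n: int
    level: float


def _has_ties(values) -> bool:
    v = np.asarray(values, dtype=float)
    return np.unique(v).size < v.size


def mann_whitney(group_a, group_b, label: str = "") -> ComparisonResult:
    """Two-sided Mann-Whitney U test for independent samples.

    Exact null distribution when the smaller group has <= 8 observations
    and there are no ties across the pooled sample; otherwise the
    tie-corrected normal approximation.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateDataError("both groups must be non-empty")
    exact = min(a.size, b.size) <= 8 and not _has_ties(np.concatenate([a, b]))
    method = "exact" if exact else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(
        label=label,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        summary_a=median_min_max(a),
        summary_b=median_min_max(b),
        n_a=a.size,
        n_b=b.size,
        method=f"mann-whitney-{method}",
    )


def wilcoxon_signed_rank(differences, label: str = "") -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (the classical
    convention).  Exact null for n <= 25 without tied magnitudes,
    otherwise the tie-corrected normal approximation.
    """
    d = np.asarray(list(differences), dtype=float)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        raise DegenerateDataError(
            "all paired differences are zero; the signed-rank test is degenerate"
        )
    exact = nonzero.size <= 25 and not _has_ties(np.abs(nonzero))
    method = "exact" if exact else "approx"
    res = scipy.stats.wilcoxon(
        nonzero, alternative="two-sided", method=method, correction=not exact
    )
    return ComparisonResult(
        label=label,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        summary_a=median_min_max(d),
        summary_b=median_min_max(d),
        n_a=d.size,
        n_b=nonzero.size,
        method=f"wilcoxon-{method}",
    )


def spearman_rho(x, y, label: str = "") -> ComparisonResult:
    """Spearman rank correlation with average ranks for ties."""
    xv = np.asarray(list(x), dtype=float)
    yv = np.asarray(list(y), dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 3:
        raise DegenerateDataError("correlation needs at least 3 pairs")
    if np.unique(xv).size == 1 or np.unique(yv).size == 1:
        raise UndefinedResultError("correlation is undefined for constant input")
    rho, p = scipy.stats.spearmanr(xv, yv)
    return ComparisonResult(
        label=label,
        statistic=float(rho),
        p_value=float(p),
        summary_a=median_min_max(xv),
        summary_b=median_min_max(yv),
        n_a=xv.size,
        n_b=yv.size,
        method="spearman",
    )


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment, order matching the input.

    The adjusted values are monotone over the sorted raw values, never
    below the raw p, never above the Bonferroni bound, and capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def equivalence_ci(
    differences,
    margin_s: float = EQUIVALENCE_MARGIN_S,
    level: float = 0.90,
) -> EquivalenceResult:
    """Two-sided t confidence interval of the mean paired difference.

    A ``level`` two-sided CI inside [-margin, +margin] is the TOST
    criterion for equivalence at significance (1 - level)/2 per side
    (level 0.90 corresponds to equivalence tests at 5%).
    """
    d = np.asarray(list(differences), dtype=float)
    if d.size < 2:
        raise DegenerateDataError("equivalence CI needs at least 2 differences")
    mean = float(d.mean())
    se = float(d.std(ddof=1) / np.sqrt(d.size))
    tcrit = float(scipy.stats.t.ppf(0.5 + level / 2.0, df=d.size - 1))
    lo, hi = mean - tcrit * se, mean + tcrit * se
    return EquivalenceResult(
        mean_difference_s=mean,
        ci90_low_s=lo,
        ci90_high_s=hi,
        margin_s=margin_s,
        equivalent=bool(-margin_s <= lo and hi <= margin_s),
        n=d.size,
        level=level,
    )


# ---------------------------------------------------------------------------
# Whole-study report


def _result_row(comparison: str, res: ComparisonResult | None, alpha, reason=""):
    if res is None:
        return {
            "comparison": comparison, "statistic": np.nan, "p_value": np.nan,
            "p_adjusted": np.nan, "summary_a": "", "summary_b": "",
            "significant": False, "skipped": True, "reason": reason,
            "method": "",
        }
    sa = f"{res.summary_a[0]:.4g} ({res.summary_a[1]:.4g}; {res.summary_a[2]:.4g})"
    sb = f"{res.summary_b[0]:.4g} ({res.summary_b[1]:.4g}; {res.summary_b[2]:.4g})"
    return {
        "comparison": comparison, "statistic": res.statistic,
        "p_value": res.p_value,
        "p_adjusted": res.p_adjusted if res.p_adjusted is not None else np.nan,
        "summary_a": sa, "summary_b": sb,
        "significant": res.significant(alpha), "skipped": False, "reason": "",
        "method": res.method,
    }


def _paired_diff(frame, key, index_cols=("subject_id",)):
    """Within-subject differences of ``key`` between two row groups."""
    a, b = frame
    merged = a.merge(b, on=list(index_cols), suffixes=("_a", "_b"))
    return (merged[f"{key}_b"] - merged[f"{key}_a"]).to_numpy(), merged


def run_study_analysis(
    metrics_table: pd.DataFrame,
    agreement_table: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
) -> dict:
    """The full inferential report of a study.

    Inputs are the per-session metrics table (one row per subject x session
    x source, as built by :func:`brushtrack.metrics.session_metrics`) and
    the per-session agreement table (subject_id, session, brush,
    matching_pct).  Emits four report frames:

    ``matching_by_brush``
        manual-vs-powered matching proportion (Mann-Whitney, baseline).
    ``area_durations``
        VO-vs-MT brushing duration per area, Wilcoxon over subjects with
        Holm adjustment across the 18 areas (baseline).
    ``vo_vs_mt``
        VO-vs-MT events and TSI (Wilcoxon) plus the Spearman correlation
        of event counts, per brush type (baseline).
    ``instruction_effect``
        baseline-vs-post-instruction TSI / isochronicity / consistency /
        events per brush type and source (Wilcoxon on within-subject
        differences).

    Comparisons that are degenerate (all-zero paired differences, constant
    groups, missing sessions) are reported as skipped rows, never as
    significant findings.
    """
    base = metrics_table[metrics_table["session"] == "baseline"]
    post = metrics_table[metrics_table["session"] == "post_instruction"]
    agree_base = agreement_table[agreement_table["session"] == "baseline"]
    report: dict[str, pd.DataFrame] = {}

    # (1) matching proportion by brush type
    rows = []
    man = agree_base.loc[agree_base["brush"] == "manual", "matching_pct"]
    pow_ = agree_base.loc[agree_base["brush"] == "powered", "matching_pct"]
    comp = "matching_pct: manual vs powered"
    if len(man) == 0 or len(pow_) == 0:
        rows.append(_result_row(comp, None, alpha, "a brush arm has no sessions"))
    elif man.nunique() == 1 and pow_.nunique() == 1 and man.iloc[0] == pow_.iloc[0]:
        rows.append(_result_row(comp, None, alpha, "both groups constant and equal"))
    else:
        rows.append(_result_row(comp, mann_whitney(man, pow_, comp), alpha))
    report["matching_by_brush"] = pd.DataFrame(rows)

    # (2) per-area VO vs MT durations, Holm over the 18 areas
    vo = base[base["source"] == "VO"]
    mt = base[base["source"] == "MT"]
    rows, live_idx, live_p = [], [], []
    for area in ALL_AREAS:
        key = f"d_{area}"
        comp = f"duration {area}: VO vs MT"
        diffs, _ = _paired_diff((vo, mt), key)
        if diffs.size == 0:
            rows.append(_result_row(comp, None, alpha, "no paired sessions"))
            continue
        if not np.any(diffs != 0):
            rows.append(_result_row(comp, None, alpha, "all paired differences zero"))
            continue
        res = wilcoxon_signed_rank(diffs, comp)
        res.summary_a = median_min_max(vo[key])
        res.summary_b = median_min_max(mt[key])
        live_idx.append(len(rows))
        live_p.append(res.p_value)
        rows.append(_result_row(comp, res, alpha))
    if live_p:
        adj = holm_adjust(live_p)
        for i, idx in enumerate(live_idx):
            rows[idx]["p_adjusted"] = adj[i]
            rows[idx]["significant"] = bool(adj[i] < alpha)
    report["area_durations"] = pd.DataFrame(rows)

    # (3) VO vs MT events / TSI and event-count correlation, per brush
    rows = []
    for brush in ("manual", "powered"):
        vo_b = vo[vo["brush"] == brush]
        mt_b = mt[mt["brush"] == brush]
        merged = vo_b.merge(mt_b, on="subject_id", suffixes=("_vo", "_mt"))
        for key in ("events", "TSI"):
            comp = f"{key} ({brush}): VO vs MT"
            if len(merged) == 0:
                rows.append(_result_row(comp, None, alpha, "no paired sessions"))
                continue
            diffs = (merged[f"{key}_mt"] - merged[f"{key}_vo"]).to_numpy()
            if not np.any(diffs != 0):
                rows.append(_result_row(comp, None, alpha, "all paired differences zero"))
                continue
            res = wilcoxon_signed_rank(diffs, comp)
            res.summary_a = median_min_max(merged[f"{key}_vo"])
            res.summary_b = median_min_max(merged[f"{key}_mt"])
            rows.append(_result_row(comp, res, alpha))
        comp = f"events ({brush}): Spearman rho VO~MT"
        try:
            rho = spearman_rho(merged["events_vo"], merged["events_mt"], comp)
            rows.append(_result_row(comp, rho, alpha))
        except (DegenerateDataError, UndefinedResultError) as exc:
            rows.append(_result_row(comp, None, alpha, str(exc)))
    report["vo_vs_mt"] = pd.DataFrame(rows)

    # (4) instruction effect per brush x source x measure
    rows = []
    for brush in ("manual", "powered"):
        for source in ("VO", "MT"):
            b_rows = base[(base["brush"] == brush) & (base["source"] == source)]
            p_rows = post[(post["brush"] == brush) & (post["source"] == source)]
            for key in ("TSI", "I", "C", "events"):
                comp = f"{key} ({brush}, {source}): baseline vs post-instruction"
                diffs, merged = _paired_diff((b_rows, p_rows), key)
                if diffs.size == 0:
                    rows.append(_result_row(comp, None, alpha, "no paired sessions"))
                    continue
                if not np.any(diffs != 0):
                    rows.append(
                        _result_row(comp, None, alpha, "all paired differences zero")
                    )
                    continue
                res = wilcoxon_signed_rank(diffs, comp)
                res.summary_a = median_min_max(merged[f"{key}_a"])
                res.summary_b = median_min_max(merged[f"{key}_b"])
                rows.append(_result_row(comp, res, alpha))
    report["instruction_effect"] = pd.DataFrame(rows)
    return report
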