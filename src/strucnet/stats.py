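"""Group comparisons, FDR-controlled nodal tests, clinical correlations,
and the mixed model on attack trajectories.

Per metric, the two groups are compared with a two-tailed Welch t-test
when a Shapiro-Wilk test (alpha = 0.05) accepts normality in both
groups, and with a Mann-Whitney U-test otherwise (exact for combined
n <= 20 without ties, tie-corrected normal approximation beyond).  Each
output row records which test ran.

Node-wise comparisons are corrected within each property family (local
efficiency, degree, betweenness; m = number of nodes per family) by the
Benjamini-Hochberg step-up procedure at q = 0.05; uncorrected p < 0.05
is flagged separately.

Clinical associations are Pearson correlations of each global metric
with each score, within group, pairwise-complete over missing scores;
symptom/functioning scales exist only for patients.

Robustness trajectories are modeled as
``global_efficiency ~ n_removed * group`` with a per-subject random
intercept, fitted by REML; the group-by-number-of-removed-nodes
interaction is the quantity of interest.  The clustering trajectory is
excluded from this model by default because its U-shaped course is not
linear in the number of removed nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .metrics import GLOBAL_METRICS

__all__ = [
    "StatsReport", "compare_two_samples", "compare_global", "compare_nodal",
    "bh_adjust", "correlate_clinical", "fit_trajectory_lmm", "run_stats",
]

CLINICAL_SCORES = ("fsiq_raw", "fsiq_adjusted", "ctt1_t", "ctt2_t",
                   "panss_total", "gaf")
PATIENT_ONLY_SCORES = ("panss_total", "gaf")


@dataclass
class StatsReport:
    global_rows: pd.DataFrame
    nodal_rows: pd.DataFrame
    correlation_rows: pd.DataFrame
    lmm_row: dict


def compare_two_samples(x: np.ndarray, y: np.ndarray) -> tuple[str, float, float]:
    """Normality-gated two-sample test.

    Returns (test_name, statistic, two-sided p).  Both groups Shapiro
    normal at alpha 0.05 -> Welch t; otherwise Mann-Whitney U (exact for
    combined n <= 20 with no ties).  Zero variance in both groups gives
    p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:
        warnings.warn("zero variance in both groups; p set to 1")
        return "degenerate", 0.0, 1.0
    normal = True
    for g in (x, y):
        if np.ptp(g) == 0.0:
            normal = False
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if sps.shapiro(g).pvalue < 0.05:
                normal = False
                break
    if normal:
        res = sps.ttest_ind(x, y, equal_var=False)
        return "welch_t", float(res.statistic), float(res.pvalue)
    n = len(x) + len(y)
    ties = len(np.unique(np.concatenate([x, y]))) < n
    method = "exact" if (n <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return "mannwhitney_u", float(res.statistic), float(res.pvalue)


def _group_frames(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    pat = df[df["group"] == "patient"]
    con = df[df["group"] == "control"]
    if len(pat) < 2 or len(con) < 2:
        raise ValueError("need at least 2 subjects per group")
    return pat, con


def compare_global(
    global_df: pd.DataFrame, metrics: tuple[str, ...] = GLOBAL_METRICS
) -> pd.DataFrame:
    """Per-metric group comparison of the global network properties.

    ``global_df`` has one row per subject with columns ``subject_id``,
    ``group`` and one column per metric.
    """
    pat, con = _group_frames(global_df)
    rows = []
    for metric in metrics:
        x = pat[metric].to_numpy(dtype=float)
        y = con[metric].to_numpy(dtype=float)
        test, statistic, p = compare_two_samples(x, y)
        rows.append(
            {
                "metric": metric,
                "patient_mean": x.mean(), "patient_sd": x.std(ddof=1),
                "control_mean": y.mean(), "control_sd": y.std(ddof=1),
                "test": test, "statistic": statistic, "p": p,
            }
        )
    return pd.DataFrame(rows)


def bh_adjust(
    p_values: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Adjusted p_(i) = min over j >= i of m * p_(j) / j, capped at 1;
    the rejected set is {adjusted <= q}.  Returns (adjusted, rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0.0) | (p > 1.0)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, adj <= q


def compare_nodal(
    nodal_df: pd.DataFrame, q: float = 0.05, pool_families: bool = False
) -> pd.DataFrame:
    """Node-wise group comparisons with FDR control.

    ``nodal_df`` is long-format with columns ``subject_id``, ``group``,
    ``property``, ``node_id``, ``node_name``, ``value``.  Tests run per
    (property, node); BH adjustment is applied within each property
    family by default (``pool_families=True`` corrects across all
    properties jointly instead).
    """
    rows = []
    for prop, pdf in nodal_df.groupby("property", sort=False):
        wide = pdf.pivot_table(
            index=["subject_id", "group"], columns="node_id", values="value"
        ).reset_index()
        pat, con = _group_frames(wide)
        names = dict(
            pdf.drop_duplicates("node_id")
            .set_index("node_id")["node_name"]
        )
        for node in sorted(c for c in wide.columns if isinstance(c, (int, np.integer))):
            x = pat[node].to_numpy(dtype=float)
            y = con[node].to_numpy(dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                test, statistic, p = compare_two_samples(x, y)
            rows.append(
                {
                    "property": prop, "node_id": int(node),
                    "node_name": names.get(node, str(node)),
                    "patient_mean": x.mean(), "patient_sd": x.std(ddof=1),
                    "control_mean": y.mean(), "control_sd": y.std(ddof=1),
                    "test": test, "statistic": statistic, "p": p,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    out["significant_at_q"] = False
    if pool_families:
        adj, rej = bh_adjust(out["p"].to_numpy(), q)
        out["p_adjusted"], out["significant_at_q"] = adj, rej
    else:
        for prop in out["property"].unique():
            mask = out["property"] == prop
            adj, rej = bh_adjust(out.loc[mask, "p"].to_numpy(), q)
            out.loc[mask, "p_adjusted"] = adj
            out.loc[mask, "significant_at_q"] = rej
    out["uncorrected_significant"] = out["p"] < 0.05
    return out


def correlate_clinical(
    global_df: pd.DataFrame,
    cohort: pd.DataFrame,
    metrics: tuple[str, ...] = GLOBAL_METRICS,
    scores: tuple[str, ...] = CLINICAL_SCORES,
    method: str = "pearson",
) -> pd.DataFrame:
    """Metric-by-score correlations within each group.

    Pearson r (or Spearman with ``method='spearman'``) with two-sided p,
    pairwise-complete over missing scores; patient-only scales are
    skipped for controls.  Cells with a constant vector or fewer than 3
    complete pairs are emitted with r = NaN and flagged.
    """
    df = global_df.merge(cohort, on=["subject_id", "group"], how="left")
    corr = sps.pearsonr if method == "pearson" else sps.spearmanr
    rows = []
    for group in ("patient", "control"):
        gdf = df[df["group"] == group]
        for score in scores:
            if group == "control" and score in PATIENT_ONLY_SCORES:
                continue
            if score not in gdf.columns:
                continue
            for metric in metrics:
                sub = gdf[[metric, score]].dropna()
                n = len(sub)
                row = {"group": group, "metric": metric, "score": score,
                       "n": n, "r": np.nan, "p": np.nan, "flag": ""}
                if n < 3:
                    row["flag"] = "too_few_pairs"
                elif sub[metric].nunique() == 1 or sub[score].nunique() == 1:
                    row["flag"] = "constant_vector"
                else:
                    res = corr(sub[metric], sub[score])
                    row["r"], row["p"] = float(res.statistic), float(res.pvalue)
                rows.append(row)
    return pd.DataFrame(rows)


def fit_trajectory_lmm(
    trajectories: pd.DataFrame,
    cohort: pd.DataFrame,
    response: str = "global_efficiency",
) -> dict:
    """Random-intercept mixed model on deletion trajectories.

    Fits ``response ~ n_removed + group + n_removed:group`` with a
    per-subject random intercept by REML and returns the interaction
    (patient slope minus control slope per removed node): estimate, SE,
    Wald z statistic and p, plus the data dimensions.
    """
    df = trajectories.merge(
        cohort[["subject_id", "group"]], on="subject_id", how="inner"
    )
    if df.empty:
        raise ValueError("no trajectory rows match the cohort")
    n_subj = df.groupby("group")["subject_id"].nunique()
    if (n_subj < 2).any() or len(n_subj) < 2:
        raise ValueError("need at least 2 subjects per group")
    if df.groupby("subject_id")["n_removed"].nunique().min() < 2:
        raise ValueError("need at least 2 steps per trajectory")
    df = df.copy()
    df["is_patient"] = (df["group"] == "patient").astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            f"{response} ~ n_removed * is_patient", df, groups=df["subject_id"]
        )
        fit = model.fit(reml=True)
    if not np.isfinite(fit.cov_re.to_numpy()).all():
        raise ValueError("singular fit: subject random-intercept variance")
    term = "n_removed:is_patient"
    est = float(fit.params[term])
    se = float(fit.bse[term])
    if not np.isfinite(se) or se == 0.0:
        raise ValueError("singular fit: interaction standard error")
    z = est / se
    return {
        "term": term,
        "estimate": est,
        "se": se,
        "statistic": float(z),
        "p": float(2.0 * sps.norm.sf(abs(z))),
        "random_intercept_var": float(fit.cov_re.iloc[0, 0]),
        "n_subjects": int(df["subject_id"].nunique()),
        "n_steps": int(df.groupby("subject_id")["n_removed"].nunique().max()),
    }


def run_stats(
    global_df: pd.DataFrame,
    nodal_df: pd.DataFrame,
    cohort: pd.DataFrame,
    trajectories: pd.DataFrame | None = None,
    q: float = 0.05,
) -> StatsReport:
    """Assemble the full statistical report."""
    lmm = {}
    if trajectories is not None and not trajectories.empty:
        lmm = fit_trajectory_lmm(trajectories, cohort)
    return StatsReport(
        global_rows=compare_global(global_df),
        nodal_rows=compare_nodal(nodal_df, q=q),
        correlation_rows=correlate_clinical(global_df, cohort),
        lmm_row=lmm,
    )
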