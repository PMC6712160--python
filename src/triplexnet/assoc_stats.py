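"""Survival and stage association screens for clique members.

Per RNA: patients are dichotomized at the median expression (ties join the
HIGH group) and the two survival curves are compared with the log-rank test.
Per triplet: a Cox proportional-hazards model with the three (log2)
expression covariates is evaluated with the global score test (3 df,
Breslow tie handling) at the null; with a binary covariate this statistic
reduces exactly to the two-group log-rank statistic on tie-free data, which
is used as a cross-check against lifelines.  Stage association is a one-way
ANOVA of expression across stages II/III/IV; samples with missing stage are
excluded from the ANOVA only.  Flags are 1 iff the raw p-value is below
0.05 (no multiple-testing correction is applied to the flags; BH-FDR
q-values are emitted alongside for reference).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .clique_mine import Triplet
from .containers import STAGES, ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)

ALPHA = 0.05

LOW, HIGH = "LOW", "HIGH"


def median_split(expr: pd.Series | np.ndarray) -> np.ndarray:
    """LOW iff value < median, HIGH iff value >= median (ties go HIGH)."""
    x = np.asarray(expr, dtype=float)
    if len(x) < 4:
        raise ValueError("median split needs at least 4 samples")
    if np.ptp(x) == 0:
        raise ValueError("constant expression: no median split possible")
    med = np.median(x)
    labels = np.where(x >= med, HIGH, LOW)
    if (labels == LOW).sum() == 0 or (labels == HIGH).sum() == 0:
        # heavy ties at the median can empty the LOW group
        raise ValueError("median split produced an empty group")
    return labels


def _align_survival(expr: pd.Series, clinical: ClinicalTable
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    common = expr.index.intersection(clinical.df.index)
    df = clinical.df.loc[common]
    usable = df["os_months"].notna() & df["event"].notna()
    df = df[usable]
    x = expr.loc[df.index].to_numpy(dtype=float)
    return x, df["os_months"].to_numpy(dtype=float), df["event"].to_numpy(dtype=int)


def univariate_logrank(expr: pd.Series, clinical: ClinicalTable
                       ) -> float:
    """Two-group log-rank p-value for the median split of one RNA.

    Returns NaN (with a warning) when no event is observed.
    """
    x, time, event = _align_survival(expr, clinical)
    labels = median_split(pd.Series(x))
    if event.sum() == 0:
        logger.warning("no events observed: log-rank undefined")
        return float("nan")
    lo, hi = labels == LOW, labels == HIGH
    res = logrank_test(time[lo], time[hi], event_observed_A=event[lo],
                       event_observed_B=event[hi])
    return float(res.p_value)


def km_curves(expr: pd.Series, clinical: ClinicalTable
              ) -> tuple[KaplanMeierFitter, KaplanMeierFitter]:
    """Kaplan-Meier fits for the LOW and HIGH median-split groups."""
    x, time, event = _align_survival(expr, clinical)
    labels = median_split(pd.Series(x))
    fits = []
    for name in (LOW, HIGH):
        mask = labels == name
        kmf = KaplanMeierFitter(label=name)
        kmf.fit(time[mask], event_observed=event[mask])
        fits.append(kmf)
    return fits[0], fits[1]


def plot_km(expr: pd.Series, clinical: ClinicalTable, path: str, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    low, high = km_curves(expr, clinical)
    fig, ax = plt.subplots(figsize=(5, 4))
    low.plot_survival_function(ax=ax)
    high.plot_survival_function(ax=ax)
    ax.set_xlabel("overall survival (months)")
    ax.set_ylabel("survival probability")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


@dataclass
class ScoreTestResult:
    chi2: float
    df: int
    p_value: float
    ridge_stabilized: bool = False


def cox_score_test(X: np.ndarray, time: np.ndarray, event: np.ndarray
                   ) -> ScoreTestResult:
    """Global score test of a Cox proportional-hazards model at beta = 0,
    with Breslow handling of tied event times.

    The score vector sums, over events, the covariate minus the risk-set
    mean; the information matrix sums the risk-set covariance.  The test is
    invariant to affine transforms of the covariates.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    n, p = X.shape
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    time, event, X = time[order], event[order], X[order]

    # suffix sums: risk set at t is every sample with observed time >= t
    s1 = np.cumsum(X[::-1], axis=0)[::-1]                     # (n, p)
    outer = X[:, :, None] * X[:, None, :]
    s2 = np.cumsum(outer[::-1], axis=0)[::-1]                 # (n, p, p)
    s0 = np.arange(n, 0, -1, dtype=float)                     # risk-set sizes

    U = np.zeros(p)
    V = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d_idx = [k for k in range(i, j) if event[k] == 1]
        d = len(d_idx)
        if d:
            mean = s1[i] / s0[i]
            U += X[d_idx].sum(axis=0) - d * mean
            V += d * (s2[i] / s0[i] - np.outer(mean, mean))
        i = j
    ridge = False
    try:
        chi2 = float(U @ np.linalg.solve(V, U))
        if not np.isfinite(chi2) or chi2 < 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        ridge = True
        eps = 1e-8 * max(np.trace(V) / max(p, 1), 1.0)
        chi2 = float(U @ np.linalg.solve(V + eps * np.eye(p), U))
        logger.warning("singular information matrix: ridge-stabilized score test")
    return ScoreTestResult(chi2, p, float(sps.chi2.sf(chi2, p)), ridge)


def multivariate_cox_p(triplet_exprs: Sequence[pd.Series], clinical: ClinicalTable,
                       coding: str = "continuous") -> float:
    """Global score-test p-value (df = number of covariates) for a Cox model
    on the member expressions of one clique.

    ``coding="continuous"`` uses the log2 expressions directly;
    ``coding="median"`` replaces each covariate by its 0/1 median split.
    Returns NaN with a warning when fewer than 10 events are available.
    """
    if coding not in ("continuous", "median"):
        raise ValueError("coding must be 'continuous' or 'median'")
    cols = []
    time = event = None
    for expr in triplet_exprs:
        x, time, event = _align_survival(expr, clinical)
        cols.append(x)
    X = np.column_stack(cols)
    if event is None or event.sum() < 10:
        logger.warning("fewer than 10 events: multivariate survival p undefined")
        return float("nan")
    if coding == "median":
        X = np.column_stack([(c >= np.median(c)).astype(float) for c in X.T])
    res = cox_score_test(X, time, event)
    return res.p_value


def stage_anova(expr: pd.Series, stages: pd.Series) -> float:
    """One-way ANOVA F-test p-value of expression across stages II/III/IV.

    Samples with missing stage are excluded; needs at least two stage groups
    with two or more samples each, otherwise NaN with a warning.
    """
    common = expr.index.intersection(stages.index)
    x = expr.loc[common]
    st = stages.loc[common]
    groups = [x[st == label].to_numpy(dtype=float) for label in STAGES]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        logger.warning("fewer than 2 usable stage groups: ANOVA undefined")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant inputs raise a scipy warning
        stat, p = sps.f_oneway(*groups)
    if not np.isfinite(p):
        logger.warning("degenerate ANOVA (constant groups)")
        return float("nan")
    return float(p)


# ---------------------------------------------------------------------------
# flag annotation
# ---------------------------------------------------------------------------


def per_rna_flags(rna_ids: Sequence[str], expr: ExpressionMatrix,
                  clinical: ClinicalTable) -> pd.DataFrame:
    """Univariate survival and stage ANOVA p-values and 0/1 flags per RNA."""
    stages = clinical.df["stage"]
    rows = []
    for tid in rna_ids:
        x = expr.row(tid)
        try:
            p_surv = univariate_logrank(x, clinical)
        except ValueError as exc:
            logger.warning("%s: survival screen skipped (%s)", tid, exc)
            p_surv = float("nan")
        p_stage = stage_anova(x, stages)
        rows.append({"rna_id": tid, "biotype": expr.biotypes.loc[tid],
                     "p_survival": p_surv, "p_stage": p_stage})
    out = pd.DataFrame(rows).set_index("rna_id")
    out["survival_flag"] = ((out["p_survival"] < ALPHA).fillna(False)).astype(int)
    out["stage_flag"] = ((out["p_stage"] < ALPHA).fillna(False)).astype(int)
    for col in ("p_survival", "p_stage"):
        q = np.full(len(out), np.nan)
        ok = out[col].notna().to_numpy()
        if ok.any():
            q[ok] = sps.false_discovery_control(out[col].to_numpy()[ok])
        out["q" + col[1:]] = q
    return out


def annotate_triplets(triplets: Sequence[Triplet], expr: ExpressionMatrix,
                      clinical: ClinicalTable, stage_rule: str = "all",
                      coding: str = "continuous") -> pd.DataFrame:
    """Flag table for a list of typed triplets.

    Per member: univariate survival and stage flags (0/1).  Per triplet: the
    multivariate Cox score-test flag, a triplet-level stage flag (1 iff ALL
    members are stage-significant, or ANY with ``stage_rule="any"``) and the
    combined ``both_significant`` flag (multivariate survival AND stage).
    Missing p-values propagate as flag 0 with the p recorded as NaN.
    """
    if stage_rule not in ("all", "any"):
        raise ValueError("stage_rule must be 'all' or 'any'")
    rna_ids = sorted({x for t in triplets for x in t.key})
    missing = [x for x in rna_ids if x not in expr.transcript_ids]
    if missing:
        raise ValueError(f"triplet members absent from expression matrix: {missing[:5]}")
    per_rna = per_rna_flags(rna_ids, expr, clinical)

    rows = []
    for t in triplets:
        mv_p = multivariate_cox_p([expr.row(x) for x in t.key], clinical, coding=coding)
        member_stage = [int(per_rna.loc[x, "stage_flag"]) for x in t.key]
        stage_flag = int(all(member_stage) if stage_rule == "all" else any(member_stage))
        mv_flag = int(bool(mv_p < ALPHA)) if np.isfinite(mv_p) else 0
        row = {
            "mrna_id": t.mrna_id, "lncrna_id": t.lncrna_id, "mirna_id": t.mirna_id,
            "multivariate_p": mv_p, "multivariate_flag": mv_flag,
            "stage_flag": stage_flag,
            "both_significant": int(mv_flag and stage_flag),
        }
        for slot, x in zip(("mrna", "lncrna", "mirna"), t.key):
            row[f"{slot}_survival_flag"] = int(per_rna.loc[x, "survival_flag"])
            row[f"{slot}_stage_flag"] = int(per_rna.loc[x, "stage_flag"])
            row[f"{slot}_p_survival"] = float(per_rna.loc[x, "p_survival"])
            row[f"{slot}_p_stage"] = float(per_rna.loc[x, "p_stage"])
        rows.append(row)
    return pd.DataFrame(rows)
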