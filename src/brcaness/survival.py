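"""Median-split survival screening of panel-gene expression.

For each gene and cancer type, patients are split at the gene's median
expression (values strictly above the median are "high"; values equal
to the median go to the "low" group), the two groups are compared by
the two-sided log-rank test, and the hazard ratio of high vs low is
derived from the log-rank observed/expected quantities,

    HR = (O_high / E_high) / (O_low / E_low),
    95% CI = exp(log HR +/- 1.96 * sqrt(1/E_high + 1/E_low)).

A gene is "risky" in a cancer type when p < 0.05 and HR > 1,
"protective" when p < 0.05 and HR < 1.  The per-cancer prognosis
feature counts the genes with p < 0.05 (an HR>1-only mode is
config-selectable).  Kaplan-Meier curves come from lifelines; the
log-rank table is computed in-package because the O/E terms feed the
hazard ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .config import PipelineConfig
from .errors import AnalysisError
from .panel import GenePanel

logger = logging.getLogger(__name__)


def median_split(values: pd.Series) -> pd.Series:
    """Label samples "high" (value > median) or "low" (value <= median).

    Raises on fewer than 2 samples.  When all values are identical the
    split is degenerate: all samples land in "low" and the result's
    ``.attrs["degenerate"]`` is True; callers exclude such genes.
    """
    if len(values) < 2:
        raise AnalysisError("median split requires at least 2 samples")
    med = float(values.median())
    labels = pd.Series(np.where(values > med, "high", "low"), index=values.index)
    labels.attrs["degenerate"] = bool((labels == "low").all() or (labels == "high").all())
    return labels


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve.

    Returns the right-continuous step function as a table of event/censor
    times and the survival probability just after each.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise AnalysisError("empty survival input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


@dataclass
class LogrankResult:
    """Two-group log-rank test with observed/expected bookkeeping."""

    statistic: float
    p: float
    o_a: float
    e_a: float
    o_b: float
    e_b: float
    variance: float
    n_a: int
    n_b: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.statistic)


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Standard (unweighted) two-sample log-rank test.

    At each distinct event time the hypergeometric expectation and
    variance of group-A deaths are accumulated; the statistic is
    (O_A - E_A)^2 / Var with a chi-square(1) two-sided p-value.  With no
    events at all the test is undefined (NaN statistic and p).
    """
    ta = np.asarray(times_a, dtype=float); ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float); eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise AnalysisError("log-rank test requires two non-empty groups")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(times[events == 1])
    o_a = e_a = var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        dying = (times == t) & (events == 1)
        d = int(dying.sum())
        d_a = int((dying & in_a).sum())
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    o_total = int(events.sum())
    if o_total == 0 or var == 0:
        return LogrankResult(np.nan, np.nan, o_a, e_a, o_total - o_a,
                             o_total - e_a, var, ta.size, tb.size)
    stat = (o_a - e_a) ** 2 / var
    p = float(stats.chi2.sf(stat, df=1))
    return LogrankResult(float(stat), p, o_a, e_a, float(o_total - o_a),
                         float(o_total - e_a), var, ta.size, tb.size)


@dataclass
class HazardRatio:
    hr: float
    ci_low: float
    ci_high: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.hr) and self.hr > 0


def hazard_ratio(result: LogrankResult) -> HazardRatio:
    """O/E hazard ratio of group A vs group B with a 95% CI.

    Undefined when either expected-event term is zero.  When one group
    has no observed events the point estimate is 0 or inf and the CI is
    degenerate at the same value.
    """
    if result.e_a == 0 or result.e_b == 0:
        return HazardRatio(np.nan, np.nan, np.nan)
    hr = (result.o_a / result.e_a) / (result.o_b / result.e_b)
    if hr == 0 or not np.isfinite(hr):
        return HazardRatio(hr, hr, hr)
    se = np.sqrt(1.0 / result.e_a + 1.0 / result.e_b)
    return HazardRatio(hr, float(hr * np.exp(-1.96 * se)), float(hr * np.exp(1.96 * se)))


def prognostic_screen(expression: pd.DataFrame, clinical: pd.DataFrame,
                      panel: GenePanel, config: PipelineConfig | None = None
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Median-split log-rank screen of every panel gene in every cancer type.

    Returns the forest table (gene x cancer: group sizes, log-rank
    statistic and p, HR with 95% CI, direction) and the per-cancer
    count of prognostic ("risky") genes.  Degenerate splits are skipped
    and logged.
    """
    config = config or PipelineConfig()
    clin = clinical.set_index("sample")
    shared = [s for s in expression.columns if s in clin.index]
    if not shared:
        raise AnalysisError("no samples shared between expression and clinical tables")
    clin = clin.loc[shared]
    genes = [g for g in panel.symbols if g in expression.index]
    rows = []
    for ctype, grp in clin.groupby("cancer_type"):
        ids = list(grp.index)
        if len(ids) < 2:
            continue
        times = grp["os_days"].to_numpy(dtype=float)
        events = grp["os_event"].to_numpy(dtype=int)
        mat = expression.loc[genes, ids].to_numpy(dtype=float)
        for gi, gene in enumerate(genes):
            vals = mat[gi]
            # same rule as median_split: strictly above the median is "high"
            hi = vals > np.median(vals)
            if not hi.any() or hi.all():
                logger.info("degenerate median split: %s in %s", gene, ctype)
                continue
            res = logrank_test(times[hi], events[hi], times[~hi], events[~hi])
            hr = hazard_ratio(res)
            direction = "none"
            if res.defined and res.p < config.survival_alpha and hr.defined:
                if hr.hr > 1:
                    direction = "risky"
                elif hr.hr < 1:
                    direction = "protective"
            rows.append(dict(
                gene=gene, cancer_type=ctype, n_high=int(hi.sum()),
                n_low=int((~hi).sum()), statistic=res.statistic, p=res.p,
                hr=hr.hr, ci_low=hr.ci_low, ci_high=hr.ci_high,
                direction=direction,
            ))
    forest = pd.DataFrame(rows)
    if len(forest):
        non_ref = forest["gene"].isin(set(panel.brcaness_genes))
        sig = forest["p"] < config.survival_alpha
        if config.risky_mode == "hr_gt_1":
            sig = sig & (forest["hr"] > 1)
        counts = (forest.loc[non_ref].assign(sig=sig[non_ref])
                  .groupby("cancer_type")["sig"].sum().astype(int))
    else:
        counts = pd.Series(dtype=int)
    return forest, counts


@dataclass
class Stratification:
    """2-group patient stratification on panel expression."""

    labels: pd.Series          # sample -> "lower" / "higher"
    silhouette: float
    group_sizes: dict


def stratify_patients(expression: pd.DataFrame, panel: GenePanel, k: int = 2,
                      config: PipelineConfig | None = None) -> Stratification:
    """Hierarchical clustering of patients on panel-gene expression.

    Euclidean distance, average linkage, tree cut at ``k`` clusters;
    with k = 2 the groups are named by mean panel expression ("lower",
    "higher").  The silhouette coefficient reports separation strength
    (low for a single tight cluster).
    """
    config = config or PipelineConfig()
    genes = [g for g in panel.symbols if g in expression.index]
    X = expression.loc[genes].T  # samples x genes
    if k > len(X):
        raise AnalysisError(f"k={k} exceeds {len(X)} samples")
    Z = linkage(X.to_numpy(), method=config.stratify_linkage,
                metric=config.stratify_metric)
    raw = fcluster(Z, t=k, criterion="maxclust")
    means = X.mean(axis=1).groupby(raw).mean().sort_values()
    names = (["lower", "higher"] if k == 2
             else [f"group{i + 1}" for i in range(len(means))])
    rename = {cl: nm for cl, nm in zip(means.index, names)}
    labels = pd.Series([rename[c] for c in raw], index=X.index)
    if len(set(raw)) > 1:
        sil = float(silhouette_score(X.to_numpy(), raw))
    else:
        sil = float("nan")
    return Stratification(labels=labels, silhouette=sil,
                          group_sizes=labels.value_counts().to_dict())


def stratified_survival(expression: pd.DataFrame, clinical: pd.DataFrame,
                        panel: GenePanel, config: PipelineConfig | None = None
                        ) -> tuple[Stratification, LogrankResult]:
    """Stratify patients on panel expression, then compare the two groups'
    overall survival by the log-rank test."""
    clin = clinical.set_index("sample")
    shared = [s for s in expression.columns if s in clin.index]
    if len(shared) < 2:
        raise AnalysisError("need >= 2 samples shared between expression and clinical")
    strat = stratify_patients(expression[shared], panel, k=2, config=config)
    lower = strat.labels == "lower"
    t = clin.loc[shared, "os_days"].to_numpy(dtype=float)
    ev = clin.loc[shared, "os_event"].to_numpy(dtype=int)
    res = logrank_test(t[lower.to_numpy()], ev[lower.to_numpy()],
                       t[~lower.to_numpy()], ev[~lower.to_numpy()])
    return strat, res
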