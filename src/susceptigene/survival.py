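"""Stage 3 of the screen: survival stratification, Kaplan-Meier, log-rank
and univariate Cox hazard ratios, implemented from first principles.

Each candidate gene is scored by dichotomizing the cohort at expression
quantiles (default: top vs bottom 25%), estimating the hazard ratio of the
high-expression group with a univariate Cox proportional-hazards model
(Breslow tie handling), and testing the separation with the two-group
log-rank statistic. HR > 1 means high expression carries worse prognosis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalTable",
    "StratifiedGroups",
    "KMCurve",
    "HazardResult",
    "stratify_by_quantile",
    "km_estimate",
    "logrank_test",
    "cox_hr",
    "hazard_screen",
]


@dataclass
class SurvivalTable:
    """Per-sample follow-up time, event indicator, and expression covariates."""

    time: pd.Series
    event: pd.Series
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.time) == 0:
            raise ValueError("empty survival table")
        if self.time.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.time <= 0).any():
            raise ValueError("follow-up times must be positive")
        ev = set(pd.unique(self.event))
        if not ev <= {0, 1}:
            raise ValueError(f"event indicator must be 0/1, found {sorted(ev)[:5]}")
        self.event = self.event.reindex(self.time.index)
        if not self.covariates.empty:
            self.covariates = self.covariates.reindex(self.time.index)

    @property
    def samples(self) -> pd.Index:
        return self.time.index

    def subset(self, samples) -> "SurvivalTable":
        cov = self.covariates.loc[samples] if not self.covariates.empty else pd.DataFrame()
        return SurvivalTable(
            time=self.time.loc[samples], event=self.event.loc[samples], covariates=cov
        )


@dataclass
class StratifiedGroups:
    high: list  # sample ids, top quantile
    low: list  # sample ids, bottom quantile
    q: float


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t); 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class HazardResult:
    gene_id: str
    log_hr: float
    hr: float
    ci95: tuple[float, float]
    se: float
    logrank_chi2: float
    logrank_p: float
    n_high: int
    n_low: int
    converged: bool = True
    note: str = ""


def stratify_by_quantile(
    values: pd.Series, q: float = 0.25
) -> StratifiedGroups:
    """Split samples into bottom-q and top-q expression groups.

    low: value <= q-quantile; high: value >= (1-q)-quantile (inclusive cuts,
    so ties at the cut fall into the extreme groups). Samples strictly
    between the cuts are excluded; q = 0.5 gives a median split covering the
    whole cohort. When heavy ties make both cuts coincide, tied samples are
    assigned to the low group to keep the groups disjoint.
    """
    if not 0 < q <= 0.5:
        raise ValueError("q must lie in (0, 0.5]")
    if len(values) < 4:
        raise ValueError("need at least 4 samples to stratify")
    v = values.to_numpy(dtype=float)
    if np.nanmax(v) == np.nanmin(v):
        raise ValueError("all expression values identical; cannot stratify")
    c_low = np.nanquantile(v, q)
    c_high = np.nanquantile(v, 1.0 - q)
    low_mask = v <= c_low
    high_mask = v >= c_high
    both = low_mask & high_mask
    if both.any():
        warnings.warn(
            "quantile cuts coincide under ties; tied samples assigned to low",
            stacklevel=2,
        )
        high_mask &= ~both
    return StratifiedGroups(
        high=list(values.index[high_mask]), low=list(values.index[low_mask]), q=q
    )


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i with
    d_i events among n_i at risk; censored observations only shrink the risk
    sets. With no events the curve is identically 1 (no event times).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    if t.size != e.size:
        raise ValueError("times and events differ in length")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    n_at_risk = np.empty(event_times.size, dtype=int)
    n_events = np.empty(event_times.size, dtype=int)
    for i, et in enumerate(event_times):
        n_at_risk[i] = int(np.sum(t >= et))
        n_events[i] = int(np.sum((t == et) & (e == 1)))
    surv = np.cumprod(1.0 - n_events / n_at_risk) if event_times.size else np.array([])
    return KMCurve(
        event_times=event_times,
        survival=surv,
        at_risk=n_at_risk,
        n_events=n_events,
    )


def _event_table(time_a, event_a, time_b, event_b):
    """Per distinct event time: (n_a at risk, n total, d_a, d total)."""
    ta, ea = np.asarray(time_a, float), np.asarray(event_a, int)
    tb, eb = np.asarray(time_b, float), np.asarray(event_b, int)
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(all_t[all_e == 1])
    for et in event_times:
        at_risk = all_t >= et
        dead = (all_t == et) & (all_e == 1)
        yield (
            int(np.sum(at_risk & in_a)),
            int(np.sum(at_risk)),
            int(np.sum(dead & in_a)),
            int(np.sum(dead)),
        )


def logrank_test(group_a: SurvivalTable, group_b: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank test.

    At each distinct event time the observed events in group A are compared
    with their hypergeometric expectation given the pooled risk set; the
    squared standardized sum is chi-square with 1 df.
    """
    if len(group_a.time) == 0 or len(group_b.time) == 0:
        raise ValueError("both groups must be non-empty")
    u = 0.0
    var = 0.0
    any_event = False
    for n_a, n, d_a, d in _event_table(
        group_a.time, group_a.event, group_b.time, group_b.event
    ):
        any_event = True
        u += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if not any_event:
        raise ValueError("no events in either group")
    if var == 0.0:
        return 0.0, 1.0
    chi2 = u * u / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), max(p, np.finfo(float).tiny)


def _cox_breslow_derivs(beta, t, e, x):
    """Log partial likelihood, score and information (Breslow ties)."""
    # ascending time; risk set of time t = suffix {t_j >= t}
    r = np.exp(beta * x)
    s0 = np.cumsum(r[::-1])[::-1]
    s1 = np.cumsum((x * r)[::-1])[::-1]
    s2 = np.cumsum((x * x * r)[::-1])[::-1]
    # first index of each tie block
    first = np.searchsorted(t, t, side="left")
    ev = e == 1
    f = first[ev]
    loglik = float(np.sum(beta * x[ev] - np.log(s0[f])))
    score = float(np.sum(x[ev] - s1[f] / s0[f]))
    info = float(np.sum(s2[f] / s0[f] - (s1[f] / s0[f]) ** 2))
    return loglik, score, info


def cox_hr(
    surv: SurvivalTable,
    group_indicator: pd.Series,
    tol: float = 1e-8,
    max_iter: int = 50,
    gene_id: str = "",
) -> HazardResult:
    """Univariate Cox proportional-hazards fit on a binary (or real)
    covariate, Newton-Raphson on the Breslow partial likelihood.

    The 95% CI comes from the observed information. Monotone likelihoods
    (complete separation of events) are returned as flagged non-converged
    results with an infinite confidence bound rather than raised.
    """
    x = group_indicator.reindex(surv.samples).to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("covariate is constant")
    if int(surv.event.sum()) < 1:
        raise ValueError("no events in the data")
    order = np.argsort(surv.time.to_numpy(), kind="stable")
    t = surv.time.to_numpy()[order]
    e = surv.event.to_numpy()[order]
    xv = x[order]
    # center for numerical stability; slope is unchanged
    xm = xv.mean()
    xv = xv - xm

    beta = 0.0
    converged = False
    note = ""
    for _ in range(max_iter):
        _, score, info = _cox_breslow_derivs(beta, t, e, xv)
        if info <= 0 or not np.isfinite(info):
            note = "degenerate information"
            break
        step = score / info
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(beta) > 30.0:
            note = "monotone likelihood (complete separation)"
            break
        if abs(step) < tol:
            converged = True
            break
    _, _, info = _cox_breslow_derivs(beta, t, e, xv)
    se = 1.0 / math.sqrt(info) if info > 0 and converged else math.inf
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    high_ids = group_indicator.index[group_indicator == 1]
    low_ids = group_indicator.index[group_indicator == 0]
    return HazardResult(
        gene_id=gene_id,
        log_hr=beta,
        hr=math.exp(beta) if abs(beta) < 700 else math.inf,
        ci95=(lo, hi),
        se=se,
        logrank_chi2=math.nan,
        logrank_p=math.nan,
        n_high=int(len(high_ids)),
        n_low=int(len(low_ids)),
        converged=converged,
        note=note,
    )


def hazard_screen(
    surv: SurvivalTable, genes, q: float = 0.25
) -> pd.DataFrame:
    """Quantile-stratified hazard screen over a gene list.

    Per gene: stratify the cohort at expression quantile ``q``, fit the Cox
    HR of high vs low, and run the log-rank test on the two groups. Genes
    that cannot be scored (constant expression, no events in the strata) are
    flagged and kept in the output rather than aborting the screen. Results
    are per-gene independent, so the gene order does not affect values.
    """
    rows = []
    for gene in genes:
        if gene not in surv.covariates.columns:
            raise KeyError(f"gene {gene!r} not among survival covariates")
        row = {
            "gene_id": gene,
            "log_hr": math.nan,
            "hr": math.nan,
            "ci_low": math.nan,
            "ci_high": math.nan,
            "logrank_chi2": math.nan,
            "logrank_p": math.nan,
            "n_high": 0,
            "n_low": 0,
            "ok": False,
            "note": "",
        }
        try:
            groups = stratify_by_quantile(surv.covariates[gene], q=q)
            members = groups.high + groups.low
            indicator = pd.Series(
                [1] * len(groups.high) + [0] * len(groups.low), index=members
            )
            sub = surv.subset(members)
            res = cox_hr(sub, indicator, gene_id=gene)
            chi2, p = logrank_test(
                sub.subset(groups.high), sub.subset(groups.low)
            )
            row.update(
                log_hr=res.log_hr,
                hr=res.hr,
                ci_low=res.ci95[0],
                ci_high=res.ci95[1],
                logrank_chi2=chi2,
                logrank_p=p,
                n_high=res.n_high,
                n_low=res.n_low,
                ok=res.converged,
                note=res.note,
            )
        except ValueError as exc:
            row["note"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def plot_km(
    curves: dict[str, tuple[np.ndarray, np.ndarray]],
    ax=None,
    title: str = "",
):
    """Step plot of one Kaplan-Meier curve per labelled group.

    ``curves`` maps a label to (times, events). Requires matplotlib.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, (times, events) in curves.items():
        km = km_estimate(times, events)
        xs = np.concatenate([[0.0], km.event_times])
        ys = np.concatenate([[1.0], km.survival])
        ax.step(xs, ys, where="post", label=label)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax
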