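"""Kaplan-Meier / log-rank screening of ce-lncRNAs, PCGs and ceRNA pairs.

Patients are dichotomized at the mean tumor expression of a gene (for a
ceRNA pair, at the mean of the per-patient average of the two genes);
high vs low groups are compared with the two-group log-rank test.
Product-limit curves and the chi-square statistic come from lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .exceptions import (
    DegenerateGroupingError,
    GeneLookupError,
    UndefinedTestError,
    ValidationError,
)
from .types import ClinicalTable

logger = logging.getLogger(__name__)


@dataclass
class SurvivalGrouping:
    """high/low patient partition at an expression cutoff (tie -> low)."""

    groups: pd.Series  # patient_id -> "high" | "low"
    cutoff_value: float

    def patients(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    n_high: int
    n_low: int
    events_high: int
    events_low: int


@dataclass
class KMCurve:
    """Product-limit survival estimate at each distinct event time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


def dichotomize_by_mean(values: pd.Series) -> SurvivalGrouping:
    """Split patients at the mean: strictly above -> high, else low."""
    if len(values) < 2:
        raise ValidationError("need >= 2 patients to dichotomize")
    cutoff = float(values.mean())
    groups = pd.Series(
        np.where(values > cutoff, "high", "low"), index=values.index
    )
    if (groups == "high").sum() == 0 or (groups == "low").sum() == 0:
        raise DegenerateGroupingError(
            "mean-expression cutoff produced an empty group (constant values?)"
        )
    return SurvivalGrouping(groups=groups, cutoff_value=cutoff)


def pair_expression(expr: pd.DataFrame, lncrna_id: str, pcg_id: str) -> pd.Series:
    """Per-patient average expression of the ceRNA pair's two genes."""
    for gid in (lncrna_id, pcg_id):
        if gid not in expr.index:
            raise GeneLookupError(f"gene {gid!r} absent from expression matrix")
    return (expr.loc[lncrna_id] + expr.loc[pcg_id]) / 2.0


def _km_curve(times: np.ndarray, events: np.ndarray) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.sort(np.unique(times[events == 1]))
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(times >= t).sum() for t in event_times])
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk)


def km_logrank(
    clinical: ClinicalTable, grouping: SurvivalGrouping
) -> tuple[dict[str, KMCurve], LogRankResult]:
    """Kaplan-Meier curves per group and the two-group log-rank test
    (chi-square, 1 df, upper-tail p)."""
    clin = clinical.indexed()
    missing = grouping.groups.index.difference(clin.index)
    if len(missing):
        raise ValidationError(
            f"patients lack clinical data: {sorted(missing)[:5]}"
        )
    curves: dict[str, KMCurve] = {}
    arrays = {}
    for group in ("high", "low"):
        pts = grouping.patients(group)
        if not pts:
            raise DegenerateGroupingError(f"group {group!r} is empty")
        sub = clin.loc[pts]
        t = sub["time"].to_numpy(dtype=float)
        e = sub["event"].to_numpy(dtype=int)
        arrays[group] = (t, e)
        curves[group] = _km_curve(t, e)
    total_events = arrays["high"][1].sum() + arrays["low"][1].sum()
    if total_events == 0:
        raise UndefinedTestError("log-rank undefined with zero events")
    res = logrank_test(
        arrays["high"][0],
        arrays["low"][0],
        event_observed_A=arrays["high"][1],
        event_observed_B=arrays["low"][1],
    )
    lr = LogRankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        n_high=len(arrays["high"][0]),
        n_low=len(arrays["low"][0]),
        events_high=int(arrays["high"][1].sum()),
        events_low=int(arrays["low"][1].sum()),
    )
    return curves, lr


def survival_screen(
    targets,
    expr: pd.DataFrame,
    clinical: ClinicalTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen genes and ceRNA pairs for survival association.

    ``targets`` is an iterable of gene ids (strings) and/or
    ``(lncrna_id, pcg_id)`` tuples; ``expr`` is the per-patient tumor
    expression matrix (genes x patients). Each target is dichotomized at
    its mean and tested by log-rank; pair rows additionally carry
    ``pair_better``: the pair is significant while neither single gene
    is. Targets whose test is undefined are skipped and logged.
    """
    clin = clinical.indexed()
    common = expr.columns.intersection(clin.index)
    single_p: dict[str, float] = {}
    rows = []

    def _test(values: pd.Series) -> LogRankResult:
        grouping = dichotomize_by_mean(values.loc[common])
        _, lr = km_logrank(clinical, grouping)
        return lr

    gene_targets = [t for t in targets if isinstance(t, str)]
    pair_targets = [t for t in targets if not isinstance(t, str)]

    for gid in gene_targets:
        try:
            lr = _test(expr.loc[gid])
        except Exception as exc:  # noqa: BLE001 - per-target isolation
            logger.warning("skipping %s: %s", gid, exc)
            continue
        single_p[gid] = lr.p_value
        rows.append(
            {
                "target": gid,
                "kind": "gene",
                "statistic": lr.statistic,
                "p_value": lr.p_value,
                "significant": lr.p_value < alpha,
                "pair_better": False,
            }
        )

    for lnc, pcg in pair_targets:
        try:
            lr = _test(pair_expression(expr, lnc, pcg))
            for gid in (lnc, pcg):
                if gid not in single_p:
                    single_p[gid] = _test(expr.loc[gid]).p_value
        except Exception as exc:  # noqa: BLE001
            logger.warning("skipping pair (%s, %s): %s", lnc, pcg, exc)
            continue
        sig = lr.p_value < alpha
        rows.append(
            {
                "target": f"{lnc}|{pcg}",
                "kind": "pair",
                "statistic": lr.statistic,
                "p_value": lr.p_value,
                "significant": sig,
                "pair_better": bool(
                    sig and single_p[lnc] >= alpha and single_p[pcg] >= alpha
                ),
            }
        )

    return pd.DataFrame(
        rows,
        columns=["target", "kind", "statistic", "p_value", "significant", "pair_better"],
    )
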