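"""Signature-based two-group survival validation.

A gene signature (e.g. the SMGs specific to a distinguished patient group)
is evaluated on an independent expression cohort: patients are split into
two groups by K-means (K=2) on the per-gene standardized signature
expression, and the survival-time separation of the groups is tested with
the two-sample log-rank test and visualized with Kaplan-Meier curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalRecord:
    """Right-censored survival observation (time in years)."""

    patient_id: str
    time: float
    event: bool

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.patient_id}")


@dataclass
class SignatureSplit:
    """K=2 assignment of cohort patients by signature expression."""

    patient_ids: list[str]
    groups: np.ndarray  # 0/1 per patient
    genes_matched: list[str]
    genes_missing: list[str]
    group_names: dict[int, str]
    degenerate: bool = False


@dataclass
class LogRankResult:
    """Two-sample log-rank test summary (1 df)."""

    statistic: float
    p_value: float
    group_sizes: tuple[int, int]
    observed: tuple[float, float]
    expected: tuple[float, float]


@dataclass
class KMCurve:
    """Product-limit survival curve: step points starting at (0, 1)."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """Survival probability S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def read_survival_table(path) -> list[SurvivalRecord]:
    """Tab-delimited table: patient_id, time_years, event (0/1)."""
    table = pd.read_csv(path, sep="\t")
    table.columns = [c.lower() for c in table.columns]
    return [
        SurvivalRecord(
            patient_id=str(row["patient_id"]),
            time=float(row["time_years"]),
            event=bool(int(row["event"])),
        )
        for _, row in table.iterrows()
    ]


def split_by_signature(
    expr: ExpressionMatrix,
    signature: list[str],
    seed: int = 0,
    replicates: int = 50,
    records: list[SurvivalRecord] | None = None,
) -> SignatureSplit:
    """K-means (K=2) split of cohort patients on signature expression.

    Signature genes are matched (uppercase, exact) against the expression
    index; each matched gene's expression is standardized (z-score across
    patients) before clustering so the split is not dominated by
    high-variance genes. When survival records are supplied, the group with
    the longer median observed time is named "low-risk" — a labeling
    convention that never feeds back into the test.
    """
    wanted = {g.upper() for g in signature if g.strip()}
    if not wanted:
        raise ValueError("empty signature gene list")
    matched = [g for g in expr.genes if g in wanted]
    missing = sorted(wanted - set(matched))
    if not matched:
        raise ValueError(f"no signature gene matches the expression index; misses: {missing}")
    if missing:
        logger.info("signature: %d/%d genes missing from expression", len(missing), len(wanted))
    if len(expr.samples) < 4:
        raise ValueError("need at least 4 patients for a K=2 split")

    X = expr.data.loc[matched].to_numpy(dtype=float).T  # patients x genes
    sd = X.std(axis=0, ddof=0)
    degenerate = bool(np.all(sd == 0.0))
    if degenerate:
        logger.warning("all patients identical on the signature; degenerate split")
        return SignatureSplit(
            patient_ids=expr.samples,
            groups=np.zeros(len(expr.samples), dtype=int),
            genes_matched=matched,
            genes_missing=missing,
            group_names={0: "all"},
            degenerate=True,
        )
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    km = KMeans(n_clusters=2, n_init=replicates, init="random", algorithm="lloyd", random_state=seed).fit(Z)
    groups = km.labels_.astype(int)

    names = {0: "group-0", 1: "group-1"}
    if records is not None:
        by_id = {r.patient_id: r for r in records}
        medians = {}
        for g in (0, 1):
            times = [
                by_id[p].time
                for p, gg in zip(expr.samples, groups)
                if gg == g and p in by_id
            ]
            medians[g] = float(np.median(times)) if times else float("nan")
        if medians[0] >= medians[1]:
            names = {0: "low-risk", 1: "high-risk"}
        else:
            names = {0: "high-risk", 1: "low-risk"}
    return SignatureSplit(
        patient_ids=expr.samples,
        groups=groups,
        genes_matched=matched,
        genes_missing=missing,
        group_names=names,
    )


def _risk_table(times, events, groups):
    """At-risk/event counts per distinct event time; events precede
    censorings at tied times (standard convention)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups, dtype=int)
    event_times = np.unique(times[events])
    rows = []
    for t in event_times:
        at_risk = times >= t
        n1 = int(np.sum(at_risk & (groups == 0)))
        n2 = int(np.sum(at_risk & (groups == 1)))
        d1 = int(np.sum(events & (times == t) & (groups == 0)))
        d2 = int(np.sum(events & (times == t) & (groups == 1)))
        rows.append((t, n1, n2, d1, d2))
    return rows


def logrank_test(records: list[SurvivalRecord], split) -> LogRankResult:
    """Standard two-sample log-rank test.

    At each distinct event time the expected events per group are
    proportional to the at-risk counts; the statistic is (O1 - E1)^2 / V
    with the hypergeometric variance V, referred to chi-square with 1 df.
    """
    groups_by_id = _groups_from_split(split)
    usable = [r for r in records if r.patient_id in groups_by_id]
    if not usable:
        raise ValueError("no survival records join the group assignment")
    times = [r.time for r in usable]
    events = [r.event for r in usable]
    groups = [groups_by_id[r.patient_id] for r in usable]
    n1 = groups.count(0)
    n2 = groups.count(1)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if not any(events):
        raise ValueError("no events: log-rank test undefined")

    O1 = E1 = V = 0.0
    total_events = 0.0
    for _, r1, r2, d1, d2 in _risk_table(times, events, groups):
        n = r1 + r2
        d = d1 + d2
        O1 += d1
        E1 += d * r1 / n
        if n > 1:
            V += d * (r1 / n) * (r2 / n) * (n - d) / (n - 1)
        total_events += d
    if V == 0.0:
        stat, p = 0.0, 1.0
    else:
        stat = (O1 - E1) ** 2 / V
        p = float(stats.chi2.sf(stat, df=1))
    return LogRankResult(
        statistic=float(stat),
        p_value=p,
        group_sizes=(n1, n2),
        observed=(O1, total_events - O1),
        expected=(E1, total_events - E1),
    )


def _groups_from_split(split) -> dict[str, int]:
    if isinstance(split, SignatureSplit):
        if split.degenerate:
            raise ValueError("degenerate signature split: test not run")
        return dict(zip(split.patient_ids, (int(g) for g in split.groups)))
    if isinstance(split, dict):
        return {str(k): int(v) for k, v in split.items()}
    raise TypeError("split must be a SignatureSplit or a patient->group mapping")


def km_curve(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimator for one group.

    The curve starts at (0, 1); censored-only intervals leave it flat.
    """
    if not records:
        raise ValueError("empty group")
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=bool)
    event_times = np.unique(times[events])
    out_t = [0.0]
    out_s = [1.0]
    out_n = [len(records)]
    out_d = [0]
    s = 1.0
    for t in event_times:
        n = int(np.sum(times >= t))
        d = int(np.sum(events & (times == t)))
        s *= 1.0 - d / n
        out_t.append(float(t))
        out_s.append(s)
        out_n.append(n)
        out_d.append(d)
    return KMCurve(
        times=np.asarray(out_t),
        survival=np.asarray(out_s),
        n_at_risk=np.asarray(out_n),
        n_events=np.asarray(out_d),
    )


def km_curves_by_group(records: list[SurvivalRecord], split) -> dict[str, KMCurve]:
    """One KM curve per group of a split, keyed by group name."""
    groups_by_id = _groups_from_split(split)
    names = split.group_names if isinstance(split, SignatureSplit) else {0: "group-0", 1: "group-1"}
    curves = {}
    for g, name in names.items():
        members = [r for r in records if groups_by_id.get(r.patient_id) == g]
        if members:
            curves[name] = km_curve(members)
    return curves
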