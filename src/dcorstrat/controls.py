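"""Negative controls and clinical subtype enrichment.

Three controls probe whether dCor-based stratification is an artifact:
(i) raw gene-set overlap — the Jaccard matrix over SMG profiles, which on
real cohorts is overwhelmingly zero and cannot separate patients; (ii)
pseudo-SMGs — size-matched random gene sets run through the same workflow;
(iii) a structure-free background expression cohort (e.g. normal tissue)
substituted for the tumor cohort. Enrichment of hormone-receptor subtypes
(ER/PR/HER2, triple-negative) within each cluster is tested with per-cluster
2x2 chi-square tests against the rest of the cohort, family-wise adjusted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .stratify import ClusterAssignment
from .variant_io import SMGProfile

logger = logging.getLogger(__name__)

MARKERS = ("ER", "PR", "HER2", "TN")


@dataclass
class JaccardMatrix:
    """Pairwise SMG-list Jaccard indices with sparsity summary."""

    values: np.ndarray
    patient_ids: list[str]
    zero_fraction: float
    n_pairs: int


@dataclass(frozen=True)
class ClinicalRecord:
    """Hormone-receptor marker statuses for one patient.

    Statuses are 'positive' / 'negative' / 'unknown'. Triple-negative status
    is derived: True only when all three markers are known negative; None
    (unknown) when any marker is unknown and the knowns are all negative.
    """

    patient_id: str
    er_status: str = "unknown"
    pr_status: str = "unknown"
    her2_status: str = "unknown"

    @property
    def triple_negative(self) -> bool | None:
        statuses = (self.er_status, self.pr_status, self.her2_status)
        if any(s == "positive" for s in statuses):
            return False
        if all(s == "negative" for s in statuses):
            return True
        return None

    def marker_status(self, marker: str) -> bool | None:
        """True = marker-positive (TN: is triple-negative); None = unknown."""
        marker = marker.upper()
        if marker == "TN":
            return self.triple_negative
        attr = {"ER": self.er_status, "PR": self.pr_status, "HER2": self.her2_status}[marker]
        if attr == "positive":
            return True
        if attr == "negative":
            return False
        return None


@dataclass
class EnrichmentResult:
    """One cluster-vs-rest 2x2 test for one marker."""

    cluster: int
    marker: str
    table: np.ndarray  # [[cluster+, cluster-], [rest+, rest-]]
    statistic: float | None
    p_value: float | None
    adjusted_p: float | None
    method: str
    n_known: int
    suppressed: bool = False


def jaccard(A, B) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets give 0 with a warning (0/0)."""
    A, B = set(A), set(B)
    union = A | B
    if not union:
        warnings.warn("Jaccard of two empty sets is undefined (0/0); returning 0", stacklevel=2)
        return 0.0
    return len(A & B) / len(union)


def jaccard_matrix(profiles: list[SMGProfile]) -> JaccardMatrix:
    """All-pairs Jaccard over SMG profiles, plus the zero-pair fraction over
    the P(P-1)/2 unordered pairs (the overlap-sparsity summary)."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    P = len(profiles)
    values = np.zeros((P, P))
    gene_sets = [p.genes for p in profiles]
    for i, gs in enumerate(gene_sets):
        values[i, i] = 1.0 if gs else 0.0
    n_zero = 0
    for i, j in combinations(range(P), 2):
        a, b = gene_sets[i], gene_sets[j]
        union = len(a | b)
        v = len(a & b) / union if union else 0.0
        values[i, j] = values[j, i] = v
        if v == 0.0:
            n_zero += 1
    n_pairs = P * (P - 1) // 2
    return JaccardMatrix(
        values=values,
        patient_ids=[p.patient_id for p in profiles],
        zero_fraction=n_zero / n_pairs,
        n_pairs=n_pairs,
    )


def pseudo_smg_profiles(
    profiles: list[SMGProfile],
    universe: list[str],
    seed: int,
) -> list[SMGProfile]:
    """Size-matched random gene sets: for each patient, draw exactly n_a
    genes uniformly without replacement from the universe."""
    max_size = max((p.size for p in profiles), default=0)
    if len(universe) < max_size:
        raise ValueError(
            f"universe ({len(universe)} genes) smaller than the largest profile ({max_size})"
        )
    rng = np.random.default_rng(seed)
    universe = list(universe)
    out = []
    for p in profiles:
        draw = rng.choice(len(universe), size=p.size, replace=False)
        out.append(SMGProfile(patient_id=p.patient_id, genes=frozenset(universe[i] for i in draw)))
    return out


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for a 2x2 table.

    Returns (statistic, p). A table with a zero margin carries no contrast;
    by convention it returns (0, 1).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0 or n == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / margins
    return float(stat), float(stats.chi2.sf(stat, df=1))


def read_clinical(path) -> list[ClinicalRecord]:
    """Tab-delimited clinical table: patient_id, er_status, pr_status,
    her2_status (values positive/negative/unknown, case-insensitive)."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    table.columns = [c.lower() for c in table.columns]

    def norm(v: str) -> str:
        v = v.strip().lower()
        return v if v in ("positive", "negative") else "unknown"

    return [
        ClinicalRecord(
            patient_id=row["patient_id"],
            er_status=norm(row.get("er_status", "unknown")),
            pr_status=norm(row.get("pr_status", "unknown")),
            her2_status=norm(row.get("her2_status", "unknown")),
        )
        for _, row in table.iterrows()
    ]


def subtype_enrichment(
    assignment: ClusterAssignment,
    clinical: list[ClinicalRecord],
    marker: str = "ER",
    *,
    unknown_threshold: float = 0.25,
    min_expected: float = 5.0,
    adjustment: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Cluster-vs-rest marker enrichment, one 2x2 test per cluster.

    Patients with unknown status are excluded from the tables. When more
    than ``unknown_threshold`` of the clustered patients have unknown status
    the tests are suppressed and only counts reported — mirroring how HER2
    and triple-negative status are handled when too sparsely recorded.
    Pearson chi-square without continuity correction; Fisher's exact test
    when any expected cell falls below ``min_expected``. P-values are
    Bonferroni-adjusted across the K cluster-level tests.
    """
    marker = marker.upper()
    if marker not in MARKERS:
        raise ValueError(f"marker must be one of {MARKERS}")
    by_patient = {c.patient_id: c for c in clinical}
    status: dict[str, bool | None] = {}
    for pid in assignment.patient_ids:
        rec = by_patient.get(pid)
        status[pid] = rec.marker_status(marker) if rec is not None else None

    n_total = len(assignment.patient_ids)
    n_unknown = sum(1 for v in status.values() if v is None)
    suppressed = n_total > 0 and (n_unknown / n_total) > unknown_threshold
    if suppressed:
        logger.info(
            "%s: %.0f%% unknown status exceeds %.0f%% threshold; tests suppressed",
            marker,
            100 * n_unknown / n_total,
            100 * unknown_threshold,
        )

    clusters = sorted(set(int(l) for l in assignment.labels))
    results: list[EnrichmentResult] = []
    for k in clusters:
        in_pos = in_neg = out_pos = out_neg = 0
        for pid, label in zip(assignment.patient_ids, assignment.labels):
            s = status[pid]
            if s is None:
                continue
            if int(label) == k:
                in_pos += s
                in_neg += not s
            else:
                out_pos += s
                out_neg += not s
        table = np.array([[in_pos, in_neg], [out_pos, out_neg]], dtype=float)
        if suppressed:
            results.append(
                EnrichmentResult(
                    cluster=k, marker=marker, table=table, statistic=None,
                    p_value=None, adjusted_p=None, method="suppressed",
                    n_known=int(table.sum()), suppressed=True,
                )
            )
            continue
        n = table.sum()
        expected_ok = True
        if n > 0:
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
            expected_ok = (expected >= min_expected).all()
        if expected_ok:
            stat, p = chi_square_2x2(table)
            method = "chi-square"
        else:
            _, p = stats.fisher_exact(table.astype(int))
            stat, method = None, "fisher-exact"
        results.append(
            EnrichmentResult(
                cluster=k, marker=marker, table=table, statistic=stat,
                p_value=float(p), adjusted_p=None, method=method, n_known=int(n),
            )
        )

    if adjustment != "bonferroni":
        raise ValueError("only Bonferroni adjustment is supported")
    m = len([r for r in results if not r.suppressed])
    for r in results:
        if not r.suppressed:
            r.adjusted_p = float(min(1.0, m * r.p_value))
            r.method += "+bonferroni"
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tab-delimited-ready summary (cluster, totals, marker counts, p-values)."""
    rows = []
    for r in results:
        rows.append(
            {
                "cluster": r.cluster,
                "marker": r.marker,
                "n_known": r.n_known,
                "cluster_pos": int(r.table[0, 0]),
                "cluster_neg": int(r.table[0, 1]),
                "rest_pos": int(r.table[1, 0]),
                "rest_neg": int(r.table[1, 1]),
                "statistic": r.statistic,
                "raw_p": r.p_value,
                "adj_p": r.adjusted_p,
                "method": r.method,
            }
        )
    return pd.DataFrame(rows)


def distinguished_cluster(results: list[EnrichmentResult]) -> int | None:
    """The cluster with the smallest adjusted p — operational definition of
    the distinguished (subtype-enriched) group. None if all suppressed."""
    tested = [r for r in results if r.adjusted_p is not None]
    if not tested:
        return None
    return min(tested, key=lambda r: r.adjusted_p).cluster
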