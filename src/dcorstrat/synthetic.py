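"""Synthetic cohorts with planted functional structure.

The generator emulates the data-generating assumptions behind the workflow:
a handful of functional gene modules drive both expression covariance
(through per-patient latent module factors and a mean shift on each planted
group's driver module) and SMG membership (a fraction of each patient's
mutated genes is drawn from their group's driver module, the rest from
background genes). One distinguished planted group is enriched for
marker-negative clinical status and carries an elevated event hazard, so
every downstream stage — stratification, controls, enrichment, survival —
can be scored against known truth without any external data.

Expression is generated directly on a log-like scale (the workflow consumes
distances on log-scale expression, not counts); run the pipeline on emitted
files with transform "none".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .controls import ClinicalRecord
from .expression import ExpressionMatrix
from .stratify import ClusterAssignment
from .survival import SurvivalRecord
from .variant_io import QUALIFYING_CLASSES, VariantRecord

#: Deterministic ordering of qualifying classes for simulated variant rows.
_QUALIFYING = sorted(QUALIFYING_CLASSES)

#: Mean survival scale (years) for the baseline-hazard groups.
BASE_SURVIVAL_SCALE_YEARS = 5.0

#: Baseline log-scale expression level.
BASELINE_EXPRESSION = 5.0

#: Decoy non-qualifying variant rows added per patient to exercise filtering.
N_DECOY_SILENT = 3


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one simulated cohort.

    ``module_shift`` is the expression mean shift of a group's driver module
    in noise-SD units; ``driver_fraction`` is the share of a patient's SMGs
    drawn from their group's driver module; ``subtype_enrichment_prob`` is
    the probability a distinguished-group patient is marker-negative
    (background rate ``background_negative_prob``).
    """

    n_patients: int = 150
    n_genes: int = 400
    n_modules: int = 3
    module_size: int = 25
    n_planted_groups: int = 3
    module_shift: float = 2.0
    latent_factor_sd: float = 1.0
    noise_sd: float = 1.0
    smg_size_range: tuple[int, int] = (5, 20)
    driver_fraction: float = 0.6
    subtype_enrichment_prob: float = 0.6
    background_negative_prob: float = 0.2
    hazard_ratio: float = 2.5
    censoring_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("n_modules * module_size must not exceed n_genes")
        if self.n_planted_groups > self.n_modules:
            raise ValueError("n_planted_groups must not exceed n_modules")
        if not (0.0 <= self.driver_fraction <= 1.0):
            raise ValueError("driver_fraction must lie in [0, 1]")
        for name in ("subtype_enrichment_prob", "background_negative_prob", "censoring_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.latent_factor_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("latent_factor_sd and noise_sd must be positive")
        lo, hi = self.smg_size_range
        if not (1 <= lo <= hi):
            raise ValueError("smg_size_range must satisfy 1 <= lo <= hi")
        if round(hi * self.driver_fraction) > self.module_size:
            raise ValueError(
                "largest driver draw exceeds module_size "
                "(reduce smg_size_range max or driver_fraction)"
            )
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.n_patients < 2 * self.n_planted_groups:
            raise ValueError("too few patients for the planted groups")


@dataclass
class SyntheticTruth:
    """Ground truth for scoring only — never read by the pipeline."""

    group_of: dict[str, int]
    driver_genes: dict[int, list[str]]
    marker_negative_prob: dict[int, float]
    hazard_rate: dict[int, float]
    distinguished_group: int = 0


@dataclass
class SyntheticCohort:
    """All emitted tables for one simulated cohort, plus the truth."""

    config: SyntheticCohortConfig
    expression: ExpressionMatrix
    normal_expression: ExpressionMatrix
    variants: list[VariantRecord]
    clinical: list[ClinicalRecord]
    survival: list[SurvivalRecord]
    truth: SyntheticTruth
    maf_table: pd.DataFrame = field(repr=False, default=None)

    def write(self, outdir) -> dict[str, Path]:
        """Emit the file dialects the pipeline reads; byte-stable per seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "maf": outdir / "mutations.maf.tsv",
            "expression": outdir / "expression.tsv",
            "normal_expression": outdir / "expression_normal.tsv",
            "clinical": outdir / "clinical.tsv",
            "survival": outdir / "survival.tsv",
            "truth": outdir / "truth.json",
        }
        self.maf_table.to_csv(paths["maf"], sep="\t", index=False)
        self.expression.data.to_csv(
            paths["expression"], sep="\t", index_label="gene_id", float_format="%.6f"
        )
        self.normal_expression.data.to_csv(
            paths["normal_expression"], sep="\t", index_label="gene_id", float_format="%.6f"
        )
        pd.DataFrame(
            [
                {
                    "patient_id": c.patient_id,
                    "er_status": c.er_status,
                    "pr_status": c.pr_status,
                    "her2_status": c.her2_status,
                }
                for c in self.clinical
            ]
        ).to_csv(paths["clinical"], sep="\t", index=False)
        pd.DataFrame(
            [
                {"patient_id": r.patient_id, "time_years": f"{r.time:.6f}", "event": int(r.event)}
                for r in self.survival
            ]
        ).to_csv(paths["survival"], sep="\t", index=False)
        truth = asdict(self.truth)
        paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
        return paths


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Simulate one cohort under the configured study conditions.

    Expression for gene g in patient p is
    ``baseline + shift * [g in driver(group(p))] + lambda_{p,m(g)} + noise``
    where lambda_{p,m} ~ N(0, latent_factor_sd) is a per-patient factor
    shared by all genes of module m, creating within-module covariance
    across the cohort. The parallel normal-background table has the same
    genes and patients but no shift and no module factors — pure noise
    around baseline — for the structure-free background control.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    c = config

    patients = [f"P{i:04d}" for i in range(c.n_patients)]
    genes = [f"G{i:04d}" for i in range(c.n_genes)]
    groups = np.array([i % c.n_planted_groups for i in range(c.n_patients)])

    module_of = np.full(c.n_genes, -1)
    modules: list[list[int]] = []
    for m in range(c.n_modules):
        idx = list(range(m * c.module_size, (m + 1) * c.module_size))
        modules.append(idx)
        module_of[idx] = m
    background_idx = np.flatnonzero(module_of < 0)

    shift = c.module_shift * c.noise_sd
    lam = rng.normal(0.0, c.latent_factor_sd, size=(c.n_patients, c.n_modules))
    values = np.full((c.n_genes, c.n_patients), BASELINE_EXPRESSION)
    for m, idx in enumerate(modules):
        values[np.ix_(idx, range(c.n_patients))] += lam[:, m][None, :]
        if m < c.n_planted_groups:
            values[np.ix_(idx, np.flatnonzero(groups == m))] += shift
    values += rng.normal(0.0, c.noise_sd, size=values.shape)
    expression = ExpressionMatrix(
        data=pd.DataFrame(values, index=genes, columns=patients),
        transform_tag="synthetic-log-scale",
    )
    normal_values = BASELINE_EXPRESSION + rng.normal(0.0, c.noise_sd, size=values.shape)
    normal_expression = ExpressionMatrix(
        data=pd.DataFrame(normal_values, index=genes, columns=patients),
        transform_tag="synthetic-log-scale",
    )

    lo, hi = c.smg_size_range
    variants: list[VariantRecord] = []
    maf_rows = []
    for p, pid in enumerate(patients):
        size = int(rng.integers(lo, hi + 1))
        n_driver = int(round(c.driver_fraction * size))
        driver_pool = modules[groups[p]]
        chosen = list(rng.choice(driver_pool, size=n_driver, replace=False))
        chosen += list(rng.choice(background_idx, size=size - n_driver, replace=False))
        for g_idx in chosen:
            vc = _QUALIFYING[int(rng.integers(len(_QUALIFYING)))]
            variants.append(VariantRecord(pid, genes[g_idx], vc))
            maf_rows.append((genes[g_idx], vc, pid))
        decoys = rng.choice(c.n_genes, size=N_DECOY_SILENT, replace=False)
        for g_idx in decoys:
            variants.append(VariantRecord(pid, genes[g_idx], "Silent"))
            maf_rows.append((genes[g_idx], "Silent", pid))
    maf_table = pd.DataFrame(
        maf_rows, columns=["Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode"]
    )

    clinical: list[ClinicalRecord] = []
    for p, pid in enumerate(patients):
        p_neg = c.subtype_enrichment_prob if groups[p] == 0 else c.background_negative_prob
        statuses = ["negative" if rng.random() < p_neg else "positive" for _ in range(3)]
        clinical.append(
            ClinicalRecord(
                patient_id=pid,
                er_status=statuses[0],
                pr_status=statuses[1],
                her2_status=statuses[2],
            )
        )

    base_rate = 1.0 / BASE_SURVIVAL_SCALE_YEARS
    rates = np.where(groups == 0, base_rate * c.hazard_ratio, base_rate)
    event_times = rng.exponential(1.0 / rates)
    n_censored = int(round(c.censoring_fraction * c.n_patients))
    censored = np.zeros(c.n_patients, dtype=bool)
    censored[rng.choice(c.n_patients, size=n_censored, replace=False)] = True
    censor_u = rng.random(c.n_patients)
    survival = []
    for p, pid in enumerate(patients):
        if censored[p]:
            survival.append(SurvivalRecord(pid, float(event_times[p] * censor_u[p]), False))
        else:
            survival.append(SurvivalRecord(pid, float(event_times[p]), True))

    truth = SyntheticTruth(
        group_of={pid: int(g) for pid, g in zip(patients, groups)},
        driver_genes={
            m: [genes[i] for i in modules[m]] for m in range(c.n_planted_groups)
        },
        marker_negative_prob={
            g: (c.subtype_enrichment_prob if g == 0 else c.background_negative_prob)
            for g in range(c.n_planted_groups)
        },
        hazard_rate={g: float(base_rate * (c.hazard_ratio if g == 0 else 1.0))
                     for g in range(c.n_planted_groups)},
        distinguished_group=0,
    )
    return SyntheticCohort(
        config=config,
        expression=expression,
        normal_expression=normal_expression,
        variants=variants,
        clinical=clinical,
        survival=survival,
        truth=truth,
        maf_table=maf_table,
    )


def score_recovery(
    assignment: ClusterAssignment, truth: SyntheticTruth
) -> tuple[float, dict[int, int]]:
    """Adjusted Rand index between cluster labels and planted groups, plus
    the maximal-overlap cluster-to-group mapping (Hungarian assignment)."""
    if set(assignment.patient_ids) != set(truth.group_of):
        raise ValueError("cluster assignment and truth cover different patients")
    true_labels = np.array([truth.group_of[p] for p in assignment.patient_ids])
    pred = np.asarray(assignment.labels)
    ari = float(adjusted_rand_score(true_labels, pred))

    clusters = sorted(set(int(x) for x in pred))
    groups = sorted(set(int(x) for x in true_labels))
    overlap = np.zeros((len(clusters), len(groups)))
    for i, k in enumerate(clusters):
        for j, g in enumerate(groups):
            overlap[i, j] = np.sum((pred == k) & (true_labels == g))
    rows, cols = linear_sum_assignment(-overlap)
    mapping = {clusters[i]: groups[j] for i, j in zip(rows, cols)}
    return ari, mapping
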