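"""End-to-end workflow orchestration.

Stages run in the workflow's order: SMG profiles -> expression submatrices ->
pairwise dCor matrix -> dissimilarity -> MDS embedding -> K-means ->
silhouettes -> group gene sets -> negative controls -> subtype enrichment ->
optional signature survival validation. Every run writes a manifest with the
seed, input checksums and per-stage counts so reruns are auditable and, for
fixed seed and inputs, bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import controls, dcor, expression, stratify, survival, variant_io

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One run's inputs and knobs; every field maps to a CLI flag."""

    maf: str | None = None
    expression: str | None = None
    clinical: str | None = None
    survival: str | None = None
    signature: str | None = None
    normal_expression: str | None = None
    outdir: str = "dcorstrat_out"
    transform: str = "log2p1"
    patient_prefix_len: int = 12
    K: int = 3
    replicates: int = 50
    seed: int = 0
    k_range: tuple[int, int] = (2, 8)
    cluster_features: str = "dissimilarity"  # or "mds"
    markers: tuple[str, ...] = ("ER", "PR", "HER2", "TN")
    enrichment_marker: str = "ER"
    unknown_threshold: float = 0.25
    control_jaccard: bool = True
    control_pseudo_smg: bool = True
    control_normal_background: bool = True

    def validate(self) -> None:
        for name in ("maf", "expression"):
            p = getattr(self, name)
            if p is None:
                raise ValueError(f"RunConfig.{name} is required")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        for name in ("clinical", "survival", "signature", "normal_expression"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.K < 2:
            raise ValueError("K must be >= 2 for clustering stages")
        if self.cluster_features not in ("dissimilarity", "mds"):
            raise ValueError("cluster_features must be 'dissimilarity' or 'mds'")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _features(diss, embedding, which):
    return diss if which == "dissimilarity" else embedding


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the manifest dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "dcorstrat",
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "inputs": {},
        "stages": {},
    }
    for name in ("maf", "expression", "clinical", "survival", "signature", "normal_expression"):
        p = getattr(config, name)
        if p is not None:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    stage = "start"
    try:
        stage = "smg"
        t0 = time.perf_counter()
        parsed = variant_io.read_maf(config.maf, patient_prefix_len=config.patient_prefix_len)
        profiles = variant_io.build_smg_profiles(parsed.records)
        variant_io.profiles_to_table(profiles).to_csv(outdir / "smg_profiles.tsv", sep="\t", index=False)
        roster = {
            "n_patients": len(profiles),
            "n_empty_profiles": sum(1 for p in profiles.values() if p.size == 0),
            "n_maf_rows": parsed.n_rows,
            "n_maf_rows_skipped": parsed.n_skipped,
        }
        (outdir / "roster.json").write_text(json.dumps(roster, indent=1, sort_keys=True) + "\n")
        manifest["stages"]["smg"] = {**roster, "seconds": round(time.perf_counter() - t0, 3)}

        stage = "expression"
        t0 = time.perf_counter()
        expr = expression.read_expression_table(config.expression, transform=config.transform)
        manifest["stages"]["expression"] = {
            "n_genes": len(expr.genes),
            "n_samples": expr.n_samples,
            "transform": expr.transform_tag,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "dcor"
        t0 = time.perf_counter()
        usable_profiles = sorted(
            (p for p in profiles.values() if p.size > 0), key=lambda p: p.patient_id
        )
        D = dcor.dcor_matrix(usable_profiles, expr)
        D.to_frame().to_csv(outdir / "dcor_matrix.tsv", sep="\t", float_format="%.10f")
        pd.DataFrame(
            sorted(D.degenerate_flags.items()), columns=["patient_id", "degenerate"]
        ).to_csv(outdir / "degenerate_flags.tsv", sep="\t", index=False)
        manifest["stages"]["dcor"] = {
            "n_patients": D.n_patients,
            "n_degenerate": sum(D.degenerate_flags.values()),
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "mds"
        t0 = time.perf_counter()
        diss = stratify.to_dissimilarity(D)
        embedding = stratify.classical_mds(diss, k=3)
        pd.DataFrame(
            embedding.coordinates,
            index=embedding.patient_ids,
            columns=[f"dim{j + 1}" for j in range(embedding.coordinates.shape[1])],
        ).to_csv(outdir / "mds_coordinates.tsv", sep="\t", index_label="patient_id", float_format="%.10f")
        manifest["stages"]["mds"] = {
            "retained_dims": embedding.retained_dims,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "cluster"
        t0 = time.perf_counter()
        feats = _features(diss, embedding, config.cluster_features)
        assign = stratify.kmeans_cluster(
            feats, config.K, replicates=config.replicates, seed=config.seed
        )
        s_values, s_mean = stratify.silhouette_profile(feats, assign)
        pd.DataFrame(
            {"patient_id": assign.patient_ids, "cluster": assign.labels, "silhouette": s_values}
        ).to_csv(outdir / "cluster_labels.tsv", sep="\t", index=False, float_format="%.6f")
        lo, hi = config.k_range
        by_k = stratify.silhouette_by_k(
            feats, range(lo, min(hi, len(assign.patient_ids) - 1) + 1),
            replicates=config.replicates, seed=config.seed,
        )
        pd.DataFrame(sorted(by_k.items()), columns=["K", "mean_silhouette"]).to_csv(
            outdir / "silhouette_by_k.tsv", sep="\t", index=False, float_format="%.6f"
        )
        manifest["stages"]["cluster"] = {
            "K": config.K,
            "within_ss": assign.within_ss,
            "mean_silhouette": s_mean,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "group_genes"
        gsets = stratify.group_specific_genes(assign, profiles)
        for k in sorted(gsets.unions):
            (outdir / f"cluster{k}_union_genes.txt").write_text(
                "\n".join(sorted(gsets.unions[k])) + "\n"
            )
            (outdir / f"cluster{k}_specific_genes.txt").write_text(
                "\n".join(sorted(gsets.specific[k])) + "\n"
            )
        manifest["stages"]["group_genes"] = {
            f"cluster{k}": {"union": len(gsets.unions[k]), "specific": len(gsets.specific[k])}
            for k in sorted(gsets.unions)
        }

        stage = "controls"
        t0 = time.perf_counter()
        control_info: dict = {}
        if config.control_jaccard:
            jm = controls.jaccard_matrix(usable_profiles)
            summary = {"n_pairs": jm.n_pairs, "zero_fraction": jm.zero_fraction}
            (outdir / "jaccard_summary.json").write_text(json.dumps(summary, indent=1) + "\n")
            control_info["jaccard"] = summary
        else:
            control_info["jaccard"] = "skipped"
        if config.control_pseudo_smg:
            pseudo = controls.pseudo_smg_profiles(usable_profiles, expr.genes, seed=config.seed)
            Dp = dcor.dcor_matrix(pseudo, expr)
            ap = stratify.kmeans_cluster(
                stratify.to_dissimilarity(Dp), config.K,
                replicates=config.replicates, seed=config.seed,
            )
            pd.DataFrame({"patient_id": ap.patient_ids, "cluster": ap.labels}).to_csv(
                outdir / "pseudo_smg_clusters.tsv", sep="\t", index=False
            )
            control_info["pseudo_smg"] = {"K": config.K, "n_patients": len(ap.patient_ids)}
        else:
            control_info["pseudo_smg"] = "skipped"
        if config.control_normal_background and config.normal_expression is not None:
            nexpr = expression.read_expression_table(
                config.normal_expression, transform=config.transform
            )
            Dn = dcor.dcor_matrix(usable_profiles, nexpr)
            an = stratify.kmeans_cluster(
                stratify.to_dissimilarity(Dn), config.K,
                replicates=config.replicates, seed=config.seed,
            )
            pd.DataFrame({"patient_id": an.patient_ids, "cluster": an.labels}).to_csv(
                outdir / "normal_background_clusters.tsv", sep="\t", index=False
            )
            control_info["normal_background"] = {"K": config.K, "n_patients": len(an.patient_ids)}
        else:
            control_info["normal_background"] = "skipped"
        control_info["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"]["controls"] = control_info

        stage = "enrichment"
        if config.clinical is not None:
            clin = controls.read_clinical(config.clinical)
            frames = []
            for marker in config.markers:
                res = controls.subtype_enrichment(
                    assign, clin, marker, unknown_threshold=config.unknown_threshold
                )
                frames.append(controls.enrichment_table(res))
            pd.concat(frames, ignore_index=True).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
            )
            primary = controls.subtype_enrichment(
                assign, clin, config.enrichment_marker,
                unknown_threshold=config.unknown_threshold,
            )
            manifest["stages"]["enrichment"] = {
                "markers": list(config.markers),
                "distinguished_cluster": controls.distinguished_cluster(primary),
            }
        else:
            manifest["stages"]["enrichment"] = "skipped"

        stage = "survival"
        if config.survival is not None and config.signature is not None:
            recs = survival.read_survival_table(config.survival)
            signature = [
                line.strip()
                for line in Path(config.signature).read_text().splitlines()
                if line.strip()
            ]
            split = survival.split_by_signature(
                expr, signature, seed=config.seed,
                replicates=config.replicates, records=recs,
            )
            if split.degenerate:
                manifest["stages"]["survival"] = {"degenerate": True}
            else:
                lr = survival.logrank_test(recs, split)
                curves = survival.km_curves_by_group(recs, split)
                for name, curve in curves.items():
                    pd.DataFrame(
                        {
                            "time": curve.times,
                            "survival": curve.survival,
                            "n_at_risk": curve.n_at_risk,
                            "n_events": curve.n_events,
                        }
                    ).to_csv(outdir / f"km_{name}.tsv", sep="\t", index=False, float_format="%.6f")
                summary = {
                    "statistic": lr.statistic,
                    "p_value": lr.p_value,
                    "group_sizes": list(lr.group_sizes),
                    "observed": list(lr.observed),
                    "expected": list(lr.expected),
                    "group_names": split.group_names,
                }
                (outdir / "logrank.json").write_text(json.dumps(summary, indent=1) + "\n")
                manifest["stages"]["survival"] = summary
        else:
            manifest["stages"]["survival"] = "skipped"
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(_dumps(manifest))
        (outdir / "PARTIAL").write_text(f"pipeline aborted in stage: {stage}\n")
        raise

    (outdir / "manifest.json").write_text(_dumps(manifest))
    return manifest


def _dumps(obj) -> str:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, Path):
            return str(o)
        raise TypeError(type(o))

    return json.dumps(obj, indent=1, sort_keys=True, default=default) + "\n"
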