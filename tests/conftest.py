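import numpy as np
import pandas as pd
import pytest

from dcorstrat import dcor, stratify, synthetic, variant_io


@pytest.fixture
def tiny_maf(tmp_path):
    """Two qualifying and one silent call across two patients."""
    path = tmp_path / "tiny.maf"
    path.write_text(
        "Hugo_Symbol\tVariant_Classification\tTumor_Sample_Barcode\tExtra\n"
        "TP53\tNonsense_Mutation\tTCGA-AA-0001-01A-11D\tx\n"
        "BRCA1\tSplice_Site\tTCGA-AA-0001-01A-11D\tx\n"
        "GATA3\tSilent\tTCGA-AA-0002-01A-11D\tx\n"
    )
    return path


@pytest.fixture
def small_expr_frame():
    """3 genes x 4 samples, small integers for hand-checkable arithmetic."""
    return pd.DataFrame(
        [[0.0, 1.0, 2.0, 3.0], [1.0, 1.0, 1.0, 1.0], [3.0, 0.0, 2.0, 1.0]],
        index=["G1", "G2", "G3"],
        columns=["S1", "S2", "S3", "S4"],
    )


@pytest.fixture
def small_expr_file(tmp_path, small_expr_frame):
    path = tmp_path / "expr.tsv"
    small_expr_frame.to_csv(path, sep="\t", index_label="gene_id")
    return path


@pytest.fixture(scope="session")
def strong_cohort():
    """One synthetic cohort under the default (strong-signal) conditions."""
    return synthetic.generate_cohort(synthetic.SyntheticCohortConfig(seed=0))


def cluster_cohort(cohort, K=3, seed=0, expression=None, profiles=None, replicates=50):
    """Profiles -> dCor -> dissimilarity -> K-means on one synthetic cohort."""
    if profiles is None:
        built = variant_io.build_smg_profiles(cohort.variants)
        profiles = sorted(
            (p for p in built.values() if p.size > 0), key=lambda p: p.patient_id
        )
    expr = expression if expression is not None else cohort.expression
    D = dcor.dcor_matrix(profiles, expr)
    diss = stratify.to_dissimilarity(D)
    return stratify.kmeans_cluster(diss, K, replicates=replicates, seed=seed), profiles
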