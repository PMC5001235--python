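"""Optional figures (requires matplotlib, installed via the ``plot`` extra)."""

from __future__ import annotations

from .stratify import ClusterAssignment, MDSEmbedding
from .survival import KMCurve


def mds_scatter(embedding: MDSEmbedding, assignment: ClusterAssignment | None = None, path=None):
    """3-D (or 2-D) scatter of the MDS embedding, colored by cluster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = embedding.coordinates
    colors = None
    if assignment is not None:
        order = {p: i for i, p in enumerate(assignment.patient_ids)}
        colors = [assignment.labels[order[p]] for p in embedding.patient_ids]
    fig = plt.figure(figsize=(6, 5))
    if coords.shape[1] >= 3:
        ax = fig.add_subplot(projection="3d")
        sc = ax.scatter(coords[:, 0], coords[:, 1], coords[:, 2], c=colors, cmap="tab10", s=15)
        ax.set_zlabel("MDS 3")
    else:
        ax = fig.add_subplot()
        sc = ax.scatter(coords[:, 0], coords[:, 1] if coords.shape[1] > 1 else 0 * coords[:, 0],
                        c=colors, cmap="tab10", s=15)
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    if colors is not None:
        fig.colorbar(sc, ax=ax, label="cluster")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def km_plot(curves: dict[str, KMCurve], path=None):
    """Step-function Kaplan-Meier curves, one per group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, curve in curves.items():
        ax.step(curve.times, curve.survival, where="post", label=name)
    ax.set_xlabel("time (years)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
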