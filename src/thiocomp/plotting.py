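"""Optional figures (requires matplotlib, installed via the ``plot`` extra)."""

from __future__ import annotations

from .contig_stats import ContigStat
from .recruitment import RecruitmentProfile


def plot_recruitment(profile: RecruitmentProfile, path) -> None:
    """Identity-vs-coverage bar chart of a recruitment profile."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    centers = (profile.bin_edges[:-1] + profile.bin_edges[1:]) / 2
    ax.bar(centers, profile.coverage, width=0.9, color="#356a9c")
    ax.set_xlabel("nucleotide identity of best alignment (%)")
    ax.set_ylabel("reference coverage (aligned bp / genome bp)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_contig_stats(stats: list[ContigStat], path) -> None:
    """Contig length vs coverage scatter, colored by best-hit E-value class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"<1e-100": "#1b7837", "<1e-50": "#7fbf7b", "<1e-10": "#d9f0d3", "none": "#bbbbbb"}
    fig, ax = plt.subplots(figsize=(6, 5))
    for cls, color in colors.items():
        xs = [s.length for s in stats if s.evalue_class == cls and s.coverage is not None]
        ys = [s.coverage for s in stats if s.evalue_class == cls and s.coverage is not None]
        ax.scatter(xs, ys, s=18, c=color, label=cls, edgecolors="k", linewidths=0.3)
    ax.set_xscale("log")
    ax.set_xlabel("contig length (bp)")
    ax.set_ylabel("fold coverage")
    ax.legend(title="best hit E", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
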