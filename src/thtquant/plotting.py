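"""Box-plot figure for a two-condition comparison.

Boxes span the 25th-75th percentile, the inner line is the median, and the
whiskers mark the 10th and 90th percentile — the same five numbers the
comparison CSV stores.
"""

from __future__ import annotations

from pathlib import Path

from .stats import ComparisonResult


def plot_comparison(result: ComparisonResult, path: str | Path) -> None:
    """Render the percentile box plot of both groups to SVG or PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.2, 4.0))
    stats = []
    for label, (p10, p25, p50, p75, p90), n in (
        (result.group_a, result.percentiles_a, result.n_a),
        (result.group_b, result.percentiles_b, result.n_b),
    ):
        stats.append(
            {
                "label": f"{label}\n(n={n})",
                "whislo": p10,
                "q1": p25,
                "med": p50,
                "q3": p75,
                "whishi": p90,
                "fliers": [],
            }
        )
    ax.bxp(stats, showfliers=False)
    ax.set_ylabel("cell mean fluorescence intensity (a.u.)")
    ax.set_title(f"FC = {result.fc:.3f}, P {result.display_p()}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
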