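"""Optional figure output mirroring the standard group-comparison panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import GroupReport

__all__ = ["save_report_figures"]


def save_report_figures(report: GroupReport, out_dir: str | Path) -> list[Path]:
    """Write histogram, box-plot and spectrum figures for a group report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    la, lb = report.labels
    paths = []

    fig, ax = plt.subplots(figsize=(6, 4))
    edges = report.histogram.bin_edges
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = np.diff(edges)
    for label, color in ((la, "tab:blue"), (lb, "tab:orange")):
        ax.bar(centers, report.histogram.counts[label], width=width,
               alpha=0.5, label=label, color=color)
    ax.set_xlabel(f"RER ({report.rate_unit})")
    ax.set_ylabel("count")
    ax.legend()
    p = out_dir / "histogram.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(4, 4))
    stats_list = []
    for label in (la, lb):
        s = report.summaries[label]
        stats_list.append({
            "label": label, "med": s.median, "q1": s.q1, "q3": s.q3,
            "whislo": max(s.min, s.fences[0]), "whishi": min(s.max, s.fences[1]),
            "fliers": np.asarray(s.outliers),
        })
    ax.bxp(stats_list)
    ax.set_ylabel(f"RER ({report.rate_unit})")
    p = out_dir / "boxplot.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, color in ((la, "tab:blue"), (lb, "tab:orange")):
        spectra = report.spectra[label]
        mean_amp = np.mean([s.amplitude for s in spectra], axis=0)
        ax.plot(spectra[0].freqs_hz, mean_amp, label=label, color=color)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel(f"amplitude ({report.rate_unit})")
    ax.legend()
    p = out_dir / "spectrum.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths
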