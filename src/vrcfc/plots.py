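"""Small summary plots for pipeline reports.

Boxplots follow the convention used throughout the analysis: the box
spans the interquartile range with a median line, whiskers extend to
1.5 x IQR, and points beyond are outliers.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["paired_freezing_plot", "width_boxplot"]


def paired_freezing_plot(
    table: pd.DataFrame, day: str, metric: str, path: str | Path
) -> None:
    """Per-mouse paired freezing in the neutral vs shock-paired context."""
    sub = table[(table["day"] == day) & (table["metric"] == metric)]
    wide = sub.pivot(index="mouse_id", columns="vr_context",
                     values="freezing_pct")
    fig, ax = plt.subplots(figsize=(3.2, 3.6))
    for _, row in wide.iterrows():
        ax.plot([0, 1], [row.get("neutral"), row.get("cfc")],
                color="0.6", marker="o", markersize=3, lw=0.8)
    ax.set_xticks([0, 1], ["neutral", "shock-paired"])
    ax.set_ylabel(f"{metric} freezing (%)")
    ax.set_title(day)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def width_boxplot(
    fields_a: pd.DataFrame, fields_b: pd.DataFrame, path: str | Path,
    labels: tuple[str, str] = ("session A", "session B"),
) -> None:
    """Place-field width distributions for two analysed sessions."""
    fig, ax = plt.subplots(figsize=(3.2, 3.6))
    ax.boxplot(
        [fields_a["width"].dropna(), fields_b["width"].dropna()],
        tick_labels=list(labels), whis=1.5,
    )
    ax.set_ylabel("place-field width (cm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
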