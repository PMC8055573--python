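"""Plot hooks (optional; require matplotlib).

Two panels mirror the pipeline's headline figures: the Wald-p-vs-cutoff
curve of the scan, and Kaplan-Meier curves for the high/low HI groups.
"""
from __future__ import annotations

import pandas as pd


def _plt():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires the 'plot' extra (matplotlib)") from exc
    return plt


def plot_cutoff_scan(scan_table: pd.DataFrame, selected: float | None = None, path: str | None = None):
    """p-value versus candidate cutoff, admissible candidates only."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ok = scan_table[scan_table["admissible"] & scan_table["p"].notna()]
    ax.plot(ok["candidate"], ok["p"], lw=1.2, color="tab:blue")
    ax.set_yscale("log")
    if selected is not None:
        ax.axvline(selected, color="tab:red", ls="--", lw=1)
    ax.set_xlabel("HI cutoff")
    ax.set_ylabel("Wald p")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_km(curves: pd.DataFrame, endpoint: str = "MACE", path: str | None = None):
    """Stepwise survival curves per group for one endpoint."""
    plt = _plt()
    sub = curves[curves["endpoint"] == endpoint] if "endpoint" in curves else curves
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for g, gc in sub.groupby("group"):
        ax.step(gc["time"], gc["survival"], where="post", label=str(g))
    ax.set_xlabel("months")
    ax.set_ylabel("event-free probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
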