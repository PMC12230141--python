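"""Bland-Altman panels for the agreement report."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["bland_altman_panel", "bland_altman_panels"]


def bland_altman_panel(ax, x, y, stats_row) -> None:
    """One difference-vs-mean panel with bias, limits and their CI bands."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    mean, diff = (x[mask] + y[mask]) / 2.0, x[mask] - y[mask]
    ax.scatter(mean, diff, s=18, facecolors="none", edgecolors="k")
    for key, style in (("bias", "--"), ("loa_lower", "-."), ("loa_upper", "-.")):
        val = stats_row.get(key)
        if val is None or not np.isfinite(val):
            continue
        ax.axhline(val, linestyle=style, color="C0")
        lo = stats_row.get(f"{key}_ci_lower" if key != "bias" else "bias_ci_lower")
        hi = stats_row.get(f"{key}_ci_upper" if key != "bias" else "bias_ci_upper")
        if lo is not None and hi is not None and np.isfinite(lo) and np.isfinite(hi):
            ax.axhspan(lo, hi, color="C0", alpha=0.12)
    ax.set_xlabel("mean of methods (dB SNR)")
    ax.set_ylabel("difference (dB SNR)")


def bland_altman_panels(thresholds: pd.DataFrame, agreement: pd.DataFrame,
                        out_path: Union[str, Path]) -> Path:
    """Grid of panels (comparison x frequency) mirroring the agreement table."""
    rows = agreement.dropna(subset=["bias"]) if "bias" in agreement else agreement.iloc[:0]
    n = max(len(rows), 1)
    ncols = min(n, 3)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4.2 * ncols, 3.2 * nrows),
                             squeeze=False)
    flat = axes.ravel()
    for ax in flat[len(rows):]:
        ax.set_visible(False)
    for ax, (_, row) in zip(flat, rows.iterrows()):
        pairs = _pair_values(thresholds, row)
        bland_altman_panel(ax, pairs[0], pairs[1], row)
        ax.set_title(f"{row.comparison} @ {row.frequency_hz/1000:g} kHz", fontsize=9)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def _pair_values(thresholds: pd.DataFrame, row) -> tuple:
    parts = row.comparison.split("_vs_") if "_vs_" in row.comparison else None
    f = row.frequency_hz

    def series(method, rep):
        sel = thresholds[(thresholds.frequency_hz == f) & (thresholds.method == method)
                         & (thresholds.repetition == rep)]
        return sel.sort_values(["participant", "channel"]).threshold_db_snr.to_numpy(float)

    if parts:
        rep_of = {"bsa": "1+2", "rms": 1, "bootstrap": 1}
        a = series(parts[0], rep_of[parts[0]])
        b = series(parts[1], rep_of[parts[1]])
    else:
        method = row.comparison.replace("_repeatability", "")
        a, b = series(method, 1), series(method, 2)
    m = min(len(a), len(b))
    return a[:m], b[:m]
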