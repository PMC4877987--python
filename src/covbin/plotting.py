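"""The two-dimensional coverage plot used to inspect and draw bins.

Scaffolds are points at (log10 coverage sample 1, log10 coverage sample
2); point area scales with the square root of scaffold length, scaffolds
below 10 kb are omitted by default, bins are colored, and a diagonal
marks stable coverage between the two samples.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .binning import GenomeBin  # noqa: E402
from .coverage import log10_coverage  # noqa: E402


def plot_coverage(profiles: pd.DataFrame,
                  bins: Sequence[GenomeBin],
                  sample_pair: tuple[str, str],
                  out: str | Path,
                  min_len: int = 10_000,
                  scale: str = "sqrt_length") -> Path:
    """Write the coverage scatter to ``out``; returns the path."""
    sel = profiles[profiles["length"] >= min_len]
    x = log10_coverage(sel[f"cov_{sample_pair[0]}"])
    y = log10_coverage(sel[f"cov_{sample_pair[1]}"])
    if scale == "sqrt_length":
        sizes = np.sqrt(sel["length"].to_numpy(dtype=float)) / 3.0
    else:
        sizes = np.full(len(sel), 20.0)
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.scatter(x, y, s=sizes, c="lightgray", edgecolors="none",
               label=f"unbinned (n={len(sel)})")
    cmap = plt.get_cmap("tab10")
    for i, b in enumerate(bins):
        m = sel.index.isin(b.scaffold_ids)
        if m.any():
            ax.scatter(np.asarray(x)[m], np.asarray(y)[m],
                       s=np.asarray(sizes)[m], color=cmap(i % 10),
                       edgecolors="none", label=b.bin_id)
    lo = min(float(np.min(x)), float(np.min(y))) - 0.2
    hi = max(float(np.max(x)), float(np.max(y))) + 0.2
    ax.plot([lo, hi], [lo, hi], color="blue", lw=0.8, alpha=0.6)
    ax.set_xlabel(f"log10 coverage, {sample_pair[0]}")
    ax.set_ylabel(f"log10 coverage, {sample_pair[1]}")
    ax.set_title(f"Differential coverage (scaffolds >= {min_len:,} bp)")
    ax.legend(loc="best", fontsize=8)
    out = Path(out)
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out
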