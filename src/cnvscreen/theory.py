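"""Closed-form power model for read-depth CNV detection.

Sequencing is modeled as drawing n reads uniformly from a mappable genome
of length lg; the number landing in a target region of length lc is then
binomial with p = lc/lg, mean μ = np and variance σ² = np(1 − p).  For a
single-copy gain or loss the expected region count shifts to δ = n(p ± p/2),
giving the detection Z-score

    Z² = (δ − μ)² / σ² = n p / (4 (1 − p)) = n lc / (4 (lg − lc)),

identical for gain and loss.  Solving for n yields the minimal read count
to reach a desired Z, and solving for lc the minimal detectable CNV length
at a given depth.  The model ignores overdispersion, mappability loss and
GC effects, so real requirements are somewhat higher; it is a lower bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: hg19-scale genome length (bp) used by default for lg.
DEFAULT_GENOME_LENGTH = 3.1e9


def _check(lc: float, lg: float) -> None:
    if lc <= 0 or lg <= 0:
        raise ValueError("lengths must be positive")
    if lc >= lg:
        raise ValueError("CNV length must be smaller than the genome length")


@dataclass(frozen=True)
class MinReads:
    """Exact and integer-rounded minimal read count."""

    exact: float
    ceiling: int


def zscore_for_reads(n: float, lc: float, lg: float = DEFAULT_GENOME_LENGTH) -> float:
    """Z-score of a single-copy CNV of length ``lc`` at ``n`` reads."""
    _check(lc, lg)
    if n <= 0:
        raise ValueError("read count must be positive")
    return math.sqrt(n * lc / (4.0 * (lg - lc)))


def min_reads(z: float, lc: float, lg: float = DEFAULT_GENOME_LENGTH) -> MinReads:
    """Minimal reads for a single-copy CNV of length ``lc`` at Z-score ``z``."""
    _check(lc, lg)
    if z <= 0:
        raise ValueError("Z must be positive")
    n = 4.0 * z * z * (lg - lc) / lc
    return MinReads(exact=n, ceiling=int(math.ceil(n)))


def min_length(z: float, n: float, lg: float = DEFAULT_GENOME_LENGTH) -> float:
    """Minimal detectable CNV length at ``n`` reads and Z-score ``z``.

    Algebraic inverse of :func:`min_reads`: lc = 4 Z² lg / (n + 4 Z²).
    """
    if lg <= 0 or n <= 0 or z <= 0:
        raise ValueError("inputs must be positive")
    return 4.0 * z * z * lg / (n + 4.0 * z * z)


def theory_table(
    z_values,
    lc_values,
    lg: float = DEFAULT_GENOME_LENGTH,
) -> pd.DataFrame:
    """Minimal read count over a (Z, CNV length) grid.

    Long format with columns ``z``, ``cnv_length``, ``min_reads``; for each
    Z the required read count decreases monotonically with CNV length.
    """
    rows = [
        {"z": float(z), "cnv_length": float(lc), "min_reads": min_reads(z, lc, lg).exact}
        for z in np.asarray(z_values, dtype=float)
        for lc in np.asarray(lc_values, dtype=float)
    ]
    return pd.DataFrame(rows)


def plot_theory_curves(table: pd.DataFrame, path) -> None:
    """Minimal-read-count curves, one line per Z-score."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for z, sub in table.groupby("z"):
        ax.plot(sub["cnv_length"] / 1e3, sub["min_reads"] / 1e6, label=f"Z = {z:g}")
    ax.set_xlabel("CNV length (kb)")
    ax.set_ylabel("minimal read count (millions)")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
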