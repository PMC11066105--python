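"""Cell-cycle phase classification from integrated DNA-stain intensity.

A nucleus in G1 carries one genome copy, in G2 two; integrated DNA-stain
(e.g. DAPI) intensity is therefore bimodal at roughly 1x and 2x a
reference value. The G1 reference is located as the mode of a kernel-
density estimate over all nuclei in an analysis batch (a plate or cell
line, never a single treatment condition, so that treatment-induced
arrest cannot move the reference). Phases are assigned by multiplicative
windows around that peak; everything between the G1 and G2 windows is S,
everything outside is left unclassified. Classification is scale
invariant: staining gain cancels out.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .stats import fit_dose_responses, pool_by_condition

__all__ = [
    "PHASES",
    "classify_phases",
    "g2_g1_ratio",
    "phase_stratified_response",
]

PHASES = ("G1", "S", "G2")
UNCLASSIFIED = "unclassified"


def classify_phases(
    integrated_dna,
    g1_window: tuple[float, float] = (0.75, 1.25),
    g2_window: tuple[float, float] = (1.75, 2.5),
    min_cells: int = 50,
) -> np.ndarray:
    """Assign G1/S/G2/unclassified per nucleus from integrated DNA intensity.

    Batches smaller than ``min_cells`` or with degenerate (all-equal)
    intensities are returned entirely unclassified — the KDE mode is not
    trustworthy there.
    """
    x = np.asarray(integrated_dna, dtype=float)
    labels = np.full(x.shape, UNCLASSIFIED, dtype=object)
    finite = np.isfinite(x) & (x > 0)
    if finite.sum() < min_cells or np.ptp(x[finite]) == 0:
        return labels
    xs = x[finite]
    kde = gaussian_kde(xs)
    grid = np.linspace(xs.min(), xs.max(), 512)
    peak = float(grid[np.argmax(kde(grid))])
    rel = x / peak
    g1 = finite & (rel >= g1_window[0]) & (rel <= g1_window[1])
    g2 = finite & (rel >= g2_window[0]) & (rel <= g2_window[1])
    s = finite & (rel > g1_window[1]) & (rel < g2_window[0])
    labels[g1] = "G1"
    labels[s] = "S"
    labels[g2] = "G2"
    return labels


def g2_g1_ratio(labels) -> float:
    """count(G2) / count(G1); raises when no G1 cells are present."""
    labels = np.asarray(labels, dtype=object)
    n_g1 = int((labels == "G1").sum())
    if n_g1 == 0:
        raise ValueError("no G1 cells: G2/G1 ratio undefined")
    return float((labels == "G2").sum()) / n_g1


def phase_stratified_response(
    nucleus_df: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dose-response fits per cell-cycle phase plus the overall fit.

    ``nucleus_df`` needs a ``phase`` column (see :func:`classify_phases`)
    besides the usual ``field_id, da, qc_pass``. Phases without enough
    conditions for a given compound are simply absent from the output.
    """
    if "phase" not in nucleus_df:
        raise ValueError("nucleus_df must carry a 'phase' column")
    chunks = []
    for phase_name, sub in [("overall", nucleus_df)] + [
        (p, nucleus_df[nucleus_df["phase"] == p]) for p in PHASES
    ]:
        if sub.empty:
            continue
        summaries = pool_by_condition(sub, metadata)
        if summaries.empty:
            continue
        fits = fit_dose_responses(summaries, alpha=alpha)
        if fits.empty:
            continue
        fits.insert(0, "phase", phase_name)
        chunks.append(fits)
    if not chunks:
        return pd.DataFrame()
    return pd.concat(chunks, ignore_index=True)
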