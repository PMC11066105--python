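"""Dose-response statistics and mechanism-of-action scoring.

Per-nucleus degree-of-aggregation (DA) values are pooled by experimental
condition (compound x cell line x concentration); for each compound the
condition means are regressed on log10 concentration, with the DMSO
(vehicle) control entering at a pseudo-concentration three orders of
magnitude below the lowest dose. A compound is "active" when the slope is
significantly non-zero (two-sided t-test, default alpha = 0.05, unadjusted;
Benjamini-Hochberg adjusted p-values are reported alongside). Mechanism-
of-action activity is the signed fraction of active compounds:
``score = sum(direction) / n_compounds`` in [-1, 1], reported only for
MoAs with at least ``min_compounds`` members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DoseResponse",
    "pool_by_condition",
    "dose_response",
    "fit_dose_responses",
    "adjust_pvalues",
    "moa_scores",
    "volcano_table",
    "DMSO_DILUTION",
]

#: the DMSO pseudo-concentration is the lowest dose divided by this factor
DMSO_DILUTION = 1000.0

_CONDITION_KEYS = ["compound", "cell_line", "concentration_m"]


@dataclass
class DoseResponse:
    compound: str
    cell_line: str
    slope: float  # DA (ADU) per log10(molar)
    slope_se: float
    t_stat: float
    p_value: float
    n_points: int
    active: bool
    direction: int  # sign(slope) if active else 0
    intercept: float = float("nan")
    moa: str | None = None
    p_adjusted: float = float("nan")


def pool_by_condition(
    nucleus_df: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Mean/SD/n of DA per condition over QC-passing nuclei.

    ``nucleus_df`` needs columns ``field_id, da, qc_pass``; ``metadata``
    maps ``field_id`` to compound, moa, concentration_m, cell_line.
    Conditions whose nuclei all fail QC are absent from the output.
    """
    meta_cols = ["field_id", "compound", "moa", "concentration_m", "cell_line"]
    merged = nucleus_df.merge(metadata[meta_cols], on="field_id", how="left")
    if merged["compound"].isna().any():
        missing = merged.loc[merged["compound"].isna(), "field_id"].unique()
        raise ValueError(f"nuclei from fields absent in metadata: {missing[:5]}")
    ok = merged[merged["qc_pass"]]
    grouped = ok.groupby(_CONDITION_KEYS + ["moa"], as_index=False).agg(
        mean_da=("da", "mean"), sd_da=("da", "std"), n_cells=("da", "size")
    )
    grouped["sd_da"] = grouped["sd_da"].fillna(0.0)
    return grouped


def _dose_axis(concentrations: np.ndarray) -> np.ndarray:
    """log10 molar axis with DMSO (0 M) placed 3 decades below the lowest
    dose, as the vehicle anchor of the regression."""
    conc = np.asarray(concentrations, dtype=float)
    if (conc < 0).any():
        raise ValueError("concentrations must be >= 0")
    nonzero = conc[conc > 0]
    if nonzero.size == 0:
        raise ValueError("need at least one non-zero dose")
    dmso_conc = nonzero.min() / DMSO_DILUTION
    return np.log10(np.where(conc == 0, dmso_conc, conc))


def dose_response(
    summary: pd.DataFrame,
    alpha: float = 0.05,
) -> DoseResponse:
    """OLS of condition-mean DA on log10 concentration for one compound.

    ``summary`` holds the condition rows of a single compound and cell
    line, including exactly one DMSO row (``concentration_m == 0``).
    Significance is the two-sided t-test of slope = 0 with n-2 df.
    """
    if summary["compound"].nunique() != 1 or summary["cell_line"].nunique() != 1:
        raise ValueError("summary must cover exactly one compound and cell line")
    n_dmso = int((summary["concentration_m"] == 0).sum())
    if n_dmso != 1:
        raise ValueError(f"expected exactly one DMSO row, found {n_dmso}")
    if len(summary) < 3:
        raise ValueError("need at least 3 condition points")
    x = _dose_axis(summary["concentration_m"].to_numpy())
    y = summary["mean_da"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all concentrations identical")
    res = sps.linregress(x, y)
    n = len(x)
    if res.stderr > 0:
        t_stat = res.slope / res.stderr
        p = float(res.pvalue)
    elif res.slope == 0:  # flat response: nothing to test
        t_stat, p = 0.0, 1.0
    else:  # exact linear relationship: zero residual variance
        t_stat, p = float(np.inf), 0.0
    active = bool(p < alpha and res.slope != 0)
    moa = summary["moa"].iloc[0] if "moa" in summary else None
    return DoseResponse(
        compound=str(summary["compound"].iloc[0]),
        cell_line=str(summary["cell_line"].iloc[0]),
        slope=float(res.slope),
        slope_se=float(res.stderr),
        t_stat=float(t_stat),
        p_value=p,
        n_points=n,
        active=active,
        direction=int(np.sign(res.slope)) if active else 0,
        intercept=float(res.intercept),
        moa=moa,
    )


def fit_dose_responses(
    summaries: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Fit every (compound, cell line) of a pooled summary table.

    Adds BH-adjusted p-values over all fits (per cell line); activity calls
    use raw p-values unless ``use_adjusted``. Compounds with too few
    conditions are skipped with a count in ``DataFrame.attrs['n_skipped']``.
    """
    rows, skipped = [], 0
    for (_, _), grp in summaries.groupby(["compound", "cell_line"]):
        try:
            rows.append(dose_response(grp, alpha=alpha).__dict__)
        except ValueError:
            skipped += 1
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = adjust_pvalues(df["p_value"].to_numpy())
        if use_adjusted:
            df["active"] = df["p_adjusted"] < alpha
            df["direction"] = np.where(df["active"], np.sign(df["slope"]), 0).astype(int)
    df.attrs["n_skipped"] = skipped
    df.attrs["alpha"] = alpha
    return df


def adjust_pvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moa_scores(
    responses: pd.DataFrame,
    min_compounds: int = 5,
    by_cell_line: bool = True,
) -> pd.DataFrame:
    """Signed activity score per MoA: sum of active directions / n compounds.

    MoAs represented by fewer than ``min_compounds`` compounds (within a
    cell line when ``by_cell_line``) are omitted.
    """
    if "moa" not in responses or responses["moa"].isna().all():
        raise ValueError("responses carry no MoA labels")
    keys = ["cell_line", "moa"] if by_cell_line and "cell_line" in responses else ["moa"]
    agg = responses.groupby(keys, as_index=False).agg(
        n_compounds=("compound", "nunique"),
        direction_sum=("direction", "sum"),
    )
    agg = agg[agg["n_compounds"] >= min_compounds].reset_index(drop=True)
    agg["score"] = agg["direction_sum"] / agg["n_compounds"]
    return agg.drop(columns="direction_sum")


def volcano_table(
    responses: pd.DataFrame,
    alpha: float = 0.05,
    neg_log10_cap: float = 300.0,
) -> pd.DataFrame:
    """Slope vs -log10 p per compound/cell line; p = 0 capped at the stated
    ceiling. The significance line is recorded in ``attrs['alpha']``."""
    if responses.empty:
        raise ValueError("no dose responses to tabulate")
    with np.errstate(divide="ignore"):
        neglog = -np.log10(responses["p_value"].to_numpy(dtype=float))
    out = pd.DataFrame(
        {
            "compound": responses["compound"],
            "cell_line": responses["cell_line"],
            "slope": responses["slope"],
            "neg_log10_p": np.minimum(neglog, neg_log10_cap),
            "active": responses["active"],
        }
    )
    out.attrs["alpha"] = alpha
    out.attrs["neg_log10_alpha"] = float(-np.log10(alpha))
    return out
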