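"""Validation experiments tying the simulator's analytic ground truth to
the measurement chain.

Each function runs a self-contained simulation study — amplitude recovery
against the ICS identity, cluster-size scaling of the degree of
aggregation, mask-shape robustness, binning sensitivity, null and
designed-effect screens, cell-cycle stratification — and returns the
measured quantities. They are what the test suite and the reproduction
script execute; problem sizes default to what a desk-scale study needs
for stable statistics.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from . import cellcycle as cc
from .ics import measure_nucleus
from .pipeline import RunConfig, analyze_fields
from .stats import fit_dose_responses, pool_by_condition
from .synthetic import (
    CompoundSpec,
    ScreenSpec,
    SimulationSpec,
    simulate_field,
    simulate_screen,
    uniform_emitter_field,
)

__all__ = [
    "amplitude_recovery",
    "da_by_cluster_size",
    "mask_shape_robustness",
    "binning_sensitivity",
    "screen_active_calls",
    "null_screen_type1",
    "power_direction",
    "cellcycle_agreement",
    "phase_slope_consistency",
]

_DOSES = (1e-8, 1e-7, 1e-6, 1e-5)  # molar: 10 nM .. 10 uM


def _measure_truth_nuclei(spec: SimulationSpec, n_nuclei: int, seed: int,
                          config: RunConfig = RunConfig()):
    """Simulate fields until ``n_nuclei`` nuclei are measured with their
    ground-truth masks; returns (per-nucleus DataFrame, truth list)."""
    rows, truths = [], []
    rng_seed = seed
    while len(rows) < n_nuclei:
        nuc, prot, truth = simulate_field(dataclasses.replace(spec, seed=rng_seed))
        rng_seed += 1
        for nt in truth.nuclei:
            if len(rows) >= n_nuclei:
                break
            mask = nt.render_mask(nuc.shape)
            da = measure_nucleus(
                prot, mask, 1, margin=config.margin, fit_radius=config.fit_radius,
                exclude_zero_lag=config.exclude_zero_lag,
                mask_normalize=config.mask_normalize,
                erode_margin=config.erode_margin,
            )
            if da.qc_pass:
                rows.append({"a": da.fit.a, "c": da.fit.c, "n_psf": da.n_psf,
                             "da": da.da, "mean_intensity": da.mean_intensity,
                             "expected_n_psf": nt.expected_n_psf,
                             "expected_da": nt.expected_da})
                truths.append(nt)
    return pd.DataFrame(rows), truths


def amplitude_recovery(n_nuclei: int = 100, seed: int = 0) -> dict:
    """ICS identity check: mean fitted amplitude vs 1/N_PSF on pure-monomer,
    background-free nuclei measured under their ground-truth masks.

    Nuclei are rendered large (radius 18-24 px, as with an unbinned 20x
    objective) because the identity assumes the beam area is small relative
    to the analysed region; tiny regions inflate the amplitude estimate.
    """
    spec = SimulationSpec(
        monomer_density=0.5, cluster_size_k=1, clustered_fraction=0.0,
        background_offset=0.0, read_noise_sigma=0.0,
        nucleus_radius_range=(18.0, 24.0), image_shape=(320, 320), n_nuclei=8,
    )
    df, _ = _measure_truth_nuclei(spec, n_nuclei, seed)
    mean_a = float(df["a"].mean())
    truth_a = float((1.0 / df["expected_n_psf"]).mean())
    return {
        "mean_fitted_a": mean_a,
        "truth_inverse_n_psf": truth_a,
        "relative_error": abs(mean_a - truth_a) / truth_a,
        "n": len(df),
    }


def da_by_cluster_size(n_per_arm: int = 100, seed: int = 0,
                       bin_factor: int = 1) -> dict:
    """Mean DA for fully clustered k=4 emitters vs k=1 monomers at fixed
    total monomer count; the analytic expectation of the ratio is k."""
    base = dict(monomer_density=0.5, background_offset=0.0, read_noise_sigma=0.0,
                nucleus_radius_range=(16.0, 20.0), image_shape=(256, 256),
                n_nuclei=8, bin_factor=bin_factor)
    config = RunConfig(min_area=50) if bin_factor > 1 else RunConfig()
    arms = {}
    for name, k, frac in [("k1", 1, 0.0), ("k4", 4, 1.0)]:
        spec = SimulationSpec(cluster_size_k=k, clustered_fraction=frac, **base)
        df, _ = _measure_truth_nuclei(spec, n_per_arm, seed, config)
        arms[name] = df["da"].to_numpy()
    m1, m4 = arms["k1"].mean(), arms["k4"].mean()
    s1, s4 = arms["k1"].std(ddof=1), arms["k4"].std(ddof=1)
    pooled = math.sqrt((s1**2 + s4**2) / 2)
    return {
        "mean_da_k1": float(m1),
        "mean_da_k4": float(m4),
        "ratio": float(m4 / m1),
        "effect_size_d": float((m4 - m1) / pooled),
        "n_per_arm": n_per_arm,
    }


def mask_shape_robustness(n_fields: int = 40, seed: int = 0) -> dict:
    """Mean DA of the same homogeneous emitter field under an elliptical vs
    an equal-area rectangular analysis mask."""
    shape = (160, 160)
    cr, ccol = shape[0] / 2, shape[1] / 2
    a_r, b_r = 24.0, 15.0  # ellipse semi-axes -> area ~1131 px
    area = math.pi * a_r * b_r
    half = math.sqrt(area) / 2  # square of the same area
    rr, col = np.mgrid[0:shape[0], 0:shape[1]]
    ell = ((rr - cr) / a_r) ** 2 + ((col - ccol) / b_r) ** 2 <= 1.0
    rect = (np.abs(rr - cr) <= half) & (np.abs(col - ccol) <= half)
    das = {"ellipse": [], "rectangle": []}
    for i in range(n_fields):
        img, _, _ = uniform_emitter_field(
            shape, 0.5, cluster_size_k=2, clustered_fraction=0.5,
            psf_sigma=1.5, seed=seed + i,
        )
        for name, m in [("ellipse", ell), ("rectangle", rect)]:
            da = measure_nucleus(img, m.astype(np.int32), 1)
            if da.qc_pass:
                das[name].append(da.da)
    me = float(np.mean(das["ellipse"]))
    mr = float(np.mean(das["rectangle"]))
    return {
        "mean_da_ellipse": me,
        "mean_da_rectangle": mr,
        "relative_difference": abs(me - mr) / ((me + mr) / 2),
        "n_fields": n_fields,
    }


def binning_sensitivity(n_per_arm: int = 60, seed: int = 0) -> dict:
    """Standardized k=4 vs k=1 DA separation with and without 2x binning."""
    unbinned = da_by_cluster_size(n_per_arm, seed, bin_factor=1)
    binned = da_by_cluster_size(n_per_arm, seed, bin_factor=2)
    return {
        "effect_size_unbinned": unbinned["effect_size_d"],
        "effect_size_binned": binned["effect_size_d"],
        "ratio_binned_over_unbinned":
            binned["effect_size_d"] / unbinned["effect_size_d"],
        "n_per_arm": n_per_arm,
    }


def _screen_base(seed: int) -> SimulationSpec:
    """Field geometry used by the screen-level experiments: compact fields
    that still yield ~6 analysable nuclei each."""
    return SimulationSpec(
        image_shape=(160, 160), n_nuclei=6, nucleus_radius_range=(10.0, 13.0),
        seed=seed,
    )


def screen_active_calls(compounds: Sequence[CompoundSpec], n_fields: int,
                        seed: int, alpha: float = 0.05,
                        base: SimulationSpec | None = None) -> pd.DataFrame:
    """Simulate a screen in memory and fit every compound; returns the
    dose-response table joined with the designed direction."""
    screen = ScreenSpec(compounds=tuple(compounds), n_fields=n_fields,
                        seed=seed, base=base if base is not None
                        else _screen_base(seed))
    fields, metadata_rows, truth_rows = simulate_screen(screen)
    meta = pd.DataFrame(metadata_rows)
    nuclei = analyze_fields(
        {fid: (nuc, prot) for fid, (nuc, prot, _) in fields.items()},
        RunConfig(min_area=150),
    )
    summaries = pool_by_condition(nuclei, meta)
    responses = fit_dose_responses(summaries, alpha=alpha)
    truth = pd.DataFrame(truth_rows)[["compound", "designed_direction"]]
    return responses.merge(truth, on="compound")


def null_screen_type1(n_compounds: int = 500, seed: int = 0,
                      alpha: float = 0.05, chunk: int = 50) -> dict:
    """Active-call rate on a screen with no designed effect anywhere.

    Compounds are fit in independent chunks (same layout, different seeds)
    so memory stays flat. Returns the rate and the binomial 99% CI around
    ``alpha`` for the realized number of fits.
    """
    flat = (0.3, 0.3, 0.3, 0.3)
    n_active = n_fit = 0
    done = 0
    while done < n_compounds:
        m = min(chunk, n_compounds - done)
        comps = [
            CompoundSpec(name=f"null{done + i}", moa="null", doses=_DOSES,
                         clustered_fractions=flat, dmso_clustered_fraction=0.3)
            for i in range(m)
        ]
        resp = screen_active_calls(comps, n_fields=1, seed=seed + done)
        n_active += int(resp["active"].sum())
        n_fit += len(resp)
        done += m
    from scipy.stats import binom

    lo, hi = binom.ppf([0.005, 0.995], n_fit, alpha) / n_fit
    return {
        "active_rate": n_active / n_fit,
        "n_fits": n_fit,
        "alpha": alpha,
        "ci99_low": float(lo),
        "ci99_high": float(hi),
    }


def power_direction(n_replicates: int = 50, seed: int = 0) -> dict:
    """Fraction of designed-active compounds called active with the correct
    sign; replicates alternate between rising and falling clustering.

    The default effect roughly 2.5x's the top-dose DA relative to vehicle
    (fully formed response of a strongly clustering compound) and each
    condition pools ~30 nuclei over four fields — far below the hundreds
    of cells per condition of a production screen, but enough for the
    condition means to resolve the trend.
    """
    base = SimulationSpec(image_shape=(192, 192), n_nuclei=8,
                          nucleus_radius_range=(10.0, 13.0))
    correct = 0
    for rep in range(n_replicates):
        if rep % 2 == 0:
            comp = CompoundSpec(name="up", moa="m", doses=_DOSES,
                                clustered_fractions=(0.2, 0.4, 0.6, 0.8),
                                dmso_clustered_fraction=0.0)
        else:
            comp = CompoundSpec(name="down", moa="m", doses=_DOSES,
                                clustered_fractions=(0.6, 0.45, 0.3, 0.15),
                                dmso_clustered_fraction=0.8)
        resp = screen_active_calls(
            [comp], n_fields=4, seed=seed + 1000 + rep,
            base=dataclasses.replace(base, seed=seed + 1000 + rep),
        )
        row = resp.iloc[0]
        if row["active"] and row["direction"] == row["designed_direction"]:
            correct += 1
    return {"fraction_correct": correct / n_replicates,
            "n_replicates": n_replicates}


def cellcycle_agreement(n_nuclei: int = 300, seed: int = 0) -> dict:
    """Phase-label agreement against the simulator's designed phases on a
    two-population (G1/G2) DNA-content mixture."""
    spec = SimulationSpec(n_nuclei=12, seed=seed, phase_weights=(0.65, 0.0, 0.35))
    intens, truth_phases = [], []
    s = seed
    while len(intens) < n_nuclei:
        nuc, _, truth = simulate_field(dataclasses.replace(spec, seed=s))
        s += 1
        img = np.asarray(nuc, float)
        combined = np.zeros(nuc.shape, dtype=bool)
        for nt in truth.nuclei:
            combined |= nt.render_mask(nuc.shape).astype(bool)
        bg = float(np.median(img[~combined]))
        for nt in truth.nuclei:
            mask = nt.render_mask(nuc.shape).astype(bool)
            intens.append(float(np.clip(img[mask] - bg, 0, None).sum()))
            truth_phases.append(nt.phase)
    labels = cc.classify_phases(np.asarray(intens[:n_nuclei]))
    truth_arr = np.asarray(truth_phases[:n_nuclei], dtype=object)
    classified = labels != cc.UNCLASSIFIED
    agree = float((labels[classified] == truth_arr[classified]).mean())
    return {"agreement": agree,
            "fraction_classified": float(classified.mean()),
            "n": int(n_nuclei)}


def phase_slope_consistency(n_replicates: int = 8, seed: int = 0) -> dict:
    """Designed phase-independent effect: per-phase dose-response slopes
    should sit within two standard errors of the overall slope.

    Each per-phase slope is an estimate with sampling noise, so the check
    is a fraction over replicate screens rather than a single draw.
    """
    comp = CompoundSpec(name="up", moa="m", doses=_DOSES,
                        clustered_fractions=(0.2, 0.4, 0.6, 0.8),
                        dmso_clustered_fraction=0.0)
    n_within = n_phases = 0
    for rep in range(n_replicates):
        rep_seed = seed + 3000 + rep
        screen = ScreenSpec(compounds=(comp,), n_fields=6, seed=rep_seed,
                            base=SimulationSpec(image_shape=(256, 256),
                                                n_nuclei=12, seed=rep_seed))
        fields, metadata_rows, _ = simulate_screen(screen)
        meta = pd.DataFrame(metadata_rows)
        nuclei = analyze_fields(
            {fid: (nuc, prot) for fid, (nuc, prot, _) in fields.items()},
            RunConfig(),
        )
        # classify phases over the whole batch
        nuclei["phase"] = cc.classify_phases(
            nuclei["integrated_dna_intensity"].to_numpy()
        )
        fits = cc.phase_stratified_response(nuclei, meta)
        overall = fits[fits["phase"] == "overall"].iloc[0]
        for phase in ("G1", "S", "G2"):
            sub = fits[fits["phase"] == phase]
            if sub.empty:
                continue
            row = sub.iloc[0]
            dev = abs(row["slope"] - overall["slope"]) / max(row["slope_se"],
                                                             1e-12)
            n_phases += 1
            n_within += dev <= 2.0
    return {"fraction_within_2se": float(n_within / n_phases),
            "n_phase_fits": int(n_phases),
            "n_replicates": n_replicates}
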