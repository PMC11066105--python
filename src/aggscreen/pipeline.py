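"""End-to-end orchestration: metadata in, result tables out.

Stages run in the order segmentation -> per-nucleus autocorrelation ->
cell-cycle classification -> condition pooling -> dose-response and MoA
scoring. Every output CSV starts with a ``# config_sha256=...`` comment
carrying the hash of the resolved configuration, and the configuration
itself is serialized into the output directory for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

from . import cellcycle as cc
from . import ics, segment, stats

__all__ = ["RunConfig", "analyze_fields", "run_pipeline", "load_metadata",
           "write_table", "read_table"]

log = logging.getLogger("aggscreen")

METADATA_COLUMNS = [
    "field_id", "nuclear_path", "protein_path", "well",
    "compound", "moa", "concentration_m", "cell_line",
]


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one pipeline run (serialized for provenance)."""

    # segmentation
    backend: str = "classical"
    smooth_sigma: float = 2.0
    min_distance: int = 8
    min_area: int = 200
    max_area: int | None = None
    drop_edge: bool = True
    # autocorrelation
    margin: int = 8
    fit_radius: int = 16
    exclude_zero_lag: bool = True
    mask_normalize: bool = True
    erode_margin: int = 2
    # statistics
    alpha: float = 0.05
    use_adjusted_p: bool = False
    min_moa_compounds: int = 5
    # cell cycle
    g1_window: tuple[float, float] = (0.75, 1.25)
    g2_window: tuple[float, float] = (1.75, 2.5)
    min_cells_per_batch: int = 50
    # misc
    seed: int = 0

    def sha256(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_metadata(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, comment="#")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing columns: {missing}")
    if meta["field_id"].duplicated().any():
        raise ValueError("duplicate field_id in metadata")
    if (meta["concentration_m"] < 0).any():
        raise ValueError("concentrations must be >= 0")
    return meta


def write_table(df: pd.DataFrame, path: str | os.PathLike, config_hash: str) -> None:
    """CSV with a provenance comment line and stable float formatting."""
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def analyze_fields(
    fields: dict[str, tuple[np.ndarray, np.ndarray]],
    config: RunConfig = RunConfig(),
) -> pd.DataFrame:
    """Segment and autocorrelate every field; one row per surviving nucleus.

    ``fields`` maps field id -> (nuclear_channel, protein_channel).
    """
    rows = []
    counts = {"segmented": 0, "filtered_out": 0, "qc_failed": 0}
    for field_id, (nuclear, protein) in fields.items():
        mask = segment.segment_nuclei(
            nuclear, backend=config.backend,
            smooth_sigma=config.smooth_sigma, min_distance=config.min_distance,
        )
        n_raw = int(mask.max())
        mask, records = segment.filter_nuclei(
            mask, min_area=config.min_area, max_area=config.max_area,
            drop_edge=config.drop_edge,
        )
        segment.measure_nuclei(records, mask, nuclear, protein)
        counts["segmented"] += n_raw
        counts["filtered_out"] += n_raw - len(records)
        for rec in records:
            da = ics.measure_nucleus(
                protein, mask, rec.label,
                margin=config.margin, fit_radius=config.fit_radius,
                exclude_zero_lag=config.exclude_zero_lag,
                mask_normalize=config.mask_normalize,
                erode_margin=config.erode_margin,
            )
            if not da.qc_pass:
                counts["qc_failed"] += 1
            fit = da.fit
            rows.append(
                {
                    "field_id": field_id,
                    "nucleus_label": rec.label,
                    "area": rec.area,
                    "mean_intensity": da.mean_intensity,
                    "integrated_dna_intensity": rec.integrated_dna_intensity,
                    "a": fit.a if fit else np.nan,
                    "b": fit.b if fit else np.nan,
                    "c": fit.c if fit else np.nan,
                    "x0": fit.x0 if fit else np.nan,
                    "y0": fit.y0 if fit else np.nan,
                    "n_psf": da.n_psf,
                    "da": da.da,
                    "qc_pass": da.qc_pass,
                }
            )
    log.info(
        "analyzed %d fields: %d nuclei segmented, %d filtered out, %d QC-failed",
        len(fields), counts["segmented"], counts["filtered_out"], counts["qc_failed"],
    )
    df = pd.DataFrame(rows)
    df.attrs["counts"] = counts
    return df


def run_pipeline(
    metadata_csv: str | os.PathLike,
    config: RunConfig = RunConfig(),
    out_dir: str | os.PathLike = "aggscreen_out",
    image_root: str | os.PathLike | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the whole analysis from a plate-metadata CSV.

    Image paths in the metadata are resolved relative to ``image_root``
    (default: the metadata file's directory). Writes per-nucleus,
    condition-summary, dose-response, MoA, volcano and per-phase CSVs plus
    the resolved config, and returns the tables.
    """
    meta = load_metadata(metadata_csv)
    root = os.path.dirname(os.fspath(metadata_csv)) if image_root is None else image_root
    fields = {}
    for row in meta.itertuples():
        npath = os.path.join(root, row.nuclear_path)
        ppath = os.path.join(root, row.protein_path)
        for p in (npath, ppath):
            if not os.path.exists(p):
                raise FileNotFoundError(f"[load] missing image for field "
                                        f"{row.field_id}: {p}")
        fields[row.field_id] = (tifffile.imread(npath), tifffile.imread(ppath))

    nuclei = analyze_fields(fields, config)
    if nuclei.empty or not nuclei["qc_pass"].any():
        raise RuntimeError("[ics] no nuclei survived segmentation and QC")

    # cell-cycle classification per batch (cell line)
    nuclei = nuclei.merge(meta[["field_id", "cell_line"]], on="field_id", how="left")
    nuclei["phase"] = cc.UNCLASSIFIED
    for _, idx in nuclei.groupby("cell_line").groups.items():
        nuclei.loc[idx, "phase"] = cc.classify_phases(
            nuclei.loc[idx, "integrated_dna_intensity"].to_numpy(),
            g1_window=config.g1_window, g2_window=config.g2_window,
            min_cells=config.min_cells_per_batch,
        )
    nuclei = nuclei.drop(columns="cell_line")

    summaries = stats.pool_by_condition(nuclei, meta)
    responses = stats.fit_dose_responses(
        summaries, alpha=config.alpha, use_adjusted=config.use_adjusted_p
    )
    if responses.empty:
        raise RuntimeError("[stats] no compound could be fit")
    volcano = stats.volcano_table(responses, alpha=config.alpha)
    try:
        moa = stats.moa_scores(responses, min_compounds=config.min_moa_compounds)
    except ValueError:
        moa = pd.DataFrame()
    phase_fits = cc.phase_stratified_response(nuclei, meta, alpha=config.alpha)

    os.makedirs(out_dir, exist_ok=True)
    h = config.sha256()
    tables = {
        "nuclei": nuclei,
        "condition_summaries": summaries,
        "dose_response": responses,
        "volcano": volcano,
        "moa_scores": moa,
        "phase_dose_response": phase_fits,
    }
    for name, df in tables.items():
        write_table(df, os.path.join(out_dir, f"{name}.csv"), h)
    with open(os.path.join(out_dir, "run_config.json"), "w") as fh:
        json.dump({"config": dataclasses.asdict(config), "sha256": h}, fh,
                  indent=2, default=str)
    log.info("wrote %d tables to %s (config %s)", len(tables), out_dir, h)
    return tables
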