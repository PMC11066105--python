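"""Synthetic multi-channel microscopy fields with known ground truth.

Generates fields that emulate a high-content nuclear-protein screen: a
DNA-stain channel containing elliptical nuclei whose integrated intensity
encodes DNA content (for cell-cycle classification), and a protein channel
in which point emitters — free monomers plus co-located clusters of ``k``
monomers — are scattered uniformly inside each nucleus, blurred by a
Gaussian point-spread function, and corrupted by shot and read noise.

Because clusters have zero spatial extent, image-correlation theory gives
an exact analytic expectation for the autocorrelation peak amplitude:
``a = 1/N_PSF`` with ``N_PSF = rho_particles * pi * w**2`` where
``w = 2 * psf_sigma`` is the e^-2 radius of the PSF intensity profile
(equivalently the e^-1 radius of the correlation peak). That identity is
the oracle the analysis modules are validated against.
"""

from __future__ import annotations

import csv
import hashlib
import math
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

__all__ = [
    "SimulationSpec",
    "NucleusTruth",
    "GroundTruth",
    "CompoundSpec",
    "ScreenSpec",
    "beam_radius",
    "simulate_field",
    "uniform_emitter_field",
    "simulate_screen",
    "bin_image",
]

#: cell-cycle phases and their relative DNA content used by the simulator
_PHASES = ("G1", "S", "G2")


def beam_radius(psf_sigma: float) -> float:
    """e^-2 radius of a Gaussian PSF ``exp(-r^2 / (2 sigma^2))``, in pixels.

    This is the beam-waist convention under which the fitted correlation-peak
    amplitude equals the inverse number of particles per beam area
    (``pi * w**2``); it also equals the e^-1 radius ``c`` of the correlation
    peak itself.
    """
    return 2.0 * float(psf_sigma)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated field.

    Lengths are in pixels unless noted; ``pixel_size`` converts to microns.
    Intensities are in camera units (ADU).
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 1.0  # um / pixel
    n_nuclei: int = 12
    nucleus_radius_range: tuple[float, float] = (12.0, 16.0)
    monomer_density: float = 0.6  # emitters / um^2 of nucleus area
    cluster_size_k: int = 1
    clustered_fraction: float = 0.0
    monomer_brightness: float = 150.0  # expected ADU (photons) per monomer
    psf_sigma: float = 1.5
    background_offset: float = 100.0
    read_noise_sigma: float = 2.0
    bin_factor: int = 1
    seed: int = 0
    # secondary knobs -----------------------------------------------------
    axis_ratio_range: tuple[float, float] = (0.75, 1.0)  # minor/major axis
    dna_total_intensity: float = 2.0e5  # integrated DNA-stain ADU at 1x content
    phase_weights: tuple[float, float, float] = (0.6, 0.15, 0.25)  # G1, S, G2
    shot_noise: bool = True

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows < 8 or cols < 8:
            raise ValueError("image_shape too small")
        if not (0.0 <= self.clustered_fraction <= 1.0):
            raise ValueError("clustered_fraction must be in [0, 1]")
        if self.cluster_size_k < 1:
            raise ValueError("cluster_size_k must be >= 1")
        if self.bin_factor < 1:
            raise ValueError("bin_factor must be >= 1")
        for name in ("pixel_size", "monomer_density", "monomer_brightness",
                     "psf_sigma", "background_offset", "read_noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        rmin, rmax = self.nucleus_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("invalid nucleus_radius_range")
        if 2 * rmax >= min(rows, cols):
            raise ValueError("nucleus radius does not fit in the image")
        if abs(sum(self.phase_weights) - 1.0) > 1e-9 or min(self.phase_weights) < 0:
            raise ValueError("phase_weights must be non-negative and sum to 1")


@dataclass
class NucleusTruth:
    """Ground truth for one simulated nucleus (output-pixel coordinates)."""

    center: tuple[float, float]  # (row, col)
    radii: tuple[float, float]  # (semi-major, semi-minor), pixels
    orientation: float  # radians
    area: float  # pixels
    phase: str
    dna_factor: float  # relative DNA content (G1 = 1, G2 = 2)
    n_monomers: int
    n_independent_particles: int  # clusters count once
    emitters: np.ndarray  # (n, 3): row, col, multiplicity
    expected_n_psf: float  # particles per beam area pi*(2 sigma)^2
    expected_da: float  # expected mean intensity / expected_n_psf (nan if empty)

    def render_mask(self, shape: tuple[int, int], label: int = 1) -> np.ndarray:
        """Integer label mask of this nucleus on a canvas of ``shape``."""
        return _ellipse_mask(shape, self.center, self.radii, self.orientation).astype(
            np.int32
        ) * label


@dataclass
class GroundTruth:
    spec: SimulationSpec
    nuclei: list[NucleusTruth] = field(default_factory=list)
    n_requested: int = 0
    n_placed: int = 0

    @property
    def has_emitters(self) -> bool:
        return any(n.n_monomers > 0 for n in self.nuclei)


def _ellipse_mask(shape, center, radii, orientation):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = math.cos(orientation), math.sin(orientation)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def _place_nuclei(spec: SimulationSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipse geometries; may place fewer
    than requested after bounded retries."""
    rows, cols = spec.image_shape
    rmin, rmax = spec.nucleus_radius_range
    placed: list[tuple[tuple[float, float], tuple[float, float], float]] = []
    max_tries = 200
    for _ in range(spec.n_nuclei):
        for _ in range(max_tries):
            a = rng.uniform(rmin, rmax)
            ratio = rng.uniform(*spec.axis_ratio_range)
            b = a * ratio
            theta = rng.uniform(0, math.pi)
            # keep whole ellipse inside the frame
            cr = rng.uniform(a + 1, rows - a - 1)
            cc = rng.uniform(a + 1, cols - a - 1)
            ok = all(
                math.hypot(cr - pc[0], cc - pc[1]) > a + pr[0] + 2.0
                for pc, pr, _ in placed
            )
            if ok:
                placed.append(((cr, cc), (a, b), theta))
                break
    return placed


def _sample_emitters(mask_idx, n_monomers, k, clustered_fraction, rng):
    """Return (n, 3) array of emitter positions and multiplicities.

    Clusters are k monomers co-located at a single point (zero extent);
    leftover monomers that do not fill a whole cluster stay monomeric.
    """
    n_clustered = int(round(clustered_fraction * n_monomers))
    n_clusters = n_clustered // k
    n_free = n_monomers - n_clusters * k
    counts = [(n_clusters, float(k)), (n_free, 1.0)]
    rows_i, cols_i = mask_idx
    out = []
    for n, mult in counts:
        if n == 0:
            continue
        pick = rng.integers(0, len(rows_i), size=n)
        r = rows_i[pick] + rng.uniform(-0.5, 0.5, size=n)
        c = cols_i[pick] + rng.uniform(-0.5, 0.5, size=n)
        out.append(np.column_stack([r, c, np.full(n, mult)]))
    if not out:
        return np.empty((0, 3))
    return np.vstack(out)


def _render_emitters(shape, emitters, brightness, psf_sigma):
    canvas = np.zeros(shape, dtype=np.float64)
    if len(emitters):
        r = np.clip(np.rint(emitters[:, 0]).astype(int), 0, shape[0] - 1)
        c = np.clip(np.rint(emitters[:, 1]).astype(int), 0, shape[1] - 1)
        np.add.at(canvas, (r, c), brightness * emitters[:, 2])
    if psf_sigma > 0:
        canvas = gaussian_filter(canvas, psf_sigma, mode="constant")
    return canvas


def bin_image(img: np.ndarray, factor: int) -> np.ndarray:
    """Sum-pool ``factor x factor`` blocks (camera-style pixel binning).

    Trailing rows/columns that do not fill a block are dropped. Total
    intensity over full blocks is conserved exactly.
    """
    if factor == 1:
        return img
    rows = (img.shape[0] // factor) * factor
    cols = (img.shape[1] // factor) * factor
    v = img[:rows, :cols].reshape(rows // factor, factor, cols // factor, factor)
    return v.sum(axis=(1, 3))


def _camera(signal: np.ndarray, spec: SimulationSpec, rng) -> np.ndarray:
    """Apply the camera model: shot noise on signal+background, read noise,
    sum-pooled binning, clipping and 16-bit quantization."""
    expected = signal + spec.background_offset
    if spec.shot_noise:
        noisy = rng.poisson(np.clip(expected, 0, None)).astype(np.float64)
    else:
        noisy = expected.astype(np.float64)
    if spec.read_noise_sigma > 0:
        noisy += rng.normal(0.0, spec.read_noise_sigma, size=noisy.shape)
    noisy = bin_image(noisy, spec.bin_factor)
    return np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)


def _dna_factor(phase: str, rng) -> float:
    if phase == "G1":
        base = 1.0
    elif phase == "G2":
        base = 2.0
    else:
        base = rng.uniform(1.05, 1.95)
    return base * rng.normal(1.0, 0.03)


def simulate_field(spec: SimulationSpec):
    """Render one field.

    Returns
    -------
    nuclear_channel, protein_channel : uint16 arrays
        The two channels after the camera model (and binning, if any).
    truth : GroundTruth
        Per-nucleus geometry, emitter lists and analytic ICS expectations.
        Coordinates are in output (post-binning) pixels.
    """
    # One seed fans out into geometry, camera and per-nucleus emitter
    # streams, so nucleus i's emitter draw depends only on (seed, i): fields
    # that differ solely in clustering parameters share geometry and
    # monomer counts nucleus-for-nucleus.
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(2 + spec.n_nuclei)
    rng = np.random.default_rng(children[0])
    camera_rng = np.random.default_rng(children[1])
    shape = spec.image_shape
    geoms = _place_nuclei(spec, rng)

    nuclear = np.zeros(shape, dtype=np.float64)
    protein = np.zeros(shape, dtype=np.float64)
    w = beam_radius(spec.psf_sigma)
    truth = GroundTruth(spec=spec, n_requested=spec.n_nuclei, n_placed=len(geoms))

    for i, (center, radii, theta) in enumerate(geoms):
        mask = _ellipse_mask(shape, center, radii, theta)
        area = float(mask.sum())
        phase = _PHASES[rng.choice(3, p=spec.phase_weights)]
        dna = _dna_factor(phase, rng)
        nuclear[mask] += dna * spec.dna_total_intensity / area

        emit_rng = np.random.default_rng(children[2 + i])
        area_um2 = area * spec.pixel_size**2
        n_monomers = int(emit_rng.poisson(spec.monomer_density * area_um2))
        emitters = _sample_emitters(
            np.nonzero(mask), n_monomers, spec.cluster_size_k,
            spec.clustered_fraction, emit_rng,
        )
        n_particles = len(emitters)
        if n_particles > 0:
            n_psf = n_particles / area * math.pi * w**2
            mean_i = n_monomers * spec.monomer_brightness / area
            expected_da = mean_i / n_psf
        else:
            n_psf = 0.0
            expected_da = float("nan")
        if len(emitters):
            protein += _render_emitters(shape, emitters, spec.monomer_brightness, 0)
        bf = spec.bin_factor
        truth.nuclei.append(
            NucleusTruth(
                center=(center[0] / bf, center[1] / bf),
                radii=(radii[0] / bf, radii[1] / bf),
                orientation=theta,
                area=area / bf**2,
                phase=phase,
                dna_factor=dna,
                n_monomers=n_monomers,
                n_independent_particles=n_particles,
                emitters=emitters / np.array([bf, bf, 1.0]),
                expected_n_psf=n_psf,
                expected_da=expected_da,
            )
        )

    if spec.psf_sigma > 0:
        protein = gaussian_filter(protein, spec.psf_sigma, mode="constant")
        nuclear = gaussian_filter(nuclear, 1.0, mode="constant")
    nuclear_img = _camera(nuclear, spec, camera_rng)
    protein_img = _camera(protein, spec, camera_rng)
    return nuclear_img, protein_img, truth


def uniform_emitter_field(
    shape: tuple[int, int],
    density: float,
    *,
    cluster_size_k: int = 1,
    clustered_fraction: float = 0.0,
    brightness: float = 150.0,
    psf_sigma: float = 1.5,
    background_offset: float = 0.0,
    read_noise_sigma: float = 0.0,
    shot_noise: bool = True,
    seed: int = 0,
):
    """Emitters spread uniformly over the whole frame (no nucleus geometry).

    Useful for measuring the same statistically homogeneous emitter field
    under differently shaped analysis masks. Density is per pixel^2 here.
    Returns (image float64, n_monomers, n_independent_particles).
    """
    rng = np.random.default_rng(seed)
    n_monomers = int(rng.poisson(density * shape[0] * shape[1]))
    full = np.ones(shape, dtype=bool)
    emitters = _sample_emitters(
        np.nonzero(full), n_monomers, cluster_size_k, clustered_fraction, rng
    )
    img = _render_emitters(shape, emitters, brightness, psf_sigma)
    img += background_offset
    if shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if read_noise_sigma > 0:
        img += rng.normal(0.0, read_noise_sigma, size=shape)
    return img, n_monomers, len(emitters)


# ---------------------------------------------------------------------------
# screen-level simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundSpec:
    """Designed behaviour of one compound across its dose series."""

    name: str
    moa: str
    doses: tuple[float, ...]  # molar, ascending, excludes DMSO
    clustered_fractions: tuple[float, ...]  # one per dose
    dmso_clustered_fraction: float = 0.0
    cluster_size_k: int = 4

    def __post_init__(self) -> None:
        if len(self.doses) < 2:
            raise ValueError("need at least two doses plus DMSO")
        if len(self.clustered_fractions) != len(self.doses):
            raise ValueError("one clustered_fraction per dose")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive (0 is reserved for DMSO)")

    @property
    def designed_direction(self) -> int:
        """+1/-1/0: the sign of the designed clustering trend over the full
        dose series (DMSO included as the zero-dose anchor)."""
        fr = (self.dmso_clustered_fraction,) + self.clustered_fractions
        span = max(fr) - min(fr)
        if span < 1e-12:
            return 0
        return 1 if fr[-1] >= fr[0] + 1e-12 else -1


@dataclass(frozen=True)
class ScreenSpec:
    compounds: tuple[CompoundSpec, ...]
    n_fields: int = 2  # fields per condition
    cell_line: str = "cellA"
    base: SimulationSpec = SimulationSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.compounds:
            raise ValueError("screen needs at least one compound")
        names = [c.name for c in self.compounds]
        if len(set(names)) != len(names):
            raise ValueError("duplicate compound names")


def simulate_screen(screen: ScreenSpec, out_dir: str | os.PathLike | None = None):
    """Simulate every (compound, dose) condition of a screen plus a per-
    compound DMSO condition.

    Returns ``(fields, metadata_rows, truth_rows)`` where ``fields`` maps
    field id -> (nuclear, protein, GroundTruth), ``metadata_rows`` is a list
    of dicts conforming to the plate-metadata schema and ``truth_rows``
    records each compound's designed activity direction. When ``out_dir`` is
    given, channels are written as 16-bit TIFFs and the tables as CSV.
    """
    root = np.random.SeedSequence(screen.seed)
    fields: dict[str, tuple[np.ndarray, np.ndarray, GroundTruth]] = {}
    metadata_rows: list[dict] = []
    truth_rows: list[dict] = []
    seen: set[tuple[str, float, int]] = set()

    for ci, comp in enumerate(screen.compounds):
        truth_rows.append(
            {
                "compound": comp.name,
                "moa": comp.moa,
                "cell_line": screen.cell_line,
                "designed_direction": comp.designed_direction,
            }
        )
        conditions = [(0.0, comp.dmso_clustered_fraction)] + list(
            zip(comp.doses, comp.clustered_fractions)
        )
        for di, (conc, frac) in enumerate(conditions):
            for fi in range(screen.n_fields):
                key = (comp.name, conc, fi)
                if key in seen:
                    raise ValueError(f"duplicate condition key {key}")
                seen.add(key)
                child = root.spawn(1)[0]
                seed = int(child.generate_state(1)[0] % (2**31 - 1))
                spec = replace(
                    screen.base,
                    clustered_fraction=frac,
                    cluster_size_k=comp.cluster_size_k,
                    seed=seed,
                )
                nuc, prot, truth = simulate_field(spec)
                field_id = f"c{ci:04d}_d{di}_f{fi}"
                fields[field_id] = (nuc, prot, truth)
                metadata_rows.append(
                    {
                        "field_id": field_id,
                        "nuclear_path": f"{field_id}_dna.tif",
                        "protein_path": f"{field_id}_protein.tif",
                        "well": f"{comp.name}:{di}",
                        "compound": comp.name,
                        "moa": comp.moa,
                        "concentration_m": conc,
                        "cell_line": screen.cell_line,
                    }
                )

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for row in metadata_rows:
            nuc, prot, _ = fields[row["field_id"]]
            tifffile.imwrite(os.path.join(out_dir, row["nuclear_path"]), nuc)
            tifffile.imwrite(os.path.join(out_dir, row["protein_path"]), prot)
        _write_csv(os.path.join(out_dir, "metadata.csv"), metadata_rows)
        _write_csv(os.path.join(out_dir, "truth.csv"), truth_rows)
    return fields, metadata_rows, truth_rows


def _write_csv(path: str, rows: Sequence[dict]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


def field_checksum(*arrays: np.ndarray) -> str:
    """SHA-256 over raw pixel data; used by determinism tests."""
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()
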