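"""Synthetic ground truth: drug-response trajectories and spheroid renders.

The generator stands in for the wet-lab screen so the whole pipeline can be
exercised with known truth.  It has two layers:

1.  **Pharmacodynamics** — each well grows one spheroid from 750 seeded
    cells under logistic growth; during the two drug-exposure windows the
    combination removes cells at a hazard proportional to ``-ln(1 - e)``
    where ``e`` is the Bliss-structured joint effect of the two doses (plus
    a tunable excess term ``synergy_alpha``).  With ``synergy_alpha = 0``
    and effectively exponential growth this makes the true viability matrix
    exactly Bliss-multiplicative (``V12 = V1 * V2 / 100``), which is the
    additive-truth oracle the synergy stage is validated against.
2.  **Rendering** — one phase-contrast-like grayscale image per well per
    imaging day: a dark disk whose radius scales with the cube root of the
    cell count (volume ∝ cells), a bright halo, a linear illumination
    gradient, speckle noise and occasional debris blobs.

All pharmacology constants here are stand-ins: the real screen's growth
rates and potencies were never published, so defaults are chosen to give a
well-spread 0–100 % endpoint viability range across the dose grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .study_design import StudyDesign, enumerate_wells

__all__ = [
    "DrugResponseParams",
    "GrowthParams",
    "RenderParams",
    "SpheroidImage",
    "hill_effect",
    "drug_effect",
    "default_response_params",
    "simulate_trajectories",
    "render_spheroid",
    "write_dataset",
    "generate_dataset",
]


@dataclass(frozen=True)
class DrugResponseParams:
    """True (simulated) pharmacology of one drug pair on one cell line.

    ``ec50_*`` (µM) and ``hill_*`` parameterize each drug's Hill effect
    ``e_i = d^h / (d^h + ec50^h)`` in [0, 1).  ``max_kill_rate`` (1/day) is
    the hazard scale shared by the pair — a single rate keeps the
    additive-truth Bliss identity exact.  Its default, 0.125 = 1 / (8 days
    of total exposure), is chosen so a full two-window course at joint
    effect ``e`` leaves survival exactly ``1 - e``: the true endpoint
    monotherapy curves are then themselves four-parameter log-logistic,
    the family the synergy stage fits.  ``synergy_alpha`` adds the excess
    joint effect ``alpha * e1 * e2``; 0 means Bliss-additive truth,
    positive means true synergy, negative antagonism.
    """

    ec50_1: float
    ec50_2: float
    hill_1: float = 1.5
    hill_2: float = 1.5
    max_kill_rate: float = 0.125
    synergy_alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50_1 <= 0 or self.ec50_2 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill_1 <= 0 or self.hill_2 <= 0:
            raise ValueError("hill slope must be positive")
        if self.max_kill_rate < 0:
            raise ValueError("max_kill_rate must be non-negative")


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth of the untreated spheroid.

    Defaults: 750 seeded cells (one spheroid per round-bottom well), growth
    rate 0.35/day and a high carrying capacity so growth stays effectively
    exponential over the 18-day window (~4e5 cells at day 18).
    """

    growth_rate: float = 0.35
    initial_cells: float = 750.0
    capacity: float = 1e8

    def __post_init__(self) -> None:
        if min(self.growth_rate, self.initial_cells, self.capacity) <= 0:
            raise ValueError("growth parameters must be positive")
        if self.initial_cells > self.capacity:
            raise ValueError("initial_cells must not exceed capacity")


@dataclass(frozen=True)
class RenderParams:
    """Rendering knobs for the synthetic phase-contrast look."""

    image_size: int = 128
    radius_scale: float = 0.30  # px per cell^(1/3)
    background_level: float = 0.72
    background_gradient_amp: float = 0.08
    speckle_sd: float = 0.02
    artifact_rate: float = 1.0  # expected debris blobs per image
    halo_width: float = 2.5
    disk_level: float = 0.25
    center_jitter: float = 2.0  # px, uniform jitter of the spheroid center

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if min(self.speckle_sd, self.background_gradient_amp, self.artifact_rate) < 0:
            raise ValueError("noise amplitudes must be non-negative")


@dataclass
class SpheroidImage:
    """One rendered well image plus the generator's truth for testing."""

    image: np.ndarray  # float in [0, 1], shape (size, size)
    center: tuple[float, float]  # (row, col) of the spheroid center, px
    radius: float  # disk radius, px (0 for an empty well)
    debris_mask: np.ndarray | None = None  # bool mask of debris pixels
    meta: dict = field(default_factory=dict)


def hill_effect(dose: float | np.ndarray, ec50: float, hill: float) -> float | np.ndarray:
    """Fractional effect of a single drug, 0 at zero dose, ->1 at saturation."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (d / ec50) ** hill, 0.0)
    out = ratio / (1.0 + ratio)
    return float(out) if np.isscalar(dose) else out


def drug_effect(d1: float, d2: float, p: DrugResponseParams) -> float:
    """Joint kill fraction of the pair at doses (d1, d2) µM, clipped to [0, 1].

    Bliss-structured: ``e = e1 + e2 - e1*e2 + alpha*e1*e2`` with ``e_i`` the
    per-drug Hill effects, so ``alpha = 0`` composes the drugs independently.
    """
    if d1 < 0 or d2 < 0:
        raise ValueError("doses must be non-negative")
    e1 = hill_effect(d1, p.ec50_1, p.hill_1)
    e2 = hill_effect(d2, p.ec50_2, p.hill_2)
    e = e1 + e2 - e1 * e2 + p.synergy_alpha * e1 * e2
    return float(np.clip(e, 0.0, 1.0))


#: Fixed seed for the stand-in pharmacology draw below: part of the study
#: definition, deliberately independent of any run seed.
_PHARMACOLOGY_SEED = 9001


def default_response_params(
    design: StudyDesign, synergy_alpha: float = 0.0
) -> dict[tuple[str, int], DrugResponseParams]:
    """One parameter set per (cell line, pair index), anchored to the doses.

    Real screens combine drugs of different potency and steepness, so each
    (line, pair) receives its own deterministic draw: the EC50 of each drug
    lands log-uniformly between the second- and fourth-highest dose of its
    dilution series (so every monotherapy row sweeps a wide viability
    range) and Hill slopes land uniformly in [1.0, 2.5].  The draw is fixed
    by a module constant — it defines the simulated screen, not its noise —
    so the same design always means the same pharmacology.
    """
    rng = np.random.default_rng(_PHARMACOLOGY_SEED)
    f = design.dilution_factor
    out: dict[tuple[str, int], DrugResponseParams] = {}
    for line in design.cell_lines:
        for k, pair in enumerate(design.drug_pairs):
            m1, m2 = pair.max_conc[line]
            lo, hi = np.log(1.0 / f**3), np.log(1.0 / f)
            s1, s2 = np.exp(rng.uniform(lo, hi, size=2))
            h1, h2 = rng.uniform(1.0, 2.5, size=2)
            out[(line, k)] = DrugResponseParams(
                ec50_1=m1 * s1,
                ec50_2=m2 * s2,
                hill_1=h1,
                hill_2=h2,
                synergy_alpha=synergy_alpha,
            )
    return out


def _exposure_hazard_scale(day: float, windows: Iterable[tuple[int, int]]) -> float:
    return 1.0 if any(s <= day < e for s, e in windows) else 0.0


def simulate_trajectories(
    design: StudyDesign,
    growth: GrowthParams | None = None,
    responses: Mapping[tuple[str, int], DrugResponseParams] | None = None,
    noise_sd: float = 5.0,
    seed: int = 0,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Integrate per-well cell counts and emit one record per well per day.

    Dynamics (fixed-step explicit Euler, step ``dt`` days)::

        dN/dt = g * N * (1 - N/K)  -  k * (-ln(1 - e)) * N   (during exposure)

    where ``e`` is the joint :func:`drug_effect` of the well's doses.  The
    hazard form ``-ln(1-e)`` equals ``e`` to first order and makes the true
    endpoint viabilities exactly Bliss-multiplicative when
    ``synergy_alpha = 0`` and growth is exponential.

    Returns a tidy DataFrame with, per (well, imaging day):
    ``true_cell_count``, ``true_viability_pct`` (noise-free ratio to the
    same-plate untreated well, the quantity the rendered image encodes) and
    ``measured_viability_pct`` (truth plus truncated Gaussian assay noise,
    sd ``noise_sd`` %; the untreated well is pinned to exactly 100).
    """
    growth = growth or GrowthParams()
    if responses is None:
        responses = default_response_params(design)
    for s, e in design.exposure_windows:
        if e > max(design.imaging_days):
            raise ValueError(f"exposure window ({s}, {e}) outside study days")

    wells = enumerate_wells(design)
    rng = np.random.default_rng(seed)

    # Per-well constant hazard multiplier k * (-ln(1 - e)).
    hazards = np.empty(len(wells))
    for idx, w in enumerate(wells.itertuples()):
        p = responses[(w.cell_line, w.pair_index)]
        e = drug_effect(w.dose1_uM, w.dose2_uM, p)
        e = min(e, 1.0 - 1e-12)
        hazards[idx] = p.max_kill_rate * (-math.log1p(-e))

    n_steps = int(round(max(design.imaging_days) / dt))
    days_wanted = set(design.imaging_days)
    counts = np.full(len(wells), growth.initial_cells)
    snapshots: dict[int, np.ndarray] = {}
    if 0 in days_wanted:
        snapshots[0] = counts.copy()
    for step in range(n_steps):
        t = step * dt
        exposed = _exposure_hazard_scale(t, design.exposure_windows)
        # Multiplicative (exponential-Euler) update: exact for piecewise-
        # constant net rates, so exponential-growth runs obey the Bliss
        # product identity to machine precision rather than O(dt).
        rate = growth.growth_rate * (1.0 - counts / growth.capacity)
        if exposed:
            rate = rate - hazards
        counts = counts * np.exp(dt * rate)
        day = (step + 1) * dt
        day_int = int(round(day))
        if abs(day - day_int) < dt / 2 and day_int in days_wanted:
            snapshots[day_int] = counts.copy()

    records = []
    untreated = ((wells["row"] == 0) & (wells["col"] == 0)).to_numpy()
    unt_plates = wells.loc[untreated, "plate_id"].to_numpy()
    for day in design.imaging_days:
        n = snapshots[day]
        ref_by_plate = dict(zip(unt_plates, n[untreated]))
        ref = wells["plate_id"].map(ref_by_plate).to_numpy()
        true_v = 100.0 * n / ref
        noise = rng.normal(0.0, noise_sd, size=len(n))
        measured = np.maximum(true_v + noise, 0.0)
        measured[untreated] = 100.0
        day_df = wells.copy()
        day_df["day"] = day
        day_df["true_cell_count"] = n
        day_df["true_viability_pct"] = true_v
        day_df["measured_viability_pct"] = measured
        records.append(day_df)
    return pd.concat(records, ignore_index=True)


def render_spheroid(
    true_cell_count: float, rp: RenderParams | None = None, seed: int = 0
) -> SpheroidImage:
    """Render one synthetic well image, deterministic given (count, rp, seed)."""
    if true_cell_count < 0:
        raise ValueError("cell count must be non-negative")
    rp = rp or RenderParams()
    rng = np.random.default_rng(seed)
    s = rp.image_size

    # Linear illumination gradient in a random direction.
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    ramp = (np.cos(theta) * xx + np.sin(theta) * yy) / s - 0.5
    img = rp.background_level + rp.background_gradient_amp * ramp

    radius = rp.radius_scale * true_cell_count ** (1.0 / 3.0)
    jitter = rng.uniform(-rp.center_jitter, rp.center_jitter, size=2)
    center = (s / 2 + jitter[0], s / 2 + jitter[1])
    if true_cell_count > 0 and radius >= 0.5:
        r = np.hypot(yy - center[0], xx - center[1])
        # Soft-edged dark disk with a bright halo ring just outside it.
        edge = 1.0 / (1.0 + np.exp((r - radius) / 0.75))
        img = img * (1 - edge) + rp.disk_level * edge
        halo = np.exp(-0.5 * ((r - radius - rp.halo_width) / rp.halo_width) ** 2)
        img += 0.12 * halo * (1 - edge)
    else:
        radius = 0.0

    debris_mask = np.zeros((s, s), dtype=bool)
    n_blobs = rng.poisson(rp.artifact_rate)
    for _ in range(n_blobs):
        by, bx = rng.uniform(2, s - 2, size=2)
        br = rng.uniform(1.0, 3.5)
        level = rng.uniform(0.1, 0.4)
        r = np.hypot(yy - by, xx - bx)
        blob = r <= br
        img[blob] = level
        debris_mask |= blob

    img += rng.normal(0.0, rp.speckle_sd, size=(s, s))
    img = np.clip(img, 0.0, 1.0)
    return SpheroidImage(
        image=img,
        center=center,
        radius=radius,
        debris_mask=debris_mask,
        meta={"true_cell_count": float(true_cell_count)},
    )


def _filename(plate: str, row: int, col: int, day: int) -> str:
    return f"{plate}__r{row}c{col}__d{day:02d}.png"


def write_dataset(
    records: pd.DataFrame,
    images: Mapping[str, np.ndarray],
    out_dir: str | Path,
    endpoint_day: int | None = None,
) -> dict[str, Path]:
    """Write images + metadata/labels/ground-truth CSVs.

    ``records`` must carry one row per image keyed by ``filename`` present
    in ``images``.  The labels CSV contains the measured endpoint viability
    only (the lysing assay is read once, on the final day); the ground-truth
    CSV keeps every day's true and measured values for evaluation.
    """
    records = records.reset_index(drop=True)
    if len(records) and "filename" not in records.columns:
        raise ValueError("records must carry a 'filename' column")
    if "filename" not in records.columns:
        records["filename"] = pd.Series(dtype=str)
    if "day" not in records.columns:
        records["day"] = pd.Series(dtype=int)
    missing = set(records["filename"]) - set(images)
    if missing:
        raise ValueError(f"no image provided for {len(missing)} records")
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    for fname in records["filename"]:
        arr = np.clip(images[fname], 0.0, 1.0)
        iio.imwrite(img_dir / fname, (arr * 255).round().astype(np.uint8))

    meta_cols = [
        "filename", "plate_id", "cell_line", "drug1", "drug2", "pair_index",
        "pair", "replicate", "row", "col", "dose1_uM", "dose2_uM", "day",
    ]
    meta_cols = [c for c in meta_cols if c in records.columns]
    paths = {
        "images": img_dir,
        "metadata": out / "metadata.csv",
        "labels": out / "labels.csv",
        "ground_truth": out / "ground_truth.csv",
    }
    records[meta_cols].to_csv(paths["metadata"], index=False)

    if endpoint_day is None:
        endpoint_day = int(records["day"].max()) if len(records) else 0
    is_endpoint = records["day"] == endpoint_day
    label_cols = meta_cols + ["measured_viability_pct"]
    label_cols = [c for c in label_cols if c in records.columns]
    records.loc[is_endpoint, label_cols].rename(
        columns={"measured_viability_pct": "viability_pct"}
    ).to_csv(paths["labels"], index=False)

    gt_cols = [c for c in meta_cols + ["true_cell_count", "true_viability_pct",
                                       "measured_viability_pct"] if c in records.columns]
    records[gt_cols].to_csv(paths["ground_truth"], index=False)
    return paths


def generate_dataset(
    design: StudyDesign,
    out_dir: str | Path,
    growth: GrowthParams | None = None,
    responses: Mapping[tuple[str, int], DrugResponseParams] | None = None,
    render_params: RenderParams | None = None,
    noise_sd: float = 5.0,
    n_empty_wells: int = 8,
    seed: int = 0,
) -> dict[str, Path]:
    """Simulate a full study and write it to disk (images + CSVs).

    Renders one image per well per imaging day plus ``n_empty_wells``
    empty-well reference images (labelled 0 % viability at the endpoint,
    mimicking the screen's empty-well training references).  Trajectory
    noise and rendering noise are independently seeded from ``seed``.
    """
    rp = render_params or RenderParams()
    traj = simulate_trajectories(
        design, growth=growth, responses=responses, noise_sd=noise_sd, seed=seed
    )
    traj["filename"] = [
        _filename(p, r, c, d)
        for p, r, c, d in zip(traj["plate_id"], traj["row"], traj["col"], traj["day"])
    ]
    seed_rng = np.random.default_rng(seed + 1)
    images: dict[str, np.ndarray] = {}
    for rec in traj.itertuples():
        sph = render_spheroid(
            rec.true_cell_count, rp, seed=int(seed_rng.integers(2**31))
        )
        images[rec.filename] = sph.image

    empties = []
    for k in range(n_empty_wells):
        fname = f"empty__{k:03d}__d{design.endpoint_day:02d}.png"
        sph = render_spheroid(0.0, rp, seed=int(seed_rng.integers(2**31)))
        images[fname] = sph.image
        empties.append(
            {
                "filename": fname,
                "plate_id": "empty",
                "cell_line": "none",
                "pair": "empty",
                "pair_index": -1,
                "replicate": 0,
                "row": -1,
                "col": -1,
                "day": design.endpoint_day,
                "true_cell_count": 0.0,
                "true_viability_pct": 0.0,
                "measured_viability_pct": 0.0,
            }
        )
    if empties:
        traj = pd.concat([traj, pd.DataFrame(empties)], ignore_index=True)
    return write_dataset(traj, images, out_dir, endpoint_day=design.endpoint_day)
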