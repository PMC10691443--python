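"""Drug-interaction scoring from 6x6 viability dose matrices.

Given a checkerboard matrix of % viabilities (row = drug-1 dose, column =
drug-2 dose, both ascending from zero), the monotherapy margins (first row
and first column) are fitted with four-parameter log-logistic (Hill)
curves.  From the fitted curves three additive reference surfaces are
built:

* **Bliss independence** — ``V_ref = V_A(d1) * V_B(d2) / 100`` (independent
  action on the fractional survival scale);
* **Loewe additivity** — the viability ``V`` solving the dose-equivalence
  relation ``d1/D_A(V) + d2/D_B(V) = 1`` with ``D_X`` the inverse Hill
  dose (sham combinations are exactly additive under this reference);
* **HSA** — the better (lower-viability) of the two monotherapies.

Synergy is the signed gap between reference (theoretical, upper) and
observed (experimental, lower) surfaces: ``delta = reference − observed``
per cell, positive where the combination kills more than the additive
expectation, summarized as the mean delta over the 25 combination wells
(a dose-step-weighted volume is also reported).

Replicate and missing-value handling follows the screen's rules: a matrix
with any missing monotherapy cell is excluded entirely; missing interior
cells are imputed at 100 % viability; surviving technical replicates are
averaged cellwise, and a lone surviving replicate is used as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "DoseMatrix",
    "HillParams",
    "SynergyResult",
    "merge_replicates",
    "apply_missing_rules",
    "fit_monotherapy",
    "hill_viability",
    "bliss_reference",
    "hsa_reference",
    "loewe_reference",
    "synergy_map",
    "compute_all",
    "matrices_from_viability",
]

METHODS = ("LOEWE", "BLISS", "HSA")


@dataclass
class DoseMatrix:
    """% viability grid aligned to two ascending dose axes (first entry 0).

    Missing cells are NaN.  Cell (0, 0) is the untreated reference; the
    first row / first column are the drug-2 / drug-1 monotherapies.
    """

    doses1: np.ndarray
    doses2: np.ndarray
    values: np.ndarray
    provenance: str = "measured"  # measured | predicted
    pair: str = ""
    cell_line: str = ""
    day: int = -1
    replicate: int = 0

    def __post_init__(self) -> None:
        self.doses1 = np.asarray(self.doses1, dtype=float)
        self.doses2 = np.asarray(self.doses2, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.doses1), len(self.doses2)):
            raise ValueError(
                f"values shape {self.values.shape} does not match dose axes "
                f"({len(self.doses1)}, {len(self.doses2)})"
            )
        for d in (self.doses1, self.doses2):
            if d[0] != 0 or np.any(np.diff(d) <= 0):
                raise ValueError("dose axes must ascend from 0")
        if np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("viability values must be non-negative")

    @property
    def monotherapy_mask(self) -> np.ndarray:
        m = np.zeros_like(self.values, dtype=bool)
        m[0, :] = True
        m[:, 0] = True
        return m

    @property
    def combination_mask(self) -> np.ndarray:
        return ~self.monotherapy_mask

    def copy(self) -> "DoseMatrix":
        return replace(self, values=self.values.copy())


@dataclass(frozen=True)
class HillParams:
    """Four-parameter log-logistic monotherapy curve on the viability scale.

    ``V(d) = emax + (e0 − emax) / (1 + (d / ec50)^slope)`` — ``e0`` the
    zero-dose viability, ``emax`` the infinite-dose floor, ``ec50`` in µM.
    ``flat`` marks a degenerate fit (inactive drug), ``poor_fit`` a curve
    that rises with dose beyond tolerance.
    """

    e0: float
    emax: float
    ec50: float
    slope: float
    flat: bool = False
    poor_fit: bool = False

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.slope <= 0:
            raise ValueError("ec50 and slope must be positive")
        if self.emax > self.e0 + 1e-9:
            raise ValueError("emax must not exceed e0")


def hill_viability(d: float | np.ndarray, p: HillParams) -> float | np.ndarray:
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (d / p.ec50) ** p.slope, 0.0)
    out = p.emax + (p.e0 - p.emax) / (1.0 + ratio)
    return float(out) if out.ndim == 0 else out


def _inverse_hill(v: float, p: HillParams) -> float:
    """Dose producing viability ``v``; inf below emax, 0 above e0."""
    if v >= p.e0:
        return 0.0
    if v <= p.emax:
        return np.inf
    return p.ec50 * ((p.e0 - v) / (v - p.emax)) ** (1.0 / p.slope)


@dataclass
class SynergyResult:
    """Reference-minus-observed synergy surface for one matrix and method."""

    method: str
    reference: np.ndarray
    delta: np.ndarray  # reference − observed; NaN where observed missing
    score: float  # mean delta over combination wells
    volume: float  # dose-step-weighted delta integral (log-dose steps)
    n_wells_used: int
    pair: str = ""
    cell_line: str = ""
    day: int = -1
    provenance: str = ""
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Replicate merging and missing-data rules
# ---------------------------------------------------------------------------

def _check_compatible(m1: DoseMatrix, m2: DoseMatrix) -> None:
    if not (
        np.array_equal(m1.doses1, m2.doses1)
        and np.array_equal(m1.doses2, m2.doses2)
    ):
        raise ValueError("replicate matrices have mismatched dose axes")


def merge_replicates(m1: DoseMatrix, m2: DoseMatrix) -> DoseMatrix:
    """Cellwise mean where both replicates are present; the lone value where
    only one is; NaN where both are missing."""
    _check_compatible(m1, m2)
    stacked = np.stack([m1.values, m2.values])
    present = ~np.isnan(stacked)
    count = present.sum(axis=0)
    merged = np.where(
        count > 0, np.nansum(np.where(present, stacked, 0.0), axis=0) / np.maximum(count, 1), np.nan
    )
    return replace(m1, values=merged, replicate=0)


def apply_missing_rules(
    m1: DoseMatrix, m2: DoseMatrix | None = None
) -> list[DoseMatrix]:
    """Apply the screen's missing-value policy to a replicate pair.

    A matrix with any missing monotherapy (first-row or first-column) cell
    is dropped entirely; in the survivors, missing interior cells are
    imputed at 100 % viability.  Returns the 0, 1, or 2 usable matrices.
    """
    usable = []
    for m in (m1, m2):
        if m is None:
            continue
        if np.isnan(m.values[m.monotherapy_mask]).any():
            logger.info(
                "matrix %s/%s rep%s day%s dropped: missing monotherapy cell",
                m.pair, m.cell_line, m.replicate, m.day,
            )
            continue
        fixed = m.copy()
        interior_nan = np.isnan(fixed.values) & fixed.combination_mask
        fixed.values[interior_nan] = 100.0
        usable.append(fixed)
    return usable


# ---------------------------------------------------------------------------
# Monotherapy curve fitting
# ---------------------------------------------------------------------------

#: Fit bounds: e0 near the normalized control (80–120 %), emax within the
#: viability scale, ec50 within two decades of the tested range, slope
#: within the pharmacologically plausible band.
_E0_BOUNDS = (80.0, 120.0)
_EMAX_BOUNDS = (0.0, 100.0)
_SLOPE_BOUNDS = (0.2, 10.0)


def fit_monotherapy(
    doses: Sequence[float], viabilities: Sequence[float]
) -> HillParams:
    """Least-squares Hill fit of one monotherapy margin.

    Multi-start over log-spaced EC50 seeds; the best-residual fit wins.
    All-equal viabilities yield a flagged flat fit; a dose-response that
    *increases* with dose beyond 5 % is flagged ``poor_fit`` but still
    returned.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    keep = np.isfinite(v)
    d, v = d[keep], v[keep]
    if len(d) < 4 or 0.0 not in d:
        raise ValueError("need >= 4 dose points including zero")

    if np.ptp(v) < 1e-9:
        level = float(v.mean())
        return HillParams(
            e0=level, emax=level, ec50=max(float(d[d > 0].min()), 1e-6),
            slope=1.0, flat=True,
        )

    nonzero = d[d > 0]
    ec50_lo = float(nonzero.min()) / 100.0
    ec50_hi = float(nonzero.max()) * 100.0
    lb = np.array([_E0_BOUNDS[0], _EMAX_BOUNDS[0], np.log(ec50_lo), _SLOPE_BOUNDS[0]])
    ub = np.array([_E0_BOUNDS[1], _EMAX_BOUNDS[1], np.log(ec50_hi), _SLOPE_BOUNDS[1]])

    def residuals(theta: np.ndarray) -> np.ndarray:
        e0, emax, log_ec50, slope = theta
        p = np.exp(log_ec50)
        with np.errstate(divide="ignore"):
            ratio = np.where(d > 0, (d / p) ** slope, 0.0)
        return emax + (e0 - emax) / (1.0 + ratio) - v

    e0_start = float(np.clip(v[d == 0].mean(), *_E0_BOUNDS))
    emax_start = float(np.clip(v.min(), 0.0, 99.0))
    best = None
    for ec50_seed in np.geomspace(nonzero.min(), nonzero.max(), 5):
        x0 = np.array([e0_start, emax_start, np.log(ec50_seed), 1.0])
        x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)
        sol = least_squares(residuals, x0, bounds=(lb, ub), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    e0, emax, log_ec50, slope = best.x
    emax = min(emax, e0)  # numerical guard; bounds already imply this
    # Rising dose-response (viability increasing with dose) -> poor fit flag.
    order = np.argsort(d)
    rises = float(np.max(np.maximum(np.diff(v[order]), 0.0), initial=0.0))
    return HillParams(
        e0=float(e0), emax=float(emax), ec50=float(np.exp(log_ec50)),
        slope=float(slope), poor_fit=rises > 5.0,
    )


# ---------------------------------------------------------------------------
# Reference surfaces
# ---------------------------------------------------------------------------

def bliss_reference(
    hA: HillParams, hB: HillParams, doses1: Sequence[float], doses2: Sequence[float]
) -> np.ndarray:
    """Independent-action surface: product of fitted monotherapy viabilities."""
    vA = hill_viability(np.asarray(doses1, float), hA)
    vB = hill_viability(np.asarray(doses2, float), hB)
    return np.outer(vA, vB) / 100.0


def hsa_reference(
    hA: HillParams, hB: HillParams, doses1: Sequence[float], doses2: Sequence[float]
) -> np.ndarray:
    """Highest-single-agent surface: the lower of the two monotherapies."""
    vA = hill_viability(np.asarray(doses1, float), hA)
    vB = hill_viability(np.asarray(doses2, float), hB)
    return np.minimum.outer(vA, vB)


def loewe_reference(
    hA: HillParams,
    hB: HillParams,
    doses1: Sequence[float],
    doses2: Sequence[float],
    tol: float = 1e-9,
) -> np.ndarray:
    """Dose-equivalence (Loewe) surface solved cellwise by bracketed root
    finding on the viability axis.

    For each cell the reference viability ``V`` satisfies
    ``d1 / D_A(V) + d2 / D_B(V) = 1``; a drug that cannot reach the effect
    level ``V`` (``V < emax``) contributes 0 to the sum.  If even the
    deepest jointly reachable effect leaves the sum above 1, the cell is
    clamped to that bound; if both curves are flat the reference is the
    untreated plane (caller flags it).
    """
    d1 = np.asarray(doses1, float)
    d2 = np.asarray(doses2, float)
    out = np.empty((len(d1), len(d2)))
    if hA.flat and hB.flat:
        out[:] = (hA.e0 + hB.e0) / 2.0
        return out
    if hA.flat:  # inactive drug 1: reference collapses to drug 2's curve
        out[:] = hill_viability(d2, hB)[None, :]
        return out
    if hB.flat:
        out[:] = hill_viability(d1, hA)[:, None]
        return out

    v_top = min(hA.e0, hB.e0)
    v_bot = max(hA.emax, hB.emax)

    def interaction_sum(v: float, a: float, b: float) -> float:
        total = 0.0
        for dose, curve in ((a, hA), (b, hB)):
            if dose <= 0:
                continue
            denom = _inverse_hill(v, curve)
            if np.isfinite(denom) and denom > 0:
                total += dose / denom
            elif denom == 0.0:
                total += np.inf
        return total

    eps = 1e-12
    for i, a in enumerate(d1):
        for j, b in enumerate(d2):
            if a <= 0 and b <= 0:
                out[i, j] = (hA.e0 + hB.e0) / 2.0
                continue
            if a <= 0:
                out[i, j] = hill_viability(b, hB)
                continue
            if b <= 0:
                out[i, j] = hill_viability(a, hA)
                continue
            lo = v_bot + eps if np.isfinite(v_bot) else eps
            hi = v_top - eps
            f = lambda v: interaction_sum(v, a, b) - 1.0
            # f increases with v: doses buy more than a full dose-equivalent
            # even at the deepest jointly reachable effect -> clamp there.
            if f(lo) >= 0:
                out[i, j] = v_bot
            elif f(hi) <= 0:
                out[i, j] = v_top
            else:
                out[i, j] = brentq(f, lo, hi, xtol=tol, rtol=8.9e-16)
    return out


_REFERENCE_BUILDERS = {
    "BLISS": bliss_reference,
    "HSA": hsa_reference,
    "LOEWE": loewe_reference,
}


# ---------------------------------------------------------------------------
# Synergy maps and orchestration
# ---------------------------------------------------------------------------

def synergy_map(
    observed: DoseMatrix, reference: np.ndarray, method: str
) -> SynergyResult:
    """Signed synergy surface and scalar score for one matrix.

    ``delta = reference − observed``: positive where the observed viability
    falls below the additive expectation (synergy).  The score is the mean
    delta over wells where both doses are non-zero; ``volume`` weights each
    cell by its log-dose step area (outermost steps use the neighboring
    step width).
    """
    if reference.shape != observed.values.shape:
        raise ValueError("reference and observed shapes differ")
    delta = reference - observed.values
    combo = observed.combination_mask & np.isfinite(observed.values)
    n = int(combo.sum())
    if n == 0:
        raise ValueError("no combination wells present: score undefined")
    score = float(delta[combo].mean())

    def _steps(doses: np.ndarray) -> np.ndarray:
        logs = np.log(doses[1:])  # combination wells exclude the zero dose
        w = np.gradient(logs) if len(logs) > 1 else np.ones(1)
        return w

    w1 = _steps(observed.doses1)
    w2 = _steps(observed.doses2)
    cell_area = np.outer(w1, w2)
    inner = delta[1:, 1:]
    inner_ok = combo[1:, 1:]
    volume = float(np.nansum(np.where(inner_ok, inner * cell_area, 0.0)))

    return SynergyResult(
        method=method,
        reference=reference,
        delta=np.where(np.isfinite(observed.values), delta, np.nan),
        score=score,
        volume=volume,
        n_wells_used=n,
        pair=observed.pair,
        cell_line=observed.cell_line,
        day=observed.day,
        provenance=observed.provenance,
    )


def _fit_margins(m: DoseMatrix) -> tuple[HillParams, HillParams]:
    hA = fit_monotherapy(m.doses1, m.values[:, 0])  # drug 1: first column
    hB = fit_monotherapy(m.doses2, m.values[0, :])  # drug 2: first row
    return hA, hB


def compute_all(
    matrices: Iterable[tuple[DoseMatrix, DoseMatrix | None]],
    methods: Sequence[str] = METHODS,
) -> list[SynergyResult]:
    """Run the full replicate → missing-rules → fit → surface → score chain.

    ``matrices`` yields replicate pairs (the second member may be None) for
    each (pair, line, day).  Samples whose replicates are all excluded by
    the monotherapy rule are absent from the output (logged), matching the
    screen's whole-sample exclusion policy.
    """
    results: list[SynergyResult] = []
    for m1, m2 in matrices:
        usable = apply_missing_rules(m1, m2)
        if not usable:
            logger.info(
                "sample %s/%s day%s excluded: no usable replicate",
                m1.pair, m1.cell_line, m1.day,
            )
            continue
        merged = usable[0] if len(usable) == 1 else merge_replicates(*usable)
        hA, hB = _fit_margins(merged)
        flags = tuple(
            f for f, on in (
                ("flat_drug1", hA.flat), ("flat_drug2", hB.flat),
                ("poor_fit_drug1", hA.poor_fit), ("poor_fit_drug2", hB.poor_fit),
                ("single_replicate", len(usable) == 1),
            ) if on
        )
        for method in methods:
            ref = _REFERENCE_BUILDERS[method.upper()](
                hA, hB, merged.doses1, merged.doses2
            )
            res = synergy_map(merged, ref, method.upper())
            res.flags = flags
            results.append(res)
    return results


def matrices_from_viability(
    df: pd.DataFrame,
    value_column: str = "viability_pct",
    provenance: str = "measured",
) -> list[tuple[DoseMatrix, DoseMatrix | None]]:
    """Group a tidy viability table into replicate matrix pairs.

    ``df`` needs columns ``pair, cell_line, day, replicate, row, col,
    dose1_uM, dose2_uM`` and the value column.  Cells absent from the table
    (or NaN, e.g. a plate-day flagged missing by normalization) become NaN
    matrix entries.  Returns one (replicate-1, replicate-2-or-None) tuple
    per (pair, cell_line, day), ordered by group key.
    """
    out: list[tuple[DoseMatrix, DoseMatrix | None]] = []
    for (pair, line, day), grp in df.groupby(["pair", "cell_line", "day"], sort=True):
        d1 = np.sort(grp["dose1_uM"].unique())
        d2 = np.sort(grp["dose2_uM"].unique())
        reps = []
        for rep, rgrp in grp.groupby("replicate", sort=True):
            vals = np.full((len(d1), len(d2)), np.nan)
            i = np.searchsorted(d1, rgrp["dose1_uM"].to_numpy())
            j = np.searchsorted(d2, rgrp["dose2_uM"].to_numpy())
            vals[i, j] = rgrp[value_column].to_numpy(float)
            reps.append(
                DoseMatrix(
                    doses1=d1, doses2=d2, values=vals, provenance=provenance,
                    pair=pair, cell_line=line, day=int(day), replicate=int(rep),
                )
            )
        out.append((reps[0], reps[1] if len(reps) > 1 else None))
    return out
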