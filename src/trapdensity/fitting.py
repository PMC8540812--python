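"""Release–recapture datasets and the two-step parameter-fitting protocol.

Marked insects are released at a ladder of distances from a single trap and
the recaptured proportion at each distance estimates the catch probability
spTfer(r).  Two parameters are extracted from such a table:

* **Step 1** fits the untransformed curve
  ``p = sptfer0 / (1 + (r/d50)**2)`` with both parameters free; only its
  ``sptfer0`` estimate is kept.  (Skipped when spTfer(0) was measured
  directly in the field.)
* **Step 2** fixes ``sptfer0`` and fits the log-transformed curve
  ``ln p = ln sptfer0 - ln(1 + (r/d50)**2)`` with ``d50`` as the single
  free parameter.  Working on the log scale gives the sparse, low-count
  observations at large distances the same weight as the near-trap points,
  which dominate an untransformed fit.

Zero-catch records have no logarithm and are excluded from step 2 (and
listed in the result); no pseudo-count is offered, since adding one would
silently change the estimator.  Both steps use unweighted ordinary least
squares by default; ``weighted=True`` uses the per-record SEMs when present.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .model import TrapSystemParams, sp_t_fer

__all__ = [
    "DistanceCatchRecord",
    "ReleaseRecaptureDataset",
    "FitResult",
    "FitError",
    "validate_dataset",
    "fit_step1_untransformed",
    "fit_step2_log",
    "fit_two_step",
    "fit_with_known_sptfer0",
]


class FitError(RuntimeError):
    """A parameter fit could not be carried out or did not converge."""


@dataclass(frozen=True)
class DistanceCatchRecord:
    """One row of a release–recapture table.

    ``proportion`` is filled in from the counts when omitted; when both are
    given they must agree to 1e-9.  ``sem`` is the standard error of the
    recapture proportion (optional; some published tables omit it).
    """

    distance: float
    n_released: int
    n_caught: int
    proportion: float | None = None
    sem: float | None = None

    def __post_init__(self) -> None:
        if self.distance < 0.0 or not math.isfinite(self.distance):
            raise ValueError(f"distance must be finite and >= 0, got {self.distance!r}")
        if self.n_released < 0 or self.n_caught < 0:
            raise ValueError("counts must be >= 0")
        if self.n_caught > self.n_released:
            raise ValueError(
                f"n_caught ({self.n_caught}) exceeds n_released ({self.n_released}) "
                f"at distance {self.distance} m"
            )
        implied = self.n_caught / self.n_released if self.n_released > 0 else 0.0
        if self.proportion is None:
            object.__setattr__(self, "proportion", implied)
        elif abs(self.proportion - implied) > 1e-9:
            raise ValueError(
                f"proportion {self.proportion} inconsistent with counts "
                f"{self.n_caught}/{self.n_released} at distance {self.distance} m"
            )
        if self.sem is not None and self.sem < 0.0:
            raise ValueError("sem must be >= 0")


@dataclass(frozen=True)
class ReleaseRecaptureDataset:
    """A distance ladder of recapture records, kept sorted by distance."""

    records: tuple[DistanceCatchRecord, ...]
    species: str = ""
    trap_type: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "records", tuple(sorted(self.records, key=lambda rec: rec.distance))
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def distances(self) -> np.ndarray:
        return np.array([rec.distance for rec in self.records], dtype=float)

    @property
    def proportions(self) -> np.ndarray:
        return np.array([rec.proportion for rec in self.records], dtype=float)

    @property
    def n_released(self) -> np.ndarray:
        return np.array([rec.n_released for rec in self.records], dtype=int)

    @property
    def n_caught(self) -> np.ndarray:
        return np.array([rec.n_caught for rec in self.records], dtype=int)

    @property
    def sems(self) -> np.ndarray:
        return np.array(
            [math.nan if rec.sem is None else rec.sem for rec in self.records],
            dtype=float,
        )


@dataclass(frozen=True)
class FitResult:
    """Outcome of a parameter fit.

    ``residuals`` are model-minus-observed recapture proportions on the
    untransformed scale for the points entering ``r_correlation`` (the
    Pearson R between observed and predicted proportions; the scale choice
    is a reporting convention and is recorded here so it is auditable).
    """

    params: TrapSystemParams
    method: str  # two_step | fixed_sptfer0 | untransformed_only
    r_correlation: float
    residuals: tuple[float, ...]
    n_points_used: int
    excluded_points: tuple[tuple[float, str], ...] = ()
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "label": self.params.label,
            "sptfer0": self.params.sptfer0,
            "d50_m": self.params.d50,
            "d50_sem_m": self.params.d50_sem,
            "rmax_m": self.params.rmax,
            "method": self.method,
            "r_correlation": self.r_correlation,
            "residuals": list(self.residuals),
            "n_points_used": self.n_points_used,
            "excluded_points": [
                {"distance_m": d, "reason": why} for d, why in self.excluded_points
            ],
            "warnings": list(self.warnings),
        }


# --------------------------------------------------------------------------
# dataset screening

def validate_dataset(ds: ReleaseRecaptureDataset) -> list[str]:
    """Screen a dataset against the experimental-design criteria.

    Checks, without ever raising on a violation:

    1. converged catch reported for at least 4 distinct distances;
    2. releases at large distances at least as big as at short distances
       (checked as n_released non-decreasing with distance);
    3. no zero-catch record between non-zero catches.

    Returns one warning string per violated criterion.
    """
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    out: list[str] = []
    ndist = len(np.unique(ds.distances))
    if ndist < 4:
        out.append(
            f"criterion 1: converged catch reported for only {ndist} distinct "
            "distances (at least 4 required for a reliable fit)"
        )
    released = ds.n_released
    if np.any(np.diff(released) < 0):
        out.append(
            "criterion 2: number released decreases with distance; far-distance "
            "proportions are estimated from smaller cohorts"
        )
    caught = ds.n_caught
    nonzero = np.flatnonzero(caught > 0)
    if nonzero.size >= 2:
        interior = caught[nonzero[0] : nonzero[-1] + 1]
        if np.any(interior == 0):
            out.append(
                "criterion 3: zero-catch data point(s) between non-zero points"
            )
    return out


def _collapse_duplicate_distances(
    ds: ReleaseRecaptureDataset,
) -> ReleaseRecaptureDataset:
    """Pool records sharing a distance (summed counts), warning if any."""
    dists = ds.distances
    if len(np.unique(dists)) == len(dists):
        return ds
    warnings.warn(
        "records at duplicate distances were pooled (counts summed) before fitting",
        UserWarning,
        stacklevel=3,
    )
    pooled: list[DistanceCatchRecord] = []
    for d in np.unique(dists):
        sel = [rec for rec in ds.records if rec.distance == d]
        released = sum(rec.n_released for rec in sel)
        caught = sum(rec.n_caught for rec in sel)
        pooled.append(DistanceCatchRecord(float(d), released, caught))
    return ReleaseRecaptureDataset(
        tuple(pooled), species=ds.species, trap_type=ds.trap_type, note=ds.note
    )


# --------------------------------------------------------------------------
# fitting internals (array level, shared by the public API and the
# delta-method uncertainty propagation)

def _initial_guess(dist: np.ndarray, prop: np.ndarray) -> tuple[float, float]:
    """Deterministic, scale-aware starting values.

    sptfer0 starts at the largest observed proportion; d50 at the median
    distance whose proportion is still at least half that maximum (a direct
    read-off of the half-catch definition from the data).
    """
    s0 = float(np.clip(prop.max(), 1e-6, 1.0))
    high = dist[prop >= 0.5 * s0]
    d0 = float(np.median(high)) if high.size else float(np.median(dist))
    if d0 <= 0.0:
        positive = dist[dist > 0]
        d0 = float(np.median(positive)) if positive.size else 1.0
    return s0, d0


def _fit_untransformed(
    dist: np.ndarray, prop: np.ndarray, sigma=None
) -> tuple[float, float]:
    if len(np.unique(dist)) < 2:
        raise FitError("need at least 2 distinct distances to fit the curve")
    if np.count_nonzero(prop > 0) < 2:
        raise FitError(
            "need at least 2 non-zero recapture proportions to fit the curve"
        )
    s0, d0 = _initial_guess(dist, prop)

    def curve(r, sptfer0, d50):
        return sptfer0 / (1.0 + (r / d50) ** 2)

    try:
        popt, _ = curve_fit(
            curve,
            dist,
            prop,
            p0=[s0, d0],
            sigma=sigma,
            bounds=([1e-12, 1e-12], [1.0, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as err:  # pragma: no cover - solver pathologies
        raise FitError(f"untransformed fit did not converge: {err}") from err
    return float(popt[0]), float(popt[1])


def _fit_log(
    dist: np.ndarray, prop: np.ndarray, sptfer0: float, sigma=None
) -> tuple[float, float]:
    mask = prop > 0
    if np.count_nonzero(mask) < 2:
        raise FitError("need at least 2 positive-catch records for the log-scale fit")
    r_pos = dist[mask]
    logp = np.log(prop[mask])
    _, d0 = _initial_guess(r_pos, prop[mask])
    offset = math.log(sptfer0)
    sigma_pos = None if sigma is None else np.asarray(sigma)[mask]

    def log_curve(r, d50):
        return offset - np.log1p((r / d50) ** 2)

    try:
        popt, pcov = curve_fit(
            log_curve,
            r_pos,
            logp,
            p0=[d0],
            sigma=sigma_pos,
            bounds=(1e-12, np.inf),
            maxfev=10_000,
        )
    except RuntimeError as err:  # pragma: no cover
        raise FitError(f"log-scale fit did not converge: {err}") from err
    var = float(pcov[0, 0])
    sem = math.sqrt(var) if math.isfinite(var) and var > 0 else 0.0
    return float(popt[0]), sem


def _delta_method_sem(
    dist: np.ndarray,
    prop: np.ndarray,
    sems: np.ndarray,
    estimator,
    base: float,
) -> float:
    """SEM of a d50 estimator by first-order propagation of the per-point SEMs.

    Central finite differences with step one SEM per observed proportion.
    Unlike the naive least-squares covariance, this accounts for the
    heteroscedastic binomial noise of recapture proportions and (for the
    two-step protocol) for the uncertainty the step-1 sptfer0 estimate
    carries into step 2.
    """
    var = 0.0
    for i, s in enumerate(sems):
        if not (math.isfinite(s) and s > 0):
            continue
        hi = prop.copy()
        hi[i] = min(1.0, hi[i] + s)
        lo = prop.copy()
        if lo[i] - s > 0:
            lo[i] = lo[i] - s
        try:
            d_hi = estimator(dist, hi)
            d_lo = estimator(dist, lo) if lo[i] != prop[i] else base
        except FitError:
            continue  # perturbed ladder degenerate; skip this direction
        sens = (d_hi - d_lo) / (hi[i] - lo[i])
        var += sens * sens * s * s
    return math.sqrt(var)


def _usable_sems(ds: ReleaseRecaptureDataset) -> np.ndarray | None:
    """Per-record SEMs when present and informative, else None."""
    sems = ds.sems
    if np.all(~np.isfinite(sems)) or not np.any(sems > 0):
        return None
    return np.where(np.isfinite(sems), sems, 0.0)


def _weight_sigma(
    ds: ReleaseRecaptureDataset, log_scale: bool
) -> np.ndarray | None:
    """Per-point sigma for SEM-weighted fits, or None when SEMs are unusable."""
    sems = ds.sems
    usable = np.isfinite(sems) & (sems > 0)
    if not usable.all():
        warnings.warn(
            "weighted fit requested but SEMs are missing or zero; "
            "falling back to unweighted least squares",
            UserWarning,
            stacklevel=4,
        )
        return None
    if log_scale:
        with np.errstate(divide="ignore"):
            return np.where(ds.proportions > 0, sems / ds.proportions, 1.0)
    return sems


# --------------------------------------------------------------------------
# public fitting API

def fit_step1_untransformed(
    ds: ReleaseRecaptureDataset, weighted: bool = False
) -> tuple[float, float]:
    """Step 1: both-parameter fit of the untransformed catch-probability curve.

    Returns point estimates ``(sptfer0, d50)``; only the ``sptfer0`` estimate
    is retained by the two-step protocol.
    """
    ds = _collapse_duplicate_distances(ds)
    sigma = _weight_sigma(ds, log_scale=False) if weighted else None
    return _fit_untransformed(ds.distances, ds.proportions, sigma)


def fit_step2_log(
    ds: ReleaseRecaptureDataset, sptfer0: float, weighted: bool = False
) -> tuple[float, float]:
    """Step 2: one-parameter fit of the log-transformed curve with sptfer0 fixed.

    Zero-catch records are excluded (their log is undefined).  Returns
    ``(d50, d50_sem)``.  When the dataset carries per-record SEMs the d50
    SEM is obtained by delta-method propagation of those SEMs through the
    fit; otherwise it falls back to the scaled least-squares covariance.
    """
    if not (0.0 < sptfer0 <= 1.0):
        raise ValueError(f"sptfer0 must be in (0, 1], got {sptfer0!r}")
    ds = _collapse_duplicate_distances(ds)
    sigma = _weight_sigma(ds, log_scale=True) if weighted else None
    d50, cov_sem = _fit_log(ds.distances, ds.proportions, sptfer0, sigma)
    sems = _usable_sems(ds)
    if sems is None:
        return d50, cov_sem

    def estimator(dist, prop):
        return _fit_log(dist, prop, sptfer0, sigma)[0]

    return d50, _delta_method_sem(ds.distances, ds.proportions, sems, estimator, d50)


def _build_result(
    ds: ReleaseRecaptureDataset,
    params: TrapSystemParams,
    method: str,
    dataset_warnings: Sequence[str],
) -> FitResult:
    mask = ds.proportions > 0
    excluded = tuple(
        (rec.distance, "zero catch: excluded from the log-scale step")
        for rec, keep in zip(ds.records, mask)
        if not keep
    )
    no_cutoff = TrapSystemParams(params.sptfer0, params.d50, None, params.d50_sem)
    predicted = sp_t_fer(ds.distances[mask], no_cutoff)
    observed = ds.proportions[mask]
    residuals = tuple(float(x) for x in (predicted - observed))
    if observed.size >= 2 and np.std(predicted) > 0 and np.std(observed) > 0:
        r_corr = float(np.corrcoef(observed, predicted)[0, 1])
    else:
        r_corr = math.nan
    return FitResult(
        params=params,
        method=method,
        r_correlation=r_corr,
        residuals=residuals,
        n_points_used=int(mask.sum()),
        excluded_points=excluded,
        warnings=tuple(dataset_warnings),
    )


def fit_two_step(
    ds: ReleaseRecaptureDataset,
    rmax: float | None = None,
    weighted: bool = False,
) -> FitResult:
    """Full two-step protocol: sptfer0 from step 1, d50 (+/- SEM) from step 2.

    Dataset-design violations are attached as warnings, never fatal; ``rmax``
    is passed through untouched (it is not estimable from recapture ladders).
    """
    dataset_warnings = validate_dataset(ds)
    ds = _collapse_duplicate_distances(ds)
    sigma_lin = _weight_sigma(ds, log_scale=False) if weighted else None
    sigma_log = _weight_sigma(ds, log_scale=True) if weighted else None

    def pipeline(dist, prop):
        s0 = _fit_untransformed(dist, prop, sigma_lin)[0]
        return s0, _fit_log(dist, prop, s0, sigma_log)

    sptfer0, (d50, cov_sem) = pipeline(ds.distances, ds.proportions)
    sems = _usable_sems(ds)
    if sems is None:
        d50_sem = cov_sem
    else:
        d50_sem = _delta_method_sem(
            ds.distances,
            ds.proportions,
            sems,
            lambda dist, prop: pipeline(dist, prop)[1][0],
            d50,
        )
    params = TrapSystemParams(
        sptfer0, d50, rmax, d50_sem, label=ds.species or "fitted trap system"
    )
    return _build_result(ds, params, "two_step", dataset_warnings)


def fit_with_known_sptfer0(
    ds: ReleaseRecaptureDataset,
    sptfer0: float,
    rmax: float | None = None,
    weighted: bool = False,
) -> FitResult:
    """Log-scale d50 fit with an empirically measured sptfer0 held fixed.

    Preferred over the two-step protocol whenever spTfer(0) was measured in
    the field: an sptfer0 estimated by curve fitting an incomplete ladder can
    be off, dragging d50 with it.
    """
    if not (0.0 < sptfer0 <= 1.0):
        raise ValueError(f"sptfer0 must be in (0, 1], got {sptfer0!r}")
    dataset_warnings = validate_dataset(ds)
    ds = _collapse_duplicate_distances(ds)
    d50, d50_sem = fit_step2_log(ds, sptfer0, weighted=weighted)
    params = TrapSystemParams(
        sptfer0, d50, rmax, d50_sem, label=ds.species or "fitted trap system"
    )
    return _build_result(ds, params, "fixed_sptfer0", dataset_warnings)
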