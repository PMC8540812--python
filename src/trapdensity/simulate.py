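"""Synthetic release–recapture experiments and trap catches.

Two sampling models, matching each statistic's sampling context:

* recapture of a released cohort is **binomial** — cohorts are finite and
  the recaptured proportion is bounded by 1;
* the catch from an unbounded wild population of uniform density is
  **Poisson** with mean ``rho / mu``, the exact model under which the
  chi-squared density interval is derived.

Distances are sampled independently (one trap, no competition between
release points).  Identical seeds give identical datasets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .fitting import DistanceCatchRecord, ReleaseRecaptureDataset
from .model import TrapSystemParams, compute_mu, sp_t_fer

__all__ = ["SimulationDesign", "simulate_release_recapture", "simulate_trap_catch"]


@dataclass(frozen=True)
class SimulationDesign:
    """Ground truth and layout of a simulated release–recapture experiment.

    ``n_released`` may be a single cohort size (used at every distance) or a
    per-distance sequence.  Releases beyond ``rmax`` are allowed but warned
    about: they can only produce structural zeros.
    """

    params: TrapSystemParams
    distances: tuple[float, ...]
    n_released: tuple[int, ...]
    seed: int
    replicates: int = 1

    def __init__(self, params, distances, n_released, seed, replicates=1):
        distances = tuple(float(d) for d in distances)
        if not distances:
            raise ValueError("at least one release distance is required")
        if any(d < 0 or not math.isfinite(d) for d in distances):
            raise ValueError("release distances must be finite and >= 0")
        if np.ndim(n_released) == 0:
            n_released = (int(n_released),) * len(distances)
        else:
            n_released = tuple(int(n) for n in n_released)
        if len(n_released) != len(distances):
            raise ValueError("n_released must be scalar or match distances in length")
        if any(n < 0 for n in n_released):
            raise ValueError("cohort sizes must be >= 0")
        if replicates < 1:
            raise ValueError("replicates must be >= 1")
        if params.rmax is not None and any(d > params.rmax for d in distances):
            warnings.warn(
                "some release distances exceed rmax; those cohorts can only "
                "yield structurally zero catches",
                UserWarning,
                stacklevel=2,
            )
        object.__setattr__(self, "params", params)
        object.__setattr__(self, "distances", distances)
        object.__setattr__(self, "n_released", n_released)
        object.__setattr__(self, "seed", int(seed))
        object.__setattr__(self, "replicates", int(replicates))


def simulate_release_recapture(
    design: SimulationDesign,
) -> list[ReleaseRecaptureDataset]:
    """Draw ``design.replicates`` binomial recapture datasets.

    For each distance, ``n_caught ~ Binomial(n_released, spTfer(distance))``.
    The recorded SEM is the binomial standard error of the observed
    proportion, ``sqrt(p_hat (1 - p_hat) / n)``.
    """
    rng = np.random.default_rng(design.seed)
    probs = np.asarray(sp_t_fer(np.array(design.distances), design.params))
    datasets: list[ReleaseRecaptureDataset] = []
    for rep in range(design.replicates):
        records = []
        for dist, n, prob in zip(design.distances, design.n_released, probs):
            caught = int(rng.binomial(n, prob)) if n > 0 else 0
            p_hat = caught / n if n > 0 else 0.0
            sem = math.sqrt(p_hat * (1.0 - p_hat) / n) if n > 0 else 0.0
            records.append(
                DistanceCatchRecord(dist, n, caught, sem=sem)
            )
        datasets.append(
            ReleaseRecaptureDataset(
                tuple(records),
                species=design.params.label or "simulated system",
                trap_type="simulated",
                note=f"simulated replicate {rep} (seed {design.seed})",
            )
        )
    return datasets


def simulate_trap_catch(
    rho: float,
    params: TrapSystemParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    size: int | None = None,
):
    """Draw trap catches ``M ~ Poisson(rho / mu)`` for uniform density ``rho``.

    Pass either a ``seed`` or an existing ``rng``.  Returns a single int when
    ``size`` is None, else an integer array of that shape.
    """
    if rho < 0 or not math.isfinite(rho):
        raise ValueError(f"density rho must be finite and >= 0, got {rho!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    lam = rho / compute_mu(params)
    draws = rng.poisson(lam, size=size)
    return int(draws) if size is None else draws
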