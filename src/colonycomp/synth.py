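"""Synthetic stand-ins for the microscopy inputs.

Three generators cover the data the analysis pipeline consumes:

* founder-cell lag-time models (parametric truncated normal, or empirical
  resampling of a measured lag list);
* founder point patterns at a target density with a two-strain
  minority/majority labelling (default 1:19 mix);
* ground-truth colonized label maps from an additively weighted Voronoi
  growth model: site ``s`` is claimed by the founder minimizing
  ``dist(s, founder) / v + lag``, i.e. by whichever lineage's expanding
  front, launched after its lag at constant radial speed ``v``, reaches the
  site first.  With equal lags this reduces exactly to the ordinary
  nearest-founder (Voronoi) partition.

The label maps have the statistical structure the winner-index analysis
assumes (contiguous per-founder patches tiling the domain, patch-size
dispersion driven by lag variability) without running the lattice simulator,
so the measurement stages can be tested against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: lag statistics measured for founder cells taken from exponential-phase
#: liquid culture: mean 53 min, standard deviation 16 min.
EXPONENTIAL_PHASE_LAG_MEAN = 53.0
EXPONENTIAL_PHASE_LAG_SD = 16.0

#: founder-cell surface densities of the low- and high-density experiments,
#: in cells per square micrometre.
RHO_LOW = 1.5e-4
RHO_HIGH = 7.2e-3


@dataclass
class LagModel:
    """Distribution of founder-cell lag times (minutes, nonnegative).

    ``kind`` is one of ``"none"`` (all lags zero), ``"normal_truncated"``
    (normal redrawn at zero, parameters ``mean``/``sd``), or ``"empirical"``
    (resampling with replacement from ``samples``).
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    samples: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "normal_truncated", "empirical"):
            raise ValueError(f"unknown lag model kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.kind == "empirical":
            if self.samples is None or len(self.samples) == 0:
                raise ValueError("empirical lag model needs a nonempty sample list")
            if np.min(self.samples) < 0:
                raise ValueError("lag samples must be nonnegative")


def exponential_phase_lag_model() -> LagModel:
    """Lag model for exponential-phase founder cells (mean 53, sd 16 min)."""
    return LagModel("normal_truncated", EXPONENTIAL_PHASE_LAG_MEAN, EXPONENTIAL_PHASE_LAG_SD)


def heat_shock_lag_model(mean: float = 106.0, sd: float = 32.0) -> LagModel:
    """Broadened lag model emulating heat-shocked stationary-phase founders.

    Heat shock lengthens and broadens the lag distribution.  The exact
    measured parameters are not available, so the defaults are a documented
    placeholder (twice the exponential-phase mean and sd) and should be
    overridden when measured values exist.
    """
    return LagModel("normal_truncated", mean, sd)


def sample_lag_times(model: LagModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` nonnegative lag times (minutes) from ``model``.

    Truncated-normal sampling redraws negative values rather than clipping,
    so no probability mass piles up at zero.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if model.kind == "none":
        return np.zeros(n)
    if model.kind == "empirical":
        return rng.choice(np.asarray(model.samples, dtype=float), size=n, replace=True)
    out = rng.normal(model.mean, model.sd, size=n)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(model.mean, model.sd, size=int(bad.sum()))
        bad = out < 0
    return out


@dataclass
class FieldSpec:
    """Geometry and statistics of one synthetic field of view.

    The domain is ``width x height`` in arbitrary length units (micrometres
    for experiment-like densities, lattice sites for simulator-like maps);
    label maps are sampled at the integer grid points.
    """

    width: float = 500.0
    height: float = 500.0
    density: float = RHO_LOW  # founders per unit area
    minority_fraction: float = 1.0 / 20.0  # 1:19 minority:majority mix
    # Front speed v (length units per minute). Chosen so that lag-time
    # differences of order sigma_lag displace patch boundaries by much less
    # than the typical founder spacing at the emulated densities; the WI
    # distribution then stays peaked near 1 with moderate dispersion, as in
    # the surface-colonization experiments.
    growth_speed: float = 0.2
    min_separation: float = 1.0  # rejection radius between founders
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("domain dimensions must be positive")
        if self.density * self.width * self.height < 2:
            raise ValueError("expected founder count density*area must be >= 2")
        if not (0 < self.minority_fraction < 1):
            raise ValueError("minority_fraction must be in (0, 1)")
        if self.growth_speed <= 0:
            raise ValueError("growth_speed must be positive")


def generate_founders(spec: FieldSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Scatter founders uniformly at the spec's density.

    The founder count is Poisson(density * area); positions are uniform with
    a hard minimum pairwise separation (dart throwing).  Labels are drawn
    independently as minority with probability ``minority_fraction``.
    Columns: ``lineage_id, x, y, label``.

    Coordinates use the raster frame in which pixel (r, c) is centred on
    (x = c, y = r), so the field rectangle is [-0.5, W-0.5] x [-0.5, H-0.5].
    """
    area = spec.width * spec.height
    n = int(rng.poisson(spec.density * area))
    n = max(n, 2)
    # crude feasibility bound for hard-disk dart throwing
    if n * np.pi * (spec.min_separation / 2) ** 2 > 0.5 * area:
        raise ValueError(
            f"density {spec.density} infeasible with min separation {spec.min_separation}"
        )
    xs = np.empty(n)
    ys = np.empty(n)
    placed = 0
    attempts = 0
    max_attempts = 200 * n + 1000
    sep2 = spec.min_separation**2
    while placed < n:
        if attempts > max_attempts:
            raise ValueError("could not place founders under the separation constraint")
        x = rng.uniform(-0.5, spec.width - 0.5)
        y = rng.uniform(-0.5, spec.height - 0.5)
        attempts += 1
        if placed and np.min((xs[:placed] - x) ** 2 + (ys[:placed] - y) ** 2) < sep2:
            continue
        xs[placed], ys[placed] = x, y
        placed += 1
    minority = rng.random(n) < spec.minority_fraction
    return pd.DataFrame(
        {
            "lineage_id": np.arange(1, n + 1),
            "x": xs,
            "y": ys,
            "label": np.where(minority, "minority", "majority"),
        }
    )


def ground_truth_label_map(
    founders: pd.DataFrame,
    lag_times: np.ndarray,
    spec: FieldSpec,
) -> np.ndarray:
    """Assign every integer grid site to the founder that reaches it first.

    Site ``(r, c)`` goes to the founder minimizing
    ``hypot(c - x, r - y) / growth_speed + lag``; ties resolve to the lowest
    lineage id.  Returns an ``(H, W)`` int32 map of lineage ids with
    ``H = round(height)``, ``W = round(width)``.
    """
    lag_times = np.asarray(lag_times, dtype=float)
    if len(lag_times) != len(founders):
        raise ValueError("need exactly one lag time per founder")
    w = int(round(spec.width))
    h = int(round(spec.height))
    fx = founders["x"].to_numpy()
    fy = founders["y"].to_numpy()
    ids = founders["lineage_id"].to_numpy()
    cols = np.arange(w, dtype=float)
    labels = np.empty((h, w), dtype=np.int32)
    # chunk over rows to bound the (rows, W, n_founders) arrival-time array
    chunk = max(1, int(4e6 / max(1, w * len(founders))))
    for r0 in range(0, h, chunk):
        r1 = min(h, r0 + chunk)
        rows = np.arange(r0, r1, dtype=float)
        d = np.sqrt(
            (cols[None, :, None] - fx[None, None, :]) ** 2
            + (rows[:, None, None] - fy[None, None, :]) ** 2
        )
        arrival = d / spec.growth_speed + lag_times[None, None, :]
        labels[r0:r1] = ids[np.argmin(arrival, axis=2)]
    return labels
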