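"""Partial-harvest scenario simulation.

Builds 210 x 210 m (14 x 14 cell) stand habitat layers for combinations
of harvest intensity (fraction of basal area removed), spatial pattern
(uniform, small-patch, large-patch) and post-harvest shrub development
(normal or herbicide-suppressed), then maps habitat value and predicts
vole abundance with both the home-range model and the habitat-value
regression.

Harvest patterns: removal groups with disk shapes whose areas are drawn
from a lognormal with fixed mode; larger area variance gives more
aggregated harvest.  Habitat components respond to local harvest
through empirical linear relations (shade from gap light, substrate
from conifer basal-area share, downed woody debris from fraction cut)
plus piecewise shrub suppression, with rank-matched autocorrelated
lognormal scatter standing in for natural within-stand variability.

The gap-light layer is a synthetic placeholder (a smoothed, increasing
function of local fraction cut) rather than output of a stand dynamics
model, so scenario results are qualitative: directions and orderings,
not absolute abundances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .core import DEFAULT_FORM, HRParams, VOLE_PARAMS, establish_population, overlap_stats
from .grids import ResourceGrid, ValueGrid
from .habitat import ResourceCoefficient, map_habitat_value

__all__ = [
    "HarvestScenario",
    "apply_harvest_pattern",
    "shade_from_gli",
    "substrate_from_pcba",
    "dwd_from_cut",
    "shrub_scenario",
    "autocorrelated_lognormal_scatter",
    "synthetic_gli",
    "build_stand",
    "run_scenario",
]

#: stand dimensions: 210 m / 15 m
STAND_SHAPE = (14, 14)

#: lognormal sigma of removal-group area per pattern (mode fixed at 1 cell)
PATTERN_SIGMA = {"small_patch": 0.05, "large_patch": 1.2}

#: default multiplicative scatter CVs per habitat layer
SCATTER_CV = {"substrate": 0.45, "dwd": 0.6, "shrub": 0.4}

#: default autocorrelation range of the scatter fields, metres
SCATTER_RANGE_M = 30.0

#: habitat-value regression coefficients (log-linear in site-mean value)
REGRESSION_COEFS = (0.856, 0.711)


@dataclass(frozen=True)
class HarvestScenario:
    """One harvest treatment: intensity, spatial pattern, shrub response."""

    intensity: float
    pattern: Literal["uniform", "small_patch", "large_patch"] = "uniform"
    shrub_mode: Literal["normal", "suppressed"] = "normal"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.intensity <= 1.0):
            raise ValueError("intensity must lie in [0, 1]")
        if self.pattern not in ("uniform", "small_patch", "large_patch"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.shrub_mode not in ("normal", "suppressed"):
            raise ValueError(f"unknown shrub mode {self.shrub_mode!r}")


def apply_harvest_pattern(
    scenario: HarvestScenario,
    shape: tuple[int, int] = STAND_SHAPE,
    rng: Optional[np.random.Generator] = None,
    tol: float = 0.02,
    max_groups: int = 100_000,
) -> np.ndarray:
    """Per-cell proportion of basal area cut (PC) for one stand.

    Uniform pattern: every cell equals the intensity.  Patch patterns:
    disk-shaped removal groups are placed at random centres, with group
    area (cells) lognormal -- mode one cell, sigma set by the pattern --
    until the grid mean is within ``tol`` of the target; cells covered
    by several groups saturate at PC = 1.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    nrow, ncol = shape
    if scenario.pattern == "uniform" or scenario.intensity == 0.0:
        return np.full(shape, scenario.intensity)
    sigma = PATTERN_SIGMA[scenario.pattern]
    mu = sigma * sigma  # lognormal mode exp(mu - sigma^2) = 1 cell
    pc = np.zeros(shape)
    rows = np.arange(nrow)[:, None]
    cols = np.arange(ncol)[None, :]
    for _ in range(max_groups):
        if pc.mean() >= scenario.intensity - tol:
            break
        area = float(rng.lognormal(mu, sigma))
        r0 = int(rng.integers(nrow))
        c0 = int(rng.integers(ncol))
        radius = np.sqrt(area / np.pi)
        dr = np.minimum(np.abs(rows - r0), nrow - np.abs(rows - r0))
        dc = np.minimum(np.abs(cols - c0), ncol - np.abs(cols - c0))
        disk = (dr * dr + dc * dc) <= max(radius, 0.5) ** 2
        add = np.where(disk, area / disk.sum(), 0.0)
        cand = np.minimum(pc + add, 1.0)
        if cand.mean() > scenario.intensity + tol:
            continue  # group too large; redraw
        pc = cand
    else:
        raise RuntimeError("could not reach target harvest intensity")
    if abs(pc.mean() - scenario.intensity) > tol:
        raise RuntimeError("could not reach target harvest intensity")
    return pc


def shade_from_gli(gli) -> np.ndarray | float:
    """Shade habitat value from gap light index (percent full sun)."""
    g = np.asarray(gli, dtype=float)
    if np.any(g < 0) or np.any(g > 100):
        raise ValueError("GLI must lie in [0, 100]")
    out = 3.6802 - 0.0132 * g
    return out if out.ndim else float(out)


def substrate_from_pcba(pcba) -> np.ndarray | float:
    """Substrate habitat value from proportion coniferous basal area."""
    p = np.asarray(pcba, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("PCBA must lie in [0, 1]")
    out = 0.1193 + 0.1816 * p
    return out if out.ndim else float(out)


def dwd_from_cut(pc) -> np.ndarray | float:
    """Late-decay downed woody debris from proportion basal area cut."""
    p = np.asarray(pc, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("PC must lie in [0, 1]")
    out = np.maximum(2.2035 - 1.8336 * p, 0.0)
    return out if out.ndim else float(out)


def shrub_scenario(pc, baseline, mode: str = "normal") -> np.ndarray | float:
    """Shrub cover after harvest.

    ``normal``: unaffected.  ``suppressed`` (post-harvest herbicide):
    unchanged below 1/3 cut, reduced to 40% of baseline above 2/3 cut,
    linear in between.
    """
    p = np.asarray(pc, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("PC must lie in [0, 1]")
    b = np.asarray(baseline, dtype=float)
    if np.any(b < 0):
        raise ValueError("baseline shrub cover must be non-negative")
    if mode == "normal":
        out = np.broadcast_arrays(b, p)[0].copy()
    elif mode == "suppressed":
        f = np.clip(1.0 - 0.6 * (p - 1.0 / 3.0) / (1.0 / 3.0), 0.4, 1.0)
        out = b * f
    else:
        raise ValueError(f"unknown shrub mode {mode!r}")
    return out if out.ndim else float(out)


def _gaussian_field(
    shape: tuple[int, int],
    range_m: float,
    resolution: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary Gaussian field with exponential covariance on the torus."""
    n = shape[0] * shape[1]
    # full covariance from the toroidal distance between every cell pair
    rows = np.arange(shape[0])
    cols = np.arange(shape[1])
    dr = np.abs(rows[:, None] - rows[None, :])
    dr = np.minimum(dr, shape[0] - dr)
    dc = np.abs(cols[:, None] - cols[None, :])
    dc = np.minimum(dc, shape[1] - dc)
    dist = np.sqrt(
        (dr[:, None, :, None] * resolution) ** 2
        + (dc[None, :, None, :] * resolution) ** 2
    ).reshape(n, n)
    cov = np.exp(-dist / range_m)
    L = cholesky(cov + 1e-10 * np.eye(n), lower=True)
    return (L @ rng.standard_normal(n)).reshape(shape)


def autocorrelated_lognormal_scatter(
    values: np.ndarray,
    cv: float,
    range_m: float = SCATTER_RANGE_M,
    seed: int = 0,
    resolution: float = 15.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Multiply a layer by spatially autocorrelated lognormal noise.

    Deviates are lognormal with mean 1 and the target CV; they are then
    rank-matched to a Gaussian random field with exponential covariance
    (range ``range_m``), which imposes spatial correlation while
    preserving the marginal distribution exactly.  cv = 0 returns the
    input unchanged.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    values = np.asarray(values, dtype=float)
    if cv == 0.0:
        return values.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    s2 = np.log(1.0 + cv * cv)
    deviates = rng.lognormal(-0.5 * s2, np.sqrt(s2), values.shape)
    fieldv = _gaussian_field(values.shape, range_m, resolution, rng)
    # rank-match: i-th smallest deviate goes where the field is i-th smallest
    flat = np.empty(values.size)
    flat[np.argsort(fieldv.ravel())] = np.sort(deviates.ravel())
    return values * flat.reshape(values.shape)


def synthetic_gli(
    pc: np.ndarray, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Synthetic gap light index from local harvest intensity.

    A placeholder for light output of a stand dynamics model:
    GLI = clamp(10 + 85 * smoothed(PC), 0, 100), where smoothing is a
    3 x 3 toroidal mean (one-cell kernel).  Non-canonical by design.
    """
    pc = np.asarray(pc, dtype=float)
    sm = np.zeros_like(pc)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            sm += np.roll(np.roll(pc, dr, axis=0), dc, axis=1)
    sm /= 9.0
    return np.clip(10.0 + 85.0 * sm, 0.0, 100.0)


@dataclass(frozen=True)
class StandMap:
    """All layers of one simulated stand."""

    pc: np.ndarray
    gli: np.ndarray
    pcba: np.ndarray
    resources: tuple  # shrub, dwd, shade, substrate ResourceGrids
    value: ValueGrid


def build_stand(
    scenario: HarvestScenario,
    coefs: Sequence[ResourceCoefficient],
    baseline: float,
    shrub_baseline: float = 1.5,
    scatter_cv: dict = SCATTER_CV,
    scatter_range_m: float = SCATTER_RANGE_M,
    pcba_beta: tuple[float, float] = (8.0, 8.0),
    rng: Optional[np.random.Generator] = None,
    shape: tuple[int, int] = STAND_SHAPE,
) -> StandMap:
    """Generate one stand's habitat layers and its mapped value grid.

    ``baseline`` is the fixed habitat-value calibration constant (the
    lowest-value habitat of the calibration data), so harvested stands
    are scored on the same absolute scale; mapped values are floored at
    zero where degradation pushes them below the calibration range.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    pc = apply_harvest_pattern(scenario, shape=shape, rng=rng)
    gli = synthetic_gli(pc, rng)
    pcba0 = float(rng.beta(*pcba_beta))
    pcba = np.full(shape, pcba0)

    shade = shade_from_gli(gli)
    substrate = autocorrelated_lognormal_scatter(
        substrate_from_pcba(pcba), scatter_cv.get("substrate", 0.0),
        scatter_range_m, rng=rng)
    dwd = autocorrelated_lognormal_scatter(
        dwd_from_cut(pc), scatter_cv.get("dwd", 0.0), scatter_range_m, rng=rng)
    shrub = autocorrelated_lognormal_scatter(
        shrub_scenario(pc, shrub_baseline, scenario.shrub_mode),
        scatter_cv.get("shrub", 0.0), scatter_range_m, rng=rng)

    resources = tuple(
        ResourceGrid(name=name, values=np.clip(vals, 0.0, None))
        for name, vals in
        (("shrub", shrub), ("dwd", dwd), ("shade", shade), ("substrate", substrate))
    )
    by_name = {c.name: c for c in coefs}
    # keep amounts inside each coefficient's integration domain
    resources = tuple(
        ResourceGrid(
            name=r.name,
            values=np.minimum(r.values, by_name[r.name].integration_upper),
        )
        for r in resources
    )
    value = map_habitat_value(resources, coefs, baseline=baseline,
                              clip_negative=True)
    return StandMap(pc=pc, gli=gli, pcba=pcba, resources=resources, value=value)


def run_scenario(
    scenario: HarvestScenario,
    coefs: Sequence[ResourceCoefficient],
    baseline: float,
    hr_params: HRParams = VOLE_PARAMS,
    replicates: int = 15,
    seed: int = 0,
    restarts: int = 2,
    form: str = DEFAULT_FORM,
    regression_coefs: tuple[float, float] = REGRESSION_COEFS,
    **stand_kwargs,
) -> pd.DataFrame:
    """Simulate replicate stands under one scenario.

    Returns one row per replicate: mean habitat value per cell, home-
    range abundance, mean home-range size (cells), percent of each home
    range shared with another, and the habitat-value regression
    prediction exp(q0 + q1 * mean V).  Deterministic per (scenario,
    seed).
    """
    q0, q1 = regression_coefs
    rows = []
    for rep in range(replicates):
        rep_seed = (seed * 100_003 + rep * 7919 + scenario.seed) & 0x7FFFFFFF
        rng = np.random.default_rng(rep_seed)
        stand = build_stand(scenario, coefs, baseline, rng=rng, **stand_kwargs)
        sol = establish_population(
            stand.value, hr_params, restarts=restarts, seed=rep_seed, form=form
        )
        st = overlap_stats(sol)
        vbar = stand.value.mean_value
        rows.append(
            dict(
                replicate=rep,
                intensity=scenario.intensity,
                pattern=scenario.pattern,
                shrub_mode=scenario.shrub_mode,
                mean_value=vbar,
                sd_value=float(stand.value.values.std()),
                abundance=sol.abundance,
                mean_size_cells=st["mean_size_cells"],
                overlap_pct=100.0 * st["mean_fraction_shared"],
                regression_abundance=float(np.exp(q0 + q1 * vbar)),
            )
        )
    return pd.DataFrame(rows)


def summarize_scenarios(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per scenario, mirroring the usual reporting layout."""
    g = results.groupby(["intensity", "pattern", "shrub_mode"])
    out = g.agg(
        mean_value=("mean_value", "mean"),
        sd_mean_value=("mean_value", "std"),
        mean_size=("mean_size_cells", "mean"),
        sd_size=("mean_size_cells", "std"),
        overlap_pct=("overlap_pct", "mean"),
        abundance=("abundance", "mean"),
        sd_abundance=("abundance", "std"),
        regression_abundance=("regression_abundance", "mean"),
    )
    return out.reset_index()
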