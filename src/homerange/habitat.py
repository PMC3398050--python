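"""Mapping local habitat value from resource-use coefficients.

A prior fine-scale habitat-use model describes how the probability of
local occurrence responds to each habitat resource (shrub cover,
late-decay downed woody debris, shade, forest-floor substrate).  Each
resource's per-unit effect ``B_i`` is either a constant or a logistic
function of availability (associations can switch off where a resource
is no longer limiting).  Integrating ``B_i`` over resource amount gives
that resource's cumulative contribution ``V_i`` to local habitat value
-- a threshold-shaped curve for logistic effects.  Summing ``V_i``
across resources and subtracting the lowest-value local habitat in the
calibration data yields an absolute per-cell habitat value ``V``.

Coefficient values for the prior habitat model are not published; they
are consumed here as configuration (see :mod:`homerange.synth` for a
plausible, explicitly non-canonical default set).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

import numpy as np
import yaml
from scipy.special import expit

from .grids import ResourceGrid, ValueGrid, toroidal_distance_offsets

__all__ = [
    "ResourceCoefficient",
    "functional_response",
    "integrate_resource_value",
    "map_habitat_value",
    "local_mean",
    "load_coefficients",
    "save_coefficients",
]

#: number of trapezoid panels spanning [0, integration_upper]
INTEGRATION_PANELS = 1000


@dataclass(frozen=True)
class ResourceCoefficient:
    """Per-unit habitat-use effect of one resource.

    ``mode="constant"``: the effect is ``b0`` at any availability.
    ``mode="logistic"``: the effect follows a 4-parameter logistic in
    availability, declining from ``upper`` toward ``lower`` around
    ``midpoint`` with steepness set by ``scale`` (this is the shape for
    resources that matter only where they are scarce).
    """

    name: str
    mode: Literal["constant", "logistic"]
    b0: float = 0.0
    lower: float = 0.0
    upper: float = 0.0
    midpoint: float = 0.0
    scale: float = 1.0
    integration_upper: float = 10.0

    def __post_init__(self):
        if self.mode not in ("constant", "logistic"):
            raise ValueError(f"unknown coefficient mode {self.mode!r}")
        if self.integration_upper <= 0:
            raise ValueError("integration_upper must be positive")
        if self.mode == "logistic" and self.scale <= 0:
            raise ValueError("logistic scale must be positive")


def functional_response(coef: ResourceCoefficient, availability) -> np.ndarray | float:
    """Per-unit effect B_i at the given availability (scalar or array).

    Constant mode ignores availability; logistic mode interpolates
    between the two asymptotes, approaching ``lower`` as availability
    grows (and ``upper`` as it falls to zero, for the usual declining
    shape).
    """
    a = np.asarray(availability, dtype=float)
    if np.any(a < 0):
        raise ValueError("availability must be non-negative")
    if coef.mode == "constant":
        out = np.full_like(a, coef.b0)
    else:
        # expit form avoids overflow far from the midpoint
        out = coef.lower + (coef.upper - coef.lower) * expit(
            -(a - coef.midpoint) / coef.scale
        )
    return out if out.ndim else float(out)


def integrate_resource_value(
    coef: ResourceCoefficient,
    amount,
    *,
    mode: Literal["sliding", "fixed"] = "sliding",
    site_availability: float | None = None,
    step: float | None = None,
) -> np.ndarray | float:
    """Cumulative habitat value V_i of a given amount of one resource.

    ``mode="sliding"`` (default) integrates the functional response as
    availability runs from 0 to ``amount``: V_i(a) = int_0^a B_i(h) dh,
    by composite trapezoid on a fixed grid of ``integration_upper``/1000
    panels.  This produces the threshold-shaped value curve for
    declining logistic effects.  ``mode="fixed"`` instead evaluates
    B_i once at ``site_availability`` and scales linearly:
    V_i(a) = B_i(s) * a.
    """
    a = np.asarray(amount, dtype=float)
    if np.any(a < 0) or np.any(a > coef.integration_upper + 1e-9):
        raise ValueError(
            f"amount outside [0, integration_upper={coef.integration_upper}]"
        )
    if mode == "fixed":
        if site_availability is None:
            raise ValueError("mode='fixed' requires site_availability")
        out = functional_response(coef, site_availability) * a
        return out if np.ndim(out) else float(out)
    if mode != "sliding":
        raise ValueError(f"unknown integration mode {mode!r}")
    if coef.mode == "constant":
        # trapezoid is exact for a constant integrand
        out = coef.b0 * a
        return out if out.ndim else float(out)
    h = step if step is not None else coef.integration_upper / INTEGRATION_PANELS
    # cumulative trapezoid on the shared knot grid, then linear blend to a
    knots = np.arange(0.0, coef.integration_upper + h * 0.5, h)
    b = functional_response(coef, knots)
    cum = np.concatenate([[0.0], np.cumsum((b[1:] + b[:-1]) * 0.5 * h)])
    # position of each amount within the knot grid
    pos = np.clip(a / h, 0.0, len(knots) - 1.0)
    lo = np.minimum(pos.astype(int), len(knots) - 2)
    frac = pos - lo
    # partial last panel, itself a trapezoid between knot lo and a
    b_at_a = functional_response(coef, np.minimum(a, coef.integration_upper))
    out = cum[lo] + (b[lo] + b_at_a) * 0.5 * frac * h
    return out if out.ndim else float(out)


def map_habitat_value(
    resources: Sequence[ResourceGrid],
    coefs: Sequence[ResourceCoefficient],
    baseline: Union[float, Literal["auto"]] = "auto",
    *,
    integration: Literal["sliding", "fixed"] = "sliding",
    clip_negative: bool = False,
) -> ValueGrid:
    """Combine resource layers into a per-cell habitat-value grid.

    Per cell, V = sum_i V_i(H_i) - baseline.  ``baseline="auto"`` uses
    the minimum of sum_i V_i over the supplied cells, so the
    lowest-value cell maps exactly to 0.  A fixed numeric baseline (for
    scoring new grids against an existing calibration) can push values
    negative; ``clip_negative`` floors those at 0.
    """
    if len(resources) != len(coefs):
        raise ValueError("need exactly one coefficient per resource grid")
    by_name = {c.name: c for c in coefs}
    if len(by_name) != len(coefs):
        raise ValueError("duplicate coefficient names")
    shape = resources[0].shape
    resolution = resources[0].resolution
    total = np.zeros(shape)
    for rg in resources:
        if rg.shape != shape:
            raise ValueError(
                f"resource grid {rg.name!r} shape {rg.shape} != {shape}"
            )
        coef = by_name.get(rg.name)
        if coef is None:
            raise ValueError(f"no coefficient supplied for resource {rg.name!r}")
        site_avail = float(rg.values.mean())
        total += integrate_resource_value(
            coef, rg.values, mode=integration, site_availability=site_avail
        )
    if baseline == "auto":
        base = float(total.min())
    else:
        base = float(baseline)
    values = total - base
    if clip_negative:
        values = np.maximum(values, 0.0)
    return ValueGrid(values=values, resolution=resolution, baseline=base)


def local_mean(grid: ResourceGrid, radius: float = 26.0) -> ResourceGrid:
    """Per-cell mean of all cell centres within ``radius`` (toroidal distance).

    Matches the field protocol of averaging habitat measurements within
    26 m of each trap station; useful when sampling layers are finer
    than the 15 m analysis grid.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    offsets = toroidal_distance_offsets(grid.shape, grid.resolution)
    mask = offsets <= radius
    # mean over the window = circular convolution with the mask kernel
    # the offsets matrix spans every modular shift (dr, dc) once, with the
    # wrap-symmetric distance, so summing rolls over the mask is the window sum
    acc = np.zeros(grid.shape)
    rows, cols = np.nonzero(mask)
    for dr, dc in zip(rows, cols):
        acc += np.roll(np.roll(grid.values, -dr, axis=0), -dc, axis=1)
    return ResourceGrid(
        name=grid.name, values=acc / mask.sum(), resolution=grid.resolution
    )


# ---------------------------------------------------------------------------
# Coefficient configuration files (YAML: one entry per resource)
# ---------------------------------------------------------------------------


def load_coefficients(path: Union[str, Path]) -> list[ResourceCoefficient]:
    raw = yaml.safe_load(Path(path).read_text())
    out = []
    for name, spec in raw.items():
        out.append(ResourceCoefficient(name=name, **spec))
    return out


def save_coefficients(
    path: Union[str, Path], coefs: Iterable[ResourceCoefficient]
) -> None:
    doc = {}
    for c in coefs:
        entry: dict = {"mode": c.mode, "integration_upper": c.integration_upper}
        if c.mode == "constant":
            entry["b0"] = c.b0
        else:
            entry.update(
                lower=c.lower, upper=c.upper, midpoint=c.midpoint, scale=c.scale
            )
        doc[c.name] = entry
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
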