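"""Seeded generators for every input the pipeline needs.

No field data accompany the model, so these generators emulate the
statistical structure of the 31 study sites: 7 x 7 cell (15 m) habitat
value grids with across-site mean 1.64 (SD 0.35) and within-site CV
about 24% with short-range spatial autocorrelation; 3-day removal
capture histories with known abundance and detectability (defaults
p_d = 0.63 and 0.42 for the two study years); and abundance datasets
with known home-range parameters for inverse-fit recovery studies.

The shipped resource-coefficient set is explicitly NON-CANONICAL: the
original habitat-use model's coefficients are unpublished, so these are
plausible stand-ins (constant positive effects for shade and substrate;
declining logistic effects for shrub and downed woody debris) calibrated
only so that mapped habitat values resemble the reported field range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .core import DEFAULT_FORM, HRParams, VOLE_PARAMS, establish_population
from .detect import CaptureHistory
from .grids import ResourceGrid, ValueGrid
from .habitat import ResourceCoefficient
from .harvest import autocorrelated_lognormal_scatter
from .invfit import AbundanceDataset

__all__ = [
    "SiteGeneratorConfig",
    "default_coefficients",
    "DEFAULT_BASELINE",
    "gen_value_grids",
    "gen_resource_grids",
    "gen_capture_histories",
    "gen_abundance_dataset",
]


@dataclass(frozen=True)
class SiteGeneratorConfig:
    """Statistical targets for synthetic field sites."""

    n_sites: int = 31
    grid_shape: tuple[int, int] = (7, 7)
    mean_value: float = 1.64
    sd_value: float = 0.35
    within_cv: float = 0.24
    autocorr_range: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if self.grid_shape[0] < 2 or self.grid_shape[1] < 2:
            raise ValueError("grids must be at least 2x2")
        if self.mean_value <= 0 or self.sd_value < 0 or self.within_cv < 0:
            raise ValueError("mean/sd/cv must be non-negative (mean positive)")


def default_coefficients() -> list[ResourceCoefficient]:
    """Plausible stand-in resource coefficients (non-canonical).

    Shade and substrate carry constant per-unit effects; shrub and
    downed woody debris have declining logistic effects (valuable only
    while scarce), which produce the threshold-shaped cumulative value
    curves.
    """
    return [
        ResourceCoefficient(name="shrub", mode="logistic", lower=0.0, upper=0.8,
                            midpoint=1.0, scale=0.3, integration_upper=5.0),
        ResourceCoefficient(name="dwd", mode="logistic", lower=0.0, upper=0.6,
                            midpoint=1.0, scale=0.25, integration_upper=4.0),
        ResourceCoefficient(name="shade", mode="constant", b0=0.35,
                            integration_upper=5.0),
        ResourceCoefficient(name="substrate", mode="constant", b0=2.0,
                            integration_upper=1.0),
    ]


#: fixed habitat-value calibration constant paired with
#: :func:`default_coefficients` -- roughly the summed resource value of the
#: poorest field-like habitat, so typical unharvested stands score ~1.5-2.5
DEFAULT_BASELINE = 0.9


def gen_value_grids(config: SiteGeneratorConfig = SiteGeneratorConfig()) -> list[ValueGrid]:
    """Synthetic per-site habitat-value grids.

    Each site draws its mean from Normal(mean_value, sd_value)
    truncated at zero, then fills cells with autocorrelated lognormal
    scatter at the within-site CV.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    out = []
    for _ in range(config.n_sites):
        mu = -1.0
        while mu <= 0.0:
            mu = rng.normal(config.mean_value, config.sd_value)
            if config.sd_value == 0.0:
                mu = config.mean_value
                break
        base = np.full(config.grid_shape, mu)
        vals = autocorrelated_lognormal_scatter(
            base, config.within_cv, config.autocorr_range, rng=rng
        )
        out.append(ValueGrid(values=vals))
    return out


def gen_resource_grids(
    config: SiteGeneratorConfig = SiteGeneratorConfig(),
    coefs: Optional[Sequence[ResourceCoefficient]] = None,
) -> list[dict]:
    """Synthetic four-resource layers per site.

    Resource availabilities are drawn around field-like site means with
    autocorrelated lognormal scatter, correlated across layers through
    a shared site-quality factor, so that mapped habitat value
    (with :func:`default_coefficients`) lands in the reported field
    range.  Returns one dict of ResourceGrids per site.
    """
    if coefs is None:
        coefs = default_coefficients()
    rng = np.random.default_rng(config.seed + 1)
    means = {"shrub": 1.5, "dwd": 2.0, "shade": 2.9, "substrate": 0.21}
    cvs = {"shrub": 0.5, "dwd": 0.6, "shade": 0.35, "substrate": 0.55}
    by_name = {c.name: c for c in coefs}
    sites = []
    for _ in range(config.n_sites):
        quality = rng.normal(1.0, 0.15)  # shared site-quality factor
        layers = {}
        for name in ("shrub", "dwd", "shade", "substrate"):
            site_mean = max(0.05, means[name] * quality)
            base = np.full(config.grid_shape, site_mean)
            vals = autocorrelated_lognormal_scatter(
                base, cvs[name], config.autocorr_range, rng=rng
            )
            vals = np.minimum(vals, by_name[name].integration_upper)
            layers[name] = ResourceGrid(name=name, values=vals)
        sites.append(layers)
    return sites


def gen_capture_histories(
    n_true: dict,
    p_d: dict,
    seed: int = 0,
) -> list[CaptureHistory]:
    """Sequential binomial removal sampling over three days.

    ``n_true``: (site, year) -> true abundance; ``p_d``: year -> daily
    detectability.  The total caught never exceeds the true abundance
    by construction.
    """
    rng = np.random.default_rng(seed)
    out = []
    for (site, year), n in sorted(n_true.items()):
        p = p_d[year]
        remaining = int(n)
        xs = []
        for _ in range(3):
            x = int(rng.binomial(remaining, p)) if remaining > 0 else 0
            xs.append(x)
            remaining -= x
        out.append(CaptureHistory(site=str(site), year=str(year), x=tuple(xs)))
    return out


def gen_abundance_dataset(
    params: HRParams = VOLE_PARAMS,
    config: SiteGeneratorConfig = SiteGeneratorConfig(),
    noise: str = "none",
    seed: int = 0,
    restarts: int = 2,
    establishment_seed: int = 0,
    form: str = DEFAULT_FORM,
) -> tuple[AbundanceDataset, dict]:
    """Ground-truth dataset for inverse-fit recovery studies.

    Runs establishment at known parameters on generated grids;
    ``noise="poisson"`` replaces each observation with a Poisson draw
    around the model prediction.  Returns the dataset and a truth
    record (parameters, noise-free predictions, seeds).
    """
    if noise not in ("none", "poisson"):
        raise ValueError("noise must be 'none' or 'poisson'")
    grids = gen_value_grids(replace(config, seed=config.seed))
    preds = np.array(
        [
            establish_population(
                g, params, restarts=restarts, seed=establishment_seed, form=form
            ).abundance
            for g in grids
        ],
        dtype=int,
    )
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        observed = rng.poisson(np.maximum(preds, 1e-9)).astype(int)
    else:
        observed = preds.copy()
    names = tuple(f"site{i + 1:02d}" for i in range(config.n_sites))
    dataset = AbundanceDataset(names=names, grids=tuple(grids), observed=observed)
    truth = {
        "params": params,
        "predictions": preds,
        "noise": noise,
        "restarts": restarts,
        "establishment_seed": establishment_seed,
        "form": form,
    }
    return dataset, truth
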