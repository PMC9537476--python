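"""Value-of-information estimation from PSA sample tables.

EVPI is the expected gain of deciding with perfect knowledge of all
parameters: ``E[max_d NMB_d] - max_d E[NMB_d]`` over the PSA draws.  With
two strategies this reduces to ``E[max(INB, 0)] - max(E[INB], 0)`` where
INB is the per-iteration incremental net monetary benefit.

EVPPI for a parameter subset S uses the regression (conditional-
expectation) estimator: a flexible smoother of INB on the columns of S
estimates ``g(θ_S) = E[INB | θ_S]``, and
``EVPPI(S) = E[max(g, 0)] - max(E[g], 0)``.  Single parameters use
penalised B-spline regression; multi-parameter sets use Gaussian-process
regression on standardised inputs.  Standard errors come from a
nonparametric bootstrap over iterations (the smoother is refitted per
replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .psa import PSASampleTable

REFERENCE_WTP = 20_000.0


def _evpi_from_inb(inb: np.ndarray) -> float:
    return float(np.mean(np.maximum(inb, 0.0)) - max(float(np.mean(inb)), 0.0))


def evpi_per_person(table: PSASampleTable, wtp: float = REFERENCE_WTP) -> float:
    """Per-person EVPI (EUR) at the given willingness-to-pay; >= 0 by
    construction."""
    if table.n_iter < 2:
        raise ValueError("need at least 2 PSA iterations")
    return _evpi_from_inb(table.incremental_nmb(wtp))


def evpi_curve(table: PSASampleTable, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """EVPI per person across a willingness-to-pay grid."""
    return pd.DataFrame(
        {"wtp": list(wtp_grid), "evpi": [evpi_per_person(table, w) for w in wtp_grid]}
    )


# ---------------------------------------------------------------------------
# EVPPI
# ---------------------------------------------------------------------------


@dataclass
class EvppiResult:
    parameters: tuple[str, ...]
    evppi: float
    se: float
    method: str
    wtp: float


@dataclass
class VOIResult:
    """Bundle of per-person EVPI and per-parameter(-set) EVPPI."""

    wtp: float
    evpi_per_person: float
    evppi: dict[str, EvppiResult] = field(default_factory=dict)
    population_evpi: float | None = None

    def to_dict(self) -> dict:
        return {
            "wtp": self.wtp,
            "evpi_per_person": self.evpi_per_person,
            "population_evpi": self.population_evpi,
            "evppi": {
                k: {"evppi": v.evppi, "se": v.se, "method": v.method}
                for k, v in self.evppi.items()
            },
        }


def _fit_spline(x: np.ndarray, y: np.ndarray, predict_x: np.ndarray) -> np.ndarray:
    from sklearn.linear_model import Ridge
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import SplineTransformer

    n_knots = min(10, max(4, len(x) // 50))
    model = make_pipeline(
        SplineTransformer(n_knots=n_knots, degree=3, extrapolation="constant"),
        Ridge(alpha=1e-3),
    )
    model.fit(x.reshape(-1, 1), y)
    return model.predict(predict_x.reshape(-1, 1))


def _fit_gp(
    x: np.ndarray, y: np.ndarray, predict_x: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

    mu, sigma = x.mean(axis=0), x.std(axis=0)
    sigma[sigma == 0] = 1.0
    xs = (x - mu) / sigma
    ps = (predict_x - mu) / sigma
    y_mu, y_sd = y.mean(), y.std() or 1.0
    ys = (y - y_mu) / y_sd

    n_fit = min(len(xs), 750)  # GP cost is cubic; a subsample suffices for the mean
    idx = rng.choice(len(xs), size=n_fit, replace=False) if len(xs) > n_fit else np.arange(len(xs))
    kernel = ConstantKernel(1.0) * RBF(length_scale=np.ones(xs.shape[1])) + WhiteKernel(1e-1)
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=False, n_restarts_optimizer=0)
    gp.fit(xs[idx], ys[idx])
    return gp.predict(ps) * y_sd + y_mu


def evppi(
    table: PSASampleTable,
    parameters: Sequence[str],
    wtp: float = REFERENCE_WTP,
    method: str | None = None,
    n_boot: int | None = None,
    seed: int = 0,
) -> EvppiResult:
    """Regression-based EVPPI of a parameter subset, with bootstrap SE.

    ``method`` defaults to ``"spline"`` for a single parameter and
    ``"gp"`` for sets.  The bootstrap resamples PSA iterations and refits
    the smoother (100 replicates for splines, 20 for the costlier GP).
    """
    if len(parameters) == 0:
        raise ValueError("parameter subset must not be empty")
    x = table.params_matrix(parameters)
    inb = table.incremental_nmb(wtp)
    if method is None:
        method = "spline" if x.shape[1] == 1 else "gp"
    if n_boot is None:
        n_boot = 100 if method == "spline" else 20
    rng = np.random.default_rng(seed)

    def estimate(xm: np.ndarray, ym: np.ndarray) -> float:
        if method == "spline":
            g = _fit_spline(xm[:, 0], ym, xm[:, 0])
        elif method == "gp":
            g = _fit_gp(xm, ym, xm, rng)
        else:
            raise ValueError(f"unknown method {method!r}")
        return _evpi_from_inb(g)

    point = estimate(x, inb)
    boots = np.empty(n_boot)
    n = len(inb)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = estimate(x[idx], inb[idx])
    return EvppiResult(
        parameters=tuple(parameters),
        evppi=point,
        se=float(boots.std(ddof=1)),
        method=method,
        wtp=wtp,
    )


def population_evpi(
    evpi_pp: float,
    annual_affected: Sequence[float],
    discount_annual: float = 0.03,
) -> float:
    """Population EVPI: per-person EVPI times the discounted number of
    persons affected by the decision, ``sum_y counts_y / (1 + r)**y``
    (year index starting at 1)."""
    if any(c < 0 for c in annual_affected):
        raise ValueError("affected counts must be >= 0")
    total = sum(
        c / (1.0 + discount_annual) ** (y + 1) for y, c in enumerate(annual_affected)
    )
    return evpi_pp * total


def voi_report(
    table: PSASampleTable,
    subsets: dict[str, Sequence[str]],
    wtp: float = REFERENCE_WTP,
    annual_affected: Sequence[float] | None = None,
    discount_annual: float = 0.03,
    seed: int = 0,
) -> VOIResult:
    """EVPI plus EVPPI for each named subset, optionally scaled to a
    population (registry counts are user-supplied, never built in)."""
    result = VOIResult(wtp=wtp, evpi_per_person=evpi_per_person(table, wtp))
    for name, params in subsets.items():
        result.evppi[name] = evppi(table, params, wtp=wtp, seed=seed)
    if annual_affected is not None:
        result.population_evpi = population_evpi(
            result.evpi_per_person, annual_affected, discount_annual
        )
    return result
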