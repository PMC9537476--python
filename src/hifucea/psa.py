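"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by sampling every parameter that
carries a standard deviation from a moment-matched distribution:

* event probabilities and shares — beta,
* response triplets — Dirichlet, concentration matched to the
  complete-response SD (keeps the triplet on the simplex),
* costs — gamma (the fracture total scales its audit components with it),
* monthly utility levels/gains/decrements — sign-preserving truncated
  normal.

Cancer-specific mortality is held fixed, mirroring its exclusion from the
deterministic sensitivity analysis.  The inner evaluator defaults to the
deterministic cohort engine, so the only noise in the sample table is
parameter uncertainty — exactly what the value-of-information estimators
assume.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import expected_outcomes_batch
from .parameters import ParameterSet, get_param, validate
from .sensitivity import _scale_fracture_total

PARAM_PREFIX = "param."
_TREATMENTS = ("hifu", "mf_ebrt", "sf_ebrt")


@dataclass
class DistributionAssignment:
    """Family and hyperparameters for one sampled quantity."""

    path: str
    family: str  # beta | gamma | dirichlet | truncnorm | normal_clipped
    mean: float | tuple
    sd: float
    hyper: dict = field(default_factory=dict)


def _beta_hyper(mean: float, sd: float) -> dict | None:
    if sd == 0.0:
        return {}
    var = sd * sd
    if var >= mean * (1.0 - mean) or mean <= 0.0 or mean >= 1.0:
        return None
    nu = mean * (1.0 - mean) / var - 1.0
    return {"a": mean * nu, "b": (1.0 - mean) * nu}


def assign_distributions(base: ParameterSet) -> list[DistributionAssignment]:
    """Moment-matched sampling distributions for every varied parameter.

    Response triplets collapse to one Dirichlet assignment per treatment;
    infeasible beta matches (SD too large for the mean) fall back to a
    clipped normal with a warning.
    """
    out: list[DistributionAssignment] = []
    for m in _TREATMENTS:
        path = f"treatments.{m}.response"
        resp = get_param(base, path)
        probs = np.array(resp.as_tuple())
        sd_c = base.sd_table[f"{path}.p_complete"]
        if sd_c > 0:
            alpha0 = probs[0] * (1.0 - probs[0]) / sd_c**2 - 1.0
            hyper = {"alpha": probs * alpha0}
        else:
            hyper = {}
        out.append(
            DistributionAssignment(
                path=path, family="dirichlet", mean=tuple(probs), sd=sd_c, hyper=hyper
            )
        )
    for path, sd in base.sd_table.items():
        if ".response." in path:
            continue
        mean = get_param(base, path)
        if path.startswith("costs."):
            hyper = {"shape": mean**2 / sd**2, "scale": sd**2 / mean} if sd > 0 else {}
            out.append(
                DistributionAssignment(path=path, family="gamma", mean=mean, sd=sd, hyper=hyper)
            )
        elif path.startswith("utilities."):
            positive = not path.split(".")[-1].startswith("du_")
            out.append(
                DistributionAssignment(
                    path=path,
                    family="truncnorm",
                    mean=mean,
                    sd=sd,
                    hyper={"positive": positive},
                )
            )
        else:  # probabilities and shares
            hyper = _beta_hyper(mean, sd)
            if hyper is None:
                warnings.warn(
                    f"{path}: SD {sd} infeasible for beta at mean {mean}; "
                    "falling back to clipped normal",
                    stacklevel=2,
                )
                out.append(
                    DistributionAssignment(path=path, family="normal_clipped", mean=mean, sd=sd)
                )
            else:
                out.append(
                    DistributionAssignment(path=path, family="beta", mean=mean, sd=sd, hyper=hyper)
                )
    return out


def _sample_one(d: DistributionAssignment, rng: np.random.Generator):
    if d.family == "dirichlet":
        return rng.dirichlet(d.hyper["alpha"])
    if d.family == "beta":
        return float(rng.beta(d.hyper["a"], d.hyper["b"]))
    if d.family == "gamma":
        if d.sd == 0.0 or d.mean == 0.0:
            return d.mean
        return float(rng.gamma(d.hyper["shape"], d.hyper["scale"]))
    if d.family == "truncnorm":
        if d.sd == 0.0:
            return d.mean
        # truncate at the sign and at the monthly-scale sanity bound (0.09)
        # so every draw stays inside the parameter model's domain
        if d.hyper["positive"]:
            lo, hi = 1e-9, 0.09 - 1e-9
        else:
            lo, hi = -(0.09 - 1e-9), 0.0
        a, b = (lo - d.mean) / d.sd, (hi - d.mean) / d.sd
        return float(stats.truncnorm.rvs(a, b, loc=d.mean, scale=d.sd, random_state=rng))
    if d.family == "normal_clipped":
        return float(np.clip(rng.normal(d.mean, d.sd), 0.0, 1.0))
    raise ValueError(f"unknown family {d.family!r}")


def draw_parameter_set(
    base: ParameterSet,
    rng: np.random.Generator,
    assignments: list[DistributionAssignment] | None = None,
) -> tuple[ParameterSet, dict[str, float]]:
    """One PSA draw; returns the sampled set and its flat parameter record.

    The draw always satisfies every :func:`~hifucea.parameters.validate`
    invariant: triplets come off a Dirichlet, the fracture-cost components
    are scaled with the sampled total, and zero-SD entries reproduce the
    base value exactly.
    """
    if assignments is None:
        assignments = assign_distributions(base)
    ps = copy.deepcopy(base)
    record: dict[str, float] = {}
    for d in assignments:
        if d.family == "dirichlet":
            probs = _sample_one(d, rng) if np.all(np.asarray(d.sd) > 0) else np.array(d.mean)
            resp = get_param(ps, d.path)
            resp.p_complete, resp.p_partial, resp.p_none = map(float, probs)
            record[f"{d.path}.p_complete"] = resp.p_complete
            record[f"{d.path}.p_partial"] = resp.p_partial
            continue
        value = _sample_one(d, rng) if d.sd > 0 else d.mean
        if d.path == "costs.c_fracture_total":
            scaled = _scale_fracture_total(ps, value)
            ps.costs = scaled.costs
        else:
            parts = d.path.split(".")
            obj = ps
            for part in parts[:-1]:
                obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
            if isinstance(obj, dict):
                obj[parts[-1]] = value
            else:
                setattr(obj, parts[-1], value)
        record[d.path] = value
    return ps, record


@dataclass
class PSASampleTable:
    """Per-iteration sampled parameters and per-strategy outcomes.

    ``df`` holds one row per iteration: parameter columns prefixed
    ``param.`` and outcome columns ``A.cost``, ``A.qaly``, ``A.pain``,
    ``B.cost``, ``B.qaly``, ``B.pain``.
    """

    df: pd.DataFrame
    seed: int | None = None
    inner: str = "cohort"

    @property
    def n_iter(self) -> int:
        return len(self.df)

    @property
    def param_cols(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith(PARAM_PREFIX)]

    def params_matrix(self, names: Sequence[str]) -> np.ndarray:
        cols = [n if n.startswith(PARAM_PREFIX) else PARAM_PREFIX + n for n in names]
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise KeyError(f"parameters not varied in this PSA: {missing}")
        return self.df[cols].to_numpy()

    def incremental_nmb(self, wtp: float) -> np.ndarray:
        d = self.df
        return wtp * (d["A.qaly"] - d["B.qaly"]).to_numpy() - (
            d["A.cost"] - d["B.cost"]
        ).to_numpy()

    def to_csv(self, path: str) -> None:
        self.df.to_csv(path, index_label="iteration")

    @classmethod
    def from_csv(cls, path: str) -> "PSASampleTable":
        return cls(df=pd.read_csv(path, index_col="iteration"))


def run_psa(
    base: ParameterSet,
    n_iter: int,
    seed: int,
    inner: str | Callable = "cohort",
    microsim_n: int = 1000,
    check_draws: bool = False,
) -> PSASampleTable:
    """Draw ``n_iter`` parameter sets and evaluate both strategies per draw.

    ``inner="cohort"`` (default) evaluates every draw exactly with the
    batched cohort engine; ``inner="microsim"`` nests a small
    microsimulation per draw (slow, only for engine cross-checks).
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    rng = np.random.default_rng(seed)
    assignments = assign_distributions(base)
    draws: list[ParameterSet] = []
    records: list[dict[str, float]] = []
    for _ in range(n_iter):
        ps, rec = draw_parameter_set(base, rng, assignments)
        if check_draws:
            diags = validate(ps)
            if diags:
                raise RuntimeError("PSA draw violated invariants: " + "; ".join(diags))
        draws.append(ps)
        records.append(rec)

    data = {PARAM_PREFIX + k: [r[k] for r in records] for k in records[0]}
    if inner == "cohort":
        for strat in ("A", "B"):
            out = expected_outcomes_batch(strat, draws)
            data[f"{strat}.cost"] = out["cost"]
            data[f"{strat}.qaly"] = out["qaly"]
            data[f"{strat}.pain"] = out["pain"]
    elif inner == "microsim":
        from .microsim import SimulationConfig, run_arm

        for strat in ("A", "B"):
            cols = {"cost": [], "qaly": [], "pain": []}
            for i, ps in enumerate(draws):
                res = run_arm(strat, ps, SimulationConfig(n_patients=microsim_n, seed=seed + i))
                cols["cost"].append(res.mean_cost)
                cols["qaly"].append(res.mean_qaly)
                cols["pain"].append(res.mean_pain_months)
            for k, v in cols.items():
                data[f"{strat}.{k}"] = v
    else:
        raise ValueError(f"unknown inner evaluator {inner!r}")
    return PSASampleTable(df=pd.DataFrame(data), seed=seed, inner=str(inner))


# ---------------------------------------------------------------------------
# CE plane and CEAC
# ---------------------------------------------------------------------------


def ceac(table: PSASampleTable, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve for strategy A.

    For each willingness-to-pay, the fraction of iterations in which
    strategy A has the higher net monetary benefit; exact ties count 0.5.
    """
    if table.n_iter == 0:
        raise ValueError("empty PSA table")
    rows = []
    for wtp in wtp_grid:
        inb = table.incremental_nmb(wtp)
        p = (np.sum(inb > 0) + 0.5 * np.sum(inb == 0)) / len(inb)
        rows.append({"wtp": wtp, "p_cost_effective": p})
    return pd.DataFrame(rows)


def ce_plane_quadrants(table: PSASampleTable) -> dict[str, float]:
    """Fractions of iterations per CE-plane quadrant (ΔE on x, ΔC on y);
    the four fractions sum to one (boundary cases join the closed quadrant
    clockwise from north-east)."""
    d = table.df
    dc = (d["A.cost"] - d["B.cost"]).to_numpy()
    de = (d["A.qaly"] - d["B.qaly"]).to_numpy()
    n = len(dc)
    ne = np.sum((de > 0) & (dc > 0))
    se = np.sum((de > 0) & (dc <= 0))
    nw = np.sum((de <= 0) & (dc > 0))
    sw = n - ne - se - nw
    return {"NE": ne / n, "SE": se / n, "NW": nw / n, "SW": sw / n}


def ce_plane_ellipse(table: PSASampleTable) -> dict[str, np.ndarray]:
    """Mean and covariance of (ΔQALY, Δcost) for a bivariate-normal 95%
    confidence ellipse on the CE plane."""
    d = table.df
    pts = np.column_stack(
        [
            (d["A.qaly"] - d["B.qaly"]).to_numpy(),
            (d["A.cost"] - d["B.cost"]).to_numpy(),
        ]
    )
    return {"mean": pts.mean(axis=0), "cov": np.cov(pts.T)}
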