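"""Synthetic fixtures: randomized valid parameter sets and PSA tables with
analytically known value-of-information.

These generators make every stage of the pipeline testable without external
data: perturbed parameter sets drive the microsimulation-vs-cohort oracle
sweeps, and the Gaussian/linear net-benefit tables provide closed-form EVPI
and EVPPI ground truths for the estimators.  Ground truths are computed
from the Gaussian closed form below, never from the estimators under test.
"""

from __future__ import annotations

import copy
import math

import numpy as np
import pandas as pd

from .parameters import ParameterSet, builtin_basecase, validate
from .psa import PSASampleTable

REFERENCE_WTP = 20_000.0


def gaussian_evpi(m: float, sigma: float) -> float:
    """Closed-form EVPI when the incremental net benefit is N(m, sigma^2):
    ``m·Φ(m/σ) + σ·φ(m/σ) - max(0, m)`` (the expected shortfall of always
    picking the on-average-better strategy)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return 0.0
    z = m / sigma
    phi = math.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
    Phi = 0.5 * math.erfc(-z / math.sqrt(2.0))
    return m * Phi + sigma * phi - max(0.0, m)


# ---------------------------------------------------------------------------
# perturbed model parameters
# ---------------------------------------------------------------------------

_PROB_ATTRS = ("p_retreat_monthly", "p_fracture_monthly")


def perturbed_params(seed: int, jitter: float = 0.2) -> ParameterSet:
    """A randomized, always-valid parameter set around the base case.

    Every scalar is scaled by ``1 + jitter·U(-1, 1)`` and clipped to its
    domain; response triplets are renormalised back onto the simplex and
    mortality is perturbed too (unlike in PSA) so that engine-equivalence
    sweeps also exercise the survival machinery.  ``jitter=0`` reproduces
    the base case exactly.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    ps = builtin_basecase()
    if jitter == 0:
        return ps
    rng = np.random.default_rng(seed)

    def j(value: float, lo: float | None = None, hi: float | None = None) -> float:
        out = value * (1.0 + jitter * rng.uniform(-1.0, 1.0))
        if lo is not None:
            out = max(out, lo)
        if hi is not None:
            out = min(out, hi)
        return out

    for tr in ps.treatments.values():
        r = tr.response
        probs = np.array([j(r.p_complete, 1e-6), j(r.p_partial, 1e-6), j(r.p_none, 1e-6)])
        probs /= probs.sum()
        r.p_complete, r.p_partial, r.p_none = map(float, probs)
        for attr in _PROB_ATTRS:
            setattr(tr, attr, j(getattr(tr, attr), 0.0, 0.9))
        if tr.p_no_response_retreat is not None:
            tr.p_no_response_retreat = j(tr.p_no_response_retreat, 0.0, 1.0)
    ps.p_relapse_monthly = j(ps.p_relapse_monthly, 0.0, 0.9)

    for mt in ps.mortality.values():
        mt.monthly_p_by_year = tuple(j(p, 1e-4, 0.5) for p in mt.monthly_p_by_year)

    mix = np.array([j(w, 1e-6) for w in ps.cancer_mix])
    ps.cancer_mix = tuple(float(w) for w in mix / mix.sum())

    u = ps.utilities
    u.u_base = j(u.u_base, 1e-4, 0.089)
    u.gain_complete = j(u.gain_complete, 1e-6, 0.089)
    u.gain_partial = j(u.gain_partial, 1e-6, 0.089)
    for attr in ("du_fracture", "du_mf_ebrt", "du_sf_ebrt", "du_hifu"):
        setattr(u, attr, -j(-getattr(u, attr), 0.0, 0.089))

    c = ps.costs
    for attr in (
        "c_mri_outpatient",
        "c_hifu_inpatient",
        "c_mf_ebrt_outpatient",
        "c_mf_ebrt_inpatient",
        "c_sf_ebrt",
        "c_opioid_monthly",
    ):
        setattr(c, attr, j(getattr(c, attr), 0.0))
    scale = 1.0 + jitter * rng.uniform(-1.0, 1.0)
    for attr in (
        "c_fracture_total",
        "c_fracture_outpatient",
        "c_fracture_inpatient",
        "c_fracture_rehabilitation",
        "c_fracture_prescriptions",
        "c_fracture_aids",
    ):
        setattr(c, attr, getattr(c, attr) * scale)

    s = ps.strategy
    s.share_hifu_firstline_A = j(s.share_hifu_firstline_A, 0.0, 1.0)
    s.share_sf_ebrt = j(s.share_sf_ebrt, 0.0, 1.0)
    s.share_ebrt_outpatient = j(s.share_ebrt_outpatient, 0.0, 1.0)

    diags = validate(ps)
    if diags:  # pragma: no cover - clipping above should prevent this
        raise RuntimeError("perturbed_params produced an invalid set: " + "; ".join(diags))
    return ps


# ---------------------------------------------------------------------------
# synthetic PSA tables with analytic VOI
# ---------------------------------------------------------------------------


def _table_from_inb(
    inb: np.ndarray, params: dict[str, np.ndarray], wtp: float
) -> PSASampleTable:
    """Wrap an incremental-net-benefit sample into a two-strategy table.

    Strategy B is held constant; strategy A differs only in QALYs by
    ``inb / wtp`` so the table's incremental NMB at ``wtp`` is exactly
    ``inb``.
    """
    n = len(inb)
    data = {f"param.{k}": v for k, v in params.items()}
    data.update(
        {
            "A.cost": np.full(n, 8000.0),
            "A.qaly": 1.0 + inb / wtp,
            "A.pain": np.full(n, 10.0),
            "B.cost": np.full(n, 8000.0),
            "B.qaly": np.full(n, 1.0),
            "B.pain": np.full(n, 9.5),
        }
    )
    return PSASampleTable(df=pd.DataFrame(data), inner="synthetic")


def gaussian_nb_psa(
    m: float, sigma: float, n_iter: int, seed: int, wtp: float = REFERENCE_WTP
) -> tuple[PSASampleTable, float]:
    """Two-strategy table whose incremental NMB is i.i.d. N(m, sigma^2),
    plus the closed-form EVPI ground truth."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    inb = rng.normal(m, sigma, size=n_iter)
    table = _table_from_inb(inb, {"inb_draw": inb}, wtp)
    return table, gaussian_evpi(m, sigma)


def linear_theta_psa(
    weights: tuple[float, ...],
    noise: float,
    n_iter: int,
    seed: int,
    wtp: float = REFERENCE_WTP,
) -> tuple[PSASampleTable, dict]:
    """Table with ``INB = Σ w_j·θ_j + ε``, θ_j ~ N(0,1), ε ~ N(0, noise²).

    Ground truth: EVPPI of subset S is the Gaussian EVPI at mean 0 and
    ``σ_S = sqrt(Σ_{j∈S} w_j²)`` (i.e. ``σ_S/sqrt(2π)``); total EVPI adds
    the noise variance.  Returned truths map subset names ``theta_j`` and
    tuples of indices to EUR values.
    """
    k = len(weights)
    if k < 2:
        raise ValueError("need at least 2 parameters")
    rng = np.random.default_rng(seed)
    theta = rng.normal(0.0, 1.0, size=(n_iter, k))
    eps = rng.normal(0.0, noise, size=n_iter) if noise > 0 else np.zeros(n_iter)
    w = np.asarray(weights, dtype=float)
    inb = theta @ w + eps
    params = {f"theta_{j}": theta[:, j] for j in range(k)}
    table = _table_from_inb(inb, params, wtp)

    truths: dict = {
        "evpi": gaussian_evpi(0.0, float(np.sqrt(w @ w + noise**2))),
    }
    for j in range(k):
        truths[f"theta_{j}"] = gaussian_evpi(0.0, abs(w[j]))
    truths["all_thetas"] = gaussian_evpi(0.0, float(np.sqrt(w @ w)))
    return table, truths
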