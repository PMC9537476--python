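"""Patient-level Monte-Carlo simulation of the identical model.

Simulates individual trajectories with the same event order, accrual rules
and discounting as :mod:`hifucea.cohort`; means converge to the cohort
engine's exact expectations (that equivalence is property-tested).

Random-number design
--------------------
Each patient owns independent substreams derived from the master seed and
the patient index alone (``SeedSequence((seed, i, stream))``), so enlarging
``n_patients`` never reshuffles earlier patients.  With common random
numbers (CRN) enabled, both strategy arms share one event stream per
patient covering cancer assignment, first-line allocation, death, relapse,
retreatment uptake, and fracture; response-category draws come from
strategy-specific streams (the treatments differ, so forcing identical
response draws would be meaningless).  Because mortality is independent of
strategy and state, a patient dies in the same cycle in both arms under
CRN, which strongly correlates the arms and shrinks the variance of
incremental outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cohort as cohort_mod
from .cohort import (
    ONSET_FRACTION_EBRT,
    ONSET_FRACTION_HIFU,
    ArmResult,
    initial_response_distribution,
    retreat_response_distribution,
)
from .parameters import CANCERS, ParameterSet, validate

_CHUNK = 64  # cycles of event uniforms drawn per refill

# substream tags
_SHARED, _RESP_A, _RESP_B, _INDEP_BASE = 0, 1, 2, 10


@dataclass
class SimulationConfig:
    """Size, seeding and pairing of a microsimulation run."""

    n_patients: int = 200_000
    seed: int = 0
    crn: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


def _patient_rng(seed: int, i: int, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, i, stream))))


class _EventStream:
    """Chunked per-cycle event uniforms: (death, relapse, retreat, fracture).

    All four uniforms are consumed every alive cycle whether or not the
    event applies, keeping CRN streams aligned across strategies.
    """

    def __init__(self, rng: np.random.Generator):
        self._rng = rng
        self._buf = rng.random((_CHUNK, 4))
        self._pos = 0

    def next(self) -> np.ndarray:
        if self._pos == len(self._buf):
            self._buf = self._rng.random((_CHUNK, 4))
            self._pos = 0
        row = self._buf[self._pos]
        self._pos += 1
        return row


def _pick(u: float, probs) -> int:
    acc = 0.0
    for k, p in enumerate(probs):
        acc += p
        if u < acc:
            return k
    return len(probs) - 1


def simulate_patient(
    strategy: str,
    params: ParameterSet,
    shared_rng: np.random.Generator,
    resp_rng: np.random.Generator,
) -> tuple[float, float, float, float]:
    """Simulate one lifetime; returns discounted (cost, qaly, pain_months)
    plus undiscounted pain months."""
    s = params.strategy
    u_cancer, u_first, u_sf = shared_rng.random(3)
    cancer = _pick(u_cancer, params.cancer_mix)
    mort = params.mortality[CANCERS[cancer]]

    if strategy == "A" and u_first < s.share_hifu_firstline_A:
        firstline = "hifu"
    else:
        firstline = "sf_ebrt" if u_sf < s.share_sf_ebrt else "mf_ebrt"

    c = params.costs
    u = params.utilities
    c_mf = s.share_ebrt_outpatient * c.c_mf_ebrt_outpatient + (
        1.0 - s.share_ebrt_outpatient
    ) * c.c_mf_ebrt_inpatient
    ebrt_blend_cost = (1.0 - s.share_sf_ebrt) * c_mf + s.share_sf_ebrt * c.c_sf_ebrt
    ebrt_blend_du = (1.0 - s.share_sf_ebrt) * u.du_mf_ebrt + (
        s.share_sf_ebrt * u.du_sf_ebrt
    )
    ebrt_blend_frac = (1.0 - s.share_sf_ebrt) * params.treatments[
        "mf_ebrt"
    ].p_fracture_monthly + s.share_sf_ebrt * params.treatments["sf_ebrt"].p_fracture_monthly
    ebrt_blend_resp = (1.0 - s.share_sf_ebrt) * np.array(
        params.treatments["mf_ebrt"].response.as_tuple()
    ) + s.share_sf_ebrt * np.array(params.treatments["sf_ebrt"].response.as_tuple())

    # retreat pathway for this patient (mirrors cohort._strata)
    if strategy == "A":
        elig_partial = s.retreat_eligibility_A == "persistent_or_partial"
        if firstline == "hifu":
            re_rate = params.treatments["hifu"].p_retreat_monthly if s.hifu_first_ebrt_retreat else 0.0
            re_cost, re_du = ebrt_blend_cost, ebrt_blend_du
            re_resp, re_onset = ebrt_blend_resp, ONSET_FRACTION_EBRT
            frac1 = ebrt_blend_frac
        else:
            re_rate = (
                params.treatments["hifu"].p_retreat_monthly
                if s.ebrt_first_retreat_rate == "strategy"
                else params.treatments[firstline].p_retreat_monthly
            )
            re_cost, re_du = c.c_hifu_inpatient, u.du_hifu
            re_resp = retreat_response_distribution("A", "hifu", params)
            re_onset = ONSET_FRACTION_HIFU
            frac1 = params.treatments["hifu"].p_fracture_monthly
    else:
        elig_partial = s.retreat_eligibility_B == "persistent_or_partial"
        re_rate = params.treatments[firstline].p_retreat_monthly
        re_cost = c_mf if firstline == "mf_ebrt" else c.c_sf_ebrt
        re_du = u.du_mf_ebrt if firstline == "mf_ebrt" else u.du_sf_ebrt
        re_resp = retreat_response_distribution("B", firstline, params)
        re_onset = ONSET_FRACTION_EBRT
        frac1 = params.treatments[firstline].p_fracture_monthly
    frac0 = params.treatments[firstline].p_fracture_monthly

    entry_resp, entry_onset = initial_response_distribution(strategy, firstline, params)
    if firstline == "hifu":
        entry_cost = c.c_mri_outpatient + c.c_hifu_inpatient
    elif firstline == "mf_ebrt":
        entry_cost = c_mf
    else:
        entry_cost = c.c_sf_ebrt
    entry_du = {"hifu": u.du_hifu, "mf_ebrt": u.du_mf_ebrt, "sf_ebrt": u.du_sf_ebrt}[firstline]

    disc_base = 1.0 / (1.0 + params.discount_annual) ** (1.0 / 12.0)
    # pain states mirror the cohort engine: 0 complete, 1 partial,
    # 2 relapsed persistent, 3 never-responded persistent
    gain = (u.gain_complete, u.gain_partial, 0.0, 0.0)
    pool_any = s.retreat_pool == "any_persistent"

    # entry cycle (t = 0)
    r = _pick(resp_rng.random(), entry_resp)
    if r == 2:
        r = 3  # never responded
    cost = entry_cost
    qaly = entry_du
    f = entry_onset if r < 2 else 0.0
    qaly += u.u_base + gain[r] * f
    pain = pain_u = f
    act_c = f if r == 0 else 0.0
    cost += c.c_opioid_monthly * (1.0 - act_c)

    events = _EventStream(shared_rng)
    retreat_used = False
    fractured = False
    d = 1.0
    for t in range(1, params.horizon_months):
        d *= disc_base
        u_death, u_relapse, u_retreat, u_fracture = events.next()
        if u_death < mort.monthly_p(t):
            break
        if r < 2 and u_relapse < params.p_relapse_monthly:
            r = 2
        # defaults: response (if any) active for the full month
        g = gain[r]
        pm = 1.0 if r < 2 else 0.0
        ac = 1.0 if r == 0 else 0.0  # complete-active fraction (no opioids)
        eligible = r == 2 or (r == 3 and pool_any) or (r == 1 and elig_partial)
        if not retreat_used and eligible and u_retreat < re_rate:
            retreat_used = True
            cost += d * re_cost
            qaly += d * re_du
            u_resp = resp_rng.random()
            if r >= 2:
                drawn = _pick(u_resp, re_resp)
                if drawn < 2:  # responded; "none" leaves pain unchanged
                    r = drawn
                    f = re_onset
                    g, pm, ac = gain[r] * f, f, (f if r == 0 else 0.0)
            else:
                p_up = (
                    re_resp[0] + re_resp[1]
                    if cohort_mod.PARTIAL_UPGRADE == "any_response"
                    else re_resp[0]
                )
                if u_resp < p_up:
                    # partial responder responds to the retreat: residual
                    # pain resolves, i.e. upgrade to complete relief
                    r = 0
                    g = u.gain_complete * re_onset + u.gain_partial * (1.0 - re_onset)
                    pm, ac = 1.0, re_onset
                # a failed attempt leaves the partial response unchanged
        if not fractured and u_fracture < (frac1 if retreat_used else frac0):
            fractured = True
            cost += d * c.c_fracture_total
            qaly += d * u.du_fracture
        qaly += d * (u.u_base + g)
        pain += d * pm
        pain_u += pm
        cost += d * c.c_opioid_monthly * (1.0 - ac)
    return cost, qaly, pain, pain_u


def _arm_streams(strategy: str, config: SimulationConfig, i: int):
    resp_tag = _RESP_A if strategy == "A" else _RESP_B
    if config.crn:
        shared = _patient_rng(config.seed, i, _SHARED)
    else:
        shared = _patient_rng(config.seed, i, _INDEP_BASE + resp_tag)
    return shared, _patient_rng(config.seed, i, resp_tag)


def run_arm(
    strategy: str,
    params: ParameterSet,
    config: SimulationConfig,
    return_patients: bool = False,
) -> ArmResult | tuple[ArmResult, np.ndarray]:
    """Simulate ``config.n_patients`` lifetimes under one strategy.

    Returns an :class:`~hifucea.cohort.ArmResult` with Monte-Carlo standard
    errors; with ``return_patients=True`` also the per-patient array of
    (cost, qaly, pain, pain_undiscounted).
    """
    diags = validate(params)
    if diags:
        raise ValueError("invalid parameter set: " + "; ".join(diags))
    n = config.n_patients
    acc = np.empty((n, 4))
    for i in range(n):
        shared, resp = _arm_streams(strategy, config, i)
        acc[i] = simulate_patient(strategy, params, shared, resp)
    mean = acc.mean(axis=0)
    se = acc.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(4)
    result = ArmResult(
        strategy=strategy,
        mean_cost=float(mean[0]),
        mean_qaly=float(mean[1]),
        mean_pain_months=float(mean[2]),
        mean_pain_months_undiscounted=float(mean[3]),
        se_cost=float(se[0]),
        se_qaly=float(se[1]),
        se_pain=float(se[2]),
        n=n,
        engine="microsim",
    )
    if return_patients:
        return result, acc
    return result


def run_paired(
    params: ParameterSet, config: SimulationConfig
) -> tuple[ArmResult, ArmResult, dict[str, float]]:
    """Run both arms and summarise the paired incremental outcomes.

    The returned dict holds the mean and standard error of the per-patient
    differences (A minus B), which is where common random numbers pay off.
    """
    res_a, acc_a = run_arm("A", params, config, return_patients=True)
    res_b, acc_b = run_arm("B", params, config, return_patients=True)
    diff = acc_a - acc_b
    n = config.n_patients
    se = diff.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(4)
    delta = {
        "delta_cost": float(diff[:, 0].mean()),
        "delta_qaly": float(diff[:, 1].mean()),
        "delta_pain_months": float(diff[:, 2].mean()),
        "se_delta_cost": float(se[0]),
        "se_delta_qaly": float(se[1]),
        "se_delta_pain": float(se[2]),
    }
    return res_a, res_b, delta
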