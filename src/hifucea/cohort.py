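"""Deterministic cohort engine.

Propagates the full joint state distribution of the model month by month and
returns *exact* expected discounted cost (EUR), QALYs, and pain-response
months per strategy.  It is the oracle against which the patient-level
microsimulation is checked, and the fast inner evaluator for probabilistic
sensitivity and value-of-information analyses (the engine is natively
batched over parameter sets).

Model mechanics
---------------
Patients enter the model in the cycle of their first-line treatment (cycle
0: treatment cost + treatment disutility + first accrual).  Each subsequent
monthly cycle applies, in this order:

1. death (cancer- and year-specific monthly probability; dead is absorbing
   and accrues nothing),
2. pain relapse: complete/partial response -> persistent pain,
3. retreatment uptake among the eligible (at most one retreatment per
   patient, never MR-HIFU after MR-HIFU); a retreated patient redraws the
   response category and incurs the retreatment cost and disutility in that
   cycle,
4. pathological fracture (at most once per patient; one-off cost and
   disutility in the event cycle),
5. accrual: utility = base + response gain + event decrements; cost =
   monthly opioid unless in complete response; response gains and
   pain-response time respect onset timing (MR-HIFU: day 7, i.e. 23/30 of
   the treatment cycle; EBRT: four weeks, i.e. nothing in the treatment
   cycle and full response from the next).

All accruals are discounted at ``(1 + r)**(-cycle/12)``.  No half-cycle
correction is applied (immaterial at monthly cycles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .parameters import CANCERS, ParameterSet, validate

#: Fraction of the treatment cycle spent in response when palliation sets in
#: after 7 days (MR-HIFU).  EBRT onset (four weeks) contributes nothing to
#: the treatment cycle.
ONSET_FRACTION_HIFU = 23.0 / 30.0
ONSET_FRACTION_EBRT = 0.0

MASS_TOL = 1e-9

STRATEGIES = ("A", "B")

#: Outcome rule for retreating a *partial* responder.  "complete_only"
#: (default) is a floored redraw: the response category is redrawn from the
#: retreat profile and the patient keeps the better of old and new states,
#: so only a complete-response draw changes anything.  "any_response"
#: instead upgrades to complete relief whenever the retreat produces any
#: response (treating the residual pain).  Either way a failed retreat
#: never worsens pain.
PARTIAL_UPGRADE = "complete_only"


class MassConservationError(RuntimeError):
    """Probability mass leaked beyond tolerance during a cohort update."""


@dataclass
class ArmResult:
    """Expected discounted outcomes of one strategy arm.

    Monte-Carlo standard errors are zero for the cohort engine; the
    microsimulation fills them in.
    """

    strategy: str
    mean_cost: float
    mean_qaly: float
    mean_pain_months: float
    se_cost: float = 0.0
    se_qaly: float = 0.0
    se_pain: float = 0.0
    n: int = 1
    mean_pain_months_undiscounted: float = float("nan")
    engine: str = "cohort"

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "engine": self.engine,
            "mean_cost": self.mean_cost,
            "mean_qaly": self.mean_qaly,
            "mean_pain_months": self.mean_pain_months,
            "mean_pain_months_undiscounted": self.mean_pain_months_undiscounted,
            "se_cost": self.se_cost,
            "se_qaly": self.se_qaly,
            "se_pain": self.se_pain,
            "n": self.n,
        }


def discount_factor(annual_rate: float, cycle: int | np.ndarray) -> float | np.ndarray:
    """Discount factor ``(1 + r)**(-cycle/12)`` for a monthly cycle index."""
    if np.any(np.asarray(annual_rate) < 0):
        raise ValueError("annual_rate must be >= 0")
    if np.any(np.asarray(cycle) < 0):
        raise ValueError("cycle must be >= 0")
    return (1.0 + annual_rate) ** (-np.asarray(cycle, dtype=float) / 12.0)


# ---------------------------------------------------------------------------
# response distributions
# ---------------------------------------------------------------------------


def initial_response_distribution(
    strategy: str, firstline: str, params: ParameterSet
) -> tuple[np.ndarray, float]:
    """Entry-cycle weights over (complete, partial, persistent) plus the
    onset fraction of the entry cycle spent in response."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    allowed = ("hifu", "mf_ebrt", "sf_ebrt") if strategy == "A" else ("mf_ebrt", "sf_ebrt")
    if firstline not in allowed:
        raise ValueError(f"modality {firstline!r} not valid for strategy {strategy}")
    r = params.treatments[firstline].response
    f = ONSET_FRACTION_HIFU if r.onset_days == 7 else ONSET_FRACTION_EBRT
    return np.array(r.as_tuple(), dtype=float), f


def retreat_response_distribution(
    strategy: str, modality_of_retreat: str, params: ParameterSet
) -> np.ndarray:
    """Weights over (complete, partial, persistent) after a retreatment.

    Strategy A retreatments use the first-line profile of the retreat
    modality (MR-HIFU after EBRT behaves like first-line MR-HIFU; EBRT after
    MR-HIFU treats radiation-naive bone).  Strategy B re-irradiation is
    inferior: no response with probability ``p_no_response_retreat`` and the
    remainder split between complete/partial in the modality's first-line
    ratio.
    """
    tr = params.treatments[modality_of_retreat]
    first = np.array(tr.response.as_tuple(), dtype=float)
    if strategy == "A":
        return first
    if strategy == "B":
        if tr.p_no_response_retreat is None:
            raise ValueError(f"{modality_of_retreat} has no re-irradiation response probability")
        p_none = tr.p_no_response_retreat
        denom = first[:2].sum()
        ratio = first[:2] / denom if denom > 0 else np.array([0.5, 0.5])
        return np.array([(1.0 - p_none) * ratio[0], (1.0 - p_none) * ratio[1], p_none])
    raise ValueError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# batched parameter arrays
# ---------------------------------------------------------------------------


@dataclass
class _Batch:
    """Parameter arrays with a leading batch axis (internal)."""

    B: int
    resp: dict[str, np.ndarray]  # modality -> (B, 3)
    onset: dict[str, float]  # modality -> scalar onset fraction
    p_retreat: dict[str, np.ndarray]  # (B,)
    p_nrr: dict[str, np.ndarray]  # (B,), re-irradiation no-response
    p_frac: dict[str, np.ndarray]  # (B,)
    du_treat: dict[str, np.ndarray]  # (B,)
    p_relapse: np.ndarray  # (B,)
    mortality: np.ndarray  # (B, 3 cancers, 5 years)
    mortality_extrap: np.ndarray  # (B, 3)
    cancer_mix: np.ndarray  # (B, 3)
    u_base: np.ndarray
    gain: np.ndarray  # (B, 2) complete/partial
    du_fracture: np.ndarray
    c_mri: np.ndarray
    c_hifu: np.ndarray
    c_mf: np.ndarray  # blended in/out-patient multi-fraction cost
    c_sf: np.ndarray
    c_fracture: np.ndarray
    c_opioid: np.ndarray
    share_hifu: np.ndarray
    share_sf: np.ndarray
    discount: float
    horizon: int
    elig_partial: dict[str, bool] = field(default_factory=dict)  # strategy -> partial eligible
    ebrt_first_retreat_rate: str = "strategy"
    hifu_first_ebrt_retreat: bool = True
    retreat_pool: str = "any_persistent"


def _compile(param_sets: Sequence[ParameterSet]) -> _Batch:
    B = len(param_sets)
    p0 = param_sets[0]
    for ps in param_sets[1:]:
        if ps.discount_annual != p0.discount_annual or ps.horizon_months != p0.horizon_months:
            raise ValueError("batched parameter sets must share discount rate and horizon")
        if ps.strategy.retreat_eligibility_A != p0.strategy.retreat_eligibility_A or (
            ps.strategy.retreat_eligibility_B != p0.strategy.retreat_eligibility_B
            or ps.strategy.retreat_pool != p0.strategy.retreat_pool
        ):
            raise ValueError("batched parameter sets must share eligibility rules")

    def arr(fn):
        return np.array([fn(ps) for ps in param_sets], dtype=float)

    resp, p_retreat, p_nrr, p_frac, du_treat, onset = {}, {}, {}, {}, {}, {}
    for m in ("hifu", "mf_ebrt", "sf_ebrt"):
        resp[m] = arr(lambda ps, m=m: ps.treatments[m].response.as_tuple())
        onset[m] = (
            ONSET_FRACTION_HIFU
            if p0.treatments[m].response.onset_days == 7
            else ONSET_FRACTION_EBRT
        )
        p_retreat[m] = arr(lambda ps, m=m: ps.treatments[m].p_retreat_monthly)
        p_frac[m] = arr(lambda ps, m=m: ps.treatments[m].p_fracture_monthly)
        du_attr = {"hifu": "du_hifu", "mf_ebrt": "du_mf_ebrt", "sf_ebrt": "du_sf_ebrt"}[m]
        du_treat[m] = arr(lambda ps, a=du_attr: getattr(ps.utilities, a))
        p_nrr[m] = arr(
            lambda ps, m=m: ps.treatments[m].p_no_response_retreat
            if ps.treatments[m].p_no_response_retreat is not None
            else np.nan
        )

    mort = np.array(
        [[ps.mortality[c].monthly_p_by_year for c in CANCERS] for ps in param_sets], dtype=float
    )
    extrap = np.array(
        [
            [
                ps.mortality[c].extrapolation_p
                if ps.mortality[c].extrapolation_p is not None
                else ps.mortality[c].monthly_p_by_year[4]
                for c in CANCERS
            ]
            for ps in param_sets
        ],
        dtype=float,
    )
    share_out = arr(lambda ps: ps.strategy.share_ebrt_outpatient)
    c_mf = arr(lambda ps: ps.costs.c_mf_ebrt_outpatient) * share_out + arr(
        lambda ps: ps.costs.c_mf_ebrt_inpatient
    ) * (1.0 - share_out)

    return _Batch(
        B=B,
        resp=resp,
        onset=onset,
        p_retreat=p_retreat,
        p_nrr=p_nrr,
        p_frac=p_frac,
        du_treat=du_treat,
        p_relapse=arr(lambda ps: ps.p_relapse_monthly),
        mortality=mort,
        mortality_extrap=extrap,
        cancer_mix=arr(lambda ps: ps.cancer_mix),
        u_base=arr(lambda ps: ps.utilities.u_base),
        gain=arr(lambda ps: (ps.utilities.gain_complete, ps.utilities.gain_partial)),
        du_fracture=arr(lambda ps: ps.utilities.du_fracture),
        c_mri=arr(lambda ps: ps.costs.c_mri_outpatient),
        c_hifu=arr(lambda ps: ps.costs.c_hifu_inpatient),
        c_mf=c_mf,
        c_sf=arr(lambda ps: ps.costs.c_sf_ebrt),
        c_fracture=arr(lambda ps: ps.costs.c_fracture_total),
        c_opioid=arr(lambda ps: ps.costs.c_opioid_monthly),
        share_hifu=arr(lambda ps: ps.strategy.share_hifu_firstline_A),
        share_sf=arr(lambda ps: ps.strategy.share_sf_ebrt),
        discount=p0.discount_annual,
        horizon=p0.horizon_months,
        elig_partial={
            "A": p0.strategy.retreat_eligibility_A == "persistent_or_partial",
            "B": p0.strategy.retreat_eligibility_B == "persistent_or_partial",
        },
        ebrt_first_retreat_rate=p0.strategy.ebrt_first_retreat_rate,
        hifu_first_ebrt_retreat=p0.strategy.hifu_first_ebrt_retreat,
        retreat_pool=p0.strategy.retreat_pool,
    )


def _strata(strategy: str, P: _Batch) -> list[dict]:
    """Per-stratum (first-line pathway) configuration for one strategy.

    Each stratum fixes the entry treatment and the retreat pathway; weights
    are batch arrays and may depend on sampled shares.
    """
    ones = np.ones(P.B)
    ebrt_blend_resp = (1.0 - P.share_sf)[:, None] * P.resp["mf_ebrt"] + P.share_sf[:, None] * P.resp["sf_ebrt"]
    ebrt_blend_cost = (1.0 - P.share_sf) * P.c_mf + P.share_sf * P.c_sf
    ebrt_blend_du = (1.0 - P.share_sf) * P.du_treat["mf_ebrt"] + P.share_sf * P.du_treat["sf_ebrt"]
    ebrt_blend_frac = (1.0 - P.share_sf) * P.p_frac["mf_ebrt"] + P.share_sf * P.p_frac["sf_ebrt"]

    def reirr(m: str) -> np.ndarray:
        first = P.resp[m]
        denom = first[:, :2].sum(axis=1, keepdims=True)
        ratio = np.where(denom > 0, first[:, :2] / np.where(denom > 0, denom, 1.0), 0.5)
        pn = P.p_nrr[m]
        out = np.empty_like(first)
        out[:, 0] = (1.0 - pn) * ratio[:, 0]
        out[:, 1] = (1.0 - pn) * ratio[:, 1]
        out[:, 2] = pn
        return out

    strata: list[dict] = []
    if strategy == "A":
        # MR-HIFU first line; optional EBRT retreatment (radiation-naive profile).
        strata.append(
            dict(
                weight=P.share_hifu,
                entry_cost=P.c_mri + P.c_hifu,
                entry_du=P.du_treat["hifu"],
                entry_resp=P.resp["hifu"],
                entry_onset=P.onset["hifu"],
                re_rate=P.p_retreat["hifu"] if P.hifu_first_ebrt_retreat else 0.0 * ones,
                re_cost=ebrt_blend_cost,
                re_du=ebrt_blend_du,
                re_resp=ebrt_blend_resp,
                re_onset=P.onset["mf_ebrt"],
                frac0=P.p_frac["hifu"],
                frac1=ebrt_blend_frac,
                elig_partial=P.elig_partial["A"],
            )
        )
        # EBRT first line (MF and SF), MR-HIFU as the retreatment.
        for m, w in (
            ("mf_ebrt", (1.0 - P.share_hifu) * (1.0 - P.share_sf)),
            ("sf_ebrt", (1.0 - P.share_hifu) * P.share_sf),
        ):
            rate = P.p_retreat["hifu"] if P.ebrt_first_retreat_rate == "strategy" else P.p_retreat[m]
            strata.append(
                dict(
                    weight=w,
                    entry_cost=P.c_mf if m == "mf_ebrt" else P.c_sf,
                    entry_du=P.du_treat[m],
                    entry_resp=P.resp[m],
                    entry_onset=P.onset[m],
                    re_rate=rate,
                    re_cost=P.c_hifu,  # no pre-treatment out-patient MRI on retreat
                    re_du=P.du_treat["hifu"],
                    re_resp=P.resp["hifu"],
                    re_onset=P.onset["hifu"],
                    frac0=P.p_frac[m],
                    frac1=P.p_frac["hifu"],
                    elig_partial=P.elig_partial["A"],
                )
            )
    elif strategy == "B":
        # EBRT first line with same-modality re-irradiation.
        for m, w in (("mf_ebrt", 1.0 - P.share_sf), ("sf_ebrt", P.share_sf)):
            cost = P.c_mf if m == "mf_ebrt" else P.c_sf
            strata.append(
                dict(
                    weight=w,
                    entry_cost=cost,
                    entry_du=P.du_treat[m],
                    entry_resp=P.resp[m],
                    entry_onset=P.onset[m],
                    re_rate=P.p_retreat[m],
                    re_cost=cost,
                    re_du=P.du_treat[m],
                    re_resp=reirr(m),
                    re_onset=P.onset[m],
                    frac0=P.p_frac[m],
                    frac1=P.p_frac[m],
                    elig_partial=P.elig_partial["B"],
                )
            )
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return strata


def _run_stratum(P: _Batch, st: dict) -> tuple[np.ndarray, ...]:
    """Propagate one stratum; returns (cost, qaly, pain, pain_undisc) of
    shape (B, 3 cancers), each per unit of entering mass.

    The pain axis distinguishes four states: 0 complete response, 1 partial
    response, 2 persistent pain after a relapsed response, 3 persistent
    pain that never responded.  States 2 and 3 accrue identically; the
    split only matters for retreatment eligibility when ``retreat_pool``
    restricts retreatment to relapsed pain.
    """
    B = P.B
    # state[b, cancer, pain state, retreat_used, fractured]
    state = np.zeros((B, 3, 4, 2, 2))
    state[:, :, 0, 0, 0] = st["entry_resp"][:, None, 0]
    state[:, :, 1, 0, 0] = st["entry_resp"][:, None, 1]
    state[:, :, 3, 0, 0] = st["entry_resp"][:, None, 2]  # never responded
    dead = np.zeros((B, 3))

    cost = np.zeros((B, 3))
    qaly = np.zeros((B, 3))
    pain = np.zeros((B, 3))
    pain_u = np.zeros((B, 3))

    disc_all = discount_factor(P.discount, np.arange(P.horizon))
    gain_c = P.gain[:, 0][:, None]
    gain_p = P.gain[:, 1][:, None]
    u_base = P.u_base[:, None]
    c_opioid = P.c_opioid[:, None]
    p_relapse = P.p_relapse[:, None]

    def accrue(
        t: int,
        newly_c: np.ndarray,
        newly_p: np.ndarray,
        upgraded_c: np.ndarray,
        onset_f: float,
    ) -> None:
        """Accrue cycle ``t``.

        ``newly_c``/``newly_p`` hold mass whose response was induced from
        persistent pain this cycle (active only for ``onset_f`` of the
        month); ``upgraded_c`` holds partial responders upgraded to complete
        this cycle (partial before onset, complete after — a full pain-
        response month either way).
        """
        d = disc_all[t]
        alive = state.sum(axis=(2, 3, 4))
        m_c = state[:, :, 0].sum(axis=(2, 3))
        m_p = state[:, :, 1].sum(axis=(2, 3))
        act_c = m_c - (1.0 - onset_f) * (newly_c + upgraded_c)
        act_p = m_p - (1.0 - onset_f) * newly_p + (1.0 - onset_f) * upgraded_c
        qaly[:] += d * (alive * u_base + gain_c * act_c + gain_p * act_p)
        pain[:] += d * (act_c + act_p)
        pain_u[:] += act_c + act_p
        cost[:] += d * c_opioid * (alive - act_c)

    zero = np.zeros((B, 3))
    # --- entry cycle (t = 0): treatment cost + disutility + first accrual
    cost += st["entry_cost"][:, None]
    qaly += st["entry_du"][:, None]
    accrue(
        0,
        state[:, :, 0].sum(axis=(2, 3)),
        state[:, :, 1].sum(axis=(2, 3)),
        zero,
        st["entry_onset"],
    )

    re_rate = st["re_rate"][:, None]
    re_resp = st["re_resp"]
    frac_p = (st["frac0"][:, None], st["frac1"][:, None])
    elig_resp = [2] if P.retreat_pool == "relapsed_only" else [2, 3]
    if st["elig_partial"]:
        elig_resp.insert(0, 1)

    for t in range(1, P.horizon):
        d = disc_all[t]
        year = t // 12
        p_d = P.mortality[:, :, year] if year < 5 else P.mortality_extrap

        # 1. death
        dead += state.sum(axis=(2, 3, 4)) * p_d
        state *= (1.0 - p_d)[:, :, None, None, None]

        # 2. relapse (complete/partial -> persistent)
        mv = state[:, :, :2] * p_relapse[:, :, None, None, None]
        state[:, :, :2] -= mv
        state[:, :, 2] += mv.sum(axis=2)

        # 3. retreatment among the eligible who have none yet.  A failed
        # attempt never worsens pain: persistent patients redraw the full
        # response profile (a "none" draw leaves them persistent).  Partial
        # responders are treated for residual pain: any response to the
        # retreat (probability p_complete + p_partial) on top of the
        # existing partial relief yields complete relief, non-responders
        # keep their partial response.
        newly = np.zeros((B, 3, 4, 2))  # [b, cancer, new pain state, fractured]
        onset_c = np.zeros((B, 3))  # persistent -> complete this cycle
        onset_p = np.zeros((B, 3))  # persistent -> partial this cycle
        upgraded = np.zeros((B, 3))  # partial -> complete this cycle
        re_total = np.zeros((B, 3))
        for r in elig_resp:
            moved = state[:, :, r, 0, :] * re_rate[:, :, None]
            state[:, :, r, 0, :] -= moved
            if r >= 2:  # persistent pain: full redraw, "none" stays put
                newly[:, :, :2] += moved[:, :, None, :] * re_resp[:, None, :2, None]
                newly[:, :, r] += moved * re_resp[:, 2][:, None, None]
                onset_c += moved.sum(axis=2) * re_resp[:, 0][:, None]
                onset_p += moved.sum(axis=2) * re_resp[:, 1][:, None]
            else:  # partial responders: floor at partial, upgrade on response
                if PARTIAL_UPGRADE == "any_response":
                    p_up = re_resp[:, 0] + re_resp[:, 1]
                else:
                    p_up = re_resp[:, 0]
                up = moved * p_up[:, None, None]
                newly[:, :, 0] += up
                newly[:, :, 1] += moved - up
                upgraded += up.sum(axis=2)
            re_total += moved.sum(axis=2)
        state[:, :, :, 1, :] += newly
        cost += d * re_total * st["re_cost"][:, None]
        qaly += d * re_total * st["re_du"][:, None]

        # 4. pathological fracture (first occurrence only)
        fr_total = np.zeros((B, 3))
        for u in (0, 1):
            moved = state[:, :, :, u, 0] * frac_p[u][:, :, None]
            state[:, :, :, u, 0] -= moved
            state[:, :, :, u, 1] += moved
            fr_total += moved.sum(axis=2)
        cost += d * fr_total * P.c_fracture[:, None]
        qaly += d * fr_total * P.du_fracture[:, None]

        # 5. accrual
        accrue(t, onset_c, onset_p, upgraded, st["re_onset"])

        if t % 60 == 0:
            leak = np.abs(state.sum(axis=(2, 3, 4)) + dead - 1.0).max()
            if leak > MASS_TOL:
                raise MassConservationError(f"mass leak {leak:.3e} at cycle {t}")

    leak = np.abs(state.sum(axis=(2, 3, 4)) + dead - 1.0).max()
    if leak > MASS_TOL:
        raise MassConservationError(f"mass leak {leak:.3e} at horizon")
    alive_end = state.sum(axis=(2, 3, 4)).max()
    if alive_end > 1e-3:
        warnings.warn(
            f"{alive_end:.2%} of the cohort still alive at the {P.horizon}-month horizon",
            stacklevel=3,
        )
    return cost, qaly, pain, pain_u


def _evaluate(strategy: str, P: _Batch) -> dict[str, np.ndarray]:
    cost = np.zeros((P.B, 3))
    qaly = np.zeros((P.B, 3))
    pain = np.zeros((P.B, 3))
    pain_u = np.zeros((P.B, 3))
    for st in _strata(strategy, P):
        c, q, p, pu = _run_stratum(P, st)
        w = st["weight"][:, None]
        cost += w * c
        qaly += w * q
        pain += w * p
        pain_u += w * pu
    mix = P.cancer_mix
    return {
        "cost": (mix * cost).sum(axis=1),
        "qaly": (mix * qaly).sum(axis=1),
        "pain": (mix * pain).sum(axis=1),
        "pain_undiscounted": (mix * pain_u).sum(axis=1),
    }


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def expected_outcomes(strategy: str, params: ParameterSet, check: bool = True) -> ArmResult:
    """Exact expected discounted outcomes of one strategy arm."""
    if check:
        diags = validate(params)
        if diags:
            raise ValueError("invalid parameter set: " + "; ".join(diags))
    out = _evaluate(strategy, _compile([params]))
    return ArmResult(
        strategy=strategy,
        mean_cost=float(out["cost"][0]),
        mean_qaly=float(out["qaly"][0]),
        mean_pain_months=float(out["pain"][0]),
        mean_pain_months_undiscounted=float(out["pain_undiscounted"][0]),
    )


def expected_outcomes_batch(
    strategy: str, param_sets: Sequence[ParameterSet]
) -> dict[str, np.ndarray]:
    """Vectorised evaluation over many parameter sets (PSA inner loop).

    Returns arrays keyed ``cost``, ``qaly``, ``pain``, ``pain_undiscounted``,
    each of shape ``(len(param_sets),)``.
    """
    return _evaluate(strategy, _compile(list(param_sets)))
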