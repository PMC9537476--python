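"""Parameter model for the MR-HIFU vs. EBRT bone-metastases cost-effectiveness model.

The model compares two palliative strategies for painful bone metastases:

* **Strategy A** — MR-guided high-intensity focused ultrasound (MR-HIFU)
  offered as first-line treatment to a share of patients (default 60%) or as
  a retreatment option after failed external-beam radiotherapy (EBRT).
* **Strategy B** — EBRT alone (multi-fraction 20 Gy / 5, with a 10% share of
  single-fraction 8 Gy), with re-irradiation for persistent pain.

Every numeric input — monthly event probabilities, monthly utility
increments, and costs in EUR (German statutory-health-insurance tariffs,
2021/2022 price level) — lives in a single :class:`ParameterSet`, which is
the unit of work passed to the cohort and microsimulation engines.
"""

from __future__ import annotations

import copy
import csv
import io
import math
from dataclasses import dataclass, field, fields, is_dataclass
from typing import Any, Iterator, Mapping

import yaml

CANCERS = ("breast", "prostate", "lung")
MODALITIES = ("hifu", "mf_ebrt", "sf_ebrt")

#: One-year overall survival reported in the cohort literature the mortality
#: table was sourced from; used only for consistency *warnings* (the monthly
#: probabilities printed in the input table imply noticeably higher survival
#: for prostate and lung than these cohort figures).
LITERATURE_ONE_YEAR_OS = {"prostate": 0.35, "lung": 0.10}

SIMPLEX_TOL = 1e-9


class ParameterError(ValueError):
    """A configuration could not be parsed into a valid :class:`ParameterSet`."""


# ---------------------------------------------------------------------------
# dataclasses
# ---------------------------------------------------------------------------


@dataclass
class ResponseProfile:
    """Distribution of the pain-response category right after a treatment.

    ``onset_days`` encodes how quickly palliation sets in: 7 days for
    MR-HIFU, 28 days for EBRT. Responders only accrue the response utility
    gain (and pain-response time) from onset onward.
    """

    p_complete: float
    p_partial: float
    p_none: float
    onset_days: int  # 7 (MR-HIFU) or 28 (EBRT)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_complete, self.p_partial, self.p_none)


@dataclass
class TreatmentParams:
    """Per-modality event probabilities.

    The per-treatment utility decrements live in :class:`UtilitySet`
    (single source of truth).  ``p_no_response_retreat`` only applies to
    re-irradiation in strategy B (probability that retreatment with EBRT
    yields no response); it is ``None`` for MR-HIFU.
    """

    response: ResponseProfile
    p_retreat_monthly: float
    p_fracture_monthly: float
    p_no_response_retreat: float | None = None


@dataclass
class MortalityTable:
    """Cancer-specific monthly death probability by year since diagnosis.

    Years 1-5 are tabulated; beyond year 5 the year-5 monthly probability is
    held constant (``extrapolation_p`` overrides that if set).
    """

    monthly_p_by_year: tuple[float, float, float, float, float]
    extrapolation_p: float | None = None

    def monthly_p(self, cycle: int) -> float:
        """Monthly death probability applying in month ``cycle`` (0-based)."""
        year = cycle // 12
        if year < 5:
            return self.monthly_p_by_year[year]
        if self.extrapolation_p is not None:
            return self.extrapolation_p
        return self.monthly_p_by_year[4]


@dataclass
class UtilitySet:
    """Monthly (cycle-adjusted) utility values.

    ``u_base`` is the utility of living with painful bone metastases for one
    month; response gains are added while in complete/partial response,
    decrements are one-off in the cycle a treatment or fracture occurs.
    """

    u_base: float
    du_fracture: float
    du_mf_ebrt: float
    du_sf_ebrt: float
    du_hifu: float
    gain_complete: float
    gain_partial: float


@dataclass
class CostSet:
    """Costs in EUR (statutory-health-insurance perspective).

    The pathological-fracture total is a one-off cost-of-illness estimate;
    its five printed components are kept for audit and must sum to the total.
    """

    c_mri_outpatient: float
    c_hifu_inpatient: float
    c_hifu_lumpsum: float
    c_hifu_lumpsum_low: float
    c_hifu_lumpsum_high: float
    c_mf_ebrt_outpatient: float
    c_mf_ebrt_inpatient: float
    c_sf_ebrt: float
    c_fracture_total: float
    c_fracture_outpatient: float
    c_fracture_inpatient: float
    c_fracture_rehabilitation: float
    c_fracture_prescriptions: float
    c_fracture_aids: float
    c_opioid_monthly: float


@dataclass
class StrategySettings:
    """Structural settings defining the two strategies.

    ``ebrt_first_retreat_rate`` selects the monthly retreat-uptake rate for
    EBRT-first patients awaiting a HIFU retreat in strategy A: ``"strategy"``
    uses the strategy-level MR-HIFU rate (0.018), ``"modality"`` the
    first-line EBRT modality's own rate. ``hifu_first_ebrt_retreat`` toggles
    whether HIFU-first patients may still receive an EBRT retreatment
    (repeat MR-HIFU is never modelled).
    """

    share_hifu_firstline_A: float = 0.60
    share_sf_ebrt: float = 0.10
    share_ebrt_outpatient: float = 0.70
    retreat_eligibility_A: str = "persistent_or_partial"
    retreat_eligibility_B: str = "persistent_only"
    max_retreatments: int = 1
    ebrt_first_retreat_rate: str = "strategy"
    hifu_first_ebrt_retreat: bool = True
    #: which persistent-pain patients may be retreated: "any_persistent"
    #: (including those who never responded to first-line treatment) or
    #: "relapsed_only" (only pain that returned after an initial response)
    retreat_pool: str = "any_persistent"


@dataclass
class ParameterSet:
    """Every input of one model evaluation (single source of truth)."""

    treatments: dict[str, TreatmentParams]
    p_relapse_monthly: float
    mortality: dict[str, MortalityTable]
    cancer_mix: tuple[float, float, float]
    utilities: UtilitySet
    costs: CostSet
    strategy: StrategySettings
    discount_annual: float = 0.03
    horizon_months: int = 600
    sd_table: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# base case
# ---------------------------------------------------------------------------


def builtin_basecase() -> ParameterSet:
    """The embedded base-case parameter set (all inputs as published)."""
    treatments = {
        # The source trial reports 23% complete and 41% partial response
        # (64% overall); no-response is their simplex complement 0.36 (the
        # published 0.350 is a rounding that would leak 1% of the cohort).
        "hifu": TreatmentParams(
            response=ResponseProfile(0.230, 0.410, 0.360, onset_days=7),
            p_retreat_monthly=0.018,
            p_fracture_monthly=0.003,
        ),
        "mf_ebrt": TreatmentParams(
            response=ResponseProfile(0.240, 0.380, 0.380, onset_days=28),
            p_retreat_monthly=0.007,
            p_fracture_monthly=0.003,
            p_no_response_retreat=0.420,
        ),
        "sf_ebrt": TreatmentParams(
            response=ResponseProfile(0.230, 0.380, 0.390, onset_days=28),
            p_retreat_monthly=0.018,
            p_fracture_monthly=0.003,
            p_no_response_retreat=0.420,
        ),
    }
    mortality = {
        "breast": MortalityTable((0.040, 0.029, 0.029, 0.027, 0.027)),
        "prostate": MortalityTable((0.053, 0.039, 0.034, 0.029, 0.028)),
        "lung": MortalityTable((0.070, 0.050, 0.050, 0.030, 0.020)),
    }
    utilities = UtilitySet(
        u_base=0.039,
        du_fracture=-0.009,
        du_mf_ebrt=-0.009,
        du_sf_ebrt=-0.004,
        du_hifu=-0.005,
        gain_complete=0.019,
        gain_partial=0.008,
    )
    costs = CostSet(
        c_mri_outpatient=118.0,
        c_hifu_inpatient=3430.0,
        c_hifu_lumpsum=5147.0,
        c_hifu_lumpsum_low=4092.0,
        c_hifu_lumpsum_high=5876.0,
        c_mf_ebrt_outpatient=2411.0,
        c_mf_ebrt_inpatient=6410.0,
        c_sf_ebrt=1486.0,
        c_fracture_total=21430.0,
        c_fracture_outpatient=1593.0,
        c_fracture_inpatient=12596.0,
        c_fracture_rehabilitation=203.0,
        c_fracture_prescriptions=5446.0,
        c_fracture_aids=1592.0,
        c_opioid_monthly=210.0,
    )
    # Standard deviations for every parameter varied in DSA/PSA.  Starred
    # costs use 20% of the mean; cancer-specific mortality is never varied.
    sd_table = {
        "treatments.hifu.response.p_complete": 0.04,
        "treatments.hifu.response.p_partial": 0.04,
        "treatments.hifu.response.p_none": 0.04,
        "treatments.mf_ebrt.response.p_complete": 0.008,
        "treatments.mf_ebrt.response.p_partial": 0.008,
        "treatments.mf_ebrt.response.p_none": 0.008,
        "treatments.sf_ebrt.response.p_complete": 0.008,
        "treatments.sf_ebrt.response.p_partial": 0.008,
        "treatments.sf_ebrt.response.p_none": 0.008,
        "treatments.hifu.p_retreat_monthly": 0.0016,
        "treatments.mf_ebrt.p_retreat_monthly": 0.0011,
        "treatments.sf_ebrt.p_retreat_monthly": 0.0016,
        "treatments.mf_ebrt.p_no_response_retreat": 0.021,
        "treatments.sf_ebrt.p_no_response_retreat": 0.021,
        "treatments.hifu.p_fracture_monthly": 0.005,
        "treatments.mf_ebrt.p_fracture_monthly": 0.0007,
        "treatments.sf_ebrt.p_fracture_monthly": 0.0007,
        "p_relapse_monthly": 0.008,
        "utilities.u_base": 0.035,
        "utilities.du_fracture": 0.021,
        "utilities.du_mf_ebrt": 0.025,
        "utilities.du_sf_ebrt": 0.014,
        "utilities.du_hifu": 0.014,
        "utilities.gain_complete": 0.001,
        "utilities.gain_partial": 0.001,
        "costs.c_hifu_inpatient": 686.0,
        "costs.c_mf_ebrt_outpatient": 482.2,
        "costs.c_mf_ebrt_inpatient": 1282.0,
        "costs.c_fracture_total": 8572.0,
        "costs.c_opioid_monthly": 84.0,
        "strategy.share_ebrt_outpatient": 0.14,
    }
    return ParameterSet(
        treatments=treatments,
        p_relapse_monthly=0.022,
        mortality=mortality,
        cancer_mix=(1 / 3, 1 / 3, 1 / 3),
        utilities=utilities,
        costs=costs,
        strategy=StrategySettings(),
        discount_annual=0.03,
        horizon_months=600,
        sd_table=sd_table,
    )


# ---------------------------------------------------------------------------
# rate conversion
# ---------------------------------------------------------------------------


def annual_to_monthly(p_annual: float) -> float:
    """Convert an annual probability to the equivalent monthly probability.

    Uses compounding, ``1 - (1 - p)**(1/12)``, the inverse of twelve
    independent monthly Bernoulli chances — not linear division.
    """
    if not 0.0 <= p_annual < 1.0:
        raise ValueError(f"annual probability must be in [0, 1), got {p_annual}")
    return 1.0 - (1.0 - p_annual) ** (1.0 / 12.0)


def monthly_to_annual(p_monthly: float) -> float:
    """Inverse of :func:`annual_to_monthly`."""
    if not 0.0 <= p_monthly < 1.0:
        raise ValueError(f"monthly probability must be in [0, 1), got {p_monthly}")
    return 1.0 - (1.0 - p_monthly) ** 12.0


# ---------------------------------------------------------------------------
# path-based access (used by DSA / PSA / scenarios)
# ---------------------------------------------------------------------------


def get_param(ps: ParameterSet, path: str) -> Any:
    """Fetch a leaf value by dotted path, e.g. ``treatments.hifu.response.p_complete``."""
    obj: Any = ps
    for part in path.split("."):
        if isinstance(obj, Mapping):
            obj = obj[part]
        else:
            obj = getattr(obj, part)
    return obj


def set_param(ps: ParameterSet, path: str, value: Any) -> ParameterSet:
    """Return a deep copy of ``ps`` with the leaf at ``path`` replaced."""
    out = copy.deepcopy(ps)
    parts = path.split(".")
    obj: Any = out
    for part in parts[:-1]:
        if isinstance(obj, Mapping):
            obj = obj[part]
        else:
            obj = getattr(obj, part)
    last = parts[-1]
    if isinstance(obj, Mapping):
        if last not in obj:
            raise KeyError(f"unknown parameter path: {path}")
        obj[last] = value
    else:
        if not hasattr(obj, last):
            raise AttributeError(f"unknown parameter path: {path}")
        setattr(obj, last, value)
    return out


def apply_overrides(ps: ParameterSet, overrides: Mapping[str, Any]) -> ParameterSet:
    """Apply a sparse ``{path: value}`` mapping, validating the result."""
    out = copy.deepcopy(ps)
    for path, value in overrides.items():
        out = set_param(out, path, value)
    diags = validate(out)
    if diags:
        raise ParameterError("overrides produced an invalid parameter set: " + "; ".join(diags))
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _check_prob(name: str, p: float, diags: list[str]) -> None:
    if not (isinstance(p, (int, float)) and 0.0 <= p <= 1.0):
        diags.append(f"{name}: probability {p!r} outside [0, 1]")


def validate(ps: ParameterSet) -> list[str]:
    """Return a list of diagnostics; empty iff every invariant holds.

    Diagnostics name the offending field and the violated invariant; they
    are returned, never raised.
    """
    diags: list[str] = []
    for name, tr in ps.treatments.items():
        r = tr.response
        for comp in ("p_complete", "p_partial", "p_none"):
            _check_prob(f"treatments.{name}.response.{comp}", getattr(r, comp), diags)
        total = r.p_complete + r.p_partial + r.p_none
        if abs(total - 1.0) > SIMPLEX_TOL:
            diags.append(
                f"treatments.{name}.response: triplet (p_complete={r.p_complete}, "
                f"p_partial={r.p_partial}, p_none={r.p_none}) sums to {total:.6g}, not 1"
            )
        if r.onset_days not in (7, 28):
            diags.append(f"treatments.{name}.response.onset_days: {r.onset_days} not in {{7, 28}}")
        _check_prob(f"treatments.{name}.p_retreat_monthly", tr.p_retreat_monthly, diags)
        _check_prob(f"treatments.{name}.p_fracture_monthly", tr.p_fracture_monthly, diags)
        if tr.p_no_response_retreat is not None:
            _check_prob(f"treatments.{name}.p_no_response_retreat", tr.p_no_response_retreat, diags)
    _check_prob("p_relapse_monthly", ps.p_relapse_monthly, diags)

    for cancer, mt in ps.mortality.items():
        if len(mt.monthly_p_by_year) != 5:
            diags.append(f"mortality.{cancer}: needs 5 yearly values")
        for i, p in enumerate(mt.monthly_p_by_year):
            if not 0.0 < p < 1.0:
                diags.append(f"mortality.{cancer}.monthly_p_by_year[{i}]: {p} not in (0, 1)")
        if mt.extrapolation_p is not None and not 0.0 < mt.extrapolation_p < 1.0:
            diags.append(f"mortality.{cancer}.extrapolation_p: {mt.extrapolation_p} not in (0, 1)")
    missing = set(CANCERS) - set(ps.mortality)
    if missing:
        diags.append(f"mortality: missing cancers {sorted(missing)}")

    if abs(sum(ps.cancer_mix) - 1.0) > SIMPLEX_TOL:
        diags.append(f"cancer_mix: {tuple(ps.cancer_mix)} sums to {sum(ps.cancer_mix):.6g}, not 1")
    for p in ps.cancer_mix:
        _check_prob("cancer_mix", p, diags)

    u = ps.utilities
    if u.u_base <= 0:
        diags.append(f"utilities.u_base: {u.u_base} must be > 0")
    for gname in ("gain_complete", "gain_partial"):
        if getattr(u, gname) <= 0:
            diags.append(f"utilities.{gname}: {getattr(u, gname)} must be > 0")
    for dname in ("du_fracture", "du_mf_ebrt", "du_sf_ebrt", "du_hifu"):
        if getattr(u, dname) > 0:
            diags.append(f"utilities.{dname}: {getattr(u, dname)} must be <= 0")
    for fname in ("u_base", "du_fracture", "du_mf_ebrt", "du_sf_ebrt", "du_hifu", "gain_complete", "gain_partial"):
        if abs(getattr(u, fname)) >= 0.09:
            diags.append(f"utilities.{fname}: |{getattr(u, fname)}| >= 0.09 (monthly-scale sanity bound)")

    c = ps.costs
    for f_ in fields(c):
        v = getattr(c, f_.name)
        if v < 0:
            diags.append(f"costs.{f_.name}: {v} must be >= 0")
    comp_sum = (
        c.c_fracture_outpatient
        + c.c_fracture_inpatient
        + c.c_fracture_rehabilitation
        + c.c_fracture_prescriptions
        + c.c_fracture_aids
    )
    if abs(comp_sum - c.c_fracture_total) > 1e-6:
        diags.append(
            f"costs.c_fracture_total: components sum to {comp_sum:.6g}, total is {c.c_fracture_total:.6g}"
        )

    s = ps.strategy
    for sname in ("share_hifu_firstline_A", "share_sf_ebrt", "share_ebrt_outpatient"):
        _check_prob(f"strategy.{sname}", getattr(s, sname), diags)
    if s.retreat_eligibility_A not in ("persistent_or_partial", "persistent_only"):
        diags.append(f"strategy.retreat_eligibility_A: {s.retreat_eligibility_A!r} unknown")
    if s.retreat_eligibility_B not in ("persistent_or_partial", "persistent_only"):
        diags.append(f"strategy.retreat_eligibility_B: {s.retreat_eligibility_B!r} unknown")
    if s.max_retreatments != 1:
        diags.append(f"strategy.max_retreatments: {s.max_retreatments} (only 1 supported)")
    if s.ebrt_first_retreat_rate not in ("strategy", "modality"):
        diags.append(f"strategy.ebrt_first_retreat_rate: {s.ebrt_first_retreat_rate!r} unknown")
    if s.retreat_pool not in ("any_persistent", "relapsed_only"):
        diags.append(f"strategy.retreat_pool: {s.retreat_pool!r} unknown")

    if ps.discount_annual < 0:
        diags.append(f"discount_annual: {ps.discount_annual} must be >= 0")
    if ps.horizon_months < 120:
        diags.append(f"horizon_months: {ps.horizon_months} must be >= 120")
    return diags


def validation_warnings(ps: ParameterSet) -> list[str]:
    """Non-fatal consistency notes, e.g. survival implied by the mortality
    table versus one-year overall survival reported in the source cohorts."""
    notes: list[str] = []
    for cancer, os_lit in LITERATURE_ONE_YEAR_OS.items():
        if cancer not in ps.mortality:
            continue
        p1 = ps.mortality[cancer].monthly_p_by_year[0]
        implied = (1.0 - p1) ** 12
        if abs(implied - os_lit) > 0.10:
            notes.append(
                f"mortality.{cancer}: year-1 monthly probability {p1} implies "
                f"{implied:.0%} one-year survival vs. {os_lit:.0%} in the source cohort"
            )
    return notes


# ---------------------------------------------------------------------------
# config I/O (YAML, strict keys, lossless round trip)
# ---------------------------------------------------------------------------


def _to_plain(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f_.name: _to_plain(getattr(obj, f_.name)) for f_ in fields(obj)}
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def to_dict(ps: ParameterSet) -> dict[str, Any]:
    """Plain nested dict mirroring the dataclass structure."""
    return _to_plain(ps)


def _build(cls: type, data: Mapping[str, Any], ctx: str) -> Any:
    if not isinstance(data, Mapping):
        raise ParameterError(f"{ctx}: expected a mapping, got {type(data).__name__}")
    names = {f_.name: f_ for f_ in fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ParameterError(f"{ctx}: unknown keys {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, f_ in names.items():
        if name not in data:
            import dataclasses as _dc

            if f_.default is not _dc.MISSING or f_.default_factory is not _dc.MISSING:  # type: ignore[misc]
                continue
            raise ParameterError(f"{ctx}: missing required field '{name}'")
        kwargs[name] = data[name]
    return cls(**kwargs)


def from_dict(data: Mapping[str, Any]) -> ParameterSet:
    """Strict inverse of :func:`to_dict`; unknown or missing keys raise
    :class:`ParameterError`, and the result is validated."""
    if not isinstance(data, Mapping):
        raise ParameterError("config root must be a mapping")
    top = dict(data)
    try:
        treatments_raw = top.pop("treatments")
        mortality_raw = top.pop("mortality")
        utilities_raw = top.pop("utilities")
        costs_raw = top.pop("costs")
        strategy_raw = top.pop("strategy")
    except KeyError as exc:
        raise ParameterError(f"missing required section {exc.args[0]!r}") from None

    treatments = {}
    for name, tr in dict(treatments_raw).items():
        if name not in MODALITIES:
            raise ParameterError(f"treatments: unknown modality {name!r}")
        tr = dict(tr)
        resp = _build(ResponseProfile, tr.pop("response", {}), f"treatments.{name}.response")
        treatments[name] = _build(TreatmentParams, {**tr, "response": resp}, f"treatments.{name}")
    missing_mod = set(MODALITIES) - set(treatments)
    if missing_mod:
        raise ParameterError(f"treatments: missing modalities {sorted(missing_mod)}")

    mortality = {}
    for cancer, mt in dict(mortality_raw).items():
        if cancer not in CANCERS:
            raise ParameterError(f"mortality: unknown cancer {cancer!r}")
        mt = dict(mt)
        if "monthly_p_by_year" in mt:
            mt["monthly_p_by_year"] = tuple(mt["monthly_p_by_year"])
        mortality[cancer] = _build(MortalityTable, mt, f"mortality.{cancer}")

    if "cancer_mix" in top:
        top["cancer_mix"] = tuple(top["cancer_mix"])
    if "sd_table" in top:
        top["sd_table"] = dict(top["sd_table"])
    ps = _build(
        ParameterSet,
        {
            **top,
            "treatments": treatments,
            "mortality": mortality,
            "utilities": _build(UtilitySet, utilities_raw, "utilities"),
            "costs": _build(CostSet, costs_raw, "costs"),
            "strategy": _build(StrategySettings, strategy_raw, "strategy"),
        },
        "parameters",
    )
    diags = validate(ps)
    if diags:
        raise ParameterError("invalid parameter set: " + "; ".join(diags))
    return ps


def save_parameters(ps: ParameterSet, path: str) -> None:
    """Write a :class:`ParameterSet` as a human-editable YAML config."""
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(ps), fh, sort_keys=False)


def load_parameters(path: str) -> ParameterSet:
    """Load and validate a YAML config written by :func:`save_parameters`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return from_dict(data)


def iter_leaf_paths(ps: ParameterSet) -> Iterator[tuple[str, Any]]:
    """Yield ``(dotted_path, value)`` for every scalar leaf (audit export)."""

    def walk(prefix: str, obj: Any) -> Iterator[tuple[str, Any]]:
        if is_dataclass(obj) and not isinstance(obj, type):
            for f_ in fields(obj):
                yield from walk(f"{prefix}{f_.name}.", getattr(obj, f_.name))
        elif isinstance(obj, Mapping):
            for k, v in obj.items():
                yield from walk(f"{prefix}{k}.", v)
        elif isinstance(obj, (list, tuple)):
            for i, v in enumerate(obj):
                yield from walk(f"{prefix}{i}.", v)
        else:
            yield prefix[:-1], obj

    yield from walk("", ps)


def parameters_to_csv(ps: ParameterSet, path_or_buf: str | io.TextIOBase) -> None:
    """Flat ``parameter,value`` CSV export of every leaf, for audit."""
    close = False
    if isinstance(path_or_buf, str):
        fh: io.TextIOBase = open(path_or_buf, "w", newline="")  # noqa: SIM115
        close = True
    else:
        fh = path_or_buf
    try:
        writer = csv.writer(fh)
        writer.writerow(["parameter", "value"])
        for p, v in iter_leaf_paths(ps):
            writer.writerow([p, v])
    finally:
        if close:
            fh.close()
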