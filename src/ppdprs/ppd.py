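"""Probability of prodromal Parkinson's disease (pPD) per the MDS research criteria.

The MDS research criteria define the probability that an individual is in
the prodromal phase of PD as a naive-Bayes update: an age-specific pretest
probability is converted to odds, multiplied by the likelihood ratio (LR)
of every assessed risk and prodromal marker, and converted back to a
posttest probability.  Markers that were not assessed ("missing")
contribute an LR of exactly 1.0, i.e. they leave the odds unchanged.

The LR values and age priors are configuration, not code: they ship as a
versioned YAML table (``data/mds_lr_table.yaml``) and can be swapped at
run time.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

PRESENT = "present"
ABSENT = "absent"
MISSING = "missing"

RISK = "risk"
PRODROMAL = "prodromal"

CUTOFFS = (0.30, 0.50, 0.80)

COGNITIVE_DOMAINS = ("memory", "language", "attention_speed", "executive", "visual_spatial")


@dataclass
class MarkerProfile:
    """One individual's marker assessment.

    ``risk_markers`` and ``prodromal_markers`` map marker names to one of
    the states ``present`` / ``absent`` / ``missing``.  Cognitive-domain
    z-scores and the dementia / MCI flags are carried along for the
    sensitivity analyses; ``pd_dlb_flag`` marks individuals with diagnosed
    PD or dementia with Lewy bodies, who are excluded from the calculation.
    """

    individual_id: str
    age: float
    sex: str  # "male" | "female"
    risk_markers: dict[str, str] = field(default_factory=dict)
    prodromal_markers: dict[str, str] = field(default_factory=dict)
    cognitive_z: dict[str, float] = field(default_factory=dict)
    dementia_flag: bool = False
    mci_flag: bool = False
    pd_dlb_flag: bool = False

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for states in (self.risk_markers, self.prodromal_markers):
            for name, state in states.items():
                if state not in (PRESENT, ABSENT, MISSING):
                    raise ValueError(f"marker {name!r} has invalid state {state!r}")


@dataclass(frozen=True)
class AgeBand:
    lo: float
    hi: float  # exclusive; math.inf for the open-ended band
    prior: float


@dataclass
class LikelihoodRatioTable:
    """Marker LRs plus the age-band pretest priors.

    ``lr_positive`` applies to present markers, ``lr_negative`` to absent
    ones; missing markers always score 1.0.  Age bands are half-open
    ``[lo, hi)`` and must partition ``[min_age, inf)``.
    """

    risk: dict[str, tuple[float, float]]
    prodromal: dict[str, tuple[float, float]]
    age_priors: list[AgeBand]
    prs_quartile_scheme: dict[str, float]
    version: str = "unversioned"
    source_hash: str = ""

    def __post_init__(self) -> None:
        for group in (self.risk, self.prodromal):
            for name, (lp, ln) in group.items():
                if lp <= 0 or ln <= 0:
                    raise ValueError(f"LRs for {name!r} must be positive")
        bands = sorted(self.age_priors, key=lambda b: b.lo)
        for a, b in zip(bands, bands[1:]):
            if a.hi != b.lo:
                raise ValueError("age bands must be contiguous")
        if bands and not math.isinf(bands[-1].hi):
            raise ValueError("last age band must be open-ended")
        self.age_priors = bands

    @property
    def min_age(self) -> float:
        return self.age_priors[0].lo

    def marker_class(self, marker: str) -> str:
        if marker in self.risk:
            return RISK
        if marker in self.prodromal:
            return PRODROMAL
        raise KeyError(f"marker {marker!r} not in LR table")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LikelihoodRatioTable":
        raw = Path(path).read_bytes()
        return cls._from_bytes(raw)

    @classmethod
    def default(cls) -> "LikelihoodRatioTable":
        """The packaged MDS-2019 table."""
        raw = resources.files("ppdprs.data").joinpath("mds_lr_table.yaml").read_bytes()
        return cls._from_bytes(raw)

    @classmethod
    def _from_bytes(cls, raw: bytes) -> "LikelihoodRatioTable":
        doc = yaml.safe_load(raw)
        bands = [AgeBand(float(b["lo"]), float(b["hi"]), float(b["prior"])) for b in doc["age_priors"]]
        risk = {k: (float(v["lr_positive"]), float(v["lr_negative"])) for k, v in doc["risk_markers"].items()}
        prod = {k: (float(v["lr_positive"]), float(v["lr_negative"])) for k, v in doc["prodromal_markers"].items()}
        scheme = {k: float(v) for k, v in doc.get("prs_quartile_scheme", {}).items()}
        return cls(
            risk=risk,
            prodromal=prod,
            age_priors=bands,
            prs_quartile_scheme=scheme,
            version=str(doc.get("version", "unversioned")),
            source_hash=hashlib.sha256(raw).hexdigest(),
        )


@dataclass
class PpdResult:
    """pPD probability for one individual, with the intermediate LRs."""

    individual_id: str
    pretest_prob: float
    risk_lr: float
    prodromal_lr: float
    total_lr: float
    posttest_prob: float
    ge_30: bool
    ge_50: bool
    ge_80: bool


def pretest_probability(age: float, table: LikelihoodRatioTable) -> float:
    """Age-band pretest probability of prodromal PD.

    Bands are half-open [lo, hi), so a boundary age belongs to the upper
    band.  Ages below the table's minimum are an error, not a zero.
    """
    if age < table.min_age:
        raise ValueError(f"age {age} below minimum age band start {table.min_age}")
    for band in table.age_priors:
        if band.lo <= age < band.hi:
            return band.prior
    raise AssertionError("age bands do not cover input")  # unreachable: last band open-ended


def marker_lr(state: str, marker: str, table: LikelihoodRatioTable) -> float:
    """LR contributed by one marker: LR+ if present, LR- if absent, 1.0 if missing."""
    group = table.risk if marker in table.risk else table.prodromal
    if marker not in group:
        raise KeyError(f"marker {marker!r} not in LR table")
    if state == MISSING:
        return 1.0
    lp, ln = group[marker]
    if state == PRESENT:
        return lp
    if state == ABSENT:
        return ln
    raise ValueError(f"invalid marker state {state!r}")


def total_lr(
    profile: MarkerProfile,
    table: LikelihoodRatioTable,
    *,
    lr_overrides: Mapping[str, float] | None = None,
) -> tuple[float, float, float]:
    """Total risk LR, total prodromal LR and their product for a profile.

    ``lr_overrides`` maps a marker name to an LR that replaces whatever the
    profile state would contribute; the sensitivity analyses (marker
    exclusion, PRS-quartile substitution) are expressed through it.
    """
    overrides = lr_overrides or {}
    risk = 1.0
    for name, state in profile.risk_markers.items():
        risk *= overrides[name] if name in overrides else marker_lr(state, name, table)
    prod = 1.0
    for name, state in profile.prodromal_markers.items():
        prod *= overrides[name] if name in overrides else marker_lr(state, name, table)
    return risk, prod, risk * prod


def posttest_probability(pretest: float, lr: float) -> float:
    """Bayes update on the odds scale: post-odds = pre-odds x LR."""
    if not 0.0 < pretest < 1.0:
        raise ValueError(f"pretest probability must be in (0, 1), got {pretest}")
    if lr <= 0:
        raise ValueError(f"total LR must be positive, got {lr}")
    if lr == 1.0:
        return pretest  # identity update, exact (e.g. an all-missing profile)
    odds = pretest / (1.0 - pretest) * lr
    return odds / (1.0 + odds)


def classify(posttest: float) -> tuple[bool, bool, bool]:
    """Flags for the >=30% (possible/probable), >=50% and >=80% (probable) cut-offs."""
    if not 0.0 <= posttest <= 1.0:
        raise ValueError(f"probability out of [0, 1]: {posttest}")
    return tuple(posttest >= c for c in CUTOFFS)  # type: ignore[return-value]


def compute_ppd(
    profile: MarkerProfile,
    table: LikelihoodRatioTable,
    *,
    lr_overrides: Mapping[str, float] | None = None,
) -> PpdResult:
    """Full per-individual calculation: pretest -> marker LRs -> posttest -> cut-offs."""
    pre = pretest_probability(profile.age, table)
    risk, prod, tot = total_lr(profile, table, lr_overrides=lr_overrides)
    post = posttest_probability(pre, tot)
    g30, g50, g80 = classify(post)
    return PpdResult(profile.individual_id, pre, risk, prod, tot, post, g30, g50, g80)


def compute_cohort(
    profiles: Iterable[MarkerProfile],
    table: LikelihoodRatioTable,
    *,
    lr_overrides_by_id: Mapping[str, Mapping[str, float]] | None = None,
    exclude_pd_dlb: bool = True,
) -> tuple[list[PpdResult], int]:
    """Compute pPD results for a cohort.

    Individuals with a PD/DLB diagnosis are excluded up front (the criteria
    target undiagnosed individuals); the number excluded is returned so the
    caller can log it.
    """
    by_id = lr_overrides_by_id or {}
    results: list[PpdResult] = []
    n_excluded = 0
    for p in profiles:
        if exclude_pd_dlb and p.pd_dlb_flag:
            n_excluded += 1
            continue
        results.append(compute_ppd(p, table, lr_overrides=by_id.get(p.individual_id)))
    return results, n_excluded


def recompute_excluding(
    profiles: Sequence[MarkerProfile],
    table: LikelihoodRatioTable,
    drop: str,
    **kwargs,
) -> tuple[list[PpdResult], int]:
    """Sensitivity rerun with one marker's LR forced to 1.0 for everyone.

    Equivalent to removing the marker from the criteria: each total LR is
    divided by exactly the factor the marker contributed.
    """
    table.marker_class(drop)  # raises KeyError for unknown markers
    overrides = {p.individual_id: {drop: 1.0} for p in profiles}
    return compute_cohort(profiles, table, lr_overrides_by_id=overrides, **kwargs)


def substitute_prs_marker(
    profiles: Sequence[MarkerProfile],
    table: LikelihoodRatioTable,
    prs_quartiles: Mapping[str, str],
    *,
    replace: str = "family_history_pd",
    scheme: Mapping[str, float] | None = None,
    **kwargs,
) -> tuple[list[PpdResult], int]:
    """Sensitivity rerun with the cohort PRS quartile as a genetic risk marker.

    The named marker's LR is replaced by the quartile-scheme LR (default:
    top quartile 1.57, middle half 1.00, bottom quartile 0.45); everything
    else is unchanged.
    """
    table.marker_class(replace)
    sch = dict(scheme) if scheme is not None else dict(table.prs_quartile_scheme)
    overrides: dict[str, dict[str, float]] = {}
    for p in profiles:
        if kwargs.get("exclude_pd_dlb", True) and p.pd_dlb_flag:
            continue
        q = prs_quartiles.get(p.individual_id)
        if q is None:
            raise KeyError(f"no PRS quartile for individual {p.individual_id!r}")
        overrides[p.individual_id] = {replace: sch[q]}
    return compute_cohort(profiles, table, lr_overrides_by_id=overrides, **kwargs)
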