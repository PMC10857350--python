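"""Soil quality index: indicator scoring and weighted aggregation.

Each minimum-data-set (MDS) indicator value ``x`` is mapped to a
unitless score in (0, 1) by the non-linear sigmoid

    S = 1 / (1 + (x / x0)^b)

with centring constant ``x0`` (by default the dataset mean of the
indicator) and slope ``b = −2.5`` for "more is better" or ``b = +2.5``
for "less is better". At ``x = x0`` either limb gives exactly 0.5, and
the two limbs are exact complements: S_more + S_less = 1 for matching
``x/x0`` and ``|b|``.

pH uses an "optimum" function: quality rises towards an agronomic
optimum band (5.5–7.0), then falls above it. It is built from a rising
limb centred at the low edge and a falling limb centred at the high
edge; by default the two limbs are combined by their pointwise minimum,
which is the unique continuous piecewise rising/falling combination
(the limbs cross near the band midpoint). The pointwise-maximum
combination is also available but is discontinuous at the band edges.

The index aggregates scores as SQI = Σ W_i · S_i with expert-opinion
weights summing to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IndicatorRule",
    "MDSConfig",
    "SQIResult",
    "DEFAULT_WEIGHTS",
    "default_mds",
    "score_indicator",
    "score_ph_optimum",
    "score_linear",
    "compute_x0",
    "aggregate_scores",
    "score_table",
    "save_mds",
    "load_mds",
]

#: Expert-opinion weights for the seven fertility indicators (sum to 1).
DEFAULT_WEIGHTS = {
    "OM": 0.35,
    "pH": 0.20,
    "TN": 0.15,
    "P": 0.10,
    "K": 0.10,
    "Ca": 0.05,
    "Mg": 0.05,
}


@dataclass
class IndicatorRule:
    """Scoring rule for one indicator.

    ``function`` is one of ``more_is_better``, ``less_is_better``,
    ``optimum``. ``x0_policy`` is ``"dataset_mean"`` (centre at the mean
    of the reference table) or ``"fixed"`` with ``x0_fixed`` set. For
    the optimum function, the rising limb is centred at ``optimum_low``
    and the falling limb at ``optimum_high``; ``optimum_combine``
    selects how the limbs merge (``"min"`` — continuous, default — or
    ``"max"`` inside the band).
    """

    name: str
    function: str
    weight: float
    b_more: float = -2.5
    b_less: float = 2.5
    x0_policy: str = "dataset_mean"
    x0_fixed: Optional[float] = None
    optimum_low: Optional[float] = None
    optimum_high: Optional[float] = None
    optimum_combine: str = "min"

    def __post_init__(self) -> None:
        if self.function not in ("more_is_better", "less_is_better", "optimum"):
            raise ValueError(f"unknown scoring function {self.function!r}")
        if not 0 < self.weight < 1:
            raise ValueError(f"{self.name}: weight must be in (0, 1)")
        if not (self.b_more < 0 < self.b_less):
            raise ValueError(f"{self.name}: need b_more < 0 < b_less")
        if self.function == "optimum":
            if self.optimum_low is None or self.optimum_high is None:
                raise ValueError(f"{self.name}: optimum thresholds required")
            if not 0 < self.optimum_low < self.optimum_high:
                raise ValueError(f"{self.name}: need 0 < optimum_low < optimum_high")
        if self.x0_policy not in ("dataset_mean", "fixed"):
            raise ValueError(f"unknown x0 policy {self.x0_policy!r}")
        if self.x0_policy == "fixed" and self.x0_fixed is None:
            raise ValueError(f"{self.name}: fixed x0 policy needs x0_fixed")
        if self.optimum_combine not in ("min", "max"):
            raise ValueError("optimum_combine must be 'min' or 'max'")


@dataclass
class MDSConfig:
    """Ordered list of indicator rules; weights must sum to 1."""

    rules: list = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            raise ValueError("indicator names must be unique")
        total = sum(r.weight for r in self.rules)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {total!r})")

    @property
    def names(self) -> list:
        return [r.name for r in self.rules]

    @property
    def weights(self) -> dict:
        return {r.name: r.weight for r in self.rules}


def default_mds() -> MDSConfig:
    """The shipped fertility MDS: OM, TN, P, K, Ca, Mg "more is better";
    pH "optimum" on the 5.5–7.0 band."""
    rules = []
    for name, w in DEFAULT_WEIGHTS.items():
        if name == "pH":
            rules.append(
                IndicatorRule(
                    name, "optimum", w, optimum_low=5.5, optimum_high=7.0
                )
            )
        else:
            rules.append(IndicatorRule(name, "more_is_better", w))
    return MDSConfig(rules=rules)


def _sigmoid(x: np.ndarray, x0: float, b: float) -> np.ndarray:
    return 1.0 / (1.0 + (x / x0) ** b)


def score_indicator(x, rule: IndicatorRule, x0: float):
    """Score values on one monotone limb; strictly inside (0, 1).

    ``more_is_better`` uses slope ``rule.b_more`` (rising),
    ``less_is_better`` uses ``rule.b_less`` (falling). Inputs must be
    positive (power-law stability); see :func:`score_table` for the
    zero-substitution applied to whole tables.
    """
    if x0 is None or not x0 > 0:
        raise ValueError(f"x0 must be positive (got {x0!r})")
    arr = np.asarray(x, dtype=float)
    if np.any(arr[np.isfinite(arr)] <= 0):
        raise ValueError("indicator values must be > 0 to be scored")
    if rule.function == "more_is_better":
        out = _sigmoid(arr, x0, rule.b_more)
    elif rule.function == "less_is_better":
        out = _sigmoid(arr, x0, rule.b_less)
    else:
        raise ValueError("use score_ph_optimum for optimum-type rules")
    return out if out.ndim else float(out)


def score_ph_optimum(x, rule: IndicatorRule):
    """Score an optimum-type indicator (pH).

    The rising limb (slope ``b_more``) is centred at ``optimum_low``
    and the falling limb (``b_less``) at ``optimum_high``. With the
    default ``"min"`` combination the score is the pointwise minimum of
    the limbs everywhere: it equals the rising limb below the limbs'
    crossing point, the falling limb above it, and is continuous. With
    ``"max"``, single limbs apply outside the band and the pointwise
    maximum inside it.
    """
    if rule.function != "optimum":
        raise ValueError("rule is not optimum-type")
    arr = np.asarray(x, dtype=float)
    if np.any(arr[np.isfinite(arr)] <= 0):
        raise ValueError("indicator values must be > 0 to be scored")
    rise = _sigmoid(arr, rule.optimum_low, rule.b_more)
    fall = _sigmoid(arr, rule.optimum_high, rule.b_less)
    if rule.optimum_combine == "min":
        out = np.minimum(rise, fall)
    else:
        out = np.where(
            arr < rule.optimum_low,
            rise,
            np.where(arr > rule.optimum_high, fall, np.maximum(rise, fall)),
        )
    return out if out.ndim else float(out)


def score_linear(values: pd.Series) -> pd.Series:
    """Min–max linear scoring variant (not the default): maps the
    observed range onto [0, 1]."""
    lo, hi = values.min(), values.max()
    if not hi > lo:
        raise ValueError("linear scoring needs a non-constant indicator")
    return (values - lo) / (hi - lo)


def compute_x0(values, policy: str = "dataset_mean", fixed: Optional[float] = None) -> float:
    """Centring constant for one indicator.

    ``dataset_mean`` returns the arithmetic mean of non-missing values
    in the reference set; ``fixed`` returns the configured constant.
    """
    if policy == "fixed":
        if fixed is None:
            raise ValueError("fixed policy needs a value")
        return float(fixed)
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("all values missing: cannot compute x0")
    m = float(arr.mean())
    if m <= 0:
        raise ValueError(f"indicator mean must be positive (got {m})")
    return m


@dataclass
class SQIResult:
    """Per-sample indicator scores, aggregated index, and bookkeeping.

    ``scores`` has one ``S_<name>`` column per indicator; ``sqi`` is NaN
    for samples excluded by the complete-case policy; ``complete``
    flags rows with every MDS indicator present.
    """

    scores: pd.DataFrame
    sqi: pd.Series
    complete: pd.Series
    pathway: str = "measured"

    @property
    def n_scored(self) -> int:
        return int(self.sqi.notna().sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        out["SQI"] = self.sqi
        out["pathway"] = self.pathway
        out["complete_case"] = self.complete
        return out


def aggregate_scores(scores: dict, mds: MDSConfig) -> float:
    """Weighted aggregation SQI = Σ W_i · S_i over the MDS indicators."""
    missing = [r.name for r in mds.rules if r.name not in scores]
    if missing:
        raise ValueError(f"scores missing for indicators {missing}")
    return float(sum(r.weight * scores[r.name] for r in mds.rules))


def _positive_floor(reference: pd.Series) -> float:
    pos = reference[reference > 0]
    if pos.empty:
        raise ValueError("indicator has no positive reference values")
    return float(pos.min()) / 2.0


def score_table(
    props: pd.DataFrame,
    mds: MDSConfig,
    x0_reference: Optional[pd.DataFrame] = None,
    missing_policy: str = "complete_case",
    pathway: str = "measured",
) -> SQIResult:
    """Score a property table and aggregate SQI = Σ W_i · S_i.

    ``x0_reference`` supplies the table whose means define each x0 (and
    whose smallest positive values define the zero-substitution floor);
    it defaults to ``props`` itself. Passing the measured table here
    lets predicted properties be scored on the measured centring.

    Non-positive values (e.g. OM or TN measured as 0) are substituted
    by half the smallest positive reference value before scoring, which
    keeps the power law defined while pinning such samples near the
    "worst" end. Under the default complete-case policy, samples
    missing any MDS indicator get NaN SQI and are flagged; the
    ``renormalize`` policy instead rescales the weights of the present
    indicators to sum to 1.
    """
    if missing_policy not in ("complete_case", "renormalize"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    ref = props if x0_reference is None else x0_reference
    missing_cols = [r.name for r in mds.rules if r.name not in props.columns]
    if missing_cols:
        raise ValueError(f"property table lacks MDS indicators {missing_cols}")

    scores = pd.DataFrame(index=props.index)
    for rule in mds.rules:
        col = props[rule.name].astype(float)
        floor = _positive_floor(ref[rule.name].dropna())
        vals = col.where(col > 0, other=floor)
        if rule.function == "optimum":
            s = score_ph_optimum(vals.to_numpy(), rule)
        else:
            x0 = compute_x0(
                ref[rule.name], policy=rule.x0_policy, fixed=rule.x0_fixed
            )
            s = score_indicator(vals.to_numpy(), rule, x0)
        scores[f"S_{rule.name}"] = np.where(col.notna(), s, np.nan)

    weights = np.array([r.weight for r in mds.rules])
    smat = scores.to_numpy()
    present = np.isfinite(smat)
    complete = present.all(axis=1)
    if missing_policy == "complete_case":
        sqi = np.where(complete, np.nansum(smat * weights, axis=1), np.nan)
    else:
        wmat = np.where(present, weights, 0.0)
        tot = wmat.sum(axis=1)
        any_present = tot > 0
        sqi = np.where(
            any_present, np.nansum(smat * wmat, axis=1) / np.where(tot > 0, tot, 1.0), np.nan
        )
    return SQIResult(
        scores=scores,
        sqi=pd.Series(sqi, index=props.index, name="SQI"),
        complete=pd.Series(complete, index=props.index, name="complete_case"),
        pathway=pathway,
    )


def save_mds(mds: MDSConfig, path) -> None:
    doc = [
        {
            k: v
            for k, v in vars(r).items()
            if v is not None
        }
        for r in mds.rules
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"rules": doc}, fh, sort_keys=False)


def load_mds(path) -> MDSConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return MDSConfig(rules=[IndicatorRule(**r) for r in doc["rules"]])
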