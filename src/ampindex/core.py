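"""Core AMPI machinery: goalpost normalization, polarity handling, aggregation.

The Adjusted Mazziotta-Pareto Index (AMPI) is a partially non-compensatory
composite index.  Each indicator column is rescaled onto a common
[70, 130]-anchored scale by a min-max ("goalpost") transformation,

    r_ij = (x_ij - Min_j) / (Max_j - Min_j) * 60 + 70,

indicators whose polarity is negative (more is worse) are reversed by taking
the complement of the normalized value with respect to 200, and each unit's
score is the mean of its normalized values minus a penalty proportional to
their horizontal variability:

    AMPI_i = M_i - S_i * cv_i,      cv_i = S_i / M_i,

so the penalty equals S_i^2 / M_i.  Two units with the same mean therefore
differ in score when one has a more unbalanced indicator profile: a deficit
in one dimension cannot be fully offset by a surplus in another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ampindex")

#: anchor and half-width of the normalized scale: values map to [70, 130]
SCALE_SPAN = 60.0
SCALE_BASE = 70.0
#: reversal pivot for negative-polarity indicators (complement w.r.t. 200)
POLARITY_PIVOT = 200.0

SdConvention = Literal["sample", "population"]
PolarityValue = Literal["positive", "negative"]
GoalpostPolicy = Literal["observed_minmax", "reference_delta"]


class ValidationError(ValueError):
    """Raised when an input panel, config, or goalpost set is invalid."""


# ---------------------------------------------------------------------------
# Panel and goalposts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndicatorPanel:
    """A units x indicators matrix with labelled rows and columns.

    Rows are territorial units (e.g. the 21 Italian regions and autonomous
    provinces), columns are numeric indicators with heterogeneous units of
    measure.  Missing values are an error state: the penalty term depends on
    the full indicator profile of each unit, so silent imputation would
    change scores.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 2:
            raise ValidationError(
                f"panel needs more than one unit, got {df.shape[0]}"
            )
        if df.shape[1] < 1:
            raise ValidationError("panel needs at least one indicator column")
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate unit labels: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate indicator labels: {dupes}")
        non_numeric = [
            c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])
        ]
        if non_numeric:
            raise ValidationError(f"non-numeric indicator columns: {non_numeric}")
        bad = np.argwhere(~np.isfinite(df.to_numpy(dtype=float)))
        if bad.size:
            cells = [
                (str(df.index[i]), str(df.columns[j])) for i, j in bad[:10]
            ]
            raise ValidationError(
                f"panel contains missing/non-finite values at (unit, indicator): {cells}"
            )

    @property
    def units(self) -> list[str]:
        return [str(u) for u in self.data.index]

    @property
    def indicators(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, indicators: Sequence[str]) -> "IndicatorPanel":
        missing = [c for c in indicators if c not in self.data.columns]
        if missing:
            raise ValidationError(f"panel is missing indicator columns: {missing}")
        return IndicatorPanel(self.data.loc[:, list(indicators)])


@dataclass(frozen=True)
class Goalposts:
    """Per-indicator (min, max) pair anchoring the min-max rescaling."""

    bounds: pd.DataFrame  # index = indicator, columns = ["min", "max"]

    def __post_init__(self) -> None:
        b = self.bounds
        if list(b.columns) != ["min", "max"]:
            raise ValidationError("goalpost frame must have columns ['min', 'max']")
        degenerate = b.index[b["max"] <= b["min"]].tolist()
        if degenerate:
            raise ValidationError(
                f"degenerate goalposts (max <= min) for indicators: {degenerate}"
            )

    @classmethod
    def from_mapping(cls, bounds: Mapping[str, tuple[float, float]]) -> "Goalposts":
        frame = pd.DataFrame(
            {
                "min": {k: float(v[0]) for k, v in bounds.items()},
                "max": {k: float(v[1]) for k, v in bounds.items()},
            }
        )
        return cls(frame[["min", "max"]])

    def for_indicators(self, indicators: Sequence[str]) -> pd.DataFrame:
        missing = [c for c in indicators if c not in self.bounds.index]
        if missing:
            raise ValidationError(f"no goalposts for indicators: {missing}")
        return self.bounds.loc[list(indicators)]


def observed_goalposts(panel: IndicatorPanel) -> Goalposts:
    """Goalposts from the observed per-indicator min/max across all units.

    This is the only choice computable from a single cross-sectional panel
    alone; it pins the normalized values exactly onto [70, 130].
    """
    df = panel.data
    return Goalposts(pd.DataFrame({"min": df.min(axis=0), "max": df.max(axis=0)}))


def reference_goalposts(panel: IndicatorPanel) -> Goalposts:
    """Reference-based goalposts: Min = ref - delta, Max = ref + delta.

    ``ref`` is the cross-unit mean and ``delta`` half the observed range, a
    convention used when scores must stay comparable across panels sharing
    the same reference.  Values may fall outside [70, 130] under this policy.
    """
    df = panel.data
    ref = df.mean(axis=0)
    delta = (df.max(axis=0) - df.min(axis=0)) / 2.0
    return Goalposts(pd.DataFrame({"min": ref - delta, "max": ref + delta}))


GOALPOST_POLICIES = {
    "observed_minmax": observed_goalposts,
    "reference_delta": reference_goalposts,
}


def make_goalposts(panel: IndicatorPanel, policy: GoalpostPolicy) -> Goalposts:
    try:
        builder = GOALPOST_POLICIES[policy]
    except KeyError:
        raise ValidationError(
            f"unknown goalpost policy {policy!r}; expected one of {sorted(GOALPOST_POLICIES)}"
        ) from None
    return builder(panel)


# ---------------------------------------------------------------------------
# Normalization and polarity
# ---------------------------------------------------------------------------


def normalize(panel: IndicatorPanel, goalposts: Goalposts) -> pd.DataFrame:
    """Min-max rescale every column onto the [70, 130]-anchored scale.

    Values falling outside [70, 130] are allowed (the goalposts may be wider
    or narrower than the observed range) but logged, never clipped.
    """
    bounds = goalposts.for_indicators(panel.indicators)
    lo = bounds["min"].to_numpy()
    hi = bounds["max"].to_numpy()
    r = (panel.values - lo) / (hi - lo) * SCALE_SPAN + SCALE_BASE
    out = pd.DataFrame(r, index=panel.data.index, columns=panel.data.columns)
    outside = (out < SCALE_BASE - 1e-9) | (out > SCALE_BASE + SCALE_SPAN + 1e-9)
    if outside.to_numpy().any():
        n_out = int(outside.to_numpy().sum())
        cols = outside.any(axis=0)
        logger.warning(
            "%d normalized value(s) outside [70, 130] in column(s) %s "
            "(raw values beyond the goalposts; kept unclipped)",
            n_out,
            list(cols.index[cols]),
        )
    return out


def apply_polarity(
    normalized: pd.DataFrame, polarities: Mapping[str, str]
) -> pd.DataFrame:
    """Reverse negative-polarity columns via the complement w.r.t. 200.

    The complement maps 70 <-> 130 and fixes 100, so the reversed column
    lives on the same scale.  Applied to the *normalized* values, after the
    min-max rescaling — equivalent to reversing raw values only when the
    goalposts are symmetric around the column mean.
    """
    out = normalized.copy()
    for col in normalized.columns:
        pol = polarities.get(str(col))
        if pol is None:
            raise ValidationError(f"no polarity declared for indicator {col!r}")
        if pol == "negative":
            out[col] = POLARITY_PIVOT - normalized[col]
        elif pol != "positive":
            raise ValidationError(
                f"unknown polarity {pol!r} for indicator {col!r}; "
                "expected 'positive' or 'negative'"
            )
    return out


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompositeScore:
    """AMPI decomposition for one unit: score = mean_level - penalty."""

    unit: str
    mean_level: float
    penalty: float
    score: float
    components: tuple[float, ...] = field(repr=False, default=())


def aggregate_ampi(
    normalized_row: Iterable[float],
    sd_convention: SdConvention = "sample",
    unit: str = "",
) -> CompositeScore:
    """Aggregate one unit's normalized values into its AMPI score.

    The penalty S*cv = S^2/M rewards balanced profiles: among units with the
    same mean, the one with the more dispersed indicator values scores lower.
    ``sd_convention`` selects the divisor of the standard deviation of the
    normalized values: "sample" (n-1, the default) or "population" (n).
    """
    row = np.asarray(list(normalized_row), dtype=float)
    if row.size < 2:
        raise ValidationError(
            f"AMPI needs at least 2 components per unit, got {row.size} "
            "(the coefficient of variation is undefined otherwise)"
        )
    if not np.all(np.isfinite(row)):
        raise ValidationError(f"non-finite normalized values for unit {unit!r}")
    mean = float(row.mean())
    if mean <= 0:
        raise ValidationError(
            f"mean of normalized values must be positive, got {mean} for unit {unit!r}"
        )
    if sd_convention == "sample":
        sd = float(row.std(ddof=1))
    elif sd_convention == "population":
        sd = float(row.std(ddof=0))
    else:
        raise ValidationError(
            f"unknown sd convention {sd_convention!r}; expected 'sample' or 'population'"
        )
    penalty = sd * sd / mean
    return CompositeScore(
        unit=unit,
        mean_level=mean,
        penalty=penalty,
        score=mean - penalty,
        components=tuple(row),
    )


def aggregate_scores(
    scores: pd.DataFrame, sd_convention: SdConvention = "sample"
) -> pd.DataFrame:
    """Aggregate already-normalized score columns row-wise (no re-scaling).

    Used both for composite-of-composites nodes (child index scores are
    already on the common [70, 130]-anchored scale) and for panels whose
    columns are pre-normalized.  Returns a frame with columns
    ``mean_level``, ``penalty``, ``score`` indexed by unit.
    """
    records = [
        aggregate_ampi(scores.loc[u], sd_convention=sd_convention, unit=str(u))
        for u in scores.index
    ]
    return pd.DataFrame(
        {
            "mean_level": [r.mean_level for r in records],
            "penalty": [r.penalty for r in records],
            "score": [r.score for r in records],
        },
        index=scores.index,
    )


def compute_index(
    panel: IndicatorPanel,
    polarities: Mapping[str, str],
    goalposts: Goalposts | None = None,
    sd_convention: SdConvention = "sample",
    goalpost_policy: GoalpostPolicy = "observed_minmax",
    allow_single_indicator: bool = False,
) -> pd.DataFrame:
    """Full pipeline for one index: normalize -> polarity -> aggregate.

    When ``goalposts`` is None they are derived from the panel under
    ``goalpost_policy``.  A single-indicator index is rejected unless
    ``allow_single_indicator`` is set, in which case the score is the
    (polarity-adjusted) normalized value itself with zero penalty.
    """
    if panel.data.shape[1] == 1 and not allow_single_indicator:
        raise ValidationError(
            "index has a single indicator; the AMPI penalty needs >= 2 "
            "components (pass allow_single_indicator=True to bypass)"
        )
    if goalposts is None:
        goalposts = make_goalposts(panel, goalpost_policy)
    adjusted = apply_polarity(normalize(panel, goalposts), polarities)
    if adjusted.shape[1] == 1:
        col = adjusted.iloc[:, 0].astype(float)
        return pd.DataFrame(
            {"mean_level": col, "penalty": 0.0, "score": col}, index=adjusted.index
        )
    return aggregate_scores(adjusted, sd_convention=sd_convention)
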