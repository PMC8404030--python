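"""Declarative index definitions and hierarchical aggregation.

The shipped catalog encodes five composite indexes of regional health-system
performance and population health: Accessibility (4 indicators), Quality —
itself the aggregation of three sub-indexes, Effectiveness (2), Safety (3)
and Responsiveness/Patient-centeredness (3) — Cost/expenditure (3), Health
status (5) and Lifestyles (10).  Each indicator carries a polarity flag;
negative-polarity indicators are reversed during normalization so every
index is oriented "higher is better".

Composite nodes aggregate their children's *scores* directly, without
re-normalizing them: child scores already live on the common
[70, 130]-anchored scale, and direct aggregation is the variant that
reproduces the published Quality column from its three sub-index columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import pandas as pd
import yaml

from .core import (
    GoalpostPolicy,
    IndicatorPanel,
    SdConvention,
    ValidationError,
    aggregate_scores,
    compute_index,
)

_DATA = resources.files("ampindex") / "data"

FIXTURE_TABLES = {
    "table3_health_lifestyles": "table3_health_lifestyles.csv",
    "table4_accessibility": "table4_accessibility.csv",
    "table5_quality": "table5_quality.csv",
    "table6_cost": "table6_cost.csv",
}


@dataclass(frozen=True)
class IndicatorDefinition:
    """Metadata for one indicator: polarity, provenance, display label."""

    key: str
    display: str
    polarity: str
    source: str = ""
    year: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValidationError(
                f"indicator {self.key!r}: polarity must be positive|negative, "
                f"got {self.polarity!r}"
            )


@dataclass(frozen=True)
class IndexDefinition:
    """A node of the index tree: either a leaf over indicators or a composite
    over child indexes (never both)."""

    name: str
    display: str = ""
    indicators: tuple[IndicatorDefinition, ...] = ()
    children: tuple["IndexDefinition", ...] = ()

    def __post_init__(self) -> None:
        if bool(self.indicators) == bool(self.children):
            raise ValidationError(
                f"index {self.name!r} must have either indicators or children, "
                "not both and not neither"
            )
        if self.children and len(self.children) < 2:
            raise ValidationError(
                f"composite index {self.name!r} needs >= 2 children"
            )
        self._check_tree()

    def _check_tree(self) -> None:
        seen_nodes: set[str] = set()
        seen_indicators: set[str] = set()
        for node in self.walk():
            if node.name in seen_nodes:
                raise ValidationError(
                    f"index name {node.name!r} appears under two parents"
                )
            seen_nodes.add(node.name)
            for ind in node.indicators:
                if ind.key in seen_indicators:
                    raise ValidationError(
                        f"indicator {ind.key!r} appears under two parents"
                    )
                seen_indicators.add(ind.key)

    @property
    def is_leaf(self) -> bool:
        return bool(self.indicators)

    def walk(self) -> Iterator["IndexDefinition"]:
        """Yield this node and every descendant, depth-first, children first
        in declaration order."""
        yield self
        for child in self.children:
            yield from child.walk()

    def leaf_indicators(self) -> list[IndicatorDefinition]:
        return [ind for node in self.walk() for ind in node.indicators]

    def polarities(self) -> dict[str, str]:
        return {ind.key: ind.polarity for ind in self.leaf_indicators()}


@dataclass(frozen=True)
class FrameworkCatalog:
    """The full set of top-level index definitions shipped or user-supplied."""

    indexes: tuple[IndexDefinition, ...]

    def __post_init__(self) -> None:
        names = [d.name for d in self.indexes]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate top-level index names: {names}")

    def get(self, name: str) -> IndexDefinition:
        for d in self.indexes:
            if d.name == name:
                return d
        raise KeyError(f"no index named {name!r} in catalog")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.indexes]


def _parse_index(node: Mapping) -> IndexDefinition:
    name = node["name"]
    display = node.get("display", name)
    if "children" in node:
        children = tuple(_parse_index(c) for c in node["children"])
        return IndexDefinition(name=name, display=display, children=children)
    indicators = tuple(
        IndicatorDefinition(
            key=i["key"],
            display=i.get("display", i["key"]),
            polarity=i["polarity"],
            source=str(i.get("source", "")),
            year=str(i.get("year", "")),
        )
        for i in node.get("indicators", [])
    )
    return IndexDefinition(name=name, display=display, indicators=indicators)


def load_catalog(path=None) -> FrameworkCatalog:
    """Load an index catalog from YAML; default is the shipped five-index one."""
    if path is None:
        text = (_DATA / "catalog.yaml").read_text(encoding="utf-8")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    try:
        raw = yaml.safe_load(text)
        indexes = tuple(_parse_index(n) for n in raw["indexes"])
    except (KeyError, TypeError, yaml.YAMLError) as exc:
        raise ValidationError(f"malformed catalog file: {exc}") from exc
    return FrameworkCatalog(indexes=indexes)


def default_catalog() -> FrameworkCatalog:
    return load_catalog(None)


# ---------------------------------------------------------------------------
# Hierarchical aggregation
# ---------------------------------------------------------------------------


def compute_hierarchy(
    panel: IndicatorPanel,
    definition: IndexDefinition,
    sd_convention: SdConvention = "sample",
    goalpost_policy: GoalpostPolicy = "observed_minmax",
) -> dict[str, pd.DataFrame]:
    """Score every node of an index tree for every unit.

    Leaf indexes run the full normalize -> polarity -> aggregate pipeline on
    their indicator columns; composite indexes aggregate their children's
    score columns directly (no re-normalization).  Returns a mapping from
    node name to its mean_level/penalty/score table, root included.
    """
    tables: dict[str, pd.DataFrame] = {}

    def _compute(node: IndexDefinition) -> pd.DataFrame:
        if node.is_leaf:
            keys = [ind.key for ind in node.indicators]
            missing = [k for k in keys if k not in panel.data.columns]
            if missing:
                raise ValidationError(
                    f"index {node.name!r} is missing indicator column(s): {missing}"
                )
            table = compute_index(
                panel.subset(keys),
                polarities=node.polarities(),
                sd_convention=sd_convention,
                goalpost_policy=goalpost_policy,
                allow_single_indicator=True,
            )
        else:
            child_scores = pd.DataFrame(
                {child.name: _compute(child)["score"] for child in node.children}
            )
            table = aggregate_scores(child_scores, sd_convention=sd_convention)
        tables[node.name] = table
        return table

    _compute(definition)
    return tables


def score_summary(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Collect the score column of every node into one units x nodes frame."""
    return pd.DataFrame({name: t["score"] for name, t in tables.items()})


# ---------------------------------------------------------------------------
# Catalog / panel validation report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CatalogReport:
    """Report-only reconciliation between a catalog and a panel."""

    missing_indicators: dict[str, list[str]]  # index name -> absent columns
    unused_columns: list[str]
    indicator_counts: dict[str, int]
    negative_polarity: list[str]

    @property
    def ok(self) -> bool:
        return not self.missing_indicators

    def lines(self) -> list[str]:
        out = []
        for idx, missing in sorted(self.missing_indicators.items()):
            out.append(f"index {idx!r} incomplete: missing {missing}")
        if self.unused_columns:
            out.append(f"unused panel columns (not an error): {self.unused_columns}")
        for idx, n in sorted(self.indicator_counts.items()):
            out.append(f"index {idx!r}: {n} indicator(s)")
        out.append(f"negative-polarity indicators: {len(self.negative_polarity)}")
        return out


def validate_catalog(
    catalog: FrameworkCatalog, panel: IndicatorPanel
) -> CatalogReport:
    """Check indicator coverage of a panel against a catalog (report-only)."""
    cols = set(panel.data.columns.astype(str))
    missing: dict[str, list[str]] = {}
    referenced: set[str] = set()
    counts: dict[str, int] = {}
    negative: list[str] = []
    for top in catalog.indexes:
        for node in top.walk():
            if not node.is_leaf:
                continue
            keys = [ind.key for ind in node.indicators]
            counts[node.name] = len(keys)
            referenced.update(keys)
            absent = [k for k in keys if k not in cols]
            if absent:
                missing[node.name] = absent
            negative.extend(
                ind.key for ind in node.indicators if ind.polarity == "negative"
            )
    unused = sorted(cols - referenced)
    return CatalogReport(
        missing_indicators=missing,
        unused_columns=unused,
        indicator_counts=counts,
        negative_polarity=negative,
    )


# ---------------------------------------------------------------------------
# Bundled published score tables
# ---------------------------------------------------------------------------


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the bundled published score tables, indexed by region.

    Available: table3_health_lifestyles (health_status + lifestyles columns),
    table4_accessibility, table5_quality (three sub-index columns plus the
    published Quality column), table6_cost.
    """
    try:
        fname = FIXTURE_TABLES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURE_TABLES)}"
        ) from None
    with (_DATA / "fixtures" / fname).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, index_col="region")


def published_scores() -> pd.DataFrame:
    """All published top-level and Quality sub-index score columns, merged on
    region: accessibility, effectiveness, safety, responsiveness, quality,
    cost_expenditure, health_status, lifestyles (21 rows)."""
    t3 = load_fixture("table3_health_lifestyles")
    t4 = load_fixture("table4_accessibility")
    t5 = load_fixture("table5_quality")
    t6 = load_fixture("table6_cost")
    merged = t4.join([t5, t6, t3], how="inner")
    if len(merged) != len(t4):
        raise ValidationError("fixture tables do not share a common region set")
    return merged
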