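"""CSV/YAML readers and writers and the end-to-end pipeline driver.

Panel CSVs: first column = unit label, remaining columns numeric indicators,
mandatory header row, UTF-8, "." decimal separator.  Every artifact written
by the pipeline embeds the package version and a hash of the run config in
a leading comment line, so outputs are traceable to their configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import IndicatorPanel, ValidationError
from .framework import (
    FrameworkCatalog,
    default_catalog,
    load_catalog,
    score_summary,
    compute_hierarchy,
    validate_catalog,
)
from .ranking import (
    correlation_long,
    rank_units,
    render_correlation_report,
    spearman_matrix,
)

logger = logging.getLogger("ampindex")


def read_panel(path: str | Path) -> IndicatorPanel:
    """Read and validate a units x indicators panel from CSV.

    Rejects empty files, duplicate unit labels and non-numeric cells with
    messages naming the offending row/column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0, encoding="utf-8", comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no data rows") from None
    except (OSError, pd.errors.ParserError) as exc:
        raise ValidationError(f"{path}: malformed CSV ({exc})") from exc
    if df.empty and df.shape[1] == 0:
        raise ValidationError(f"{path}: no data rows")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate unit label(s): {dupes}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric cell(s) in column {col!r} at unit(s) "
                f"{list(map(str, bad[:5]))}"
            )
        df[col] = coerced
    df.index = df.index.astype(str)
    return IndicatorPanel(df)


def _header(config_hash: str) -> str:
    return f"# ampindex {__version__} config_hash={config_hash}\n"


def write_table(df: pd.DataFrame, path: Path, config_hash: str = "-") -> None:
    """Write a frame to CSV with the traceability header, full precision."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header(config_hash))
        df.to_csv(fh)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    panel: str
    catalog: str | None = None  # None -> shipped catalog
    sd_convention: str = "sample"
    goalpost_policy: str = "observed_minmax"
    out_dir: str = "ampindex_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.sd_convention not in ("sample", "population"):
            raise ValidationError(
                f"sd_convention must be sample|population, got {self.sd_convention!r}"
            )
        if self.goalpost_policy not in ("observed_minmax", "reference_delta"):
            raise ValidationError(
                "goalpost_policy must be observed_minmax|reference_delta, "
                f"got {self.goalpost_policy!r}"
            )

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config key(s): {sorted(unknown)}")
    if "panel" not in raw:
        raise ValidationError(f"{path}: config must set 'panel'")
    return RunConfig(**raw)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full workflow: panel -> per-index scores -> ranks -> correlations.

    Writes, under ``config.out_dir``: one scores CSV per index node (root
    and sub-indexes), one rank table per top-level index, the Spearman
    correlation report (text) and its long-format CSV twin.  Returns the
    artifact paths keyed by short name.  Deterministic: identical config and
    inputs give identical artifacts.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    digest = config.digest()
    artifacts: dict[str, Path] = {}

    logger.info("reading panel %s", config.panel)
    panel = read_panel(config.panel)
    catalog: FrameworkCatalog = (
        default_catalog() if config.catalog is None else load_catalog(config.catalog)
    )
    report = validate_catalog(catalog, panel)
    for line in report.lines():
        logger.info("catalog check: %s", line)
    if not report.ok:
        raise ValidationError(
            "panel does not cover the catalog: "
            + "; ".join(
                f"{idx} missing {m}" for idx, m in report.missing_indicators.items()
            )
        )

    top_scores = {}
    for definition in catalog.indexes:
        tables = compute_hierarchy(
            panel,
            definition,
            sd_convention=config.sd_convention,  # type: ignore[arg-type]
            goalpost_policy=config.goalpost_policy,  # type: ignore[arg-type]
        )
        for node_name, table in tables.items():
            p = out / f"scores_{node_name}.csv"
            write_table(table, p, digest)
            artifacts[f"scores_{node_name}"] = p
        root = tables[definition.name]["score"]
        top_scores[definition.name] = root
        rank_path = out / f"rank_{definition.name}.csv"
        write_table(
            rank_units(root, name="score").set_index("unit"), rank_path, digest
        )
        artifacts[f"rank_{definition.name}"] = rank_path

    matrix = spearman_matrix(pd.DataFrame(top_scores))
    long_path = out / "correlations.csv"
    write_table(correlation_long(matrix).set_index("index_a"), long_path, digest)
    artifacts["correlations"] = long_path
    report_path = out / "correlations.txt"
    report_path.write_text(
        _header(digest) + render_correlation_report(matrix) + "\n", encoding="utf-8"
    )
    artifacts["correlations_report"] = report_path
    logger.info("wrote %d artifacts to %s", len(artifacts), out)
    return artifacts


def hierarchy_scores(
    panel: IndicatorPanel,
    catalog: FrameworkCatalog,
    sd_convention: str = "sample",
    goalpost_policy: str = "observed_minmax",
) -> pd.DataFrame:
    """Convenience: units x nodes score frame for every index in a catalog."""
    frames = []
    for definition in catalog.indexes:
        tables = compute_hierarchy(
            panel,
            definition,
            sd_convention=sd_convention,  # type: ignore[arg-type]
            goalpost_policy=goalpost_policy,  # type: ignore[arg-type]
        )
        frames.append(score_summary(tables))
    return pd.concat(frames, axis=1)
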