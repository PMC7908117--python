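"""Panel CSV input, rank-report output, and run configuration.

The single input dialect is a wide CSV: rows are observation points,
columns are series, UTF-8, comma delimiter, period decimal mark. An
optional leading non-numeric column is treated as observation labels. One
named column is the reference; every other numeric column becomes a
comparator, in file order.

Report output mirrors the usual presentation of grey-relation results:
one degree row and one rank row per model, factors as columns. Display
rounding is half-up at a configurable number of decimals (4 by default, 5
for the second synthetic degree, matching how these numbers are
conventionally printed) and never feeds back into computation; the JSON
report carries full-precision degrees alongside the rounded display
strings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .errors import GreyRankError, MissingReferenceError, ParseError
from .models import DEFAULT_EPSILON, GraModel
from .sequence import Panel, Series
from .synthesis import DEFAULT_THETA, RankTable

__all__ = [
    "RunConfig",
    "read_panel_csv",
    "write_panel_csv",
    "write_rank_report",
    "round_half_up",
]

ALL_MODELS = tuple(GraModel)


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one `compute` run."""

    epsilon: float = DEFAULT_EPSILON
    theta: float = DEFAULT_THETA
    models: tuple[GraModel, ...] = ALL_MODELS
    reference: str = "satisfaction"
    output_format: str = "csv"
    decimals: int = 4
    ssgra_decimals: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon <= 1.0):
            raise GreyRankError(f"epsilon must be in (0, 1], got {self.epsilon}")
        if not (0.0 <= self.theta <= 1.0):
            raise GreyRankError(f"theta must be in [0, 1], got {self.theta}")
        if not self.models:
            raise GreyRankError("model list must be non-empty")
        if self.output_format not in ("csv", "json"):
            raise GreyRankError(f"unknown output format {self.output_format!r}")
        if self.decimals < 1:
            raise GreyRankError(f"decimals must be >= 1, got {self.decimals}")

    def decimals_for(self, model: GraModel) -> int:
        return self.ssgra_decimals if model is GraModel.SSGRA else self.decimals


def round_half_up(value: float, decimals: int) -> str:
    """Decimal half-up rounding to a fixed number of places, as text.

    Applied to the shortest decimal representation of the float so that
    e.g. a blend equal to 0.78435 prints as "0.7844" rather than falling
    victim to the binary representation 0.78434999....
    """
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def read_panel_csv(path: str | Path, reference_column: str) -> Panel:
    """Parse a wide panel CSV into a :class:`Panel`.

    Raises
    ------
    ParseError
        On unreadable files or non-numeric cells (the message names the
        row and column).
    MissingReferenceError
        If ``reference_column`` is not among the numeric columns.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty or df.shape[1] == 0:
        raise ParseError(f"{path}: no data rows")

    columns = list(df.columns)
    # A leading label column (observation ids) is allowed and skipped.
    start = 0
    if columns and columns[0] != reference_column:
        try:
            df[columns[0]].astype(float)
        except (TypeError, ValueError):
            start = 1
    numeric: dict[str, Series] = {}
    for col in columns[start:]:
        raw = df[col]
        values = []
        for i, cell in enumerate(raw):
            try:
                values.append(float(cell))
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric cell at row {i + 2}, column {col!r}: "
                    f"{cell!r}"
                ) from None
        numeric[col] = Series(col, values)

    if reference_column not in numeric:
        raise MissingReferenceError(
            f"{path}: reference column {reference_column!r} not found among "
            f"{sorted(numeric)}"
        )
    comparators = tuple(s for name, s in numeric.items() if name != reference_column)
    return Panel(reference=numeric[reference_column], comparators=comparators)


def write_panel_csv(panel: Panel, path: str | Path, labels: list[str] | None = None) -> None:
    """Write a panel in the wide dialect :func:`read_panel_csv` consumes.

    Values are written in repr form, so a write/read round trip is exact.
    """
    path = Path(path)
    data: dict[str, list] = {}
    if labels is not None:
        data["observation"] = list(labels)
    data[panel.reference.name] = [repr(float(v)) for v in panel.reference.values]
    for s in panel.comparators:
        data[s.name] = [repr(float(v)) for v in s.values]
    pd.DataFrame(data).to_csv(path, index=False)


def _report_frame(tables: list[RankTable], config: RunConfig) -> pd.DataFrame:
    factors = list(tables[0].degrees)
    rows = []
    for table in tables:
        nd = config.decimals_for(table.model)
        rows.append(
            {
                "model": table.model.value,
                "row": "degree",
                **{f: round_half_up(table.degrees[f], nd) for f in factors},
            }
        )
        rows.append(
            {
                "model": table.model.value,
                "row": "rank",
                **{f: table.ranks[f] for f in factors},
            }
        )
    return pd.DataFrame(rows)


def write_rank_report(
    tables: list[RankTable], config: RunConfig, path: str | Path
) -> None:
    """Write degree and rank rows for each model to CSV or JSON.

    CSV: one degree row plus one rank row per model, factors as columns,
    degrees rounded per ``config``. JSON additionally carries the
    full-precision degrees.
    """
    if not tables:
        raise GreyRankError("no rank tables to write")
    path = Path(path)
    try:
        if config.output_format == "json":
            payload = {
                "epsilon": config.epsilon,
                "theta": config.theta,
                "models": {
                    t.model.value: {
                        "degrees": t.degrees,
                        "display": {
                            f: round_half_up(v, config.decimals_for(t.model))
                            for f, v in t.degrees.items()
                        },
                        "ranks": t.ranks,
                        "has_ties": t.has_ties,
                    }
                    for t in tables
                },
            }
            path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
        else:
            _report_frame(tables, config).to_csv(path, index=False)
    except OSError as exc:
        raise GreyRankError(f"cannot write report to {path}: {exc}") from exc
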