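"""Bundled study data and the verification / reproduction harness.

The package ships the published region-level panel from the Chinese
healthcare-satisfaction study — mean satisfaction score plus five resource
indicators over eight regions (four economic regions, four municipalities),
for the pooled 2013&2015 period and each year separately — together with
the study's published degree-and-rank tables for all five models.

Two classes of check run against these tables:

* **asserting checks** that depend only on the published numbers
  themselves: every synthetic degree must equal the theta = 0.5 blend of
  its two base-model cells up to print rounding, and re-ranking every
  published degree row must reproduce the published rank row exactly;
* an **exploratory recomputation** that runs the full pipeline on the
  region-level panel and reports recomputed degrees side by side with the
  published ones. The study's sequence construction (what the observation
  axis indexed, and how individual survey scores were paired with
  province-level resources) is not recoverable from the published tables,
  so this comparison is informational and never asserted.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .models import DEFAULT_EPSILON, GraModel
from .sequence import Panel, Series
from .synthesis import (
    DEFAULT_THETA,
    compute_all,
    first_synthetic_degree,
    rank_factors,
    second_synthetic_degree,
)

__all__ = [
    "Period",
    "REFERENCE_COLUMN",
    "FACTOR_COLUMNS",
    "load_fixture",
    "load_published_tables",
    "fixture_checksum",
    "verify_synthetic_identities",
    "verify_rank_consistency",
    "exploratory_recompute",
    "IdentityReport",
    "RankReport",
    "RecomputeReport",
]

REFERENCE_COLUMN = "satisfaction"
FACTOR_COLUMNS = (
    "health_exp_pct_gdp",
    "gov_pct_health_exp",
    "oop_pct",
    "beds_per_1000",
    "workforce_per_1000",
)


class Period(enum.Enum):
    """Observation period of the bundled panel."""

    POOLED_2013_2015 = "pooled_2013_2015"
    Y2013 = "y2013"
    Y2015 = "y2015"


_PANEL_FILES = {
    Period.POOLED_2013_2015: "panel_pooled_2013_2015.csv",
    Period.Y2013: "panel_2013.csv",
    Period.Y2015: "panel_2015.csv",
}

# Synthetic-degree component pairing: SDGRA blends absolute+relative,
# SSGRA blends Deng+absolute.
_SYNTH_COMPONENTS = {
    GraModel.SDGRA: (GraModel.ABSOLUTE, GraModel.RELATIVE, first_synthetic_degree),
    GraModel.SSGRA: (GraModel.DENG, GraModel.ABSOLUTE, second_synthetic_degree),
}


def _read_data(name: str) -> str:
    return resources.files("greyrank.data").joinpath(name).read_text(encoding="utf-8")


def _panel_frame(period: Period) -> pd.DataFrame:
    from io import StringIO

    return pd.read_csv(StringIO(_read_data(_PANEL_FILES[period])))


def load_fixture(period: Period = Period.POOLED_2013_2015) -> Panel:
    """The bundled 8-region panel for one period, satisfaction as reference."""
    df = _panel_frame(period)
    reference = Series(REFERENCE_COLUMN, df[REFERENCE_COLUMN].to_numpy(dtype=float))
    comparators = tuple(
        Series(col, df[col].to_numpy(dtype=float)) for col in FACTOR_COLUMNS
    )
    return Panel(reference=reference, comparators=comparators)


def load_published_tables() -> dict:
    """The published degree/rank tables as a nested dict (see the JSON file)."""
    return json.loads(_read_data("published_tables.json"))


def fixture_checksum() -> str:
    """SHA-256 over the embedded panel values, for integrity tests.

    Canonical form: period key, then each region row joined by commas with
    values in repr form, newline-separated.
    """
    h = hashlib.sha256()
    for period in Period:
        df = _panel_frame(period)
        h.update(period.value.encode())
        for _, row in df.iterrows():
            cells = [str(row["region"])] + [
                repr(float(row[c])) for c in (REFERENCE_COLUMN, *FACTOR_COLUMNS)
            ]
            h.update((",".join(cells) + "\n").encode())
    return h.hexdigest()


@dataclass(frozen=True)
class IdentityCell:
    period: str
    model: GraModel
    factor: str
    recomputed: float
    published: float

    @property
    def diff(self) -> float:
        return abs(self.recomputed - self.published)


@dataclass(frozen=True)
class IdentityReport:
    tol: float
    cells: tuple[IdentityCell, ...]

    @property
    def passed(self) -> bool:
        return all(c.diff <= self.tol for c in self.cells)

    @property
    def max_diff(self) -> float:
        return max(c.diff for c in self.cells)

    def failures(self) -> list[IdentityCell]:
        return [c for c in self.cells if c.diff > self.tol]


def verify_synthetic_identities(tol: float = 5e-5) -> IdentityReport:
    """Check every published synthetic cell against the blend of its bases.

    For each period table and each factor, recompute SDGRA and SSGRA at
    theta = 0.5 from the published base-model degrees and compare with the
    published synthetic degree. The default tolerance 5e-5 covers the 4-5
    decimal rounding of the published numbers.
    """
    if tol <= 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    tables = load_published_tables()
    factors = tables["factors"]
    cells = []
    for period, models in tables["periods"].items():
        for synth, (first, second, blend) in _SYNTH_COMPONENTS.items():
            for j, factor in enumerate(factors):
                recomputed = blend(
                    models[first.value]["degrees"][j],
                    models[second.value]["degrees"][j],
                    0.5,
                )
                cells.append(
                    IdentityCell(
                        period=period,
                        model=synth,
                        factor=factor,
                        recomputed=recomputed,
                        published=models[synth.value]["degrees"][j],
                    )
                )
    return IdentityReport(tol=tol, cells=tuple(cells))


@dataclass(frozen=True)
class RankRow:
    label: str
    published: tuple[int, ...]
    recomputed: tuple[int, ...]

    @property
    def matches(self) -> bool:
        return self.published == self.recomputed


@dataclass(frozen=True)
class RankReport:
    rows: tuple[RankRow, ...]

    @property
    def passed(self) -> bool:
        return all(r.matches for r in self.rows)

    def failures(self) -> list[RankRow]:
        return [r for r in self.rows if not r.matches]


def _rerank(degrees: list[float], factors: list[str]) -> tuple[int, ...]:
    table = rank_factors(dict(zip(factors, degrees)))
    return tuple(table.ranks[f] for f in factors)


def verify_rank_consistency() -> RankReport:
    """Re-rank every published degree row and compare with the published ranks.

    Covers all five model rows in each of the three period tables plus the
    eight per-region Deng rows (23 rows in total).
    """
    tables = load_published_tables()
    factors = tables["factors"]
    rows = []
    for period, models in tables["periods"].items():
        for model_name, entry in models.items():
            rows.append(
                RankRow(
                    label=f"{period}/{model_name}",
                    published=tuple(entry["ranks"]),
                    recomputed=_rerank(entry["degrees"], factors),
                )
            )
    for region, entry in tables["regions"].items():
        rows.append(
            RankRow(
                label=f"regions/{region}",
                published=tuple(entry["ranks"]),
                recomputed=_rerank(entry["degrees"], factors),
            )
        )
    return RankReport(rows=tuple(rows))


@dataclass(frozen=True)
class RecomputeReport:
    """Side-by-side comparison of recomputed vs published degrees.

    Informational only: the published degrees were computed from sequences
    whose construction is not recoverable from the region-level panel, so
    differences here are expected and never asserted.
    """

    period: Period
    epsilon: float
    theta: float
    factors: tuple[str, ...]
    recomputed_degrees: dict[str, dict[str, float]] = field(default_factory=dict)
    recomputed_ranks: dict[str, dict[str, int]] = field(default_factory=dict)
    published_degrees: dict[str, dict[str, float]] = field(default_factory=dict)
    published_ranks: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def degree_diffs(self) -> dict[str, dict[str, float]]:
        return {
            model: {
                f: abs(self.recomputed_degrees[model][f] - pub[f])
                for f in self.factors
            }
            for model, pub in self.published_degrees.items()
        }

    @property
    def rank_agreement(self) -> dict[str, float]:
        """Fraction of factors with identical rank, per model."""
        out = {}
        for model, pub in self.published_ranks.items():
            rec = self.recomputed_ranks[model]
            out[model] = sum(rec[f] == pub[f] for f in self.factors) / len(
                self.factors
            )
        return out

    @property
    def kendall_tau(self) -> dict[str, float]:
        """Kendall's tau between recomputed and published rank vectors."""
        from scipy.stats import kendalltau

        out = {}
        for model, pub in self.published_ranks.items():
            rec = self.recomputed_ranks[model]
            tau = kendalltau(
                [rec[f] for f in self.factors], [pub[f] for f in self.factors]
            ).statistic
            out[model] = float(tau)
        return out


def exploratory_recompute(
    period: Period = Period.POOLED_2013_2015,
    epsilon: float = DEFAULT_EPSILON,
    theta: float = DEFAULT_THETA,
) -> RecomputeReport:
    """Run all five models on the bundled regional panel and compare.

    The observation axis is the eight regions — the only panel published at
    full precision. The report juxtaposes recomputed degrees/ranks with the
    published period table and summarizes rank agreement; it asserts
    nothing (see class docstring).
    """
    panel = load_fixture(period)
    tables = load_published_tables()
    published = tables["periods"][period.value]
    factors = tuple(tables["factors"])

    recomputed_degrees: dict[str, dict[str, float]] = {}
    recomputed_ranks: dict[str, dict[str, int]] = {}
    for table in compute_all(panel, epsilon=epsilon, theta=theta):
        recomputed_degrees[table.model.value] = dict(table.degrees)
        recomputed_ranks[table.model.value] = dict(table.ranks)

    published_degrees = {
        model: dict(zip(factors, entry["degrees"]))
        for model, entry in published.items()
    }
    published_ranks = {
        model: dict(zip(factors, entry["ranks"]))
        for model, entry in published.items()
    }
    return RecomputeReport(
        period=period,
        epsilon=epsilon,
        theta=theta,
        factors=factors,
        recomputed_degrees=recomputed_degrees,
        recomputed_ranks=recomputed_ranks,
        published_degrees=published_degrees,
        published_ranks=published_ranks,
    )
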