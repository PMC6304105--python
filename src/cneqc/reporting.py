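"""Machine-readable run reports.

Percentages are rounded half-away-from-zero to one decimal (the convention
used when quoting recovery rates like "94.7%"); the raw rationals are
always emitted alongside.  Every report embeds the full effective
configuration and a hash of it for provenance, and validates against the
published schema (``schemas/report.schema.json``, exported from
:class:`ReportEnvelope`).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any

from pydantic import BaseModel, Field

__all__ = [
    "round_half_away",
    "percent",
    "ratio",
    "ReportEnvelope",
    "config_hash",
    "make_report",
    "write_report",
]

TOOL_NAME = "cneqc"


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (so 94.65 -> 94.7, -0.25 -> -0.3 at one
    decimal), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def percent(numerator: int | float, denominator: int | float, ndigits: int = 1) -> dict[str, Any]:
    """A percentage with its raw rational: {numerator, denominator, raw,
    percent} where ``percent`` is rounded half-away-from-zero."""
    if denominator == 0:
        raise ValueError("percentage with zero denominator")
    raw = numerator / denominator
    return {
        "numerator": numerator,
        "denominator": denominator,
        "raw": raw,
        "percent": round_half_away(100 * raw, ndigits),
    }


def ratio(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """A plain ratio rounded half-away-from-zero to ``ndigits``."""
    if denominator == 0:
        raise ValueError("ratio with zero denominator")
    return round_half_away(numerator / denominator, ndigits)


class ReportEnvelope(BaseModel):
    """Envelope common to every subcommand report."""

    tool: str = TOOL_NAME
    version: str
    subcommand: str
    timestamp: str
    config: dict[str, Any] = Field(default_factory=dict)
    config_sha256: str
    summary: dict[str, Any] = Field(default_factory=dict)


def config_hash(config: dict[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def make_report(subcommand: str, config: dict[str, Any], summary: dict[str, Any]) -> ReportEnvelope:
    from . import __version__

    return ReportEnvelope(
        version=__version__,
        subcommand=subcommand,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        config=config,
        config_sha256=config_hash(config),
        summary=summary,
    )


def write_report(path: str | Path, subcommand: str, config: dict[str, Any], summary: dict[str, Any]) -> ReportEnvelope:
    report = make_report(subcommand, config, summary)
    Path(path).write_text(report.model_dump_json(indent=2) + "\n")
    return report


def export_schema(path: str | Path) -> None:
    """Write the JSON schema the reports validate against."""
    Path(path).write_text(json.dumps(ReportEnvelope.model_json_schema(), indent=2) + "\n")
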