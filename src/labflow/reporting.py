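"""Short and long audit reports over an experiment.

The *short* report lists every executed activity of an experiment — one row
per execution, in time order — with when it ran and who ran it.  The *long*
report additionally details every attribute value and every consumed and
produced artifact.  File-typed values are always rendered as path plus
checksum, never raw bytes.  Reports export as plain text, RFC-4180 CSV, or
Markdown.
"""

from __future__ import annotations

import csv
import datetime as dt
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Sequence, Union

from .engine import Artifact, ExperimentRef, Lims
from .value_validation import FileRef, TypedValue

__all__ = ["ReportRow", "short_report", "long_report", "export_report", "render_value"]


def _iso(t: dt.datetime) -> str:
    return t.astimezone(dt.timezone.utc).isoformat().replace("+00:00", "Z")


def render_value(v: TypedValue) -> str:
    """Human-readable rendering; files show identity (path + checksum)."""
    if isinstance(v, FileRef):
        return f"{v.path} (sha256={v.sha256})"
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, dt.date):
        return v.isoformat()
    return str(v)


def _artifact_summary(art: Artifact, with_values: bool = True) -> str:
    if with_values and art.values:
        inner = ", ".join(f"{k}={render_value(v)}" for k, v in art.values.items())
        return f"{art.artifact_type}:{art.id}{{{inner}}}"
    return f"{art.artifact_type}:{art.id}"


@dataclass
class ReportRow:
    """One executed activity; detail fields are filled in the long form only."""

    sample_label: str
    activity: str
    repetition_index: int
    executed_at: str
    executed_by: str
    execution_id: str
    values: dict[str, str] = field(default_factory=dict)
    consumed: list[str] = field(default_factory=list)
    produced: list[str] = field(default_factory=list)


def _rows(lims: Lims, experiment: ExperimentRef, detailed: bool) -> list[ReportRow]:
    exp = lims._experiment(experiment)
    rows: list[ReportRow] = []
    for ex in lims.experiment_executions(exp):  # already (executed_at, id)-ordered
        trace = lims.traces[ex.trace_id]
        act = exp.workflow.activities[ex.activity_id]
        row = ReportRow(
            sample_label=trace.sample_label,
            activity=act.name or act.id,
            repetition_index=ex.repetition_index,
            executed_at=_iso(ex.executed_at),
            executed_by=ex.executed_by,
            execution_id=ex.id,
        )
        if detailed:
            row.values = {k: render_value(v) for k, v in ex.values.items()}
            row.consumed = [_artifact_summary(lims.artifacts[a]) for a in ex.consumed_artifacts]
            row.produced = [_artifact_summary(lims.artifacts[a]) for a in ex.produced_artifacts]
        rows.append(row)
    return rows


def short_report(lims: Lims, experiment: ExperimentRef) -> list[ReportRow]:
    """One row per execution, time-ordered; no attribute values."""
    return _rows(lims, experiment, detailed=False)


def long_report(lims: Lims, experiment: ExperimentRef) -> list[ReportRow]:
    """As :func:`short_report`, plus attribute values and artifact listings."""
    return _rows(lims, experiment, detailed=True)


SHORT_COLUMNS = ["sample", "activity", "repetition", "executed_at", "executed_by"]
LONG_COLUMNS = SHORT_COLUMNS + ["values", "consumed", "produced"]


def _cells(row: ReportRow, detailed: bool) -> list[str]:
    cells = [
        row.sample_label,
        row.activity,
        str(row.repetition_index),
        row.executed_at,
        row.executed_by,
    ]
    if detailed:
        cells.append("; ".join(f"{k}={v}" for k, v in row.values.items()))
        cells.append("; ".join(row.consumed))
        cells.append("; ".join(row.produced))
    return cells


def export_report(
    rows: Sequence[ReportRow],
    format: str = "text",
    sink: Union[str, Path, BinaryIO, None] = None,
) -> bytes:
    """Render report rows to ``text``, ``csv`` (RFC 4180) or ``markdown``.

    Returns the rendered bytes; if ``sink`` is a path or binary file object
    the bytes are also written there.  An unknown format is a usage error.
    """
    detailed = any(r.values or r.consumed or r.produced for r in rows)
    columns = LONG_COLUMNS if detailed else SHORT_COLUMNS
    table = [_cells(r, detailed) for r in rows]

    if format == "csv":
        buf = io.StringIO(newline="")
        writer = csv.writer(buf, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
        writer.writerow(columns)
        writer.writerows(table)
        data = buf.getvalue().encode("utf-8")
    elif format == "markdown":
        def esc(cell: str) -> str:
            return cell.replace("|", "\\|")

        lines = [
            "| " + " | ".join(columns) + " |",
            "| " + " | ".join("---" for _ in columns) + " |",
        ]
        lines += ["| " + " | ".join(esc(c) for c in row) + " |" for row in table]
        data = ("\n".join(lines) + "\n").encode("utf-8")
    elif format == "text":
        widths = [
            max(len(col), *(len(row[i]) for row in table)) if table else len(col)
            for i, col in enumerate(columns)
        ]
        def fmt(cells: Sequence[str]) -> str:
            return "  ".join(c.ljust(w) for c, w in zip(cells, widths)).rstrip()

        lines = [fmt(columns), fmt(["-" * w for w in widths])]
        lines += [fmt(row) for row in table]
        data = ("\n".join(lines) + "\n").encode("utf-8")
    else:
        raise ValueError(f"unknown report format {format!r} (use text, csv or markdown)")

    if sink is not None:
        if isinstance(sink, (str, Path)):
            Path(sink).write_bytes(data)
        else:
            sink.write(data)
    return data
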