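"""Campaign record files and run logging.

Records are plain CSV with a fixed header::

    entry,mixer,equiv,tfoh_mol_pct,temp_c,conc_m,flow_ml_min,residence_min,yield_pct,note

``residence_min`` and ``note`` are optional columns.  Mixer labels are
stored as ASCII (``comet_x``, ``beta_type``, ``t_shaped``) to keep CSV
round-trips encoding-safe; display names carry the proper typography.
Yields are NMR yields in percent; an isolated yield printed alongside
(e.g. "96 (93)") belongs in ``note``, not in the data column.  A missing
yield marks a proposed-but-not-yet-run condition and is only accepted when
explicitly allowed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

from .param_space import Condition, ParameterSpace, ValidationError

__all__ = ["ExperimentRecord", "read_records", "write_records", "configure_logging"]

#: canonical record columns (condition columns in space declaration order)
CONDITION_COLUMNS = ("mixer", "equiv", "tfoh_mol_pct", "temp_c", "conc_m", "flow_ml_min")
REQUIRED_COLUMNS = ("entry",) + CONDITION_COLUMNS + ("yield_pct",)
OPTIONAL_COLUMNS = ("residence_min", "note")


@dataclass(frozen=True)
class ExperimentRecord:
    """One flow experiment: a condition plus its observed NMR yield."""

    entry: int
    condition: Condition
    residence_min: float | None = None
    yield_pct: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.entry < 1:
            raise ValidationError(f"entry must be ≥ 1, got {self.entry}")
        if self.yield_pct is not None and not 0.0 <= self.yield_pct <= 100.0:
            raise ValidationError(
                f"entry {self.entry}: yield {self.yield_pct} outside [0, 100]"
            )


def _parse_float(text: str, column: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValidationError(
            f"line {lineno}: unparseable number {text!r} in column {column!r}"
        ) from None


def read_records(
    source,
    space: ParameterSpace | None = None,
    allow_pending: bool = False,
    ignore_columns: tuple[str, ...] = (),
) -> list[ExperimentRecord]:
    """Read and validate a campaign CSV.

    When ``space`` is given each row's condition is validated against it
    (bounds and mixer labels).  Errors carry the offending line number.
    ``ignore_columns`` tolerates known extra columns (a proposal file adds
    ``acq_value`` and ``round``) without parsing them.
    """
    if hasattr(source, "read"):
        rows = list(csv.DictReader(source))
    else:
        with open(source, "r", encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh))
    if not rows:
        raise ValidationError("records file is empty")
    header = set(rows[0].keys())
    unknown = (header - set(REQUIRED_COLUMNS) - set(OPTIONAL_COLUMNS)
               - set(ignore_columns))
    if unknown:
        raise ValidationError(f"unknown column(s) {sorted(unknown)}")
    missing = set(REQUIRED_COLUMNS) - header
    if missing:
        raise ValidationError(f"missing column(s) {sorted(missing)}")

    records: list[ExperimentRecord] = []
    seen_entries: set[int] = set()
    for i, row in enumerate(rows):
        lineno = i + 2  # header is line 1
        try:
            entry = int(row["entry"])
        except ValueError:
            raise ValidationError(
                f"line {lineno}: unparseable entry {row['entry']!r}"
            ) from None
        if entry in seen_entries:
            raise ValidationError(f"line {lineno}: duplicate entry {entry}")
        seen_entries.add(entry)

        assignments: dict[str, object] = {"mixer": row["mixer"]}
        for col in CONDITION_COLUMNS[1:]:
            assignments[col] = _parse_float(row[col], col, lineno)
        condition = Condition(assignments)

        yield_text = (row.get("yield_pct") or "").strip()
        if yield_text == "":
            if not allow_pending:
                raise ValidationError(
                    f"line {lineno}: missing yield (pending rows not allowed here)"
                )
            yield_pct = None
        else:
            yield_pct = _parse_float(yield_text, "yield_pct", lineno)

        residence_text = (row.get("residence_min") or "").strip()
        residence = (
            _parse_float(residence_text, "residence_min", lineno)
            if residence_text
            else None
        )
        try:
            record = ExperimentRecord(
                entry=entry,
                condition=condition,
                residence_min=residence,
                yield_pct=yield_pct,
                note=(row.get("note") or "").strip(),
            )
            if space is not None:
                space.validate(condition)
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from None
        records.append(record)
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_records(records, path_or_buf) -> None:
    """Write records with the canonical header; lossless round-trip."""
    columns = ("entry",) + CONDITION_COLUMNS + OPTIONAL_COLUMNS[:1] + ("yield_pct", "note")

    def _write(fh) -> None:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for r in records:
            writer.writerow(
                [
                    r.entry,
                    r.condition["mixer"],
                    *[_fmt(r.condition[c]) for c in CONDITION_COLUMNS[1:]],
                    _fmt(r.residence_min),
                    _fmt(r.yield_pct),
                    r.note,
                ]
            )

    if hasattr(path_or_buf, "write"):
        _write(path_or_buf)
    else:
        with open(path_or_buf, "w", encoding="utf-8", newline="") as fh:
            _write(fh)


def configure_logging(logfile=None, level=logging.INFO) -> None:
    """Route package logs (fit summaries, proposals, seeds) to stderr and
    optionally a plain-text run log."""
    root = logging.getLogger("flowbo")
    root.setLevel(level)
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    handler = logging.StreamHandler()
    handler.setFormatter(fmt)
    root.addHandler(handler)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        root.addHandler(fh)
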