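"""Mascot Generic Format (MGF) peak-list reading, writing and counting.

The number of well-formed ``BEGIN IONS``/``END IONS`` blocks in the deposited
peak lists is the authoritative count of *submitted* MS2 spectra — the
denominator of the bulk identification rate. Counting is streaming and never
materialises peak arrays.

Dialect notes (tolerant reading of converter output):

* ``CHARGE`` accepted as ``2+``, ``+2`` or ``2``.
* ``PEPMASS`` accepted as one or two whitespace-separated numbers; the second
  is the precursor intensity and is discarded with a log note.
* Blank lines and ``#`` comments outside blocks are ignored; inside blocks
  they are ignored with a warning.
* A block with zero peak lines still counts as one submitted spectrum: the
  denominator is acquisition events, not usable spectra.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrumRecord",
    "PeakListSummary",
    "MgfFormatError",
    "count_ms2_spectra",
    "read_mgf",
    "write_mgf",
    "summarize_peaklist",
]


class MgfFormatError(ValueError):
    """Malformed MGF input; carries the offending 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)
        self.line_number = line_number


@dataclass
class SpectrumRecord:
    """One MS2 scan read from an MGF block.

    ``ordinal`` is the 0-based position of the block within its file; it is
    unique and contiguous by construction. ``extra_params`` preserves header
    keys the reader does not interpret (e.g. ``SCANS``).
    """

    run_id: str
    ordinal: int
    title: str | None = None
    precursor_mz: float | None = None
    charge: int | None = None
    rt_seconds: float | None = None
    mz: list[float] = field(default_factory=list)
    intensity: list[float] = field(default_factory=list)
    extra_params: dict[str, str] = field(default_factory=dict)

    @property
    def spectrum_key(self) -> str:
        """Identity key for joining to identifications.

        TITLE when present, else ``index=<ordinal>`` — mirroring the
        mzIdentML ``spectrumID`` convention for title-less peak lists.
        """
        return self.title if self.title else f"index={self.ordinal}"

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz, self.intensity))


@dataclass
class PeakListSummary:
    """Per-run tally of submitted MS2 spectra."""

    run_id: str
    path: str
    n_ms2: int
    has_titles: bool


_CHARGE_RE = re.compile(r"^(?:(\d+)\+|\+(\d+)|(\d+))$")


def _parse_charge(token: str, line_number: int) -> int:
    m = _CHARGE_RE.match(token.strip())
    if not m:
        raise MgfFormatError(f"unrecognised CHARGE token {token!r}", line_number)
    return int(next(g for g in m.groups() if g is not None))


def _parse_pepmass(value: str, line_number: int) -> float:
    tokens = value.split()
    if not tokens:
        raise MgfFormatError("empty PEPMASS value", line_number)
    try:
        mz = float(tokens[0])
    except ValueError:
        raise MgfFormatError(f"non-numeric PEPMASS {tokens[0]!r}", line_number) from None
    if len(tokens) > 1:
        logger.debug(
            "PEPMASS carries precursor intensity %r (line %d); discarded",
            tokens[1], line_number,
        )
    return mz


def count_ms2_spectra(mgf_stream: IO[str]) -> int:
    """Count well-formed ``BEGIN IONS``/``END IONS`` blocks in a stream.

    Streaming: peaks are never materialised. An unterminated block raises
    :class:`MgfFormatError` naming the line of its ``BEGIN IONS``.
    """
    n = 0
    begin_line: int | None = None
    line_number = 0
    for line_number, line in enumerate(mgf_stream, start=1):
        stripped = line.strip()
        if stripped == "BEGIN IONS":
            if begin_line is not None:
                raise MgfFormatError(
                    "BEGIN IONS inside an unterminated block opened", begin_line
                )
            begin_line = line_number
        elif stripped == "END IONS":
            if begin_line is None:
                raise MgfFormatError("END IONS without matching BEGIN IONS", line_number)
            begin_line = None
            n += 1
    if begin_line is not None:
        raise MgfFormatError("unterminated BEGIN IONS block opened", begin_line)
    return n


def read_mgf(mgf_stream: IO[str], run_id: str) -> Iterator[SpectrumRecord]:
    """Lazily yield :class:`SpectrumRecord` objects in file order.

    Ordinals are assigned by block position. TITLE, PEPMASS, CHARGE and
    RTINSECONDS are interpreted; other ``KEY=VALUE`` headers are preserved in
    ``extra_params``.
    """
    record: SpectrumRecord | None = None
    begin_line: int | None = None
    ordinal = 0
    line_number = 0
    for line_number, line in enumerate(mgf_stream, start=1):
        stripped = line.strip()
        if record is None:
            if stripped == "BEGIN IONS":
                record = SpectrumRecord(run_id=run_id, ordinal=ordinal)
                begin_line = line_number
            elif stripped == "END IONS":
                raise MgfFormatError("END IONS without matching BEGIN IONS", line_number)
            elif not stripped or stripped.startswith("#"):
                continue
            else:
                logger.warning(
                    "ignoring unexpected line outside MGF block (line %d): %r",
                    line_number, stripped,
                )
            continue
        # inside a block
        if stripped == "END IONS":
            yield record
            record = None
            begin_line = None
            ordinal += 1
        elif stripped == "BEGIN IONS":
            raise MgfFormatError("BEGIN IONS inside an unterminated block opened", begin_line)
        elif not stripped or stripped.startswith("#"):
            logger.warning("ignoring blank/comment line inside MGF block (line %d)", line_number)
        elif "=" in stripped and not stripped[0].isdigit():
            key, _, value = stripped.partition("=")
            key = key.strip().upper()
            value = value.strip()
            if key == "TITLE":
                record.title = value
            elif key == "PEPMASS":
                record.precursor_mz = _parse_pepmass(value, line_number)
            elif key == "CHARGE":
                record.charge = _parse_charge(value, line_number)
            elif key == "RTINSECONDS":
                try:
                    record.rt_seconds = float(value)
                except ValueError:
                    raise MgfFormatError(
                        f"non-numeric RTINSECONDS {value!r}", line_number
                    ) from None
            else:
                record.extra_params[key] = value
        else:
            tokens = stripped.split()
            try:
                mz = float(tokens[0])
                inten = float(tokens[1]) if len(tokens) > 1 else 0.0
            except (ValueError, IndexError):
                raise MgfFormatError(
                    f"unparseable peak line {stripped!r}", line_number
                ) from None
            record.mz.append(mz)
            record.intensity.append(inten)
    if record is not None:
        raise MgfFormatError("unterminated BEGIN IONS block opened", begin_line)


def _fmt(x: float) -> str:
    """Format a number at 6 significant digits without exponent clutter."""
    return f"{x:.6g}"


def write_mgf(records: Iterable[SpectrumRecord], out_stream: IO[str]) -> int:
    """Write records as MGF blocks; returns the number written."""
    n = 0
    for rec in records:
        out_stream.write("BEGIN IONS\n")
        if rec.title is not None:
            out_stream.write(f"TITLE={rec.title}\n")
        if rec.precursor_mz is not None:
            out_stream.write(f"PEPMASS={_fmt(rec.precursor_mz)}\n")
        if rec.charge is not None:
            out_stream.write(f"CHARGE={rec.charge}+\n")
        if rec.rt_seconds is not None:
            out_stream.write(f"RTINSECONDS={_fmt(rec.rt_seconds)}\n")
        for key, value in rec.extra_params.items():
            out_stream.write(f"{key}={value}\n")
        for mz, inten in zip(rec.mz, rec.intensity):
            out_stream.write(f"{_fmt(mz)} {_fmt(inten)}\n")
        out_stream.write("END IONS\n\n")
        n += 1
    return n


def summarize_peaklist(path: str | Path, run_id: str | None = None) -> PeakListSummary:
    """Count submitted spectra in an MGF file and note whether titles exist."""
    path = Path(path)
    rid = run_id if run_id is not None else path.stem
    n = 0
    has_titles = False
    begin_line: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for line_number, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped == "BEGIN IONS":
                if begin_line is not None:
                    raise MgfFormatError(
                        "BEGIN IONS inside an unterminated block opened", begin_line
                    )
                begin_line = line_number
            elif stripped == "END IONS":
                if begin_line is None:
                    raise MgfFormatError(
                        "END IONS without matching BEGIN IONS", line_number
                    )
                begin_line = None
                n += 1
            elif begin_line is not None and stripped.upper().startswith("TITLE="):
                has_titles = True
    if begin_line is not None:
        raise MgfFormatError("unterminated BEGIN IONS block opened", begin_line)
    return PeakListSummary(run_id=rid, path=str(path), n_ms2=n, has_titles=has_titles)
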