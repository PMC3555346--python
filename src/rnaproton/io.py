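"""Readers and writers for assigned-shift tables and reports.

Supported inputs: NMR-STAR (2.1 and 3.1) atom-chemical-shift loops and a
simple tab-separated dialect.  Only the seven non-exchangeable protons the
model covers are retained from STAR files; other atoms are counted and
logged.  Writers emit bit-stable CSV (sorted keys, fixed decimals).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .model import ATOMS_BY_BASE, normalize_atom_name

logger = logging.getLogger(__name__)

__all__ = [
    "ShiftRecord",
    "ShiftTable",
    "read_nmrstar_shifts",
    "read_shift_tsv",
    "write_shift_tsv",
    "write_report_csv",
    "read_manifest",
    "write_manifest",
]

_MODEL_ATOMS = frozenset({"H2", "H8", "H5", "H6", "H1'", "H2'", "H3'"})


@dataclass(frozen=True)
class ShiftRecord:
    """One assigned chemical shift."""

    residue: int
    base: str
    atom: str
    shift: float  # ppm
    ambiguity: int | None = None


@dataclass
class ShiftTable:
    """Assigned shifts of one deposition, unique per (residue, atom)."""

    deposition_id: str
    records: list[ShiftRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for rec in self.records:
            if not math.isfinite(rec.shift):
                raise ValueError(
                    f"{self.deposition_id}: non-finite shift for "
                    f"residue {rec.residue} {rec.atom}"
                )
            k = (rec.residue, rec.atom)
            if k in seen:
                raise ValueError(
                    f"{self.deposition_id}: duplicate shift for residue "
                    f"{rec.residue} atom {rec.atom}"
                )
            seen.add(k)

    def __len__(self) -> int:
        return len(self.records)

    def renumbered(self, offset: int) -> "ShiftTable":
        """Shift residue numbering by ``offset`` (maps deposition numbering
        onto the annotation's 1-based contiguous numbering)."""
        return ShiftTable(
            self.deposition_id,
            [
                ShiftRecord(r.residue + offset, r.base, r.atom, r.shift, r.ambiguity)
                for r in self.records
            ],
        )


# ---------------------------------------------------------------------------
# NMR-STAR


def _star_tokens(text: str) -> Iterable[str]:
    """Tokenize a STAR file: whitespace-separated values, quoted strings,
    comments stripped.  Semicolon-delimited multiline values are skipped."""
    in_semicolon = False
    for line in text.splitlines():
        if line.startswith(";"):
            in_semicolon = not in_semicolon
            continue
        if in_semicolon:
            continue
        rest = line.strip()
        while rest:
            if rest.startswith("#"):
                break
            if rest[0] in "'\"":
                quote = rest[0]
                end = rest.find(quote, 1)
                if end < 0:
                    raise ValueError(f"unterminated quote in line {line!r}")
                yield rest[1:end]
                rest = rest[end + 1:].strip()
            else:
                parts = rest.split(None, 1)
                yield parts[0]
                rest = parts[1].strip() if len(parts) > 1 else ""


# Tag-name alternatives for the columns we need, NMR-STAR 3.1 and 2.1.
_SEQ_TAGS = ("_atom_chem_shift.seq_id", "_atom_chem_shift.comp_index_id",
             "_residue_seq_code")
_COMP_TAGS = ("_atom_chem_shift.comp_id", "_residue_label")
_ATOM_TAGS = ("_atom_chem_shift.atom_id", "_atom_name")
_VAL_TAGS = ("_atom_chem_shift.val", "_chem_shift_value")
_AMB_TAGS = ("_atom_chem_shift.ambiguity_code", "_chem_shift_ambiguity_code")


def _find_column(tags: list[str], wanted: tuple[str, ...]) -> int | None:
    lower = [t.lower() for t in tags]
    for w in wanted:
        if w in lower:
            return lower.index(w)
    return None


def read_nmrstar_shifts(source, deposition_id: str | None = None) -> ShiftTable:
    """Extract the ¹H shifts the model covers from an NMR-STAR file.

    Handles both 3.1 (``_Atom_chem_shift.*``) and 2.1 (``_Residue_seq_code``
    etc.) chemical-shift loops.  Atom-name variants (H1*, H1′) are
    normalized; atoms outside the model's seven protons are skipped with a
    logged count.  Raises if no chemical-shift loop is found.
    """
    if hasattr(source, "read"):
        text = source.read()
        name = deposition_id or "nmrstar"
    else:
        path = Path(source)
        text = path.read_text()
        name = deposition_id or path.stem

    tokens = list(_star_tokens(text))
    records: list[ShiftRecord] = []
    skipped = 0
    found_loop = False
    i = 0
    while i < len(tokens):
        if tokens[i].lower() != "loop_":
            i += 1
            continue
        i += 1
        tags: list[str] = []
        while i < len(tokens) and tokens[i].startswith("_"):
            tags.append(tokens[i])
            i += 1
        cols = {
            "seq": _find_column(tags, _SEQ_TAGS),
            "comp": _find_column(tags, _COMP_TAGS),
            "atom": _find_column(tags, _ATOM_TAGS),
            "val": _find_column(tags, _VAL_TAGS),
        }
        amb_col = _find_column(tags, _AMB_TAGS)
        data: list[str] = []
        while i < len(tokens) and tokens[i].lower() != "stop_":
            data.append(tokens[i])
            i += 1
        if any(v is None for v in cols.values()):
            continue  # not a chemical-shift loop
        found_loop = True
        width = len(tags)
        if len(data) % width:
            raise ValueError(f"{name}: ragged chemical-shift loop")
        for off in range(0, len(data), width):
            row = data[off:off + width]
            atom = normalize_atom_name(row[cols["atom"]])
            if atom not in _MODEL_ATOMS:
                skipped += 1
                continue
            base = row[cols["comp"]].strip().upper().replace("T", "U")
            if base not in ATOMS_BY_BASE or atom not in ATOMS_BY_BASE[base]:
                skipped += 1
                continue
            raw_val = row[cols["val"]]
            try:
                value = float(raw_val)
            except ValueError as exc:
                raise ValueError(
                    f"{name}: unparseable shift value {raw_val!r}"
                ) from exc
            amb = None
            if amb_col is not None and row[amb_col] not in (".", "?"):
                amb = int(row[amb_col])
            records.append(
                ShiftRecord(int(row[cols["seq"]]), base, atom, value, amb)
            )
    if not found_loop:
        raise ValueError(f"{name}: no atom-chemical-shift loop found")
    if skipped:
        logger.info("%s: skipped %d non-model atom rows", name, skipped)
    return ShiftTable(deposition_id=name, records=records)


# ---------------------------------------------------------------------------
# TSV dialect

_SHIFT_COLUMNS = ("residue", "base", "atom", "shift", "ambiguity")


def write_shift_tsv(table: ShiftTable, path) -> None:
    lines = ["\t".join(_SHIFT_COLUMNS)]
    for rec in sorted(table.records, key=lambda r: (r.residue, r.atom)):
        lines.append(
            "\t".join(
                [
                    str(rec.residue),
                    rec.base,
                    rec.atom,
                    f"{rec.shift:.4f}",
                    "." if rec.ambiguity is None else str(rec.ambiguity),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_shift_tsv(source, deposition_id: str | None = None) -> ShiftTable:
    if hasattr(source, "read"):
        text = source.read()
        name = deposition_id or "shifts"
    else:
        path = Path(source)
        text = path.read_text()
        name = deposition_id or path.stem.removesuffix(".shifts")
    rows = [ln.split("\t") for ln in text.splitlines() if ln.strip()]
    if not rows:
        raise ValueError(f"{name}: empty shift table")
    header = [h.strip() for h in rows[0]]
    missing = [c for c in _SHIFT_COLUMNS[:4] if c not in header]
    if missing:
        raise ValueError(f"{name}: missing columns {missing}")
    col = {c: header.index(c) for c in header}
    records = []
    for raw in rows[1:]:
        amb = None
        if "ambiguity" in col and raw[col["ambiguity"]].strip() != ".":
            amb = int(raw[col["ambiguity"]])
        records.append(
            ShiftRecord(
                residue=int(raw[col["residue"]]),
                base=raw[col["base"]].strip().upper().replace("T", "U"),
                atom=normalize_atom_name(raw[col["atom"]]),
                shift=float(raw[col["shift"]]),
                ambiguity=amb,
            )
        )
    return ShiftTable(deposition_id=name, records=records)


# ---------------------------------------------------------------------------
# Reports and manifests


def write_report_csv(rows: Sequence[dict], path, columns: Sequence[str]) -> None:
    """Write a report as CSV with a fixed column order and fixed decimal
    formatting, so identical inputs give byte-identical files."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for row in rows:
            out = []
            for c in columns:
                v = row.get(c, "")
                if isinstance(v, float):
                    out.append("" if math.isnan(v) else f"{v:.4f}")
                elif isinstance(v, bool):
                    out.append(str(int(v)))
                else:
                    out.append(str(v))
            writer.writerow(out)


def write_manifest(entries: Sequence[dict], path) -> None:
    """Write a corpus manifest: a YAML list of depositions, each with
    ``id``, ``annotations`` and ``shifts`` paths (relative to the manifest)."""
    Path(path).write_text(yaml.safe_dump(list(entries), sort_keys=False))


def read_manifest(path) -> list[dict]:
    path = Path(path)
    entries = yaml.safe_load(path.read_text())
    if not isinstance(entries, list):
        raise ValueError(f"{path}: manifest must be a list of depositions")
    for e in entries:
        for fld in ("id", "annotations", "shifts"):
            if fld not in e:
                raise ValueError(f"{path}: manifest entry missing {fld!r}")
    return entries
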