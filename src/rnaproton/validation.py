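"""Assignment validation against the triplet shift model.

A single deposition is re-referenced against model predictions (robust
trimmed-mean offset, so genuine outliers do not corrupt the estimate) and
every assigned shift is scored as z = (observed - offset - predicted) /
rms(atom group).  Assignments beyond the z threshold are flagged as
candidate misassignments, referencing errors, or sites of non-helical
structure / intermolecular contact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import ResidueAnnotation, derive_attributes
from .io import ShiftTable, write_report_csv
from .model import ATOMS_BY_BASE, AtomKey, CoefficientTable, predict_shift

logger = logging.getLogger(__name__)

__all__ = ["ValidationRow", "ValidationReport", "reference_offset", "validate_deposition"]


@dataclass
class ValidationRow:
    residue: int
    key: AtomKey
    observed: float
    predicted: float | None  # None: residue has no triplet context
    deviation: float | None  # observed - offset - predicted
    z: float | None
    flagged: bool


@dataclass
class ValidationReport:
    deposition_id: str
    estimated_offset: float
    z_threshold: float
    rows: list[ValidationRow]

    @property
    def n_flagged(self) -> int:
        return sum(r.flagged for r in self.rows)

    @property
    def n_predicted(self) -> int:
        return sum(r.predicted is not None for r in self.rows)

    def to_csv(self, path) -> None:
        records = [
            {
                "residue": r.residue,
                "base": r.key.base,
                "atom": r.key.atom,
                "observed": r.observed,
                "predicted": float("nan") if r.predicted is None else r.predicted,
                "deviation": float("nan") if r.deviation is None else r.deviation,
                "z": float("nan") if r.z is None else r.z,
                "flagged": r.flagged,
            }
            for r in self.rows
        ]
        write_report_csv(
            records,
            path,
            columns=(
                "residue", "base", "atom", "observed", "predicted",
                "deviation", "z", "flagged",
            ),
        )

    def summary(self) -> str:
        lines = [
            f"deposition {self.deposition_id}: {len(self.rows)} shifts, "
            f"{self.n_predicted} with predictions, "
            f"offset {self.estimated_offset:+.4f} ppm, "
            f"{self.n_flagged} flagged at |z| > {self.z_threshold:g}",
        ]
        for r in self.rows:
            if r.flagged:
                lines.append(
                    f"  residue {r.residue:4d} {r.key}: observed "
                    f"{r.observed:.3f}, predicted {r.predicted:.3f}, "
                    f"z = {r.z:+.1f}"
                )
        return "\n".join(lines)


def reference_offset(
    deviations: Sequence[float], trim_fraction: float = 0.10
) -> float:
    """Offset estimate: mean prediction error after discarding the largest
    ``trim_fraction`` of absolute deviations (keeps a few true outliers
    from dragging the reference correction; 0 gives the plain mean)."""
    if len(deviations) == 0:
        raise ValueError("no eligible shifts to estimate a reference offset")
    if not 0 <= trim_fraction < 1:
        raise ValueError("trim_fraction must be in [0, 1)")
    dev = np.asarray(deviations, dtype=float)
    n_drop = int(trim_fraction * len(dev))
    if n_drop:
        keep = np.argsort(np.abs(dev))[: len(dev) - n_drop]
        dev = dev[keep]
    return float(np.mean(dev))


def validate_deposition(
    shifts: ShiftTable,
    annots: Sequence[ResidueAnnotation],
    table: CoefficientTable,
    z_threshold: float = 3.0,
    trim_fraction: float = 0.10,
) -> ValidationReport:
    """Screen one deposition's assignments against the model.

    Shifts on residues without a triplet context are reported with no
    prediction (never silently dropped); eligible rows get deviation and
    z = deviation / rms(key) after subtraction of the estimated reference
    offset, and are flagged when |z| strictly exceeds the threshold.  Rows
    are sorted by |z| descending (no-prediction rows last).
    """
    raw: list[tuple] = []
    for rec in shifts.records:
        if not 1 <= rec.residue <= len(annots):
            raise ValueError(
                f"shift for residue {rec.residue} outside annotation range"
            )
        if rec.atom not in ATOMS_BY_BASE[rec.base]:
            raise ValueError(
                f"atom {rec.atom} is not legal for base {rec.base} "
                f"(residue {rec.residue})"
            )
        key = AtomKey(rec.base, rec.atom)
        attrs = derive_attributes(annots, rec.residue)
        if attrs is None or key not in table:
            raw.append((rec, key, None))
        else:
            raw.append((rec, key, predict_shift(key, attrs, table)))

    eligible = [(rec, key, pred) for rec, key, pred in raw if pred is not None]
    if not eligible:
        raise ValueError(
            f"{shifts.deposition_id}: no shifts with a triplet-context prediction"
        )
    offset = reference_offset(
        [rec.shift - pred for rec, _, pred in eligible], trim_fraction
    )

    rows: list[ValidationRow] = []
    for rec, key, pred in raw:
        if pred is None:
            rows.append(
                ValidationRow(rec.residue, key, rec.shift, None, None, None, False)
            )
            continue
        deviation = rec.shift - offset - pred
        rms = table[key].rms
        z = deviation / rms if rms > 0 else math.inf * np.sign(deviation or 1)
        rows.append(
            ValidationRow(
                rec.residue, key, rec.shift, pred, deviation, float(z),
                flagged=abs(z) > z_threshold,
            )
        )
    rows.sort(key=lambda r: (-abs(r.z) if r.z is not None else math.inf, r.residue))
    return ValidationReport(
        deposition_id=shifts.deposition_id,
        estimated_offset=offset,
        z_threshold=z_threshold,
        rows=rows,
    )
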