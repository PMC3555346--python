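"""Additive chemical-shift-increment model for RNA non-exchangeable protons.

The predicted shift of a proton on the central residue of a stacked
base-pair triplet is a base (constant) shift — the canonical uXu context —
plus the sum of per-attribute increments for whichever of the 15 binary
neighborhood attributes are present.  A packaged reference coefficient set,
fitted on curated BMRB depositions of A-form helical RNA, covers all 19
legal (nucleotide, atom) combinations; freshly fitted tables share the same
schema.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import (
    ATTRIBUTE_NAMES,
    ResidueAnnotation,
    TripletAttributes,
    derive_attributes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtomKey",
    "CoefficientRow",
    "CoefficientTable",
    "ATOMS_BY_BASE",
    "ALL_ATOM_KEYS",
    "load_packaged_table",
    "predict_shift",
    "predict_deposition",
]

#: Legal proton names per nucleotide: purines lack H5, pyrimidines lack
#: H2/H8, and A is the only base with an (aromatic) H2.
ATOMS_BY_BASE: Mapping[str, tuple[str, ...]] = {
    "A": ("H2", "H8", "H1'", "H2'", "H3'"),
    "G": ("H8", "H1'", "H2'", "H3'"),
    "C": ("H5", "H6", "H1'", "H2'", "H3'"),
    "U": ("H5", "H6", "H1'", "H2'", "H3'"),
}

_ATOM_ALIASES = {
    "H1*": "H1'", "H1′": "H1'", "H1`": "H1'",
    "H2*": "H2'", "H2′": "H2'", "H2`": "H2'",
    "H3*": "H3'", "H3′": "H3'", "H3`": "H3'",
}


def normalize_atom_name(name: str) -> str:
    """Map prime/star/unicode-prime spellings onto the canonical atom name."""
    name = name.strip().upper()
    return _ATOM_ALIASES.get(name, name)


@dataclass(frozen=True, order=True)
class AtomKey:
    """One of the 19 legal (nucleotide, proton) regression groups."""

    base: str
    atom: str

    def __post_init__(self) -> None:
        atom = normalize_atom_name(self.atom)
        object.__setattr__(self, "atom", atom)
        if self.base not in ATOMS_BY_BASE:
            raise ValueError(f"illegal base {self.base!r}")
        if atom not in ATOMS_BY_BASE[self.base]:
            raise ValueError(f"atom {atom!r} is not legal for base {self.base!r}")

    def __str__(self) -> str:  # e.g. "A-H2"
        return f"{self.base}-{self.atom}"


#: All 19 legal keys in table order (aromatic first, then ribose).
ALL_ATOM_KEYS: tuple[AtomKey, ...] = tuple(
    AtomKey(base, atom)
    for atom_group in (("H2", "H8"), ("H5", "H6"), ("H1'",), ("H2'",), ("H3'",))
    for base in "AGCU"
    for atom in atom_group
    if atom in ATOMS_BY_BASE[base]
)
assert len(ALL_ATOM_KEYS) == 19


@dataclass
class CoefficientRow:
    """Constant + 15 attribute increments (ppm) and fit statistics for one
    AtomKey.  A zero increment means the attribute was excluded by variable
    selection (or absent from the training design); zeros are stored
    explicitly so fitted and packaged tables share one schema."""

    key: AtomKey
    const: float
    contrib: dict[str, float]
    corr: float = float("nan")
    rms: float = float("nan")
    nobs: int = 0
    xcorr: float = float("nan")
    xrms: float = float("nan")
    ntrim: int = 0

    def __post_init__(self) -> None:
        missing = set(ATTRIBUTE_NAMES) - set(self.contrib)
        if missing:
            raise ValueError(f"{self.key}: missing contributions {sorted(missing)}")


@dataclass
class CoefficientTable:
    """Coefficient rows keyed by AtomKey, with a provenance label
    ("packaged" for the distributed reference set, "fitted" otherwise)."""

    rows: dict[AtomKey, CoefficientRow]
    provenance: str = "fitted"

    def __getitem__(self, key: AtomKey) -> CoefficientRow:
        return self.rows[key]

    def __contains__(self, key: AtomKey) -> bool:
        return key in self.rows

    def __len__(self) -> int:
        return len(self.rows)

    # --- CSV (de)serialization, mirroring the published table layout -----

    _CSV_ATTRS = (
        "pre_a", "pre_c", "pre_g", "pre_gu", "pre_ug",
        "suc_a", "suc_c", "suc_g", "suc_gu", "suc_ug",
        "5ter", "3ter", "3loop", "5loop", "GU",
    )
    _CSV_TO_FLAG = {
        "5ter": "ter5", "3ter": "ter3", "3loop": "loop3", "5loop": "loop5",
        "GU": "gu_central",
    }

    def to_csv(self, path) -> None:
        header = ["base", "atom", "const", *self._CSV_ATTRS,
                  "corr", "rms", "nobs", "xcorr", "xrms", "ntrim"]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            for key in sorted(self.rows, key=ALL_ATOM_KEYS.index):
                row = self.rows[key]
                rec = [key.base, key.atom, repr(row.const)]
                for col in self._CSV_ATTRS:
                    flag = self._CSV_TO_FLAG.get(col, col)
                    rec.append(repr(row.contrib[flag]))
                rec += [f"{row.corr:.4f}", f"{row.rms:.4f}", row.nobs,
                        f"{row.xcorr:.4f}", f"{row.xrms:.4f}", row.ntrim]
                writer.writerow(rec)

    @classmethod
    def from_csv(cls, source, provenance: str = "fitted") -> "CoefficientTable":
        if hasattr(source, "read"):
            reader = csv.DictReader(source)
        else:
            reader = csv.DictReader(Path(source).open())
        rows: dict[AtomKey, CoefficientRow] = {}
        for rec in reader:
            key = AtomKey(rec["base"].strip(), rec["atom"].strip())
            contrib = {
                cls._CSV_TO_FLAG.get(col, col): float(rec[col])
                for col in cls._CSV_ATTRS
            }
            rows[key] = CoefficientRow(
                key=key,
                const=float(rec["const"]),
                contrib=contrib,
                corr=float(rec["corr"]),
                rms=float(rec["rms"]),
                nobs=int(rec["nobs"]),
                xcorr=float(rec["xcorr"]),
                xrms=float(rec["xrms"]),
                ntrim=int(rec["ntrim"]),
            )
        table = cls(rows=rows, provenance=provenance)
        if provenance == "packaged" and len(rows) != len(ALL_ATOM_KEYS):
            raise ValueError("packaged table must cover all 19 atom keys")
        return table


def load_packaged_table() -> CoefficientTable:
    """Load the packaged reference coefficient set (all 19 atom keys,
    four-decimal ppm values)."""
    ref = resources.files("rnaproton").joinpath("data/coefficients.csv")
    with ref.open() as fh:
        return CoefficientTable.from_csv(fh, provenance="packaged")


def predict_shift(
    key: AtomKey, attrs: TripletAttributes, table: CoefficientTable
) -> float:
    """Predicted shift (ppm, downfield positive): constant plus the
    increment of every attribute present."""
    if attrs.central_base != key.base:
        raise ValueError(
            f"attribute central base {attrs.central_base} != key base {key.base}"
        )
    if key not in table:
        raise KeyError(f"no coefficients for {key}")
    row = table[key]
    return row.const + sum(row.contrib[flag] for flag in attrs.flags)


def predict_deposition(
    annots: Sequence[ResidueAnnotation], table: CoefficientTable
) -> list[tuple[int, AtomKey, float]]:
    """Predict every legal proton of every eligible residue.

    Residues without a derivable triplet context are omitted (a reason is
    logged at DEBUG level); output is sorted by residue then atom order.
    """
    out: list[tuple[int, AtomKey, float]] = []
    for a in annots:
        attrs = derive_attributes(annots, a.index)
        if attrs is None:
            logger.debug(
                "residue %d (%s): no stacked triplet context, skipped",
                a.index, a.base,
            )
            continue
        for atom in ATOMS_BY_BASE[a.base]:
            key = AtomKey(a.base, atom)
            if key in table:
                out.append((a.index, key, predict_shift(key, attrs, table)))
    return out
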