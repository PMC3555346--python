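"""Secondary-structure annotation and base-pair-triplet attribute encoding.

An A-form helix is described residue by residue: base identity, pairing
partner, pair class (Watson-Crick, G:U wobble, or unpaired), and flags for
loop membership and long-range contacts.  From three consecutive stacked
base pairs the 15 binary neighborhood attributes of the additive shift
model are derived for the central residue.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ATTRIBUTE_NAMES",
    "ResidueAnnotation",
    "TripletAttributes",
    "parse_pairing",
    "parse_annotation_table",
    "write_annotation_table",
    "derive_attributes",
]

#: The 15 binary context variables of the additive model, in canonical order.
ATTRIBUTE_NAMES: tuple[str, ...] = (
    "pre_a", "pre_c", "pre_g", "pre_gu", "pre_ug",
    "suc_a", "suc_c", "suc_g", "suc_gu", "suc_ug",
    "ter5", "ter3", "loop3", "loop5", "gu_central",
)

_BASES = frozenset("ACGU")
_WC_PAIRS = {frozenset({"A", "U"}), frozenset({"G", "C"})}
_WOBBLE_PAIR = frozenset({"G", "U"})

# Bracket tiers for (pseudoknotted) dot-bracket notation.
_OPENERS = "([{<"
_CLOSERS = ")]}>"


@dataclass(frozen=True)
class ResidueAnnotation:
    """Per-residue secondary-structure annotation (1-based numbering).

    ``pair_class`` is ``"WC"`` for A:U / G:C, ``"wobble"`` for G:U, and
    ``"unpaired"`` otherwise; mismatched (non-WC, non-wobble) bracket pairs
    are recorded as unpaired with ``in_loop`` set.
    """

    index: int
    base: str
    partner: int | None = None
    pair_class: str = "unpaired"
    in_loop: bool = False
    long_range: bool = False
    terminal5: bool = False
    terminal3: bool = False

    def __post_init__(self) -> None:
        if self.base not in _BASES:
            raise ValueError(f"illegal base {self.base!r} at residue {self.index}")
        if self.pair_class not in ("WC", "wobble", "unpaired"):
            raise ValueError(f"unknown pair_class {self.pair_class!r}")
        if (self.partner is None) != (self.pair_class == "unpaired"):
            raise ValueError(
                f"residue {self.index}: partner must be present iff paired"
            )

    @property
    def paired(self) -> bool:
        return self.pair_class in ("WC", "wobble")


@dataclass(frozen=True)
class TripletAttributes:
    """The 15 binary attributes of an eligible central residue.

    The baseline (all flags clear) is the canonical uXu triplet: the central
    residue flanked by WC-paired uridines, with WC-paired i-2 and i+2
    neighbors.  pre_gu / pre_ug (and the suc_* counterparts) are *wobble*
    attributes that substitute for the identity attribute of the neighbor.
    """

    central_base: str
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.central_base not in _BASES:
            raise ValueError(f"illegal central base {self.central_base!r}")
        unknown = set(self.flags) - set(ATTRIBUTE_NAMES)
        if unknown:
            raise ValueError(f"unknown attribute flags {sorted(unknown)}")
        pre = self.flags & {"pre_a", "pre_c", "pre_g", "pre_gu", "pre_ug"}
        suc = self.flags & {"suc_a", "suc_c", "suc_g", "suc_gu", "suc_ug"}
        if len(pre) > 1 or len(suc) > 1:
            raise ValueError("at most one pre_* and one suc_* flag may be set")
        if {"ter5", "loop5"} <= self.flags or {"ter3", "loop3"} <= self.flags:
            raise ValueError("ter and loop flags on the same side are exclusive")
        if "gu_central" in self.flags and self.central_base not in ("G", "U"):
            raise ValueError("gu_central requires a G or U central base")

    def __contains__(self, flag: str) -> bool:
        return flag in self.flags


def _classify(base_i: str, base_j: str) -> str:
    combo = frozenset({base_i, base_j})
    if combo in _WC_PAIRS:
        return "WC"
    if combo == _WOBBLE_PAIR:
        return "wobble"
    return "unpaired"


def _normalize_sequence(sequence: str) -> str:
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - _BASES
    if bad:
        raise ValueError(f"illegal sequence characters {sorted(bad)}")
    return seq


def parse_pairing(dotbracket: str, sequence: str) -> list[ResidueAnnotation]:
    """Build per-residue annotations from dot-bracket notation.

    Pair class is assigned from the base combination: A:U and G:C are WC,
    G:U is a wobble; any other bracketed combination (a mismatched pair) is
    demoted to unpaired with ``in_loop`` set on both residues.  Pseudoknots
    may use the ``[]``, ``{}`` and ``<>`` tiers.
    """
    seq = _normalize_sequence(sequence)
    db = dotbracket.strip()
    if len(db) != len(seq):
        raise ValueError(
            f"structure length {len(db)} != sequence length {len(seq)}"
        )
    partner: dict[int, int] = {}
    stacks: list[list[int]] = [[] for _ in _OPENERS]
    for pos, ch in enumerate(db, start=1):
        if ch == ".":
            continue
        tier_open = _OPENERS.find(ch)
        tier_close = _CLOSERS.find(ch)
        if tier_open >= 0:
            stacks[tier_open].append(pos)
        elif tier_close >= 0:
            if not stacks[tier_close]:
                raise ValueError(f"unbalanced {ch!r} at position {pos}")
            opener = stacks[tier_close].pop()
            partner[opener] = pos
            partner[pos] = opener
        else:
            raise ValueError(f"illegal structure character {ch!r} at {pos}")
    for tier, stack in zip(_OPENERS, stacks):
        if stack:
            raise ValueError(f"unbalanced {tier!r} at position {stack[-1]}")

    n = len(seq)
    annots = []
    for i in range(1, n + 1):
        j = partner.get(i)
        if j is None:
            cls = "unpaired"
        else:
            cls = _classify(seq[i - 1], seq[j - 1])
        annots.append(
            ResidueAnnotation(
                index=i,
                base=seq[i - 1],
                partner=j if cls != "unpaired" else None,
                pair_class=cls,
                in_loop=cls == "unpaired",
                terminal5=i == 1,
                terminal3=i == n,
            )
        )
    return annots


_TABLE_COLUMNS = ("index", "base", "partner", "pair_class", "in_loop", "long_range")


def write_annotation_table(annots: Sequence[ResidueAnnotation], path) -> None:
    """Write annotations to the tab-separated annotation dialect."""
    lines = ["\t".join(_TABLE_COLUMNS)]
    for a in annots:
        lines.append(
            "\t".join(
                [
                    str(a.index),
                    a.base,
                    "." if a.partner is None else str(a.partner),
                    a.pair_class,
                    str(int(a.in_loop)),
                    str(int(a.long_range)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def parse_annotation_table(source) -> list[ResidueAnnotation]:
    """Read the annotation TSV dialect (columns: index, base, partner,
    pair_class, in_loop, long_range; partner "." when unpaired).

    Unlike dot-bracket input, the table can mark paired residues as
    ``in_loop`` (e.g. stacked but non-WC contexts) or ``long_range``.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    rows = [ln.split("\t") for ln in text.splitlines() if ln.strip()]
    if not rows:
        raise ValueError("empty annotation table")
    header = [h.strip() for h in rows[0]]
    missing = [c for c in _TABLE_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"annotation table missing columns {missing}")
    col = {name: header.index(name) for name in _TABLE_COLUMNS}
    annots = []
    for raw in rows[1:]:
        idx = int(raw[col["index"]])
        partner_field = raw[col["partner"]].strip()
        partner = None if partner_field == "." else int(partner_field)
        pair_class = raw[col["pair_class"]].strip()
        annots.append(
            ResidueAnnotation(
                index=idx,
                base=raw[col["base"]].strip().upper().replace("T", "U"),
                partner=partner,
                pair_class=pair_class,
                in_loop=bool(int(raw[col["in_loop"]])),
                long_range=bool(int(raw[col["long_range"]])),
            )
        )
    annots.sort(key=lambda a: a.index)
    expected = list(range(annots[0].index, annots[0].index + len(annots)))
    if [a.index for a in annots] != expected:
        raise ValueError("non-contiguous residue numbering in annotation table")
    if annots[0].index != 1:
        # renumber to 1-based contiguous, preserving partners
        off = annots[0].index - 1
        annots = [
            replace(
                a,
                index=a.index - off,
                partner=None if a.partner is None else a.partner - off,
            )
            for a in annots
        ]
    annots = [
        replace(a, terminal5=a.index == 1, terminal3=a.index == len(annots))
        for a in annots
    ]
    for a in annots:
        if a.partner is not None:
            if not 1 <= a.partner <= len(annots):
                raise ValueError(f"residue {a.index}: partner out of range")
            if annots[a.partner - 1].partner != a.index:
                raise ValueError(f"residue {a.index}: pairing not symmetric")
    return annots


def derive_attributes(
    annots: Sequence[ResidueAnnotation], i: int
) -> TripletAttributes | None:
    """Derive the 15-attribute encoding of residue ``i`` (1-based).

    Returns ``None`` ("ineligible") unless residues i-1, i, i+1 all exist,
    are all base-paired (WC or wobble), and their partners stack as a
    contiguous helix (partner(i-1) = partner(i)+1, partner(i+1) =
    partner(i)-1).

    Flag rules for the 5' side (the 3' side is symmetric):

    * identity of i-1 when not a WC-paired U: ``pre_a`` / ``pre_c`` /
      ``pre_g``; a G in a wobble sets ``pre_gu`` *instead of* ``pre_g``; a
      U in a wobble sets ``pre_ug`` (replacing the U baseline);
    * ``ter5`` when i-2 does not exist; ``loop5`` when i-2 exists but is in
      a loop, mismatched pair, or long-range contact; no flag when i-2 is
      WC/wobble paired.
    """
    n = len(annots)
    if not 1 <= i <= n:
        raise IndexError(f"residue index {i} out of range 1..{n}")
    if i - 2 < 0 or i >= n:
        return None
    prev, cen, nxt = annots[i - 2], annots[i - 1], annots[i]
    if not (prev.paired and cen.paired and nxt.paired):
        return None
    if prev.partner != cen.partner + 1 or nxt.partner != cen.partner - 1:
        return None

    flags: set[str] = set()

    def neighbor_flag(res: ResidueAnnotation, side: str) -> None:
        if res.pair_class == "wobble":
            flags.add(f"{side}_gu" if res.base == "G" else f"{side}_ug")
        elif res.base != "U":
            flags.add(f"{side}_{res.base.lower()}")

    neighbor_flag(prev, "pre")
    neighbor_flag(nxt, "suc")
    if cen.pair_class == "wobble":
        flags.add("gu_central")

    def context_flag(idx0: int, ter: str, loop: str) -> None:
        if idx0 < 0 or idx0 >= n:
            flags.add(ter)
        else:
            res = annots[idx0]
            if res.in_loop or res.long_range or not res.paired:
                flags.add(loop)

    context_flag(i - 3, "ter5", "loop5")
    context_flag(i + 1, "ter3", "loop3")
    return TripletAttributes(central_base=cen.base, flags=frozenset(flags))


def eligible_residues(annots: Sequence[ResidueAnnotation]) -> list[int]:
    """1-based indices of all residues with a derivable triplet context."""
    return [
        a.index for a in annots if derive_attributes(annots, a.index) is not None
    ]
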