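"""Synthetic annotated depositions with the statistical structure the
training pipeline assumes.

Each deposition is a random multi-hairpin secondary structure (stems of at
least three pairs, hairpin loops, single-stranded linkers, optional G:U
wobbles).  Attributes are always derived from the generated structure by
the real annotation module — never sampled directly — so the generator and
the annotator cannot drift apart.  Observed shifts are model predictions
from a generating coefficient table plus Gaussian noise, a per-deposition
reference offset, and sparse large-magnitude outliers; a truth sidecar
records the offsets and outlier positions for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import ResidueAnnotation, parse_pairing, write_annotation_table
from .io import ShiftRecord, ShiftTable, write_manifest, write_shift_tsv
from .model import ATOMS_BY_BASE, AtomKey, CoefficientTable, load_packaged_table, predict_deposition

__all__ = ["SimulationConfig", "DepositionTruth", "generate_deposition", "generate_corpus"]

_WC_CHOICES = (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"))
_WOBBLE_CHOICES = (("G", "U"), ("U", "G"))
_LOOP_BASES = "ACGU"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic corpus.

    Defaults emulate a curated helical-RNA shift corpus: about 300
    observations per atom group over 20 depositions, 0.05 ppm assignment
    noise, per-deposition referencing offsets of scale 0.03 ppm, and 1 %
    gross outliers displaced by 10 noise SDs.
    """

    n_depositions: int = 20
    n_stems: int = 4
    stem_min: int = 7
    stem_max: int = 11
    wobble_prob: float = 0.10
    loop_min: int = 3
    loop_max: int = 6
    linker_min: int = 1
    linker_max: int = 3
    noise_sigma: float = 0.05  # ppm
    offset_scale: float = 0.03  # ppm
    outlier_rate: float = 0.01
    outlier_magnitude: float = 10.0  # in units of noise_sigma
    seed: int = 0
    table: CoefficientTable | None = None  # generating model; packaged if None

    def __post_init__(self) -> None:
        for p in (self.wobble_prob, self.outlier_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.noise_sigma < 0 or self.offset_scale < 0:
            raise ValueError("noise and offset scales must be non-negative")
        if self.stem_min < 3:
            raise ValueError("stems must have at least 3 pairs to host a triplet")
        if self.n_stems < 1 or self.n_depositions < 1:
            raise ValueError("need at least one stem and one deposition")


@dataclass
class DepositionTruth:
    """What the generator knows: the injected offset and outlier positions."""

    deposition_id: str
    offset: float
    outliers: list[tuple[int, str]]  # (residue, atom)


def _random_structure(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[str, str]:
    """One multi-hairpin molecule as (sequence, dot-bracket).

    The molecule starts and ends in a stem so that terminal (ter5/ter3)
    triplet contexts occur; linkers and hairpin loops provide loop5/loop3
    contexts.
    """
    seq_parts: list[str] = []
    db_parts: list[str] = []
    for s in range(cfg.n_stems):
        L = int(rng.integers(cfg.stem_min, cfg.stem_max + 1))
        five, three = [], []
        for _ in range(L):
            if rng.random() < cfg.wobble_prob:
                a, b = _WOBBLE_CHOICES[rng.integers(2)]
            else:
                a, b = _WC_CHOICES[rng.integers(4)]
            five.append(a)
            three.append(b)
        loop_len = int(rng.integers(cfg.loop_min, cfg.loop_max + 1))
        loop = "".join(rng.choice(list(_LOOP_BASES), size=loop_len))
        seq_parts.append("".join(five) + loop + "".join(reversed(three)))
        db_parts.append("(" * L + "." * loop_len + ")" * L)
        if s < cfg.n_stems - 1:
            linker_len = int(rng.integers(cfg.linker_min, cfg.linker_max + 1))
            seq_parts.append("".join(rng.choice(list(_LOOP_BASES), size=linker_len)))
            db_parts.append("." * linker_len)
    return "".join(seq_parts), "".join(db_parts)


def generate_deposition(
    cfg: SimulationConfig, seed: int, deposition_id: str = "synth"
) -> tuple[list[ResidueAnnotation], ShiftTable, DepositionTruth]:
    """Generate one synthetic deposition, deterministic per seed."""
    rng = np.random.default_rng(seed)
    table = cfg.table if cfg.table is not None else load_packaged_table()

    for _ in range(50):
        seq, db = _random_structure(rng, cfg)
        annots = parse_pairing(db, seq)
        predictions = predict_deposition(annots, table)
        if predictions:
            break
    else:
        raise ValueError("configuration cannot yield any eligible triplet")

    offset = float(rng.normal(0.0, cfg.offset_scale)) if cfg.offset_scale else 0.0
    records: list[ShiftRecord] = []
    outliers: list[tuple[int, str]] = []
    for residue, key, pred in predictions:
        value = pred + offset
        if cfg.noise_sigma:
            value += float(rng.normal(0.0, cfg.noise_sigma))
        if cfg.outlier_rate and rng.random() < cfg.outlier_rate:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            value += sign * cfg.outlier_magnitude * cfg.noise_sigma
            outliers.append((residue, key.atom))
        records.append(ShiftRecord(residue, key.base, key.atom, float(value)))
    shifts = ShiftTable(deposition_id=deposition_id, records=records)
    truth = DepositionTruth(deposition_id=deposition_id, offset=offset, outliers=outliers)
    return annots, shifts, truth


def generate_corpus(cfg: SimulationConfig, out_dir) -> Path:
    """Write a corpus to disk in the formats the training CLI consumes.

    Produces ``<id>.annot.tsv`` and ``<id>.shifts.tsv`` per deposition, a
    ``manifest.yaml``, and a ``truth.json`` sidecar with the injected
    offsets and outlier positions.  Returns the manifest path; refuses to
    overwrite an existing manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.yaml"
    if manifest_path.exists():
        raise FileExistsError(f"{manifest_path} already exists")
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_depositions)
    entries, truths = [], []
    for d, dep_seed in enumerate(seeds):
        dep_id = f"synth{d:03d}"
        annots, shifts, truth = generate_deposition(
            cfg, seed=int(dep_seed), deposition_id=dep_id
        )
        annot_file = f"{dep_id}.annot.tsv"
        shift_file = f"{dep_id}.shifts.tsv"
        write_annotation_table(annots, out_dir / annot_file)
        write_shift_tsv(shifts, out_dir / shift_file)
        entries.append({"id": dep_id, "annotations": annot_file, "shifts": shift_file})
        truths.append(
            {
                "deposition_id": dep_id,
                "offset": truth.offset,
                "outliers": [list(o) for o in truth.outliers],
            }
        )
    write_manifest(entries, manifest_path)
    (out_dir / "truth.json").write_text(json.dumps(truths, indent=1))
    return manifest_path
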