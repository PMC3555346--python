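"""Shared fixtures and synthetic-group helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from rnaproton import (
    AtomKey,
    CoefficientRow,
    ShiftObservation,
    TripletAttributes,
    load_packaged_table,
)

PRE_OPTIONS = (None, "pre_a", "pre_c", "pre_g", "pre_gu", "pre_ug")
SUC_OPTIONS = (None, "suc_a", "suc_c", "suc_g", "suc_gu", "suc_ug")
FIVE_OPTIONS = (None, "ter5", "loop5")
THREE_OPTIONS = (None, "ter3", "loop3")


@pytest.fixture(scope="session")
def packaged_table():
    return load_packaged_table()


def random_attrs(base: str, rng: np.random.Generator) -> TripletAttributes:
    """A uniformly random legal attribute combination for ``base``."""
    flags = set()
    for options in (PRE_OPTIONS, SUC_OPTIONS, FIVE_OPTIONS, THREE_OPTIONS):
        pick = options[rng.integers(len(options))]
        if pick is not None:
            flags.add(pick)
    if base in "GU" and rng.random() < 0.3:
        flags.add("gu_central")
    return TripletAttributes(base, frozenset(flags))


def synth_group(
    key: AtomKey,
    n: int,
    sigma: float,
    rng: np.random.Generator,
    row: CoefficientRow,
    deposition: str = "dep",
) -> list[ShiftObservation]:
    """Observations drawn from a known generating coefficient row."""
    obs = []
    for i in range(n):
        attrs = random_attrs(key.base, rng)
        delta = row.const + sum(row.contrib[f] for f in attrs.flags)
        if sigma:
            delta += rng.normal(0.0, sigma)
        obs.append(ShiftObservation(deposition, i + 2, key, float(delta), attrs))
    return obs


def coefficient_errors(fitted, truth, keys=None) -> np.ndarray:
    """Absolute errors of constant + 15 contributions, pooled over keys."""
    from rnaproton import ATTRIBUTE_NAMES

    keys = keys if keys is not None else list(fitted.rows)
    errs = []
    for key in keys:
        f, t = fitted[key], truth[key]
        errs.append(abs(f.const - t.const))
        errs.extend(abs(f.contrib[a] - t.contrib[a]) for a in ATTRIBUTE_NAMES)
    return np.array(errs)


def build_corpus(cfg, tag="dep"):
    """In-memory synthetic corpus: (observations, truths)."""
    from rnaproton.simulate import generate_deposition
    from rnaproton.training import observations_from_deposition

    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_depositions)
    corpus, truths = [], []
    for d, s in enumerate(seeds):
        dep_id = f"{tag}{d:03d}"
        annots, shifts, truth = generate_deposition(cfg, int(s), dep_id)
        corpus.extend(observations_from_deposition(dep_id, annots, shifts))
        truths.append(truth)
    return corpus, truths
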