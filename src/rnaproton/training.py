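"""Fitting pipeline for the additive triplet shift model.

Per (nucleotide, atom) group: ordinary least squares over the 15 binary
neighborhood attributes with principled variable selection (greedy backward
elimination under BIC by default) that sets unsupported coefficients to
exactly zero; two-pass outlier trimming at three times the pass-1 rms;
two-pass automatic per-deposition re-referencing; and stratified k-fold
cross-validation for honest error estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .annotation import ATTRIBUTE_NAMES, ResidueAnnotation, TripletAttributes, derive_attributes
from .io import ShiftTable, read_manifest, read_nmrstar_shifts, read_shift_tsv
from .annotation import parse_annotation_table
from .model import AtomKey, CoefficientRow, CoefficientTable, predict_shift

logger = logging.getLogger(__name__)

__all__ = [
    "ShiftObservation",
    "FitReport",
    "observations_from_deposition",
    "load_corpus",
    "fit_atom_group",
    "fit_with_trimming",
    "rereference_and_fit",
    "cross_validate",
    "compute_group_means",
]


@dataclass(frozen=True)
class ShiftObservation:
    """One assigned shift with its derived attribute context."""

    deposition_id: str
    residue: int
    key: AtomKey
    shift: float  # ppm, observed
    attrs: TripletAttributes

    def __post_init__(self) -> None:
        if self.attrs.central_base != self.key.base:
            raise ValueError(
                f"{self.deposition_id} residue {self.residue}: attribute "
                f"base {self.attrs.central_base} != key base {self.key.base}"
            )


@dataclass
class FitReport:
    """Outcome of the full training pipeline."""

    table: CoefficientTable
    dropped_outliers: list[ShiftObservation]
    reference_offsets: dict[str, float]


def observations_from_deposition(
    deposition_id: str,
    annots: Sequence[ResidueAnnotation],
    shifts: ShiftTable,
    include_ambiguous: bool = False,
) -> list[ShiftObservation]:
    """Attach triplet attributes to each assigned shift of a deposition.

    Shifts on ineligible residues are skipped; ambiguous assignments
    (ambiguity code > 1) are excluded from training unless requested.
    """
    attrs_cache: dict[int, TripletAttributes | None] = {}
    out = []
    for rec in shifts.records:
        if not 1 <= rec.residue <= len(annots):
            raise ValueError(
                f"{deposition_id}: shift for residue {rec.residue} outside "
                f"annotation range 1..{len(annots)}"
            )
        annot = annots[rec.residue - 1]
        if rec.base != annot.base:
            raise ValueError(
                f"{deposition_id} residue {rec.residue}: shift-table base "
                f"{rec.base} != annotation base {annot.base}"
            )
        if rec.ambiguity is not None and rec.ambiguity > 1 and not include_ambiguous:
            continue
        if rec.residue not in attrs_cache:
            attrs_cache[rec.residue] = derive_attributes(annots, rec.residue)
        attrs = attrs_cache[rec.residue]
        if attrs is None:
            continue
        out.append(
            ShiftObservation(
                deposition_id=deposition_id,
                residue=rec.residue,
                key=AtomKey(rec.base, rec.atom),
                shift=rec.shift,
                attrs=attrs,
            )
        )
    return out


def load_corpus(manifest_path) -> list[ShiftObservation]:
    """Load every deposition listed in a YAML manifest into one
    observation list (paths resolved relative to the manifest)."""
    manifest_path = Path(manifest_path)
    corpus: list[ShiftObservation] = []
    for entry in read_manifest(manifest_path):
        base = manifest_path.parent
        annots = parse_annotation_table(base / entry["annotations"])
        shift_path = base / entry["shifts"]
        if shift_path.suffix.lower() in (".str", ".star"):
            shifts = read_nmrstar_shifts(shift_path, deposition_id=entry["id"])
        else:
            shifts = read_shift_tsv(shift_path, deposition_id=entry["id"])
        corpus.extend(observations_from_deposition(entry["id"], annots, shifts))
    return corpus


# ---------------------------------------------------------------------------
# Per-group regression with variable selection


def _design(obs: Sequence[ShiftObservation]) -> tuple[np.ndarray, np.ndarray]:
    X = np.zeros((len(obs), len(ATTRIBUTE_NAMES)))
    for r, o in enumerate(obs):
        for c, name in enumerate(ATTRIBUTE_NAMES):
            if name in o.attrs.flags:
                X[r, c] = 1.0
    y = np.array([o.shift for o in obs])
    return X, y


def _ols(X: np.ndarray, y: np.ndarray, cols: Sequence[int]) -> tuple[np.ndarray, float]:
    """Least squares with intercept on the selected columns; returns
    (coefficients over the full 15-slot vector with intercept last, RSS)."""
    A = np.column_stack([X[:, list(cols)], np.ones(len(y))])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    full = np.zeros(X.shape[1] + 1)
    for j, c in enumerate(cols):
        full[c] = beta[j]
    full[-1] = beta[-1]
    return full, float(resid @ resid)


def _bic(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood BIC; floor the variance to keep log finite on
    # (near-)perfect fits.
    sigma2 = max(rss / n, 1e-30)
    return n * np.log(sigma2) + k * np.log(n)


def _select_backward_bic(X: np.ndarray, y: np.ndarray, cols: list[int]) -> list[int]:
    """Greedy backward elimination: drop the regressor whose removal most
    improves BIC, until no single removal improves it."""
    cols = list(cols)
    _, rss = _ols(X, y, cols)
    best = _bic(rss, len(y), len(cols) + 1)
    improved = True
    while improved and cols:
        improved = False
        candidate_scores = []
        for c in cols:
            trial = [d for d in cols if d != c]
            _, rss_t = _ols(X, y, trial)
            candidate_scores.append((_bic(rss_t, len(y), len(trial) + 1), c))
        score, drop = min(candidate_scores)
        if score < best:
            best = score
            cols.remove(drop)
            improved = True
    return cols


def _select_lasso(X: np.ndarray, y: np.ndarray, cols: list[int]) -> list[int]:
    """L1-path selection: keep the support chosen by an information-criterion
    lasso, then refit by plain least squares."""
    from sklearn.linear_model import LassoLarsIC

    sub = X[:, cols]
    est = LassoLarsIC(criterion="bic")
    est.fit(sub, y)
    return [c for c, b in zip(cols, est.coef_) if abs(b) > 1e-12]


def fit_atom_group(
    obs: Sequence[ShiftObservation], method: str = "bic"
) -> CoefficientRow:
    """Fit one (nucleotide, atom) group.

    ``method``: "bic" (default; backward elimination), "ols" (no
    selection), or "lasso" (L1-path support, OLS refit).  Attributes absent
    from the design are unidentifiable and get coefficient exactly 0;
    selection may zero further columns.
    """
    obs = list(obs)
    if len(obs) < 2:
        raise ValueError("need at least 2 observations to fit a group")
    key = obs[0].key
    if any(o.key != key for o in obs):
        raise ValueError("fit_atom_group expects observations of a single key")
    X, y = _design(obs)
    supported = [c for c in range(X.shape[1]) if X[:, c].any()]
    unsupported = [ATTRIBUTE_NAMES[c] for c in range(X.shape[1]) if c not in supported]
    if unsupported:
        logger.debug("%s: unidentifiable attributes %s", key, unsupported)

    if np.ptp(y) == 0.0:
        coef = np.zeros(X.shape[1] + 1)
        coef[-1] = float(y[0]) if len(y) else 0.0
    else:
        if method == "ols":
            cols = supported
        elif method == "bic":
            cols = _select_backward_bic(X, y, supported)
        elif method == "lasso":
            cols = _select_lasso(X, y, supported)
        else:
            raise ValueError(f"unknown selection method {method!r}")
        coef, _ = _ols(X, y, cols)

    yhat = X @ coef[:-1] + coef[-1]
    resid = y - yhat
    rms = float(np.sqrt(np.mean(resid**2)))
    if np.std(yhat) > 0 and np.std(y) > 0:
        corr = float(np.corrcoef(y, yhat)[0, 1])
    else:
        corr = 0.0
    contrib = {name: float(coef[c]) for c, name in enumerate(ATTRIBUTE_NAMES)}
    return CoefficientRow(
        key=key,
        const=float(coef[-1]),
        contrib=contrib,
        corr=corr,
        rms=rms,
        nobs=len(obs),
    )


def _row_predict(row: CoefficientRow, attrs: TripletAttributes) -> float:
    return row.const + sum(row.contrib[f] for f in attrs.flags)


def fit_with_trimming(
    obs: Sequence[ShiftObservation],
    method: str = "bic",
    multiplier: float = 3.0,
) -> tuple[CoefficientRow, list[ShiftObservation]]:
    """Two-pass fit: pass 1 on all data, drop observations whose residual
    magnitude strictly exceeds ``multiplier`` times the pass-1 rms, pass 2
    on the trimmed set.  Exactly two passes; ties at the threshold are
    retained."""
    obs = list(obs)
    first = fit_atom_group(obs, method=method)
    threshold = multiplier * first.rms
    kept, dropped = [], []
    for o in obs:
        resid = abs(o.shift - _row_predict(first, o.attrs))
        (dropped if resid > threshold else kept).append(o)
    if not dropped:
        return first, []
    if len(kept) < 2:
        raise ValueError("trimming would leave fewer than 2 observations")
    second = fit_atom_group(kept, method=method)
    second.ntrim = len(dropped)
    return second, dropped


def _group_by_key(
    corpus: Iterable[ShiftObservation],
) -> dict[AtomKey, list[ShiftObservation]]:
    groups: dict[AtomKey, list[ShiftObservation]] = {}
    for o in corpus:
        groups.setdefault(o.key, []).append(o)
    return groups


def _full_analysis(
    corpus: Sequence[ShiftObservation], method: str, multiplier: float
) -> tuple[dict[AtomKey, CoefficientRow], list[ShiftObservation], list[ShiftObservation]]:
    rows: dict[AtomKey, CoefficientRow] = {}
    retained: list[ShiftObservation] = []
    dropped: list[ShiftObservation] = []
    for key, group in sorted(_group_by_key(corpus).items()):
        row, drops = fit_with_trimming(group, method=method, multiplier=multiplier)
        rows[key] = row
        drop_set = {id(o) for o in drops}
        retained.extend(o for o in group if id(o) not in drop_set)
        dropped.extend(drops)
    return rows, retained, dropped


def rereference_and_fit(
    corpus: Sequence[ShiftObservation],
    method: str = "bic",
    multiplier: float = 3.0,
    cv_folds: int | None = 10,
    seed: int = 0,
    reference: CoefficientTable | None = None,
) -> FitReport:
    """Full training pipeline with automatic re-referencing.

    By default (``reference=None``, the self-referenced scheme) the
    complete per-group analysis (two-pass trimming included) is run once;
    each deposition's reference offset is the mean prediction error of its
    retained shifts, pooled over all atom types; every shift of the
    deposition is corrected by that offset and the complete analysis is
    rerun.  Self-referenced offsets are identifiable only up to a global
    constant shared with the regression intercepts (the count-weighted
    offset mean is pinned near zero), so they measure *relative*
    referencing errors between depositions.

    With ``reference`` set to a fixed coefficient table, offsets are the
    plain mean deviation from that table's predictions instead.  This
    anchors the reference frame externally: adding a constant to one
    deposition's shifts then changes exactly that offset, by that
    constant, and nothing else.

    Cross-validated statistics (xcorr/xrms) are computed on the corrected,
    trimmed data when ``cv_folds`` is set.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty corpus")
    deviations: dict[str, list[float]] = {}
    if reference is not None:
        for o in corpus:
            if o.key in reference:
                dev = o.shift - _row_predict(reference[o.key], o.attrs)
                deviations.setdefault(o.deposition_id, []).append(dev)
    else:
        rows1, retained1, _ = _full_analysis(corpus, method, multiplier)
        for o in retained1:
            dev = o.shift - _row_predict(rows1[o.key], o.attrs)
            deviations.setdefault(o.deposition_id, []).append(dev)
    offsets: dict[str, float] = {}
    for dep in sorted({o.deposition_id for o in corpus}):
        devs = deviations.get(dep)
        if not devs:
            logger.warning("deposition %s has no eligible retained shifts; offset 0", dep)
            offsets[dep] = 0.0
        else:
            offsets[dep] = float(np.mean(devs))

    corrected = [
        ShiftObservation(
            o.deposition_id, o.residue, o.key, o.shift - offsets[o.deposition_id], o.attrs
        )
        for o in corpus
    ]
    rows2, retained2, dropped2 = _full_analysis(corrected, method, multiplier)

    if cv_folds:
        xstats = cross_validate(retained2, folds=cv_folds, seed=seed, method=method)
        for key, (xcorr, xrms) in xstats.items():
            rows2[key].xcorr = xcorr
            rows2[key].xrms = xrms

    table = CoefficientTable(rows=rows2, provenance="fitted")
    return FitReport(
        table=table, dropped_outliers=dropped2, reference_offsets=offsets
    )


def cross_validate(
    corpus: Sequence[ShiftObservation],
    folds: int = 10,
    seed: int = 0,
    method: str = "bic",
) -> dict[AtomKey, tuple[float, float]]:
    """Stratified k-fold cross-validation, one stratum per AtomKey group.

    Held-out predictions are pooled across folds before computing the
    per-key cross-validated correlation and rms.  Groups smaller than the
    fold count fall back to leave-one-out (logged).  Deterministic per seed.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    out: dict[AtomKey, tuple[float, float]] = {}
    for key, group in sorted(_group_by_key(corpus).items()):
        n = len(group)
        k = folds
        if n < folds:
            logger.info("%s: %d observations < %d folds, using leave-one-out", key, n, folds)
            k = n
        order = rng.permutation(n)
        assignment = np.empty(n, dtype=int)
        assignment[order] = np.arange(n) % k
        y_true = np.empty(n)
        y_pred = np.empty(n)
        for fold in range(k):
            test_idx = np.flatnonzero(assignment == fold)
            train = [group[j] for j in np.flatnonzero(assignment != fold)]
            row = fit_atom_group(train, method=method)
            for j in test_idx:
                y_true[j] = group[j].shift
                y_pred[j] = _row_predict(row, group[j].attrs)
        resid = y_true - y_pred
        xrms = float(np.sqrt(np.mean(resid**2)))
        if np.std(y_pred) > 0 and np.std(y_true) > 0:
            xcorr = float(np.corrcoef(y_true, y_pred)[0, 1])
        else:
            xcorr = 0.0
        out[key] = (xcorr, xrms)
    return out


# ---------------------------------------------------------------------------
# Group means

_CANONICAL_ALLOWED = frozenset(
    {"pre_a", "pre_c", "pre_g", "suc_a", "suc_c", "suc_g"}
)


def _triplet_sequence(attrs: TripletAttributes) -> str:
    def side(prefix: str) -> str:
        for b in "acg":
            if f"{prefix}_{b}" in attrs.flags:
                return b
        if f"{prefix}_gu" in attrs.flags:
            return "g"
        return "u"  # WC-paired U baseline, or a U in a wobble (pre/suc_ug)

    return side("pre") + attrs.central_base + side("suc")


def compute_group_means(
    corpus: Sequence[ShiftObservation], grouping: str = "triplet"
) -> dict[tuple[str, AtomKey], float]:
    """Mean observed shift per (triplet sequence, AtomKey).

    ``grouping="triplet"`` averages all observations of a triplet sequence;
    ``grouping="canonical"`` keeps only fully canonical contexts (GC/AU
    pairs throughout, WC-paired i-2 and i+2: no wobble, terminal or loop
    flags).  Empty groups are simply absent from the result.
    """
    if grouping not in ("triplet", "canonical"):
        raise ValueError(f"unknown grouping {grouping!r}")
    sums: dict[tuple[str, AtomKey], list[float]] = {}
    for o in corpus:
        if grouping == "canonical" and not set(o.attrs.flags) <= _CANONICAL_ALLOWED:
            continue
        label = _triplet_sequence(o.attrs)
        sums.setdefault((label, o.key), []).append(o.shift)
    return {k: float(np.mean(v)) for k, v in sums.items()}
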