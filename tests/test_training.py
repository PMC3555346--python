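"""Regression fitting, outlier trimming, re-referencing and cross-validation."""

import numpy as np
import pytest

from rnaproton import (
    ATTRIBUTE_NAMES,
    AtomKey,
    ShiftObservation,
    TripletAttributes,
    compute_group_means,
    cross_validate,
    fit_atom_group,
    fit_with_trimming,
    rereference_and_fit,
)
from rnaproton.training import _design, _row_predict
from conftest import build_corpus, coefficient_errors, random_attrs, synth_group

from rnaproton import SimulationConfig


KEY = AtomKey("A", "H2")


class TestFitAtomGroup:
    def test_noiseless_exact_recovery(self, packaged_table):
        rng = np.random.default_rng(0)
        row = packaged_table[KEY]
        obs = synth_group(KEY, 250, 0.0, rng, row)
        fit = fit_atom_group(obs, method="bic")
        assert fit.const == pytest.approx(row.const, abs=1e-8)
        for a in ATTRIBUTE_NAMES:
            assert fit.contrib[a] == pytest.approx(row.contrib[a], abs=1e-8)
        assert fit.rms < 1e-10

    def test_absent_attribute_coefficient_is_zero(self, packaged_table):
        rng = np.random.default_rng(1)
        row = packaged_table[KEY]
        obs = [
            o for o in synth_group(KEY, 150, 0.01, rng, row)
            if "ter5" not in o.attrs.flags
        ]
        fit = fit_atom_group(obs)
        assert fit.contrib["ter5"] == 0.0

    def test_ols_matches_normal_equations_oracle(self, packaged_table):
        """Plain least squares agrees with a direct solve of X'Xb = X'y on
        the supported columns."""
        rng = np.random.default_rng(2)
        obs = synth_group(KEY, 120, 0.05, rng, packaged_table[KEY])
        fit = fit_atom_group(obs, method="ols")
        X, y = _design(obs)
        support = [c for c in range(X.shape[1]) if X[:, c].any()]
        A = np.column_stack([X[:, support], np.ones(len(y))])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        for j, c in enumerate(support):
            assert fit.contrib[ATTRIBUTE_NAMES[c]] == pytest.approx(beta[j], abs=1e-8)
        assert fit.const == pytest.approx(beta[-1], abs=1e-8)

    def test_identical_responses_degenerate(self):
        attrs = TripletAttributes("A")
        obs = [ShiftObservation("d", i + 2, KEY, 7.5, attrs) for i in range(5)]
        fit = fit_atom_group(obs)
        assert fit.const == 7.5
        assert all(v == 0.0 for v in fit.contrib.values())

    def test_requires_two_observations(self):
        obs = [ShiftObservation("d", 2, KEY, 7.0, TripletAttributes("A"))]
        with pytest.raises(ValueError):
            fit_atom_group(obs)

    def test_mixed_keys_rejected(self, packaged_table):
        rng = np.random.default_rng(3)
        obs = synth_group(KEY, 5, 0.0, rng, packaged_table[KEY])
        other = AtomKey("A", "H8")
        obs += synth_group(other, 5, 0.0, rng, packaged_table[other])
        with pytest.raises(ValueError):
            fit_atom_group(obs)


class TestTrimming:
    def test_clean_group_drops_nothing(self, packaged_table):
        rng = np.random.default_rng(4)
        obs = synth_group(KEY, 150, 0.05, rng, packaged_table[KEY])
        fit, dropped = fit_with_trimming(obs)
        # with Gaussian noise at n=150 a |z|>3 residual is possible but the
        # refit must equal the plain fit when nothing is dropped
        if not dropped:
            plain = fit_atom_group(obs)
            assert fit.const == plain.const

    def test_single_injected_outlier_dropped(self, packaged_table):
        rng = np.random.default_rng(5)
        obs = synth_group(KEY, 120, 0.03, rng, packaged_table[KEY])
        bad = ShiftObservation("d", 999, KEY, obs[0].shift + 10 * 0.03 * 10, obs[0].attrs)
        fit, dropped = fit_with_trimming(obs + [bad])
        assert dropped == [bad]
        assert fit.ntrim == 1 and fit.nobs == 120

    def test_hand_rolled_threshold_oracle(self, packaged_table):
        """Two-pass trimming reproduces an independent residual/3rms filter."""
        rng = np.random.default_rng(6)
        row = packaged_table[KEY]
        for _ in range(10):
            n = int(rng.integers(20, 60))
            obs = synth_group(KEY, n, 0.05, rng, row)
            for j in rng.choice(n, size=2, replace=False):
                obs[j] = ShiftObservation(
                    "d", obs[j].residue, KEY, obs[j].shift + rng.choice([-1, 1]) * 0.6,
                    obs[j].attrs,
                )
            first = fit_atom_group(obs)
            resid = np.array([o.shift - _row_predict(first, o.attrs) for o in obs])
            expect_drop = {i for i in range(n) if abs(resid[i]) > 3 * first.rms}
            _, dropped = fit_with_trimming(obs)
            got = {obs.index(o) for o in dropped}
            assert got == expect_drop

    def test_opposite_outliers_refit_improves(self, packaged_table):
        rng = np.random.default_rng(7)
        row = packaged_table[KEY]
        obs = synth_group(KEY, 200, 0.03, rng, row)
        o1, o2 = obs[0], obs[1]
        obs[0] = ShiftObservation("d", o1.residue, KEY, o1.shift + 1.0, o1.attrs)
        obs[1] = ShiftObservation("d", o2.residue, KEY, o2.shift - 1.0, o2.attrs)
        pass1 = fit_atom_group(obs)
        fit, dropped = fit_with_trimming(obs)
        assert set(dropped) == {obs[0], obs[1]}
        def sup_err(f):
            errs = [abs(f.const - row.const)] + [
                abs(f.contrib[a] - row.contrib[a]) for a in ATTRIBUTE_NAMES
            ]
            return max(errs)
        assert sup_err(fit) <= sup_err(pass1)


class TestRereference:
    def test_global_translation_absorbed_in_constants(self):
        """Adding one constant to every deposition leaves the attribute
        increments untouched and moves all constants by that constant."""
        cfg = SimulationConfig(seed=11, n_depositions=5, outlier_rate=0.0)
        corpus, _ = build_corpus(cfg)
        shifted = [
            ShiftObservation(o.deposition_id, o.residue, o.key, o.shift + 0.3, o.attrs)
            for o in corpus
        ]
        rep_a = rereference_and_fit(corpus, cv_folds=None)
        rep_b = rereference_and_fit(shifted, cv_folds=None)
        for key, row_a in rep_a.table.rows.items():
            row_b = rep_b.table[key]
            assert row_b.const - row_a.const == pytest.approx(0.3, abs=1e-9)
            for a in ATTRIBUTE_NAMES:
                assert row_b.contrib[a] == pytest.approx(row_a.contrib[a], abs=1e-9)

    def test_anchored_equivariance_is_exact(self, packaged_table):
        cfg = SimulationConfig(seed=12, n_depositions=4, outlier_rate=0.0)
        corpus, _ = build_corpus(cfg)
        shifted = [
            ShiftObservation(
                o.deposition_id, o.residue, o.key,
                o.shift + (0.07 if o.deposition_id.endswith("000") else 0.0), o.attrs,
            )
            for o in corpus
        ]
        rep_a = rereference_and_fit(corpus, cv_folds=None, reference=packaged_table)
        rep_b = rereference_and_fit(shifted, cv_folds=None, reference=packaged_table)
        for dep, off_a in rep_a.reference_offsets.items():
            expect = 0.07 if dep.endswith("000") else 0.0
            assert rep_b.reference_offsets[dep] - off_a == pytest.approx(expect, abs=1e-12)
        for key, row_a in rep_a.table.rows.items():
            assert rep_b.table[key].const == row_a.const

    def test_offset_recovery_anchored_to_truth(self, packaged_table):
        cfg = SimulationConfig(seed=13, n_depositions=6, outlier_rate=0.0)
        corpus, truths = build_corpus(cfg)
        rep = rereference_and_fit(corpus, cv_folds=None, reference=packaged_table)
        for truth in truths:
            n = sum(o.deposition_id == truth.deposition_id for o in corpus)
            tol = 3 * cfg.noise_sigma / np.sqrt(n)
            assert rep.reference_offsets[truth.deposition_id] == pytest.approx(
                truth.offset, abs=tol
            )

    def test_zero_offsets_near_idempotent(self):
        cfg = SimulationConfig(seed=14, n_depositions=5, offset_scale=0.0,
                               outlier_rate=0.0)
        corpus, _ = build_corpus(cfg)
        rep = rereference_and_fit(corpus, method="ols", cv_folds=None)
        assert max(abs(v) for v in rep.reference_offsets.values()) < 0.02
        from rnaproton.training import _full_analysis
        rows_plain, _, _ = _full_analysis(corpus, "ols", 3.0)
        for key, row in rep.table.rows.items():
            assert row.const == pytest.approx(rows_plain[key].const, abs=0.01)


class TestCrossValidation:
    def test_noiseless_corpus_has_zero_xrms(self):
        # corpus must be large enough that every attribute keeps design
        # support within each 90 % training fold
        cfg = SimulationConfig(seed=15, noise_sigma=0.0,
                               offset_scale=0.0, outlier_rate=0.0)
        corpus, _ = build_corpus(cfg)
        stats = cross_validate(corpus, folds=10, seed=0)
        assert all(xrms < 1e-6 for _, xrms in stats.values())

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=16, n_depositions=3, outlier_rate=0.0)
        corpus, _ = build_corpus(cfg)
        a = cross_validate(corpus, folds=5, seed=42)
        b = cross_validate(corpus, folds=5, seed=42)
        assert a == b

    def test_small_group_leave_one_out(self, packaged_table):
        rng = np.random.default_rng(17)
        obs = synth_group(KEY, 6, 0.05, rng, packaged_table[KEY])
        stats = cross_validate(obs, folds=10, seed=0)
        assert KEY in stats  # falls back to leave-one-out rather than failing

    def test_rejects_single_fold(self):
        with pytest.raises(ValueError):
            cross_validate([], folds=1)


class TestGroupMeans:
    def test_canonical_mean_of_identical_observations(self):
        attrs = TripletAttributes("A")  # canonical uAu baseline
        obs = [ShiftObservation("d", i + 2, KEY, 7.03, attrs) for i in range(4)]
        means = compute_group_means(obs, grouping="canonical")
        assert means[("uAu", KEY)] == pytest.approx(7.03)

    def test_canonical_excludes_flagged_contexts(self):
        canonical = TripletAttributes("A", frozenset({"pre_g", "suc_c"}))
        flagged = TripletAttributes("A", frozenset({"pre_g", "suc_c", "loop5"}))
        obs = [
            ShiftObservation("d", 2, KEY, 7.8, canonical),
            ShiftObservation("d", 3, KEY, 9.9, flagged),
        ]
        can = compute_group_means(obs, grouping="canonical")
        assert can[("gAc", KEY)] == pytest.approx(7.8)
        full = compute_group_means(obs, grouping="triplet")
        assert full[("gAc", KEY)] == pytest.approx((7.8 + 9.9) / 2)

    def test_empty_groups_absent(self):
        means = compute_group_means([], grouping="triplet")
        assert means == {}

    def test_synthetic_canonical_means_match_generator(self, packaged_table):
        cfg = SimulationConfig(seed=18, n_depositions=8, offset_scale=0.0,
                               outlier_rate=0.0, wobble_prob=0.0)
        corpus, _ = build_corpus(cfg)
        means = compute_group_means(corpus, grouping="canonical")
        identity = {"pre_a", "pre_c", "pre_g", "suc_a", "suc_c", "suc_g"}
        groups: dict = {}
        for o in corpus:
            if set(o.attrs.flags) <= identity:
                groups.setdefault((o.key, o.attrs), []).append(o)
        checked = 0
        from rnaproton.training import _triplet_sequence

        for (key, attrs), group in groups.items():
            n = len(group)
            if n < 10:
                continue
            label = _triplet_sequence(attrs)
            expected = _row_predict(packaged_table[key], attrs)
            assert means[(label, key)] == pytest.approx(
                expected, abs=3 * cfg.noise_sigma / np.sqrt(n)
            )
            checked += 1
        assert checked > 5
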