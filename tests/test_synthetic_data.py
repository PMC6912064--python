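"""Cohort simulator: determinism, truth coverage, planted structure."""

import json

import numpy as np
import pytest

from ctdnatrack.pipeline_io import PipelineError
from ctdnatrack.synthetic_data import (
    PANEL_GENES,
    SimulationConfig,
    simulate_clinical,
    simulate_clone_tree,
    simulate_cohort,
    simulate_read_counts,
    simulate_trajectories,
    write_cohort,
)


class TestCloneTree:
    def test_single_founder(self):
        assert simulate_clone_tree(1, 0) == {0: None}

    def test_deterministic(self):
        assert simulate_clone_tree(4, 7) == simulate_clone_tree(4, 7)

    def test_invalid_count(self):
        with pytest.raises(PipelineError):
            simulate_clone_tree(0, 0)

    def test_rootedness_sweep(self):
        for seed in range(50):
            tree = simulate_clone_tree(5, seed)
            assert tree[0] is None
            for c in range(1, 5):
                assert 0 <= tree[c] < c  # parent precedes child


class TestTrajectories:
    days = [0, 30, 60, 90, 120, 150, 180]

    def test_responder_founder_decreasing(self):
        rng = np.random.default_rng(1)
        phi, _ = simulate_trajectories({0: None}, "responder", self.days, rng)
        assert np.all(np.diff(phi[0]) < 0)

    def test_relapse_has_rising_resistance_before_pd(self):
        rng = np.random.default_rng(2)
        phi, meta = simulate_trajectories({0: None, 1: 0}, "relapse", self.days, rng)
        res = meta["resistance_clone"]
        assert res is not None
        traj = phi[res]
        rising = [traj[i + 1] > traj[i] for i in range(len(traj) - 1)]
        assert any(rising[i] and rising[i + 1] for i in range(len(rising) - 1))
        assert meta["emergence_day"] < meta["pd_day"]

    def test_constraints_hold_exactly_sweep(self):
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(1, 6))
            arch = ["responder", "stable", "progressor", "relapse"][seed % 4]
            if arch == "relapse":
                n = max(n, 2)
            tree = simulate_clone_tree(n, rng)
            phi, _ = simulate_trajectories(tree, arch, self.days, rng)
            for c, par in tree.items():
                if par is not None:
                    assert np.all(phi[c] <= phi[par] + 1e-9)
            for par in {p for p in tree.values() if p is not None}:
                kids = [c for c, p in tree.items() if p == par]
                assert np.all(sum(phi[k] for k in kids) <= phi[par] + 1e-9)


class TestReadCounts:
    def test_zero_prevalence_zero_alt(self):
        rng = np.random.default_rng(0)
        depth, alt = simulate_read_counts(np.zeros(100), 3000, np.full(100, 0.5), rng)
        assert alt.sum() == 0

    def test_binomial_mean(self):
        rng = np.random.default_rng(1)
        depth, alt = simulate_read_counts(np.full(100, 0.3), 3000, np.full(100, 0.5), rng)
        assert np.mean(alt / depth) == pytest.approx(0.15, abs=0.01)


class TestClinical:
    def test_strong_shrinkage_is_pr(self):
        rng = np.random.default_rng(3)
        tf = np.array([0.4, 0.25, 0.1, 0.02])  # 60%+ diameter decrease
        rec = simulate_clinical("P1", [0, 30, 60, 90], tf, rng, noise_frac=0.0)
        assert rec.best_response == "PR"
        assert not rec.event

    def test_flat_diameters_sd_censored(self):
        rng = np.random.default_rng(4)
        tf = np.full(4, 0.2)
        rec = simulate_clinical("P1", [0, 30, 60, 90], tf, rng, noise_frac=0.0)
        assert rec.best_response == "SD"
        assert not rec.event
        assert rec.pfs_days == 90

    def test_growth_triggers_confirmed_pd(self):
        rng = np.random.default_rng(5)
        tf = np.array([0.1, 0.1, 0.3, 0.5, 0.7])
        rec = simulate_clinical("P1", [0, 30, 60, 90, 120], tf, rng, noise_frac=0.0)
        assert rec.event
        assert rec.pd_day is not None


class TestCohort:
    def test_default_shape(self, default_cohort):
        assert len(default_cohort.patients) == 12
        assert sum(len(p.series) for p in default_cohort.patients) == 44
        eligible = [p for p in default_cohort.patients if len(p.series) >= 3]
        assert len(eligible) == 5

    def test_truth_covers_every_emitted_variant(self, default_cohort):
        for p in default_cohort.patients:
            truth = p.truth_origin()
            for s in p.series:
                for v in s.variants:
                    assert v.key in truth

    def test_confounders_present(self, default_cohort):
        assert len(default_cohort.popdb) == 12 * 5
        assert all(af >= 0.001 for af in default_cohort.popdb.values())
        assert all(n > 2 for n in default_cohort.normal_evidence.values())
        origins = {
            m.origin for p in default_cohort.patients for m in p.mutations
        }
        assert origins == {"somatic", "common_germline", "chip", "private_germline"}

    def test_germline_snps_near_half_vaf(self, default_cohort):
        p = default_cohort.patients[0]
        germ = {m.key for m in p.mutations if m.origin == "common_germline"}
        for s in p.series:
            for v in s.variants:
                if v.key in germ:
                    assert abs(v.vaf - 0.5) < 0.05

    def test_panel_size(self):
        assert len(PANEL_GENES) == 329

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        cfg = SimulationConfig(seed=77, n_patients=2, samples_per_patient=(3, 2),
                               archetypes=("responder", "stable"))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(simulate_cohort(cfg), d1)
        write_cohort(simulate_cohort(cfg), d2)
        files = sorted(f.relative_to(d1) for f in d1.rglob("*") if f.is_file())
        assert files
        for f in files:
            left = (d1 / f).read_bytes()
            right = (d2 / f).read_bytes()
            # sample-sheet VCF paths embed the output dir; compare the rest
            if f.name == "sample_sheet.tsv":
                left = left.replace(str(d1).encode(), b"X")
                right = right.replace(str(d2).encode(), b"X")
            assert left == right, f

    def test_truth_json_schema(self, tmp_path):
        cfg = SimulationConfig(seed=7, n_patients=2, samples_per_patient=(3, 2),
                               archetypes=("relapse", "stable"))
        cohort = simulate_cohort(cfg)
        paths = write_cohort(cohort, tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert set(truth) == {"P01", "P02"}
        assert truth["P01"]["resistance_clone"] is not None
        assert truth["P02"]["resistance_clone"] is None
        n_variants = sum(len(v["variants"]) for v in truth.values())
        assert n_variants == sum(len(p.mutations) for p in cohort.patients)


class TestEndToEndRecovery:
    def test_clone_count_recovered_for_most_patients(self):
        """Full filter+cluster pipeline finds the planted clone number in
        >=80% of eligible patients."""
        from ctdnatrack.clonal_inference import DPConfig, dp_cluster
        from ctdnatrack.variant_filtering import apply_filter_cascade

        cohort = simulate_cohort(SimulationConfig(seed=3))
        ok = tot = 0
        for p in cohort.patients:
            if len(p.series) < 3:
                continue
            apply_filter_cascade(p.series, cohort.popdb, cohort.normal_evidence)
            res = dp_cluster(
                p.series, DPConfig(n_iterations=2500, burn_in=600, thin=4), seed=7
            )
            tot += 1
            ok += res.n_clusters == p.n_clones
        assert tot == 5
        assert ok / tot >= 0.8
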