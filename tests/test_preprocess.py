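"""QC filters, the beta<->M transform pair, and ComBat batch correction."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cupclf import (
    BetaMatrix,
    QCParams,
    ValidationError,
    beta_to_m,
    combat_adjust,
    filter_probes,
    filter_samples,
    m_to_beta,
)
from cupclf.io import ProbeAnnotations


def _annotations(entries):
    """entries: list of (probe_id, chromosome, snp_overlap)."""
    return ProbeAnnotations(
        pd.DataFrame(
            {
                "chromosome": [c for _, c, _ in entries],
                "position": range(len(entries)),
                "snp_overlap": [s for _, _, s in entries],
            },
            index=pd.Index([p for p, _, _ in entries], name="probe_id"),
        )
    )


class TestFilterProbes:
    def test_rule_attribution_counts(self):
        # 10 probes: 2 on chrX, 1 SNP-flagged autosomal, 1 with 20% missing
        entries = [
            ("pX1", "chrX", False), ("pX2", "chrX", False),
            ("pS", "chr2", True), ("pM", "chr3", False),
        ] + [(f"ok{i}", "chr1", False) for i in range(6)]
        ann = _annotations(entries)
        values = np.full((10, 10), 0.5)
        values[3, :2] = np.nan  # pM: 20% missing
        bm = BetaMatrix([p for p, _, _ in entries], [f"s{j}" for j in range(10)], values)
        out, report = filter_probes(bm, ann, QCParams())
        assert out.probe_ids == [f"ok{i}" for i in range(6)]
        assert report.probes_removed == {"unannotated": 0, "sex": 2, "snp": 1, "missing": 1}
        assert report.total_probes_removed + report.probes_retained == 10

    def test_clean_matrix_is_identity(self):
        ann = _annotations([(f"p{i}", "chr5", False) for i in range(4)])
        bm = BetaMatrix([f"p{i}" for i in range(4)], ["a", "b"], np.full((4, 2), 0.3))
        out, report = filter_probes(bm, ann)
        assert out.probe_ids == bm.probe_ids
        np.testing.assert_array_equal(out.values, bm.values)
        assert report.total_probes_removed == 0

    def test_sex_and_snp_probe_attributed_to_sex_rule(self):
        ann = _annotations([("pXS", "chrX", True), ("ok", "chr1", False)])
        bm = BetaMatrix(["pXS", "ok"], ["a", "b"], np.full((2, 2), 0.4))
        _, report = filter_probes(bm, ann)
        assert report.probes_removed["sex"] == 1
        assert report.probes_removed["snp"] == 0

    def test_unannotated_probe_fails_qc(self):
        ann = _annotations([("known", "chr1", False)])
        bm = BetaMatrix(["known", "mystery"], ["a", "b"], np.full((2, 2), 0.4))
        out, report = filter_probes(bm, ann)
        assert out.probe_ids == ["known"]
        assert report.probes_removed["unannotated"] == 1

    def test_all_removed_raises(self):
        ann = _annotations([("pX", "chrX", False)])
        bm = BetaMatrix(["pX"], ["a", "b"], np.full((1, 2), 0.4))
        with pytest.raises(ValidationError, match="empty matrix"):
            filter_probes(bm, ann)


class TestFilterSamples:
    def test_high_missingness_sample_dropped(self):
        values = np.full((10, 5), 0.5)
        values[:5, 2] = np.nan  # sample s2: 50% missing
        bm = BetaMatrix([f"p{i}" for i in range(10)], [f"s{j}" for j in range(5)], values)
        out, report = filter_samples(bm, QCParams(max_sample_missing_frac=0.10))
        assert out.sample_ids == ["s0", "s1", "s3", "s4"]
        assert report.samples_removed == 1

    def test_no_missing_is_identity(self):
        bm = BetaMatrix(["p"], ["a", "b"], np.array([[0.2, 0.9]]))
        out, _ = filter_samples(bm)
        assert out.sample_ids == ["a", "b"]

    def test_threshold_one_keeps_everything(self):
        values = np.full((4, 3), np.nan)
        values[0] = 0.5
        bm = BetaMatrix([f"p{i}" for i in range(4)], ["a", "b", "c"], values)
        out, _ = filter_samples(bm, QCParams(max_sample_missing_frac=1.0))
        assert out.n_samples == 3


class TestBetaMTransforms:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.5, 0.0), (0.8, 2.0), (0.0, -19.931567126628412)],
    )
    def test_known_values(self, beta, expected):
        assert beta_to_m(np.array([beta]), 1e-6)[0] == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("m,expected", [(0.0, 0.5), (2.0, 0.8)])
    def test_inverse_known_values(self, m, expected):
        assert m_to_beta(np.array([m]))[0] == pytest.approx(expected, abs=1e-12)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(0.01, 0.99, size=(50, 20))
        assert np.abs(m_to_beta(beta_to_m(b)) - b).max() < 1e-9

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=1e-4, max_value=1 - 1e-4))
    def test_antisymmetry_and_monotonicity(self, b):
        m = beta_to_m(np.array([b, 1 - b, min(b + 1e-4, 1 - 1e-5)]))
        assert m[0] == pytest.approx(-m[1], abs=1e-9)
        assert m[2] >= m[0]

    def test_nan_passes_through(self):
        m = beta_to_m(np.array([0.5, np.nan]))
        assert np.isnan(m[1]) and m[0] == 0.0

    def test_bad_epsilon_rejected(self):
        with pytest.raises(ValidationError):
            beta_to_m(np.array([0.5]), epsilon=0.7)


class TestCombat:
    def _shifted(self, seed=0, n_probes=200, per_batch=50, shift=1.0, noise_sd=1.0):
        rng = np.random.default_rng(seed)
        base = rng.normal(0.0, noise_sd, size=(n_probes, 2 * per_batch))
        base += rng.uniform(-3, 3, size=(n_probes, 1))  # probe baselines
        base[:, per_batch:] += shift
        batches = ["b1"] * per_batch + ["b2"] * per_batch
        return base, batches

    def test_single_batch_passthrough(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 12))
        out = combat_adjust(x, ["only"] * 12)
        assert np.abs(out - x).max() < 1e-8

    def test_batch_mean_gap_removed(self):
        # EB shrinkage leaves per-probe estimation noise of order
        # noise_sd * sqrt(2/n) in the batch-mean gap, so the per-probe
        # threshold is checked at a realistic M-value noise level (0.25)
        x, batches = self._shifted(noise_sd=0.25)
        out = combat_adjust(x, batches)
        gap = np.abs(out[:, :50].mean(axis=1) - out[:, 50:].mean(axis=1))
        assert (gap < 0.1).mean() >= 0.95

    def test_mean_gap_reduced_fivefold_at_high_noise(self):
        x, batches = self._shifted(noise_sd=1.0)
        out = combat_adjust(x, batches)
        gap_before = np.abs(x[:, :50].mean(axis=1) - x[:, 50:].mean(axis=1)).mean()
        gap_after = np.abs(out[:, :50].mean(axis=1) - out[:, 50:].mean(axis=1)).mean()
        assert gap_before / gap_after >= 5.0

    def test_permutation_equivariance(self):
        x, batches = self._shifted(seed=3, n_probes=40, per_batch=10)
        out = combat_adjust(x, batches)
        rng = np.random.default_rng(4)
        perm = rng.permutation(x.shape[1])
        out_perm = combat_adjust(x[:, perm], [batches[j] for j in perm])
        np.testing.assert_allclose(out_perm, out[:, perm], atol=1e-10)

    def test_tiny_batch_named_in_error(self):
        x = np.zeros((5, 3))
        with pytest.raises(ValidationError, match="lonely"):
            combat_adjust(x, ["a", "a", "lonely"])

    def test_shape_and_missingness_mask_preserved(self):
        x, batches = self._shifted(seed=5, n_probes=60, per_batch=20)
        mask = np.random.default_rng(6).random(x.shape) < 0.05
        x[mask] = np.nan
        out = combat_adjust(x, batches)
        assert out.shape == x.shape
        np.testing.assert_array_equal(np.isnan(out), mask)

    def test_grand_mean_approximately_preserved(self):
        x, batches = self._shifted(seed=7)
        out = combat_adjust(x, batches)
        drift = np.abs(out.mean(axis=1) - x.mean(axis=1))
        assert drift.max() < 0.05

    def test_matches_bioconductor_sva(self, tmp_path):
        """Independent oracle: sva::ComBat on the same matrix via Rscript."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript is required for the ComBat cross-check")
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, size=(60, 24))
        x[:, 12:] = x[:, 12:] * 1.3 + 0.8
        batches = ["a"] * 12 + ["b"] * 12
        np.savetxt(tmp_path / "m.csv", x, delimiter=",")
        script = tmp_path / "combat.R"
        script.write_text(
            'suppressMessages(library(sva))\n'
            f'x <- as.matrix(read.csv("{tmp_path}/m.csv", header=FALSE))\n'
            'batch <- c(rep("a", 12), rep("b", 12))\n'
            'adj <- ComBat(dat=x, batch=batch, par.prior=TRUE, prior.plots=FALSE)\n'
            f'write.table(adj, "{tmp_path}/adj.csv", sep=",", '
            'row.names=FALSE, col.names=FALSE)\n'
        )
        subprocess.run(
            ["Rscript", str(script)], check=True, capture_output=True, text=True
        )
        expected = np.loadtxt(tmp_path / "adj.csv", delimiter=",")
        ours = combat_adjust(x, batches)
        assert np.abs(ours - expected).max() < 1e-8
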