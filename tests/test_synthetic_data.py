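"""Synthetic-study generator: determinism, planted structure, recovery."""

import numpy as np
import pandas as pd
import pytest

from epiquant import core_index, preprocess, qpcr_quant, specificity
from epiquant import synthetic_data as sd
from epiquant.qpcr_quant import copies_per_cm2

SMALL = sd.SyntheticConfig(
    tissues=("Anod", "Ulva"),
    months=("Jan", "Feb", "Jun", "Jul"),
    deficits=(("Ulva", "Feb", 2),),
    n_core=3,
    n_host_specific_per_host=1,
    n_seasonal=2,
    n_background=20,
    n_organellar=1,
    n_contaminants=3,
    depth=5000,
)


class TestGenerateTruth:
    def test_deterministic_per_seed(self):
        a = sd.generate_truth(SMALL, seed=4)
        b = sd.generate_truth(SMALL, seed=4)
        pd.testing.assert_frame_equal(a.true_relab, b.true_relab)
        pd.testing.assert_series_equal(a.true_loads, b.true_loads)
        c = sd.generate_truth(SMALL, seed=5)
        assert not np.allclose(a.true_loads, c.true_loads)

    def test_loads_stay_within_clamp(self):
        config = sd.SyntheticConfig(load_log10_sd=1.5)  # heavy tails forced in
        for seed in range(5):
            truth = sd.generate_truth(config, seed=seed)
            assert (truth.true_loads >= config.load_clamp[0]).all()
            assert (truth.true_loads <= config.load_clamp[1]).all()

    def test_default_design_shape(self, default_truth):
        assert len(default_truth.real_ids) == 208
        assert len(default_truth.metadata.control_ids) == 2

    def test_core_taxa_present_in_every_design_slot(self, default_truth):
        core_asvs = default_truth.roles.index[default_truth.roles == "core"]
        sub = default_truth.true_relab.loc[default_truth.real_ids, core_asvs]
        assert (sub > 0).all().all()

    def test_relative_abundances_sum_to_one(self, default_truth):
        np.testing.assert_allclose(
            default_truth.true_relab.sum(axis=1).to_numpy(), 1.0, rtol=1e-9)

    def test_host_specific_taxa_absent_off_host(self, default_truth):
        meta = default_truth.metadata.table
        for genus, host in default_truth.host_specific.items():
            asvs = [a for a in default_truth.roles.index
                    if default_truth.genus_of(a) == genus]
            off = [s for s in default_truth.real_ids
                   if meta.loc[s, "host"] != host]
            assert (default_truth.true_relab.loc[off, asvs] == 0).all().all()

    def test_contaminants_bounded_in_real_samples(self, default_truth):
        config = default_truth.config
        rel = default_truth.true_relab.loc[default_truth.real_ids,
                                           default_truth.contaminant_asvs]
        assert ((rel > 0).sum(axis=0) <= config.contaminant_freq).all()
        assert (rel.max(axis=0) < 0.015).all()
        ctrl = default_truth.true_relab.loc[default_truth.metadata.control_ids,
                                            default_truth.contaminant_asvs]
        assert (ctrl > 0).all().all()

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            sd.generate_truth(sd.SyntheticConfig(n_core=0, n_seasonal=0,
                                                 n_background=0), seed=0)


class TestSimulateReads:
    def test_row_sums_equal_depth(self, default_truth, default_reads):
        assert (default_reads.counts.sum(axis=1)
                == default_truth.config.depth).all()

    def test_zero_truth_taxon_never_sequenced(self, default_truth,
                                              default_reads):
        zero_mask = default_truth.true_relab == 0
        assert (default_reads.counts.to_numpy()[zero_mask.to_numpy()] == 0).all()

    def test_read_fractions_converge_to_truth(self):
        truth = sd.generate_truth(SMALL, seed=8)
        sample = truth.real_ids[0]
        probs = truth.true_relab.loc[sample].to_numpy()
        depth = 5000
        totals = np.zeros_like(probs)
        n_rep = 100
        for rep in range(n_rep):
            reads = sd.simulate_reads(truth, depth=depth, seed=1000 + rep)
            totals += reads.counts.loc[sample].to_numpy()
        frac = totals / (n_rep * depth)
        se = np.sqrt(probs * (1 - probs) / (n_rep * depth))
        assert (np.abs(frac - probs) <= 3 * se + 1e-12).mean() > 0.98

    def test_zero_depth_rejected(self, default_truth):
        with pytest.raises(ValueError, match="depth"):
            sd.simulate_reads(default_truth, depth=0, seed=0)


class TestSimulateQpcr:
    def test_zero_cv_reproduces_true_loads(self, default_truth):
        table = sd.simulate_qpcr(default_truth, cv=0.0, seed=0)
        loads = qpcr_quant.attach_loads(default_truth.metadata, table)
        np.testing.assert_allclose(loads["N"],
                                   default_truth.true_loads.loc[loads.index],
                                   rtol=1e-9)

    def test_formula_roundtrip(self, default_truth, default_qpcr):
        meta = default_truth.metadata.table
        loads = qpcr_quant.attach_loads(default_truth.metadata, default_qpcr)
        for _, row in default_qpcr.head(20).iterrows():
            C = row["C"]
            c_eff = C if C < 0.5 else 0.5
            n_direct = copies_per_cm2(row["copies_in_reaction"], C, c=c_eff)
            assert loads.loc[row["sample_id"], "N"] == pytest.approx(
                n_direct, rel=1e-9)

    def test_log_residual_sd_matches_cv(self):
        truth = sd.generate_truth(seed=2)
        cv = 0.3
        residuals = []
        for seed in range(5):  # 5 x 208 = 1040 residuals
            table = sd.simulate_qpcr(truth, cv=cv, seed=seed)
            loads = qpcr_quant.attach_loads(truth.metadata, table)
            residuals.append(np.log(loads["N"]
                                    / truth.true_loads.loc[loads.index]))
        sd_hat = np.concatenate(residuals).std()
        assert abs(sd_hat - cv) / cv < 0.2

    def test_negative_cv_rejected(self, default_truth):
        with pytest.raises(ValueError, match="cv"):
            sd.simulate_qpcr(default_truth, cv=-0.1, seed=0)


class TestRecovery:
    def test_core_recovery_perfect_without_dropout(self, default_truth,
                                                   default_pipeline):
        metrics = sd.evaluate_recovery(
            default_truth,
            core_set=default_pipeline["core"],
            flagged_contaminants=default_pipeline["report"].flagged,
        ).set_index("metric")["value"]
        assert metrics["core_precision"] == 1.0
        assert metrics["core_recall"] == 1.0
        assert metrics["contaminant_precision"] == 1.0
        assert metrics["contaminant_recall"] == 1.0

    def test_host_specific_taxa_fill_their_exclusive_cells(
            self, default_truth, default_pipeline):
        membership = specificity.host_membership(
            default_pipeline["genus_counts"], default_truth.metadata)
        metrics = sd.evaluate_recovery(
            default_truth,
            core_set=default_pipeline["core"],
            flagged_contaminants=default_pipeline["report"].flagged,
            genus_membership=membership,
        ).set_index("metric")["value"]
        assert metrics["host_specific_exclusive_fraction"] == 1.0

    def test_intra_species_pairs_share_more_than_inter_phylum(
            self, default_truth, default_pipeline):
        counts = default_pipeline["filtered"].counts
        meta = default_truth.metadata.table
        subset = [s for s in counts.index
                  if int(meta.loc[s, "replicate"]) == 1
                  and meta.loc[s, "month"] in ("Jan", "Feb", "Jun")]
        pairs = specificity.pairwise_shared(counts.loc[subset],
                                            default_truth.metadata)
        res = specificity.group_comparison(pairs)
        assert res.medians["intra-species"] > res.medians["inter-phylum"]

    def test_core_recovery_degrades_with_dropout(self):
        recalls = []
        for dropout in (0.0, 0.35, 0.7):
            config = sd.SyntheticConfig(dropout=dropout)
            truth = sd.generate_truth(config, seed=19)
            reads = sd.simulate_reads(truth, seed=20)
            table, _ = preprocess.remove_organellar(reads, truth.taxonomy)
            _, filtered = preprocess.flag_contaminants(
                table, truth.metadata.control_ids)
            genus_counts, _ = preprocess.pool_by_rank(
                filtered.counts, truth.taxonomy, "genus")
            idx = core_index.core_index_table(genus_counts, truth.metadata)
            _, core = core_index.classify_core(idx)
            found = set(core) & set(truth.core_genera)
            recalls.append(len(found) / len(truth.core_genera))
        assert recalls[0] == 1.0
        assert recalls[0] >= recalls[1] >= recalls[2]
        assert recalls[2] < 1.0


class TestCompositionalArtifact:
    def test_constant_taxon_under_load_shift(self):
        """A taxon with constant absolute abundance under a 5x summer load
        rise: the quantitative estimate stays near fold 1 while the
        relative-only estimate collapses to ~1/5."""
        truth = sd.make_constant_taxon_truth(fold=5.0, seed=31)
        reads = sd.simulate_reads(truth, seed=32)
        qpcr = sd.simulate_qpcr(truth, cv=0.05, seed=33)
        loads = qpcr_quant.attach_loads(truth.metadata, qpcr)
        real = truth.real_ids
        absolute = preprocess.scale_to_absolute(
            reads.subset_samples(real), loads["N"])
        genus_abs, _ = preprocess.pool_by_rank(absolute, truth.taxonomy,
                                               "genus")
        rel = reads.counts.loc[real].div(reads.counts.loc[real].sum(axis=1),
                                         axis=0)
        genus_rel, _ = preprocess.pool_by_rank(rel, truth.taxonomy, "genus")

        fold_q = sd.estimate_fold_change(genus_abs, truth.metadata,
                                         "ConstFocal", "summer", "winter")
        fold_r = sd.estimate_fold_change(genus_rel, truth.metadata,
                                         "ConstFocal", "summer", "winter")
        assert fold_q == pytest.approx(1.0, rel=0.15)
        assert fold_r == pytest.approx(0.2, rel=0.15)


def test_seasonal_fold_error_smaller_for_quantitative_estimate(
        default_truth, default_pipeline):
    metrics = sd.evaluate_recovery(
        default_truth,
        core_set=default_pipeline["core"],
        flagged_contaminants=default_pipeline["report"].flagged,
        absolute_genus=default_pipeline["genus_abs"],
        relative_genus=default_pipeline["rel_genus"],
    ).set_index("metric")["value"]
    quant = metrics[metrics.index.str.startswith("fold_error_quantitative")]
    assert len(quant) > 0
    assert (quant < 0.5).all()  # log-scale error under 50% of the true fold


def test_simulated_env_table_exposes_planted_collinearity(default_truth):
    from epiquant.community_stats import env_prune
    from epiquant.io_model import ENV_VARIABLES

    env = sd.simulate_env(default_truth, seed=3)
    assert list(env.columns) == list(ENV_VARIABLES)
    assert len(env) == 10
    res = env_prune(env)
    # the planted collinear pairs (pH~T, SiOH4~NO3) lose one member each
    assert len(set(res.removed) & {"pH", "T"}) >= 1
    assert len(set(res.removed) & {"SiOH4", "NO3"}) >= 1


def test_write_fixture_roundtrip(tmp_path, default_truth):
    from epiquant import io_model

    paths = sd.write_fixture(default_truth, tmp_path / "fix", reads_seed=1,
                             qpcr_seed=2)
    table = io_model.read_asv_table(paths["asv_table"])
    assert len(table.sample_ids) == 210
    meta = io_model.read_sample_metadata(paths["metadata"])
    assert len(meta.control_ids) == 2
    truth_table = pd.read_csv(paths["truth"], sep="\t", index_col=0)
    assert (truth_table["role"] == "core").sum() == 20  # 2 ASVs per core genus
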