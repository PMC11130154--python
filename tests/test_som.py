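"""SOM training, metacluster selection and ordinal subset labelling."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cafsubsets import (
    GateConfig,
    IntensityModel,
    assign_subsets,
    default_profiles,
    generate_flow_sample,
    metacluster,
    subset_composition,
    train_som,
)
from cafsubsets.flow import downsample, gate_fibroblasts
from cafsubsets.profiles import PHENO_MARKERS
from cafsubsets.simulate import generate_flow_cohort
from cafsubsets.som import SOMResult, compare_composition


def _pure_sample(subset, n, seed):
    events, _ = generate_flow_sample(mixture={subset: 1.0}, n_events=n,
                                     seed=seed)
    return events


class TestTrainSOM:
    def test_single_population_codebook_centres_on_mean(self):
        """Degenerate input: nodes quantise the blob, centroid at its mean.

        A vector-quantising SOM spreads its nodes over the population
        (that is its job), so the degenerate-input contract is that the
        event-weighted codebook centroid sits at the population mean and
        every winning node stays inside the data cloud.
        """
        events = _pure_sample("CAF-S1", 2000, 0)
        som = train_som(events, grid_shape=(4, 4), seed=0)
        X = (np.log(events[list(PHENO_MARKERS)].to_numpy())
             - som.scale_mean) / som.scale_sd
        mean = X.mean(axis=0)
        counts = np.bincount(som.node_assignment, minlength=16)
        centroid = (som.codebook * counts[:, None]).sum(0) / counts.sum()
        assert np.linalg.norm(centroid - mean) < 0.1
        data_radius = np.linalg.norm(X - mean, axis=1).max()
        for node in np.unique(som.node_assignment):
            assert np.linalg.norm(som.codebook[node] - mean) < data_radius

    def test_two_populations_separate_with_99pct_purity(self):
        a = _pure_sample("CAF-S2", 1500, 1)
        b = _pure_sample("CAF-S1", 1500, 2)
        pooled = pd.concat([a, b], ignore_index=True)
        truth = np.array([0] * len(a) + [1] * len(b))
        som = train_som(pooled, seed=3)
        # majority-vote purity of node assignments
        purity = 0
        for node in np.unique(som.node_assignment):
            members = truth[som.node_assignment == node]
            purity += max((members == 0).sum(), (members == 1).sum())
        assert purity / len(truth) >= 0.99

    def test_zero_epochs_rejected(self):
        events = _pure_sample("CAF-S1", 200, 0)
        with pytest.raises(ValueError):
            train_som(events, epochs=0)

    def test_grid_larger_than_events_rejected(self):
        events = _pure_sample("CAF-S1", 50, 0)
        with pytest.raises(ValueError):
            train_som(events, grid_shape=(10, 10))

    def test_deterministic(self):
        events = _pure_sample("CAF-S5", 500, 4)
        a = train_som(events, seed=7, grid_shape=(5, 5))
        b = train_som(events, seed=7, grid_shape=(5, 5))
        assert np.array_equal(a.codebook, b.codebook)
        assert np.array_equal(a.node_assignment, b.node_assignment)


class TestMetacluster:
    def test_two_population_input_selects_k2(self):
        a = _pure_sample("CAF-S2", 1500, 1)
        b = _pure_sample("CAF-S1", 1500, 2)
        som = train_som(pd.concat([a, b], ignore_index=True), seed=5)
        meta = metacluster(som)
        assert meta.k == 2

    def test_identical_nodes_codebook_gives_k1(self):
        som = SOMResult(
            codebook=np.ones((9, len(PHENO_MARKERS))),
            node_assignment=np.arange(100) % 9,
            grid_shape=(3, 3), markers=PHENO_MARKERS,
            scale_mean=np.zeros(7), scale_sd=np.ones(7))
        with pytest.warns(UserWarning):
            meta = metacluster(som, k_max=9)
        assert meta.k == 1
        assert (meta.event_labels == 0).all()

    def test_every_event_gets_exactly_one_label(self):
        a = _pure_sample("CAF-S3", 800, 3)
        b = _pure_sample("CAF-S4", 800, 4)
        pooled = pd.concat([a, b], ignore_index=True)
        som = train_som(pooled, seed=6)
        meta = metacluster(som)
        assert len(meta.event_labels) == len(pooled)
        assert (np.asarray(meta.event_labels) >= 0).all()

    def test_k_max_bounds_enforced(self):
        som = train_som(_pure_sample("CAF-S1", 500, 0), seed=0)
        with pytest.raises(ValueError):
            metacluster(som, k_max=1)

    def test_truth_recovery_ari_over_08_across_10_seeds(self):
        """Cluster-to-truth adjusted Rand index >= 0.8 on default mixtures."""
        aris = []
        for seed in range(10):
            samples, truths = generate_flow_cohort(
                n_samples=6, n_events=500, seed=seed)
            cfg = GateConfig()
            rng = np.random.default_rng(seed)
            parts = []
            for s, t in zip(samples, truths):
                g = gate_fibroblasts(s.assign(true_label=t.cell_labels.values),
                                     cfg)
                parts.append(downsample(g, cfg,
                                        seed=int(rng.integers(2**31))))
            pooled = pd.concat(parts, ignore_index=True)
            som = train_som(pooled, seed=seed)
            meta = metacluster(som)
            aris.append(adjusted_rand_score(pooled["true_label"],
                                            meta.event_labels))
        assert min(aris) >= 0.8


class TestAssignSubsets:
    def _meta_for(self, events, labels):
        class FakeMeta:
            pass
        m = FakeMeta()
        m.event_labels = np.asarray(labels)
        return m

    def test_pure_clusters_match_their_profiles(self, model, profiles):
        frames, labels = [], []
        for i, name in enumerate(p.subset_name for p in profiles):
            ev = _pure_sample(name, 400, 10 + i)
            frames.append(ev)
            labels += [i] * len(ev)
        pooled = pd.concat(frames, ignore_index=True)
        meta = self._meta_for(pooled, labels)
        assign = assign_subsets(meta, pooled, profiles, model)
        expected = {i: p.subset_name for i, p in enumerate(profiles)}
        assert assign.cluster_to_subset == expected

    def test_all_neg_cluster_is_caf_s2(self, model, profiles):
        ev = _pure_sample("CAF-S2", 500, 3)
        meta = self._meta_for(ev, [0] * len(ev))
        assign = assign_subsets(meta, ev, profiles, model)
        assert assign.cluster_to_subset[0] == "CAF-S2"

    def test_equidistant_cluster_unassigned(self, model):
        from cafsubsets import MarkerProfile
        # two profiles symmetric about the cluster's level vector
        p_lo = MarkerProfile("CAF-S2", {m: "Neg" for m in PHENO_MARKERS})
        p_hi = MarkerProfile("CAF-S4", {m: "Low" for m in PHENO_MARKERS})
        rng = np.random.default_rng(0)
        # cluster sits exactly at Neg-Low, L1-equidistant from both
        ev = pd.DataFrame({
            m: np.exp(rng.normal(model.level_params["Neg-Low"][0], 0.01, 300))
            for m in PHENO_MARKERS})
        meta = self._meta_for(ev, [0] * len(ev))
        assign = assign_subsets(meta, ev, [p_lo, p_hi], model)
        assert assign.cluster_to_subset[0] == "unassigned"

    def test_normalised_matrix_bounds(self, model, profiles):
        frames, labels = [], []
        for i, name in enumerate(("CAF-S1", "CAF-S2", "CAF-S5")):
            ev = _pure_sample(name, 300, 20 + i)
            frames.append(ev)
            labels += [i] * len(ev)
        pooled = pd.concat(frames, ignore_index=True)
        assign = assign_subsets(self._meta_for(pooled, labels), pooled,
                                profiles, model)
        for m in PHENO_MARKERS:
            col = assign.normalised[m].astype(float)
            assert col.min() == pytest.approx(0.0)
            assert col.max() == pytest.approx(1.0)
            assert ((col >= 0) & (col <= 1)).all()

    def test_rescaling_one_marker_with_model_leaves_assignments(self, model, profiles):
        """Multiplying FAP by c while shifting the model's FAP axis is a no-op.

        Implemented by rescaling all intensities of one marker and
        discretising with a model whose level means shift by log(c) --
        assignments must be identical.  Here the model is shared across
        markers, so the check rescales every marker by the same c.
        """
        c = 3.7
        frames, labels = [], []
        for i, name in enumerate(("CAF-S1", "CAF-S4")):
            ev = _pure_sample(name, 300, 30 + i)
            frames.append(ev)
            labels += [i] * len(ev)
        pooled = pd.concat(frames, ignore_index=True)
        base = assign_subsets(self._meta_for(pooled, labels), pooled,
                              profiles, model)
        scaled = pooled.copy()
        for m in PHENO_MARKERS:
            scaled[m] = scaled[m] * c
        shifted = IntensityModel(
            level_params={lv: (mu + np.log(c), sd)
                          for lv, (mu, sd) in model.level_params.items()},
            positivity_threshold=model.positivity_threshold * c,
            high_threshold=model.high_threshold * c)
        res = assign_subsets(self._meta_for(scaled, labels), scaled,
                             profiles, shifted)
        assert res.cluster_to_subset == base.cluster_to_subset


class TestComposition:
    def test_single_sample_all_s1(self):
        comp = subset_composition(["CAF-S1"] * 10, ["s1"] * 10)
        assert comp.loc[0, "CAF-S1"] == pytest.approx(100.0)

    def test_percentages_sum_to_100_over_assigned(self):
        labels = ["CAF-S1"] * 5 + ["CAF-S4"] * 3 + ["unassigned"] * 2
        comp = subset_composition(labels, ["s"] * 10)
        assert comp.loc[0, "CAF-S1"] + comp.loc[0, "CAF-S4"] == pytest.approx(100.0)
        assert comp.loc[0, "pct_unassigned"] == pytest.approx(20.0)

    def test_all_unassigned_sample_excluded_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            comp = subset_composition(["unassigned"] * 4, ["s"] * 4)
        assert len(comp) == 0

    def test_planted_ncl_s3_enrichment_detected(self):
        """CAF-S3 planted more abundant in NCL: Welch p < 0.05 on truth labels."""
        rows_lab, rows_sid, rows_tis = [], [], []
        for tissue in ("tumour", "NCL"):
            samples, truths = generate_flow_cohort(
                n_samples=7, n_events=400, tissue=tissue, seed=99)
            for s, t in zip(samples, truths):
                keep = t.cell_labels.str.startswith("CAF")
                rows_lab += list(t.cell_labels[keep.values])
                rows_sid += [s["sample_id"].iloc[0]] * int(keep.sum())
                rows_tis += [tissue] * int(keep.sum())
        comp = subset_composition(rows_lab, rows_sid, rows_tis)
        res = compare_composition(comp)
        assert res.loc["CAF-S3", "p"] < 0.05
        assert res.loc["CAF-S3", "mean_ncl"] > res.loc["CAF-S3", "mean_tumour"]
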