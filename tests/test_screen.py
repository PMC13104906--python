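"""Signatures, embedding/clustering, dose-response, interactions, subtypes."""

import numpy as np
import pandas as pd
import pytest

from archscreen.screen import (
    build_signatures,
    cluster_loci,
    cross_context_correlation,
    dose_response,
    embed_and_cluster,
    interaction,
    subtype_cells,
)


def make_sheet(conditions, reps=2, extra=None):
    rows = []
    for cond in conditions:
        for r in range(reps):
            row = {
                "sample_id": f"{cond}_r{r}", "condition": cond,
                "compound": cond, "dose": 1.0, "time": 24.0,
                "is_vehicle": cond == "vehicle",
            }
            if extra:
                row.update(extra.get(cond, {}))
            rows.append(row)
    return pd.DataFrame(rows)


def make_profiles(sheet, means, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = {}
    for _, r in sheet.iterrows():
        mu = np.asarray(means[r["condition"]], dtype=float)
        rows[r["sample_id"]] = mu + rng.normal(0, noise, size=mu.size)
    return pd.DataFrame.from_dict(rows, orient="index")


class TestSignatures:
    def test_vehicle_signature_is_zero(self):
        sheet = make_sheet(["vehicle", "drug"])
        base = np.linspace(0.01, 0.02, 30)
        profiles = make_profiles(sheet, {"vehicle": base, "drug": base + 0.004})
        sig = build_signatures(profiles, sheet)
        assert np.allclose(sig.centroids.loc["vehicle"], 0.0)
        assert np.allclose(sig.centroids.loc["drug"], 0.004)

    def test_centroid_of_identical_replicates(self):
        sheet = make_sheet(["vehicle", "drug"], reps=4)
        base = np.full(20, 0.017)
        profiles = make_profiles(sheet, {"vehicle": base, "drug": base + 0.002})
        sig = build_signatures(profiles, sheet)
        one_rep = sig.replicates.loc["drug_r0"]
        assert np.allclose(sig.centroids.loc["drug"], one_rep)

    def test_missing_vehicle_rejected(self):
        sheet = make_sheet(["drug"])
        profiles = make_profiles(sheet, {"drug": np.full(10, 0.017)})
        with pytest.raises(ValueError):
            build_signatures(profiles, sheet)


class TestEmbedAndCluster:
    def planted_signatures(self, seed=0):
        rng = np.random.default_rng(seed)
        base = np.zeros(60)
        rows = {}
        for i in range(3):
            v = base.copy(); v[:20] = 0.004 * (i + 1)
            rows[f"modeA_{i}"] = v + rng.normal(0, 2e-4, 60)
        for i in range(3):
            v = base.copy(); v[30:50] = -0.004 * (i + 1)
            rows[f"modeB_{i}"] = v + rng.normal(0, 2e-4, 60)
        return pd.DataFrame.from_dict(rows, orient="index")

    def test_two_planted_modes_separate(self):
        from sklearn.metrics import rand_score

        for seed in range(5):
            sig = self.planted_signatures(seed)
            emb = embed_and_cluster(sig, n_clusters=2, seed=seed, run_umap=False)
            truth = [0, 0, 0, 1, 1, 1]
            assert rand_score(truth, emb.labels) > 0.95

    def test_duplicated_condition_merges_first(self):
        sig = self.planted_signatures()
        dup = pd.concat([sig, sig.iloc[[0]].rename(index={"modeA_0": "dup"})])
        emb = embed_and_cluster(dup, n_clusters=2, run_umap=False)
        first = emb.linkage[0]
        names = list(dup.index)
        merged = {names[int(first[0])], names[int(first[1])]}
        assert merged == {"modeA_0", "dup"}

    def test_explained_variance_nonincreasing(self):
        emb = embed_and_cluster(self.planted_signatures(), run_umap=False)
        assert np.all(np.diff(emb.explained_variance_ratio) <= 1e-12)

    def test_constant_matrix_rejected(self):
        sig = pd.DataFrame(np.zeros((4, 10)))
        with pytest.raises(ValueError):
            embed_and_cluster(sig, run_umap=False)

    def test_seeded_umap_reproducible(self):
        sig = self.planted_signatures()
        a = embed_and_cluster(sig, seed=3)
        b = embed_and_cluster(sig, seed=3)
        assert np.array_equal(a.umap, b.umap)
        assert np.array_equal(a.labels, b.labels)


class TestNewickExport:
    def test_linkage_round_trips_leaf_names(self):
        from archscreen.screen import linkage_to_newick

        sig = TestEmbedAndCluster().planted_signatures()
        emb = embed_and_cluster(sig, n_clusters=2, run_umap=False)
        nwk = linkage_to_newick(emb.linkage, sig.index)
        assert nwk.endswith(";")
        for name in sig.index:
            assert name in nwk
        # parses as a tree with the right number of leaves
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert tree.count_terminals() == len(sig.index)


class TestClusterLoci:
    def test_three_planted_trajectories(self):
        rng = np.random.default_rng(0)
        patterns = np.array([[1.0, 0.0, -1.0], [0.0, 1.0, 0.0], [-1.0, -1.0, 1.0]])
        truth = np.repeat([0, 1, 2], 30)
        for seed in range(10):
            mat = patterns[truth] * 0.004 + rng.normal(0, 4e-4, size=(90, 3))
            labels, means = cluster_loci(mat, k=3, seed=seed)
            # map clusters to majority truth and score
            acc = 0
            for k in range(3):
                members = truth[labels == k]
                if members.size:
                    acc += np.max(np.bincount(members, minlength=3))
            assert acc / 90 >= 0.95

    def test_k1_returns_global_mean(self):
        mat = np.random.default_rng(1).normal(size=(10, 4))
        labels, means = cluster_loci(mat, k=1, seed=0)
        assert np.all(labels == 0)
        assert np.allclose(means[0], mat.mean(axis=0))

    def test_identical_loci_single_populated_cluster(self):
        mat = np.tile([0.1, 0.2, 0.3], (8, 1))
        labels, _ = cluster_loci(mat, k=2, seed=0)
        assert len(set(labels)) == 1

    def test_k_exceeding_loci_rejected(self):
        with pytest.raises(ValueError):
            cluster_loci(np.zeros((3, 2)), k=5)


class TestDoseResponse:
    def make_dose_table(self, doses, effect_per_dose, reps=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for r in range(reps):
            rows.append({"sample_id": f"v{r}", "condition": "vehicle",
                         "compound": "vehicle", "dose": 0.0,
                         "intermingling": 0.05 + rng.normal(0, 1e-3)})
        for d, eff in zip(doses, effect_per_dose):
            for r in range(reps):
                rows.append({"sample_id": f"d{d}_{r}", "condition": f"drug@{d}",
                             "compound": "drug", "dose": d,
                             "intermingling": 0.05 + eff + rng.normal(0, 1e-3)})
        return pd.DataFrame(rows).set_index("sample_id")

    def dummy_signatures(self, tbl):
        from archscreen.screen import TreatmentSignatures

        conds = tbl["condition"].unique()
        cents = pd.DataFrame(np.zeros((len(conds), 5)), index=conds)
        return TreatmentSignatures(cents, cents, None, None)

    def test_monotone_grid_unflagged(self):
        tbl = self.make_dose_table([1, 10, 100], [0.01, 0.02, 0.04])
        res = dose_response(tbl, self.dummy_signatures(tbl), "drug",
                            attributes=["intermingling"])
        assert not res["sign_switch"].any()
        changes = res.sort_values("dose")["change"].to_numpy()
        assert np.all(np.diff(changes) > 0)

    def test_sign_switch_flagged(self):
        tbl = self.make_dose_table([1, 10, 100], [0.01, -0.02, 0.04])
        res = dose_response(tbl, self.dummy_signatures(tbl), "drug",
                            attributes=["intermingling"])
        assert res["sign_switch"].all()

    def test_single_dose_rejected(self):
        tbl = self.make_dose_table([1], [0.01])
        with pytest.raises(ValueError):
            dose_response(tbl, self.dummy_signatures(tbl), "drug")

    def test_sem_shrinks_with_replicates(self):
        sems = []
        for reps in (4, 16):
            tbl = self.make_dose_table([1, 10], [0.01, 0.02], reps=reps, seed=2)
            res = dose_response(tbl, self.dummy_signatures(tbl), "drug",
                                attributes=["intermingling"])
            sems.append(res["sem"].mean())
        assert sems[1] < sems[0] * 0.75


class TestInteraction:
    def test_exact_additive(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=40), rng.normal(size=40)
        res = interaction(a, b, a + b)
        assert res["residual_norm"] == 0.0
        assert res["labels"] == ["additive"]

    def test_amplified_combination_is_potentiation(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=40), rng.normal(size=40)
        res = interaction(a, b, 2 * (a + b))
        assert "potentiation" in res["labels"]

    def test_weak_combination_is_antagonism(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=40), rng.normal(size=40)
        res = interaction(a, b, 0.1 * a)
        assert "antagonism" in res["labels"]

    def test_orthogonal_emergent_axis_detected(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=40), rng.normal(size=40)
        axis = rng.normal(size=40)
        axis -= axis @ (a + b) / np.sum((a + b) ** 2) * (a + b)
        axis /= np.linalg.norm(axis)
        res = interaction(a, b, a + b + 3.0 * axis, pc_axes=axis[None, :])
        assert "emergence" in res["labels"]
        assert abs(res["residual_pc_cosine"][0]) > 0.9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            interaction(np.zeros(3), np.zeros(3), np.zeros(4))


class TestSubtypes:
    def make_cells(self, n_per=30, sep=0.004, seed=0):
        rng = np.random.default_rng(seed)
        t1 = np.full(50, 0.015)
        t2 = t1.copy(); t2[:25] += sep
        cells = {}
        truth = []
        for i in range(n_per):
            cells[f"c1_{i}"] = t1 + rng.normal(0, 5e-4, 50)
            truth.append(0)
        for i in range(n_per):
            cells[f"c2_{i}"] = t2 + rng.normal(0, 5e-4, 50)
            truth.append(1)
        return pd.DataFrame.from_dict(cells, orient="index"), np.array(truth)

    def test_two_template_recovery(self):
        profiles, truth = self.make_cells()
        emb, _, _ = subtype_cells(profiles, seed=0, run_umap=False)
        acc = max(np.mean(emb.labels == truth), np.mean(emb.labels != truth))
        assert acc > 0.95

    def test_single_template_abundance_shift_null(self):
        pvals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            profiles, _ = self.make_cells(sep=0.0, seed=seed)
            treatment = pd.Series(
                rng.permutation(["veh"] * 30 + ["drug"] * 30),
                index=profiles.index,
            )
            _, _, p = subtype_cells(
                profiles, seed=seed, treatment=treatment, run_umap=False
            )
            pvals.append(p)
        assert np.min(pvals) > 0.001  # no systematic abundance artifact

    def test_too_few_cells_rejected(self):
        profiles, _ = self.make_cells(n_per=5)
        with pytest.raises(ValueError):
            subtype_cells(profiles.iloc[:10], run_umap=False)


class TestCrossContext:
    def test_identical_vectors(self):
        v = np.linspace(-1, 1, 50)
        r, n, p = cross_context_correlation(v, v)
        assert r == pytest.approx(1.0) and n == 50

    def test_negated_vector(self):
        v = np.linspace(-1, 1, 50)
        r, _, _ = cross_context_correlation(v, -v)
        assert r == pytest.approx(-1.0)

    def test_independent_vectors_uncorrelated(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            r, _, _ = cross_context_correlation(
                rng.normal(size=500), rng.normal(size=500)
            )
            hits += abs(r) < 0.15
        assert hits >= 9

    def test_too_few_shared_loci_rejected(self):
        a = np.full(20, np.nan); a[:5] = 1.0
        with pytest.raises(ValueError):
            cross_context_correlation(a, a)
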