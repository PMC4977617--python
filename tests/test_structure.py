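import numpy as np
import pytest

import phenodiv as pv
from phenodiv.structure import StructureRun, best_k

from conftest import make_records


@pytest.fixture(scope="module")
def strong_two_clump(catalog):
    """Admixed panel with near-pure ancestries and strongly diverged clusters."""
    spec = pv.odisha_like_spec(n=60, seed=11, with_groups=False, catalog=catalog)
    tm, true_q, true_p = pv.simulate_admixed(
        spec, pv.AdmixtureSpec(k=2, alpha=0.05, divergence=10.0, seed=11)
    )
    return tm, true_q, true_p


def fake_run(k, lnp):
    return StructureRun(
        k=k, ids=[], trait_keys=[], q=np.zeros((0, k)), p={}, ln_p_data=lnp,
        alpha=1.0, burn_in=1, reps=1, seed=None, trace=np.zeros(2),
    )


class TestFit:
    def test_k1_gives_unit_ancestry_and_observed_frequencies(self, toy_catalog):
        rows = [
            {"COL": "Red", "SHP": "Round", "SIZ": "Small"},
            {"COL": "Red", "SHP": "Oval", "SIZ": "Small"},
            {"COL": "Blue", "SHP": "Round", "SIZ": "Small"},
            {"COL": "Red", "SHP": "Round", "SIZ": "Large"},
        ]
        tm = make_records(toy_catalog, rows)
        run = pv.fit_structure(tm, 1, burn_in=200, reps=800, seed=0)
        assert np.allclose(run.q, 1.0)
        ft = pv.frequencies(tm)
        for t in toy_catalog.traits:
            # posterior mean under Dirichlet(1) prior: (count + 1) / (n + S)
            counts = ft.p[t.key] * ft.n[t.key]
            smoothed = (counts + 1) / (ft.n[t.key] + t.n_states)
            assert np.allclose(run.p[t.key][0], smoothed, atol=0.05)

    def test_rows_stochastic(self, strong_two_clump):
        tm, _, _ = strong_two_clump
        run = pv.fit_structure(tm, 3, burn_in=100, reps=200, seed=1)
        assert np.allclose(run.q.sum(axis=1), 1.0, atol=1e-9)
        for key in run.p:
            assert np.allclose(run.p[key].sum(axis=1), 1.0, atol=1e-9)

    def test_recovery_with_matched_prior(self, strong_two_clump):
        """Fitting with the generating ancestry concentration recovers the
        true memberships closely: >=90 % correct hard assignment, Q MAE <= 0.1."""
        tm, true_q, _ = strong_two_clump
        run = pv.fit_structure(tm, 2, alpha=0.05, burn_in=500, reps=1500, seed=3)
        order = pv.align_clusters(run.q, true_q)
        q = run.q[:, order]
        acc = (q.argmax(1) == true_q.argmax(1)).mean()
        assert acc >= 0.90
        assert np.abs(q - true_q).mean() <= 0.10

    def test_label_switching_between_seeds(self, strong_two_clump):
        pytest.importorskip("sklearn")
        from sklearn.metrics import adjusted_rand_score

        tm, _, _ = strong_two_clump
        r1 = pv.fit_structure(tm, 2, burn_in=300, reps=900, seed=5)
        r2 = pv.fit_structure(tm, 2, burn_in=300, reps=900, seed=6)
        ari = adjusted_rand_score(r1.q.argmax(1), r2.q.argmax(1))
        assert ari >= 0.9

    def test_loglik_trace_stabilizes(self, strong_two_clump):
        tm, _, _ = strong_two_clump
        run = pv.fit_structure(tm, 2, burn_in=500, reps=2000, seed=7)
        post = run.trace[run.burn_in:]
        q3 = post[len(post) // 2: 3 * len(post) // 4]
        q4 = post[3 * len(post) // 4:]
        assert abs(q4.mean() - q3.mean()) <= 2 * post.std()

    def test_invalid_arguments(self, strong_two_clump):
        tm, _, _ = strong_two_clump
        with pytest.raises(ValueError):
            pv.fit_structure(tm, 0, seed=0)
        with pytest.raises(ValueError):
            pv.fit_structure(tm, 2, alpha=0.0, seed=0)


class TestEvanno:
    def test_constructed_kink_at_two(self):
        runs = []
        means = {1: -1000.0, 2: -500.0, 3: -480.0, 4: -470.0}
        for k, m in means.items():
            for d in (-1.0, 1.0):
                runs.append(fake_run(k, m + d))
        table = pv.evanno(runs)
        assert best_k(table) == 2
        # |L''(2)| = |-480 - 2(-500) + (-1000)| = 480
        row = table.loc[table["K"] == 2].iloc[0]
        assert row["Lsecond"] == pytest.approx(480.0)

    def test_zero_sd_reported_missing(self):
        runs = [fake_run(k, v) for k in (1, 2, 3) for v in (-100.0 - k, -100.0 - k)]
        table = pv.evanno(runs)
        assert np.isnan(table.loc[table["K"] == 2, "deltaK"]).all()

    def test_flat_lnp_still_returns_table(self):
        runs = [fake_run(k, -50.0 + 0.01 * i) for k in (1, 2, 3) for i in (0, 1)]
        table = pv.evanno(runs)
        assert len(table) == 3
        assert np.isfinite(table.loc[table["K"] == 2, "Lsecond"]).all()

    def test_requires_consecutive_ks_and_replicates(self):
        with pytest.raises(ValueError):
            pv.evanno([fake_run(1, -1.0), fake_run(1, -2.0), fake_run(3, -1.0),
                       fake_run(3, -2.0)])
        with pytest.raises(ValueError):
            pv.evanno([fake_run(k, -1.0) for k in (1, 2, 3)])


class TestAssign:
    def make_run(self, q):
        q = np.asarray(q, dtype=float)
        return StructureRun(
            k=q.shape[1], ids=[f"A{i}" for i in range(len(q))], trait_keys=[],
            q=q, p={}, ln_p_data=0.0, alpha=1.0, burn_in=1, reps=1, seed=None,
            trace=np.zeros(2),
        )

    def test_clear_and_admixed_rows(self):
        ass = pv.assign(self.make_run([[0.95, 0.05], [0.6, 0.4], [0.2, 0.8]]))
        assert list(ass.table["status"]) == ["assigned", "admixed", "admixed"]
        assert list(ass.table["cluster"]) == [1, 1, 2]

    def test_boundary_is_admixed(self):
        ass = pv.assign(self.make_run([[0.8, 0.2]]))
        assert ass.table["status"].iloc[0] == "admixed"

    def test_shares_are_mean_memberships(self):
        run = self.make_run([[0.9, 0.1], [0.7, 0.3]])
        ass = pv.assign(run)
        assert np.allclose(ass.shares, [0.8, 0.2])

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            pv.assign(self.make_run([[1.0]]), threshold=1.5)

    def test_admixed_counts_match_thresholding(self, strong_two_clump):
        tm, _, _ = strong_two_clump
        run = pv.fit_structure(tm, 2, burn_in=200, reps=600, seed=9)
        ass = pv.assign(run)
        assert len(ass.admixed_ids) == int((run.q.max(axis=1) <= 0.80).sum())


class TestClusterFst:
    def test_disjoint_clusters_give_one(self, toy_catalog):
        a = {"COL": "Red", "SHP": "Round", "SIZ": "Small"}
        b = {"COL": "Blue", "SHP": "Oval", "SIZ": "Large"}
        tm = make_records(toy_catalog, [a] * 3 + [b] * 3)
        q = np.array([[1.0, 0.0]] * 3 + [[0.0, 1.0]] * 3)
        run = StructureRun(
            k=2, ids=tm.ids, trait_keys=toy_catalog.trait_keys, q=q, p={},
            ln_p_data=0.0, alpha=1.0, burn_in=1, reps=1, seed=None, trace=np.zeros(2),
        )
        fst = pv.cluster_fst(tm, pv.assign(run))
        assert fst[1] == pytest.approx(1.0)
        assert fst[2] == pytest.approx(1.0)

    def test_agrees_with_amova_phi(self, strong_two_clump):
        tm, true_q, _ = strong_two_clump
        run = pv.fit_structure(tm, 2, burn_in=200, reps=600, seed=10)
        ass = pv.assign(run)
        fst = pv.cluster_fst(tm, ass)
        tab = ass.table
        members = set(tab.loc[(tab["cluster"] == 1) & (tab["status"] == "assigned"),
                              "accession_id"])
        labels = ["in" if i in members else "out" for i in tm.ids]
        ref = pv.amova(pv.encode_binary(tm), groups=labels, n_permutations=0)
        assert fst[1] == pytest.approx(ref.phi_st, abs=1e-12)
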