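import numpy as np
import pytest
from scipy import stats

from paleobite.microwear import (FEATURE_NAMES, MicrowearCounts,
                                 MicrowearDietClassifier, PCoA, classify_diet,
                                 intra_observer_error, microwear_distance,
                                 normalize_counts, pcoa)
from paleobite.simulate import (default_guild_concentrations,
                                simulate_microwear_guilds)


def counts(values, **kw):
    kw.setdefault("specimen_id", "s1")
    return MicrowearCounts(counts=np.asarray(values, float), **kw)


@pytest.fixture
def guild_profiles():
    return [normalize_counts(c)
            for c in simulate_microwear_guilds(n_per_guild=8, seed=21)]


class TestNormalize:
    def test_equal_counts(self):
        p = normalize_counts(counts([4] * 9))
        assert p.percentages == pytest.approx(np.full(9, 100 / 9))

    def test_single_feature(self):
        p = normalize_counts(counts([9] + [0] * 8))
        assert p.percentages[0] == 100.0
        assert p.percentages[1:] == pytest.approx(np.zeros(8))

    def test_sums_to_100(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = normalize_counts(counts(rng.integers(0, 30, 9)
                                        + np.eye(9)[0]))
            assert p.percentages.sum() == pytest.approx(100.0)

    def test_zero_total_unanalysable(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_counts(counts([0] * 9))

    def test_damaged_specimen_excluded(self):
        with pytest.raises(ValueError, match="damaged"):
            normalize_counts(counts([5] * 9, damaged=True))


class TestDistance:
    def test_identical_profiles_zero(self):
        p = normalize_counts(counts([3, 1, 4, 1, 5, 9, 2, 6, 5]))
        D = microwear_distance([p, p], metric="bray-curtis")
        assert D[0, 1] == pytest.approx(0.0)

    def test_disjoint_support_braycurtis_one(self):
        a = normalize_counts(counts([10, 0, 0, 0, 0, 0, 0, 0, 0]))
        b = normalize_counts(counts([0, 10, 0, 0, 0, 0, 0, 0, 0]))
        D = microwear_distance([a, b])
        assert D[0, 1] == pytest.approx(1.0)

    def test_euclidean_matches_direct_computation(self, guild_profiles):
        D = microwear_distance(guild_profiles, metric="euclidean")
        X = np.vstack([p.percentages for p in guild_profiles])
        for i in range(0, len(X), 7):
            for j in range(0, len(X), 5):
                assert D[i, j] == pytest.approx(
                    np.linalg.norm(X[i] - X[j]))

    def test_symmetry_zero_diagonal_and_range(self, guild_profiles):
        D = microwear_distance(guild_profiles)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert (D >= 0).all() and (D <= 1.0 + 1e-12).all()

    def test_unknown_metric(self, guild_profiles):
        with pytest.raises(ValueError):
            microwear_distance(guild_profiles, metric="manhattan")

    def test_scaling_invariance_of_pipeline(self):
        """Multiplying raw counts by a constant changes nothing downstream."""
        rng = np.random.default_rng(8)
        raw = rng.integers(1, 40, (6, 9))
        p1 = [normalize_counts(counts(r)) for r in raw]
        p2 = [normalize_counts(counts(r * 7)) for r in raw]
        assert np.allclose(microwear_distance(p1), microwear_distance(p2))


class TestPcoa:
    def test_matches_pca_scores_for_euclidean_input(self):
        rng = np.random.default_rng(0)
        X = rng.dirichlet(np.ones(9), 20) * 100
        from scipy.spatial.distance import pdist, squareform
        res = pcoa(squareform(pdist(X)))
        Xc = X - X.mean(axis=0)
        u, s, _ = np.linalg.svd(Xc, full_matrices=False)
        scores = u * s
        for i in range(min(res.coordinates.shape[1], int((s > 1e-8).sum()))):
            diff = min(np.abs(res.coordinates[:, i] - scores[:, i]).max(),
                       np.abs(res.coordinates[:, i] + scores[:, i]).max())
            assert diff < 1e-8

    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [2.0], [5.0]])
        D = np.abs(pts - pts.T)
        res = pcoa(D)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_positive_eigenvalue_sum_equals_centered_ss(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 4))
        from scipy.spatial.distance import pdist, squareform
        res = pcoa(squareform(pdist(X)))
        Xc = X - X.mean(axis=0)
        assert res.eigenvalues[res.eigenvalues > 1e-9].sum() == \
            pytest.approx((Xc**2).sum())

    def test_distances_reproduced_when_euclidean(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 3))
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(X))
        res = pcoa(D)
        D2 = squareform(pdist(res.coordinates))
        assert np.allclose(D, D2, atol=1e-8)

    def test_asymmetric_input_rejected(self):
        D = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            pcoa(D)

    def test_matches_skbio_reference(self, guild_profiles):
        """Independent cross-check against scikit-bio's PCoA on the same
        Bray-Curtis matrix (eigenvalues and axis-wise coordinates)."""
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        D = microwear_distance(guild_profiles)
        mine = pcoa(D)
        theirs = skbio_pcoa(D)
        ev = theirs.eigvals.to_numpy()
        k = min(5, mine.coordinates.shape[1])
        assert mine.eigenvalues[:k] == pytest.approx(ev[:k], abs=1e-8)
        for i in range(k):
            a, b = mine.coordinates[:, i], theirs.samples.to_numpy()[:, i]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-6

    def test_projection_reproduces_training_coordinates(self, guild_profiles):
        D = microwear_distance(guild_profiles)
        model = PCoA().fit(D)
        proj = model.transform(D)
        assert np.allclose(proj, model.coordinates_, atol=1e-6)


class TestIntraObserver:
    def vectors(self, n=12, seed=4):
        rng = np.random.default_rng(seed)
        first = rng.integers(0, 25, (n, 9)) + 1
        return first

    def test_identical_recounts_rho_one(self):
        first = self.vectors()
        rep = intra_observer_error(first, first)
        assert rep["total_features"]["rho"] == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        totals = np.arange(1, 11)
        first = np.tile(totals[:, None], (1, 9))
        second = first[::-1]
        rep = intra_observer_error(first, second)
        assert rep["total_features"]["rho"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self):
        rng = np.random.default_rng(11)
        first = rng.integers(0, 30, (15, 9))
        second = first + rng.integers(-3, 4, (15, 9))
        rep = intra_observer_error(first, second)
        a, b = first.sum(axis=1), second.sum(axis=1)
        expect = np.corrcoef(stats.rankdata(a), stats.rankdata(b))[0, 1]
        assert rep["total_features"]["rho"] == pytest.approx(expect)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            intra_observer_error(self.vectors(12), self.vectors(10))


class TestClassifier:
    def test_identical_query_nearest_at_zero(self, guild_profiles):
        r = classify_diet(guild_profiles[0], guild_profiles, k=3)
        assert r["neighbours"][0]["specimen_id"] == \
            guild_profiles[0].specimen_id
        assert r["neighbours"][0]["distance"] == pytest.approx(0.0, abs=1e-9)

    def test_k_too_large_rejected(self, guild_profiles):
        with pytest.raises(ValueError):
            MicrowearDietClassifier(k=200).fit(guild_profiles)

    def test_tie_reported_not_dropped(self):
        # two references, one from each guild: k=2 vote must tie
        a = normalize_counts(counts([10, 0, 0, 0, 0, 0, 0, 0, 0],
                                    diet_category="carnivory",
                                    specimen_id="a"))
        b = normalize_counts(counts([0, 0, 0, 0, 10, 0, 0, 0, 0],
                                    diet_category="herbivory",
                                    specimen_id="b"))
        q = normalize_counts(counts([5, 0, 0, 0, 5, 0, 0, 0, 0],
                                    specimen_id="q"))
        r = classify_diet(q, [a, b], k=2)
        assert r["tie"]
        assert set(r["predicted"]) == {"carnivory", "herbivory"}

    def test_well_separated_guild_centroid_wins(self):
        cons = {
            "carnivory": np.array([30, 20, 30, 30, 2, 2, 2, 2, 2], float),
            "herbivory": np.array([2, 2, 2, 2, 30, 30, 30, 20, 10], float),
        }
        refs = [normalize_counts(c) for c in simulate_microwear_guilds(
            n_per_guild=10, concentrations=cons, concentration_scale=5.0,
            seed=2)]
        carn = [p.percentages for p in refs
                if p.diet_category == "carnivory"]
        centroid = np.mean(carn, axis=0)
        centroid = centroid / centroid.sum() * 100
        q = type(refs[0])(specimen_id="q", percentages=centroid)
        r = classify_diet(q, refs, k=5)
        assert r["predicted"] == ["carnivory"]

    def test_loo_accuracy_beats_no_information_rate(self, guild_profiles):
        labels = [p.diet_category for p in guild_profiles]
        hits = 0
        for i, q in enumerate(guild_profiles):
            refs = guild_profiles[:i] + guild_profiles[i + 1:]
            r = classify_diet(q, refs, k=5)
            hits += labels[i] in r["predicted"]
        accuracy = hits / len(guild_profiles)
        nir = max(labels.count(l) for l in set(labels)) / len(labels)
        assert accuracy > nir

    def test_axis1_separates_pit_vs_scratch_guilds(self):
        """Carnivores (pit-heavy) and herbivores (scratch-heavy) occupy
        opposite ends of the first ordination axis."""
        refs = [normalize_counts(c) for c in simulate_microwear_guilds(
            n_per_guild=10, concentration_scale=4.0, seed=6)]
        clf = MicrowearDietClassifier(k=3).fit(refs)
        axis1 = clf.ordination_.coordinates_[:, 0]
        carn = axis1[clf.labels_ == "carnivory"].mean()
        herb = axis1[clf.labels_ == "herbivory"].mean()
        omni = axis1[clf.labels_ == "omnivory"].mean()
        assert (carn < omni < herb) or (herb < omni < carn)
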