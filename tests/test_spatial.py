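import numpy as np
import pytest

from ovismt.spatial import (
    DistanceClassSpec,
    _class_r,
    _double_center,
    autocorrelogram,
    genetic_distance_matrix,
    geographic_distances,
)
from ovismt.synthetic import ClineSpec, gen_spatial_panel


def _quiet_correlogram(*args, **kwargs):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return autocorrelogram(*args, **kwargs)


class TestGeneticDistance:
    def test_all_same_zero_matrix(self):
        d2 = genetic_distance_matrix(["A"] * 4)
        assert (d2 == 0).all()

    def test_two_labels_unit_distance(self):
        d2 = genetic_distance_matrix(["A", "B"])
        assert d2[0, 1] == 1.0 and d2[0, 0] == 0.0

    def test_triangle_counts(self):
        d2 = genetic_distance_matrix(["A", "A", "B"])
        iu = np.triu_indices(3, 1)
        assert d2[iu].sum() == 2.0  # exactly two unit entries per triangle

    def test_unassigned_rejected(self):
        with pytest.raises(ValueError, match="unassigned"):
            genetic_distance_matrix(["A", "unassigned"])


class TestGeography:
    def test_haversine_known_distance(self):
        # Ankara (39.93N, 32.86E) to Istanbul (41.01N, 28.98E): ~350 km
        d = geographic_distances(
            np.array([[39.93, 32.86], [41.01, 28.98]]), "great_circle"
        )
        assert 340 < d[0, 1] < 365

    def test_planar_euclidean(self):
        d = geographic_distances(np.array([[0.0, 0.0], [3.0, 4.0]]), "planar")
        assert d[0, 1] == pytest.approx(5.0)


class TestCorrelogram:
    def test_double_centering_row_sums_zero(self):
        rng = np.random.default_rng(0)
        lab = rng.choice(["A", "B", "C"], 20)
        C = _double_center(genetic_distance_matrix(lab))
        assert np.abs(C.sum(axis=0)).max() < 1e-9

    def test_two_deme_closed_form(self):
        """Two demes fixed for different haplogroups: r=1 within demes and
        r=-1 between (hand-verifiable on n=4: c_ij = -(d2_ij - 0.5)/2)."""
        labels = ["A", "A", "B", "B"]
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1000.0, 0.0], [1000.0, 0.0]])
        spec = DistanceClassSpec(class_width_km=150.0, n_classes=14, metric="planar")
        res = _quiet_correlogram(
            genetic_distance_matrix(labels), coords, spec, n_perm=99, n_boot=100, seed=0
        )
        assert res.r[0] == pytest.approx(1.0)  # within-deme class
        assert res.r[6] == pytest.approx(-1.0)  # the 900-1050 km class
        assert np.isnan(res.r[3])  # no pairs at intermediate distances

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        lab = rng.choice(["A", "B", "C"], 30)
        coords = rng.uniform(0, 1000, size=(30, 2))
        spec = DistanceClassSpec(150.0, 8, "planar")
        swap = {"A": "E", "B": "X", "C": "D"}
        r1 = _quiet_correlogram(
            genetic_distance_matrix(lab), coords, spec, 99, 100, seed=1
        ).r
        r2 = _quiet_correlogram(
            genetic_distance_matrix([swap[x] for x in lab]),
            coords,
            spec,
            99,
            100,
            seed=1,
        ).r
        np.testing.assert_allclose(r1, r2)

    def test_null_panel_r_inside_belt(self):
        """Random labels over locations: r stays inside the permutation
        belt in nearly all classes (averaged over seeds)."""
        inside = total = 0
        for s in range(25):
            df = gen_spatial_panel(10, 6, cline=None, seed=s)
            spec = DistanceClassSpec(150.0, 10, "planar")
            res = _quiet_correlogram(
                genetic_distance_matrix(df["haplogroup"].tolist()),
                df[["x_km", "y_km"]].to_numpy(),
                spec,
                n_perm=199,
                n_boot=100,
                seed=1000 + s,
            )
            ok = ~np.isnan(res.r)
            total += ok.sum()
            inside += (
                (res.r[ok] >= res.belt_lo[ok]) & (res.r[ok] <= res.belt_hi[ok])
            ).sum()
        assert inside / total > 0.9

    def test_cline_signal_shortest_class(self):
        """A strong west-east cline: the shortest-distance class shows
        positive autocorrelation above the belt at p <= 0.001."""
        df = gen_spatial_panel(
            24, 12, cline=ClineSpec("B", 0.85, 0.05), extent_km=1800.0, seed=3
        )
        spec = DistanceClassSpec(150.0, 12, "planar")
        res = autocorrelogram(
            genetic_distance_matrix(df["haplogroup"].tolist()),
            df[["x_km", "y_km"]].to_numpy(),
            spec,
            n_perm=999,
            n_boot=1000,
            seed=5,
        )
        assert res.r[0] > res.belt_hi[0]
        assert res.p[0] <= 0.002  # 2/(999+1): the equal-tail floor

    def test_zero_variance_rejected(self):
        coords = np.zeros((4, 2))
        with pytest.raises(ValueError, match="variance"):
            _quiet_correlogram(np.zeros((4, 4)), coords, None, 99, 100, 0)

    def test_permutation_p_validity(self):
        """Under the null, P(p <= alpha) <= alpha + 0.02 (valid, possibly
        conservative, permutation p-values)."""
        alphas = {0.05: 0, 0.001: 0}
        n_seeds = 200
        spec = DistanceClassSpec(150.0, 6, "planar")
        for s in range(n_seeds):
            df = gen_spatial_panel(8, 5, cline=None, seed=5000 + s)
            res = _quiet_correlogram(
                genetic_distance_matrix(df["haplogroup"].tolist()),
                df[["x_km", "y_km"]].to_numpy(),
                spec,
                n_perm=199,
                n_boot=0 + 100,
                seed=6000 + s,
            )
            p0 = res.p[0]  # first class always has within-flock pairs
            for a in alphas:
                if p0 <= a:
                    alphas[a] += 1
        for a, hits in alphas.items():
            assert hits / n_seeds <= a + 0.02
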