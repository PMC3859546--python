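import numpy as np
import pytest

from ovismt import coalescent as coal
from ovismt.coalescent import DemographySpec, sim_summary
from ovismt.diversity import pairwise_diff_matrix
from ovismt.synthetic import (
    ClineSpec,
    HaplogroupSpec,
    default_panel_specs,
    gen_coalescent,
    gen_haplogroup_panel,
    gen_spatial_panel,
    synthetic_reference,
)


class TestPanelGenerator:
    def test_same_seed_identical(self):
        specs = default_panel_specs()
        a = gen_haplogroup_panel(specs, 20, seed=3)
        b = gen_haplogroup_panel(specs, 20, seed=3)
        assert [(r.id, r.residues) for r in a] == [(r.id, r.residues) for r in b]

    def test_duplicate_signature_rejected(self):
        s1 = HaplogroupSpec("A", {15459: "T"}, 75, 0.5)
        s2 = HaplogroupSpec("Z", {15459: "T"}, 76, 0.5)
        with pytest.raises(ValueError, match="signature"):
            gen_haplogroup_panel([s1, s2], 5, seed=0)

    def test_diagnostic_bases_present(self, panel, syn_ref):
        from ovismt.datasets import DIAGNOSTIC_RULES
        from ovismt.synthetic import REF_START

        for rec in panel:
            rule = DIAGNOSTIC_RULES.get(rec.meta["true_hpg"], {})
            if rec.meta["true_hpg"] == "X":
                rule = {15466: "T"}
            for pos, base in rule.items():
                assert rec.residues[pos - REF_START] == base

    def test_cluster_ii_units_are_76(self):
        specs = [HaplogroupSpec("C", {15509: "G"}, 76, 1.0)]
        recs = gen_haplogroup_panel(specs, 10, private_mut_rate=0.0, seed=4)
        ref = synthetic_reference()
        from ovismt.synthetic import REF_START, REPEAT_START

        pre = REPEAT_START - REF_START
        for r in recs:
            n_units = r.meta["n_units"]
            # prefix fixed, first unit 75, later units 76 each
            expected = pre + 75 + (n_units - 1) * 76 + (len(ref) - pre - 4 * 75)
            assert len(r) == expected

    def test_unit_count_range(self, panel):
        assert all(3 <= r.meta["n_units"] <= 5 for r in panel)


class TestCoalescent:
    def test_same_seed_identical(self):
        dem = DemographySpec("constant", 5.0, n=10, L=500)
        a = gen_coalescent(dem, seed=9)
        b = gen_coalescent(dem, seed=9)
        assert [r.residues for r in a] == [r.residues for r in b]

    def test_mean_pairwise_matches_theta(self):
        """Constant-size coalescent: E[pi] = theta."""
        theta, n, reps = 5.0, 50, 2000
        dem = DemographySpec("constant", theta, n=n)
        rng = np.random.default_rng(17)
        vals = np.array([sim_summary(dem, rng)[1] for _ in range(reps)])
        se = vals.std(ddof=1) / np.sqrt(reps)
        assert abs(vals.mean() - theta) < 3 * se

    def test_watterson_expectation(self):
        """Constant-size coalescent: E[S / a1] = theta."""
        theta, n, reps = 5.0, 50, 2000
        a1 = (1.0 / np.arange(1, n)).sum()
        dem = DemographySpec("constant", theta, n=n)
        rng = np.random.default_rng(23)
        vals = np.array([sim_summary(dem, rng)[0] / a1 for _ in range(reps)])
        se = vals.std(ddof=1) / np.sqrt(reps)
        assert abs(vals.mean() - theta) < 3 * se

    def test_sequences_reproduce_branch_counts(self):
        """Sequence realization preserves the genealogy's pairwise counts."""
        dem = DemographySpec("constant", 4.0, n=12, L=2000)
        rng = np.random.default_rng(31)
        gen = coal.drop_mutations(coal.sim_genealogy(dem, rng), rng)
        n = gen.n
        D_tree = np.zeros((n, n), dtype=int)
        for mb, x in zip(gen.mutations, gen.carriers):
            D_tree += int(mb) * (x[:, None] ^ x[None, :])
        seqs = coal.genealogy_sequences(gen, rng, dem.L)
        D_seq, _ = pairwise_diff_matrix(seqs)
        assert (D_seq == D_tree).all()

    def test_too_small_L_raises(self):
        dem = DemographySpec("sudden_expansion", 1.0, 100.0, 10.0, n=20, L=3)
        with pytest.raises(ValueError, match="L"):
            gen_coalescent(dem, seed=0)

    def test_segregating_sites_match_msprime(self):
        """Independent-simulator check on the distribution of S."""
        msprime = pytest.importorskip("msprime")
        theta, n, reps = 5.0, 20, 1000
        dem = DemographySpec("constant", theta, n=n)
        rng = np.random.default_rng(7)
        mine = np.array([sim_summary(dem, rng)[0] for _ in range(reps)])
        # msprime: haploid pop of size 1 => pair coalescence E[T2]=1 gen;
        # per-lineage mutation rate theta/2 reproduces E[pairwise] = theta
        other = np.empty(reps)
        for i, ts in enumerate(
            msprime.sim_ancestry(
                samples=n,
                ploidy=1,
                population_size=1.0,
                sequence_length=1,
                num_replicates=reps,
                random_seed=1234,
            )
        ):
            mts = msprime.sim_mutations(
                ts,
                rate=theta / 2.0,
                random_seed=i + 1,
                discrete_genome=False,
            )
            other[i] = mts.num_sites
        se = np.sqrt(mine.var(ddof=1) / reps + other.var(ddof=1) / reps)
        assert abs(mine.mean() - other.mean()) < 3 * se
        assert abs(mine.std(ddof=1) - other.std(ddof=1)) / other.std(ddof=1) < 0.15


class TestSpatialPanel:
    def test_same_seed_identical(self):
        a = gen_spatial_panel(5, 4, cline=ClineSpec(), seed=2)
        b = gen_spatial_panel(5, 4, cline=ClineSpec(), seed=2)
        assert a.equals(b)

    def test_degenerate_extent_raises(self):
        with pytest.raises(ValueError):
            gen_spatial_panel(5, 4, extent_km=0.0, seed=0)

    def test_null_cline_location_independent(self):
        """No gradient: haplogroup ~ location chi-square non-significant
        at alpha=0.01 in >= 95% of seeds."""
        from scipy.stats import chi2_contingency

        hits = 0
        n_seeds = 100
        for s in range(n_seeds):
            df = gen_spatial_panel(12, 10, cline=None, seed=s)
            df["west"] = df["x_km"] < df["x_km"].median()
            tab = df.groupby(["west", "haplogroup"]).size().unstack(fill_value=0)
            _, p, _, _ = chi2_contingency(tab.to_numpy())
            if p >= 0.01:
                hits += 1
        assert hits >= 95

    def test_cline_moves_frequency(self):
        df = gen_spatial_panel(
            30, 20, cline=ClineSpec("B", west_freq=0.8, east_freq=0.1), seed=5
        )
        west = df[df.x_km < 500]
        east = df[df.x_km > 1000]
        fw = (west.haplogroup == "B").mean()
        fe = (east.haplogroup == "B").mean()
        assert fw > fe + 0.2
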