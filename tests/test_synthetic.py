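import numpy as np
import pytest

from fmtgraft.diversity import shannon
from fmtgraft.experiments import engraftment_recovery
from fmtgraft.profile_io import ValidationError
from fmtgraft.simulate import (
    CohortParams,
    PATHOGEN_SPECIES,
    simulate_baseline_communities,
    simulate_cohort,
    simulate_post_fmt_series,
    simulate_slurry,
    simulate_taxonomy,
    simulate_tree,
)


class TestTree:
    def test_two_taxa_cherry(self):
        tree = simulate_tree(2, seed=0)
        assert tree.count(tips=True) == 2

    def test_binary_tree_arithmetic(self):
        tree = simulate_tree(50, seed=1)
        assert tree.count(tips=True) == 50
        internal = sum(1 for n in tree.non_tips(include_self=True))
        assert internal == 49

    def test_fixed_seed_identical_newick(self):
        a = str(simulate_tree(20, seed=5))
        b = str(simulate_tree(20, seed=5))
        assert a == b

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValidationError):
            simulate_tree(1)

    def test_all_branch_lengths_positive(self):
        tree = simulate_tree(30, seed=2)
        assert all(n.length > 0 for n in tree.traverse(include_self=False))


class TestTaxonomy:
    def test_two_phyla_dominate(self):
        _, lineages = simulate_taxonomy(400, seed=0)
        phyla = [
            next(p[3:] for p in lin.split(";") if p.startswith("p__"))
            for lin in lineages.values()
        ]
        counts = {p: phyla.count(p) for p in set(phyla)}
        top2 = sorted(counts.values(), reverse=True)[:2]
        assert sum(top2) / len(phyla) > 0.6
        assert len(counts) >= 15  # ~20 phyla present

    def test_pathogen_species_included(self):
        feature_ids, lineages = simulate_taxonomy(50, seed=0)
        species = {name for name, _ in PATHOGEN_SPECIES}
        found = {
            part[3:]
            for lin in lineages.values()
            for part in lin.split(";")
            if part.startswith("s__")
        }
        assert species <= found


class TestBaseline:
    def test_dysbiosis_targets_hit_at_depth(self):
        """Sampled pathogen abundances land near their configured targets."""
        params = CohortParams(
            n_taxa=250, depth_mean=5000, depth_dispersion=0.0, drift_rate=0.0, seed=3
        )
        table, records, _ = simulate_baseline_communities(params)
        dysbiotic = "R1"
        col = table.sample_counts(f"{dysbiotic}_B0")
        total = col.sum()
        for i, (_, target) in enumerate(PATHOGEN_SPECIES):
            got = col[i] / total
            assert got == pytest.approx(target, abs=0.03)

    def test_high_concentration_maximizes_evenness(self):
        params = CohortParams(
            n_taxa=100, concentration=1e6, peripheral_carriage=1.0,
            donor_overlap=1.0, dysbiosis_spec={}, seed=4,
        )
        _, _, latents = simulate_baseline_communities(params)
        comp = latents["D1"]
        # all taxa carried, near-equal base means within dominant phyla:
        # Shannon approaches the uniform limit log2(n)
        h = shannon((comp * 1e9).astype(int), log_base=2)
        assert h > 0.9 * np.log2(100)

    def test_zero_drift_keeps_composition_fixed(self):
        params = CohortParams(
            n_taxa=80, drift_rate=0.0, depth_mean=50_000, depth_dispersion=0.0, seed=5
        )
        table, _, latents = simulate_baseline_communities(params)
        comp = latents["D1"]
        for t in range(3):
            col = table.sample_counts(f"D1_B{t}")
            observed = col / col.sum()
            # multinomial noise only: each abundant taxon near its latent value
            big = comp > 0.01
            assert np.allclose(observed[big], comp[big], atol=0.01)

    def test_dysbiosis_targets_above_one_rejected(self):
        with pytest.raises(ValidationError):
            CohortParams(n_taxa=10, dysbiosis_spec={"OGU00000": 0.7, "OGU00001": 0.5})


class TestSlurry:
    def test_single_donor_identity(self):
        profile = {"a": 0.25, "b": 0.75}
        mixture, counts = simulate_slurry([profile], [1.0], depth=1000, seed=0)
        assert mixture == pytest.approx(profile)
        assert sum(counts.values()) == 1000

    def test_disjoint_donors_half_mass_each(self):
        a = {"a1": 0.6, "a2": 0.4}
        b = {"b1": 1.0}
        mixture, _ = simulate_slurry([a, b], [0.5, 0.5], depth=5000, seed=1)
        assert set(mixture) == {"a1", "a2", "b1"}
        assert mixture["a1"] + mixture["a2"] == pytest.approx(0.5)
        assert mixture["b1"] == pytest.approx(0.5)

    def test_latent_mixture_is_weighted_average(self):
        profiles = [{"x": 1.0}, {"x": 0.5, "y": 0.5}, {"y": 1.0}]
        w = [0.3, 0.3, 0.4]
        mixture, _ = simulate_slurry(profiles, w, depth=100, seed=2)
        assert mixture["x"] == pytest.approx(0.3 * 1.0 + 0.3 * 0.5)
        assert mixture["y"] == pytest.approx(0.3 * 0.5 + 0.4 * 1.0)

    def test_weight_validation(self):
        with pytest.raises(ValidationError):
            simulate_slurry([{"a": 1.0}], [0.5, 0.5], depth=10, seed=0)
        with pytest.raises(ValidationError):
            simulate_slurry([{"a": 1.0}, {"b": 1.0}], [0.7, 0.7], depth=10, seed=0)


class TestPostFmtSeries:
    @staticmethod
    def setup_comps(n=40, seed=0):
        rng = np.random.default_rng(seed)
        feature_ids = [f"t{i}" for i in range(n)]
        pre = np.zeros(n)
        pre[: n // 2] = rng.dirichlet(np.ones(n // 2))
        slurry = np.zeros(n)
        slurry[n // 4:] = rng.dirichlet(np.ones(n - n // 4))
        return feature_ids, pre, slurry

    def test_no_events_when_probabilities_zero(self):
        fids, pre, slurry = self.setup_comps()
        params = CohortParams(
            n_taxa=40, n_fmts=1, engraftment_prob=0.0, exclusion_prob=0.0,
            dysbiosis_spec={}, seed=0,
        )
        _, truth = simulate_post_fmt_series(pre, [slurry], params, 0, fids)
        assert truth["1"]["engrafted"] == []
        assert truth["1"]["excluded"] == []

    def test_certain_engraftment(self):
        fids, pre, slurry = self.setup_comps()
        params = CohortParams(
            n_taxa=40, n_fmts=1, engraftment_prob=1.0, exclusion_prob=0.0,
            dysbiosis_spec={}, seed=0,
        )
        _, truth = simulate_post_fmt_series(pre, [slurry], params, 0, fids)
        assert set(truth["1"]["engrafted"]) == set(truth["1"]["introduced"])
        assert len(truth["1"]["introduced"]) == 20  # slurry-only taxa

    def test_slurry_count_mismatch_rejected(self):
        fids, pre, slurry = self.setup_comps()
        params = CohortParams(n_taxa=40, n_fmts=3, dysbiosis_spec={}, seed=0)
        with pytest.raises(ValidationError):
            simulate_post_fmt_series(pre, [slurry], params, 0, fids)


class TestCohort:
    def test_sample_arithmetic_matches_design(self, small_cohort):
        # 7 donors x 3 + 4 recipients x (3+8) + 3 controls x (3+8) + 8 slurries
        assert small_cohort.table.n_samples == 7 * 3 + 4 * 11 + 3 * 11 + 8
        roles = [r.role for r in small_cohort.records]
        assert roles.count("slurry") == 8

    def test_fixed_seed_byte_identical_outputs(self, tmp_path):
        params = CohortParams(n_taxa=60, seed=9)
        simulate_cohort(params, out_dir=tmp_path / "a")
        simulate_cohort(params, out_dir=tmp_path / "b")
        for name in ("table.tsv", "metadata.tsv", "tree.nwk", "lineages.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_refuses_to_overwrite(self, tmp_path):
        params = CohortParams(n_taxa=60, seed=9)
        simulate_cohort(params, out_dir=tmp_path)
        with pytest.raises(FileExistsError):
            simulate_cohort(params, out_dir=tmp_path)
        simulate_cohort(params, out_dir=tmp_path, overwrite=True)

    def test_ground_truth_engrafted_subset_of_introduced(self, small_cohort):
        truth = small_cohort.truth
        for rid, per_fmt in truth.per_recipient.items():
            for fmt, rec in per_fmt.items():
                assert set(rec["engrafted"]) <= set(rec["introduced"])
                assert set(rec["excluded"]) <= set(rec["excludable"])

    def test_donor_overlap_monotonically_reduces_introduced(self):
        means = []
        for overlap in (0.1, 0.4, 0.7):
            params = CohortParams(n_taxa=150, donor_overlap=overlap, seed=13)
            bundle = simulate_cohort(params)
            intro = [
                len(bundle.truth.introduced(rid, 1))
                for rid in bundle.truth.per_recipient
            ]
            means.append(np.mean(intro))
        assert means[0] > means[1] > means[2]


class TestRecovery:
    def test_truth_agreement_at_deep_sequencing(self):
        """Measured engraftment calls match latent truth for >=99% of taxa."""
        res = engraftment_recovery(0.3, n_sims=3, seed=29)
        assert res["agreement"] >= 0.99
        assert res["mean_n_introduced"] >= 500

    def test_estimated_rate_unbiased_over_replicates(self):
        """Mean estimate over 100 simulated cohorts within +/-0.02 of p_e."""
        res = engraftment_recovery(0.3, n_sims=100, seed=31)
        assert abs(res["estimated_rate"] - 0.3) <= 0.02
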