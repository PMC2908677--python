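import math

import numpy as np
import pytest

from puf3regulon.motif import call_targets, compile_profile
from puf3regulon.null_model import estimate_gc
from puf3regulon.simulate import (
    CladeSpec,
    SimulationConfig,
    simulate_expression,
    simulate_fitness,
    simulate_reference,
    simulate_species,
    simulate_study,
    write_bundle,
)


def small_config(**overrides):
    defaults = dict(
        clades=[
            CladeSpec("cladeA", 2, gc=0.38, motif_rate_mito=0.5, wgd="split"),
            CladeSpec("cladeB", 2, gc=0.5, motif_rate_mito=0.1),
        ],
        n_genes=120,
        n_mito=40,
        cds_codons=60,
        n_reference_genes=8,
        n_conditions=30,
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_mito_exceeding_genes_rejected(self):
        with pytest.raises(ValueError, match="n_mito"):
            small_config(n_mito=500)

    def test_gc_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            small_config(clades=[CladeSpec("x", 2, gc=1.4)])


class TestSimulateSpecies:
    def _one(self, config, seed=0):
        ref = simulate_reference(config, np.random.default_rng(0))
        return ref, simulate_species(
            config, config.clades[0], 0, ref, np.random.SeedSequence(seed)
        )

    def test_same_seed_byte_identical(self, tmp_path):
        config = small_config()
        bundles = []
        for run in range(2):
            out = tmp_path / f"run{run}"
            write_bundle(simulate_study(config), out)
            bundles.append(out)
        for name in sorted(p.name for p in bundles[0].iterdir()):
            assert (bundles[0] / name).read_bytes() == (bundles[1] / name).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        a = simulate_study(small_config(seed=1))
        b = simulate_study(small_config(seed=2))
        sp = next(iter(a.datasets))
        assert a.datasets[sp].downstream != b.datasets[sp].downstream

    def test_generated_gc_close_to_configured(self):
        config = small_config(n_genes=600, n_mito=50)
        ref, (ds, _, _) = self._one(config)
        model = estimate_gc(ds, "full_region")
        assert abs(model.gc - 0.38) < 0.01

    def test_rate_one_makes_every_mito_gene_a_target(self):
        config = small_config(
            clades=[CladeSpec("c", 1, gc=0.38, motif_rate_mito=1.0)],
            core_enrichment=1.0,
        )
        ref, (ds, orthologs, designated) = self._one(config)
        targets = call_targets(ds, compile_profile(config.profile))
        assert designated <= targets.targets
        ref_of = orthologs.by_species_gene()
        mito_sp = {g for g in ds.genes if ref_of[g] & ref.mito}
        assert mito_sp <= targets.targets

    def test_chance_targets_match_closed_form_when_rate_zero(self):
        config = small_config(
            clades=[CladeSpec("c", 1, gc=0.5, motif_rate_mito=0.0)],
            n_genes=1000, n_mito=10, motif_rate_background=0.0,
        )
        ref, (ds, _, designated) = self._one(config, seed=3)
        assert designated == set()
        profile = compile_profile(config.profile)
        targets = call_targets(ds, profile)
        p = profile.match_probability(0.5)
        n_positions = 243  # starts 0..242 keep the full 8-mer inside 250 bp
        p_gene = 1 - (1 - p) ** n_positions
        n = len(ds.genes)
        sd = math.sqrt(n * p_gene * (1 - p_gene))
        assert abs(len(targets.targets) - n * p_gene) <= 3 * sd + 1

    def test_fixtures_pass_io_validators(self):
        # SpeciesDataset construction validates alphabets and lengths
        config = small_config()
        ref, (ds, orthologs, _) = self._one(config)
        assert all(len(c) % 3 == 0 for c in ds.cds.values())
        sp_genes = set(ds.downstream)
        assert {s for s, _ in orthologs.pairs} == sp_genes

    def test_planting_preserves_length_and_window(self):
        config = small_config(
            clades=[CladeSpec("c", 1, gc=0.38, motif_rate_mito=1.0)],
            core_enrichment=1.0,
        )
        ref, (ds, orthologs, designated) = self._one(config)
        profile = compile_profile(config.profile)
        for g in designated:
            assert len(ds.downstream[g]) == config.downstream_length
            targets = call_targets(ds, profile, utr_cutoff=config.placement_window)
            assert g in targets.targets


class TestSimulateExpression:
    def test_zero_rho_gives_near_zero_mean_correlation(self):
        config = small_config(expression_rho=0.0, n_conditions=400, expression_shift=0.0)
        rng = np.random.default_rng(0)
        m = simulate_expression(config, [f"b{i}" for i in range(15)],
                                [f"o{i}" for i in range(15)], rng)
        block = m.iloc[:15].to_numpy()
        corr = np.corrcoef(block)
        off = corr[np.triu_indices(15, k=1)]
        assert abs(off.mean()) < 0.02

    def test_planted_rho_recovered(self):
        config = small_config(expression_rho=0.5, n_conditions=1011)
        rng = np.random.default_rng(1)
        m = simulate_expression(config, [f"b{i}" for i in range(20)],
                                [f"o{i}" for i in range(5)], rng)
        corr = np.corrcoef(m.iloc[:20].to_numpy())
        off = corr[np.triu_indices(20, k=1)]
        assert off.mean() == pytest.approx(0.5, abs=0.05)

    def test_shift_increases_down_classification(self):
        from puf3regulon.expression import classify_regulation

        config = small_config(expression_shift=1.0, n_conditions=30)
        rng = np.random.default_rng(2)
        block = [f"b{i}" for i in range(50)]
        other = [f"o{i}" for i in range(50)]
        m = simulate_expression(config, block, other, rng)
        down_block = classify_regulation(m, "YPD", genes=block).n_down
        down_other = classify_regulation(m, "YPD", genes=other).n_down
        assert down_block > down_other

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression(small_config(n_conditions=2), ["a"], ["b"],
                                np.random.default_rng(0))


class TestSimulateFitness:
    def test_effect_only_in_nonfermentative_condition(self):
        config = small_config(fitness_effect=2.0)
        rng = np.random.default_rng(3)
        block = [f"b{i}" for i in range(100)]
        other = [f"o{i}" for i in range(100)]
        table = simulate_fitness(config, block, other, rng)
        by = table.groupby("condition").apply(
            lambda d: d[d.gene.str.startswith("b")].relative_growth.mean()
            - d[d.gene.str.startswith("o")].relative_growth.mean(),
            include_groups=False,
        )
        assert abs(by["YPD"]) < 0.08
        assert by["YPE"] < -0.1

    def test_zero_effect_is_null(self):
        config = small_config(fitness_effect=0.0)
        rng = np.random.default_rng(4)
        table = simulate_fitness(config, ["b1", "b2"], ["o1", "o2"], rng)
        assert len(table) == 8


class TestSimulateStudy:
    def test_structure_and_designations(self):
        bundle = simulate_study(small_config())
        assert len(bundle.datasets) == 4
        for sp, ds in bundle.datasets.items():
            assert bundle.designated[sp] <= set(ds.downstream)
            refs = {r for _, r in bundle.orthologs[sp].pairs}
            annotated = set(bundle.reference.annotation.localization)
            assert refs <= annotated
        assert bundle.focal_species in bundle.datasets
        assert set(bundle.expression.columns[0:1]) == {"YPD"}

    def test_clade_rates_reflected_in_designations(self):
        bundle = simulate_study(small_config(n_genes=400, n_mito=150, seed=5))
        rates = {}
        for sp, ds in bundle.datasets.items():
            ref_of = bundle.orthologs[sp].by_species_gene()
            mito = {g for g in ds.genes if ref_of[g] & bundle.reference.mito}
            rates[sp] = len(bundle.designated[sp] & mito) / len(mito)
        a = np.mean([r for sp, r in rates.items() if sp.startswith("cladeA")])
        b = np.mean([r for sp, r in rates.items() if sp.startswith("cladeB")])
        assert a == pytest.approx(0.5, abs=0.12)
        assert b == pytest.approx(0.1, abs=0.08)
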