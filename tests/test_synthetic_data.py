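"""Generator contracts: determinism, Poisson structure, cross logic, fixtures."""

import math

import numpy as np
import pandas as pd
import pytest

from lethalmap import io
from lethalmap.complementation_mapping import DeficiencyPanel
from lethalmap.synthetic_data import (
    Fly,
    Mutation,
    PopulationSample,
    SimConfig,
    SublineRecord,
    WildChromosome,
    build_gene_catalog,
    sample_sublines,
    simulate_cross,
    simulate_deficiency_panel,
    simulate_population,
    simulate_read_depths,
    simulate_screen,
    simulate_screen_crosses,
    simulate_variant_tables,
    stage_rng,
)
from lethalmap.variant_filtering import classify_deletion_carrier, depth_ratio


def chrom(cid, positions, gene_ids=None, cls="TE_insertion", ibd=None):
    gene_ids = gene_ids or list(range(len(positions)))
    muts = tuple(
        Mutation(position=p, gene_id=g, mutation_class=cls)
        for p, g in zip(positions, gene_ids)
    )
    return WildChromosome(chrom_id=cid, lethal_mutations=muts, ibd_group=ibd)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [("lambda_true", -0.1), ("female_fraction", 1.2), ("chromosome_length", 0),
         ("miss_probability", -0.01), ("n_flies", 0),
         ("deficiency_size_range", (0, 100)), ("sublines_per_fly_weights", (-1, 2))],
    )
    def test_invalid_fields_rejected(self, field, value):
        with pytest.raises(ValueError):
            SimConfig(**{field: value})

    def test_weights_normalized(self):
        cfg = SimConfig(sublines_per_fly_weights=(2, 1, 1))
        assert sum(cfg.sublines_per_fly_weights) == pytest.approx(1.0)

    def test_oversized_deficiencies_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(chromosome_length=10_000, deficiency_size_range=(200, 20_000))


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_tables(self, small_config, tmp_path):
        outs = []
        for run in range(2):
            bundle = simulate_screen(small_config)
            sub = tmp_path / f"sub{run}.tsv"
            cross = tmp_path / f"cross{run}.tsv"
            io.write_subline_table(bundle.sublines, sub)
            io.write_cross_table(bundle.deficiency_crosses, cross)
            outs.append((sub.read_bytes(), cross.read_bytes()))
        assert outs[0] == outs[1]

    def test_stage_streams_are_partitioned(self, small_config):
        """Changing a crosses-stage parameter leaves the population and
        panel untouched."""
        import dataclasses

        other = dataclasses.replace(small_config, offspring_mean=90.0)
        pop1 = simulate_population(small_config)
        pop2 = simulate_population(other)
        assert [f.chromosome_pair[0].lethal_mutations for f in pop1.flies] == [
            f.chromosome_pair[0].lethal_mutations for f in pop2.flies
        ]
        p1 = simulate_deficiency_panel(small_config)
        p2 = simulate_deficiency_panel(other)
        pd.testing.assert_frame_equal(p1.deficiencies, p2.deficiencies)


class TestPopulation:
    def test_zero_rate_means_no_lethals(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, lambda_true=0.0)
        pop = simulate_population(cfg)
        sublines = sample_sublines(pop, cfg)
        assert all(not s.lethal for s in sublines)

    def test_poisson_zero_class_matches_rate(self):
        """Fraction of chromosomes with >=1 lethal approximates
        1 - exp(-lambda) (binomial error bound, 10,000 chromosomes)."""
        lam = 0.639
        cfg = SimConfig(n_flies=5000, lambda_true=lam, ibd_fraction=0.0, seed=2)
        pop = simulate_population(cfg)
        flags = [c.lethal for f in pop.flies for c in f.chromosome_pair]
        expected = 1 - math.exp(-lam)
        se = math.sqrt(expected * (1 - expected) / len(flags))
        assert abs(np.mean(flags) - expected) < 3 * se

    def test_mutations_lie_inside_their_genes(self, small_config):
        pop = simulate_population(small_config)
        catalog = pop.catalog
        for fly in pop.flies:
            for c in fly.chromosome_pair:
                for m in c.lethal_mutations:
                    s, e = catalog.interval(m.gene_id)
                    assert s <= m.position <= e

    def test_ibd_flies_share_ancestor_chromosome(self):
        cfg = SimConfig(n_flies=200, ibd_fraction=0.2, seed=4)
        pop = simulate_population(cfg)
        groups = {}
        for f in pop.flies:
            for c in f.chromosome_pair:
                if c.ibd_group:
                    groups.setdefault(c.ibd_group, []).append(c.lethal_mutations)
        assert groups, "expected some IBD carriers"
        for muts in groups.values():
            assert all(m == muts[0] for m in muts)


class TestSublines:
    def fly_pop(self, pair, sex="M", n=2000, weights=(1.0,)):
        cfg = SimConfig(n_flies=1, sublines_per_fly_weights=weights, seed=9)
        flies = [Fly(f"fly{i:05d}", sex, 2018, pair) for i in range(n)]
        return PopulationSample(flies=flies, catalog=build_gene_catalog(cfg), config=cfg), cfg

    def test_male_heterozygous_fly_yields_half_lethal_sublines(self):
        pair = (chrom("a", [1000]), chrom("b", []))
        pop, cfg = self.fly_pop(pair)
        subs = sample_sublines(pop, cfg)
        frac = np.mean([s.lethal for s in subs])
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / len(subs))

    def test_nonlethal_fly_yields_no_lethal_sublines(self):
        pair = (chrom("a", []), chrom("b", []))
        pop, cfg = self.fly_pop(pair, n=200)
        assert not any(s.lethal for s in sample_sublines(pop, cfg))

    def test_female_recombinant_carries_shared_mutation_always(self):
        # same lethal position on both homologues: any crossover keeps it
        pair = (chrom("a", [5000]), chrom("b", [5000]))
        pop, cfg = self.fly_pop(pair, sex="F", n=300)
        assert all(s.lethal for s in sample_sublines(pop, cfg))

    def test_female_recombinant_mixes_arms(self):
        # lethal at the first base: lethality equals the left-arm donor,
        # drawn evenly, so about half of recombinants carry it
        pair = (chrom("a", [1]), chrom("b", []))
        pop, cfg = self.fly_pop(pair, sex="F", n=2000)
        frac = np.mean([s.lethal for s in sample_sublines(pop, cfg)])
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / 2000)

    def test_subline_counts_follow_weights(self, small_config):
        pop = simulate_population(small_config)
        subs = sample_sublines(pop, small_config)
        per_fly = pd.Series([s.fly_id for s in subs]).value_counts()
        assert set(per_fly.unique()) <= {1, 2, 3}
        assert len(per_fly) == small_config.n_flies


class TestDeficiencyPanel:
    def test_whole_chromosome_deficiency(self):
        panel = DeficiencyPanel(
            deficiencies=pd.DataFrame(
                {"deficiency_id": ["Df001"], "start": [1], "end": [1000]}
            ),
            chromosome_length=1000,
        )
        assert panel.union_coverage() == 1.0

    def test_union_idempotent_for_duplicates(self):
        panel = DeficiencyPanel(
            deficiencies=pd.DataFrame(
                {"deficiency_id": ["a", "b"], "start": [100, 100], "end": [400, 400]}
            ),
            chromosome_length=1000,
        )
        assert panel.union_coverage() == pytest.approx(301 / 1000)

    def test_union_matches_per_base_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 10))
            starts = rng.integers(1, 900, size=n)
            ends = starts + rng.integers(1, 120, size=n)
            ends = np.minimum(ends, 1000)
            panel = DeficiencyPanel(
                deficiencies=pd.DataFrame(
                    {"deficiency_id": [f"d{i}" for i in range(n)],
                     "start": starts, "end": ends}
                ),
                chromosome_length=1000,
            )
            occupancy = np.zeros(1000, dtype=bool)
            for s, e in zip(starts, ends):
                occupancy[s - 1 : e] = True
            assert panel.union_coverage() == pytest.approx(occupancy.mean())

    def test_generated_panel_matches_study_coverage(self):
        panel = simulate_deficiency_panel(SimConfig(seed=11))
        assert 0.55 <= panel.union_coverage() <= 0.85
        sizes = panel.deficiencies["end"] - panel.deficiencies["start"] + 1
        assert sizes.between(160_000, 1_600_000).all()

    def test_per_line_coverage_subset(self):
        panel = simulate_deficiency_panel(SimConfig(seed=11))
        ids = list(panel.deficiencies["deficiency_id"][:10])
        sub_cov = panel.coverage_for(ids)
        assert 0 < sub_cov < panel.union_coverage() + 1e-12
        with pytest.raises(KeyError):
            panel.coverage_for(["missing"])


class TestCrossLogic:
    def straight_fraction(self, chromosome, tester, cfg, n=400):
        rng = np.random.default_rng(5)
        tot = stra = 0
        for _ in range(n):
            res = simulate_cross(chromosome, tester, cfg, rng)
            tot += res.curly_n + res.straight_n
            stra += res.straight_n
        return stra / tot

    def test_punnett_expectations(self, small_config):
        lethal = chrom("a", [500_000], gene_ids=[50])
        clean = chrom("b", [])
        # non-lethal x balancer sibling: survivors 2 curly : 1 straight
        frac = self.straight_fraction(clean, "balancer_sibling", small_config)
        assert frac == pytest.approx(1 / 3, abs=0.02)
        # lethal chromosome x sibling: no straight survivors
        assert self.straight_fraction(lethal, "balancer_sibling", small_config) == 0.0
        # lethal inside the deficiency: all survivors balanced
        df_hit = ("deficiency", "Df1", 400_000, 600_000)
        assert self.straight_fraction(lethal, df_hit, small_config) == 0.0
        # lethal outside the deficiency: complementation, 1/3 straight
        df_miss = ("deficiency", "Df2", 700_000, 900_000)
        assert self.straight_fraction(lethal, df_miss, small_config) == pytest.approx(
            1 / 3, abs=0.02
        )

    def test_knockout_and_allelism_logic(self, small_config):
        a = chrom("a", [500_000], gene_ids=[50])
        b = chrom("b", [500_500], gene_ids=[50])
        c = chrom("c", [700_000], gene_ids=[70])
        assert self.straight_fraction(a, ("knockout", 50), small_config, n=50) == 0.0
        assert self.straight_fraction(a, ("knockout", 70), small_config, n=50) > 0.2
        assert self.straight_fraction(a, ("allelism", b), small_config, n=50) == 0.0
        assert self.straight_fraction(a, ("allelism", c), small_config, n=50) > 0.2

    def test_escapers_appear_with_miss_probability(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, miss_probability=1.0)
        lethal = chrom("a", [500_000], gene_ids=[50])
        rng = np.random.default_rng(0)
        res = simulate_cross(lethal, "balancer_sibling", cfg, rng)
        assert res.straight_n == 1

    def test_vectorized_crosses_respect_genotype_logic(self, small_config):
        pop = simulate_population(small_config)
        subs = sample_sublines(pop, small_config)
        lines = {s.subline_id: s.chromosome for s in subs if s.lethal}
        panel = simulate_deficiency_panel(small_config)
        crosses = simulate_screen_crosses(
            lines, panel, small_config, np.random.default_rng(3)
        )
        panel_ivs = dict(
            zip(panel.deficiencies["deficiency_id"],
                zip(panel.deficiencies["start"], panel.deficiencies["end"]))
        )
        for row in crosses.itertuples():
            s, e = panel_ivs[row.tester_id]
            hit = any(
                s <= m.position <= e for m in lines[row.line_id].lethal_mutations
            )
            if hit:
                assert row.straight_n == 0


class TestVariantTables:
    def test_zero_background_leaves_only_causal_records(self, small_config):
        pop = simulate_population(small_config)
        sample_sublines(pop, small_config)
        tables = simulate_variant_tables(pop, background_rate=0.0, seed=7)
        by_id = {s.subline_id: s for s in pop.sublines}
        assert tables, "expected lethal lines"
        for line, recs in tables.items():
            muts = by_id[line].chromosome.lethal_mutations
            assert len(recs) == len(muts)
            assert {r.pos for r in recs} == {m.position for m in muts}
            assert all(r.impact == "HIGH" for r in recs)

    def test_ibd_pairs_share_more_background_than_others(self):
        cfg = SimConfig(n_flies=300, ibd_fraction=0.3, lambda_true=1.0, seed=3)
        pop = simulate_population(cfg)
        sample_sublines(pop, cfg)
        tables = simulate_variant_tables(pop, background_rate=40.0, seed=3)
        by_group = {}
        by_id = {s.subline_id: s for s in pop.sublines}
        for line in tables:
            g = by_id[line].chromosome.ibd_group
            if g:
                by_group.setdefault(g, []).append(line)
        pair = next(v for v in by_group.values() if len(v) >= 2)[:2]
        non_ibd = [l for l in tables if by_id[l].chromosome.ibd_group is None]

        def shared(a, b):
            ka = {v.key() for v in tables[a]}
            kb = {v.key() for v in tables[b]}
            return len(ka & kb)

        assert shared(*pair) > shared(pair[0], non_ibd[0])
        assert shared(*pair) > shared(non_ibd[0], non_ibd[1])

    def test_vcf_round_trip(self, small_config, tmp_path):
        pop = simulate_population(small_config)
        sample_sublines(pop, small_config)
        tables = simulate_variant_tables(pop, background_rate=10.0, seed=7)
        line, recs = next((l, r) for l, r in tables.items() if r)
        path = tmp_path / "line.vcf"
        io.write_variant_vcf(recs, path, contigs={"2": small_config.chromosome_length})
        back = io.read_variant_vcf(path, carrier_line=line)
        orig = sorted(recs, key=lambda r: (r.chrom, r.pos, r.var_class))
        back = sorted(back, key=lambda r: (r.chrom, r.pos, r.var_class))
        assert [
            (r.chrom, r.pos, r.ref, r.alt, r.var_class, r.impact, r.length)
            for r in orig
        ] == [
            (r.chrom, r.pos, r.ref, r.alt, r.var_class, r.impact, r.length)
            for r in back
        ]


class TestReadDepths:
    def test_deletion_flag_halves_target_ratio(self):
        carrier = simulate_read_depths(125.0, heterozygous_deletion=True, seed=1)
        result = depth_ratio(carrier)
        assert 0.4 < result.ratio < 0.65
        assert classify_deletion_carrier(result)

    def test_no_deletion_gives_unity(self):
        control = simulate_read_depths(125.0, heterozygous_deletion=False, seed=1)
        result = depth_ratio(control)
        assert 0.9 < result.ratio < 1.1
        assert not classify_deletion_carrier(result)

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            simulate_read_depths(0.0)


class TestScreenBundleFixtures:
    def test_tables_feed_every_downstream_module(self, small_config, tmp_path):
        """The emitted fixture files round-trip and carry every column the
        downstream estimators require."""
        bundle = simulate_screen(small_config)
        io.write_subline_table(bundle.sublines, tmp_path / "sub.tsv")
        io.write_cross_table(bundle.deficiency_crosses, tmp_path / "cross.tsv")
        io.write_allelism_table(bundle.allelism_results, tmp_path / "all.tsv")
        io.write_deficiency_bed(bundle.panel, tmp_path / "panel.bed")

        sub = io.read_subline_table(tmp_path / "sub.tsv")
        assert {"subline_id", "fly_id", "sex", "year", "lethal"} <= set(sub.columns)
        allelism = io.read_allelism_table(tmp_path / "all.tsv")
        assert allelism == bundle.allelism_results
        panel = io.read_deficiency_bed(
            tmp_path / "panel.bed", small_config.chromosome_length
        )
        pd.testing.assert_frame_equal(
            panel.deficiencies.reset_index(drop=True),
            bundle.panel.deficiencies.astype(panel.deficiencies.dtypes),
        )

        from lethalmap.frequency_estimation import count_distinct_chromosomes

        count = count_distinct_chromosomes(sub, allelism, seed=0)
        assert 0 < count.n_total <= len(sub)
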