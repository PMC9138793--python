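"""Gene-drop simulator, planted causal variants, simulated annotations, and
faithful reconstruction of the three study families."""

import itertools

import numpy as np
import pytest

import famseg
from famseg import (
    CausalSpec,
    SegregationConfig,
    SimulationConfig,
    VariantKey,
    build_paper_fixture,
    gene_drop,
    mendelian_violations,
    plant_causal_variant,
    simulate_annotations,
)
from famseg.pedigree import Individual, Pedigree, Phenotype


def trio_pedigree():
    return Pedigree.from_members(
        "T",
        [
            Individual("dad", sex="male", sequenced=True),
            Individual("mom", sex="female", sequenced=True),
            Individual("kid", "dad", "mom", "female", sequenced=True),
        ],
    )


class TestGeneDrop:
    def test_af_zero_and_one_are_degenerate(self):
        ped = trio_pedigree()
        m0 = gene_drop(ped, [0.0] * 5, seed=1)
        m1 = gene_drop(ped, [1.0] * 5, seed=1)
        assert np.all(m0.calls == 0)
        assert np.all(m1.calls == 2)

    def test_same_seed_is_byte_identical(self):
        ped = trio_pedigree()
        a = gene_drop(ped, [0.3] * 50, seed=7)
        b = gene_drop(ped, [0.3] * 50, seed=7)
        assert a == b

    def test_male_x_is_hemizygous_maternal(self):
        ped = trio_pedigree()
        boy = Pedigree.from_members(
            "T",
            list(ped)[:2] + [Individual("kid", "dad", "mom", "male", sequenced=True)],
        )
        keys = [VariantKey("chrX", 1000 + i, "A", "G") for i in range(200)]
        m = gene_drop(boy, [0.5] * 200, seed=3, keys=keys)
        kid = m.calls[:, m.individuals.index("kid")]
        assert set(np.unique(kid)) <= {0, 2}  # never heterozygous on male X
        assert m.hemizygous[:, m.individuals.index("kid")].all()
        assert mendelian_violations(m, boy) == []

    def test_out_of_range_af_rejected(self):
        with pytest.raises(ValueError):
            gene_drop(trio_pedigree(), [1.5], seed=0)

    def test_violation_checker_catches_corruption(self):
        ped = trio_pedigree()
        m = gene_drop(ped, [0.0] * 3, seed=0)
        m.calls[1, m.individuals.index("kid")] = 2  # impossible: parents are 0/0
        assert len(mendelian_violations(m, ped)) == 1


class TestPlantedVariants:
    def test_full_penetrance_affected_equals_carriers(self, fixtures):
        ped = fixtures["Family1"].pedigree
        base = gene_drop(ped, [0.0], seed=5)
        _, affected, truth = plant_causal_variant(
            base, ped, CausalSpec("MO1", penetrance=1.0, phenocopy_rate=0.0), seed=5
        )
        assert {i for i, a in affected.items() if a} == set(truth["carriers"])

    def test_zero_penetrance_no_affected_carriers(self, fixtures):
        ped = fixtures["Family1"].pedigree
        base = gene_drop(ped, [0.0], seed=5)
        _, affected, truth = plant_causal_variant(
            base, ped, CausalSpec("MO1", penetrance=0.0, phenocopy_rate=0.0), seed=5
        )
        assert not any(affected[i] for i in truth["carriers"])

    def test_planted_transmission_is_mendelian(self, fixtures):
        ped = fixtures["Family1"].pedigree
        base = gene_drop(ped, [0.1] * 10, seed=11)
        m, _, _ = plant_causal_variant(base, ped, CausalSpec("MO1"), seed=11)
        assert mendelian_violations(m, ped) == []

    def test_strict_recovery_rate_matches_enumeration(self, fixtures):
        """With penetrance f, a maternally planted dominant variant survives
        the strict filter (obligates = affected, everyone unaffected must not
        carry) exactly when every carrier is penetrant.  The expected rate is
        computed by exhaustive enumeration over the 2^4 child transmissions
        and per-carrier penetrance outcomes, and compared with 1,000
        Monte-Carlo replicates within 3 binomial standard errors."""
        ped = fixtures["Family1"].pedigree
        f = 0.8
        children = ["PB1", "SI1A", "SI1B", "SI1C"]
        # enumeration oracle: mother always carries; each child w.p. 1/2;
        # survival <=> all carriers affected: sum_S (1/16) * f^(1+|S|)
        p_expected = sum(
            (1 / 16) * f ** (1 + sum(s))
            for s in itertools.product([0, 1], repeat=len(children))
        )

        sequenced = set(ped.sequenced_ids)
        hits = 0
        n = 1000
        rng = np.random.default_rng(2024)
        empty = famseg.GenotypeMatrix([], list(ped.individuals), np.zeros((0, len(ped)), np.int8))
        for _ in range(n):
            m, affected, truth = plant_causal_variant(
                empty, ped, CausalSpec("MO1", penetrance=f), rng
            )
            aff = {i for i in sequenced if affected[i]}
            unaff = sequenced - aff
            config = SegregationConfig(obligate_carriers=frozenset(aff), hard_excluders=frozenset(unaff))
            (o,) = famseg.segregate_strict([truth["key"]], m.subset_individuals(sorted(sequenced)), config)
            hits += o.stratum == famseg.STRICT
        se = (p_expected * (1 - p_expected) / n) ** 0.5
        assert abs(hits / n - p_expected) < 3 * se


class TestSimulatedAnnotations:
    def test_seeded_table_is_identical_on_rerun(self):
        keys = [VariantKey("chr1", 100 + i, "A", "G") for i in range(50)]
        cfg = SimulationConfig(n_variants=50, seed=9)
        assert simulate_annotations(keys, cfg).equals(simulate_annotations(keys, cfg))

    def test_pure_missense_mix(self):
        keys = [VariantKey("chr1", 100 + i, "A", "G") for i in range(30)]
        cfg = SimulationConfig(consequence_mix={"missense": 1.0}, seed=1)
        table = simulate_annotations(keys, cfg)
        assert (table["consequence"] == "missense").all()

    def test_rare_fraction_matches_analytic_mixture_mass(self, tmp_path):
        n = 10_000
        keys = [VariantKey("chr1", 100 + i, "A", "G") for i in range(n)]
        cfg = SimulationConfig(n_variants=n, seed=42)
        table = simulate_annotations(keys, cfg)
        path = tmp_path / "sim.tsv"
        table.to_csv(path, sep="\t", index=False)
        raw = famseg.read_annotation_table(path)
        annos = famseg.build_annotations(raw)
        frac = sum(1 for a in annos if a.mmaf < 0.001) / n
        expected = cfg.af_mass_below(0.001)
        se = (expected * (1 - expected) / n) ** 0.5
        assert abs(frac - expected) < 3 * se

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationConfig(consequence_mix={"missense": 0.5})


class TestStudyFamilyFixtures:
    def test_tables_reproduced_exactly(self, fixtures, cascades):
        """Every published row (gene, position, stratum, MMAF, CADD) comes
        back out of the cascade — no extras, no omissions."""
        for fid, fx in fixtures.items():
            candidates, _ = cascades[fid]
            produced = {
                (c.annotation.key, c.annotation.gene, c.filter_index,
                 c.annotation.mmaf, c.annotation.cadd)
                for c in candidates
            }
            expected = set()
            for row in fx.expected:
                chrom, pos = row["position"].split(":")
                key = VariantKey(chrom, int(pos), row["ref"], row["alt"])
                expected.add((key, row["gene"], row["filter"], row["mmaf"], row["cadd"]))
            assert produced == expected, fid

    def test_no_decoy_survives_any_cascade(self, cascades):
        for candidates, _ in cascades.values():
            assert not any(c.annotation.gene.startswith("DCY") for c in candidates)

    def test_fixtures_contain_enough_decoys_per_failure_mode(self, fixtures):
        for fx in fixtures.values():
            decoys = [a for a in fx.annotations if a.gene.startswith("DCY")]
            for mode in ("DCYPOP", "DCYNEX", "DCYCAD", "DCYSEG"):
                assert sum(1 for a in decoys if a.gene.startswith(mode)) >= 4

    def test_family2_keeps_x_linked_candidate(self, cascades):
        candidates, _ = cascades["Family2"]
        med14 = [c for c in candidates if c.annotation.gene == "MED14"]
        assert len(med14) == 1
        assert med14[0].annotation.key.chrom == "chrX"
        assert med14[0].stratum == famseg.SLACK_ONLY

    def test_fixture_genotypes_mendelian_except_published_anomaly(self, fixtures):
        # Families 1 and 2 are fully Mendelian-consistent.  In Family 3 the
        # single strict-filter variant (PRKD1) is carried by both brothers
        # but neither parent — exactly the published carrier pattern, which
        # the checker rightly flags as un-Mendelian (de-novo-like).
        assert mendelian_violations(fixtures["Family1"].genotypes, fixtures["Family1"].pedigree) == []
        assert mendelian_violations(fixtures["Family2"].genotypes, fixtures["Family2"].pedigree) == []
        v3 = mendelian_violations(fixtures["Family3"].genotypes, fixtures["Family3"].pedigree)
        assert {(k.chrom, k.pos, who) for k, who in v3} == {
            ("chr14", 30108088, "BR3A"),
            ("chr14", 30108088, "BR3B"),
        }

    def test_fixture_files_are_deterministic(self, tmp_path, fixtures):
        a = famseg.write_fixture_files(fixtures["Family3"], tmp_path / "a")
        b = famseg.write_fixture_files(build_paper_fixture("Family3"), tmp_path / "b")
        for name in a:
            assert a[name].read_bytes() == b[name].read_bytes(), name

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="Family9"):
            build_paper_fixture("Family9")
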