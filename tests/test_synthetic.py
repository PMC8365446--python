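"""Synthetic-data generators: families, genomes, trees, assays."""

import numpy as np
import pandas as pd
import pytest

from nrdmotif.kinetics import mm_rate, si_rate
from nrdmotif.phylo import StateTree, fitch_count, is_monophyletic, \
    parse_newick
from nrdmotif.synthetic import (APICAL_SPAN, BACKBONE, AssaySpec, FamilySpec,
                                GenomeSpec, TreeScenario, generate_family,
                                generate_genomes, generate_tree_states,
                                reference_anchor, simulate_assay)

from _oracles import enumeration_parsimony


class TestFamilySpecValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="motif_fractions"):
            FamilySpec(n_sequences=5, motif_fractions={"PNSP": 0.6,
                                                       "PAGR": 0.5})

    def test_rates_bounded(self):
        with pytest.raises(ValueError, match="substitution_rate"):
            FamilySpec(n_sequences=5, motif_fractions={"PNSP": 1.0},
                       substitution_rate=1.5)

    def test_n_sequences_positive(self):
        with pytest.raises(ValueError, match="n_sequences"):
            FamilySpec(n_sequences=0, motif_fractions={"PNSP": 1.0})


class TestGenerateFamily:
    def test_zero_noise_exact_fractions_and_positions(self):
        spec = FamilySpec(n_sequences=10,
                          motif_fractions={"PNSP": 0.5, "PAGR": 0.5},
                          substitution_rate=0.0, seed=0)
        seqs, truth = generate_family(spec)
        assert len(seqs) == 10
        assert truth.motif.value_counts().to_dict() == {"PNSP": 5, "PAGR": 5}
        lo = APICAL_SPAN[0]
        for (sid, seq), row in zip(seqs, truth.itertuples()):
            assert row.start == lo
            assert seq[row.start - 1:row.end] == row.motif

    def test_truth_covers_every_sequence(self):
        spec = FamilySpec(n_sequences=25,
                          motif_fractions={"PNSP": 0.4, "PAGR": 0.6},
                          seed=1)
        seqs, truth = generate_family(spec)
        assert set(truth.seq_id) == {sid for sid, _ in seqs}

    def test_census_fractions_match_planting_at_scale(self):
        fr = {"PNSP": 0.44, "PAGR": 0.522, "PSMR": 0.021, "PQGSP": 0.017}
        spec = FamilySpec(n_sequences=1000, motif_fractions=fr, seed=5)
        _, truth = generate_family(spec)
        counts = truth.motif.value_counts()
        # deterministic largest-remainder allocation: exact to 1 sequence
        for m, f in fr.items():
            assert abs(counts[m] - 1000 * f) <= 1

    def test_mutations_never_touch_planted_motif(self):
        spec = FamilySpec(n_sequences=60,
                          motif_fractions={"PNSP": 0.5, "PQGSP": 0.5},
                          substitution_rate=0.3, indel_rate=0.05, seed=3)
        seqs, truth = generate_family(spec)
        for (sid, seq), row in zip(seqs, truth.itertuples()):
            assert seq[row.start - 1:row.end] == row.motif

    def test_deterministic_under_fixed_seed(self):
        spec = FamilySpec(n_sequences=20,
                          motif_fractions={"PNSP": 0.5, "PAGR": 0.5},
                          substitution_rate=0.2, indel_rate=0.02, seed=9)
        a_seqs, a_truth = generate_family(spec)
        b_seqs, b_truth = generate_family(spec)
        assert a_seqs == b_seqs
        assert a_truth.equals(b_truth)

    def test_backbone_carries_reference_loop(self):
        ref = reference_anchor()
        assert len(BACKBONE) == 150
        assert ref.apical_motif == "PAGR"


class TestGenerateGenomes:
    def test_direct_construction_counts(self):
        spec = GenomeSpec(n_genomes=3,
                          copy_number_distribution={2: 2 / 3, 1: 1 / 3},
                          specificity_mix={"MIXED": 0.5, "NTP_ONLY": 0.5},
                          seed=0)
        genomes, truth = generate_genomes(spec)
        assert len(genomes) == 3
        multi = truth[truth.n_copies >= 2]
        assert len(multi) == 2
        assert set(multi.category) == {"MIXED", "NTP_ONLY"}

    def test_published_scale_deterministic_counts(self):
        spec = GenomeSpec(
            n_genomes=1108, copy_number_distribution={2: 1.0},
            specificity_mix={"MIXED": 760 / 1108, "NTP_ONLY": 113 / 1108,
                             "NDP_ONLY": 235 / 1108},
            seed=7)
        _, truth = generate_genomes(spec)
        counts = truth.category.value_counts().to_dict()
        assert counts == {"MIXED": 760, "NDP_ONLY": 235, "NTP_ONLY": 113}

    def test_seed_changes_content_not_counts(self):
        kw = dict(n_genomes=40, copy_number_distribution={2: 0.8, 3: 0.2},
                  specificity_mix={"MIXED": 0.7, "NDP_ONLY": 0.3})
        g1, t1 = generate_genomes(GenomeSpec(seed=1, **kw))
        g2, t2 = generate_genomes(GenomeSpec(seed=2, **kw))
        assert (t1.category.value_counts().to_dict()
                == t2.category.value_counts().to_dict())
        seqs1 = [s for _, m in g1 for _, s in m]
        seqs2 = [s for _, m in g2 for _, s in m]
        assert seqs1 != seqs2

    def test_copies_carry_category_consistent_motifs(self):
        from nrdmotif.anchor import PairwiseMotifExtractor
        from nrdmotif.specificity import SpecificityClassifier

        spec = GenomeSpec(n_genomes=12,
                          copy_number_distribution={2: 0.5, 3: 0.5},
                          specificity_mix={"MIXED": 0.5, "NTP_ONLY": 0.25,
                                           "NDP_ONLY": 0.25},
                          seed=4)
        genomes, truth = generate_genomes(spec)
        ext = PairwiseMotifExtractor(reference=reference_anchor()).fit()
        clf = SpecificityClassifier().fit()
        cats = dict(zip(truth.genome_id, truth.category))
        for gid, members in genomes:
            labels = {l.label for l in clf.predict(ext.transform(members))}
            if cats[gid] == "MIXED":
                assert labels == {"NDP", "NTP"}
            elif cats[gid] == "NTP_ONLY":
                assert labels == {"NTP"}
            elif cats[gid] == "NDP_ONLY":
                assert labels == {"NDP"}

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(n_genomes=0, copy_number_distribution={2: 1.0},
                       specificity_mix={"MIXED": 1.0})
        with pytest.raises(ValueError, match="copy number"):
            GenomeSpec(n_genomes=5, copy_number_distribution={0: 1.0},
                       specificity_mix={"MIXED": 1.0})


class TestGenerateTreeStates:
    def test_single_origin_always_monophyletic(self):
        for seed in range(5):
            sc = TreeScenario(n_tips=64, scenario="SINGLE_ORIGIN", seed=seed)
            nwk, states = generate_tree_states(sc)
            st = StateTree(tree=parse_newick(nwk), tip_states=states)
            assert fitch_count(st) == 1
            assert is_monophyletic(st, "NDP").monophyletic

    def test_k_origins_fitch_count_is_k(self):
        sc = TreeScenario(n_tips=64, scenario="K_ORIGINS", k_origins=3,
                          seed=2)
        nwk, states = generate_tree_states(sc)
        st = StateTree(tree=parse_newick(nwk), tip_states=states)
        assert fitch_count(st) == 3

    def test_k_origins_verified_by_enumeration_on_small_tree(self):
        sc = TreeScenario(n_tips=12, scenario="K_ORIGINS", k_origins=3,
                          clade_fraction=0.4, seed=1)
        nwk, states = generate_tree_states(sc)
        st = StateTree(tree=parse_newick(nwk), tip_states=states)
        assert fitch_count(st) == 3
        assert enumeration_parsimony(st.tree, states) == 3

    def test_random_states_match_enumeration_oracle(self):
        for seed in range(6):
            sc = TreeScenario(n_tips=8, scenario="RANDOM", seed=seed)
            nwk, states = generate_tree_states(sc)
            if len(set(states.values())) < 2:
                continue
            st = StateTree(tree=parse_newick(nwk), tip_states=states)
            assert fitch_count(st) == enumeration_parsimony(st.tree, states)

    def test_incompatible_clade_fraction_rejected(self):
        with pytest.raises(ValueError, match="ancestral"):
            generate_tree_states(TreeScenario(
                n_tips=8, scenario="K_ORIGINS", k_origins=5,
                clade_fraction=0.7))

    def test_deterministic_under_seed(self):
        sc = TreeScenario(n_tips=32, seed=11)
        assert generate_tree_states(sc) == generate_tree_states(sc)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            TreeScenario(n_tips=3)
        with pytest.raises(ValueError):
            TreeScenario(n_tips=8, clade_fraction=1.0)


class TestSimulateAssay:
    def test_noiseless_follows_mm_exactly(self):
        spec = AssaySpec(true_kcat=47.6, true_km=0.30, noise_cv=0.0,
                         replicates=1)
        df = simulate_assay(spec)
        expected = mm_rate(df.substrate_mM.values, 47.6, 0.30)
        assert np.allclose(df.rate_per_min.values, expected)
        at_km = df[np.isclose(df.substrate_mM, 0.30)]
        assert at_km.rate_per_min.iloc[0] == pytest.approx(23.8)

    def test_inhibition_curve_decreases_at_high_substrate(self):
        spec = AssaySpec(true_kcat=3.8, true_km=6.85, true_ki=5.0,
                         substrate_grid=tuple(np.linspace(0.5, 40, 12)),
                         noise_cv=0.0, replicates=1)
        df = simulate_assay(spec)
        v = df.rate_per_min.values
        assert v[-1] < v.max()
        expected = si_rate(df.substrate_mM.values, 3.8, 6.85, 5.0)
        assert np.allclose(v, expected)

    def test_reproducible_under_fixed_seed(self):
        spec = AssaySpec(noise_cv=0.05, seed=13)
        a = simulate_assay(spec)
        b = simulate_assay(spec)
        assert a.equals(b)

    def test_noise_is_multiplicative_and_nonnegative(self):
        spec = AssaySpec(noise_cv=0.8, replicates=20, seed=1)
        df = simulate_assay(spec)
        assert (df.rate_per_min >= 0).all()

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            AssaySpec(true_km=-1)
        with pytest.raises(ValueError):
            AssaySpec(replicates=0)
        with pytest.raises(ValueError):
            AssaySpec(substrate_grid=(0.0, 1.0))
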