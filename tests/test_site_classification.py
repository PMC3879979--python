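import numpy as np
import pytest

from strandbalance import (
    Phylogeny,
    classify_gene,
    classify_site,
    enumerate_mprs,
    is_variable,
    summarize_genes,
    variable_site_mask,
)
from strandbalance.site_classification import GeneChangeSummary

from conftest import make_alignment


class TestIsVariable:
    def test_monomorphic_column(self):
        assert not is_variable("KKKK", "KKK")

    def test_residue_variant_anywhere(self):
        assert is_variable("KKKK", "KKR")
        assert is_variable("KKRK", "KKK")

    def test_outgroup_gap_counts_as_variant(self):
        assert is_variable("KKKK", "KK-")

    def test_x_is_not_a_variant(self):
        assert not is_variable("KKKK", "KXK")

    def test_all_variable_mode(self):
        assert is_variable("KKKK", "KKK", mode="all_variable")


class TestVariableMask:
    def test_observed_subset_of_all_variable(self, quartet_tree):
        aln = make_alignment(
            {"A": "MKV", "B": "MKV", "C": "MKI", "D": "MKV"}, {"OG1": "M-V"}
        )
        obs = variable_site_mask(aln, "observed")
        allv = variable_site_mask(aln, "all_variable")
        assert list(obs) == [False, True, True]  # outgroup gap + focal variant
        assert (obs <= allv).all()

    def test_interpolated_promotes_to_target(self):
        aln = make_alignment({"A": "MKVL", "B": "MKVL", "C": "MKVI", "D": "MKVL"})
        rng = np.random.default_rng(0)
        mask = variable_site_mask(aln, "interpolated", fraction=0.75, rng=rng)
        assert mask.sum() == 3
        assert mask[3]  # the observed variable site stays variable

    def test_interpolated_fraction_below_observed_rejected(self):
        aln = make_alignment({"A": "KV", "B": "KI", "C": "KV", "D": "KV"})
        with pytest.raises(ValueError):
            variable_site_mask(aln, "interpolated", fraction=0.0,
                               rng=np.random.default_rng(0))


class TestClassifySite:
    def classify(self, states, tree, policy):
        recon = enumerate_mprs(states, tree)
        return classify_site(recon, tree, policy=policy)

    def test_few_changes_never_parallel(self, quartet_tree):
        for states in ({l: "K" for l in "ABCD"},
                       {"A": "I", "B": "K", "C": "K", "D": "K"}):
            sc = self.classify(states, quartet_tree, "any_mpr")
            assert not sc.parallel and not sc.convergent
        assert self.classify({l: "K" for l in "ABCD"}, quartet_tree,
                             "all_mprs").label == "invariant"

    def test_cherry_split_is_single_hit(self, quartet_tree):
        # one change on an internal stem explains a two-versus-two split
        sc = self.classify({"A": "I", "B": "I", "C": "V", "D": "V"},
                           quartet_tree, "any_mpr")
        assert sc.label == "single_hit"
        assert not sc.parallel

    def test_discordant_split_parallel_under_any_mpr(self, quartet_tree):
        # ((A,B),(C,D)) with A,C sharing a derived residue: some MPRs put
        # two independent V->I events on terminal branches
        states = {"A": "I", "B": "V", "C": "I", "D": "V"}
        assert self.classify(states, quartet_tree, "any_mpr").parallel

    def test_any_mpr_flags_contain_all_mpr_flags(self, quartet_tree):
        import itertools

        for pattern in itertools.product("IVL", repeat=4):
            states = dict(zip("ABCD", pattern))
            strict = self.classify(states, quartet_tree, "all_mprs")
            loose = self.classify(states, quartet_tree, "any_mpr")
            assert (not strict.parallel) or loose.parallel
            assert (not strict.convergent) or loose.convergent

    def test_unambiguous_parallel_flagged_under_all_mprs(self, quartet_tree):
        # both MPRs for the discordant split carry a parallel pair (two
        # V->I terminal events, or two I->V terminal events), so even the
        # conservative policy flags the site
        states = {"A": "I", "B": "V", "C": "I", "D": "V"}
        recon = enumerate_mprs(states, quartet_tree)
        strict = classify_site(recon, quartet_tree, policy="all_mprs")
        assert strict.parallel
        assert not strict.convergent

    def test_ambiguous_reconstruction_splits_the_policies(self):
        # some MPRs for this pattern show a parallel A->T pair, others a
        # convergent (A->T, V->T) pair: only the permissive policy flags
        tree = Phylogeny.ladder(("L1", "L2", "L3", "L4", "L5"))
        states = {"L1": "T", "L2": "A", "L3": "A", "L4": "V", "L5": "T"}
        recon = enumerate_mprs(states, tree)
        strict = classify_site(recon, tree, policy="all_mprs")
        loose = classify_site(recon, tree, policy="any_mpr")
        assert not strict.parallel and not strict.convergent
        assert loose.parallel and loose.convergent

    def test_convergent_requires_different_ancestors(self):
        # 5-leaf ladder: L1..L5; derived T reached from two different
        # ancestral residues in separate lineages
        tree = Phylogeny.ladder(("L1", "L2", "L3", "L4", "L5"))
        states = {"L1": "T", "L2": "A", "L3": "A", "L4": "V", "L5": "T"}
        recon = enumerate_mprs(states, tree)
        loose = classify_site(recon, tree, policy="any_mpr")
        assert loose.label == "multihit"


class TestGeneSummaries:
    def test_counts_conserved_and_multihit(self, quartet_tree):
        aln = make_alignment(
            {"A": "IKI", "B": "VKV", "C": "IKV", "D": "VKV"},
            gene_id="g1", strand="lagging",
        )
        sites, summary = classify_gene(aln, quartet_tree)
        assert summary.C == sum(s.n_changes for s in sites)
        assert summary.multihit_sites == sum(1 for s in sites if s.n_changes >= 2)
        assert summary.C >= 2 * summary.multihit_sites

    def test_parallel_and_multihit_flags(self, quartet_tree):
        aln = make_alignment(
            {"A": "I", "B": "V", "C": "I", "D": "V"}, gene_id="gp"
        )
        _, summary = classify_gene(aln, quartet_tree, policy="any_mpr")
        assert summary.has_parallel
        assert summary.multihit_sites == 1

    def test_all_invariant_table(self, quartet_tree):
        summaries = []
        for k, strand in enumerate(["leading"] * 3 + ["lagging"] * 2):
            aln = make_alignment({l: "MKV" for l in "ABCD"},
                                 gene_id=f"g{k}", strand=strand)
            summaries.append(classify_gene(aln, quartet_tree)[1])
        _, table = summarize_genes(summaries)
        assert table == {
            "leading_parallel": 0, "leading_total": 3,
            "lagging_parallel": 0, "lagging_total": 2,
        }

    def test_unknown_strand_is_hard_error(self):
        s = GeneChangeSummary("g1", "unknown", 10, 2, 1, 0, False, False)
        with pytest.raises(ValueError):
            summarize_genes([s])

    def test_strand_table_overrides(self, quartet_tree):
        aln = make_alignment({l: "MKV" for l in "ABCD"}, gene_id="g9")
        _, summary = classify_gene(aln, quartet_tree)
        resolved, table = summarize_genes([summary], {"g9": "lagging"})
        assert resolved[0].strand == "lagging"
        assert table["lagging_total"] == 1
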