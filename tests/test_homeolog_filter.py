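"""Alignment QC boundaries, NJ construction, and the partition-search oracle."""

import itertools
import random

import dendropy
import pytest

import zwscan as z
from zwscan.errors import AlignmentError
from zwscan.homeolog_filter import (
    ACCEPTED,
    Assessment,
    GeneFamily,
    _rooted_clone,
    _valid_partition,
    assess_homeology,
    build_nj_tree,
    p_distance_matrix,
    run_filter,
    select_for_coalescent,
    ungapped_length,
)
from zwscan.synthetic_data import GeneFamSimConfig, simulate_gene_families


def make_gene_family(seqs, tree_newick=None, family_id="fam"):
    names = list(seqs)
    tree = None
    if tree_newick:
        tree = dendropy.Tree.get(data=tree_newick, schema="newick")
    return GeneFamily(
        family_id=family_id,
        names=names,
        sequences=dict(seqs),
        species={n: n.split("|", 1)[0] for n in names},
        tree=tree,
    )


def random_sequences(names, length, rng):
    return {n: "".join(rng.choice("ACGT") for _ in range(length)) for n in names}


class TestAlignmentQC:
    def _family(self, n_cols, species_tips):
        rng = random.Random(0)
        seqs = random_sequences(species_tips, n_cols, rng)
        return make_gene_family(seqs)

    def test_ungapped_299_fails_300_passes(self):
        tips = ["a|c1", "a|c2", "b|c1", "c|c1"]
        assert not z.alignment_qc(self._family(299, tips)).passed
        assert z.alignment_qc(self._family(300, tips)).passed

    def test_gap_columns_excluded(self):
        seqs = {"a|c1": "AC-T" * 100, "a|c2": "ACG-" * 100,
                "b|c1": "ACGT" * 100, "c|c1": "ACGT" * 100}
        fam = make_gene_family(seqs)
        assert ungapped_length(fam) == 200  # only the first 2 of each 4 columns
        assert not z.alignment_qc(fam, z.FilterConfig(min_ungapped_bp=300)).passed
        assert z.alignment_qc(fam, z.FilterConfig(min_ungapped_bp=200)).passed

    def test_two_ingroup_species_fails_three_passes(self):
        assert not z.alignment_qc(self._family(400, ["a|c1", "a|c2", "b|c1"])).passed
        assert z.alignment_qc(self._family(400, ["a|c1", "a|c2", "b|c1", "c|c1"])).passed

    def test_needs_a_duplicated_species(self):
        fam = self._family(400, ["a|c1", "b|c1", "c|c1", "d|c1"])
        result = z.alignment_qc(fam)
        assert not result.passed and "two_sequences" in result.reason

    def test_outgroup_not_counted_as_ingroup(self):
        fam = self._family(400, ["a|c1", "a|c2", "b|c1", "out|c1"])
        cfg = z.FilterConfig(outgroup_species="out")
        assert not z.alignment_qc(fam, cfg).passed  # only 2 ingroup species


class TestNeighborJoining:
    def test_three_leaves_three_point_formulas(self):
        # sequences built so d(ab)=0.1, d(ac)=0.2, d(bc)=0.3 over 100 sites
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        c = "A" * 10 + "G" * 20 + "A" * 70
        fam = make_gene_family({"a|1": a, "b|1": b, "c|1": c})
        _, dist = p_distance_matrix(fam)
        assert dist[0, 1] == pytest.approx(0.10)
        assert dist[0, 2] == pytest.approx(0.20)
        assert dist[1, 2] == pytest.approx(0.30)
        tree = build_nj_tree(fam)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        # three-point formulas: la = (dab + dac - dbc) / 2, etc.
        assert lengths["a|1"] == pytest.approx(0.0, abs=1e-12)
        assert lengths["b|1"] == pytest.approx(0.10)
        assert lengths["c|1"] == pytest.approx(0.20)

    @staticmethod
    def _quartet_pairs(tree):
        """The sister pairs implied by the single internal split of an
        unrooted 4-taxon tree (a 2-tip clade and its complement)."""
        all_tips = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
        pairs = set()
        for node in tree.preorder_internal_node_iter():
            if node is tree.seed_node:
                continue
            below = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(below) == 2:
                pairs |= {below, all_tips - below}
        return pairs

    @pytest.mark.parametrize("seed", range(8))
    def test_quartet_matches_four_point_oracle(self, seed):
        """For 4 taxa, NJ must join the pair given by the four-point
        condition: the pairing whose within-pair distance sum is smallest."""
        rng = random.Random(seed)
        names = ["a|1", "b|1", "c|1", "d|1"]
        seqs = random_sequences(names, 300, rng)
        fam = make_gene_family(seqs)
        _, d = p_distance_matrix(fam)
        pairings = {
            frozenset({"a|1", "b|1"}): d[0, 1] + d[2, 3],
            frozenset({"a|1", "c|1"}): d[0, 2] + d[1, 3],
            frozenset({"a|1", "d|1"}): d[0, 3] + d[1, 2],
        }
        ranked = sorted(pairings.items(), key=lambda kv: kv[1])
        if ranked[1][1] - ranked[0][1] < 1e-9:
            pytest.skip("tied quartet")
        tree = build_nj_tree(fam)
        assert ranked[0][0] in self._quartet_pairs(tree)

    def test_identical_sequences_zero_lengths_deterministic(self):
        seqs = {n: "ACGT" * 50 for n in ["a|1", "b|1", "c|1", "d|1"]}
        t1 = build_nj_tree(make_gene_family(seqs))
        t2 = build_nj_tree(make_gene_family(seqs))
        for tree in (t1, t2):
            assert all(abs(e.length or 0.0) < 1e-12
                       for e in tree.preorder_edge_iter())
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_disjoint_gap_pair_raises_naming_pair(self):
        seqs = {"a|1": "AAAA----", "b|1": "----TTTT", "c|1": "AAAATTTT"}
        with pytest.raises(AlignmentError, match="a\\|1.*b\\|1"):
            p_distance_matrix(make_gene_family(seqs))

    def test_too_few_sequences(self):
        with pytest.raises(AlignmentError, match=">= 3"):
            build_nj_tree(make_gene_family({"a|1": "ACGT", "b|1": "ACGA"}))


class TestAssessHomeology:
    def _family_with_tree(self, newick, length=40):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        names = [lf.taxon.label for lf in tree.leaf_node_iter()]
        rng = random.Random(1)
        seqs = random_sequences(names, length, rng)
        fam = make_gene_family(seqs)
        fam.tree = tree
        return fam

    def test_textbook_duplication_topology_accepted(self):
        nwk = ("('out|c1':3,(('a|c1':1,('b|c1':0.5,'c|c1':0.5):0.5):1,"
               "('a|c2':1.5,'d|c1':1.5):0.5):1);")
        fam = self._family_with_tree(nwk)
        result = assess_homeology(fam, z.FilterConfig(outgroup_species="out"))
        assert result.kind == "accept"
        assert set(map(frozenset, result.partition)) == {
            frozenset({"a|c1", "b|c1", "c|c1"}), frozenset({"a|c2", "d|c1"})}

    def test_sister_duplicates_rejected(self):
        nwk = ("('out|c1':3,((('a|c1':0.2,'a|c2':0.2):0.8,'b|c1':1):0.5,"
               "('c|c1':1,'d|c1':1):0.5):1);")
        fam = self._family_with_tree(nwk)
        result = assess_homeology(fam, z.FilterConfig(outgroup_species="out"))
        assert result.kind == "reject"
        assert result.reason == "sister_duplicates"

    def test_near_identical_tips_pruned_to_longest(self):
        rng = random.Random(3)
        base = random_sequences(["a|c1", "b|c1", "c|c1"], 400, rng)
        b_variant = base["b|c1"][:380] + "-" * 20  # shorter ungapped copy
        seqs = dict(base)
        seqs["b|c1v"] = b_variant
        nwk = ("(('b|c1':0.001,'b|c1v':0.001):0.3,"
               "('a|c1':0.3,'c|c1':0.3):0.1);")
        fam = make_gene_family(seqs, nwk)
        result = assess_homeology(fam, z.FilterConfig())
        assert result.kind == "prune"
        assert result.tips_to_drop == ["b|c1v"]

    def test_enumeration_oracle_on_random_trees(self):
        """Accept/reject decisions match exhaustive clade enumeration on
        random topologies of up to 8 ingroup tips."""
        config = z.FilterConfig(outgroup_species="out")
        rng = random.Random(2024)
        n_checked = accepts = 0
        for _ in range(120):
            n_tips = rng.randint(3, 8)
            species = [rng.choice("abcde") for _ in range(n_tips)]
            tips = [f"{sp}|t{i}" for i, sp in enumerate(species)] + ["out|c1"]
            nodes = [f"'{t}':{rng.uniform(0.05, 0.5):.3f}" for t in tips]
            while len(nodes) > 1:
                i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
                a, b = nodes.pop(i), nodes.pop(j)
                nodes.append(f"({a},{b}):{rng.uniform(0.05, 0.5):.3f}")
            fam = self._family_with_tree(nodes[0] + ";", length=60)
            result = assess_homeology(fam, config)
            expected = self._oracle_accept(fam, config)
            assert (result.kind == "accept") == expected, fam.tree.as_string(
                schema="newick")
            n_checked += 1
            accepts += result.kind == "accept"
        assert n_checked == 120 and 0 < accepts < n_checked

    @staticmethod
    def _oracle_accept(fam, config):
        """Independent check: enumerate every tip subset, keep those that
        form a clade below an internal non-root node, test the criteria."""
        tree = _rooted_clone(fam, config)
        taxa = {lf.taxon.label: lf.taxon for lf in tree.leaf_node_iter()}
        ingroup = set(fam.ingroup_names(config.outgroup_species))
        labels = sorted(taxa)
        for r in range(2, len(labels)):
            for subset in itertools.combinations(labels, r):
                mrca = tree.mrca(taxa=[taxa[l] for l in subset])
                clade = {lf.taxon.label for lf in mrca.leaf_iter()}
                if clade != set(subset) or mrca is tree.seed_node:
                    continue
                below = frozenset(clade & ingroup)
                above = frozenset(ingroup - below)
                if _valid_partition(below, above, fam.species):
                    return True
        return False


class TestRunFilter:
    def test_short_alignment_rejected_before_tree(self):
        rng = random.Random(5)
        fam = make_gene_family(
            random_sequences(["a|c1", "a|c2", "b|c1", "c|c1"], 100, rng))
        accepted, audit = run_filter([fam], z.FilterConfig())
        assert accepted == []
        assert audit[0].rounds_used == 0
        assert "ungapped" in audit[0].reason

    def test_one_lineage_lost_rejected(self):
        sims = simulate_gene_families(GeneFamSimConfig(n_families=1, seed=7))
        fam, truth = sims[0]
        crippled = fam.without(truth.partition[1])  # drop the whole c2 lineage
        accepted, audit = run_filter([crippled],
                                     z.FilterConfig(outgroup_species="xtro"))
        assert accepted == []
        assert audit[0].reason == "no_species_with_two_sequences"

    def test_splice_variant_resolved_within_two_rounds(self):
        sims = simulate_gene_families(
            GeneFamSimConfig(n_families=10, splice_variant_prob=1.0, seed=11))
        families = [f for f, _ in sims]
        accepted, audit = run_filter(families, z.FilterConfig(outgroup_species="xtro"))
        assert len(accepted) == 10
        truth_by_id = {t.family_id: t for _, t in sims}
        for fam, rec in zip(accepted, audit):
            assert rec.rounds_used == 2  # prune then re-assess
            truth = truth_by_id[fam.family_id]
            assert set(map(frozenset, fam.partition)) == set(
                map(frozenset, truth.partition))
            for var in truth.splice_variants:
                assert var not in fam.names

    def test_lineage_specific_duplication_never_accepted(self):
        """Families whose only duplication postdates speciation must not be
        mistaken for genome-duplication families."""
        rng = random.Random(13)
        families = []
        for k in range(20):
            sims = simulate_gene_families(GeneFamSimConfig(n_families=1, seed=100 + k))
            fam, truth = sims[0]
            single = fam.without(truth.partition[1])  # one copy per species
            src = sorted(truth.partition[0])[rng.randrange(len(truth.partition[0]))]
            dup = list(single.sequences[src])
            for pos in rng.sample(range(len(dup)), int(0.03 * len(dup))):
                dup[pos] = rng.choice([c for c in "ACGT" if c != dup[pos]])
            single.names.append(src + "d")
            single.sequences[src + "d"] = "".join(dup)
            single.species[src + "d"] = single.species[src]
            families.append(single)
        accepted, audit = run_filter(families, z.FilterConfig(outgroup_species="xtro"))
        assert accepted == []

    def test_audit_accounts_for_every_family_once(self):
        sims = simulate_gene_families(
            GeneFamSimConfig(n_families=30, loss_prob=0.3,
                             splice_variant_prob=0.2, seed=19))
        families = [f for f, _ in sims]
        accepted, audit = run_filter(families, z.FilterConfig(outgroup_species="xtro"))
        assert sorted(a.family_id for a in audit) == sorted(f.family_id for f in families)
        for fam in accepted:
            original = next(f for f in families if f.family_id == fam.family_id)
            assert len(fam.names) <= len(original.names)


class TestSelectForCoalescent:
    def _accepted_family(self, seed=23):
        sims = simulate_gene_families(GeneFamSimConfig(n_families=1, seed=seed))
        accepted, _ = run_filter([sims[0][0]], z.FilterConfig(outgroup_species="xtro"))
        return accepted[0]

    def test_longest_other_lineage_sequence_kept(self):
        fam = self._accepted_family()
        other = sorted(fam.partition[1])
        # shorten all but one 'other' sequence so the longest is unambiguous
        for n in other[1:]:
            fam.sequences[n] = fam.sequences[n][:-30] + "-" * 30
        reduced, status = select_for_coalescent(fam, {"xlae", "xbor", "xcli",
                                                      "xall", "xlar"})
        assert status == "ok"
        assert reduced.partition[1] == frozenset({other[0]})
        assert len(reduced.names) == 6  # 5 orthologs + 1 homeolog anchor

    def test_tie_broken_by_seed_deterministically(self):
        fam = self._accepted_family()
        required = {"xlae", "xbor", "xcli", "xall", "xlar"}
        picks = {select_for_coalescent(fam, required, seed=s)[0].partition[1]
                 for s in (1, 1, 1)}
        assert len(picks) == 1  # same seed, same choice
        all_equal_lengths = len({fam.ungapped_seq_length(n)
                                 for n in fam.partition[1]}) == 1
        if all_equal_lengths:
            varied = {next(iter(select_for_coalescent(fam, required, seed=s)[0]
                                .partition[1])) for s in range(30)}
            assert len(varied) > 1  # different seeds explore the ties

    def test_single_other_sequence_kept(self):
        fam = self._accepted_family()
        keep_one = next(iter(fam.partition[1]))
        drop = set(fam.partition[1]) - {keep_one}
        reduced_fam = fam.without(drop)
        reduced_fam.status = ACCEPTED
        reduced_fam.partition = (fam.partition[0], frozenset({keep_one}))
        out, status = select_for_coalescent(reduced_fam,
                                            {"xlae", "xbor", "xcli", "xall", "xlar"})
        assert status == "ok" and out.partition[1] == frozenset({keep_one})

    def test_incomplete_lineage_not_eligible(self):
        fam = self._accepted_family()
        out, status = select_for_coalescent(fam, {"xlae", "xbor", "nosuch"})
        assert out is None and status == "no_complete_lineage"
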