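"""Pruning likelihood against independent oracles."""

import itertools

import numpy as np
import pytest

from omegak.alignment import CodonAlignment
from omegak.genetic_code import CODON_INDEX, SENSE_CODONS
from omegak.likelihood import PruningEngine, log_likelihood
from omegak.model import CodonModel
from omegak.rates import SpectralQ, build_rate_matrix, expected_rate
from omegak.trees import LabelledTree

from conftest import random_alignment


def brute_force_lnl(aln, tree, model, scaler=1.0):
    """Explicit summation over all ancestral codon-state combinations.

    Every unknown (root/internal) node gets its own 61-state axis and
    the joint probability is summed over the full state space in one
    einsum — no pruning recursion, no partial likelihoods.
    """
    pi = model.codon_freqs
    omegas_ref = model.omegas
    omegas_test = model.test_omegas()
    props = model.proportions
    qs = [build_rate_matrix(model.kappa, w, pi, normalise=False) for w in omegas_ref]
    rho = sum(p * expected_rate(q, pi) for p, q in zip(props, qs))

    def pmat(w, t):
        q = build_rate_matrix(model.kappa, w, pi, normalise=False) / rho
        return SpectralQ(q, pi).transition(t * scaler)

    unknown = [tree.root] + [
        nd for nd in range(tree.n_nodes) if tree.children[nd] and nd != tree.root
    ]
    axis = {nd: chr(ord("a") + i) for i, nd in enumerate(unknown)}
    row_of = {t: i for i, t in enumerate(aln.taxa)}
    codes = {
        nd: [
            CODON_INDEX[aln.seqs[row_of[taxon]][3 * i : 3 * i + 3]]
            for i in range(aln.n_codons)
        ]
        for nd, taxon in tree.taxon_of.items()
    }

    total = 0.0
    for site in range(aln.n_codons):
        site_like = 0.0
        for ci in range(len(props)):
            subs, operands = [axis[tree.root]], [pi]
            for nd in range(tree.n_nodes):
                parent = tree.parent[nd]
                if parent == -1:
                    continue
                w = omegas_test[ci] if tree.is_test[nd] else omegas_ref[ci]
                p = pmat(w, tree.blen[nd])
                if nd in axis:  # internal child: full matrix
                    subs.append(axis[parent] + axis[nd])
                    operands.append(p)
                else:  # leaf: column at the observed codon
                    subs.append(axis[parent])
                    operands.append(p[:, codes[nd][site]])
            like = np.einsum(",".join(subs) + "->", *operands)
            site_like += props[ci] * like
        total += np.log(site_like)
    return total


class TestPruningOracle:
    @pytest.mark.parametrize(
        "newick,taxa,n_codons,seed",
        [
            ("(A:0.1,(B{test}:0.2,C{test}:0.15){test}:0.05);", "ABC", 5, 7),
            ("(A:0.08,B:0.3,C:0.12);", "ABC", 8, 11),
            ("((A:0.1,B{test}:0.2):0.07,(C:0.15,D:0.05):0.04);", "ABCD", 10, 13),
        ],
    )
    def test_matches_ancestral_enumeration(self, newick, taxa, n_codons, seed, skew_pi):
        tree = LabelledTree.from_newick(newick)
        aln = random_alignment(list(taxa), n_codons, seed=seed)
        model = CodonModel(2.0, skew_pi, [(0.2, 0.5), (1.0, 0.3), (2.5, 0.2)], k=0.4)
        got = log_likelihood(aln, tree, model)
        want = brute_force_lnl(aln, tree, model)
        assert got == pytest.approx(want, rel=1e-10)

    def test_degenerate_tree_reduces_to_pi(self, skew_pi):
        """All branch lengths 0 with identical sequences: lnL is the log
        probability of the root draw."""
        tree = LabelledTree.from_newick("(A:0,(B:0,C:0):0);")
        seq = "".join(SENSE_CODONS[i] for i in [0, 17, 60, 5, 5])
        aln = CodonAlignment(["A", "B", "C"], [seq] * 3)
        model = CodonModel(2.0, skew_pi, [(0.5, 1.0)])
        want = sum(np.log(skew_pi[CODON_INDEX[seq[3 * i : 3 * i + 3]]]) for i in range(5))
        assert log_likelihood(aln, tree, model) == pytest.approx(want, rel=1e-12)

    def test_k_equal_one_erases_partition(self, small_alignment, skew_pi):
        labelled = LabelledTree.from_newick(
            "(A:0.1,(B{test}:0.2,C{test}:0.15){test}:0.05);"
        )
        plain = LabelledTree.from_newick("(A:0.1,(B:0.2,C:0.15):0.05);")
        model = CodonModel(2.0, skew_pi, [(0.2, 0.6), (2.0, 0.4)], k=1.0)
        assert log_likelihood(small_alignment, labelled, model) == pytest.approx(
            log_likelihood(small_alignment, plain, model), abs=1e-9
        )

    def test_rerooting_invariance(self, skew_pi):
        """The reversible model's likelihood does not depend on where
        the (unrooted) tree is rooted."""
        import dendropy

        rng = np.random.default_rng(5)
        base = "((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.07,E:0.3);"
        aln = random_alignment(list("ABCDE"), 12, seed=3)
        model = CodonModel(2.0, skew_pi, [(0.3, 0.7), (1.5, 0.3)], k=0.5)

        def lnl_of(newick):
            tree = LabelledTree.from_newick(newick).with_labels(["A", "B"], mode="tips")
            return log_likelihood(aln, tree, model)

        def reference_edges(tree):
            # splitting a test-labelled branch would move part of it to
            # the reference regime; root only on reference edges
            return [
                e for e in tree.preorder_edge_iter()
                if e.length and (
                    e.head_node.taxon is None
                    or e.head_node.taxon.label not in ("A", "B")
                )
            ]

        reference = lnl_of(base)
        tree = dendropy.Tree.get(data=base, schema="newick")
        edges = reference_edges(tree)
        for _ in range(3):
            e = edges[rng.integers(len(edges))]
            tree.reroot_at_edge(
                e, update_bipartitions=False,
                length1=e.length / 2, length2=e.length / 2,
            )
            rerooted = tree.as_string(schema="newick").replace("[&R] ", "").strip()
            assert lnl_of(rerooted) == pytest.approx(reference, abs=1e-8)
            edges = reference_edges(tree)

    def test_missing_data_sums_over_codons(self, skew_pi):
        tree = LabelledTree.from_newick("(A:0.1,(B:0.2,C:0.15):0.05);")
        model = CodonModel(2.0, skew_pi, [(0.5, 1.0)])
        aln_full = random_alignment(["A", "B", "C"], 4, seed=2)
        gapped = [
            aln_full.seqs[0][:3] + "---" + aln_full.seqs[0][6:],
            aln_full.seqs[1],
            aln_full.seqs[2],
        ]
        aln_gap = CodonAlignment(["A", "B", "C"], gapped)
        # marginalising A at site 1 must equal the explicit codon sum
        total = 0.0
        for codon in range(61):
            seqs = list(aln_full.seqs)
            seqs[0] = seqs[0][:3] + SENSE_CODONS[codon] + seqs[0][6:]
            alt = CodonAlignment(["A", "B", "C"], seqs)
            total_i = np.exp(
                PruningEngine(alt, tree).site_logliks(model)[1]
            )
            total += total_i
        site_ll = PruningEngine(aln_gap, tree).site_logliks(model)[1]
        assert np.exp(site_ll) == pytest.approx(total, rel=1e-9)

    def test_taxon_mismatch_named(self, small_alignment):
        tree = LabelledTree.from_newick("(A:0.1,(B:0.2,X:0.15):0.05);")
        with pytest.raises(ValueError, match="'C'"):
            PruningEngine(small_alignment, tree)
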