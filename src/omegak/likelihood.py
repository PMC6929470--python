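"""Felsenstein pruning likelihood for omega^k codon mixture models.

The engine compresses the alignment into unique site patterns, runs a
batched post-order pruning pass over all omega categories at once
(reference branches use omega_i, test branches omega_i^k), and combines
categories on the log scale.  Rate matrices for the whole mixture are
normalised by the expected substitution rate of the *reference*
mixture, so branch lengths are expected substitutions per codon site
under the reference process.

Because the optimiser re-evaluates the likelihood at nearby parameter
values (finite-difference gradients), the engine keeps an LRU cache of
unnormalised spectral decompositions keyed by (kappa, omega, pi): the
mixture normalisation only rescales eigenvalues, so cached spectra are
reused across changes of proportions, scaler, and k.

A complementary outside (pre-order) pass supports the branch-site
machinery: with all of the tree fixed to a background process, the
likelihood as a function of one focal branch's transition matrix is a
cheap bilinear form, which makes per-branch mixture fits inexpensive.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .alignment import CodonAlignment
from .genetic_code import N_CODONS
from .model import CodonModel
from .rates import SpectralQ, build_rate_matrix, expected_rate
from .trees import LabelledTree

_RESCALE_FLOOR = 1e-260


class _SpectrumCache:
    """LRU cache of unnormalised MG94 spectral decompositions.

    Entries hold (lam, left, right, rate) for Q(kappa, omega, pi); the
    normalised process Q/rho shares eigenvectors with Q and has
    eigenvalues lam/rho, so one entry serves every normalisation.
    """

    def __init__(self, maxsize: int = 96):
        self.maxsize = maxsize
        self._d: OrderedDict = OrderedDict()

    def get(self, kappa: float, omega: float, pi: np.ndarray, pi_key):
        key = (round(float(kappa), 10), round(float(omega), 10), pi_key)
        hit = self._d.get(key)
        if hit is not None:
            self._d.move_to_end(key)
            return hit
        q = build_rate_matrix(kappa, omega, pi, normalise=False)
        spec = SpectralQ(q, pi)
        entry = (spec.lam, spec.left, spec.right, expected_rate(q, pi))
        self._d[key] = entry
        if len(self._d) > self.maxsize:
            self._d.popitem(last=False)
        return entry


class PruningEngine:
    """Per-dataset likelihood evaluator (pattern-compressed)."""

    def __init__(self, aln: CodonAlignment, tree: LabelledTree):
        leaf_by_name = tree.leaf_index()
        missing = [t for t in aln.taxa if t not in leaf_by_name]
        if missing:
            raise ValueError(
                f"alignment taxa not present in tree: {missing[0]!r}"
                + (f" (+{len(missing) - 1} more)" if len(missing) > 1 else "")
            )
        self.tree = tree
        self.aln = aln
        self._spectra = _SpectrumCache()

        masks = aln.leaf_partials()  # (n_taxa, n_sites, 61)
        n_sites = masks.shape[1]
        flat = masks.transpose(1, 0, 2).reshape(n_sites, -1)
        patterns, inverse, counts = np.unique(
            flat, axis=0, return_inverse=True, return_counts=True
        )
        self.pattern_weights = counts.astype(float)
        self.pattern_of_site = inverse
        self.n_patterns = patterns.shape[0]
        self.n_sites = n_sites
        pat_masks = patterns.reshape(self.n_patterns, aln.n_taxa, N_CODONS)

        # leaf partials per tree node; leaves absent from the alignment
        # carry all-ones vectors (missing data)
        self.leaf_partials: dict[int, np.ndarray] = {}
        taxon_row = {t: i for i, t in enumerate(aln.taxa)}
        for node, taxon in tree.taxon_of.items():
            if taxon in taxon_row:
                self.leaf_partials[node] = np.ascontiguousarray(
                    pat_masks[:, taxon_row[taxon], :].astype(float)
                )
            else:
                self.leaf_partials[node] = np.ones((self.n_patterns, N_CODONS))

        self.postorder = tree.postorder
        self.children = tree.children
        self.parent = tree.parent
        self.blen = tree.blen.copy()
        self.is_test = tree.is_test.copy()
        self.root = tree.root
        self.branches = [nd for nd in range(tree.n_nodes) if self.parent[nd] != -1]

    # -- transition matrices -----------------------------------------

    def _category_pmats(self, kappa, pi, props, omegas_ref, omegas_test, scaler):
        """(ncat, n_nodes, 61, 61) transition matrices for every branch.

        All categories share one normalisation rho, the expected
        substitution rate of the reference mixture, so branch lengths
        are expected substitutions/site under the reference process.
        """
        pi = np.asarray(pi, dtype=float)
        pi_key = hash(pi.tobytes())
        ref_entries = [self._spectra.get(kappa, w, pi, pi_key) for w in omegas_ref]
        rho = float(sum(p * e[3] for p, e in zip(props, ref_entries)))
        if rho <= 0:
            raise ValueError("reference mixture has zero expected rate")
        test_entries = [self._spectra.get(kappa, w, pi, pi_key) for w in omegas_test]

        ncat = len(omegas_ref)
        n_nodes = len(self.parent)
        ts = self.blen * (scaler / rho)
        pmats = np.empty((ncat, n_nodes, N_CODONS, N_CODONS))
        ref_nodes = [nd for nd in self.branches if not self.is_test[nd]]
        test_nodes = [nd for nd in self.branches if self.is_test[nd]]
        for ci in range(ncat):
            for nodes, (lam, left, right, _) in (
                (ref_nodes, ref_entries[ci]),
                (test_nodes, test_entries[ci]),
            ):
                if not nodes:
                    continue
                e = np.exp(np.multiply.outer(ts[nodes], lam))  # (m, 61)
                p = (left[None, :, :] * e[:, None, :]) @ right
                np.clip(p, 0.0, None, out=p)
                pmats[ci, nodes] = p
        return pmats

    # -- inside (pruning) pass ---------------------------------------

    def _inside(self, pmats: np.ndarray):
        """Batched post-order partials over all categories.

        Returns (down, logscale): ``down[node]`` has shape
        (ncat, n_patterns, 61); ``logscale`` (ncat, n_patterns)
        accumulates per-pattern rescaling at the root.
        """
        ncat = pmats.shape[0]
        down: dict[int, np.ndarray] = {}
        logscale = np.zeros((ncat, self.n_patterns))
        # rescaling is only checked every few internal nodes: partials on
        # study-sized trees stay far above the underflow floor
        internal_seen = 0
        for nd in self.postorder:
            kids = self.children[nd]
            if not kids:
                down[nd] = np.broadcast_to(
                    self.leaf_partials[nd], (ncat, self.n_patterns, N_CODONS)
                )
                continue
            acc = None
            for c in kids:
                term = down[c] @ pmats[:, c].transpose(0, 2, 1)
                acc = term if acc is None else acc * term
                del down[c]
            internal_seen += 1
            if internal_seen % 8 == 0 or nd == self.root:
                m = acc.max(axis=2)
                if m.min() < _RESCALE_FLOOR:
                    safe = np.where(m > 0, m, 1.0)
                    acc = acc / safe[:, :, None]
                    logscale += np.log(safe)
            down[nd] = acc
        return down[self.root], logscale

    def _mixture_site_loglik(self, pi, pmats, props):
        """Per-pattern log-likelihood of the category mixture."""
        root_down, logscale = self._inside(pmats)
        site_l = root_down @ pi  # (ncat, npat)
        keep = np.asarray(props) > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            per_cat = np.log(site_l) + logscale
            log_props = np.where(keep, np.log(np.where(keep, props, 1.0)), -np.inf)
        stacked = per_cat + log_props[:, None]
        mx = stacked.max(axis=0)
        mx = np.where(np.isfinite(mx), mx, 0.0)
        with np.errstate(divide="ignore"):
            out = mx + np.log(np.exp(stacked - mx[None, :]).sum(axis=0))
        return out

    # -- public likelihoods ------------------------------------------

    def lnL(self, model: CodonModel, scaler: float = 1.0) -> float:
        """Log-likelihood of the alignment under a site-mixture model."""
        pmats = self._category_pmats(
            model.kappa,
            model.codon_freqs,
            model.proportions,
            model.omegas,
            model.test_omegas(),
            scaler,
        )
        site_ll = self._mixture_site_loglik(model.codon_freqs, pmats, model.proportions)
        return float(site_ll @ self.pattern_weights)

    def site_logliks(self, model: CodonModel, scaler: float = 1.0) -> np.ndarray:
        """Per-site (uncompressed) log-likelihoods."""
        pmats = self._category_pmats(
            model.kappa,
            model.codon_freqs,
            model.proportions,
            model.omegas,
            model.test_omegas(),
            scaler,
        )
        site_ll = self._mixture_site_loglik(model.codon_freqs, pmats, model.proportions)
        return site_ll[self.pattern_of_site]

    # -- branch-site support -----------------------------------------

    def branch_context(self, kappa, pi, omega_bg, scaler=1.0):
        """Background-process inside/outside pass for focal-branch fits."""
        return BranchContext(self, kappa, np.asarray(pi, float), omega_bg, scaler)


class BranchContext:
    """Everything of the tree frozen to a single background omega; the
    likelihood as a function of one focal branch's omega mixture.

    The focal branch keeps the background normalisation, so its length
    stays in background expected-substitutions units while its omega
    mixture varies (the branch-site convention)."""

    def __init__(self, engine: PruningEngine, kappa, pi, omega_bg, scaler):
        self.engine = engine
        self.kappa = kappa
        self.pi = pi
        self.pi_key = hash(np.asarray(pi, float).tobytes())
        self.omega_bg = omega_bg
        self.scaler = scaler

        lam, left, right, rate = engine._spectra.get(kappa, omega_bg, pi, self.pi_key)
        self.rho = rate
        ts = engine.blen * (scaler / rate)
        self.pmats = {}
        for nd in engine.branches:
            e = np.exp(lam * ts[nd])
            self.pmats[nd] = np.clip((left * e[None, :]) @ right, 0.0, None)
        self._inside_pass()
        self._outside_pass()

    def _inside_pass(self):
        eng = self.engine
        down: dict[int, np.ndarray] = {}
        scales: dict[int, np.ndarray] = {}
        for nd in eng.postorder:
            kids = eng.children[nd]
            if not kids:
                down[nd] = eng.leaf_partials[nd]
                scales[nd] = np.zeros(eng.n_patterns)
                continue
            acc = None
            sc = np.zeros(eng.n_patterns)
            for c in kids:
                term = down[c] @ self.pmats[c].T
                acc = term if acc is None else acc * term
                sc += scales[c]
            m = acc.max(axis=1)
            if m.min() < _RESCALE_FLOOR:
                safe = np.where(m > 0, m, 1.0)
                acc = acc / safe[:, None]
                sc += np.log(safe)
            down[nd] = acc
            scales[nd] = sc
        self.down = down
        self.down_scales = scales

    def _outside_pass(self):
        """out[node]: likelihood of data outside node's subtree as a
        function of the state at the *parent end* of node's branch,
        including pi at the root."""
        eng = self.engine
        out: dict[int, np.ndarray] = {}
        out_scales: dict[int, np.ndarray] = {}
        root = eng.root
        for nd in reversed(eng.postorder):
            kids = eng.children[nd]
            if not kids:
                continue
            if nd == root:
                base = np.tile(self.pi, (eng.n_patterns, 1))
                base_sc = np.zeros(eng.n_patterns)
            else:
                base = out[nd] @ self.pmats[nd]
                base_sc = out_scales[nd]
            for c in kids:
                acc = base.copy()
                sc = base_sc.copy()
                for s in kids:
                    if s == c:
                        continue
                    acc *= self.down[s] @ self.pmats[s].T
                    sc += self.down_scales[s]
                m = acc.max(axis=1)
                if m.min() < _RESCALE_FLOOR:
                    safe = np.where(m > 0, m, 1.0)
                    acc = acc / safe[:, None]
                    sc += np.log(safe)
                out[c] = acc
                out_scales[c] = sc
        self.out = out
        self.out_scales = out_scales

    def background_lnL(self) -> float:
        site = self.down[self.engine.root] @ self.pi
        ll = np.log(site) + self.down_scales[self.engine.root]
        return float(ll @ self.engine.pattern_weights)

    def branch_lnL(self, node: int, omegas, props) -> float:
        """lnL with the branch above ``node`` given an omega mixture and
        every other branch at the background omega."""
        eng = self.engine
        if eng.parent[node] == -1:
            raise ValueError("the root carries no branch")
        t = eng.blen[node] * (self.scaler / self.rho)
        pre = self.out[node]  # (npat, 61) at parent end
        below = self.down[node]
        sc = self.out_scales[node] + self.down_scales[node]
        site = np.zeros(eng.n_patterns)
        for w, p in zip(omegas, props):
            if p <= 0:
                continue
            lam, left, right, _ = eng._spectra.get(
                self.kappa, float(w), self.pi, self.pi_key
            )
            pmat = np.clip((left * np.exp(lam * t)[None, :]) @ right, 0.0, None)
            site += p * np.einsum("pi,ij,pj->p", pre, pmat, below, optimize=True)
        with np.errstate(divide="ignore"):
            ll = np.log(site) + sc
        val = float(ll @ eng.pattern_weights)
        return val


def log_likelihood(
    aln: CodonAlignment, tree: LabelledTree, model: CodonModel, scaler: float = 1.0
) -> float:
    """Pruning log-likelihood of a codon alignment under an omega^k model."""
    return PruningEngine(aln, tree).lnL(model, scaler)
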