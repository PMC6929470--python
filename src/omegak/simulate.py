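"""Forward simulation of codon alignments and planted-truth studies.

The default study emulates the comparative design the package targets:
a 10-taxon salmonid-like tree whose two foreground cherries (whitefish-
and charr-like genus pairs) are labelled as test branches, orthogroups
planted in four selection classes —

* relaxed       k < 1 on test branches (default 0.2)
* neutral       k = 1
* intensified   k > 1 on test branches (default 5)
* episodic      k = 1 background plus one test branch with a fraction of
                sites under strong positive selection (omega = 5 on 20%
                of sites by default)

— and GO annotations with terms planted preferentially on one class at a
configured odds ratio.  Every output is a deterministic function of the
master seed; each orthogroup gets its own RNG stream derived from
(master seed, orthogroup index) so subsets reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import CodonAlignment, write_codon_alignment
from .genetic_code import SENSE_CODONS
from .likelihood import PruningEngine  # noqa: F401  (re-exported convenience)
from .model import CodonModel
from .rates import SpectralQ, build_rate_matrix, expected_rate, f3x4_frequencies
from .trees import LabelledTree

FOREGROUND_GROUPS = [
    ["Coregonus_sp1", "Coregonus_sp2"],
    ["Salvelinus_sp1", "Salvelinus_sp2"],
]

_DEFAULT_NEWICK = (
    "(((Coregonus_sp1:0.04,Coregonus_sp2:0.045):0.09,Thymallus_sp:0.18):0.07,"
    "((Salvelinus_sp1:0.035,Salvelinus_sp2:0.04):0.09,"
    "((Salmo_sp1:0.07,Salmo_sp2:0.065):0.1,"
    "(Oncorhynchus_sp1:0.075,Oncorhynchus_sp2:0.07):0.1):0.07):0.08,"
    "Esox_sp:0.2);"
)

#: plausible coding-sequence positional nucleotide frequencies (rows =
#: codon positions, columns = ACGT)
DEFAULT_POSITIONAL_NT = np.array(
    [
        [0.26, 0.21, 0.31, 0.22],
        [0.30, 0.23, 0.18, 0.29],
        [0.22, 0.28, 0.26, 0.24],
    ]
)

DEFAULT_KAPPA = 2.5
# the conserved bin sits at omega = 0.15 rather than near 0: as omega -> 0
# the test-branch deformation omega^k degenerates along a k*ln(omega) ridge
# and the selection-intensity exponent stops being recoverable
DEFAULT_OMEGAS = (0.15, 0.8, 2.0)
DEFAULT_PROPS = (0.45, 0.45, 0.1)


def default_tree(labelled: bool = True) -> LabelledTree:
    """The fixed 10-taxon study tree (two labelled foreground cherries)."""
    tree = LabelledTree.from_newick(_DEFAULT_NEWICK)
    if labelled:
        tree = tree.with_labels(FOREGROUND_GROUPS, mode="clade")
    return tree


def default_model(k: float = 1.0) -> CodonModel:
    return CodonModel(
        kappa=DEFAULT_KAPPA,
        codon_freqs=f3x4_frequencies(DEFAULT_POSITIONAL_NT),
        omega_categories=list(zip(DEFAULT_OMEGAS, DEFAULT_PROPS)),
        k=k,
    )


@dataclass
class Episode:
    """A diversifying-selection episode on one test branch."""

    omega: float = 5.0
    fraction: float = 0.2
    branch: int | None = None  # node id; None = longest test branch


def _sample_states(p: np.ndarray, parents: np.ndarray, rng) -> np.ndarray:
    """Child states for each site given parent states and one P matrix."""
    cum = np.cumsum(p, axis=1)
    u = rng.random(parents.shape[0])
    rows = cum[parents]
    return (rows >= np.minimum(u, rows[:, -1] - 1e-15)[:, None]).argmax(axis=1)


def simulate_alignment(
    tree: LabelledTree,
    model: CodonModel,
    n_codons: int,
    seed=None,
    *,
    rng=None,
    episode: Episode | None = None,
) -> CodonAlignment:
    """Simulate a gapless codon alignment under the omega^k model.

    Root codons are drawn from pi; each site is assigned an omega
    category; branches evolve by the category's transition matrix, with
    test branches using omega_i^k.  ``episode`` overrides one test
    branch: a random site fraction evolves there at the episode omega.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    pi = model.codon_freqs
    props = model.proportions
    omegas_ref = model.omegas
    omegas_test = model.test_omegas()

    qs = [build_rate_matrix(model.kappa, w, pi, normalise=False) for w in omegas_ref]
    rho = sum(p * expected_rate(q, pi) for p, q in zip(props, qs))
    spectra = {}

    def spectrum(w: float) -> SpectralQ:
        key = round(float(w), 12)
        if key not in spectra:
            q = build_rate_matrix(model.kappa, float(w), pi, normalise=False)
            spectra[key] = SpectralQ(q / rho, pi)
        return spectra[key]

    site_cat = rng.choice(len(props), size=n_codons, p=props)
    root_state = rng.choice(len(pi), size=n_codons, p=pi)

    ep_branch = None
    ep_sites = None
    if episode is not None:
        test_nodes = [
            nd for nd in range(tree.n_nodes)
            if tree.parent[nd] != -1 and tree.is_test[nd]
        ]
        if not test_nodes:
            raise ValueError("episode requested but the tree has no test branches")
        if episode.branch is not None:
            if episode.branch not in test_nodes:
                raise ValueError(f"episode branch {episode.branch} is not a test branch")
            ep_branch = episode.branch
        else:
            ep_branch = max(test_nodes, key=lambda nd: tree.blen[nd])
        n_ep = int(round(episode.fraction * n_codons))
        ep_sites = rng.choice(n_codons, size=n_ep, replace=False)

    states = {tree.root: root_state}
    for nd in reversed(tree.postorder):  # preorder
        for child in tree.children[nd]:
            t = tree.blen[child]
            parent_states = states[nd]
            child_states = np.empty(n_codons, dtype=np.int64)
            for ci in range(len(props)):
                sel = site_cat == ci
                if not sel.any():
                    continue
                w = omegas_test[ci] if tree.is_test[child] else omegas_ref[ci]
                pmat = spectrum(w).transition(t)
                child_states[sel] = _sample_states(pmat, parent_states[sel], rng)
            if ep_branch is not None and child == ep_branch and len(ep_sites):
                pmat = spectrum(episode.omega).transition(t)
                child_states[ep_sites] = _sample_states(
                    pmat, parent_states[ep_sites], rng
                )
            states[child] = child_states

    leaf_ids = sorted(tree.taxon_of)
    taxa = [tree.taxon_of[i] for i in leaf_ids]
    seqs = [
        "".join(SENSE_CODONS[s] for s in states[i]) for i in leaf_ids
    ]
    aln = CodonAlignment(taxa, seqs)
    aln.site_categories = site_cat  # planted truth, for tests
    aln.episode_branch = ep_branch
    aln.episode_sites = None if ep_sites is None else np.sort(ep_sites)
    return aln


# -- study-level simulation ------------------------------------------


@dataclass
class ClassSpec:
    """One selection class in the study design."""

    label: str  # relaxed | neutral | intensified | episodic
    count: int
    k: float = 1.0
    episode: Episode | None = None

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("class count must be >= 0")
        if self.label not in ("relaxed", "neutral", "intensified", "episodic"):
            raise ValueError(f"unknown class label {self.label!r}")


@dataclass
class GOConfig:
    n_terms: int = 60
    mean_terms_per_og: float = 3.0
    planted_terms: dict = field(
        default_factory=lambda: {"relaxed": 1, "intensified": 1}
    )  # class -> number of planted terms
    baseline_prob: float = 0.12
    odds_ratio: float = 10.0


DEFAULT_CLASS_TABLE = [
    ClassSpec("relaxed", 20, k=0.2),
    ClassSpec("neutral", 20, k=1.0),
    ClassSpec("intensified", 20, k=5.0),
]


@dataclass
class SimulationConfig:
    tree: LabelledTree = field(default_factory=default_tree)
    n_codons: int = 300
    class_table: list = field(default_factory=lambda: list(DEFAULT_CLASS_TABLE))
    go_config: GOConfig = field(default_factory=GOConfig)
    kappa: float = DEFAULT_KAPPA
    omegas: tuple = DEFAULT_OMEGAS
    props: tuple = DEFAULT_PROPS
    seed: int = 0


@dataclass
class Study:
    """A simulated orthogroup study with its planted truth."""

    orthogroups: dict  # og_id -> (CodonAlignment, LabelledTree)
    go_map: dict  # og_id -> set of GO term ids
    truth: pd.DataFrame
    go_truth: pd.DataFrame  # term, enriched_in_class
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for og_id, (aln, tree) in self.orthogroups.items():
            write_codon_alignment(aln, outdir / f"{og_id}.fasta")
            tree.write(outdir / f"{og_id}.nwk")
        rows = [
            {"orthogroup_id": og, "go_terms": ";".join(sorted(terms))}
            for og, terms in self.go_map.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "go_map.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.go_truth.to_csv(outdir / "go_truth.tsv", sep="\t", index=False)


def _go_term_name(i: int) -> str:
    return f"GO:{i + 1:07d}"


def simulate_study(config: SimulationConfig) -> Study:
    """Simulate a full orthogroup study with planted classes and GO terms."""
    tree = config.tree
    base = CodonModel(
        kappa=config.kappa,
        codon_freqs=f3x4_frequencies(DEFAULT_POSITIONAL_NT),
        omega_categories=list(zip(config.omegas, config.props)),
        k=1.0,
    )

    orthogroups = {}
    truth_rows = []
    og_index = 0
    for spec in config.class_table:
        for _ in range(spec.count):
            og_id = f"OG{og_index:04d}"
            rng = np.random.default_rng((config.seed, og_index))
            episode = spec.episode
            if spec.label == "episodic" and episode is None:
                episode = Episode()
            model = replace(base, k=spec.k) if spec.k != base.k else base
            aln = simulate_alignment(
                tree, model, config.n_codons, rng=rng, episode=episode
            )
            orthogroups[og_id] = (aln, tree)
            truth_rows.append(
                {
                    "orthogroup_id": og_id,
                    "class": spec.label,
                    "true_k": spec.k,
                    "episodic_branch": (
                        aln.episode_branch if episode is not None else -1
                    ),
                    "episodic_fraction": (
                        episode.fraction if episode is not None else 0.0
                    ),
                }
            )
            og_index += 1

    truth = pd.DataFrame(truth_rows)
    go_map, go_truth = _simulate_go(config, truth)
    return Study(orthogroups, go_map, truth, go_truth, config)


def simulate_go_annotations(config: SimulationConfig, truth: pd.DataFrame):
    """GO maps alone (planted enrichment included) for an existing
    study truth table — used to replicate annotation noise around one
    set of fitted orthogroups."""
    return _simulate_go(config, truth)


def _simulate_go(config: SimulationConfig, truth: pd.DataFrame):
    gc = config.go_config
    rng = np.random.default_rng((config.seed, 982_451_653))
    og_ids = truth["orthogroup_id"].tolist()
    classes = dict(zip(truth["orthogroup_id"], truth["class"]))

    planted = []  # (term, class)
    term_idx = 0
    for cls, n in gc.planted_terms.items():
        if cls not in set(classes.values()):
            continue
        for _ in range(n):
            planted.append((_go_term_name(term_idx), cls))
            term_idx += 1
    background_terms = [
        _go_term_name(i) for i in range(term_idx, gc.n_terms)
    ]

    go_map: dict[str, set] = {og: set() for og in og_ids}
    p0 = gc.baseline_prob
    odds0 = p0 / (1 - p0)
    p1 = gc.odds_ratio * odds0 / (1 + gc.odds_ratio * odds0)
    for term, cls in planted:
        for og in og_ids:
            p = p1 if classes[og] == cls else p0
            if rng.random() < p:
                go_map[og].add(term)
    if background_terms:
        for og in og_ids:
            n = rng.poisson(gc.mean_terms_per_og)
            if n > 0:
                picks = rng.choice(
                    len(background_terms), size=min(n, len(background_terms)),
                    replace=False,
                )
                go_map[og].update(background_terms[i] for i in picks)

    go_truth = pd.DataFrame(
        [{"term": t, "enriched_in_class": c} for t, c in planted]
        + [{"term": t, "enriched_in_class": ""} for t in background_terms]
    )
    return go_map, go_truth


# -- mock transcripts for the filtering pipeline ---------------------
#
# The filter fixture plants one group per violation class next to clean
# groups, so the audit log of the filter pipeline can be compared with
# the planted truth exactly.

from .orthogroups import (  # noqa: E402  (fixture generator lives with the simulator)
    Member,
    RawOrthogroup,
    ReferenceGeneMap,
    longest_orf,
    reverse_complement,
)

_NT = "ACGT"


def _random_sense_codon(rng) -> str:
    while True:
        codon = "".join(_NT[i] for i in rng.integers(0, 4, 3))
        if codon not in ("TAA", "TAG", "TGA"):
            return codon


def random_cds(rng, n_codons: int) -> str:
    """ATG + random sense codons + stop."""
    body = "".join(_random_sense_codon(rng) for _ in range(n_codons - 2))
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + body + stop


def _orf_free_flank(rng, length: int) -> str:
    """Random flank containing no ATG (forward start) and no CAT
    (reverse-strand start read on the forward sequence)."""
    out: list[str] = []
    while len(out) < length:
        ch = _NT[rng.integers(0, 4)]
        tail = "".join(out[-2:]) + ch
        if tail.endswith(("ATG", "CAT")):
            continue
        out.append(ch)
    return "".join(out)


def embed_in_utrs(rng, cds: str, utr_range=(30, 120), reverse: bool = False) -> str:
    """Place a CDS between ORF-free UTR flanks; optionally report the
    reverse-complement strand.  Junctions are re-drawn until no start
    codon spans a flank/CDS boundary and the planted CDS is recovered
    as the longest ORF on either strand."""
    for _ in range(40):
        left = _orf_free_flank(rng, int(rng.integers(*utr_range)))
        right = _orf_free_flank(rng, int(rng.integers(*utr_range)))
        transcript = left + cds + right
        window_bad = any(
            x in (transcript[max(0, len(left) - 2) : len(left) + 2],
                  transcript[len(left) + len(cds) - 2 : len(left) + len(cds) + 2])
            for x in ("ATG", "CAT")
        )
        # the CDS's own ATG at the junction is expected; only reverse
        # starts or upstream extensions are a problem, caught below
        orf = longest_orf(transcript, min_len=min(len(cds), 200), both_strands=True)
        if orf is not None and orf.sequence == cds and not window_bad:
            return reverse_complement(transcript) if reverse else transcript
    raise RuntimeError("could not embed CDS without spurious ORFs")


def generate_mock_transcripts(
    reference_map: dict,
    seed=None,
    *,
    rng=None,
    utr_range=(30, 120),
    reverse_prob: float = 0.3,
) -> dict:
    """(species, gene_id) -> transcript, embedding each CDS of a
    species->gene->CDS mapping in UTR flanks; a ``reverse_prob``
    fraction of transcripts is reported on the reverse strand."""
    if rng is None:
        rng = np.random.default_rng(seed)
    out = {}
    for (species, gene_id), cds in reference_map.items():
        reverse = bool(rng.random() < reverse_prob)
        out[(species, gene_id)] = embed_in_utrs(
            rng, cds, utr_range=utr_range, reverse=reverse
        )
    return out


@dataclass
class FilterStudy:
    """Mock raw orthogroups with planted filter violations."""

    raw_groups: list
    reference_map: ReferenceGeneMap
    expected_dropped: dict  # group_id -> stage expected to drop it
    transcripts: dict  # (species, gene_id) -> transcript


def _mutated_cds(rng, cds: str, rate: float = 0.05) -> str:
    codons = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
    for i in range(len(codons)):
        if rng.random() < rate:
            codons[i] = _random_sense_codon(rng)
    return cds[:3] + "".join(codons) + cds[-3:]


def simulate_filter_study(seed=0, n_good: int = 12, n_species: int = 25) -> FilterStudy:
    """A filter-pipeline fixture: ``n_good`` clean orthogroups plus one
    group per planted violation class (unmapped members, collapsed
    orthologue, copy excess, too small, too large, too few taxa,
    duplicated orthogroup, short ORFs only)."""
    rng = np.random.default_rng((seed, 424_243))
    species = [f"Sp{i:02d}" for i in range(1, n_species + 1)]
    ref_cds: dict[str, str] = {}
    orthologues: dict[str, set] = {}
    groups: list[RawOrthogroup] = []
    expected: dict[str, str] = {}
    transcripts: dict = {}

    def new_ref(name: str, n_codons: int | None = None) -> str:
        n = int(n_codons or rng.integers(100, 200))
        ref_cds[name] = random_cds(rng, n)
        return name

    def add_member(group, sp, gene, cds, mapped_to=None, mutate=True):
        seq = _mutated_cds(rng, cds) if mutate else cds
        reverse = bool(rng.random() < 0.3)
        tr = embed_in_utrs(rng, seq, reverse=reverse)
        transcripts[(sp, gene)] = tr
        if mapped_to:
            orthologues[gene] = set(mapped_to)
        group.members.append(Member(sp, gene, tr))

    # clean groups: one reference gene, eight species, one copy each
    for i in range(n_good):
        ref = new_ref(f"REF{i:04d}")
        g = RawOrthogroup(f"OGF{i:04d}")
        for sp in species[:8]:
            add_member(g, sp, f"{sp}_g{i}", ref_cds[ref], mapped_to=[ref])
        groups.append(g)

    # unmapped: members that hit nothing in the reference genome
    g = RawOrthogroup("VIOL_unmapped")
    orphan = random_cds(rng, 150)
    for sp in species[:8]:
        add_member(g, sp, f"{sp}_orphan", orphan, mapped_to=None)
    groups.append(g)
    expected[g.id] = "match_reference"

    # collapsed orthologue: reference predicts 2 genes, one species has 1
    ra, rb = new_ref("REFCOLa"), new_ref("REFCOLb")
    g = RawOrthogroup("VIOL_collapsed")
    for sp in species[:7]:
        add_member(g, sp, f"{sp}_ca", ref_cds[ra], mapped_to=[ra])
        add_member(g, sp, f"{sp}_cb", ref_cds[rb], mapped_to=[rb])
    add_member(g, species[7], f"{species[7]}_ca", ref_cds[ra], mapped_to=[ra])
    groups.append(g)
    expected[g.id] = "collapsed"

    # copy excess: one species with five copies
    rc = new_ref("REFCOPY")
    g = RawOrthogroup("VIOL_copies")
    for j in range(5):
        add_member(g, species[0], f"{species[0]}_x{j}", ref_cds[rc], mapped_to=[rc])
    for sp in species[1:8]:
        add_member(g, sp, f"{sp}_x", ref_cds[rc], mapped_to=[rc])
    groups.append(g)
    expected[g.id] = "collapsed"

    # too small (6 sequences)
    rs = new_ref("REFSMALL")
    g = RawOrthogroup("VIOL_small")
    for sp in species[:6]:
        add_member(g, sp, f"{sp}_s", ref_cds[rs], mapped_to=[rs])
    groups.append(g)
    expected[g.id] = "size_taxon"

    # too large (84 sequences over 21 species, all copy counts <= 4)
    rl = new_ref("REFLARGE", n_codons=110)
    g = RawOrthogroup("VIOL_large")
    for sp in species[:21]:
        for j in range(4):
            add_member(g, sp, f"{sp}_L{j}", ref_cds[rl], mapped_to=[rl])
    groups.append(g)
    expected[g.id] = "size_taxon"

    # too few taxa (8 sequences over 6 species)
    rt = new_ref("REFTAXA")
    g = RawOrthogroup("VIOL_taxa")
    for sp in species[:6]:
        add_member(g, sp, f"{sp}_t", ref_cds[rt], mapped_to=[rt])
    add_member(g, species[0], f"{species[0]}_t2", ref_cds[rt], mapped_to=[rt])
    add_member(g, species[1], f"{species[1]}_t2", ref_cds[rt], mapped_to=[rt])
    groups.append(g)
    expected[g.id] = "size_taxon"

    # duplicated orthogroup: byte-identical copy of the first clean group
    dup = RawOrthogroup("VIOL_dup", members=list(groups[0].members))
    groups.append(dup)
    expected[dup.id] = "merge_dedup"

    # short ORFs only (150 nt < 200 nt minimum)
    ro = new_ref("REFSHORT", n_codons=50)  # 150 nt
    g = RawOrthogroup("VIOL_shortorf")
    for sp in species[:7]:
        add_member(g, sp, f"{sp}_sh", ref_cds[ro], mapped_to=[ro], mutate=False)
    groups.append(g)
    expected[g.id] = "orf"

    ref_map = ReferenceGeneMap(cds=ref_cds, orthologues=orthologues)
    return FilterStudy(groups, ref_map, expected, transcripts)
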