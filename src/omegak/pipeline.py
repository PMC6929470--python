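"""Staged analysis pipeline: simulate -> filter -> fit -> classify ->
enrich -> gsea -> report.

Each stage reads its inputs from the run directory and writes TSV/JSON
outputs plus a machine-readable manifest (stage, input/output hashes,
seed, row counts), so a full run and the chained per-stage commands
produce identical artefacts and any bundle can be reproduced from its
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignment import read_codon_alignment
from .relax import FitConfig
from .selection import branch_site_table, screen_orthogroups
from .simulate import (
    ClassSpec,
    Episode,
    GOConfig,
    SimulationConfig,
    simulate_filter_study,
    simulate_study,
)
from .stats import (
    classify_orthogroups,
    enrichment_table,
    go_term_k_tests,
    gsea,
    overlap_stats,
    sign_balance_test,
    transform_k,
    wilcoxon_signed_rank,
)
from .orthogroups import filter_pipeline
from .trees import read_newick

logger = logging.getLogger(__name__)

STAGES = ["simulate", "filter", "fit", "classify", "enrich", "gsea", "report"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    Thresholds mirror the analysis defaults: minimum ORF length 200 nt,
    orthogroup size 7..80 sequences over >= 7 taxa, FDR 0.10, alpha
    0.05, 10,000 GSEA permutations, k capped at 50.
    """

    outdir: str = "results/run"
    seed: int = 1
    stages: list = field(default_factory=lambda: list(STAGES))
    # study design
    n_codons: int = 300
    n_relaxed: int = 20
    n_neutral: int = 20
    n_intensified: int = 20
    n_episodic: int = 0
    relaxed_k: float = 0.2
    intensified_k: float = 5.0
    # filtering thresholds
    min_orf_len: int = 200
    min_seqs: int = 7
    max_seqs: int = 80
    min_taxa: int = 7
    max_copies: int = 4
    # statistics
    fdr: float = 0.10
    alpha: float = 0.05
    n_perm: int = 10_000
    k_max: float = 50.0
    min_go_n: int = 5
    min_set_size: int = 5
    # selection-test machinery
    run_branch_site: bool = True
    label_mode: str = "clade"
    # foreground taxon groups; empty = keep the labels carried by the
    # input trees (the simulator's default foreground)
    foreground: list = field(default_factory=list)

    def validate(self) -> None:
        if not 0 < self.fdr < 1 or not 0 < self.alpha < 1:
            raise ValueError("fdr and alpha must lie in (0, 1)")
        if self.min_seqs > self.max_seqs:
            raise ValueError("min_seqs must not exceed max_seqs")
        for name in ("n_codons", "min_orf_len", "n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, seed, inputs, outputs, counts):
    manifest = {
        "stage": stage,
        "seed": seed,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        "row_counts": counts,
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _study_dir(outdir: Path) -> Path:
    return outdir / "study"


def _load_study_orthogroups(outdir: Path):
    study_dir = _study_dir(outdir)
    if not study_dir.is_dir():
        raise FileNotFoundError(
            "missing simulate-stage output; run the 'simulate' stage first"
        )
    orthogroups = {}
    for fasta in sorted(study_dir.glob("OG*.fasta")):
        og_id = fasta.stem
        aln = read_codon_alignment(fasta)
        tree = read_newick(study_dir / f"{og_id}.nwk")
        orthogroups[og_id] = (aln, tree)
    return orthogroups


def _load_go_map(outdir: Path) -> dict:
    path = _study_dir(outdir) / "go_map.tsv"
    if not path.exists():
        raise FileNotFoundError("missing go_map.tsv; run the 'simulate' stage first")
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return {
        row.orthogroup_id: set(row.go_terms.split(";")) if row.go_terms else set()
        for row in df.itertuples()
    }


# -- stages ----------------------------------------------------------


def stage_simulate(cfg: RunConfig, outdir: Path):
    classes = []
    if cfg.n_relaxed:
        classes.append(ClassSpec("relaxed", cfg.n_relaxed, k=cfg.relaxed_k))
    if cfg.n_neutral:
        classes.append(ClassSpec("neutral", cfg.n_neutral, k=1.0))
    if cfg.n_intensified:
        classes.append(ClassSpec("intensified", cfg.n_intensified, k=cfg.intensified_k))
    if cfg.n_episodic:
        classes.append(ClassSpec("episodic", cfg.n_episodic, k=1.0, episode=Episode()))
    sim = SimulationConfig(
        n_codons=cfg.n_codons, class_table=classes, go_config=GOConfig(), seed=cfg.seed
    )
    study = simulate_study(sim)
    study.write(_study_dir(outdir))
    outputs = sorted(_study_dir(outdir).glob("*"))
    return _write_manifest(
        outdir, "simulate", cfg.seed, [], outputs,
        {"orthogroups": len(study.orthogroups)},
    )


def stage_filter(cfg: RunConfig, outdir: Path):
    fs = simulate_filter_study(seed=cfg.seed)
    kept, audit = filter_pipeline(
        fs.raw_groups, fs.reference_map,
        min_orf_len=cfg.min_orf_len, min_seqs=cfg.min_seqs,
        max_seqs=cfg.max_seqs, min_taxa=cfg.min_taxa, max_copies=cfg.max_copies,
    )
    audit_path = outdir / "filter_audit.tsv"
    audit.to_csv(audit_path, sep="\t", index=False)
    truth = pd.DataFrame(
        [{"group_id": g, "expected_stage": s} for g, s in sorted(fs.expected_dropped.items())]
    )
    truth_path = outdir / "filter_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return _write_manifest(
        outdir, "filter", cfg.seed, [], [audit_path, truth_path],
        {"kept_groups": len(kept), "audit_rows": len(audit)},
    )


def stage_fit(cfg: RunConfig, outdir: Path):
    orthogroups = _load_study_orthogroups(outdir)
    if cfg.foreground:
        from .trees import label_foreground

        orthogroups = {
            og: (aln, label_foreground(tree, cfg.foreground, mode=cfg.label_mode))
            for og, (aln, tree) in orthogroups.items()
        }
    fit_cfg = FitConfig(k_max=cfg.k_max)
    table, _, bs_results = screen_orthogroups(
        orthogroups, config=fit_cfg, run_branch_site=cfg.run_branch_site,
        progress=True, return_details=True,
    )
    ktable_path = outdir / "ktable.tsv"
    table.to_csv(ktable_path, sep="\t", index=False)
    outputs = [ktable_path]
    if cfg.run_branch_site:
        bs_path = outdir / "branch_site.tsv"
        branch_site_table(bs_results).to_csv(bs_path, sep="\t", index=False)
        outputs.append(bs_path)
    ins = sorted(_study_dir(outdir).glob("OG*.fasta"))
    return _write_manifest(
        outdir, "fit", cfg.seed, ins, outputs, {"orthogroups": len(table)}
    )


def stage_classify(cfg: RunConfig, outdir: Path):
    ktable_path = outdir / "ktable.tsv"
    if not ktable_path.exists():
        raise FileNotFoundError("missing ktable.tsv; run the 'fit' stage first")
    table = pd.read_csv(ktable_path, sep="\t")
    classified = classify_orthogroups(table, fdr=cfg.fdr)
    out_path = outdir / "classification.tsv"
    classified.to_csv(out_path, sep="\t", index=False)

    k = classified["k_hat"].dropna().to_numpy()
    wil = wilcoxon_signed_rank(k, mu=1.0)
    sign = sign_balance_test(k)
    summary = {
        "n_orthogroups": int(len(classified)),
        "median_k": float(np.median(k)) if k.size else np.nan,
        "n_k_below_1": int((k < 1).sum()),
        "n_k_above_1": int((k > 1).sum()),
        "wilcoxon_V": wil.statistic,
        "wilcoxon_p": wil.p,
        "sign_test_p": sign.p,
        "n_relaxed": int(classified["relaxed"].sum()),
        "n_intensified": int(classified["intensified"].sum()),
        "n_diversifying": int(classified["diversifying"].sum()),
        "fdr": cfg.fdr,
    }
    sum_path = outdir / "selection_summary.json"
    sum_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    from .viz import plot_k_histogram

    plot_k_histogram(k, outdir / "k_histogram.png")
    return _write_manifest(
        outdir, "classify", cfg.seed, [ktable_path], [out_path, sum_path],
        {"orthogroups": len(classified)},
    )


def stage_enrich(cfg: RunConfig, outdir: Path):
    cls_path = outdir / "classification.tsv"
    if not cls_path.exists():
        raise FileNotFoundError("missing classification.tsv; run 'classify' first")
    classified = pd.read_csv(cls_path, sep="\t")
    go_map = _load_go_map(outdir)
    universe = {og for og in classified["orthogroup_id"] if go_map.get(og)}

    outputs = []
    for label in ("relaxed", "intensified", "diversifying"):
        selected = set(classified.loc[classified[label], "orthogroup_id"]) & universe
        tab = enrichment_table(
            selected, universe, go_map, fdr=cfg.fdr, alpha=cfg.alpha
        )
        path = outdir / f"enrichment_{label}.tsv"
        tab.to_csv(path, sep="\t", index=False)
        outputs.append(path)

    go_k = go_term_k_tests(go_map, classified, alpha=cfg.alpha, min_n=cfg.min_go_n)
    gk_path = outdir / "go_k_tests.tsv"
    go_k.to_csv(gk_path, sep="\t", index=False)
    outputs.append(gk_path)
    from .viz import plot_go_k_violins

    k_of = dict(zip(classified["orthogroup_id"], classified["k_hat"]))
    plot_go_k_violins(go_k, k_of, go_map, outdir / "go_k_violins.png")

    n_uni = len(set(classified["orthogroup_id"]))
    rel = set(classified.loc[classified["relaxed"], "orthogroup_id"])
    inte = set(classified.loc[classified["intensified"], "orthogroup_id"])
    div = set(classified.loc[classified["diversifying"], "orthogroup_id"])
    overlaps = {}
    for name, (a, b) in {
        "relaxed_vs_diversifying": (rel, div),
        "intensified_vs_diversifying": (inte, div),
    }.items():
        exp, obs, p = overlap_stats(a, b, n_uni)
        overlaps[name] = {"expected": exp, "observed": obs, "fisher_p": p}
    ov_path = outdir / "overlap.json"
    ov_path.write_text(json.dumps(overlaps, indent=2, sort_keys=True) + "\n")
    outputs.append(ov_path)
    return _write_manifest(
        outdir, "enrich", cfg.seed, [cls_path], outputs,
        {"tested_terms": int(len(go_k))},
    )


def stage_gsea(cfg: RunConfig, outdir: Path):
    cls_path = outdir / "classification.tsv"
    if not cls_path.exists():
        raise FileNotFoundError("missing classification.tsv; run 'classify' first")
    classified = pd.read_csv(cls_path, sep="\t")
    go_map = _load_go_map(outdir)
    scores = {
        row.orthogroup_id: transform_k(row.k_hat)
        for row in classified.itertuples()
        if np.isfinite(row.k_hat)
    }
    gene_sets: dict[str, set] = {}
    for og, terms in go_map.items():
        for t in terms:
            gene_sets.setdefault(t, set()).add(og)
    results = gsea(
        scores, gene_sets, n_perm=cfg.n_perm, seed=(cfg.seed, 77),
        min_set_size=cfg.min_set_size,
    )
    table = pd.DataFrame(
        [
            {
                "gene_set": r.gene_set, "size": r.size, "ES": r.es, "NES": r.nes,
                "p": r.p, "q": r.q, "leading_edge": ";".join(r.leading_edge),
            }
            for r in results
        ]
    )
    path = outdir / "gsea.tsv"
    table.to_csv(path, sep="\t", index=False)
    from .viz import plot_gsea_top

    plot_gsea_top(results, outdir / "gsea_top.png")
    return _write_manifest(
        outdir, "gsea", cfg.seed, [cls_path], [path], {"gene_sets": len(table)}
    )


def stage_report(cfg: RunConfig, outdir: Path):
    manifests = sorted(outdir.glob("manifest_*.json"))
    bundle = {
        "config": dataclasses.asdict(cfg),
        "stages": [json.loads(p.read_text()) for p in manifests if "report" not in p.name],
    }
    path = outdir / "report.json"
    path.write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
    return _write_manifest(outdir, "report", cfg.seed, manifests, [path], {})


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "fit": stage_fit,
    "classify": stage_classify,
    "enrich": stage_enrich,
    "gsea": stage_gsea,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the stage manifests."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    manifests = {}
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        logger.info("running stage %s", stage)
        manifests[stage] = _STAGE_FUNCS[stage](cfg, outdir)
    return manifests
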