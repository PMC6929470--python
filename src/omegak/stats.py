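"""Downstream statistics over the per-orthogroup k-table.

Covers the distribution-level Wilcoxon test of k against the neutral
expectation of 1, the relaxed-vs-intensified count comparison, per-GO
k-deviation tests, Fisher enrichment with FDR control, overlap
hypergeometrics, the bounded k transform, and permutation GSEA over
transformed-k scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .correction import multiple_correction

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str
    n_effective: int


def wilcoxon_signed_rank(values, mu: float = 0.0, alternative: str = "two-sided") -> TestResult:
    """One-sample Wilcoxon signed-rank test of ``values`` against ``mu``.

    Zero differences are dropped; tied ranks are averaged.  The exact
    null (sign-pattern enumeration) is used for n <= 25 without ties;
    otherwise the normal approximation with continuity and tie
    correction.  If every difference is zero, p = 1 with n_effective 0.
    """
    d = np.asarray(values, dtype=float) - mu
    if d.size == 0:
        raise ValueError("need at least one value")
    d = d[d != 0]
    if d.size == 0:
        return TestResult(statistic=0.0, p=1.0, method="wilcoxon-degenerate", n_effective=0)
    has_ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(
        d, alternative=alternative, correction=(method == "approx"), method=method
    )
    # scipy reports W = min tail for two-sided exact; V = sum of positive ranks
    ranks = sps.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    return TestResult(
        statistic=v, p=float(res.pvalue), method=f"wilcoxon-{method}",
        n_effective=int(d.size),
    )


def sign_balance_test(k_values, alternative: str = "two-sided") -> TestResult:
    """Compare the number of k < 1 vs k > 1 orthogroups.

    Exact binomial sign test against 0.5 (k = 1 values dropped);
    ``alternative='greater'`` asks whether k < 1 predominates.
    """
    k = np.asarray(k_values, dtype=float)
    lo = int((k < 1).sum())
    hi = int((k > 1).sum())
    n = lo + hi
    if n == 0:
        return TestResult(statistic=0.0, p=1.0, method="sign-degenerate", n_effective=0)
    res = sps.binomtest(lo, n, 0.5, alternative=alternative)
    return TestResult(statistic=float(lo), p=float(res.pvalue), method="sign-binomial", n_effective=n)


# -- GO-level k statistics -------------------------------------------


def go_term_k_tests(
    go_map: dict, k_table: pd.DataFrame, alpha: float = 0.05, min_n: int = 5
) -> pd.DataFrame:
    """Per-GO-term Wilcoxon tests of member k values against 1.

    Terms annotating fewer than ``min_n`` orthogroups (with a k value)
    are excluded.  Returns one row per tested term with the member
    count, mean and median k, V, p, and the deviation direction; the
    ``deviant`` flag marks p < alpha.
    """
    k_of = dict(zip(k_table["orthogroup_id"], k_table["k_hat"]))
    by_term: dict[str, list[float]] = {}
    for og, terms in go_map.items():
        if og not in k_of or not np.isfinite(k_of[og]):
            continue
        for t in terms:
            by_term.setdefault(t, []).append(float(k_of[og]))
    rows = []
    for term in sorted(by_term):
        ks = np.array(by_term[term])
        if ks.size < min_n:
            continue
        res = wilcoxon_signed_rank(ks, mu=1.0, alternative="two-sided")
        med = float(np.median(ks))
        rows.append(
            {
                "term": term,
                "n": int(ks.size),
                "mean_k": float(ks.mean()),
                "median_k": med,
                "V": res.statistic,
                "p": res.p,
                "direction": "relaxed" if med < 1 else ("intensified" if med > 1 else "neutral"),
                "deviant": bool(res.p < alpha),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["term", "n", "mean_k", "median_k", "V", "p", "direction", "deviant"],
    )


# -- enrichment ------------------------------------------------------


def fisher_enrichment(
    term: str,
    selected: set,
    universe: set,
    go_map: dict,
    tail: str = "over",
) -> float:
    """One-tailed hypergeometric p for over-/under-representation of a
    GO term in ``selected`` against ``universe``."""
    if not selected <= universe:
        raise ValueError("selected set must be a subset of the universe")
    if tail not in ("over", "under"):
        raise ValueError(f"tail must be 'over' or 'under', got {tail!r}")
    with_term = {og for og in universe if term in go_map.get(og, ())}
    if not with_term:
        return 1.0
    n_sel = len(selected)
    k_sel = len(selected & with_term)
    big_n, big_k = len(universe), len(with_term)
    if tail == "over":
        return float(sps.hypergeom.sf(k_sel - 1, big_n, big_k, n_sel))
    return float(sps.hypergeom.cdf(k_sel, big_n, big_k, n_sel))


def enrichment_table(
    selected: set,
    universe: set,
    go_map: dict,
    fdr: float = 0.10,
    alpha: float = 0.05,
    tail: str = "over",
    min_count: int = 1,
) -> pd.DataFrame:
    """Batch Fisher enrichment over every term seen in the universe.

    ``significant`` marks BH-FDR q < ``fdr``; ``trend`` marks
    uncorrected p < ``alpha`` (the convention used for reporting
    over-representation tendencies below the FDR cut)."""
    terms = sorted({t for og in universe for t in go_map.get(og, ())})
    rows = []
    for term in terms:
        with_term = {og for og in universe if term in go_map.get(og, ())}
        k_sel = len(selected & with_term)
        if tail == "over" and k_sel < min_count:
            continue
        p = fisher_enrichment(term, selected, universe, go_map, tail=tail)
        rows.append(
            {
                "term": term,
                "in_selected": k_sel,
                "selected_size": len(selected),
                "in_universe": len(with_term),
                "universe_size": len(universe),
                "p": p,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["term", "in_selected", "selected_size", "in_universe", "universe_size", "p"],
    )
    if len(table):
        table["q"] = multiple_correction(table["p"].to_numpy(), "bh")
        table["significant"] = table["q"] < fdr
        table["trend"] = table["p"] < alpha
        table = table.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        table["q"] = []
        table["significant"] = []
        table["trend"] = []
    return table


def overlap_stats(set_a: set, set_b: set, universe_size: int):
    """Expected vs observed overlap of two orthogroup sets.

    Returns (expected, observed, one-tailed Fisher p for an overlap at
    least as large)."""
    if universe_size <= 0:
        raise ValueError("universe size must be positive")
    if len(set_a) > universe_size or len(set_b) > universe_size:
        raise ValueError("set larger than the universe")
    expected = len(set_a) * len(set_b) / universe_size
    observed = len(set_a & set_b)
    if not set_a or not set_b:
        return expected, observed, 1.0
    p = float(
        sps.hypergeom.sf(observed - 1, universe_size, len(set_a), len(set_b))
    )
    return expected, observed, p


# -- transformed-k GSEA ----------------------------------------------


def transform_k(k):
    """Map k in [0, 50] to a score in [-1, 1]: (k - 1)/(k + 1).

    Strictly increasing, 0 at the neutral k = 1, negative for relaxed
    and positive for intensified selection."""
    arr = np.asarray(k, dtype=float)
    if np.any(arr < 0):
        raise ValueError("k must be >= 0")
    out = (arr - 1.0) / (arr + 1.0)
    return float(out) if np.isscalar(k) else out


def rank_transform_k(k):
    """Rank-based alternative score in [-1, 1] (ties averaged)."""
    arr = np.asarray(k, dtype=float)
    ranks = sps.rankdata(arr)
    return (ranks - 0.5) / len(arr) * 2.0 - 1.0


def read_gmt(path) -> dict:
    """Gene sets from a GMT file: name <tab> description <tab> members."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {i}: fewer than 3 fields")
            sets[fields[0]] = {m for m in fields[2:] if m}
    return sets


@dataclass
class GSEAResult:
    gene_set: str
    es: float
    nes: float
    p: float
    q: float = np.nan
    size: int = 0
    leading_edge: list = field(default_factory=list)


def _running_es(order_scores: np.ndarray, in_set: np.ndarray, weight: float):
    """Weighted Kolmogorov-Smirnov running sum; returns (ES, index)."""
    w = np.abs(order_scores) ** weight
    hit_w = np.where(in_set, w, 0.0)
    total_hit = hit_w.sum()
    n_miss = (~in_set).sum()
    if total_hit == 0 or n_miss == 0:
        return 0.0, -1
    p_hit = np.cumsum(hit_w) / total_hit
    p_miss = np.cumsum(~in_set) / n_miss
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i]), i


def gsea(
    scores: dict,
    gene_sets: dict,
    n_perm: int = 10_000,
    weight: float = 1.0,
    seed=None,
    min_set_size: int = 5,
) -> list[GSEAResult]:
    """Permutation GSEA of per-orthogroup scores over gene sets.

    Orthogroups are ranked by decreasing score; the enrichment score is
    the extremum of the weighted running sum; the null permutes gene
    labels (``n_perm`` draws, seeded); NES = ES / mean |null ES| of
    matching sign; p = (1 + #{null >= observed, matching sign}) /
    (n_perm + 1); q is BH across sets.
    """
    ids = sorted(scores)
    vals = np.array([scores[g] for g in ids], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("scores must be finite")
    order = np.argsort(-vals, kind="stable")
    ranked_ids = [ids[i] for i in order]
    ranked_scores = vals[order]
    id_pos = {g: i for i, g in enumerate(ranked_ids)}
    rng = np.random.default_rng(seed)

    results = []
    for name in sorted(gene_sets):
        members = [g for g in gene_sets[name] if g in id_pos]
        if len(members) < min_set_size:
            logger.info("gene set %s skipped (%d members present)", name, len(members))
            continue
        in_set = np.zeros(len(ranked_ids), dtype=bool)
        in_set[[id_pos[g] for g in members]] = True
        es, i_max = _running_es(ranked_scores, in_set, weight)

        null = np.empty(n_perm)
        m = in_set.sum()
        for b in range(n_perm):
            perm = np.zeros(len(ranked_ids), dtype=bool)
            perm[rng.choice(len(ranked_ids), size=m, replace=False)] = True
            null[b], _ = _running_es(ranked_scores, perm, weight)

        same_sign = null * np.sign(es) if es != 0 else np.abs(null)
        pos = same_sign[same_sign > 0]
        denom = pos.mean() if pos.size else 1.0
        nes = es / denom if denom > 0 else 0.0
        # sign-conditional permutation p (GSEA convention): exceedances
        # among matching-sign nulls over the matching-sign count
        p = (1.0 + float((pos >= abs(es)).sum())) / (pos.size + 1.0)

        if es >= 0:
            leading = [g for g in ranked_ids[: i_max + 1] if g in set(members)]
        else:
            leading = [g for g in ranked_ids[i_max:] if g in set(members)]
        results.append(
            GSEAResult(
                gene_set=name, es=es, nes=float(nes), p=float(p),
                size=len(members), leading_edge=leading,
            )
        )
    qs = multiple_correction([r.p for r in results], "bh") if results else []
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def top_gene_sets(results: list[GSEAResult], n: int = 10):
    """Top-n positive (intensified) and top-n negative (relaxed) sets
    by |NES|."""
    pos = sorted((r for r in results if r.nes > 0), key=lambda r: -r.nes)[:n]
    neg = sorted((r for r in results if r.nes < 0), key=lambda r: r.nes)[:n]
    return pos, neg


# -- classification --------------------------------------------------


def classify_orthogroups(k_table: pd.DataFrame, fdr: float = 0.10) -> pd.DataFrame:
    """Selection-class flags at an FDR threshold.

    relaxed: k < 1 and relax q < fdr; intensified: k > 1 and relax q <
    fdr; diversifying: branch-site q < fdr.  Flags are non-exclusive
    across the two tests.  Orthogroups without a converged fit stay
    unclassified (all flags False) and are logged."""
    out = k_table.copy()
    missing = out["k_hat"].isna() | out["q_BH"].isna()
    if missing.any():
        logger.warning(
            "%d orthogroups lack a converged relax fit and stay unclassified",
            int(missing.sum()),
        )
    sig = (out["q_BH"] < fdr) & ~missing
    out["relaxed"] = sig & (out["k_hat"] < 1)
    out["intensified"] = sig & (out["k_hat"] > 1)
    if "bs_q" in out:
        out["diversifying"] = out["bs_q"].notna() & (out["bs_q"] < fdr)
    else:
        out["diversifying"] = False
    return out
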