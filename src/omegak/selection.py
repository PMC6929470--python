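"""Per-orthogroup selection screening: RELAX-style + branch-site tests.

``screen_orthogroups`` runs both tests over a set of orthogroups,
sharing the pattern-compressed likelihood engine between them, applies
Benjamini-Hochberg (and Bonferroni) correction across orthogroups, and
assembles the k-table that all downstream statistics consume.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .branch_site import BranchSiteResult, attach_branch_site_q, fit_branch_site
from .correction import multiple_correction
from .likelihood import PruningEngine
from .relax import FitConfig, RelaxResult, fit_relax
from .trees import LabelledTree

logger = logging.getLogger(__name__)

RELAX_COLUMNS = [
    "orthogroup_id",
    "k_hat",
    "lnL_null",
    "lnL_alt",
    "LRT",
    "p",
    "q_BH",
    "p_bonferroni",
    "direction",
]


def screen_orthogroups(
    orthogroups: Mapping[str, tuple[CodonAlignment, LabelledTree]],
    config: FitConfig | None = None,
    run_branch_site: bool = True,
    progress: bool = False,
    return_details: bool = False,
):
    """Run the selection tests on every orthogroup and build the k-table.

    Returns a data frame with one row per orthogroup: the RELAX-style
    columns (k_hat, log-likelihoods, LRT, p, BH q, Bonferroni p,
    direction) and, when ``run_branch_site`` is set, the branch-site
    orthogroup-level p and q.  Orthogroups whose fits fail to converge
    are flagged and excluded from the correction families.
    """
    config = config or FitConfig()
    relax_results: list[RelaxResult] = []
    bs_results: list[BranchSiteResult] = []
    for i, (og_id, (aln, tree)) in enumerate(orthogroups.items()):
        engine = PruningEngine(aln, tree)
        rr = fit_relax(aln, tree, config=config, orthogroup_id=og_id, engine=engine)
        relax_results.append(rr)
        if run_branch_site:
            br = fit_branch_site(
                aln, tree, config=config, orthogroup_id=og_id, engine=engine
            )
            bs_results.append(br)
        if progress and (i + 1) % 10 == 0:
            logger.info("screened %d/%d orthogroups", i + 1, len(orthogroups))

    ok = [r.converged for r in relax_results]
    ps = [r.p for r, c in zip(relax_results, ok) if c]
    qs = multiple_correction(ps, "bh") if ps else np.array([])
    bonf = multiple_correction(ps, "bonferroni") if ps else np.array([])
    q_iter = iter(qs)
    b_iter = iter(bonf)

    rows = []
    for r, conv in zip(relax_results, ok):
        rows.append(
            {
                "orthogroup_id": r.orthogroup_id,
                "k_hat": r.k_hat,
                "lnL_null": r.lnL_null,
                "lnL_alt": r.lnL_alt,
                "LRT": r.lrt,
                "p": r.p if conv else np.nan,
                "q_BH": float(next(q_iter)) if conv else np.nan,
                "p_bonferroni": float(next(b_iter)) if conv else np.nan,
                "direction": r.direction if conv else "unconverged",
                "converged": conv,
            }
        )
    table = pd.DataFrame(rows)

    if run_branch_site:
        attach_branch_site_q(bs_results)
        bs = pd.DataFrame(
            {
                "orthogroup_id": [r.orthogroup_id for r in bs_results],
                "bs_p": [r.p for r in bs_results],
                "bs_q": [r.q for r in bs_results],
            }
        )
        table = table.merge(bs, on="orthogroup_id", how="left")
    else:
        table["bs_p"] = np.nan
        table["bs_q"] = np.nan
    if return_details:
        return table, relax_results, bs_results
    return table


def branch_site_table(results: Iterable[BranchSiteResult]) -> pd.DataFrame:
    """One row per test branch: the per-branch fits behind the
    orthogroup-level branch-site p-values."""
    rows = []
    for r in results:
        for f in r.branch_fits:
            rows.append(
                {
                    "orthogroup_id": r.orthogroup_id,
                    "branch_node": f.node,
                    "n_categories": f.n_categories,
                    "omegas": ";".join(f"{w:.6g}" for w in f.omegas),
                    "proportions": ";".join(f"{p:.6g}" for p in f.props),
                    "lnL": f.lnl,
                    "lnL_constrained": f.lnl_constrained,
                    "LRT": f.lrt,
                    "p_raw": f.p_raw,
                    "p_holm": f.p_corrected,
                }
            )
    return pd.DataFrame(rows)
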