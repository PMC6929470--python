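"""Simplified adaptive branch-site test for diversifying selection.

Mirrors the aBSREL idea at desk scale: the tree evolves under a single
background omega (estimated together with kappa and a branch-length
scaler), and each *test* branch in turn receives its own omega mixture
with 1..3 categories.  The category count is chosen by AICc
("adaptive"); the chosen model is tested against the same model with
all of that branch's omegas constrained <= 1 by a likelihood-ratio
test with df = number of omega categories.  Branch p-values are
Holm-corrected within the orthogroup; the orthogroup-level p is the
smallest corrected branch p, and q-values are computed across
orthogroups (Benjamini-Hochberg).

Because only one branch's transition matrix varies during each branch
fit, the likelihood is evaluated from cached inside/outside partials,
which makes the per-branch optimisation cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .alignment import CodonAlignment
from .correction import multiple_correction
from .likelihood import BranchContext, PruningEngine
from .relax import FitConfig, _frequencies, single_omega_fit
from .trees import LabelledTree

logger = logging.getLogger(__name__)

_OMEGA_MAX = 50.0
_OPT = dict(maxiter=60, ftol=2.5e-10, gtol=1e-6, eps=1e-4)


@dataclass
class BranchFit:
    node: int
    n_categories: int
    omegas: tuple
    props: tuple
    lnl: float
    lnl_constrained: float
    lrt: float
    p_raw: float
    p_corrected: float = 1.0
    aicc: float = np.nan


@dataclass
class BranchSiteResult:
    orthogroup_id: str
    branch_fits: list[BranchFit] = field(default_factory=list)
    p: float = 1.0  # orthogroup level: min Holm-corrected branch p
    q: float | None = None
    converged: bool = True
    kappa: float = 1.0
    omega_background: float = 1.0


def _aicc(lnl: float, n_params: int, n_obs: int) -> float:
    penalty = 2.0 * n_params * (n_params + 1) / max(n_obs - n_params - 1, 1)
    return 2.0 * n_params - 2.0 * lnl + penalty


def _unpack_branch(theta, j: int):
    omegas = np.exp(theta[:j])
    props = np.empty(j)
    rest = 1.0
    for i in range(j - 1):
        s = theta[j + i]
        props[i] = rest * s
        rest *= 1.0 - s
    props[j - 1] = rest
    return omegas, props


def _fit_branch_mixture(
    ctx: BranchContext, node: int, j: int, omega_start: float, constrain: bool
):
    """ML omega mixture with j categories on one focal branch.

    ``constrain`` caps every category at omega = 1 (the null of the
    diversifying-selection LRT).
    """
    hi = 0.0 if constrain else np.log(_OMEGA_MAX)
    bounds = [(np.log(1e-5), hi)] * j + [(1e-3, 1 - 1e-3)] * (j - 1)

    w0 = np.log(np.clip(omega_start, 1e-5, np.exp(hi)))
    x0 = [w0]
    seeds = [3.0, 10.0]
    for extra in range(j - 1):
        w = min(seeds[extra], 1.0) if constrain else seeds[extra]
        x0.append(np.log(np.clip(w, 1e-5, np.exp(hi))))
    x0 += [0.85] * (j - 1)
    x0 = np.array(x0)

    def neg(theta):
        omegas, props = _unpack_branch(theta, j)
        val = -ctx.branch_lnL(node, omegas, props)
        return val if np.isfinite(val) else 1e12

    res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds, options=_OPT)
    omegas, props = _unpack_branch(res.x, j)
    order = np.argsort(omegas)
    return tuple(omegas[order]), tuple(props[order]), -float(res.fun), res.success


def fit_branch_site(
    aln: CodonAlignment,
    tree: LabelledTree,
    config: FitConfig | None = None,
    orthogroup_id: str = "",
    engine: PruningEngine | None = None,
    max_categories: int = 3,
) -> BranchSiteResult:
    """Adaptive branch-site diversifying-selection test on all test
    branches of a labelled tree."""
    config = config or FitConfig()
    if not tree.is_test.any():
        raise ValueError("tree has no test branches")
    engine = engine or PruningEngine(aln, tree)
    pi = _frequencies(aln, config)

    kappa, scaler, omega_bg, _ = single_omega_fit(engine, pi)
    ctx = engine.branch_context(kappa, pi, omega_bg, scaler)
    n_obs = aln.n_codons
    base_params = 3  # kappa, scaler, background omega

    test_nodes = [nd for nd in engine.branches if engine.is_test[nd]]
    fits: list[BranchFit] = []
    converged = True
    for node in test_nodes:
        best = None
        for j in range(1, max_categories + 1):
            omegas, props, lnl, ok = _fit_branch_mixture(
                ctx, node, j, omega_bg, constrain=False
            )
            converged &= ok
            aicc = _aicc(lnl, base_params + 2 * j - 1, n_obs)
            if best is not None and aicc >= best[3]:
                break  # adding categories stopped paying
            best = (j, omegas, props, aicc, lnl)
        j, omegas, props, aicc, lnl = best

        if max(omegas) <= 1.0:
            # the chosen model already satisfies the constrained null
            lnl_con, lrt, p_raw = lnl, 0.0, 1.0
        else:
            _, _, lnl_con, ok = _fit_branch_mixture(
                ctx, node, j, min(omega_bg, 1.0), constrain=True
            )
            converged &= ok
            lnl_con = min(lnl_con, lnl)
            lrt = max(0.0, 2.0 * (lnl - lnl_con))
            p_raw = float(chi2.sf(lrt, df=j))
        fits.append(
            BranchFit(
                node=int(node),
                n_categories=j,
                omegas=omegas,
                props=props,
                lnl=lnl,
                lnl_constrained=lnl_con,
                lrt=lrt,
                p_raw=p_raw,
                aicc=aicc,
            )
        )

    corrected = multiple_correction([f.p_raw for f in fits], method="holm")
    for f, pc in zip(fits, corrected):
        f.p_corrected = float(pc)
    result = BranchSiteResult(
        orthogroup_id=orthogroup_id,
        branch_fits=fits,
        p=float(min((f.p_corrected for f in fits), default=1.0)),
        q=None,
        converged=converged,
        kappa=kappa,
        omega_background=omega_bg,
    )
    if not converged:
        logger.warning("branch-site fit did not fully converge for %s", orthogroup_id)
    return result


def attach_branch_site_q(results: list[BranchSiteResult]) -> None:
    """Benjamini-Hochberg q-values across orthogroups, in place."""
    qs = multiple_correction([r.p for r in results], method="bh")
    for r, q in zip(results, qs):
        r.q = float(q)
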