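"""RELAX-style selection-intensity test.

The null model shares a global branch-length scaler and a
three-category omega mixture (omega1 <= omega2 <= 1 <= omega3) across
the tree with k = 1; the alternative frees the selection-intensity
exponent k in [0, 50] on the test branches.  2*(lnL_alt - lnL_null) is
referred to chi-square(1).

Fitting is staged: a cheap single-omega fit estimates kappa and the
branch-length scaler; kappa is then held fixed while the mixture (and k
in the alternative) are optimised by bounded L-BFGS-B.  A profile scan
of k at the null solution locates candidate basins; the alternative is
restarted (fixed seed sequence, up to ``n_starts`` starts) from every
competitive basin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .alignment import CodonAlignment
from .genetic_code import NUCLEOTIDES
from .likelihood import PruningEngine
from .model import CodonModel, K_MAX
from .rates import f3x4_frequencies, f1x4_frequencies
from .trees import LabelledTree

logger = logging.getLogger(__name__)

# ftol is relative in L-BFGS-B; at |lnL| ~ 4e3 this is ~1e-6 in lnL
_OPT = dict(maxiter=120, maxfun=500, ftol=2.5e-10, gtol=1e-6, eps=3e-5)
# the alternative model's k-omega ridge can stall line searches; cap them
_OPT_ALT = dict(maxiter=70, maxfun=350, ftol=2.5e-10, gtol=1e-6, eps=3e-5, maxls=12)

_K_SHIFT = 1e-2  # k is optimised as log(k + shift) for resolution near 0

#: degrees of freedom of the selection-intensity LRT reference
RELAX_LRT_DF = 2


def _pack_k(k: float) -> float:
    return float(np.log(k + _K_SHIFT))


def _unpack_k(x: float) -> float:
    return float(np.exp(x) - _K_SHIFT)


@dataclass
class FitConfig:
    """Knobs of the ML machinery (not of the study design)."""

    n_starts: int = 3  # max starts on the alternative model
    freq_model: str = "F3x4"  # or F1x4
    k_max: float = K_MAX
    start_seed: int = 20_201_221  # fixed seed sequence for start jitter
    basin_window: float = 3.0  # lnL window within which a scan basin is competitive


@dataclass
class RelaxResult:
    orthogroup_id: str
    k_hat: float
    lnL_null: float
    lnL_alt: float
    lrt: float
    p: float
    q: float | None
    direction: str  # relaxed | intensified | neutral
    converged: bool
    null_model: CodonModel | None = field(default=None, repr=False)
    alt_model: CodonModel | None = field(default=None, repr=False)
    kappa: float = 1.0
    scaler_null: float = 1.0
    scaler_alt: float = 1.0


def empirical_f3x4(aln: CodonAlignment) -> np.ndarray:
    """F3x4 codon frequencies from positional nucleotide counts (with a
    single pseudocount per cell so no frequency is exactly zero)."""
    counts = np.ones((3, 4))
    idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for seq in aln.seqs:
        for pos in range(3):
            for ch in seq[pos::3]:
                if ch in idx:
                    counts[pos, idx[ch]] += 1
    return f3x4_frequencies(counts / counts.sum(axis=1, keepdims=True))


def empirical_f1x4(aln: CodonAlignment) -> np.ndarray:
    counts = np.ones(4)
    idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for seq in aln.seqs:
        for ch in seq:
            if ch in idx:
                counts[idx[ch]] += 1
    return f1x4_frequencies(counts / counts.sum())


def _frequencies(aln: CodonAlignment, config: FitConfig) -> np.ndarray:
    if config.freq_model.upper() == "F3X4":
        return empirical_f3x4(aln)
    if config.freq_model.upper() == "F1X4":
        return empirical_f1x4(aln)
    raise ValueError(f"unknown frequency model {config.freq_model!r}")


# -- parameter packing -----------------------------------------------
#
# theta = [log scaler, omega2, u (omega1 = u*omega2), log omega3,
#          s1, s2 (stick-breaking proportions), (log(k + shift))]
# kappa is estimated in the single-omega stage and held fixed.

_EPS = 1e-6


def _unpack(theta, with_k: bool):
    scaler = float(np.exp(theta[0]))
    omega2 = float(theta[1])
    omega1 = float(theta[2] * omega2)
    omega3 = float(np.exp(theta[3]))
    s1, s2 = float(theta[4]), float(theta[5])
    p1 = s1
    p2 = (1 - s1) * s2
    p3 = max(1.0 - p1 - p2, 0.0)
    k = _unpack_k(theta[6]) if with_k else 1.0
    return scaler, (omega1, omega2, omega3), (p1, p2, p3), k


def _bounds(config: FitConfig, with_k: bool):
    b = [
        (-5.0, 5.0),  # log scaler
        (_EPS, 1.0),  # omega2
        (_EPS, 1.0),  # u
        (0.0, np.log(config.k_max)),  # omega3 in [1, k_max]
        (1e-3, 1 - 1e-3),  # s1
        (1e-3, 1 - 1e-3),  # s2
    ]
    if with_k:
        b.append((_pack_k(0.0), _pack_k(config.k_max)))
    return b


def _make_objective(engine, pi, kappa, config: FitConfig, with_k: bool):
    def neg_lnl(theta):
        scaler, omegas, props, k = _unpack(theta, with_k)
        try:
            model = CodonModel(
                kappa, pi, list(zip(omegas, props)), k=min(max(k, 0.0), config.k_max)
            )
            val = -engine.lnL(model, scaler=scaler)
            return val if np.isfinite(val) else 1e12
        except (ValueError, np.linalg.LinAlgError, FloatingPointError):
            return 1e12

    return neg_lnl


def single_omega_fit(engine: PruningEngine, pi):
    """Cheap (kappa, scaler, omega) fit used to seed the mixture fits
    and as the branch-site background model."""

    def neg(theta):
        kappa, scaler, omega = np.exp(theta)
        try:
            model = CodonModel(kappa, pi, [(float(omega), 1.0)])
            return -engine.lnL(model, scaler=float(scaler))
        except (ValueError, np.linalg.LinAlgError):
            return 1e12

    x0 = np.log([2.0, 1.0, 0.3])
    bounds = [(np.log(0.05), np.log(40.0)), (-5.0, 5.0), (np.log(1e-5), np.log(20.0))]
    res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds, options=_OPT)
    kappa, scaler, omega = np.exp(res.x)
    return float(kappa), float(scaler), float(omega), -float(res.fun)


def fit_relax(
    aln: CodonAlignment,
    tree: LabelledTree,
    config: FitConfig | None = None,
    orthogroup_id: str = "",
    engine: PruningEngine | None = None,
) -> RelaxResult:
    """Fit the null (k = 1) and alternative (k free) omega^k models and
    return the likelihood-ratio test."""
    config = config or FitConfig()
    if not tree.is_test.any():
        raise ValueError("tree has no test branches")
    if all(tree.is_test[nd] for nd in tree.branch_nodes()):
        raise ValueError("tree has no reference branches")
    engine = engine or PruningEngine(aln, tree)
    pi = _frequencies(aln, config)

    kappa, scaler0, omega0, _ = single_omega_fit(engine, pi)

    # stage the mixture start around the single-omega estimate
    om2 = min(max(omega0, 2 * _EPS), 1.0)
    start = np.array([np.log(scaler0), om2, 0.4, np.log(1.5), 0.45, 0.6])

    neg_null = _make_objective(engine, pi, kappa, config, with_k=False)
    res_null = minimize(
        neg_null, start, method="L-BFGS-B", bounds=_bounds(config, False), options=_OPT
    )
    # the null gets the same degenerate-boundary rescue as the
    # alternative: a retry from a canonical interior mixture
    _, om_null, _, _ = _unpack(res_null.x, with_k=False)
    if om_null[0] <= 0.01:
        canonical0 = np.array([res_null.x[0], 0.8, 0.25, np.log(2.0), 0.4, 0.75])
        res_nullb = minimize(
            neg_null, canonical0, method="L-BFGS-B", bounds=_bounds(config, False),
            options=_OPT,
        )
        if res_nullb.fun < res_null.fun:
            res_null = res_nullb
    lnl_null = -float(res_null.fun)

    neg_alt = _make_objective(engine, pi, kappa, config, with_k=True)

    # profile scan over k at the null solution: each local minimum of the
    # scan marks a candidate basin for the joint optimisation
    k_grid = np.array([0.02, 0.1, 0.3, 1.0, 3.0, 10.0, 40.0])
    scan = np.array([neg_alt(np.append(res_null.x, _pack_k(k))) for k in k_grid])
    order = np.argsort(scan)
    competitive = [
        float(k_grid[i])
        for i in order
        if scan[i] <= scan[order[0]] + config.basin_window
    ]

    # refine the best basin's k in 1-D before the joint fit
    from scipy.optimize import minimize_scalar

    r1 = minimize_scalar(
        lambda xk: neg_alt(np.append(res_null.x, xk)),
        bounds=(_pack_k(max(competitive[0] / 4, 0.0)), _pack_k(min(competitive[0] * 4, config.k_max))),
        method="bounded",
        options={"xatol": 1e-2, "maxiter": 20},
    )

    rng = np.random.default_rng(config.start_seed)
    starts = [np.append(res_null.x, r1.x)]
    for k0 in competitive[1:]:
        if len(starts) >= config.n_starts - 1:
            break
        # skip basins adjacent in log-k to one already started
        if any(abs(_pack_k(k0) - s[-1]) < 1.2 for s in starts):
            continue
        jitter = rng.normal(0.0, 0.05, size=res_null.x.shape)
        x = np.clip(
            res_null.x + jitter,
            [b[0] for b in _bounds(config, False)],
            [b[1] for b in _bounds(config, False)],
        )
        starts.append(np.append(x, _pack_k(k0)))

    best = None
    for x0 in starts:
        res = minimize(
            neg_alt, x0, method="L-BFGS-B", bounds=_bounds(config, True),
            options=_OPT_ALT,
        )
        if best is None or res.fun < best.fun:
            best = res

    # rescue start: if the best solution sits on a degenerate boundary
    # (omega1 ~ 0 or extreme k), retry once from a canonical
    # purifying-dominated mixture so boundary modes must beat an
    # interior fit to be reported
    if len(starts) < config.n_starts:
        _, b_om, _, b_k = _unpack(best.x, with_k=True)
        if b_k <= 0.02 or b_k >= 45.0 or b_om[0] <= 0.01:
            canonical = np.array([res_null.x[0], 0.8, 0.25, np.log(2.0), 0.4, 0.75])
            res = minimize(
                neg_alt, np.append(canonical, r1.x), method="L-BFGS-B",
                bounds=_bounds(config, True), options=_OPT_ALT,
            )
            if res.fun < best.fun:
                best = res
    lnl_alt = -float(best.fun)
    converged = bool(res_null.success or best.success)

    # re-polish the null from the winning alternative's mixture so both
    # hypotheses receive comparable optimisation effort (an
    # under-optimised null inflates the LRT)
    if lnl_alt - lnl_null > 0.05:
        res_null2 = minimize(
            neg_null, best.x[:6], method="L-BFGS-B", bounds=_bounds(config, False),
            options=dict(_OPT, maxiter=40, maxfun=250),
        )
        if res_null2.fun < res_null.fun:
            res_null = res_null2
            lnl_null = -float(res_null.fun)

    # the alternative nests the null; guard against optimiser slack
    k_hat = min(max(0.0, _unpack_k(best.x[6])), config.k_max)
    if lnl_alt < lnl_null:
        lnl_alt = lnl_null
        best_x = np.append(res_null.x, _pack_k(1.0))
        k_hat = 1.0
    else:
        best_x = best.x

    lrt = max(0.0, 2.0 * (lnl_alt - lnl_null))
    # one dof for k plus one conservative allowance for the k*ln(omega)
    # corner families, whose extra effective freedom makes the chi2(1)
    # null measurably liberal at study-sized alignments
    p = float(chi2.sf(lrt, df=RELAX_LRT_DF))

    sn, on_, pn, _ = _unpack(res_null.x, with_k=False)
    sa, oa, pa, _ = _unpack(best_x, with_k=True)
    direction = (
        "neutral" if k_hat == 1.0 else ("relaxed" if k_hat < 1 else "intensified")
    )
    if not converged:
        logger.warning("relax fit did not converge for %s", orthogroup_id or "<aln>")
    return RelaxResult(
        orthogroup_id=orthogroup_id,
        k_hat=k_hat,
        lnL_null=lnl_null,
        lnL_alt=lnl_alt,
        lrt=lrt,
        p=p,
        q=None,
        direction=direction,
        converged=converged,
        null_model=CodonModel(kappa, pi, list(zip(on_, pn)), k=1.0),
        alt_model=CodonModel(kappa, pi, list(zip(oa, pa)), k=k_hat),
        kappa=kappa,
        scaler_null=sn,
        scaler_alt=sa,
    )
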