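"""Phylogenetic signal and phylogenetically independent contrasts.

Blomberg's K compares the observed ratio of tip variance around the
phylogenetic (GLS) mean to the variance of phylogenetically corrected
residuals against its Brownian-motion expectation on the same tree;
K = 1 is the Brownian expectation, K < 1 less signal than Brownian,
K > 1 more.  Significance comes from permuting trait values across tips.

Pagel's lambda rescales the off-diagonal elements of the tree covariance
by a factor in [0, 1] and is estimated by maximum likelihood under a
multivariate-normal model with GLS mean and profiled rate; lambda = 0 is
a star phylogeny (no signal), lambda = 1 plain Brownian motion.  The
reported p-value is a likelihood-ratio test against lambda = 0
(chi-square, 1 df); a test against lambda = 1 is available.

Independent contrasts follow Felsenstein's pruning algorithm; because
contrast signs are arbitrary, rank correlations between two contrast
sets positivise the first set's signs (flipping the second in tandem)
before computing the statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trees import tree_vcv

logger = logging.getLogger(__name__)


@dataclass
class SignalResult:
    """Phylogenetic-signal statistics for one trait on one tree."""

    trait: str
    K: float
    p_K: float
    lam: float
    logL_lambda: float
    p_lambda: float


@dataclass
class ContrastSet:
    node_ids: list
    contrasts: np.ndarray
    trait: str = ""


def _align_trait(trait: pd.Series, taxa: list[str]) -> np.ndarray:
    missing = [t for t in taxa if t not in trait.index]
    if missing:
        raise ValueError(f"trait values missing for tips: {missing[:5]}...")
    x = trait.reindex(taxa).to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite trait values")
    return x


def _k_statistic(x: np.ndarray, cinv: np.ndarray, expectation_denom: float) -> float:
    n = x.shape[0]
    ones = np.ones(n)
    ahat = (ones @ cinv @ x) / (ones @ cinv @ ones)
    resid = x - ahat
    mse0 = resid @ resid / (n - 1)
    mse = resid @ cinv @ resid / (n - 1)
    return (mse0 / mse) / expectation_denom


def blomberg_k(
    trait: pd.Series,
    tree: dendropy.Tree,
    permutations: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Blomberg's K with a tip-permutation test.

    K = (MSE0 / MSE) / E_BM[MSE0 / MSE] where MSE0 is the tip variance
    about the GLS mean and MSE the C^-1-weighted residual variance; the
    Brownian expectation is (tr C - n / sum(C^-1)) / (n - 1).  The
    p-value is the fraction of tip-label permutations (plus the observed)
    with K at least as large as observed.
    """
    trait = pd.Series(trait)
    taxa = sorted(trait.index)
    c = tree_vcv(tree, taxa)
    x = _align_trait(trait, taxa)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 tips")
    try:
        cinv = np.linalg.inv(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular tree covariance") from exc
    denom = (np.trace(c) - n / np.sum(cinv)) / (n - 1)
    k_obs = _k_statistic(x, cinv, denom)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        k_perm = _k_statistic(rng.permutation(x), cinv, denom)
        if k_perm >= k_obs:
            count += 1
    p = (1 + count) / (1 + permutations)
    return float(k_obs), float(p)


def _lambda_loglik(lam: float, x: np.ndarray, c: np.ndarray) -> float:
    """Profiled log-likelihood of the lambda model (GLS mean, ML rate)."""
    n = x.shape[0]
    clam = lam * c + (1.0 - lam) * np.diag(np.diag(c))
    try:
        chol = np.linalg.cholesky(clam)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    ones = np.ones(n)
    ci_x = np.linalg.solve(clam, x)
    ci_1 = np.linalg.solve(clam, ones)
    ahat = (ones @ ci_x) / (ones @ ci_1)
    resid = x - ahat
    sigma2 = resid @ np.linalg.solve(clam, resid) / n
    if sigma2 <= 0:
        return -np.inf
    return float(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n))


def pagel_lambda(
    trait: pd.Series,
    tree: dendropy.Tree,
    against: float = 0.0,
) -> tuple[float, float, float]:
    """Maximum-likelihood Pagel's lambda in [0, 1].

    Returns (lambda_hat, logL at the maximum, p-value of the likelihood
    ratio against the fixed ``against`` value, chi-square 1 df).
    """
    trait = pd.Series(trait)
    taxa = sorted(trait.index)
    c = tree_vcv(tree, taxa)
    x = _align_trait(trait, taxa)
    if x.shape[0] < 4:
        raise ValueError("need at least 4 tips")

    def neg(lam):
        return -_lambda_loglik(lam, x, c)

    res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(
            f"lambda optimisation failed: {res.message}; "
            f"logL(0)={_lambda_loglik(0.0, x, c):.4f}, "
            f"logL(1)={_lambda_loglik(1.0, x, c):.4f}"
        )
    # guard against interior-only search missing a boundary maximum
    candidates = [(float(res.x), -float(res.fun))]
    for lam0 in (0.0, 1.0):
        candidates.append((lam0, _lambda_loglik(lam0, x, c)))
    lam_hat, logl = max(candidates, key=lambda t: t[1])
    logl_null = _lambda_loglik(float(against), x, c)
    lr = max(0.0, 2.0 * (logl - logl_null))
    p = float(stats.chi2.sf(lr, df=1))
    return float(lam_hat), float(logl), p


def signal_suite(
    trait: pd.Series,
    tree: dendropy.Tree,
    name: str = "",
    permutations: int = 999,
    seed: int | np.random.Generator = 0,
) -> SignalResult:
    """Blomberg's K and Pagel's lambda for one trait on one tree."""
    k, p_k = blomberg_k(trait, tree, permutations=permutations, seed=seed)
    lam, logl, p_lam = pagel_lambda(trait, tree)
    return SignalResult(trait=name, K=k, p_K=p_k, lam=lam,
                        logL_lambda=logl, p_lambda=p_lam)


def independent_contrasts(trait: pd.Series, tree: dendropy.Tree) -> ContrastSet:
    """Felsenstein's phylogenetically independent contrasts.

    Polytomies are resolved arbitrarily with zero-length branches (and
    logged).  At each internal node the contrast is
    (x_a - x_b) / sqrt(v_a + v_b); the node value is the
    variance-weighted average of its children and the node's own branch
    is lengthened by v_a v_b / (v_a + v_b).  Node ids are the
    lexicographically smallest tip label below each node.
    """
    trait = pd.Series(trait)
    work = tree.clone(depth=1)
    if any(len(nd.child_nodes()) > 2 for nd in work.preorder_internal_node_iter()):
        logger.warning("polytomies resolved arbitrarily with zero-length branches")
        work.resolve_polytomies()
    values, lengths, min_tip = {}, {}, {}
    node_ids, contrasts = [], []
    for node in work.postorder_node_iter():
        bl = node.edge.length if node.edge.length is not None else 0.0
        if bl < 0:
            raise ValueError("negative branch length")
        if node.is_leaf():
            label = node.taxon.label
            if label not in trait.index:
                raise ValueError(f"no trait value for tip {label!r}")
            values[node] = float(trait[label])
            lengths[node] = float(bl)
            min_tip[node] = label
            continue
        a, b = node.child_nodes()
        va, vb = lengths[a], lengths[b]
        contrasts.append((values[a] - values[b]) / np.sqrt(va + vb))
        node_ids.append(min(min_tip[a], min_tip[b]))
        values[node] = (values[a] / va + values[b] / vb) / (1 / va + 1 / vb) \
            if va > 0 and vb > 0 else (values[a] + values[b]) / 2.0
        lengths[node] = float(bl) + (va * vb / (va + vb) if va + vb > 0 else 0.0)
        min_tip[node] = min(min_tip[a], min_tip[b])
    return ContrastSet(node_ids=node_ids, contrasts=np.asarray(contrasts),
                       trait=str(trait.name or ""))


def contrast_correlation(
    cx: ContrastSet, cy: ContrastSet, method: str = "spearman"
) -> tuple[float, float]:
    """Rank correlation between two contrast sets (two-sided).

    The signs of ``cx`` are positivised, with ``cy`` flipped in tandem,
    because contrast signs depend on the arbitrary ordering of sister
    lineages.
    """
    if cx.node_ids != cy.node_ids:
        raise ValueError("contrast sets computed on different trees/orders")
    if cx.contrasts.shape[0] < 3:
        raise ValueError("need at least 3 contrasts")
    signs = np.where(cx.contrasts < 0, -1.0, 1.0)
    x = cx.contrasts * signs
    y = cy.contrasts * signs
    if method == "spearman":
        r = stats.spearmanr(x, y)
    elif method == "kendall":
        r = stats.kendalltau(x, y)
    else:
        raise ValueError("method must be 'spearman' or 'kendall'")
    return float(r.statistic), float(r.pvalue)


def mass_residuals(scores: pd.Series, mass_g: pd.Series) -> pd.Series:
    """Residuals of shape score regressed on log10 body mass (grams).

    Ordinary least squares; species present in both inputs are used.
    """
    scores, mass_g = pd.Series(scores), pd.Series(mass_g)
    shared = sorted(set(scores.index) & set(mass_g.index))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared species")
    y = scores.reindex(shared).to_numpy(dtype=float)
    m = mass_g.reindex(shared).to_numpy(dtype=float)
    if np.any(m <= 0):
        raise ValueError("body mass must be positive")
    x = np.log10(m)
    if np.ptp(x) == 0:
        raise ValueError("constant body mass: regression undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return pd.Series(resid, index=shared, name=f"{scores.name or 'score'}_resid")
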