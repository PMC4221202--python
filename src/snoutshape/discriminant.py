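"""Two-group canonical variates analysis on retained PC scores.

With two a-priori groups a single discriminant axis exists: the leading
eigenvector of W^-1 B, where W is the pooled within-group SSCP and B the
between-group SSCP.  Group distinctiveness is summarised by Wilks'
Lambda = det(W) / det(W + B) and the log-likelihood-ratio index

    phi = -(n - 1 - (k + g) / 2) * ln(Lambda)        (Bartlett's form, g = 2)

whose null distribution is approximated three ways: a chi-square with
k (g - 1) degrees of freedom, a Monte Carlo null (pseudo-replicates drawn
from a normal with the pooled per-column mean and variance), and a
bootstrap null (rows resampled with replacement from the pooled observed
scores, destroying the group structure).  Classification is by distance
to the group centroids along the canonical axis, which equals Mahalanobis
distance under the unit pooled-within-variance scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import stats

from .ordination import PcaModel, pca_project


@dataclass
class GroupedScores:
    """PC scores with two-group labels (e.g. browser / grazer)."""

    ids: list
    scores: np.ndarray  # (n, k)
    labels: np.ndarray  # (n,) strings, exactly 2 distinct values

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.scores.shape[0] != self.labels.shape[0]:
            raise ValueError("scores and labels length mismatch")

    @property
    def groups(self) -> list:
        return sorted(set(self.labels.tolist()))


@dataclass
class CvaModel:
    groups: list                    # 2 group names, sorted
    discriminant_vector: np.ndarray  # (k,), unit pooled within variance
    cv_scores: np.ndarray            # (n,)
    centroids: dict                  # group -> centroid on the CV axis
    grand_mean: np.ndarray           # (k,) mean of the score rows
    wilks_lambda: float
    phi: float
    p_chi2: float
    n: int
    k: int
    labels: np.ndarray = None
    ids: list = None

    def transform(self, scores: np.ndarray) -> np.ndarray:
        """Map (m, k) PC scores to canonical scores."""
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        if scores.shape[1] != self.k:
            raise ValueError("dimension mismatch")
        return (scores - self.grand_mean) @ self.discriminant_vector


@dataclass
class ConfusionMatrix:
    groups: list
    counts: np.ndarray  # (2, 2), rows = true group, cols = assigned

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def percent_correct(self) -> float:
        return 100.0 * float(np.trace(self.counts)) / self.n

    def as_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "counts": self.counts.tolist(),
            "percent_correct": self.percent_correct,
        }


@dataclass
class NullDistribution:
    mode: str                 # "montecarlo" or "bootstrap"
    phi_values: np.ndarray    # (R,)
    phi_observed: float
    p_value: float            # #{phi_r >= phi_obs} / R
    p_conservative: float     # (#{phi_r >= phi_obs} + 1) / (R + 1)


def _sscp(scores: np.ndarray, labels: np.ndarray, groups: list):
    """Pooled within-group and between-group SSCP matrices."""
    grand = scores.mean(axis=0)
    w = np.zeros((scores.shape[1],) * 2)
    b = np.zeros_like(w)
    for g in groups:
        rows = scores[labels == g]
        mu = rows.mean(axis=0)
        dev = rows - mu
        w += dev.T @ dev
        dg = mu - grand
        b += rows.shape[0] * np.outer(dg, dg)
    return w, b, grand


def _wilks_phi(w, b, n, k, g=2, bartlett=True):
    sign_w, logdet_w = np.linalg.slogdet(w)
    sign_t, logdet_t = np.linalg.slogdet(w + b)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError("singular SSCP")
    lam = float(np.exp(logdet_w - logdet_t))
    scale = (n - 1 - (k + g) / 2) if bartlett else n
    phi = float(-scale * (logdet_w - logdet_t))
    return lam, phi


def cva_fit(data: GroupedScores, bartlett: bool = True) -> CvaModel:
    """Fit the two-group CVA.

    The discriminant vector is the leading eigenvector of W^-1 B, scaled
    so the pooled within-group variance of the canonical scores is 1, and
    oriented so the alphabetically first group's centroid is positive.

    ``bartlett=False`` switches phi to the unscaled -n ln(Lambda) form.
    """
    groups = data.groups
    if len(groups) != 2:
        raise ValueError(f"exactly 2 groups required, got {groups}")
    scores, labels = data.scores, data.labels
    n, k = scores.shape
    for g in groups:
        if np.sum(labels == g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    if n < k + 2:
        raise ValueError("too few specimens for the retained axes")
    w, b, grand = _sscp(scores, labels, groups)
    try:
        m = np.linalg.solve(w, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-group SSCP; retain fewer PC axes"
        ) from exc
    eigvals, eigvecs = scipy.linalg.eig(m)
    lead = int(np.argmax(eigvals.real))
    v = eigvecs[:, lead].real
    # unit pooled within-group variance of the projections
    within_var = float(v @ w @ v) / (n - len(groups))
    if within_var <= 0:
        raise ValueError("degenerate within-group dispersion")
    v = v / np.sqrt(within_var)
    cv = (scores - grand) @ v
    centroids = {g: float(cv[labels == g].mean()) for g in groups}
    if centroids[groups[0]] < centroids[groups[1]]:
        v = -v
        cv = -cv
        centroids = {g: -c for g, c in centroids.items()}
    lam, phi = _wilks_phi(w, b, n, k, bartlett=bartlett)
    p_chi2 = float(stats.chi2.sf(phi, df=k))
    return CvaModel(
        groups=groups,
        discriminant_vector=v,
        cv_scores=cv,
        centroids=centroids,
        grand_mean=grand,
        wilks_lambda=lam,
        phi=phi,
        p_chi2=p_chi2,
        n=n,
        k=k,
        labels=labels.copy(),
        ids=list(data.ids) if data.ids is not None else None,
    )


def assign(model: CvaModel, cv_scores: np.ndarray):
    """Nearest-centroid assignment on the canonical axis.

    Ties go to the alphabetically first group; tie rows are flagged.
    """
    cv_scores = np.atleast_1d(np.asarray(cv_scores, dtype=float))
    g0, g1 = model.groups
    d0 = np.abs(cv_scores - model.centroids[g0])
    d1 = np.abs(cv_scores - model.centroids[g1])
    assigned = np.where(d0 <= d1, g0, g1)
    ties = d0 == d1
    return assigned, np.column_stack([d0, d1]), ties


def classify(model: CvaModel, scores: np.ndarray, labels: np.ndarray):
    """Classify scored specimens; returns assignments and a confusion matrix."""
    cv = model.transform(scores)
    assigned, _, _ = assign(model, cv)
    labels = np.asarray(labels)
    counts = np.zeros((2, 2), dtype=int)
    for i, g_true in enumerate(model.groups):
        for j, g_hat in enumerate(model.groups):
            counts[i, j] = int(np.sum((labels == g_true) & (assigned == g_hat)))
    return assigned, ConfusionMatrix(groups=model.groups, counts=counts)


def jackknife(data: GroupedScores, bartlett: bool = True) -> ConfusionMatrix:
    """Leave-one-out cross-validated confusion matrix.

    Each specimen is held out, the CVA refitted on the remaining n - 1,
    and the holdout projected and assigned to the nearer centroid.
    """
    groups = data.groups
    n = data.scores.shape[0]
    for g in groups:
        if np.sum(data.labels == g) < 3:
            raise ValueError(f"group {g!r} too small for leave-one-out")
    counts = np.zeros((2, 2), dtype=int)
    for hold in range(n):
        keep = np.arange(n) != hold
        sub = GroupedScores(
            ids=None, scores=data.scores[keep], labels=data.labels[keep]
        )
        model = cva_fit(sub, bartlett=bartlett)
        cv = model.transform(data.scores[hold])
        assigned, _, _ = assign(model, cv)
        i = groups.index(data.labels[hold])
        j = groups.index(assigned[0])
        counts[i, j] += 1
    return ConfusionMatrix(groups=groups, counts=counts)


def _null_pvalues(phi_values: np.ndarray, phi_obs: float):
    count = int(np.sum(phi_values >= phi_obs))
    r = phi_values.shape[0]
    return count / r, (count + 1) / (r + 1)


def _phi_fast(scores: np.ndarray, n1: int, bartlett: bool = True) -> float:
    """Lambda/phi for a replicate split into the first n1 rows vs the rest.

    Determinant-only path: the discriminant vector is not needed for the
    null distributions.
    """
    n, k = scores.shape
    x1, x2 = scores[:n1], scores[n1:]
    d1 = x1 - x1.mean(axis=0)
    d2 = x2 - x2.mean(axis=0)
    w = d1.T @ d1 + d2.T @ d2
    dt = scores - scores.mean(axis=0)
    t = dt.T @ dt
    sign_w, logdet_w = np.linalg.slogdet(w)
    sign_t, logdet_t = np.linalg.slogdet(t)
    scale = (n - 1 - (k + 2) / 2) if bartlett else n
    return float(-scale * (logdet_w - logdet_t))


def null_montecarlo(
    data: GroupedScores,
    R: int = 1000,
    seed: int | np.random.Generator = 0,
    bartlett: bool = True,
) -> NullDistribution:
    """Monte Carlo null for phi.

    Each pseudo-replicate draws n x k values column-wise iid normal with
    the pooled (group-blind) mean and variance of the observed scores,
    keeps the observed group sizes as labels, and records the replicate
    phi.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    model = cva_fit(data, bartlett=bartlett)
    scores = data.scores
    mu = scores.mean(axis=0)
    sd = scores.std(axis=0, ddof=1)
    n1 = int(np.sum(data.labels == model.groups[0]))
    n, k = scores.shape
    draws = rng.standard_normal((R, n, k)) * sd + mu
    phis = np.array([_phi_fast(draws[r], n1, bartlett) for r in range(R)])
    p, p_cons = _null_pvalues(phis, model.phi)
    return NullDistribution("montecarlo", phis, model.phi, p, p_cons)


def null_bootstrap(
    data: GroupedScores,
    R: int = 1000,
    seed: int | np.random.Generator = 0,
    bartlett: bool = True,
    permute: bool = False,
) -> NullDistribution:
    """Bootstrap null for phi: group structure destroyed by resampling.

    Each pseudo-replicate resamples the n observed score rows with
    replacement (``permute=True`` shuffles without replacement instead)
    and assigns the first n1 rows to group 1 and the rest to group 2.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    model = cva_fit(data, bartlett=bartlett)
    scores = data.scores
    n1 = int(np.sum(data.labels == model.groups[0]))
    n = scores.shape[0]
    phis = np.empty(R)
    for r in range(R):
        rows = rng.permutation(n) if permute else rng.integers(0, n, size=n)
        phis[r] = _phi_fast(scores[rows], n1, bartlett)
    p, p_cons = _null_pvalues(phis, model.phi)
    return NullDistribution("bootstrap", phis, model.phi, p, p_cons)


def project_unknowns(
    model: CvaModel,
    pca: PcaModel,
    aligned_unknowns: np.ndarray,
    ids: list | None = None,
):
    """Assign unknown specimens through the PC and CV spaces.

    Unknowns must already be superimposed into the knowns' consensus
    frame.  Returns a list of per-specimen records with the canonical
    score, distances to both centroids, the provisional assignment, and
    an ``outside_observed_range`` flag for specimens beyond either
    group's observed canonical range (assignments that cannot be
    justified from the fitted space).
    """
    pc_scores = pca_project(pca, aligned_unknowns)
    cv = model.transform(pc_scores[:, : model.k])
    assigned, dists, ties = assign(model, cv)
    g0, g1 = model.groups
    lo = {g: float(model.cv_scores[model.labels == g].min()) for g in model.groups}
    hi = {g: float(model.cv_scores[model.labels == g].max()) for g in model.groups}
    records = []
    for i in range(cv.shape[0]):
        outside = not any(lo[g] <= cv[i] <= hi[g] for g in model.groups)
        records.append(
            {
                "id": ids[i] if ids is not None else i,
                "cv_score": float(cv[i]),
                "assigned": str(assigned[i]),
                f"distance_{g0}": float(dists[i, 0]),
                f"distance_{g1}": float(dists[i, 1]),
                "tie": bool(ties[i]),
                "outside_observed_range": outside,
            }
        )
    return records
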