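"""PCA outlier gating and PLS-DA with VIP, cross-validated Q2, and permutation p.

The sleep-state discrimination chain is: PCA on the preprocessed matrix with
a Hotelling-T2 gate at the 95% ellipse (first two components) to drop
aberrant samples, then PLS-DA (NIPALS PLS2 on column-centered one-hot class
indicators, three components by default) scored by

* VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ), where
  SSY_a is the Y variance captured by component a — so mean(VIP^2) = 1;
* Q2 = 1 - PRESS/TSS over held-out one-hot Y in stratified cross-validation;
* a label-permutation p for class separation, with the between/within sum of
  squares of component-1 scores as the test statistic.

Sign convention throughout: the largest-magnitude element of each loading /
weight vector is made positive, so fits are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .core_data import DataError, ProcessedMatrix


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    if isinstance(X, ProcessedMatrix):
        return np.asarray(X.values, dtype=float), list(X.sample_ids), list(X.metabolite_ids)
    return np.asarray(X, dtype=float), None, None


def _fix_signs(vectors: np.ndarray, *followers: np.ndarray) -> None:
    """Flip each column so its largest-magnitude entry is positive (in place)."""
    for a in range(vectors.shape[1]):
        j = int(np.argmax(np.abs(vectors[:, a])))
        if vectors[j, a] < 0:
            vectors[:, a] *= -1
            for f in followers:
                f[:, a] *= -1


# ---------------------------------------------------------------------------
# PCA and the Hotelling outlier gate
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    k: int
    eigenvalues: np.ndarray
    sample_ids: list[str] | None = None
    metabolite_ids: list[str] | None = None


def pca_fit(X, k: int) -> PcaModel:
    """Principal axes of the column-centered data via SVD.

    Deterministic up to the fixed sign convention; ``k`` must not exceed
    min(n_samples - 1, n_metabolites).
    """
    M, sample_ids, met_ids = _as_matrix(X)
    n, p = M.shape
    if k > min(n - 1, p) or k < 1:
        raise DataError(f"k={k} out of range for {n} samples x {p} variables")
    Xc = M - M.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T.copy()
    _fix_signs(loadings, scores)
    total = float(np.sum(s**2))
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    eig = (s[:k] ** 2) / (n - 1)
    return PcaModel(
        scores=scores, loadings=loadings, explained_variance_fraction=frac,
        k=k, eigenvalues=eig, sample_ids=sample_ids, metabolite_ids=met_ids,
    )


def hotelling_outliers(model: PcaModel, level: float = 0.95) -> set:
    """Samples outside the Hotelling-T2 ellipse of the first two components.

    A sample is flagged iff T2 = t1^2/lam1 + t2^2/lam2 exceeds
    (2 (n-1) / (n-2)) * F_{2, n-2}(level). Returns sample ids when the model
    carries them, else row indices; possibly empty.
    """
    if model.k < 2:
        raise DataError("hotelling_outliers needs a model with k >= 2")
    n = model.scores.shape[0]
    if n <= 3:
        raise DataError("Hotelling gate undefined for n <= 3")
    t = model.scores[:, :2]
    lam = t.var(axis=0, ddof=1)
    if np.any(lam == 0):
        return set()
    t2 = np.sum(t**2 / lam, axis=1)
    thr = (2.0 * (n - 1) / (n - 2)) * stats.f.ppf(level, 2, n - 2)
    flagged = np.nonzero(t2 > thr)[0]
    if model.sample_ids is not None:
        return {model.sample_ids[int(i)] for i in flagged}
    return {int(i) for i in flagged}


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS PLS2 on one-hot class indicators)
# ---------------------------------------------------------------------------

@dataclass
class PlsdaModel:
    n_components: int
    class_levels: list[str]
    x_scores: np.ndarray       # n x A
    x_weights: np.ndarray      # p x A
    x_loadings: np.ndarray     # p x A
    y_loadings: np.ndarray     # g x A
    ssy: np.ndarray            # Y sum-of-squares captured per component
    r2y: float
    x_mean: np.ndarray
    y_mean: np.ndarray
    vip: np.ndarray | None = None
    q2: float | None = None
    perm_p: float | None = None
    metabolite_ids: list[str] | None = None
    sample_ids: list[str] | None = None


def _one_hot(labels: np.ndarray, levels: list[str]) -> np.ndarray:
    Y = np.zeros((len(labels), len(levels)))
    for g, lev in enumerate(levels):
        Y[labels == lev, g] = 1.0
    return Y


def _nipals_pls2(
    Xc: np.ndarray, Yc: np.ndarray, n_components: int,
    tol: float = 1e-12, max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS recursion on centered X, Y. Returns (W, T, P, C, ssy)."""
    n, p = Xc.shape
    g = Yc.shape[1]
    A = n_components
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    C = np.zeros((g, A))
    ssy = np.zeros(A)
    Xr, Yr = Xc.copy(), Yc.copy()
    for a in range(A):
        col = int(np.argmax(np.sum(Yr**2, axis=0)))
        u = Yr[:, col].copy()
        if np.dot(u, u) <= tol:
            break  # Y residual exhausted; remaining components stay zero
        t = np.zeros(n)
        for _ in range(max_iter):
            w = Xr.T @ u / (u @ u)
            nw = np.linalg.norm(w)
            if nw == 0:
                break  # X residual orthogonal to u (e.g. constant X)
            w /= nw
            t_new = Xr @ w
            c = Yr.T @ t_new / (t_new @ t_new)
            u_new = Yr @ c / (c @ c)
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                t, u = t_new, u_new
                break
            t, u = t_new, u_new
        if np.linalg.norm(t) == 0:
            break
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w, t, c = -w, -t, -c
        tt = t @ t
        p_load = Xr.T @ t / tt
        Xr -= np.outer(t, p_load)
        ssy[a] = tt * (c @ c)
        Yr -= np.outer(t, c)
        W[:, a], T[:, a], P[:, a], C[:, a] = w, t, p_load, c
    return W, T, P, C, ssy


def plsda_fit(
    X, labels, n_components: int = 3, compute_vip: bool = True
) -> PlsdaModel:
    """Fit PLS-DA: NIPALS PLS2 of column-centered X on centered one-hot Y.

    Requires >= 2 classes with >= 3 samples each. ``r2y`` is the fraction of
    Y variance explained by the fitted components.
    """
    M, sample_ids, met_ids = _as_matrix(X)
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != M.shape[0]:
        raise DataError("labels length must equal number of samples")
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise DataError("PLS-DA needs >= 2 classes")
    for lev in levels:
        if np.sum(labels == lev) < 3:
            raise DataError(f"class {lev!r} has < 3 samples")
    bound = min(M.shape[0] - 1, M.shape[1])
    if not 1 <= n_components <= bound:
        raise DataError(f"n_components must be in [1, {bound}]")
    x_mean = M.mean(axis=0)
    Y = _one_hot(labels, levels)
    y_mean = Y.mean(axis=0)
    Xc, Yc = M - x_mean, Y - y_mean
    W, T, P, C, ssy = _nipals_pls2(Xc, Yc, n_components)
    Yhat = T @ C.T
    tss = float(np.sum(Yc**2))
    r2y = 1.0 - float(np.sum((Yc - Yhat) ** 2)) / tss if tss > 0 else 0.0
    model = PlsdaModel(
        n_components=n_components, class_levels=levels,
        x_scores=T, x_weights=W, x_loadings=P, y_loadings=C, ssy=ssy,
        r2y=r2y, x_mean=x_mean, y_mean=y_mean,
        metabolite_ids=met_ids, sample_ids=sample_ids,
    )
    if compute_vip:
        model.vip = vip_scores(model)
    return model


def vip_scores(model: PlsdaModel) -> np.ndarray:
    """Variable importance in projection; mean(VIP^2) = 1 by construction."""
    W, ssy = model.x_weights, model.ssy
    total = float(np.sum(ssy))
    if total <= 0:
        raise DataError("zero explained Y variance; VIP undefined")
    p = W.shape[0]
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    w2 = (W / norms) ** 2
    return np.sqrt(p * (w2 @ ssy) / total)


def select_top_vip(model: PlsdaModel, fraction: float = 0.05) -> list[str]:
    """Top ceil(fraction * p) metabolites by VIP; ties broken lexicographically."""
    if not 0 < fraction <= 1:
        raise DataError("fraction must be in (0, 1]")
    vip = model.vip if model.vip is not None else vip_scores(model)
    ids = model.metabolite_ids or [f"var{j}" for j in range(len(vip))]
    order = sorted(range(len(ids)), key=lambda j: (-vip[j], ids[j]))
    k = math.ceil(fraction * len(ids))
    return [ids[j] for j in order[:k]]


def _predict_Y(
    W: np.ndarray, P: np.ndarray, C: np.ndarray,
    Xnew: np.ndarray, x_mean: np.ndarray, y_mean: np.ndarray,
) -> np.ndarray:
    """One-hot prediction via the PLS regression coefficients B = W (P'W)^-1 C'."""
    A = W.shape[1]
    used = [a for a in range(A) if np.any(W[:, a])]
    if not used:
        return np.tile(y_mean, (Xnew.shape[0], 1))
    Wu, Pu, Cu = W[:, used], P[:, used], C[:, used]
    B = Wu @ np.linalg.solve(Pu.T @ Wu, Cu.T)
    return (Xnew - x_mean) @ B + y_mean


def plsda_predict(model: PlsdaModel, Xnew) -> np.ndarray:
    M, _, _ = _as_matrix(Xnew)
    return _predict_Y(
        model.x_weights, model.x_loadings, model.y_loadings,
        M, model.x_mean, model.y_mean,
    )


def q2_cross_validate(
    X, labels, n_components: int = 3, folds: int = 10, seed=None
) -> float:
    """Q2 = 1 - PRESS/TSS over held-out one-hot Y, stratified k-fold.

    ``folds == n`` runs leave-one-out. Fold assignment is seeded. PRESS and
    TSS are accumulated across folds against training-fold means, then
    combined; a fold configuration that would leave a class out of training
    raises before any fitting.
    """
    M, _, _ = _as_matrix(X)
    labels = np.asarray([str(l) for l in labels])
    n = M.shape[0]
    levels = sorted(set(labels))
    counts = {lev: int(np.sum(labels == lev)) for lev in levels}
    if folds == n:
        splitter = LeaveOneOut().split(M)
        if min(counts.values()) < 2:
            raise DataError("leave-one-out needs >= 2 samples per class")
    else:
        if folds > min(counts.values()):
            raise DataError(
                f"folds={folds} exceeds smallest class count "
                f"{min(counts.values())}; a fold would lack a class"
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=_to_int_seed(seed))
        splitter = skf.split(M, labels)
    press = 0.0
    tss = 0.0
    for train, test in splitter:
        if set(labels[train]) != set(levels):
            raise DataError("a training fold lacks a class")
        x_mean = M[train].mean(axis=0)
        Ytr = _one_hot(labels[train], levels)
        y_mean = Ytr.mean(axis=0)
        A = min(n_components, len(train) - 1, M.shape[1])
        W, T, P, C, _ = _nipals_pls2(M[train] - x_mean, Ytr - y_mean, A)
        Yte = _one_hot(labels[test], levels)
        Yhat = _predict_Y(W, P, C, M[test], x_mean, y_mean)
        press += float(np.sum((Yte - Yhat) ** 2))
        tss += float(np.sum((Yte - y_mean) ** 2))
    return 1.0 - press / tss


def _to_int_seed(seed) -> int | None:
    if seed is None or isinstance(seed, (int, np.integer)):
        return None if seed is None else int(seed)
    # Generator or SeedSequence: derive a bounded integer
    return int(np.random.default_rng(seed).integers(0, 2**31 - 1))


def _separation_statistic(t1: np.ndarray, labels: np.ndarray) -> float:
    """Between/within sum of squares of component-1 scores."""
    grand = t1.mean()
    between = 0.0
    within = 0.0
    for lev in np.unique(labels):
        g = t1[labels == lev]
        between += len(g) * (g.mean() - grand) ** 2
        within += float(np.sum((g - g.mean()) ** 2))
    if within <= 1e-300:
        return math.inf if between > 1e-300 else 0.0
    return between / within


def label_permutation_test(
    X, labels, n_components: int = 3, n_perm: int = 1000, seed=None
) -> float:
    """Permutation p for PLS-DA class separation.

    The statistic is the between/within sum-of-squares ratio of the
    component-1 scores; labels are permuted and the model refit each time.
    p = (1 + #{stat_perm >= stat_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    M, _, _ = _as_matrix(X)
    labels = np.asarray([str(l) for l in labels])
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise DataError("need >= 2 classes")
    rng = np.random.default_rng(seed)
    x_mean = M.mean(axis=0)
    Xc = M - x_mean

    def comp1_stat(lab: np.ndarray) -> float:
        Y = _one_hot(lab, levels)
        _, T, _, _, _ = _nipals_pls2(Xc, Y - Y.mean(axis=0), 1)
        return _separation_statistic(T[:, 0], lab)

    stat_obs = comp1_stat(labels)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if comp1_stat(perm) >= stat_obs:
            count += 1
    return (1 + count) / (n_perm + 1)
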