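"""Partial least squares discriminant analysis of community composition.

PLS-DA regresses the autoscaled OTU abundance matrix (x-block) on a dummy
one-hot coding of the sample groups (y-block) with the iterative NIPALS
scheme, deflating both blocks after each component. Samples are classified by
the arg-max of the predicted dummy response. Model validation follows the
usual chemometric recipe: stratified cross-validation chooses the number of
latent components by misclassification rate, and a label-permutation test on
the cross-validated error yields the p value for the grouping factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import OtuDataset, subset_dataset

MAX_ITER = 2000
TOL = 1e-10

CONTRASTS = ("M-vs-D1-vs-D2", "M-vs-D", "D1-vs-D2")


@dataclass
class Autoscaling:
    mean: np.ndarray
    scale: np.ndarray
    kept: np.ndarray       # indices of retained (non-constant) columns
    dropped: np.ndarray    # indices of zero-variance columns

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X[:, self.kept] - self.mean) / self.scale

    def invert(self, Xs: np.ndarray) -> np.ndarray:
        return Xs * self.scale + self.mean


@dataclass
class PlsdaModel:
    n_components: int
    classes: np.ndarray
    scaling: Autoscaling
    y_mean: np.ndarray
    x_scores: np.ndarray    # T (n x A)
    x_weights: np.ndarray   # W (p x A)
    x_loadings: np.ndarray  # P (p x A)
    y_loadings: np.ndarray  # Q (q x A)
    explained_y: np.ndarray  # per-component fraction of Y variance
    explained_x: np.ndarray
    n_iter: list[int] = field(default_factory=list)

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        a = self.n_components if n_components is None else n_components
        W, P, Q = self.x_weights[:, :a], self.x_loadings[:, :a], self.y_loadings[:, :a]
        PtW = P.T @ W
        try:
            return W @ np.linalg.solve(PtW, Q.T)
        except np.linalg.LinAlgError:
            # degenerate trailing component (tiny training folds): least-squares fallback
            return W @ (np.linalg.pinv(PtW) @ Q.T)

    def predict_scores(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        Xs = self.scaling.apply(np.asarray(X, dtype=float))
        return Xs @ self.coefficients(n_components) + self.y_mean

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        yhat = self.predict_scores(X, n_components)
        return self.classes[np.argmax(yhat, axis=1)]


def autoscale(X: np.ndarray) -> tuple[np.ndarray, Autoscaling]:
    """Center columns to zero mean and scale to unit (ddof=1) variance;
    zero-variance columns are dropped and recorded."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >=2 samples to autoscale")
    sd = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size == 0:
        raise ValueError("all columns have zero variance")
    sc = Autoscaling(X[:, kept].mean(axis=0), sd[kept], kept, np.flatnonzero(sd == 0))
    return sc.apply(X), sc


def _dummy(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    return (labels[:, None] == classes[None, :]).astype(float), classes


def fit_plsda(X: np.ndarray, labels, n_components: int,
              min_class_size: int = 2) -> PlsdaModel:
    """NIPALS PLS2 of autoscaled X against centered one-hot Y.

    ``min_class_size`` is relaxed to 1 for internal cross-validation refits,
    where a small class may be reduced to a single training sample.
    """
    labels = np.asarray(labels)
    Y0, classes = _dummy(labels)
    if len(classes) < 2:
        raise ValueError("need >=2 classes")
    for cls in classes:
        if (labels == cls).sum() < min_class_size:
            raise ValueError(f"class {cls!r} has <{min_class_size} samples")
    Xs, scaling = autoscale(np.asarray(X, dtype=float))
    n, p = Xs.shape
    max_comp = min(n - 1, p)
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in 1..{max_comp}")
    y_mean = Y0.mean(axis=0)
    Y = Y0 - y_mean
    ssx, ssy = (Xs ** 2).sum(), (Y ** 2).sum()
    E, F = Xs.copy(), Y.copy()
    T = np.empty((n, n_components)); W = np.empty((p, n_components))
    P = np.empty((p, n_components)); Q = np.empty((Y.shape[1], n_components))
    ev_y, ev_x, iters = [], [], []
    for a in range(n_components):
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        t_old = np.zeros(n)
        for it in range(MAX_ITER):
            w = E.T @ u / (u @ u)
            nw = np.linalg.norm(w)
            if nw == 0:
                raise RuntimeError(f"component {a + 1}: zero weight vector (residual X exhausted)")
            w /= nw
            t = E @ w
            q = F.T @ t / (t @ t)
            u = F @ q / (q @ q)
            change = np.linalg.norm(t - t_old) / max(1.0, np.linalg.norm(t))
            if change < TOL:
                break
            t_old = t
        else:
            # near-tied leading eigenvalues converge slowly; accept a component
            # that is stationary to 1e-4 but flag genuine divergence
            if change >= 1e-4:
                raise RuntimeError(f"NIPALS did not converge for component {a + 1} "
                                   f"after {MAX_ITER} iterations (score change {change:.2e})")
        iters.append(it + 1)
        pl = E.T @ t / (t @ t)
        E = E - np.outer(t, pl)
        F = F - np.outer(t, q)
        T[:, a], W[:, a], P[:, a], Q[:, a] = t, w, pl, q
        ev_x.append(float((t @ t) * (pl @ pl) / ssx))
        ev_y.append(float((t @ t) * (q @ q) / ssy))
    return PlsdaModel(n_components, classes, scaling, y_mean, T, W, P, Q,
                      np.array(ev_y), np.array(ev_x), iters)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded stratified folds; every fold keeps all classes where possible."""
    labels = np.asarray(labels)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % n_folds].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds if len(f)]


def cross_validate(X: np.ndarray, labels, n_folds: int = 7,
                   component_grid: range | list[int] | None = None,
                   seed: int = 0,
                   rng: np.random.Generator | None = None) -> tuple[np.ndarray, int]:
    """Stratified CV misclassification (%) per component count.

    Returns (error per grid point, chosen component count); the choice
    minimises CV error, ties resolved toward fewer components. The model is
    refit per fold (autoscaling included), and each truncation of the
    component sequence is evaluated from the same fold fit.
    """
    labels = np.asarray(labels)
    X = np.asarray(X, dtype=float)
    if n_folds < 2:
        raise ValueError("need >=2 folds")
    n_folds = min(n_folds, int(min(np.bincount(np.unique(labels, return_inverse=True)[1]))))
    if n_folds < 2:
        raise ValueError("smallest class too small to stratify")
    if rng is None:
        rng = np.random.default_rng(seed)
    max_comp = min(X.shape[0] - int(np.ceil(X.shape[0] / n_folds)) - 1, X.shape[1], 10)
    grid = list(component_grid) if component_grid is not None else list(range(1, max_comp + 1))
    errors = np.zeros(len(grid))
    n_total = 0
    for test in stratified_folds(labels, n_folds, rng):
        train = np.setdiff1d(np.arange(len(labels)), test)
        if len(np.unique(labels[train])) < len(np.unique(labels)):
            raise ValueError("a training fold lost a class; reduce n_folds")
        model, mc = None, max(grid)
        # small folds can exhaust X (or lose columns to autoscaling) before
        # max(grid) components; back off rather than fail the whole CV
        while model is None:
            try:
                model = fit_plsda(X[train], labels[train], mc, min_class_size=1)
            except (RuntimeError, ValueError) as exc:
                if "n_components" not in str(exc) and "zero weight" not in str(exc) \
                        and "converge" not in str(exc):
                    raise
                mc -= 1
                if mc < 1:
                    raise
        for gi, a in enumerate(grid):
            pred = model.predict(X[test], min(a, mc))
            errors[gi] += int(np.sum(pred != labels[test]))
        n_total += len(test)
    errors = 100.0 * errors / n_total
    best = grid[int(np.argmin(errors))]  # argmin takes the first (fewest) on ties
    return errors, best


def permutation_pvalue(X: np.ndarray, labels, n_perm: int = 999, seed: int = 0,
                       n_folds: int = 7,
                       observed_error: float | None = None) -> tuple[float, float]:
    """Label-permutation p value for the PLS-DA grouping factor.

    The statistic is the minimum cross-validated misclassification over the
    component grid; p = (1 + #{permuted error <= observed}) / (n_perm + 1).
    Returns (p, observed CV error %).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    if observed_error is None:
        errs, _ = cross_validate(X, labels, n_folds, rng=np.random.default_rng(rng.integers(2 ** 31)))
        observed_error = float(errs.min())
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        errs, _ = cross_validate(X, perm, n_folds, rng=np.random.default_rng(rng.integers(2 ** 31)))
        if errs.min() <= observed_error:
            hits += 1
    return (1 + hits) / (n_perm + 1), observed_error


@dataclass
class PlsdaResult:
    contrast: str
    classes: list[str]
    n_components: int
    explained_variance_y: float   # percent, cumulative over chosen components
    explained_variance_x: float
    cv_misclassification: float   # percent (the chemometric "sensitivity" complement)
    p_value: float
    n_permutations: int
    seed: int


def contrast_labels(ds: OtuDataset, contrast: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(X, labels, sample_ids) for one of the network contrasts."""
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {CONTRASTS}")
    roles = {"M-vs-D1-vs-D2": ["mother_root", "daughter_root"],
             "M-vs-D": ["mother_root", "daughter_root"],
             "D1-vs-D2": ["daughter_root"]}[contrast]
    sub = subset_dataset(ds, {"role": roles}, description=f"contrast {contrast}")
    meta = sub.samples
    if contrast == "M-vs-D":
        labels = np.where(meta["role"] == "mother_root", "M", "D")
    else:
        labels = meta["position"].astype(str).to_numpy()
    return sub.counts.to_numpy(dtype=float), labels, list(sub.counts.index)


def run_contrast(ds: OtuDataset, contrast: str, n_perm: int = 999,
                 n_folds: int = 7, seed: int = 0) -> PlsdaResult:
    """Full PLS-DA pipeline for one contrast: CV component choice, final fit,
    and label-permutation p value."""
    X, labels, _ = contrast_labels(ds, contrast)
    rng = np.random.default_rng(seed)
    errs, ncomp = cross_validate(X, labels, n_folds, rng=np.random.default_rng(rng.integers(2 ** 31)))
    model = fit_plsda(X, labels, ncomp)
    p, obs_err = permutation_pvalue(X, labels, n_perm, seed=int(rng.integers(2 ** 31)),
                                    n_folds=n_folds, observed_error=float(errs.min()))
    return PlsdaResult(contrast, [str(c) for c in model.classes], ncomp,
                       100.0 * float(model.explained_y.sum()),
                       100.0 * float(model.explained_x.sum()),
                       float(errs.min()), float(p), n_perm, seed)
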