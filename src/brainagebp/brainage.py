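"""Brain-age estimation: preprocessing, PCA, relevance vector regression,
leave-one-subject-out estimation and age-bias correction.

The estimation pipeline mirrors the standard BrainAGE framework:

1. gray-matter volumes (optional) are smoothed with a Gaussian kernel of a
   given FWHM and block-averaged to a coarser resolution, then vectorised;
2. features are orthogonalized with respect to the scanner covariate;
3. dimensionality is reduced with principal component analysis;
4. a relevance vector regression (sparse Bayesian kernel regression fitted
   by type-II maximum likelihood) maps reduced features to chronological
   age;
5. each subject's scans are predicted by a model trained with that subject
   entirely held out (leave-one-subject-out), so no scan informs its own
   prediction;
6. the brain-age gap (estimated minus chronological age) is residualised on
   chronological age, yielding a BrainAGE score uncorrelated with age.

A positive BrainAGE means an older-appearing brain; a negative one, younger.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.decomposition import PCA

from .synthetic import FeatureMatrix

logger = logging.getLogger(__name__)

GAUSS_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM = factor * sigma


# ---------------------------------------------------------------------------
# volume preprocessing


@dataclass
class Volume:
    """A 3-D intensity grid with isotropic or anisotropic voxel sizes (mm)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be three positive numbers")
        if not np.isfinite(self.data).all():
            raise ValueError("volume intensities must be finite")

    @classmethod
    def from_nifti(cls, path) -> "Volume":
        import nibabel as nib
        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.get_fdata(), dtype=float), zooms)

    def to_nifti(self, path) -> None:
        import nibabel as nib
        affine = np.diag([*self.voxel_size, 1.0])
        nib.save(nib.Nifti1Image(self.data, affine), str(path))


def fwhm_to_sigma(fwhm: float, voxel: float) -> float:
    """Gaussian sigma in voxel units for a kernel of ``fwhm`` millimetres."""
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    if fwhm < 0:
        raise ValueError("FWHM must be non-negative")
    return fwhm / (GAUSS_FWHM_FACTOR * voxel)


def preprocess_volume(vol: Volume, fwhm: float, target_res: float) -> Volume:
    """Gaussian-smooth at ``fwhm`` mm then block-average to ``target_res`` mm.

    The target resolution must be an integer multiple of each axis's voxel
    size; trailing voxels that do not fill a block are cropped (logged).
    """
    factors = []
    for v in vol.voxel_size:
        if target_res < v:
            raise ValueError("target resolution must be at least the voxel size")
        ratio = target_res / v
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"target resolution {target_res} mm is not an integer multiple "
                f"of the voxel size {v} mm")
        factors.append(int(round(ratio)))

    sigmas = [fwhm_to_sigma(fwhm, v) for v in vol.voxel_size]
    smoothed = ndimage.gaussian_filter(vol.data, sigma=sigmas, mode="nearest")

    shape = smoothed.shape
    cropped_shape = tuple((s // f) * f for s, f in zip(shape, factors))
    if cropped_shape != shape:
        logger.info("cropping volume from %s to %s for block averaging",
                    shape, cropped_shape)
        smoothed = smoothed[tuple(slice(0, c) for c in cropped_shape)]
    new_shape = []
    for s, f in zip(cropped_shape, factors):
        new_shape.extend([s // f, f])
    blocks = smoothed.reshape(new_shape)
    out = blocks.mean(axis=(1, 3, 5))
    return Volume(out, (target_res,) * 3)


def vectorize_volumes(volumes: list[Volume]) -> np.ndarray:
    """Stack flattened volumes into an (n_scans, n_voxels) feature array."""
    if not volumes:
        raise ValueError("no volumes supplied")
    shapes = {v.data.shape for v in volumes}
    if len(shapes) != 1:
        raise ValueError(f"volumes have differing shapes: {shapes}")
    return np.stack([v.data.ravel() for v in volumes])


# ---------------------------------------------------------------------------
# scanner orthogonalization


def orthogonalize_scanner(fm: FeatureMatrix) -> FeatureMatrix:
    """Residualise every feature on scanner indicators (plus intercept).

    With a single scanner this reduces to mean-centering. The operation is
    idempotent and leaves residual features uncorrelated with every scanner
    indicator.
    """
    labels = fm.scanner.astype(str)
    counts = labels.value_counts()
    if (counts == 0).any():
        raise ValueError("empty scanner group in label set")
    dummies = pd.get_dummies(labels, drop_first=True).to_numpy(dtype=float)
    design = np.column_stack([np.ones(fm.n_scans), dummies]) \
        if dummies.size else np.ones((fm.n_scans, 1))
    X = fm.data.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ coef
    return FeatureMatrix(
        data=pd.DataFrame(resid, index=fm.data.index, columns=fm.data.columns),
        scanner=fm.scanner, subject_id=fm.subject_id, age=fm.age)


# ---------------------------------------------------------------------------
# PCA reduction


@dataclass
class PCABasis:
    """Fitted principal-component basis (means, loadings, retained k)."""

    mean: np.ndarray
    components: np.ndarray          # (k, p), orthonormal rows
    k: int
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean) @ self.components.T


def fit_pca_basis(X: np.ndarray, k: int | float | None = 0.95) -> PCABasis:
    """Fit a PCA basis on training scans only.

    ``k`` may be an integer count, a fractional explained-variance target in
    (0, 1), or None for the full basis. Counts above min(n-1, p) are clipped
    with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 scans")
    k_max = min(n - 1, p)
    full = PCA(n_components=k_max, svd_solver="full").fit(X)
    if k is None:
        k_eff = k_max
    elif isinstance(k, float) and 0 < k < 1:
        cum = np.cumsum(full.explained_variance_ratio_)
        k_eff = int(np.searchsorted(cum, k - 1e-12) + 1)
        k_eff = min(k_eff, k_max)
    else:
        k_eff = int(k)
        if k_eff > k_max:
            logger.warning("requested k=%d exceeds min(n-1, p)=%d; clipped",
                           k_eff, k_max)
            k_eff = k_max
        if k_eff < 1:
            raise ValueError("k must be at least 1")
    return PCABasis(
        mean=full.mean_,
        components=full.components_[:k_eff],
        k=k_eff,
        explained_variance_ratio=full.explained_variance_ratio_[:k_eff],
    )


# ---------------------------------------------------------------------------
# relevance vector regression (Tipping's type-II maximum likelihood)


def _kernel(kernel: str, X: np.ndarray, Z: np.ndarray,
            width: float | None = None, degree: int = 3) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if kernel == "linear":
        return X @ Z.T
    if kernel == "rbf":
        w = width if width is not None else math.sqrt(X.shape[1])
        d2 = (np.sum(X ** 2, axis=1)[:, None] + np.sum(Z ** 2, axis=1)[None, :]
              - 2.0 * X @ Z.T)
        return np.exp(-np.maximum(d2, 0.0) / (2.0 * w ** 2))
    if kernel == "poly":
        return (1.0 + X @ Z.T) ** degree
    raise ValueError(f"unknown kernel {kernel!r}")


@dataclass
class RVRModel:
    """A fitted relevance vector regression.

    ``weights`` has one entry per relevance vector; ``alpha`` holds the
    per-weight precisions of the surviving basis functions and ``beta`` the
    noise precision. ``bias`` is always retained.
    """

    kernel: str
    kernel_width: float | None
    kernel_degree: int
    relevance_vectors: np.ndarray       # (m, d) inputs of surviving basis fns
    relevance_indices: np.ndarray       # indices into the training set
    weights: np.ndarray                 # (m,)
    bias: float
    alpha: np.ndarray                   # (m,) precisions, > 0
    beta: float                         # noise precision, > 0
    n_features: int
    converged: bool
    n_iter: int
    evidence_log: list[float] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "kernel": self.kernel,
            "kernel_width": self.kernel_width,
            "kernel_degree": self.kernel_degree,
            "relevance_vectors": self.relevance_vectors.tolist(),
            "relevance_indices": self.relevance_indices.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "alpha": self.alpha.tolist(),
            "beta": self.beta,
            "n_features": self.n_features,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "RVRModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            kernel=d["kernel"], kernel_width=d["kernel_width"],
            kernel_degree=d["kernel_degree"],
            relevance_vectors=np.asarray(d["relevance_vectors"], dtype=float),
            relevance_indices=np.asarray(d["relevance_indices"], dtype=int),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            alpha=np.asarray(d["alpha"], dtype=float), beta=float(d["beta"]),
            n_features=int(d["n_features"]), converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
        )


def _log_evidence(Phi, y, alpha, beta):
    """log marginal likelihood log p(y | alpha, beta)."""
    n = len(y)
    C = np.eye(n) / beta + (Phi / alpha) @ Phi.T
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    sol = np.linalg.solve(C, y)
    return float(-0.5 * (n * math.log(2 * math.pi) + logdet + y @ sol))


def rvr_fit(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "linear",
    kernel_width: float | None = None,
    kernel_degree: int = 3,
    tol: float = 1e-6,
    max_iter: int = 1000,
    alpha_cap: float = 1e12,
    fixed_alpha: float | None = None,
    prune: bool = True,
    basis: str = "kernel",
    include_bias: bool = True,
    compute_evidence: bool = True,
) -> RVRModel:
    """Fit a relevance vector regression by type-II maximum likelihood.

    The basis is the kernel expansion over training points (``basis='kernel'``,
    the RVM default) or the raw feature columns (``basis='design'``, used for
    closed-form cross-checks). Hyperparameters iterate the standard updates
    alpha_i <- gamma_i / mu_i^2 and beta <- (n - sum gamma_i) / ||y - Phi mu||^2
    with gamma_i = 1 - alpha_i Sigma_ii; basis functions whose alpha exceeds
    ``alpha_cap`` are pruned. With ``fixed_alpha`` set, all alphas are held at
    that shared value (and pruning disabled), in which case the posterior mean
    coincides with ridge regression at lambda = alpha / beta.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in inputs")
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 training points")

    if basis == "kernel":
        Phi_basis = _kernel(kernel, X, X, kernel_width, kernel_degree)
        basis_inputs = X
    elif basis == "design":
        Phi_basis = X
        basis_inputs = np.eye(d)  # placeholder; prediction uses weights directly
    else:
        raise ValueError("basis must be 'kernel' or 'design'")

    if include_bias:
        Phi = np.column_stack([np.ones(n), Phi_basis])
    else:
        Phi = Phi_basis
    m_total = Phi.shape[1]
    bias_idx = 0 if include_bias else None

    y_var = float(np.var(y))
    if y_var == 0.0:
        # constant target: bias-only model
        return RVRModel(
            kernel=kernel, kernel_width=kernel_width, kernel_degree=kernel_degree,
            relevance_vectors=np.empty((0, d)), relevance_indices=np.empty(0, int),
            weights=np.empty(0), bias=float(y[0]) if include_bias else 0.0,
            alpha=np.empty(0), beta=alpha_cap, n_features=d,
            converged=True, n_iter=0, evidence_log=[])

    if fixed_alpha is not None:
        prune = False
        alpha = np.full(m_total, float(fixed_alpha))
    else:
        alpha = np.full(m_total, 1e-6)
    beta = 1.0 / (0.1 * y_var)

    active = np.ones(m_total, dtype=bool)
    converged = False
    evidence_log: list[float] = []
    mu_full = np.zeros(m_total)
    it = 0
    for it in range(1, max_iter + 1):
        active_iter = active.copy()
        A = alpha[active_iter]
        Phi_a = Phi[:, active_iter]
        H = beta * (Phi_a.T @ Phi_a) + np.diag(A)
        try:
            Sigma = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            Sigma = np.linalg.pinv(H)
        mu = beta * Sigma @ (Phi_a.T @ y)
        gamma = 1.0 - A * np.diag(Sigma)

        if compute_evidence:
            evidence_log.append(_log_evidence(Phi_a, y, A, beta))

        mu_full = np.zeros(m_total)
        mu_full[active_iter] = mu
        if fixed_alpha is not None:
            converged = True
            break

        rss = float(np.sum((y - Phi_a @ mu) ** 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_new = np.where(mu ** 2 > 0, gamma / mu ** 2, alpha_cap * 10)
        alpha_new = np.clip(alpha_new, 1e-12, alpha_cap * 10)
        beta_new = max(float((n - gamma.sum()) / max(rss, 1e-12)), 1e-12)
        beta_new = min(beta_new, 1e12)
        delta = float(np.max(np.abs(np.log(alpha_new)
                                    - np.log(alpha[active_iter]))))
        delta = max(delta, abs(math.log(beta_new) - math.log(beta)))
        alpha[active_iter] = alpha_new
        beta = beta_new
        if prune:
            over = alpha > alpha_cap
            if bias_idx is not None:
                over[bias_idx] = False
            active = active & ~over
        if delta < tol:
            converged = True
            break

    if fixed_alpha is None and active.any():
        # final posterior on the surviving basis set
        A = alpha[active]
        Phi_a = Phi[:, active]
        H = beta * (Phi_a.T @ Phi_a) + np.diag(A)
        try:
            Sigma = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            Sigma = np.linalg.pinv(H)
        mu_full = np.zeros(m_total)
        mu_full[active] = beta * Sigma @ (Phi_a.T @ y)
    elif fixed_alpha is not None:
        active = np.ones(m_total, dtype=bool)

    if not active.any():
        logger.warning("no basis functions survived pruning; bias-only model")
        return RVRModel(
            kernel=kernel, kernel_width=kernel_width, kernel_degree=kernel_degree,
            relevance_vectors=np.empty((0, d)), relevance_indices=np.empty(0, int),
            weights=np.empty(0), bias=float(np.mean(y)),
            alpha=np.empty(0), beta=beta, n_features=d,
            converged=converged, n_iter=it, evidence_log=evidence_log)

    active_idx = np.flatnonzero(active)
    if include_bias:
        bias_w = float(mu_full[0]) if active[0] else 0.0
        rel_cols = active_idx[active_idx != 0] - 1
    else:
        bias_w = 0.0
        rel_cols = active_idx
    if basis == "kernel":
        rel_vectors = basis_inputs[rel_cols]
    else:
        rel_vectors = np.empty((len(rel_cols), d))
    weights = mu_full[rel_cols + (1 if include_bias else 0)]
    alphas = alpha[rel_cols + (1 if include_bias else 0)]

    model = RVRModel(
        kernel=kernel, kernel_width=kernel_width, kernel_degree=kernel_degree,
        relevance_vectors=rel_vectors, relevance_indices=rel_cols,
        weights=weights, bias=bias_w, alpha=alphas, beta=beta,
        n_features=d, converged=converged, n_iter=it,
        evidence_log=evidence_log)
    model._basis = basis  # type: ignore[attr-defined]
    return model


def rvr_predict(model: RVRModel, X_new: np.ndarray) -> np.ndarray:
    """Predict ages for new inputs via the kernel expansion over relevance
    vectors plus the bias."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X_new.shape[1]} does not match training "
            f"dimension {model.n_features}")
    basis = getattr(model, "_basis", "kernel")
    if len(model.weights) == 0:
        return np.full(X_new.shape[0], model.bias)
    if basis == "design":
        cols = X_new[:, model.relevance_indices]
        return cols @ model.weights + model.bias
    K = _kernel(model.kernel, X_new, model.relevance_vectors,
                model.kernel_width, model.kernel_degree)
    return K @ model.weights + model.bias


# ---------------------------------------------------------------------------
# leave-one-subject-out estimation and bias correction


def estimate_brainage_loso(
    fm: FeatureMatrix,
    pca_k: int | float | None = 0.95,
    pca_cap_n_minus_2: bool = True,
    **rvr_kwargs,
) -> pd.DataFrame:
    """Estimate each scan's brain age with its subject entirely held out.

    For every subject, a PCA basis and an RVR are refit on all *other*
    subjects' scans and that subject's scans are predicted by the held-out
    model. Returns a frame indexed by scan id with columns subject_id, age,
    estimated_age and fold. A leakage audit is enforced: a scan never
    contributes to its own training fold.
    """
    subjects = fm.subject_id.unique()
    if len(subjects) < 3:
        raise ValueError("leave-one-subject-out needs at least 3 subjects")
    counts = fm.subject_id.value_counts()
    if (counts == 0).any():
        raise ValueError("subject with zero scans")

    X_all = fm.data.to_numpy(dtype=float)
    ages = fm.age.to_numpy(dtype=float)
    sub = fm.subject_id.to_numpy()
    est = np.full(fm.n_scans, np.nan)
    fold = np.empty(fm.n_scans, dtype=object)

    for s in subjects:
        test_mask = sub == s
        train_mask = ~test_mask
        assert not (test_mask & train_mask).any()
        X_tr, y_tr = X_all[train_mask], ages[train_mask]
        k = pca_k
        if pca_cap_n_minus_2 and isinstance(k, (int, np.integer)):
            k = min(int(k), max(X_tr.shape[0] - 2, 1))
        basis = fit_pca_basis(X_tr, k=k)
        if pca_cap_n_minus_2 and basis.k > max(X_tr.shape[0] - 2, 1):
            basis = fit_pca_basis(X_tr, k=max(X_tr.shape[0] - 2, 1))
        Z_tr = basis.transform(X_tr)
        model = rvr_fit(Z_tr, y_tr, **rvr_kwargs)
        est[test_mask] = rvr_predict(model, basis.transform(X_all[test_mask]))
        fold[test_mask] = f"loso_{s}"

    out = pd.DataFrame({
        "subject_id": fm.subject_id,
        "age": fm.age,
        "estimated_age": est,
        "fold": fold,
    }, index=fm.data.index)
    leaks = (out["fold"] != "loso_" + out["subject_id"]).sum()
    if leaks:
        raise AssertionError(f"{leaks} scans assigned to a foreign fold")
    return out


def bias_correct(estimates: pd.DataFrame | np.ndarray,
                 ages: np.ndarray | None = None) -> pd.DataFrame:
    """Residualise the brain-age gap on chronological age.

    Accepts either the frame from :func:`estimate_brainage_loso` or two
    arrays (estimated ages, chronological ages). Fits gap = a + b age by
    ordinary least squares on the full sample and returns the frame with a
    ``brainage`` column holding the residuals, which are exactly
    uncorrelated with age.
    """
    if isinstance(estimates, pd.DataFrame):
        frame = estimates.copy()
        est = frame["estimated_age"].to_numpy(dtype=float)
        age = frame["age"].to_numpy(dtype=float)
    else:
        est = np.asarray(estimates, dtype=float)
        age = np.asarray(ages, dtype=float)
        frame = pd.DataFrame({"age": age, "estimated_age": est})
    if len(est) < 3:
        raise ValueError("need at least 3 estimates for bias correction")
    if np.var(age) == 0:
        raise ValueError("zero variance in age; cannot fit the bias model")
    gap = est - age
    b, a = np.polyfit(age, gap, 1)
    frame["brainage"] = gap - (a + b * age)
    return frame


def brainage_diagnostics(estimates: pd.DataFrame) -> dict[str, float]:
    """Mean absolute deviation (pre-correction) and the post-correction
    correlation of BrainAGE with age."""
    if len(estimates) == 0:
        raise ValueError("empty estimate table")
    est = estimates["estimated_age"].to_numpy(dtype=float)
    age = estimates["age"].to_numpy(dtype=float)
    out = {"mad_years": float(np.mean(np.abs(est - age)))}
    if "brainage" in estimates.columns and np.var(age) > 0 \
            and np.var(estimates["brainage"].to_numpy()) > 0:
        out["corr_brainage_age"] = float(
            np.corrcoef(estimates["brainage"], age)[0, 1])
    else:
        out["corr_brainage_age"] = float("nan")
    return out
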