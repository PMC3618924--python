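"""Blind feature extraction: PCA whitening followed by fixed-point ICA.

A patch x (flattened to a length side^2 vector) is modelled as a linear
mixture of statistically independent non-Gaussian sources,

    x_i = sum_j a_ij s_j,

where the columns of the mixing matrix A are basis images and the
coefficients s_j are the features fed to the classifiers.  The basis is
learned from training patches only: centre by the mean patch, reduce with
PCA to the component count (with whitening), then run the FastICA
fixed-point iteration with the log-cosh negentropy contrast
(g(u) = tanh(u)) and symmetric orthogonalization.

After fitting, components are ordered by descending log-cosh
non-Gaussianity and signs are fixed so each basis image's
largest-magnitude pixel is positive, which makes downstream training
seed-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .roi import ROIPatch

__all__ = ["ICABasis", "FeatureVector", "ICAConvergenceError", "fit_basis", "project", "reconstruct"]

# E[log cosh(u)] for standard normal u; deviation from it measures non-Gaussianity
_GAUSS_LOGCOSH = 0.37456732


class ICAConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge; carries per-restart diagnostics."""

    def __init__(self, message: str, diagnostics: list[dict]):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class ICABasis:
    """Learned ICA basis mapping patches to coefficient features.

    ``whitening`` (n x d) projects a centred flattened patch onto the
    whitened PCA subspace; ``unmixing`` (n x n) rotates it onto independent
    components; ``mixing`` (d x n) holds the basis images as columns and is
    the pseudo-inverse of the composite forward operator.
    """

    patch_side: int
    n_components: int
    mean: np.ndarray
    whitening: np.ndarray
    unmixing: np.ndarray
    mixing: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def extractor(self) -> np.ndarray:
        """Composite forward operator W @ whitening (n x d)."""
        return self.unmixing @ self.whitening

    def basis_images(self) -> np.ndarray:
        """Mixing-matrix columns reshaped to (n, side, side) basis images."""
        s = self.patch_side
        return self.mixing.T.reshape(self.n_components, s, s)

    def save(self, path: str | Path) -> None:
        meta = dict(self.meta)
        meta.update(patch_side=self.patch_side, n_components=self.n_components)
        np.savez(
            path,
            mean=self.mean,
            whitening=self.whitening,
            unmixing=self.unmixing,
            mixing=self.mixing,
            meta=np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ICABasis":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            return cls(
                patch_side=int(meta.pop("patch_side")),
                n_components=int(meta.pop("n_components")),
                mean=z["mean"],
                whitening=z["whitening"],
                unmixing=z["unmixing"],
                mixing=z["mixing"],
                meta=meta,
            )


@dataclass
class FeatureVector:
    """ICA expansion coefficients of one patch, with its labels."""

    coeffs: np.ndarray
    label: str
    density: int
    source_id: str = ""


def _as_matrix(patches: Sequence[ROIPatch] | np.ndarray) -> np.ndarray:
    if isinstance(patches, np.ndarray):
        X = np.asarray(patches, dtype=float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        return X
    return np.stack([p.pixels.ravel() for p in patches]).astype(float)


def fit_basis(
    patches: Sequence[ROIPatch] | np.ndarray,
    n_components: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 1000,
    restarts: int = 5,
    min_patch_factor: int = 10,
    on_fail: str = "raise",
) -> ICABasis:
    """Learn an ICA basis from training patches.

    Requires at least ``min_patch_factor * n_components`` patches.  Up to
    ``restarts`` seeded re-initialisations are attempted on non-convergence;
    if all fail, an :class:`ICAConvergenceError` carrying the per-restart
    iteration log is raised (expected for sources that are actually
    Gaussian, for which the rotation is unidentifiable).  With
    ``on_fail="best"`` the lowest-residual restart is returned instead,
    flagged ``converged: False`` in ``meta`` — at small sample sizes the
    symmetric iteration can limit-cycle near a fixed point, and the
    near-fixed-point rotation is still a usable basis.
    """
    X = _as_matrix(patches)
    m, d = X.shape
    if m < min_patch_factor * n_components:
        raise ValueError(
            f"need at least {min_patch_factor * n_components} patches to fit "
            f"{n_components} components, got {m}"
        )
    patch_side = int(round(d**0.5))

    mean = X.mean(axis=0)
    Xc = X - mean
    # PCA whitening to exactly n_components via thin SVD
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if S[n_components - 1] < 1e-12 * S[0]:
        raise ValueError("training patches are rank-deficient at the requested dimension")
    whitening = (Vt[:n_components] / S[:n_components, None]) * np.sqrt(m)
    Z = whitening @ Xc.T  # (n, m), identity covariance

    diagnostics: list[dict] = []
    W = None
    converged = False
    best_try: tuple[float, np.ndarray] | None = None
    ss = np.random.SeedSequence([seed, n_components])
    for attempt, child in enumerate(ss.spawn(restarts)):
        rng = np.random.default_rng(child)
        W0 = np.linalg.qr(rng.standard_normal((n_components, n_components)))[0]
        W_try, n_iter, final_delta = _fastica_symmetric(Z, W0, tol, max_iter)
        diagnostics.append(
            {"restart": attempt, "n_iter": n_iter, "final_delta": float(final_delta),
             "converged": final_delta < tol}
        )
        if best_try is None or final_delta < best_try[0]:
            best_try = (final_delta, W_try)
        if final_delta < tol:
            W = W_try
            converged = True
            break
    if W is None:
        if on_fail != "best":
            raise ICAConvergenceError(
                f"FastICA did not converge in {max_iter} iterations over {restarts} "
                f"restarts (best residual {best_try[0]:.3g}); "
                "sources may be Gaussian or nearly so",
                diagnostics,
            )
        W = best_try[1]

    # deterministic ordering: descending log-cosh non-Gaussianity
    Shat = W @ Z
    negentropy = (np.mean(np.log(np.cosh(Shat)), axis=1) - _GAUSS_LOGCOSH) ** 2
    order = np.argsort(-negentropy)
    W = W[order]

    extractor = W @ whitening
    mixing = np.linalg.pinv(extractor)  # (d, n)
    # sign convention: each basis image's largest-|.| pixel is positive
    for j in range(n_components):
        k = int(np.argmax(np.abs(mixing[:, j])))
        if mixing[k, j] < 0:
            mixing[:, j] *= -1.0
            W[j] *= -1.0

    return ICABasis(
        patch_side=patch_side,
        n_components=n_components,
        mean=mean,
        whitening=whitening,
        unmixing=W,
        mixing=mixing,
        meta={
            "seed": seed,
            "tol": tol,
            "max_iter": max_iter,
            "convergence_log": diagnostics,
            "converged": converged,
            "n_training_patches": m,
        },
    )


def _fastica_symmetric(
    Z: np.ndarray, W: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, int, float]:
    """Symmetric fixed-point FastICA with the log-cosh contrast."""
    m = Z.shape[1]
    delta = np.inf
    for it in range(1, max_iter + 1):
        G = np.tanh(W @ Z)
        W_new = (G @ Z.T) / m - np.diag(np.mean(1.0 - G * G, axis=1)) @ W
        W_new = _sym_decorrelate(W_new)
        delta = float(np.max(np.abs(1.0 - np.abs(np.sum(W_new * W, axis=1)))))
        W = W_new
        if delta < tol:
            return W, it, delta
    return W, max_iter, delta


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^(-1/2) W via symmetric eigendecomposition."""
    vals, vecs = np.linalg.eigh(W @ W.T)
    return (vecs / np.sqrt(np.maximum(vals, 1e-18))) @ vecs.T @ W


def project(
    patch: ROIPatch | np.ndarray, basis: ICABasis
) -> FeatureVector | np.ndarray:
    """Coefficients of a patch in the ICA basis: W @ whitening @ (x - mean).

    Accepts a single :class:`ROIPatch` (returns a :class:`FeatureVector`)
    or an array of flattened/stacked patches (returns a coefficient array).
    """
    if isinstance(patch, ROIPatch):
        if patch.side != basis.patch_side:
            raise ValueError(
                f"patch side {patch.side} does not match basis side {basis.patch_side}"
            )
        coeffs = basis.extractor @ (patch.pixels.ravel() - basis.mean)
        return FeatureVector(
            coeffs=coeffs, label=patch.label, density=patch.density, source_id=patch.source_id
        )
    X = _as_matrix(patch)
    if X.shape[-1] != basis.mean.size:
        raise ValueError("patch dimension does not match basis")
    return (X - basis.mean) @ basis.extractor.T


def reconstruct(
    fv: FeatureVector | np.ndarray, basis: ICABasis, clip: bool = False
) -> np.ndarray:
    """Rebuild a patch from coefficients: mean + A @ s (clipped on request)."""
    coeffs = fv.coeffs if isinstance(fv, FeatureVector) else np.asarray(fv, dtype=float)
    if coeffs.shape[-1] != basis.n_components:
        raise ValueError("coefficient length does not match basis component count")
    flat = basis.mean + coeffs @ basis.mixing.T
    if clip:
        flat = np.clip(flat, 0.0, 1.0)
    if flat.ndim == 1:
        return flat.reshape(basis.patch_side, basis.patch_side)
    return flat.reshape(-1, basis.patch_side, basis.patch_side)
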