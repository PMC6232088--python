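"""Per-DoF ridge regression, λ selection, mirroring, and output smoothing.

The decoder maps the normalized EMG feature vector of each 18 Hz frame to
the position/angle of each of the 7 exoskeleton DoFs with an independent
ridge-regressed linear model per DoF.  Every feature column participates in
every DoF's model — the interface deliberately does not pre-select muscles,
so compensatory activations of unrelated muscles are visible in the
feedback.  Ridge shrinkage also splits weight evenly across collinear
columns, penalizing agonist-antagonist co-activation instead of loading one
muscle arbitrarily.

λ policy: within-session decoders select λ per DoF by nested
cross-validation over a grid of 15 consecutive powers of ten spanning
[1e-7, 1e7], scored by mean inner-validation correlation with ties broken
toward the larger (more regularized) λ.  All transfer schemes use a fixed
λ = 1e4.

The mirror transform negates the sign-convention DoFs (lateral translation,
forearm rotation, pronation-supination by default) about a configurable
neutral posture so a trajectory recorded with one arm can calibrate a
decoder for the other.

Predictions are smoothed with a backward weighted moving average — a 550 ms
(10-frame) window with linearly decreasing weights — to avoid jerky
exoskeleton commands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_data import KinematicRecording, MirrorSpec, ValidationError

__all__ = [
    "RidgeDecoder",
    "add_intercept",
    "fit_ridge",
    "select_lambda_nested_cv",
    "mirror_transform",
    "predict_stream",
    "smooth_predictions",
    "smoother_weights",
]


@dataclass
class RidgeDecoder:
    """Fitted per-DoF linear weights plus binding metadata.

    ``weights`` is ``[(n_feature_columns + 1) x n_dofs]`` with the intercept
    in the last row.  ``feature_names`` fixes the column binding: prediction
    refuses feature matrices whose names disagree, so a decoder calibrated
    in one run can be applied safely in another.
    """

    weights: np.ndarray
    lambda_per_dof: np.ndarray
    feature_names: tuple[str, ...]
    dof_names: tuple[str, ...]
    mirror: MirrorSpec | None = None
    provenance: dict = field(default_factory=dict)
    #: per-DoF (low, high) output clamp, from the calibration kinematics'
    #: range plus margin — the exoskeleton cannot execute commands beyond
    #: its travel, so predictions are saturated accordingly
    output_bounds: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.lambda_per_dof = np.asarray(self.lambda_per_dof, dtype=float)
        if self.weights.shape[0] != len(self.feature_names) + 1:
            raise ValidationError(
                f"decoder.weights: {self.weights.shape[0]} rows for "
                f"{len(self.feature_names)} features (+1 intercept expected)"
            )
        if self.weights.shape[1] != len(self.dof_names):
            raise ValidationError("decoder.weights: column count != number of DoFs")
        if self.lambda_per_dof.shape != (self.weights.shape[1],):
            raise ValidationError("decoder.lambda_per_dof: one λ per DoF required")

    # -- serialization --------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "weights": self.weights.tolist(),
                "lambda_per_dof": self.lambda_per_dof.tolist(),
                "feature_names": list(self.feature_names),
                "dof_names": list(self.dof_names),
                "mirror": self.mirror.to_dict() if self.mirror else None,
                "provenance": self.provenance,
                "output_bounds": (
                    self.output_bounds.tolist() if self.output_bounds is not None else None
                ),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str | Path) -> "RidgeDecoder":
        p = Path(doc)
        text = p.read_text() if p.exists() else str(doc)
        d = json.loads(text)
        return cls(
            weights=np.asarray(d["weights"]),
            lambda_per_dof=np.asarray(d["lambda_per_dof"]),
            feature_names=tuple(d["feature_names"]),
            dof_names=tuple(d["dof_names"]),
            mirror=MirrorSpec.from_dict(d["mirror"]) if d.get("mirror") else None,
            provenance=d.get("provenance", {}),
            output_bounds=(
                np.asarray(d["output_bounds"]) if d.get("output_bounds") is not None else None
            ),
        )


def add_intercept(X: np.ndarray) -> np.ndarray:
    """Append the all-ones intercept column."""
    X = np.asarray(X, dtype=float)
    return np.hstack([X, np.ones((X.shape[0], 1))])


def _ridge_solve(X1: np.ndarray, Y: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Solve the ridge normal equations with an unpenalized intercept.

    Uses the centering identity (center features and targets, solve the
    penalized part, recover the intercept from the means) and an SVD of the
    centered feature block, so heavily collinear feature sets stay
    numerically stable across the whole λ grid.  Algebraically identical to
    solving ``(XᵀX + λD) w = Xᵀy`` with D = identity except a zero in the
    intercept slot.
    """
    Xc = X1[:, :-1]
    xm = Xc.mean(axis=0)
    ym = Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc - xm, full_matrices=False)
    UtY = U.T @ (Y - ym)
    p1 = X1.shape[1]
    W = np.empty((p1, Y.shape[1]))
    for d in range(Y.shape[1]):
        shrink = s / (s**2 + lams[d])
        w = Vt.T @ (shrink * UtY[:, d])
        W[:-1, d] = w
        W[-1, d] = ym[d] - xm @ w
    return W


def fit_ridge(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float | np.ndarray,
    feature_names: tuple[str, ...] | None = None,
    dof_names: tuple[str, ...] | None = None,
    mirror: MirrorSpec | None = None,
    provenance: dict | None = None,
) -> RidgeDecoder:
    """Closed-form ridge fit with an unpenalized intercept.

    Per DoF ``d`` solves ``(XᵀX + λ_d D) w = Xᵀ y_d`` where ``X`` is the
    feature matrix with an appended intercept column and ``D`` is the
    identity with a zero in the intercept position.

    Raises for λ < 0, and for λ = 0 on rank-deficient ``X`` (the
    unregularized normal equations have no unique solution there).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p1 = X.shape
    if n < 2:
        raise ValidationError(f"fit_ridge: need at least 2 frames, got {n}")
    if not np.isfinite(X).all() or not np.isfinite(Y).all():
        raise ValidationError("fit_ridge: non-finite values in X or Y")
    n_dofs = Y.shape[1]
    lams = np.broadcast_to(np.atleast_1d(np.asarray(lam, dtype=float)), (n_dofs,)).copy()
    if (lams < 0).any():
        raise ValidationError(f"fit_ridge: λ must be >= 0, got {lams}")

    if (lams == 0).any() and np.linalg.matrix_rank(X) < p1:
        raise ValidationError(
            "fit_ridge: X is rank-deficient and λ = 0; use λ > 0 for a unique solution"
        )

    W = _ridge_solve(X, Y, lams)
    # exoskeleton travel limits: calibration range per DoF plus 25% margin
    lo, hi = Y.min(axis=0), Y.max(axis=0)
    margin = 0.25 * np.maximum(hi - lo, 1e-9)
    bounds = np.column_stack([lo - margin, hi + margin])

    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(p1 - 1))
    if dof_names is None:
        dof_names = tuple(f"dof{i}" for i in range(n_dofs))
    return RidgeDecoder(
        weights=W,
        lambda_per_dof=lams,
        feature_names=feature_names,
        dof_names=dof_names,
        mirror=mirror,
        provenance=provenance or {},
        output_bounds=bounds,
    )


def _contiguous_folds(n: int, k: int) -> list[np.ndarray]:
    """Split row indices 0..n-1 into k contiguous, near-equal blocks."""
    bounds = np.linspace(0, n, k + 1).round().astype(int)
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(k)]


def _cc_columns(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson correlation of two vectors; non-finite (degenerate) -> 0."""
    ys = y - y.mean()
    hs = yhat - yhat.mean()
    denom = np.sqrt((ys * ys).sum() * (hs * hs).sum())
    if denom <= 0:
        return 0.0
    return float((ys * hs).sum() / denom)


def select_lambda_nested_cv(
    X: np.ndarray,
    Y: np.ndarray,
    grid: tuple[float, ...] | None = None,
    inner_folds: int = 5,
) -> np.ndarray:
    """Per-DoF λ by an inner contiguous K-fold grid search.

    ``X`` already carries the intercept column.  Each λ in the grid is
    scored by the mean inner-validation Pearson correlation; the arg-max λ
    is returned per DoF, with ties broken toward the larger λ.  Degenerate
    validation correlations (constant predictions or targets) score 0.
    """
    if grid is None:
        from .core_data import LAMBDA_GRID

        grid = LAMBDA_GRID
    grid = tuple(sorted(float(g) for g in grid))
    if len(grid) == 0:
        raise ValidationError("select_lambda_nested_cv: empty λ grid")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p1 = X.shape
    n_dofs = Y.shape[1]
    folds = _contiguous_folds(n, inner_folds)

    scores = np.zeros((len(grid), n_dofs))
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        Xtr, Ytr = X[mask, :-1], Y[mask]
        Xva, Yva = X[fold, :-1], Y[fold]
        # one SVD of the centered training block serves the whole λ grid
        xm, ym = Xtr.mean(axis=0), Ytr.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xtr - xm, full_matrices=False)
        UtY = U.T @ (Ytr - ym)
        Z = (Xva - xm) @ Vt.T
        for gi, lam in enumerate(grid):
            P = Z @ ((s / (s**2 + lam))[:, None] * UtY) + ym
            for d in range(n_dofs):
                scores[gi, d] += _cc_columns(Yva[:, d], P[:, d])
    scores /= len(folds)

    lams = np.empty(n_dofs)
    for d in range(n_dofs):
        best = scores[:, d].max()
        # ties (within float equality) broken toward larger λ
        lams[d] = max(lam for gi, lam in enumerate(grid) if scores[gi, d] >= best - 1e-12)
    return lams


def mirror_transform(kin: KinematicRecording, spec: MirrorSpec) -> KinematicRecording:
    """Flip the sign-convention DoFs about their neutral and toggle the arm.

    An involution: applying it twice restores the original recording.
    """
    mask, neutral = spec.as_arrays()
    out = kin.samples.copy()
    out[:, mask] = 2.0 * neutral[mask] - out[:, mask]
    other = "left" if kin.arm_side == "right" else "right"
    return kin.copy_with(samples=out, arm_side=other)


def predict_stream(
    decoder: RidgeDecoder, X: np.ndarray, feature_names: tuple[str, ...] | None = None
) -> np.ndarray:
    """Frame-by-frame linear prediction; consults no future samples.

    If ``feature_names`` is given it must match the decoder's binding order
    exactly — names, not positions, are authoritative.  Predictions are
    saturated at the decoder's per-DoF output bounds (the exoskeleton's
    effective travel), when present.
    """
    X = np.asarray(X, dtype=float)
    if feature_names is not None and tuple(feature_names) != tuple(decoder.feature_names):
        raise ValidationError(
            "predict_stream: feature binding mismatch between decoder and input"
        )
    if X.shape[1] != len(decoder.feature_names):
        raise ValidationError(
            f"predict_stream: {X.shape[1]} feature columns, decoder expects "
            f"{len(decoder.feature_names)}"
        )
    pred = add_intercept(X) @ decoder.weights
    if decoder.output_bounds is not None:
        np.clip(pred, decoder.output_bounds[:, 0], decoder.output_bounds[:, 1], out=pred)
    return pred


def smoother_weights(window_ms: float = 550.0, rate_hz: float = 18.0) -> np.ndarray:
    """Linearly decreasing backward weights, normalized to sum 1.

    550 ms at 18 Hz spans 9.9 frames, rounded to K = 10; weight at lag k is
    (K − k) / ΣK, i.e. (10/55, 9/55, ..., 1/55).
    """
    K = int(round(window_ms / 1000.0 * rate_hz))
    K = max(K, 1)
    w = np.arange(K, 0, -1, dtype=float)
    return w / w.sum()


def smooth_predictions(
    pred: np.ndarray, window_ms: float = 550.0, rate_hz: float = 18.0
) -> np.ndarray:
    """Backward weighted moving average with warm-up renormalization.

    ``out[t] = Σ_k w_k · pred[t−k]`` over the available lags; frames younger
    than the window use the truncated weight vector renormalized to sum 1.
    Causal by construction.
    """
    pred = np.asarray(pred, dtype=float)
    squeeze = pred.ndim == 1
    if squeeze:
        pred = pred[:, None]
    w = smoother_weights(window_ms, rate_hz)
    K = len(w)
    n = pred.shape[0]
    out = np.empty_like(pred)
    for c in range(pred.shape[1]):
        full = np.convolve(pred[:, c], w)[:n]
        out[:, c] = full
    # warm-up: renormalize the truncated weight tail
    for t in range(min(K - 1, n)):
        wt = w[: t + 1]
        out[t] = (wt[::-1] / wt.sum()) @ pred[: t + 1]
    return out[:, 0] if squeeze else out
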