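"""PLS-DA by NIPALS, with VIP scores and new-sample projection.

Partial least squares–discriminant analysis regresses a column-centered
one-hot class indicator matrix ``Y`` (samples × classes) on the
preprocessed metabolite matrix ``X``.  Components are extracted one at
a time by the classical NIPALS alternation

    w ∝ X'u,  ||w|| = 1;   t = X w;   q ∝ Y't / t't;   u = Y q

iterated to convergence of the score vector, after which ``X`` is
deflated by ``t p'`` (``p = X't / t't``) and ``Y`` by ``t q'``.  The
Y sum of squares captured by component ``a`` (``SSY_a``, the drop in
||Y||² at deflation) weights the VIP summary

    VIP_j = sqrt( p · Σ_a SSY_a · w_ja² / Σ_a SSY_a )

with ``p`` the number of variables and unit-norm weight columns, so the
mean of VIP² over variables is identically 1.  A variable with
VIP > 1 contributes more than an average share of the explained class
variance; that threshold gates the downstream metabolite
classification.

Sign convention: each weight column is flipped so its largest-magnitude
entry is positive (scores, loadings and Y-loadings flip with it), which
makes fits reproducible across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class PlsdaModel:
    """A fitted PLS-DA model (all matrices dense numpy)."""

    n_components: int
    scores: np.ndarray  # T, samples × A
    weights: np.ndarray  # W, variables × A, unit-norm columns
    x_loadings: np.ndarray  # P, variables × A
    y_loadings: np.ndarray  # Q, classes × A
    explained_y_ss: np.ndarray  # SSY_a per component
    class_order: list[str]
    y_means: np.ndarray  # column means used to center Y
    total_y_ss: float
    n_iterations: list[int] = field(default_factory=list)

    @property
    def n_variables(self) -> int:
        return self.weights.shape[0]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "scores": self.scores.tolist(),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "explained_y_ss": self.explained_y_ss.tolist(),
            "class_order": list(self.class_order),
            "y_means": self.y_means.tolist(),
            "total_y_ss": self.total_y_ss,
            "n_iterations": list(self.n_iterations),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlsdaModel":
        return cls(
            n_components=d["n_components"],
            scores=np.asarray(d["scores"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            explained_y_ss=np.asarray(d["explained_y_ss"], dtype=float),
            class_order=list(d["class_order"]),
            y_means=np.asarray(d["y_means"], dtype=float),
            total_y_ss=float(d["total_y_ss"]),
            n_iterations=list(d.get("n_iterations", [])),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PlsdaModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def one_hot(groups, class_order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """One-hot indicator matrix; class order = first appearance unless given."""
    groups = list(groups)
    if class_order is None:
        class_order = list(dict.fromkeys(groups))
    idx = {g: i for i, g in enumerate(class_order)}
    Y = np.zeros((len(groups), len(class_order)))
    for r, g in enumerate(groups):
        Y[r, idx[g]] = 1.0
    return Y, class_order


def fit_plsda(
    X: np.ndarray,
    groups,
    n_components: int = 2,
    tol: float = 1e-10,
    max_iter: int = 20_000,
) -> PlsdaModel:
    """Fit PLS-DA on preprocessed ``X`` (assumed column-centered).

    Raises :class:`ValidationError` for fewer than two classes, too many
    components, or NIPALS non-convergence (reporting the component and
    the residual score change).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    groups = list(groups)
    if len(groups) != n:
        raise ValidationError("group labels do not match the number of rows of X")
    Y_raw, class_order = one_hot(groups)
    if len(class_order) < 2:
        raise ValidationError("PLS-DA requires at least 2 distinct groups")
    max_comp = min(n - 1, p)
    if not 1 <= n_components <= max_comp:
        raise ValidationError(
            f"n_components must lie in [1, {max_comp}] for this matrix, got {n_components}"
        )

    y_means = Y_raw.mean(axis=0)
    Y = Y_raw - y_means
    total_y_ss = float(np.sum(Y**2))

    Xd, Yd = X.copy(), Y.copy()
    T = np.zeros((n, n_components))
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((len(class_order), n_components))
    ssy = np.zeros(n_components)
    n_iters: list[int] = []

    for a in range(n_components):
        # deterministic start: the Y column with largest residual variance
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
        if not np.any(u):
            raise ValidationError(f"Y residual exhausted before component {a + 1}")
        t_old = np.zeros(n)
        for it in range(1, max_iter + 1):
            w = Xd.T @ u
            w_norm = np.linalg.norm(w)
            if w_norm == 0:
                raise ValidationError(f"X residual exhausted at component {a + 1}")
            w /= w_norm
            t = Xd @ w
            tt = float(t @ t)
            if tt == 0:
                raise ValidationError(f"degenerate score vector at component {a + 1}")
            q = Yd.T @ t / tt
            u = Yd @ q
            delta = np.linalg.norm(t - t_old) / np.linalg.norm(t)
            t_old = t
            if delta < tol:
                break
        else:
            raise ValidationError(
                f"NIPALS did not converge for component {a + 1} "
                f"after {max_iter} iterations (residual score change {delta:.3e})"
            )
        n_iters.append(it)

        # fix the sign so the dominant weight entry is positive
        if w[int(np.argmax(np.abs(w)))] < 0:
            w, t, q = -w, -t, -q
        tt = float(t @ t)
        pl = Xd.T @ t / tt

        ss_before = float(np.sum(Yd**2))
        Xd = Xd - np.outer(t, pl)
        Yd = Yd - np.outer(t, q)
        ssy[a] = ss_before - float(np.sum(Yd**2))

        T[:, a], W[:, a], P[:, a], Q[:, a] = t, w, pl, q

    return PlsdaModel(
        n_components=n_components,
        scores=T,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        explained_y_ss=ssy,
        class_order=class_order,
        y_means=y_means,
        total_y_ss=total_y_ss,
        n_iterations=n_iters,
    )


def compute_vip(model: PlsdaModel, metabolite_ids: list[str] | None = None) -> pd.DataFrame:
    """VIP per variable: cumulative over components plus per-component columns.

    Returns a frame indexed by variable with columns ``vip`` and
    ``vip_comp1..A``; the mean of ``vip**2`` is 1 by construction.
    Raises on a degenerate fit with zero explained Y sum of squares.
    """
    ssy = model.explained_y_ss
    ssy_total = float(ssy.sum())
    if ssy_total <= 0:
        raise ValidationError("degenerate fit: explained Y sum of squares is zero")
    W = model.weights
    p = model.n_variables
    w_norm2 = (W**2) / np.sum(W**2, axis=0)  # unit-norm columns; kept explicit for safety
    vip = np.sqrt(p * (w_norm2 @ ssy) / ssy_total)
    per_comp = np.sqrt(p * w_norm2)  # single-term VIP: the SSY_a factor cancels
    index = metabolite_ids if metabolite_ids is not None else list(range(p))
    if len(index) != p:
        raise ValidationError("metabolite id list does not match the number of variables")
    out = pd.DataFrame({"vip": vip}, index=pd.Index(index, name="metabolite"))
    for a in range(model.n_components):
        out[f"vip_comp{a + 1}"] = per_comp[:, a]
    return out


def project(model: PlsdaModel, X_new: np.ndarray) -> np.ndarray:
    """Scores for new (identically preprocessed) samples.

    Uses the deflation-consistent rotation ``R = W (P'W)^{-1}`` so that
    projecting the training matrix reproduces the training scores.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_variables:
        raise ValidationError(
            f"X_new has {X_new.shape[1]} variables, model expects {model.n_variables}"
        )
    R = model.weights @ np.linalg.inv(model.x_loadings.T @ model.weights)
    return X_new @ R
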