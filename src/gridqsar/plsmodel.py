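"""Partial least squares regression for grid descriptor blocks.

PLS1 is computed by the NIPALS algorithm on mean-centered X and y with no
autoscaling, the convention for field-based 3D-QSAR. For a single response
each NIPALS component is a closed-form power step, so the fit is exactly
deterministic. Model quality follows the usual QSAR bookkeeping:

* r^2 = 1 - RSS/SS, SEE = sqrt(RSS/(n-c-1)),
  F = (r^2/c) / ((1-r^2)/(n-c-1)) on the training fit;
* q^2 = 1 - PRESS/SS and SEP = sqrt(PRESS/(n-c-1)) from leave-one-out
  cross-validation, each left-out sample predicted by a model refit on the
  remaining n-1;
* the optimal number of components (ONC) maximizes LOO q^2 with a
  parsimony tie-break (smallest c within 0.005 of the maximum).

Field contributions and StDev*Coeff contour values are derived from the
regression coefficients and the per-column standard deviations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .fields import DescriptorBlock, GridSpec


@dataclass
class PlsModel:
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, c) NIPALS weight vectors
    x_loadings: np.ndarray  # (p, c)
    y_loadings: np.ndarray  # (c,)
    scores: np.ndarray  # (n, c) training scores
    coefficients: np.ndarray  # (p,) regression coefficients on centered X
    n_components: int
    n_samples: int
    r2: float
    see: float
    f_value: float
    fitted: np.ndarray  # training-set fitted values
    residuals: np.ndarray
    q2: float | None = None
    sep: float | None = None
    onc: int | None = None
    contributions: dict[str, float] = dc_field(default_factory=dict)

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        """Predicted response: ``y_mean + (X_new - x_mean) @ coefficients``."""
        x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
        if x_new.shape[1] != self.x_mean.shape[0]:
            raise ValueError(
                f"X has {x_new.shape[1]} columns, model expects {self.x_mean.shape[0]}"
            )
        return self.y_mean + (x_new - self.x_mean) @ self.coefficients

    def transform(self, x_new: np.ndarray) -> np.ndarray:
        """Project new rows into the latent-component (score) space."""
        x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
        if x_new.shape[1] != self.x_mean.shape[0]:
            raise ValueError("column mismatch")
        rot = self.weights @ np.linalg.inv(self.x_loadings.T @ self.weights)
        return (x_new - self.x_mean) @ rot

    def to_json(self) -> str:
        payload = {
            "n_components": self.n_components,
            "n_samples": self.n_samples,
            "y_mean": self.y_mean,
            "x_mean": self.x_mean.tolist(),
            "coefficients": self.coefficients.tolist(),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "r2": self.r2,
            "see": self.see,
            "f_value": self.f_value,
            "q2": self.q2,
            "sep": self.sep,
            "onc": self.onc,
            "contributions": self.contributions,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PlsModel":
        d = json.loads(text)
        x_mean = np.array(d["x_mean"])
        coef = np.array(d["coefficients"])
        w = np.array(d["weights"])
        p_load = np.array(d["x_loadings"])
        model = cls(
            x_mean=x_mean,
            y_mean=float(d["y_mean"]),
            weights=w,
            x_loadings=p_load,
            y_loadings=np.array(d["y_loadings"]),
            scores=np.zeros((d["n_samples"], d["n_components"])),
            coefficients=coef,
            n_components=int(d["n_components"]),
            n_samples=int(d["n_samples"]),
            r2=float(d["r2"]),
            see=float(d["see"]),
            f_value=float(d["f_value"]),
            fitted=np.array([]),
            residuals=np.array([]),
            q2=d.get("q2"),
            sep=d.get("sep"),
            onc=d.get("onc"),
            contributions=d.get("contributions", {}),
        )
        return model


@dataclass
class ContourField:
    """Per grid point and kind: PLS coefficient x column SD, mapped back to
    the lattice. Filtered-out columns stay at zero. ``favored_level`` /
    ``disfavored_level`` are display isovalues at contribution percentiles
    (default 80/20) of the nonzero values per kind."""

    grid: GridSpec
    values: dict[str, np.ndarray]  # kind -> (n_points,) stdev*coeff
    favored_level: dict[str, float]
    disfavored_level: dict[str, float]


def _check_xy(X: np.ndarray, y: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on sample count")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.allclose(y, y[0]):
        raise ValueError("response has zero variance")
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} outside [1, min(n-1, p)] = "
            f"[1, {min(n - 1, p)}]"
        )
    return X, y


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PlsModel:
    """Fit NIPALS PLS1 on mean-centered ``X`` and ``y`` (no autoscaling)."""
    X, y = _check_xy(X, y, n_components)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    Xd, yd = Xc.copy(), yc.copy()
    x_scale = max(float(np.linalg.norm(Xc)), 1e-30)
    y_scale = max(float(np.linalg.norm(yc)), 1e-30)
    used = 0
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        # stop once residual covariance is numerically exhausted (rank-deficient X)
        if norm < 1e-10 * x_scale * y_scale:
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-20 * x_scale**2:
            break
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t) / tt
        W[:, a], P[:, a], Q[a], T[:, a] = w, p_a, q_a, t
        Xd = Xd - np.outer(t, p_a)
        yd = yd - q_a * t
        used += 1
    W, P, Q, T = W[:, :used], P[:, :used], Q[:used], T[:, :used]
    if used == 0:
        raise ValueError("X carries no covariance with y; cannot fit")
    coef = W @ np.linalg.solve(P.T @ W, Q)

    fitted = y_mean + Xc @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    ss = float(yc @ yc)
    c = used
    r2 = 1.0 - rss / ss
    dof = n - c - 1
    see = float(np.sqrt(rss / dof)) if dof > 0 else float("nan")
    f_value = (r2 / c) / ((1.0 - r2) / dof) if dof > 0 and r2 < 1.0 else float("inf")
    return PlsModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        coefficients=coef,
        n_components=c,
        n_samples=n,
        r2=r2,
        see=see,
        f_value=f_value,
        fitted=fitted,
        residuals=resid,
    )


def loo_q2(X: np.ndarray, y: np.ndarray, n_components: int) -> tuple[float, float, float]:
    """Leave-one-out cross-validation: returns ``(q2, sep, press)``.

    Each sample is predicted by a PLS model refit on the other n-1 samples;
    ``q2 = 1 - PRESS/SS`` and ``SEP = sqrt(PRESS/(n-c-1))``.
    """
    X, y = _check_xy(X, y, n_components)
    n = len(y)
    if n < 4:
        raise ValueError("LOO needs at least 4 samples")
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        sub = fit_pls(X[keep], y[keep], min(n_components, n - 2))
        preds[i] = sub.predict(X[i : i + 1])[0]
    press = float(np.sum((y - preds) ** 2))
    ss = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / ss
    dof = n - n_components - 1
    sep = float(np.sqrt(press / dof)) if dof > 0 else float("nan")
    return q2, sep, press


def select_onc(
    X: np.ndarray, y: np.ndarray, max_components: int = 10, tie_tol: float = 0.005
) -> tuple[int, dict[int, float]]:
    """Scan component counts 1..max and pick the LOO-q2 optimum.

    Ties break toward fewer components: the smallest c whose q2 is within
    ``tie_tol`` of the maximum wins. Returns ``(onc, q2_by_component)``.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    upper = min(max_components, len(y) - 2, X.shape[1])
    profile: dict[int, float] = {}
    for c in range(1, upper + 1):
        profile[c] = loo_q2(X, y, c)[0]
    best = max(profile.values())
    onc = min(c for c, q in profile.items() if q >= best - tie_tol)
    return onc, profile


def field_contributions(model: PlsModel, block: DescriptorBlock) -> dict[str, float]:
    """Percentage contribution of each field kind:
    ``sum_{cols of kind} |coef_j| * sd_j``, normalized to 100."""
    meta = block.kept_meta()
    if len(meta) != len(model.coefficients):
        raise ValueError("model was not fitted on this block's kept columns")
    sd = block.filtered().std(axis=0, ddof=1)
    weight = np.abs(model.coefficients) * sd
    totals = pd.Series(weight).groupby(meta["kind"].to_numpy()).sum()
    grand = totals.sum()
    if grand == 0:
        return {k: 0.0 for k in totals.index}
    return {k: float(100.0 * v / grand) for k, v in totals.items()}


def stdev_coeff_field(
    model: PlsModel,
    block: DescriptorBlock,
    favored_pct: float = 80.0,
    disfavored_pct: float = 20.0,
) -> ContourField:
    """StDev*Coeff contour values per kind, mapped to the grid.

    Kept column j contributes ``coef_j * sd_j`` at its grid point;
    filtered-out columns are zero. Display levels are percentiles of the
    nonzero values per kind (favored high, disfavored low).
    """
    meta = block.kept_meta()
    if len(meta) != len(model.coefficients):
        raise ValueError("model was not fitted on this block's kept columns")
    sd = block.filtered().std(axis=0, ddof=1)
    vals = model.coefficients * sd
    out: dict[str, np.ndarray] = {}
    fav: dict[str, float] = {}
    dis: dict[str, float] = {}
    for kind in block.kinds():
        arr = np.zeros(block.grid.n_points)
        sel = meta["kind"] == kind
        arr[meta.loc[sel, "point"].to_numpy()] = vals[sel.to_numpy()]
        out[kind] = arr
        nz = arr[arr != 0]
        if nz.size:
            fav[kind] = float(np.percentile(nz, favored_pct))
            dis[kind] = float(np.percentile(nz, disfavored_pct))
        else:
            fav[kind] = 0.0
            dis[kind] = 0.0
    return ContourField(grid=block.grid, values=out, favored_level=fav, disfavored_level=dis)


def predict(model: PlsModel, x_new: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`PlsModel.predict`."""
    return model.predict(x_new)
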