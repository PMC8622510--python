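"""Model-quality battery for 3D-QSAR PLS models.

Covers four layers of evidence:

* internal fitness — chi-squared (sum of squared residuals over squared
  observed values), RMSE with an n-1 denominator, MAE and RSS;
* external predictivity — the Golbraikh-Tropsha through-origin slopes and
  r0^2 checks, Roy's rm^2 family, the QF3^2 external Q^2 normalized by
  training variance, and Lin's concordance correlation coefficient, each
  with its conventional pass threshold;
* progressive scrambling — controlled within-bin perturbation of the
  response; model stability is summarized by the scrambled Q^2, cSDEP and
  the sensitivity slope dq^2/dr^2_yy' evaluated at the critical
  perturbation r^2_yy' = 0.85 (slopes above 1.2 flag instability);
* applicability domain — leverage in latent-component space against
  standardized residuals (the Williams plot), with warning leverage
  h* = 3(p+1)/n.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .plsmodel import PlsModel, fit_pls, loo_q2

#: Conventional pass thresholds (Golbraikh-Tropsha / Roy / QF3 practice).
THRESHOLDS = {
    "k": (0.85, 1.15),
    "k_prime": (0.85, 1.15),
    "abs_diff_r0": 0.3,  # |r0^2 - r'0^2| < 0.3
    "rel_gap": 0.1,  # (r^2 - r0^2)/r^2 < 0.1
    "rm2": 0.5,
    "rm2_bar": 0.5,
    "qf3_2": 0.6,
    "chi2": 0.5,  # chi2 < 0.5 indicates adequate fitness
    "rmse": 0.3,
}

#: Progressive-scrambling stability limit on dq^2/dr^2_yy'.
STABILITY_SLOPE_LIMIT = 1.2
#: Critical perturbation level at which scrambling statistics are read off.
CRITICAL_RYY2 = 0.85


# ---------------------------------------------------------------------------
# internal fitness


def fitness_metrics(
    y: np.ndarray, yhat: np.ndarray, chi2_denominator: str = "squared"
) -> dict[str, float]:
    """Internal fitness metrics of observed vs predicted activities.

    chi2 defaults to ``sum (y-yhat)^2 / y^2`` (``chi2_denominator=
    "squared"``); the Pearson-style ``/ y`` variant is selectable. RMSE uses
    the n-1 denominator. Requires nonzero ``y`` for chi2.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape or len(y) < 2:
        raise ValueError("need equal-length vectors with at least 2 entries")
    resid = y - yhat
    rss = float(resid @ resid)
    if np.any(y == 0):
        raise ValueError("chi2 undefined for zero observed values")
    if chi2_denominator == "squared":
        chi2 = float(np.sum(resid**2 / y**2))
    elif chi2_denominator == "linear":
        chi2 = float(np.sum(resid**2 / y))
    else:
        raise ValueError(f"unknown chi2_denominator {chi2_denominator!r}")
    rmse = float(np.sqrt(rss / (len(y) - 1)))
    mae = float(np.mean(np.abs(resid)))
    return {"chi2": chi2, "rmse": rmse, "mae": mae, "rss": rss}


# ---------------------------------------------------------------------------
# external predictivity


@dataclass
class ValidationReport:
    chi2: float
    rmse: float
    mae: float
    rss: float
    r2: float
    k: float
    k_prime: float
    r0_2: float
    r0_2_prime: float
    abs_diff_r0: float
    rel_gap: float
    rm2: float
    rm2_prime: float
    rm2_bar: float
    delta_rm2: float
    qf3_2: float
    ccc: float
    pass_flags: dict[str, bool] = dc_field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in (
            "chi2",
            "rmse",
            "mae",
            "rss",
            "r2",
            "k",
            "k_prime",
            "abs_diff_r0",
            "rel_gap",
            "rm2",
            "rm2_bar",
            "delta_rm2",
            "qf3_2",
            "ccc",
        ):
            rows.append(
                {
                    "metric": name,
                    "value": getattr(self, name),
                    "passes": self.pass_flags.get(name, None),
                }
            )
        return pd.DataFrame(rows)


def concordance_correlation(y: np.ndarray, yhat: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    my, mp = y.mean(), yhat.mean()
    sy2 = np.mean((y - my) ** 2)
    sp2 = np.mean((yhat - mp) ** 2)
    sxy = np.mean((y - my) * (yhat - mp))
    return float(2.0 * sxy / (sy2 + sp2 + (my - mp) ** 2))


def external_metrics(
    y_test: np.ndarray, yhat_test: np.ndarray, y_train: np.ndarray
) -> ValidationReport:
    """Full external-validation battery on the test set.

    ``r^2`` is the squared Pearson correlation of observed vs predicted.
    ``k = sum(y*yhat)/sum(yhat^2)`` and ``k' = sum(y*yhat)/sum(y^2)`` are
    the through-origin regression slopes; ``r0^2`` (``r'0^2``) measures the
    through-origin fit of observed-vs-predicted (predicted-vs-observed).
    ``rm^2 = r^2 (1 - sqrt(|r^2 - r0^2|))``, the bar variant averages the
    two directions and ``delta rm^2`` is their absolute difference.
    ``QF3^2 = 1 - [PRESS_test/n_test] / [SS_train/n_train]`` and ``ccc`` is
    Lin's concordance correlation. ``pass_flags`` applies the conventional
    thresholds.
    """
    y = np.asarray(y_test, dtype=float).ravel()
    yh = np.asarray(yhat_test, dtype=float).ravel()
    ytr = np.asarray(y_train, dtype=float).ravel()
    if len(y) < 3:
        raise ValueError("need at least 3 test compounds")
    if np.allclose(y, y[0]):
        raise ValueError("test activities are constant; metrics undefined")

    fit = fitness_metrics(y, yh)
    r = np.corrcoef(y, yh)[0, 1]
    r2 = float(r * r)

    k = float(np.sum(y * yh) / np.sum(yh**2))
    k_prime = float(np.sum(y * yh) / np.sum(y**2))
    ss_y = float(np.sum((y - y.mean()) ** 2))
    ss_yh = float(np.sum((yh - yh.mean()) ** 2))
    r0_2 = 1.0 - float(np.sum((y - k * yh) ** 2)) / ss_y
    r0_2_prime = 1.0 - float(np.sum((yh - k_prime * y) ** 2)) / ss_yh
    abs_diff_r0 = abs(r0_2 - r0_2_prime)
    rel_gap = (r2 - r0_2) / r2 if r2 > 0 else float("nan")
    rm2 = r2 * (1.0 - np.sqrt(abs(r2 - r0_2)))
    rm2_prime = r2 * (1.0 - np.sqrt(abs(r2 - r0_2_prime)))
    rm2_bar = 0.5 * (rm2 + rm2_prime)
    delta_rm2 = abs(rm2 - rm2_prime)
    qf3_2 = 1.0 - (float(np.sum((y - yh) ** 2)) / len(y)) / (
        float(np.sum((ytr - ytr.mean()) ** 2)) / len(ytr)
    )
    ccc = concordance_correlation(y, yh)

    report = ValidationReport(
        chi2=fit["chi2"],
        rmse=fit["rmse"],
        mae=fit["mae"],
        rss=fit["rss"],
        r2=r2,
        k=k,
        k_prime=k_prime,
        r0_2=r0_2,
        r0_2_prime=r0_2_prime,
        abs_diff_r0=abs_diff_r0,
        rel_gap=rel_gap,
        rm2=float(rm2),
        rm2_prime=float(rm2_prime),
        rm2_bar=float(rm2_bar),
        delta_rm2=float(delta_rm2),
        qf3_2=float(qf3_2),
        ccc=ccc,
    )
    lo, hi = THRESHOLDS["k"]
    report.pass_flags = {
        "k": lo <= k <= hi,
        "k_prime": lo <= k_prime <= hi,
        "abs_diff_r0": abs_diff_r0 < THRESHOLDS["abs_diff_r0"],
        "rel_gap": rel_gap < THRESHOLDS["rel_gap"],
        "rm2": rm2 > THRESHOLDS["rm2"],
        "rm2_bar": rm2_bar > THRESHOLDS["rm2_bar"],
        "qf3_2": qf3_2 > THRESHOLDS["qf3_2"],
        "chi2": fit["chi2"] < THRESHOLDS["chi2"],
        "rmse": fit["rmse"] < THRESHOLDS["rmse"],
    }
    return report


# ---------------------------------------------------------------------------
# progressive scrambling


@dataclass
class ScramblingResult:
    """Per component count: Q^2, cSDEP and dq^2/dr^2_yy' at the critical
    perturbation, plus the raw (r^2_yy', q^2, sdep) samples."""

    table: pd.DataFrame  # columns: components, q2_critical, csdep, slope
    samples: pd.DataFrame  # columns: components, r2yy, q2, sdep
    n_scrambles: int
    bin_min: int
    bin_max: int
    seed: int

    def is_stable(self, components: int, limit: float = STABILITY_SLOPE_LIMIT) -> bool:
        row = self.table.loc[self.table["components"] == components]
        if row.empty:
            raise KeyError(f"no scrambling result for {components} components")
        return classify_stability(float(row["slope"].iloc[0]), limit) == "stable"


def classify_stability(slope: float, limit: float = STABILITY_SLOPE_LIMIT) -> str:
    """A model is stable when the scrambling sensitivity slope does not
    exceed the limit (1.2 by convention)."""
    return "stable" if slope <= limit else "unstable"


def _perturb_response(
    y_sorted_idx: np.ndarray, y: np.ndarray, strength: float, bin_size: int, rng
) -> np.ndarray:
    """One scrambling draw of graded ``strength`` in [0, 1].

    Strength 0 is the identity. Mild strengths permute within consecutive
    activity bins of the sorted response (preserving most of the
    correlation with the original y); stronger draws additionally swap a
    growing fraction of entries globally, driving r^2_yy' toward zero.
    """
    y_new = y.copy()
    if strength <= 0:
        return y_new
    order = y_sorted_idx
    n = len(y)
    p_bin = min(1.0, 2.0 * strength)
    for start in range(0, n, bin_size):
        members = order[start : start + bin_size]
        if len(members) > 1 and rng.random() < p_bin:
            y_new[members] = y_new[rng.permutation(members)]
    n_swap = int(round(max(0.0, strength - 0.3) * n))
    if n_swap >= 1:
        a = rng.choice(n, size=n_swap, replace=False)
        b = rng.permutation(a)
        y_new[a] = y_new[b]
    return y_new


def progressive_scrambling(
    X: np.ndarray,
    y: np.ndarray,
    onc: int,
    n_scrambles: int = 100,
    bin_min: int = 2,
    bin_max: int = 10,
    seed: int = 0,
    critical: float = CRITICAL_RYY2,
) -> ScramblingResult:
    """Progressive scrambling of the response against the fixed descriptors.

    Each scramble draws a bin size in [bin_min, bin_max], partitions the
    activity-sorted response into consecutive bins, permutes within bins,
    and applies additional global swaps of graded strength so the scrambles
    span a range of residual correlation r^2_yy' with the original y. For
    every scramble and component count 1..onc the LOO q^2 and SDEP of the
    perturbed response are recorded. Per component count the summary fits a
    quadratic of q^2 (and SDEP) against r^2_yy' and reads off the value and
    the derivative dq^2/dr^2_yy' at the critical perturbation (0.85).
    """
    if n_scrambles < 10:
        raise ValueError("need at least 10 scrambles")
    if bin_min > bin_max:
        raise ValueError("bin_min must not exceed bin_max")
    if bin_min < 1:
        raise ValueError("bin sizes must be positive")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    # graded strengths spanning the identity to near-total scrambling
    strengths = np.linspace(0.0, 1.0, n_scrambles)
    records = []
    for s in strengths:
        bin_size = int(rng.integers(bin_min, bin_max + 1))
        y_pert = _perturb_response(order, y, float(s), bin_size, rng)
        r = np.corrcoef(y, y_pert)[0, 1]
        r2yy = float(r * r)
        for c in range(1, onc + 1):
            q2, sdep, _ = loo_q2(X, y_pert, c)
            records.append({"components": c, "r2yy": r2yy, "q2": q2, "sdep": sdep})
    samples = pd.DataFrame.from_records(records)

    rows = []
    for c, grp in samples.groupby("components"):
        coef_q = np.polyfit(grp["r2yy"], grp["q2"], 2)
        coef_s = np.polyfit(grp["r2yy"], grp["sdep"], 2)
        q2_crit = float(np.polyval(coef_q, critical))
        csdep = float(np.polyval(coef_s, critical))
        slope = float(2.0 * coef_q[0] * critical + coef_q[1])
        rows.append(
            {"components": int(c), "q2_critical": q2_crit, "csdep": csdep, "slope": slope}
        )
    return ScramblingResult(
        table=pd.DataFrame(rows),
        samples=samples,
        n_scrambles=n_scrambles,
        bin_min=bin_min,
        bin_max=bin_max,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# applicability domain


@dataclass
class AdReport:
    """Williams-plot bookkeeping: per-compound leverage, standardized
    residual, and the outlier flag; ``h_star = 3(p+1)/n``."""

    table: pd.DataFrame  # columns: leverage, std_residual, set_label, outlier
    h_star: float

    def outliers(self) -> pd.DataFrame:
        return self.table[self.table["outlier"]]


def applicability_domain(
    train_scores: np.ndarray,
    test_scores: np.ndarray | None,
    residuals_train: np.ndarray,
    residuals_test: np.ndarray | None,
    onc: int,
    residual_limit: float = 3.0,
) -> AdReport:
    """Leverage-based applicability domain in latent-component space.

    Training leverage ``h_i = 1/n + t_i^T (T^T T)^{-1} t_i`` on centered
    training scores (so the training centroid sits at h = 1/n); test rows
    are projected with the same centering. Warning leverage
    ``h* = 3(p+1)/n`` with p = onc. Standardized residuals are scaled by
    the training residual SD; a compound is flagged when ``h > h*`` or
    ``|std residual| > residual_limit``.
    """
    T = np.atleast_2d(np.asarray(train_scores, dtype=float))
    rtr = np.asarray(residuals_train, dtype=float).ravel()
    n = T.shape[0]
    if rtr.shape[0] != n:
        raise ValueError("training scores and residuals disagree on length")
    center = T.mean(axis=0)
    Tc = T - center
    gram = Tc.T @ Tc
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise np.linalg.LinAlgError("singular score covariance; reduce components")
    ginv = np.linalg.inv(gram)

    def leverage(scores: np.ndarray) -> np.ndarray:
        sc = np.atleast_2d(scores) - center
        return 1.0 / n + np.einsum("ij,jk,ik->i", sc, ginv, sc)

    h_star = 3.0 * (onc + 1) / n
    sd = float(rtr.std(ddof=1))
    if sd == 0:
        raise ValueError("zero training residual variance")

    rows = []
    for h, res in zip(leverage(T), rtr / sd):
        rows.append({"leverage": float(h), "std_residual": float(res), "set_label": "train"})
    if test_scores is not None and len(np.atleast_2d(test_scores)):
        rte = np.asarray(residuals_test, dtype=float).ravel()
        for h, res in zip(leverage(test_scores), rte / sd):
            rows.append(
                {"leverage": float(h), "std_residual": float(res), "set_label": "test"}
            )
    table = pd.DataFrame(rows)
    table["outlier"] = (table["leverage"] > h_star) | (
        table["std_residual"].abs() > residual_limit
    )
    return AdReport(table=table, h_star=h_star)


def williams_plot(report: AdReport, path: str, residual_limit: float = 3.0) -> None:
    """Render the Williams plot (leverage vs standardized residual) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, marker in (("train", "o"), ("test", "s")):
        sub = report.table[report.table["set_label"] == label]
        ax.scatter(sub["leverage"], sub["std_residual"], marker=marker, label=label)
    ax.axhline(residual_limit, color="r", ls="--", lw=0.8)
    ax.axhline(-residual_limit, color="r", ls="--", lw=0.8)
    ax.axvline(report.h_star, color="r", ls=":", lw=0.8, label="h*")
    ax.set_xlabel("leverage")
    ax.set_ylabel("standardized residual")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
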