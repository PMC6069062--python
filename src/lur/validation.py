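"""Model validation: leave-one-out cross-validation, error metrics, and
residual spatial autocorrelation (Moran's I with a permutation test)."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FoldError, ZeroVarianceError
from .features import DISTANCE_FLOOR, PredictorMatrix
from .selection import LurFit

DEFAULT_PERMUTATIONS = 999


@dataclass
class ValidationReport:
    loocv_r2: float
    model_r2: float
    rmse: float
    nmb: float
    loocv_rmse: float
    loocv_nmb: float
    morans_i: float
    morans_p: float
    n_sites: int

    def to_dict(self) -> dict:
        return asdict(self)


def loocv(
    fit: LurFit,
    matrix: PredictorMatrix,
    response: np.ndarray | pd.Series,
    r2_method: str = "pearson",
) -> tuple[np.ndarray, float]:
    """Leave-one-out predictions with the term set frozen.

    For each site the coefficients are re-estimated on the other n-1 sites by
    explicit refit (selection is never re-run) and the held-out site is
    predicted.  ``r2_method`` is ``"pearson"`` (squared correlation of
    observed vs predicted, the default) or ``"sse"`` (1 - SSE/SST).
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    names = fit.term_names
    X = matrix.values_for(names) if names else np.empty((n, 0))
    A = np.column_stack([np.ones(n), X])
    p = A.shape[1]
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        A_i = A[mask]
        if np.linalg.matrix_rank(A_i) < p:
            raise FoldError(f"fold {i} (site {matrix.frame.index[i]!r}): design is rank deficient")
        coef, _, _, _ = np.linalg.lstsq(A_i, y[mask], rcond=None)
        preds[i] = A[i] @ coef
    return preds, _r2(y, preds, r2_method)


def _r2(obs: np.ndarray, pred: np.ndarray, method: str) -> float:
    if method == "pearson":
        if np.std(pred) == 0 or np.std(obs) == 0:
            return 0.0
        return float(np.corrcoef(obs, pred)[0, 1] ** 2)
    if method == "sse":
        ss_tot = float(((obs - obs.mean()) ** 2).sum())
        if ss_tot == 0:
            return 0.0
        return 1.0 - float(((obs - pred) ** 2).sum()) / ss_tot
    raise ValueError(f"unknown r2 method {method!r}")


def error_metrics(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """Return (RMSE, NMB).  NMB is NaN (undefined) when sum(observed) == 0."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0 or obs.shape != pred.shape:
        raise ValueError("observed and predicted must be equal-length and non-empty")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    denom = obs.sum()
    nmb = float((pred - obs).sum() / denom) if denom != 0 else float("nan")
    return rmse, nmb


@dataclass
class MoransResult:
    statistic: float
    p_value: float
    expected: float
    n_permutations: int


def spatial_weights(coords: np.ndarray, floor: float = DISTANCE_FLOOR) -> np.ndarray:
    """Row-standardised inverse-distance weights with zero diagonal."""
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    d = np.maximum(d, floor)
    w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    row = w.sum(axis=1, keepdims=True)
    return w / row


def morans_i(
    residuals: np.ndarray,
    coords: np.ndarray,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    floor: float = DISTANCE_FLOOR,
) -> MoransResult:
    """Moran's I with a two-sided permutation test.

    I = (n / S0) * (z' W z) / (z' z) with z the centred residuals and W the
    row-standardised inverse-distance weights.  The p-value counts permuted
    statistics whose absolute deviation from the null expectation -1/(n-1) is
    at least that of the observed one, so the minimum attainable p is
    1/(n_permutations + 1).
    """
    z = np.asarray(residuals, dtype=float)
    n = len(z)
    if n < 4:
        raise ValueError("Moran's I requires at least 4 sites")
    if np.ptp(z) == 0:
        raise ZeroVarianceError("residuals have zero variance")
    z = z - z.mean()
    W = spatial_weights(coords, floor)
    s0 = W.sum()
    denom = float(z @ z)
    i_obs = float((n / s0) * (z @ W @ z) / denom)
    mu = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_permutations, n)), axis=1)
    Z = z[perm_idx]  # (K, n); centring and z'z are permutation-invariant
    i_perm = (n / s0) * np.einsum("kn,kn->k", Z @ W.T, Z) / denom
    extreme = np.abs(i_perm - mu) >= np.abs(i_obs - mu) - 1e-15
    p = (1 + int(extreme.sum())) / (n_permutations + 1)
    return MoransResult(statistic=i_obs, p_value=float(p), expected=mu, n_permutations=n_permutations)


def validate(
    fit: LurFit,
    matrix: PredictorMatrix,
    response: np.ndarray | pd.Series,
    coords: np.ndarray,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    r2_method: str = "pearson",
) -> tuple[ValidationReport, np.ndarray]:
    """Full validation report plus the LOOCV predictions."""
    y = np.asarray(response, dtype=float)
    names = fit.term_names
    X = matrix.values_for(names) if names else np.empty((len(y), 0))
    in_sample = fit.predict(X)
    rmse, nmb = error_metrics(y, in_sample)
    preds, cv_r2 = loocv(fit, matrix, y, r2_method)
    cv_rmse, cv_nmb = error_metrics(y, preds)
    moran = morans_i(y - in_sample, coords, n_permutations=n_permutations, seed=seed)
    report = ValidationReport(
        loocv_r2=cv_r2,
        model_r2=fit.r_squared,
        rmse=rmse,
        nmb=nmb,
        loocv_rmse=cv_rmse,
        loocv_nmb=cv_nmb,
        morans_i=moran.statistic,
        morans_p=moran.p_value,
        n_sites=len(y),
    )
    return report, preds


def write_validation(
    fit: LurFit,
    report: ValidationReport,
    preds: np.ndarray,
    observed: np.ndarray,
    site_ids: Sequence,
    fit_path=None,
    csv_path=None,
    plot_path=None,
) -> None:
    """Persist validation: fit JSON with a validation block, per-fold CSV,
    and an observed-vs-predicted scatter with the dotted 1:1 line."""
    if fit_path is not None:
        payload = fit.to_dict()
        payload["validation"] = report.to_dict()
        Path(fit_path).write_text(json.dumps(payload, indent=1))
    if csv_path is not None:
        pd.DataFrame({"site_id": list(site_ids), "observed": observed, "predicted": preds}).to_csv(
            csv_path, index=False
        )
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(observed, preds, s=18, alpha=0.8)
        lo = min(float(np.min(observed)), float(np.min(preds)))
        hi = max(float(np.max(observed)), float(np.max(preds)))
        ax.plot([lo, hi], [lo, hi], linestyle=":", color="k", linewidth=1)
        ax.set_xlabel("observed (ug/m3)")
        ax.set_ylabel("LOOCV predicted (ug/m3)")
        ax.set_title(f"{fit.pollutant.upper()} {fit.season}: LOOCV R2 = {report.loocv_r2:.2f}")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
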