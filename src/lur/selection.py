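"""Sign-constrained supervised forward selection with diagnostic pruning.

The selection starts from an intercept-only model and, at each step, adds the
eligible candidate with the largest gain in R-squared, subject to: the
candidate's own coefficient must carry its expected sign, every previously
accepted term must keep its expected sign, and the gain must be at least 1%.
The fitted model is then pruned on collinearity (VIF < 3), significance
(p < 0.1) and re-checked signs; influential sites (Cook's D >= 1) are flagged
but never removed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import EmptyMatrixError
from .features import PredictorMatrix, PredictorSpec

logger = logging.getLogger(__name__)

MIN_GAIN = 0.01
SCREEN_FRACTION = 0.10
VIF_MAX = 3.0
P_MAX = 0.1
COOKS_D_MAX = 1.0


@dataclass
class LurTerm:
    name: str
    coefficient: float
    expected_sign: str
    p_value: float
    vif: float
    incremental_r2: float
    spec: dict = field(default_factory=dict)


@dataclass
class LurFit:
    """A fitted land-use-regression model with its selection trace."""

    pollutant: str
    season: str
    intercept: float
    terms: list[LurTerm]
    r_squared: float
    adj_r_squared: float
    n_sites: int
    max_cooks_d: float = 0.0
    influential_sites: list = field(default_factory=list)
    selection_trace: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def coefficients(self) -> np.ndarray:
        return np.array([t.coefficient for t in self.terms])

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not self.terms:
            n = X.shape[0] if X.ndim == 2 else len(X)
            return np.full(n, self.intercept)
        return self.intercept + X @ self.coefficients()

    def to_dict(self) -> dict:
        return {
            "pollutant": self.pollutant,
            "season": self.season,
            "intercept": self.intercept,
            "terms": [asdict(t) for t in self.terms],
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "n_sites": self.n_sites,
            "max_cooks_d": self.max_cooks_d,
            "influential_sites": list(self.influential_sites),
            "selection_trace": self.selection_trace,
            "notes": self.notes,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "LurFit":
        terms = [LurTerm(**t) for t in d["terms"]]
        return cls(
            pollutant=d["pollutant"], season=d["season"], intercept=d["intercept"],
            terms=terms, r_squared=d["r_squared"], adj_r_squared=d.get("adj_r_squared", float("nan")),
            n_sites=d["n_sites"], max_cooks_d=d.get("max_cooks_d", 0.0),
            influential_sites=d.get("influential_sites", []),
            selection_trace=d.get("selection_trace", []), notes=d.get("notes", []),
        )

    @classmethod
    def from_json(cls, path) -> "LurFit":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def summary_table(self) -> str:
        """Human-readable summary mirroring a published model table."""
        lines = [
            f"{self.pollutant.upper()} {self.season} model  (N = {self.n_sites})",
            f"R2 = {self.r_squared:.3f}   adj. R2 = {self.adj_r_squared:.3f}   "
            f"max Cook's D = {self.max_cooks_d:.3f}",
            f"intercept = {self.intercept:.4g}",
            f"{'predictor':<22}{'coef':>12}{'sign':>6}{'p':>10}{'VIF':>8}{'incr R2':>9}",
        ]
        for t in self.terms:
            lines.append(
                f"{t.name:<22}{t.coefficient:>12.4g}{t.expected_sign:>6}"
                f"{t.p_value:>10.3g}{t.vif:>8.2f}{t.incremental_r2:>9.3f}"
            )
        if not self.terms:
            lines.append("(intercept-only model)")
        return "\n".join(lines)


def screen_candidates(matrix: PredictorMatrix, min_fraction: float = SCREEN_FRACTION) -> list[str]:
    """Columns whose fraction of non-zero values exceeds ``min_fraction``.

    Constant columns are dropped unconditionally (they carry no information
    even when every value is non-zero).
    """
    frame = matrix.frame
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise EmptyMatrixError("predictor matrix is empty")
    kept = []
    for col in frame.columns:
        vals = frame[col].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            continue
        if (vals != 0).mean() > min_fraction:
            kept.append(col)
    return kept


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Fast OLS with intercept; returns (coefs incl. intercept, r_squared)."""
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return coef, 0.0
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return coef, r2


def _adjust_r2(r2: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def vif(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1 - R2_j), regressing column j on the others (with intercept).

    A single column has VIF 1 by definition; perfect collinearity yields +inf.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    k = X.shape[1]
    if k == 1:
        return np.ones(1)
    out = np.empty(k)
    for j in range(k):
        others = np.delete(X, j, axis=1)
        _, r2 = _ols(X[:, j], others)
        out[j] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _signs_ok(coefs: np.ndarray, specs: Sequence[PredictorSpec]) -> bool:
    return all(c * s.sign_value > 0 for c, s in zip(coefs, specs))


def forward_select(
    response: np.ndarray | pd.Series,
    matrix: PredictorMatrix,
    candidates: Sequence[str] | None = None,
    pollutant: str = "",
    season: str = "",
    min_gain: float = MIN_GAIN,
    use_adjusted_r2: bool = False,
) -> LurFit:
    """Supervised forward selection under sign constraints.

    Ties in gain are broken by lexicographic predictor name, making the
    procedure fully deterministic.  The full per-step trace (every candidate,
    its gain or veto reason) is recorded on the returned fit.
    """
    y = np.asarray(response, dtype=float)
    if candidates is None:
        candidates = screen_candidates(matrix)
    remaining = sorted(candidates)
    selected: list[str] = []
    trace: list[dict] = []
    current_r2 = 0.0
    current_score = 0.0  # criterion scale (plain or adjusted R2)
    n = len(y)

    step = 0
    while remaining:
        step += 1
        best: tuple[float, str] | None = None
        step_log: list[dict] = []
        for name in remaining:
            cols = selected + [name]
            X = matrix.values_for(cols)
            coef, r2 = _ols(y, X)
            score = _adjust_r2(r2, n, len(cols)) if use_adjusted_r2 else r2
            gain = score - current_score
            specs = [matrix.specs[c] for c in cols]
            if not _signs_ok(coef[1:], specs):
                bad = [s.name for c, s in zip(coef[1:], specs) if c * s.sign_value <= 0]
                step_log.append({"candidate": name, "gain": gain, "eligible": False,
                                 "veto": f"sign violation: {bad}"})
                continue
            step_log.append({"candidate": name, "gain": gain, "eligible": True, "r2": r2})
            if best is None or gain > best[0]:
                best = (gain, name)
        accepted = None
        if best is not None and best[0] >= min_gain - 1e-12:
            accepted = best[1]
            selected.append(accepted)
            remaining.remove(accepted)
            _, current_r2 = _ols(y, matrix.values_for(selected))
            current_score = (
                _adjust_r2(current_r2, n, len(selected)) if use_adjusted_r2 else current_r2
            )
        trace.append({"step": step, "candidates": step_log, "accepted": accepted,
                      "r2": current_r2})
        if accepted is None:
            break

    fit = _finalize_fit(y, matrix, selected, pollutant, season, trace)
    _note_nested_radii(fit, matrix)
    if fit.terms and len(fit.terms) > n / 10:
        logger.warning("model has %d terms for %d sites (> n/10)", len(fit.terms), n)
    return fit


def _finalize_fit(
    y: np.ndarray,
    matrix: PredictorMatrix,
    selected: list[str],
    pollutant: str,
    season: str,
    trace: list[dict],
) -> LurFit:
    n = len(y)
    if not selected:
        return LurFit(
            pollutant=pollutant, season=season, intercept=float(np.mean(y)), terms=[],
            r_squared=0.0, adj_r_squared=0.0, n_sites=n, selection_trace=trace,
        )
    X = matrix.values_for(selected)
    A = sm.add_constant(X)
    res = sm.OLS(y, A).fit()
    vifs = vif(X)
    # incremental R2 along the accepted order
    incr = []
    prev = 0.0
    for i in range(len(selected)):
        _, r2_i = _ols(y, matrix.values_for(selected[: i + 1]))
        incr.append(r2_i - prev)
        prev = r2_i
    terms = [
        LurTerm(
            name=name,
            coefficient=float(res.params[i + 1]),
            expected_sign=matrix.specs[name].expected_sign,
            p_value=float(res.pvalues[i + 1]),
            vif=float(vifs[i]),
            incremental_r2=float(incr[i]),
            spec=matrix.specs[name].to_dict(),
        )
        for i, name in enumerate(selected)
    ]
    return LurFit(
        pollutant=pollutant, season=season, intercept=float(res.params[0]), terms=terms,
        r_squared=float(res.rsquared), adj_r_squared=_adjust_r2(float(res.rsquared), n, len(selected)),
        n_sites=n, selection_trace=trace,
    )


def _note_nested_radii(fit: LurFit, matrix: PredictorMatrix) -> None:
    by_source: dict[tuple, list[str]] = {}
    for t in fit.terms:
        spec = matrix.specs[t.name]
        if spec.buffer_radius is not None:
            by_source.setdefault((spec.source_category, spec.aggregation), []).append(t.name)
    for key, names in by_source.items():
        if len(names) > 1:
            fit.notes.append(f"nested radii co-occur for {key[0]}/{key[1]}: {sorted(names)}")
            logger.info("nested radii co-occur: %s", sorted(names))


def cooks_distance(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Definitional Cook's D from the hat matrix; 0 when the fit is exact."""
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    n, p = A.shape
    H = A @ np.linalg.pinv(A.T @ A) @ A.T
    h = np.diag(H)
    resid = y - H @ y
    dof = n - p
    if dof <= 0:
        return np.zeros(n)
    s2 = float(resid @ resid) / dof
    if s2 <= 1e-300:
        return np.zeros(n)
    return resid**2 * h / (p * s2 * (1 - h) ** 2)


def prune_diagnostics(
    fit: LurFit,
    matrix: PredictorMatrix,
    response: np.ndarray | pd.Series,
    vif_max: float = VIF_MAX,
    p_max: float = P_MAX,
    cooks_max: float = COOKS_D_MAX,
) -> LurFit:
    """Iterative diagnostic pruning: VIF first, then p-values, then signs.

    Terms are dropped one at a time (highest VIF, then highest p, then any
    term whose refitted sign contradicts its expectation) with a refit after
    every drop.  Cook's D is computed on the final model; sites at or above
    the threshold are flagged, never removed.
    """
    y = np.asarray(response, dtype=float)
    selected = list(fit.term_names)

    def refit(names: list[str]) -> LurFit:
        return _finalize_fit(y, matrix, names, fit.pollutant, fit.season, fit.selection_trace)

    current = refit(selected) if selected else fit
    # 1) collinearity
    while len(current.terms) >= 2:
        vifs = np.array([t.vif for t in current.terms])
        if np.nanmax(vifs) < vif_max:
            break
        drop = current.terms[int(np.argmax(vifs))].name
        selected.remove(drop)
        current = refit(selected)
        current.notes.append(f"dropped {drop}: VIF >= {vif_max}")
    # 2) significance
    while current.terms:
        ps = np.array([t.p_value for t in current.terms])
        if np.nanmax(ps) < p_max:
            break
        drop = current.terms[int(np.argmax(ps))].name
        selected.remove(drop)
        current = refit(selected)
        current.notes.append(f"dropped {drop}: p >= {p_max}")
    # 3) signs can flip after pruning; enforce the direction constraint
    while current.terms:
        bad = [t for t in current.terms if t.coefficient * (1 if t.expected_sign == "+" else -1) <= 0]
        if not bad:
            break
        drop = max(bad, key=lambda t: t.p_value).name
        selected.remove(drop)
        current = refit(selected)
        current.notes.append(f"dropped {drop}: sign flipped after pruning")
    if not current.terms and fit.terms:
        logger.info("diagnostic pruning removed every term; returning intercept-only fit")
        current.notes.append("pruning emptied the model; intercept-only fit returned")

    X = matrix.values_for(current.term_names) if current.terms else np.empty((len(y), 0))
    d = cooks_distance(y, X)
    current.max_cooks_d = float(np.max(d)) if len(d) else 0.0
    site_ids = list(matrix.frame.index)
    current.influential_sites = [site_ids[i] for i in np.nonzero(d >= cooks_max)[0]]
    if current.influential_sites:
        logger.warning("sites flagged with Cook's D >= %s: %s", cooks_max, current.influential_sites)
    return current


def fit_lur(
    response: np.ndarray | pd.Series,
    matrix: PredictorMatrix,
    pollutant: str = "",
    season: str = "",
    min_gain: float = MIN_GAIN,
    screen_fraction: float = SCREEN_FRACTION,
    vif_max: float = VIF_MAX,
    p_max: float = P_MAX,
    use_adjusted_r2: bool = False,
) -> LurFit:
    """Screen, select, and prune in one call."""
    candidates = screen_candidates(matrix, screen_fraction)
    fit = forward_select(
        response, matrix, candidates, pollutant=pollutant, season=season,
        min_gain=min_gain, use_adjusted_r2=use_adjusted_r2,
    )
    return prune_diagnostics(fit, matrix, response, vif_max=vif_max, p_max=p_max)
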