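"""Confidence-parameter (theta) selection by interleaved cross-validation.

The procedure: split frames into interleaved training/validation halves,
fit the reweighting on the training half over a descending theta grid
(warm-started), transfer the dual parameters to the validation half, and
track fit quality and Wasserstein distribution distances per theta.  The
selected theta* is where the validation chi-square is minimal (default
rule) or where the train/validation distance curve has maximum curvature
(advisory elbow rule); after selection the full ensemble is re-fit at
theta*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, wasserstein_distance

from .ensemble import (
    ObservableMatrix,
    TargetSet,
    WeightVector,
    uniform_weights,
)
from .errors import ValidationError
from .solver import (
    ReweightSolution,
    SolverSettings,
    apply_lambdas,
    chi2_red,
    lambda_rms,
    solve_bme,
)

__all__ = [
    "SplitIndices",
    "ThetaScanRecord",
    "ThetaScanResult",
    "ThetaSelection",
    "split_interleaved",
    "wasserstein_weighted",
    "mean_distribution_distance",
    "theta_scan",
    "select_theta",
    "runs_test",
    "refit_full_ensemble",
    "lag1_autocorrelation",
    "default_theta_grid",
]


@dataclass
class SplitIndices:
    """Train/validation frame positions (1-based, as in the file order)."""

    train: np.ndarray
    validation: np.ndarray

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=int)
        self.validation = np.asarray(self.validation, dtype=int)
        if set(self.train) & set(self.validation):
            raise ValidationError("train and validation sets must be disjoint")
        if abs(len(self.train) - len(self.validation)) > 1:
            raise ValidationError("train and validation sizes may differ by at most 1")

    @property
    def train0(self) -> np.ndarray:
        """0-based row indices of the training frames."""
        return self.train - 1

    @property
    def validation0(self) -> np.ndarray:
        return self.validation - 1


def split_interleaved(n_frames: int) -> SplitIndices:
    """Odd frame positions (1-based) go to training, even to validation."""
    if n_frames < 4:
        raise ValidationError("need at least 4 frames to split")
    pos = np.arange(1, n_frames + 1)
    return SplitIndices(train=pos[0::2], validation=pos[1::2])


@dataclass
class ThetaScanRecord:
    theta: float
    chi2_t: float
    chi2_v: float
    neff_t: float
    lambda_rms: float
    d_tv: float
    converged: bool
    d_tg: Optional[float] = None
    d_vg: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "theta": self.theta,
            "chi2_t": self.chi2_t,
            "chi2_v": self.chi2_v,
            "neff_t": self.neff_t,
            "lambda_rms": self.lambda_rms,
            "d_tv": self.d_tv,
            "converged": self.converged,
        }
        if self.d_tg is not None:
            d["d_tg"] = self.d_tg
            d["d_vg"] = self.d_vg
        return d


@dataclass
class ThetaScanResult:
    records: list[ThetaScanRecord]
    split: SplitIndices
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        thetas = [r.theta for r in self.records]
        if any(b >= a for a, b in zip(thetas, thetas[1:])):
            raise ValidationError("scan records must be ordered by strictly decreasing theta")

    @property
    def benchmark_mode(self) -> bool:
        return bool(self.records) and self.records[0].d_tg is not None

    def converged_records(self) -> list[ThetaScanRecord]:
        return [r for r in self.records if r.converged]

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "records": [r.to_dict() for r in self.records],
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def to_tsv(self, path: str) -> None:
        cols = ["theta", "chi2_t", "chi2_v", "neff_t", "lambda_rms", "d_tv"]
        if self.benchmark_mode:
            cols += ["d_tg", "d_vg"]
        cols += ["converged"]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in self.records:
                d = r.to_dict()
                fh.write(
                    "\t".join(
                        str(int(d[c])) if c == "converged" else "%.17g" % d[c]
                        for c in cols
                    )
                    + "\n"
                )


@dataclass
class ThetaSelection:
    theta_star: float
    rule: str
    diagnostics: str = ""

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"theta_star": self.theta_star, "rule": self.rule, "diagnostics": self.diagnostics},
                fh,
                indent=2,
            )
            fh.write("\n")


def default_theta_grid(
    hi: float = 1e2, lo: float = 1e-3, n_points: int = 30
) -> np.ndarray:
    """Descending log-spaced theta grid (default 30 points, 1e2 -> 1e-3)."""
    if not (hi > lo > 0) or n_points < 2:
        raise ValidationError("grid must satisfy hi > lo > 0 and n_points >= 2")
    return np.logspace(np.log10(hi), np.log10(lo), n_points)


def wasserstein_weighted(
    values_a: np.ndarray,
    w_a: WeightVector,
    values_b: np.ndarray,
    w_b: WeightVector,
) -> float:
    """First-order Wasserstein distance between two weighted empirical
    distributions (area between their CDFs over the merged support)."""
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if values_a.size == 0 or values_b.size == 0:
        raise ValidationError("value vectors must be nonempty")
    if values_a.shape != (len(w_a),) or values_b.shape != (len(w_b),):
        raise ValidationError("values and weights must have equal length")
    ka = w_a.weights > 0
    kb = w_b.weights > 0
    return float(
        wasserstein_distance(
            values_a[ka], values_b[kb], w_a.weights[ka], w_b.weights[kb]
        )
    )


def mean_distribution_distance(
    matrix_a: ObservableMatrix,
    w_a: WeightVector,
    matrix_b: ObservableMatrix,
    w_b: WeightVector,
) -> float:
    """Mean over observables of the column-wise weighted Wasserstein distance."""
    if matrix_a.tags != matrix_b.tags:
        raise ValidationError("matrices must share observable tags and order")
    dists = [
        wasserstein_weighted(matrix_a.values[:, j], w_a, matrix_b.values[:, j], w_b)
        for j in range(matrix_a.n_observables)
    ]
    return float(np.mean(dists))


def theta_scan(
    matrix: ObservableMatrix,
    targets: TargetSet,
    theta_grid: Sequence[float] | np.ndarray | None = None,
    w0: WeightVector | None = None,
    settings: SolverSettings | None = None,
    target_matrix: ObservableMatrix | None = None,
    target_weights: WeightVector | None = None,
) -> ThetaScanResult:
    """Scan a descending theta grid with the interleaved split.

    For each theta the training half is fit (warm-started from the previous
    theta), the dual parameters are transferred to the validation half, and
    fit statistics plus distribution distances are recorded.  When a target
    ensemble is supplied (benchmark mode) the distances of train and
    validation to the target distribution are recorded as well.
    """
    grid = np.asarray(
        default_theta_grid() if theta_grid is None else theta_grid, dtype=float
    )
    if np.any(grid <= 0):
        raise ValidationError("theta grid must be strictly positive")
    grid = np.sort(grid)[::-1]
    if np.any(np.diff(grid) == 0):
        raise ValidationError("theta grid must not contain duplicates")

    if (target_matrix is None) != (target_weights is None):
        raise ValidationError("target_matrix and target_weights must be given together")
    if target_matrix is not None and target_matrix.tags != matrix.tags:
        raise ValidationError("target ensemble must share observable tags")

    split = split_interleaved(matrix.n_frames)
    train_m = matrix.take_frames(split.train0)
    val_m = matrix.take_frames(split.validation0)
    if w0 is not None and len(w0) != matrix.n_frames:
        raise ValidationError("prior weight length does not match frame count")
    # uniform priors on each half (a nonuniform global prior is restricted
    # and renormalized per half)
    if w0 is None:
        w0t = uniform_weights(train_m.n_frames, "train prior")
        w0v = uniform_weights(val_m.n_frames, "validation prior")
    else:
        wt = w0.weights[split.train0]
        wv = w0.weights[split.validation0]
        w0t = WeightVector(wt / wt.sum(), "train prior")
        w0v = WeightVector(wv / wv.sum(), "validation prior")

    base = settings or SolverSettings()
    lam = np.zeros(matrix.n_observables)
    records: list[ThetaScanRecord] = []
    for theta in grid:
        fit_settings = SolverSettings(
            grad_tol=base.grad_tol,
            max_iter=base.max_iter,
            lambda_init=lam.copy(),
            warm_start=True,
        )
        sol = solve_bme(train_m, targets, theta, w0t, fit_settings)
        if sol.converged:
            lam = sol.lambdas
        wv_re = apply_lambdas(val_m, sol.lambdas, w0v)
        rec = ThetaScanRecord(
            theta=float(theta),
            chi2_t=sol.chi2_red,
            chi2_v=chi2_red(val_m, wv_re, targets),
            neff_t=sol.n_eff,
            lambda_rms=lambda_rms(sol.lambdas),
            d_tv=mean_distribution_distance(train_m, sol.weights, val_m, wv_re),
            converged=sol.converged,
        )
        if target_matrix is not None:
            rec.d_tg = mean_distribution_distance(
                train_m, sol.weights, target_matrix, target_weights
            )
            rec.d_vg = mean_distribution_distance(
                val_m, wv_re, target_matrix, target_weights
            )
        records.append(rec)
    return ThetaScanResult(
        records=records,
        split=split,
        metadata={
            "theta_grid": [float(t) for t in grid],
            "n_frames": matrix.n_frames,
            "n_observables": matrix.n_observables,
            "benchmark_mode": target_matrix is not None,
        },
    )


def _elbow_theta(thetas: np.ndarray, d_tv: np.ndarray) -> float:
    """Theta of maximum discrete second difference of d_tv versus ln(theta)."""
    x = np.log(thetas)
    curv = np.empty(len(x) - 2)
    for i in range(1, len(x) - 1):
        h1 = x[i] - x[i - 1]
        h2 = x[i + 1] - x[i]
        # nonuniform central second difference
        curv[i - 1] = 2 * (
            d_tv[i - 1] / (h1 * (h1 + h2))
            - d_tv[i] / (h1 * h2)
            + d_tv[i + 1] / (h2 * (h1 + h2))
        )
    return float(thetas[1 + int(np.argmax(curv))])


def select_theta(scan: ThetaScanResult, rule: str = "min_chi2_v") -> ThetaSelection:
    """Select theta* from a scan.

    ``min_chi2_v``: the largest grid theta attaining the minimal validation
    chi-square (ties break toward least reweighting).  ``d_tv_elbow``: the
    theta of maximum discrete second difference of d_tv against ln(theta).
    """
    if rule not in ("min_chi2_v", "d_tv_elbow"):
        raise ValidationError(f"unknown selection rule {rule!r}")
    recs = scan.converged_records()
    if len(recs) < 3:
        raise ValidationError("need at least 3 converged scan points to select theta")
    thetas = np.array([r.theta for r in recs])
    chi2_v = np.array([r.chi2_v for r in recs])
    d_tv = np.array([r.d_tv for r in recs])

    # records are descending in theta, so argmin returns the largest theta on ties
    i_min = int(np.argmin(chi2_v))
    theta_chi = float(thetas[i_min])
    theta_elbow = _elbow_theta(thetas, d_tv)

    notes = [f"min_chi2_v at theta={theta_chi:g}", f"d_tv_elbow at theta={theta_elbow:g}"]
    if i_min == len(recs) - 1:
        notes.append("no overfitting detected in grid (chi2_v minimal at smallest theta)")
    theta_star = theta_chi if rule == "min_chi2_v" else theta_elbow
    return ThetaSelection(theta_star=theta_star, rule=rule, diagnostics="; ".join(notes))


def runs_test(residuals: np.ndarray) -> tuple[int, float, float]:
    """Wald-Wolfowitz runs test on the signs of ordered residuals.

    Zeros are dropped.  Returns (number of runs, normal-approximation z,
    two-sided p).  A one-signed sequence is degenerate (zero variance); it
    is reported as a single run with z=0, p=1.
    """
    residuals = np.asarray(residuals, dtype=float)
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n = len(signs)
    if n < 2:
        raise ValidationError("need at least 2 nonzero residuals for the runs test")
    n_pos = int(np.sum(signs > 0))
    n_neg = n - n_pos
    n_runs = int(1 + np.sum(signs[1:] != signs[:-1]))
    if n_pos == 0 or n_neg == 0:
        return n_runs, 0.0, 1.0
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    z = (n_runs - mu) / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return n_runs, float(z), min(p, 1.0)


def refit_full_ensemble(
    matrix: ObservableMatrix,
    targets: TargetSet,
    theta_star: float,
    settings: SolverSettings | None = None,
) -> ReweightSolution:
    """Re-fit all frames with uniform prior at the selected theta."""
    return solve_bme(
        matrix, targets, theta_star, uniform_weights(matrix.n_frames), settings
    )


def lag1_autocorrelation(matrix: ObservableMatrix) -> np.ndarray:
    """Per-observable lag-1 frame autocorrelation (diagnostic for the
    interleaved split's same-distribution premise)."""
    v = matrix.values
    if v.shape[0] < 3:
        raise ValidationError("need at least 3 frames for a lag-1 autocorrelation")
    x = v - v.mean(axis=0)
    denom = np.sum(x * x, axis=0)
    num = np.sum(x[1:] * x[:-1], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    return r
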