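"""Least-squares estimation of the ribosome recycle number from competition curves.

The competition assay yields matched pairs (N, n): extra peptides per active
ribosome made without (N) and with (n) a sequestering competitor mRNA at the
same time point.  The model predicts

    n(N) = ((1-P)/P) * (1 - exp(-P*N))

with a single free parameter, the per-step mRNA release probability P; the
rate k cancels in (N, n) space and is not fitted.  The recycle number
n_rec = (1-P)/P is reported as a deterministic transform of the estimate,
never fitted independently.  Uncertainty comes from a case-resampling
bootstrap over the (N, n) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .kinetics import n_of_N, p_of_recycle_number, recycle_number

__all__ = [
    "CompetitionCurve",
    "FitResult",
    "BootstrapCI",
    "fit_competition",
    "bootstrap_ci",
]

log = logging.getLogger(__name__)

P_BOUNDS = (1e-6, 1.0)


@dataclass(frozen=True)
class CompetitionCurve:
    """Matched (N, n) pairs of a competition experiment, sorted by N.

    ``plateau`` flags pairs where the simulated/measured series had exhausted
    the fMet pool; they are retained here but excluded from fitting by
    default.
    """

    N: np.ndarray
    n: np.ndarray
    plateau: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        N = np.asarray(self.N, dtype=float)
        n = np.asarray(self.n, dtype=float)
        if N.shape != n.shape or N.ndim != 1:
            raise ValueError("N and n must be 1-D arrays of equal length")
        if np.any(N < 0):
            raise ValueError("N values must be nonnegative")
        plateau = (
            np.zeros(N.size, dtype=bool)
            if self.plateau is None
            else np.asarray(self.plateau, dtype=bool)
        )
        if plateau.shape != N.shape:
            raise ValueError("plateau flags must match the number of pairs")
        order = np.argsort(N, kind="stable")
        object.__setattr__(self, "N", N[order])
        object.__setattr__(self, "n", n[order])
        object.__setattr__(self, "plateau", plateau[order])

    @property
    def pairs(self) -> list[tuple[float, float]]:
        return list(zip(self.N.tolist(), self.n.tolist()))

    def __len__(self) -> int:
        return int(self.N.size)


@dataclass(frozen=True)
class FitResult:
    """Point estimate of the release probability and derived recycle number."""

    P_hat: float
    n_rec_hat: float
    residual_ss: float
    n_points: int
    n_dropped_plateau: int
    converged: bool
    diagnostic: str = ""
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0

    def to_dict(self) -> dict:
        return {
            "P_hat": self.P_hat,
            "n_rec_hat": self.n_rec_hat,
            "residual_ss": self.residual_ss,
            "n_points": self.n_points,
            "n_dropped_plateau": self.n_dropped_plateau,
            "converged": self.converged,
            "diagnostic": self.diagnostic,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
        }


def _usable_pairs(
    curve: CompetitionCurve, drop_plateau: bool
) -> tuple[np.ndarray, np.ndarray, int]:
    keep = ~curve.plateau if drop_plateau else np.ones(len(curve), dtype=bool)
    dropped = int(len(curve) - keep.sum())
    if dropped:
        log.info("excluding %d fMet-plateau pair(s) from fit", dropped)
    return curve.N[keep], curve.n[keep], dropped


def _sse(P: float, N: np.ndarray, n: np.ndarray, w: np.ndarray) -> float:
    r = n - n_of_N(P, N)
    return float(np.dot(w * r, r))


def _minimize_sse(N: np.ndarray, n: np.ndarray, w: np.ndarray, P0: float) -> float:
    """Global-ish 1-D minimization: coarse log grid, then bounded refinement."""
    lo, hi = P_BOUNDS
    grid = np.geomspace(lo, hi, 80)
    if lo < P0 < hi:
        grid = np.sort(np.append(grid, P0))
    resid = n[None, :] - n_of_N(grid[:, None], N[None, :])
    sse = np.einsum("ij,ij->i", resid * w[None, :], resid)
    i = int(np.argmin(sse))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]
    if a == b:
        return float(grid[i])
    res = minimize_scalar(
        _sse, bounds=(a, b), args=(N, n, w), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x) if res.fun <= sse[i] else float(grid[i])


def fit_competition(
    curve: CompetitionCurve,
    weighted: bool = False,
    drop_plateau: bool = True,
) -> FitResult:
    """Fit the release probability P to a competition curve by least squares.

    Minimizes sum_i w_i (n_i - n(N_i; P))^2 over P in [1e-6, 1].  Weights are
    uniform by default; ``weighted=True`` uses inverse-variance weights
    1/max(n, 1)^2 appropriate for constant-CV multiplicative noise.  Pairs
    flagged as fMet-plateau are excluded (with a logged count) unless
    ``drop_plateau`` is False.  Points with n > N (possible under noise) are
    retained unclipped.
    """
    N, n, dropped = _usable_pairs(curve, drop_plateau)
    if N.size < 3:
        raise ValueError(f"need at least 3 usable (N, n) pairs, have {N.size}")
    if not np.any(N > 0):
        raise ValueError("need at least one pair with N > 0")

    if np.all(n[N > 0] <= 0):
        # no peptide beyond the first under competition: release is certain
        return FitResult(
            P_hat=1.0, n_rec_hat=0.0,
            residual_ss=_sse(1.0, N, n, np.ones_like(N)),
            n_points=int(N.size), n_dropped_plateau=dropped, converged=True,
            diagnostic="all n = 0 with positive N: P_hat pinned to 1 (n_rec = 0)",
        )

    w = 1.0 / np.maximum(n, 1.0) ** 2 if weighted else np.ones_like(N)
    P0 = float(np.clip(p_of_recycle_number(max(float(n.max()), 0.0)), *P_BOUNDS))
    P_hat = _minimize_sse(N, n, w, P0)

    lo, hi = P_BOUNDS
    converged, diag = True, ""
    if P_hat <= 2 * lo:
        converged = False
        diag = "P at lower bound: curve indistinguishable from n = N, n_rec effectively infinite"
    elif P_hat >= hi * (1 - 1e-12):
        P_hat = hi
        converged = False
        diag = "P at upper bound"
    return FitResult(
        P_hat=P_hat,
        n_rec_hat=float(recycle_number(P_hat)),
        residual_ss=_sse(P_hat, N, n, w),
        n_points=int(N.size),
        n_dropped_plateau=dropped,
        converged=converged,
        diagnostic=diag,
    )


@dataclass(frozen=True)
class BootstrapCI:
    ci_low: float
    ci_high: float
    n_rec_hat: float
    n_boot: int
    n_skipped: int


def bootstrap_ci(
    curve: CompetitionCurve,
    n_boot: int = 1000,
    seed: int = 0,
    weighted: bool = False,
    drop_plateau: bool = True,
    level: float = 0.95,
) -> BootstrapCI:
    """Percentile bootstrap interval on n_rec by case-resampling (N, n) pairs.

    Resamples with fewer than 3 distinct pairs (or no positive N) cannot be
    fitted; they are skipped and counted.  The interval is widened, if
    necessary, to contain the full-data point estimate.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    point = fit_competition(curve, weighted=weighted, drop_plateau=drop_plateau)
    N, n, _ = _usable_pairs(curve, drop_plateau)
    rng = np.random.default_rng(seed)
    reps, skipped = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, N.size, size=N.size)
        if np.unique(idx).size < 3 or not np.any(N[idx] > 0):
            skipped += 1
            continue
        sub = CompetitionCurve(N=N[idx], n=n[idx])
        try:
            reps.append(fit_competition(sub, weighted=weighted, drop_plateau=False).n_rec_hat)
        except ValueError:
            skipped += 1
    if not reps:
        raise ValueError("all bootstrap resamples were degenerate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(reps, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(
        ci_low=float(min(lo, point.n_rec_hat)),
        ci_high=float(max(hi, point.n_rec_hat)),
        n_rec_hat=point.n_rec_hat,
        n_boot=n_boot,
        n_skipped=skipped,
    )


def fit_with_ci(
    curve: CompetitionCurve,
    n_boot: int = 0,
    seed: int = 0,
    weighted: bool = False,
    drop_plateau: bool = True,
) -> FitResult:
    """Convenience: point fit, optionally augmented with a bootstrap CI."""
    fit = fit_competition(curve, weighted=weighted, drop_plateau=drop_plateau)
    if n_boot:
        ci = bootstrap_ci(
            curve, n_boot=n_boot, seed=seed, weighted=weighted, drop_plateau=drop_plateau
        )
        fit = FitResult(
            **{**fit.to_dict(), "ci_low": ci.ci_low, "ci_high": ci.ci_high, "n_boot": n_boot}
        )
    return fit
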