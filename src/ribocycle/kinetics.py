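"""Closed-form kinetics of reiterative minigene translation.

A ribosome initiating on a short mRNA (a bacterial minigene such as *mccA*)
makes a first peptide with probability 1 and may then reinitiate on the same
message without dissociating.  At each recycling step the mRNA is released
with probability ``P``; peptide-bond formation proceeds at rate ``k``
peptides per minute per mRNA-bound ribosome.  Without a competing mRNA a
released ribosome immediately reinitiates on another minigene copy, so the
expected yield per active ribosome grows linearly::

    y(t) = 1 + k*t = 1 + N

With a sequestering competitor mRNA present, a released ribosome is lost
irreversibly, giving the saturating form::

    y_c(t) = 1 + ((1-P)/P) * (1 - exp(-P*k*t)) = 1 + n

Eliminating time yields the competition curve ``n(N)`` whose asymptote is the
ribosome recycle number ``n_rec = (1-P)/P`` — the expected number of extra
peptides made before the mRNA is released.  These expressions are the model
fitted to competition-assay data by :mod:`ribocycle.fitting`.

All functions accept scalars or NumPy arrays and are evaluated with
``expm1``-based exponentials so they stay accurate for the small release
probabilities (P ~ 0.01) typical of efficiently recycled heptapeptide
templates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RecyclingParams",
    "peptides_no_competition",
    "peptides_with_competition",
    "n_of_N",
    "n_of_cycles_discrete",
    "recycle_number",
    "p_of_recycle_number",
]

#: smallest release probability treated as distinguishable from "never leaves"
_P_FLOOR = np.finfo(float).tiny


@dataclass(frozen=True)
class RecyclingParams:
    """Kinetic parameters of the reiterative-translation model.

    Parameters
    ----------
    P:
        Probability that the mRNA is released from the ribosome at any single
        recycling step; dimensionless, in (0, 1].
    k:
        Peptide-formation rate per mRNA-bound ribosome, peptides/minute; > 0.
    """

    P: float
    k: float

    def __post_init__(self) -> None:
        if not (0.0 < self.P <= 1.0):
            raise ValueError(f"release probability P must be in (0, 1], got {self.P}")
        if not self.k > 0.0:
            raise ValueError(f"peptide-formation rate k must be > 0, got {self.k}")

    @property
    def n_rec(self) -> float:
        """Recycle number (1-P)/P implied by these parameters."""
        return recycle_number(self.P)


def _check_P(P) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if np.any(P <= 0.0) or np.any(P > 1.0):
        raise ValueError("release probability P must be in (0, 1]")
    return np.maximum(P, _P_FLOOR)


def _check_nonneg(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0):
        raise ValueError(f"{name} must be nonnegative")
    return x


def peptides_no_competition(params: RecyclingParams, t) -> np.ndarray | float:
    """Expected peptides per active ribosome without competitor, y(t) = 1 + k*t.

    Reinitiation on free minigene mRNA is lossless and instantaneous, so the
    release probability does not enter; yield grows linearly from y(0) = 1
    (the first peptide is made with probability 1).
    """
    t = _check_nonneg(t, "time t")
    y = 1.0 + params.k * t
    return y if y.ndim else float(y)


def peptides_with_competition(params: RecyclingParams, t) -> np.ndarray | float:
    """Expected peptides per ribosome with a sequestering competitor.

    y_c(t) = 1 + ((1-P)/P) * (1 - exp(-P*k*t)); monotone in t, approaching
    the plateau 1 + (1-P)/P = 1 + n_rec as t -> infinity.
    """
    t = _check_nonneg(t, "time t")
    P = _check_P(params.P)
    y = 1.0 + (1.0 - P) / P * -np.expm1(-P * params.k * t)
    return y if y.ndim else float(y)


def n_of_N(P, N) -> np.ndarray | float:
    """Competition curve n(N) = ((1-P)/P) * (1 - exp(-P*N)).

    ``N = k*t`` is the extra yield without competition and ``n`` the extra
    yield with competition at the same time point; time cancels, so the curve
    depends on P alone.  For small P and N, n ~ (1-P)*N ~ N.
    """
    P = _check_P(P)
    N = _check_nonneg(N, "N")
    n = (1.0 - P) / P * -np.expm1(-P * N)
    return n if n.ndim else float(n)


def n_of_cycles_discrete(P, cycles) -> np.ndarray | float:
    """Discrete-step expectation of extra peptides after ``cycles`` recycling steps.

    The per-step derivation gives E[n] = sum_{j=1..m} (1-P)^j
    = ((1-P)/P) * (1 - (1-P)^m) for m completed cycles; :func:`n_of_N` is its
    continuous (large-m, small-P) limit with N = m.  Used to cross-check the
    stochastic simulator against theory.
    """
    P = _check_P(P)
    m = np.asarray(cycles, dtype=float)
    if np.any(m < 0):
        raise ValueError("cycle count must be nonnegative")
    n = (1.0 - P) / P * -np.expm1(m * np.log1p(-np.minimum(P, np.nextafter(1.0, 0.0))))
    # exact 0 when P == 1: no survival past the first peptide
    n = np.where(P >= 1.0, 0.0, n)
    return n if n.ndim else float(n)


def recycle_number(P) -> np.ndarray | float:
    """Recycle number n_rec = (1-P)/P, the expected reinitiations before release.

    n_rec = 0 means the ribosome dissociates after the first peptide (P = 1).
    P = 0 is rejected: the ribosome never leaves the mRNA and the competition
    curve degenerates to the n = N line (n_rec infinite).
    """
    P = np.asarray(P, dtype=float)
    if np.any(P <= 0.0):
        raise ValueError(
            "P = 0 means the ribosome never dissociates (n_rec infinite); "
            "treat this case as the n = N line"
        )
    if np.any(P > 1.0):
        raise ValueError("release probability P must be in (0, 1]")
    r = (1.0 - P) / P
    return r if r.ndim else float(r)


def p_of_recycle_number(n_rec) -> np.ndarray | float:
    """Inverse transform P = 1/(1 + n_rec)."""
    n_rec = np.asarray(n_rec, dtype=float)
    if np.any(n_rec < 0.0):
        raise ValueError("recycle number must be nonnegative")
    P = 1.0 / (1.0 + n_rec)
    return P if P.ndim else float(P)
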