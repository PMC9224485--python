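"""The surface-adsorption retention law a(Y; k) and estimation of k.

Retention of diffusing nanoparticles on barrier surfaces is described by a
Langmuir-type saturation law in the surface parameter Y: the adsorbed
fraction is kY/(1+kY), so the fraction of diffusive transport that
survives — the retardation coefficient — is

    a(Y; k) = 1 - kY/(1+kY) = 1/(1+kY).

A single dimensionless constant k per wettability class captures the
affinity of particles for the surface.  k can be read off one (Y, a)
observation, but is estimated more robustly by pooled nonlinear least
squares over a set of observations, which is what
:func:`fit_model_constant` does.

The objective sum((a_i - 1/(1+k Y_i))^2) is unimodal in k >= 0 for
observations with a in (0, 1], so a single bounded descent suffices; the
test suite guards this with an exhaustive grid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RetentionObservation",
    "AdsorptionFitResult",
    "retention_fraction",
    "invert_retention",
    "model_constant_from_single",
    "fit_model_constant",
]


@dataclass(frozen=True)
class RetentionObservation:
    """One measured (surface parameter, retardation) pair.

    ``a`` may exceed 1 in noisy data (flagged downstream, never truncated);
    it must be strictly positive.  ``group`` records the wettability class
    the observation belongs to (``hydrophilic`` / ``hydrophobic`` /
    ``mixed``).
    """

    Y: float
    a: float
    group: str = "hydrophilic"
    particle_label: str = ""

    def __post_init__(self) -> None:
        if self.Y < 0:
            raise ValueError(f"Y must be non-negative, got {self.Y!r}")
        if not self.a > 0:
            raise ValueError(f"a must be strictly positive, got {self.a!r}")


@dataclass(frozen=True)
class AdsorptionFitResult:
    """Fitted model constant with residual diagnostics.

    Attributes
    ----------
    k : float
        Fitted model constant, >= 0.
    rss : float
        Residual sum of squares in a-space.
    n_obs : int
        Number of observations used.
    residuals : tuple of float
        Per-observation a_obs - a_pred, in input order.
    flagged : tuple of int
        Indices of observations with a > 1 (kept in the fit).
    note : str
        Free-text remark on degenerate fits (e.g. all a = 1 => k = 0).
    """

    k: float
    rss: float
    n_obs: int
    residuals: tuple[float, ...] = ()
    flagged: tuple[int, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"k must be non-negative, got {self.k!r}")
        if self.rss < 0:
            raise ValueError(f"rss must be non-negative, got {self.rss!r}")

    def to_dict(self) -> dict:
        """JSON-ready summary {k, rss, n_obs}."""
        return {"k": self.k, "rss": self.rss, "n_obs": self.n_obs}


def retention_fraction(Y, k):
    """Surviving fraction of diffusive transport, a = 1/(1 + k*Y).

    Accepts scalars or numpy arrays; both arguments must be non-negative.
    a(0, k) = a(Y, 0) = 1 (no surface or no affinity means no retention),
    and a decreases strictly in both arguments.
    """
    Y = np.asarray(Y, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(Y < 0):
        raise ValueError("Y must be non-negative")
    if np.any(k < 0):
        raise ValueError("k must be non-negative")
    out = 1.0 / (1.0 + k * Y)
    return out.item() if out.ndim == 0 else out


def invert_retention(a: float, k: float) -> float:
    """Surface parameter producing retardation ``a`` at constant ``k``:
    Y = (1/a - 1)/k.  Exact inverse of :func:`retention_fraction`."""
    if not (0 < a <= 1):
        raise ValueError(f"a must lie in (0, 1], got {a!r}")
    if not k > 0:
        raise ValueError(f"k must be strictly positive, got {k!r}")
    return (1.0 / a - 1.0) / k


def model_constant_from_single(a: float, Y: float) -> float:
    """Model constant from a single observation: k = (1/a - 1)/Y.

    A quick route when only one measurement through a barrier of known Y
    is available; pooled fitting over several observations is preferred.
    """
    if not (0 < a <= 1):
        raise ValueError(f"a must lie in (0, 1], got {a!r}")
    if Y == 0:
        if a < 1:
            raise ValueError(
                "inconsistent observation: a < 1 requires surface (Y > 0)"
            )
        return 0.0
    if Y < 0:
        raise ValueError(f"Y must be non-negative, got {Y!r}")
    return (1.0 / a - 1.0) / Y


def fit_model_constant(
    observations: list[RetentionObservation],
) -> AdsorptionFitResult:
    """Estimate k by unweighted nonlinear least squares in a-space.

    Minimizes sum((a_obs - 1/(1 + k*Y_obs))^2) over k >= 0 with a
    trust-region bounded solver, initialized at the median of the
    single-point estimates (1/a - 1)/Y.  Observations with a > 1
    (possible under measurement noise) are retained but their indices
    are reported in ``flagged``.
    """
    if len(observations) == 0:
        raise ValueError("need at least one observation to fit k")
    Y = np.array([o.Y for o in observations], dtype=float)
    a = np.array([o.a for o in observations], dtype=float)
    flagged = tuple(int(i) for i in np.nonzero(a > 1)[0])

    if np.all(a >= 1):
        residuals = a - 1.0
        return AdsorptionFitResult(
            k=0.0,
            rss=float(np.sum(residuals**2)),
            n_obs=len(observations),
            residuals=tuple(residuals),
            flagged=flagged,
            note="no retention observed (all a >= 1); k = 0",
        )

    # Median single-point estimate over informative points as the start.
    informative = (Y > 0) & (a < 1)
    k0 = float(np.median((1.0 / a[informative] - 1.0) / Y[informative]))

    sol = least_squares(
        lambda k: 1.0 / (1.0 + k[0] * Y) - a,
        x0=[max(k0, 1e-12)],
        bounds=([0.0], [np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=200,
    )
    k_hat = float(sol.x[0])
    residuals = a - 1.0 / (1.0 + k_hat * Y)
    return AdsorptionFitResult(
        k=k_hat,
        rss=float(np.sum(residuals**2)),
        n_obs=len(observations),
        residuals=tuple(residuals),
        flagged=flagged,
    )
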