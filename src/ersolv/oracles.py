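"""Independent brute-force free-energy estimators.

These estimators provide ground truth on toy systems for validating the
energy-representation functional: Widom test-particle insertion, Bennett's
acceptance ratio (BAR), the linear-response approximation (LRA), and the
hard-core cavity estimate -RT ln p0.  Non-convergence (e.g. every insertion
overlapping) is reported as data via the ``converged`` flag, not raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .constants import R_KCAL
from .sampling import InsertionSamples

__all__ = ["OracleEstimate", "widom", "bar", "lra", "hardcore_ev"]


@dataclass
class OracleEstimate:
    method: str
    dG: float
    standard_error: float
    n_samples: int
    converged: bool = True


def _widom_dg(nu: np.ndarray, beta: float) -> float:
    """-RT ln <exp(-beta nu)> via a log-sum-exp, tolerant of huge nu."""
    return float(-(logsumexp(-beta * nu) - np.log(len(nu))) / beta)


def widom(
    insertions: Union[InsertionSamples, np.ndarray],
    temperature: Optional[float] = None,
    n_boot: int = 200,
    seed: int = 0,
) -> OracleEstimate:
    """Widom insertion estimate dG = -RT ln <exp(-beta nu)> over insertions.

    The standard error comes from a block bootstrap over frames (insertions
    from the same frame share a solvent configuration and are resampled
    together); a plain array input is treated as independent samples.
    """
    if isinstance(insertions, InsertionSamples):
        nu = insertions.totals
        frames = insertions.frame_index
        if temperature is None:
            temperature = insertions.temperature
    else:
        nu = np.asarray(insertions, dtype=float)
        frames = np.arange(len(nu))
        if temperature is None:
            raise ValueError("temperature required for raw-array input")
    if len(nu) == 0:
        raise ValueError("need at least one insertion")
    beta = 1.0 / (R_KCAL * temperature)
    arg = -beta * nu
    shift = arg.max()
    if not np.isfinite(shift) or np.all(np.isinf(nu)):
        return OracleEstimate("widom", np.inf, np.inf, len(nu), converged=False)
    w = np.exp(arg - shift)
    if w.sum() == 0.0:
        return OracleEstimate("widom", np.inf, np.inf, len(nu), converged=False)
    dg = _widom_dg(nu, beta)
    # block bootstrap over frames
    uniq = np.unique(frames)
    nf = len(uniq)
    sums = np.zeros(nf)
    counts = np.zeros(nf)
    pos = np.searchsorted(uniq, frames)
    np.add.at(sums, pos, w)
    np.add.at(counts, pos, 1.0)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, nf, size=(n_boot, nf))
    boot_mean = sums[idx].sum(axis=1) / counts[idx].sum(axis=1)
    valid = boot_mean > 0
    if valid.sum() < 2:
        return OracleEstimate("widom", dg, np.inf, len(nu), converged=False)
    boot_dg = -(np.log(boot_mean[valid]) + shift) / beta
    return OracleEstimate("widom", dg, float(np.std(boot_dg)), len(nu))


def _bar_residual(df, fwd, rev, beta, m):
    a = logsumexp(-np.logaddexp(0.0, m + beta * (fwd - df)))
    b = logsumexp(-np.logaddexp(0.0, -m + beta * (df - rev)))
    return a - b


def _bar_solve(fwd, rev, beta, m, tol):
    # infinite forward works (hard overlaps) carry zero Fermi weight; they
    # enter only through m, which the caller computed from the full counts
    fwd = fwd[np.isfinite(fwd)]
    rev = rev[np.isfinite(rev)]
    if len(fwd) == 0 or len(rev) == 0:
        return None
    lo = min(fwd.min(), rev.min()) - 100.0 / beta
    hi = max(fwd.max(), rev.max()) + 100.0 / beta
    try:
        flo = _bar_residual(lo, fwd, rev, beta, m)
        fhi = _bar_residual(hi, fwd, rev, beta, m)
        if not (np.isfinite(flo) and np.isfinite(fhi)) or flo * fhi > 0:
            return None
        return brentq(_bar_residual, lo, hi, args=(fwd, rev, beta, m), xtol=tol)
    except (ValueError, RuntimeError):
        return None


def bar(
    forward_deltas: np.ndarray,
    reverse_deltas: np.ndarray,
    temperature: float,
    tol: float = 1e-10,
    n_boot: int = 100,
    seed: int = 0,
) -> OracleEstimate:
    """Bennett acceptance ratio between the uncoupled and coupled states.

    Both inputs are energy differences U_coupled - U_uncoupled: forward
    values evaluated on reference-system insertions, reverse values on
    solution-system frames (i.e. the sampled nu in each ensemble).  The
    self-consistent Bennett equation is solved by bracketing and bisection
    to ``tol``; the standard error comes from a paired bootstrap.
    """
    fwd = np.asarray(forward_deltas, dtype=float)
    rev = np.asarray(reverse_deltas, dtype=float)
    if len(fwd) == 0 or len(rev) == 0:
        raise ValueError("both sample sets must be non-empty")
    beta = 1.0 / (R_KCAL * temperature)
    m = np.log(len(fwd) / len(rev))
    root = _bar_solve(fwd, rev, beta, m, tol)
    if root is None:
        return OracleEstimate("bar", np.nan, np.inf, len(fwd) + len(rev), converged=False)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        bf = fwd[rng.integers(0, len(fwd), len(fwd))]
        br = rev[rng.integers(0, len(rev), len(rev))]
        r = _bar_solve(bf, br, beta, m, tol)
        if r is not None:
            boots.append(r)
    se = float(np.std(boots)) if len(boots) >= 2 else np.inf
    return OracleEstimate("bar", float(root), se, len(fwd) + len(rev))


def lra(mean_solution: float, mean_insertion: float) -> float:
    """Linear-response estimate (<nu>_solution + <nu>_reference) / 2 (kcal/mol)."""
    return 0.5 * (mean_solution + mean_insertion)


def hardcore_ev(p0: float, temperature: float) -> OracleEstimate:
    """Cavity free energy -RT ln p0 from the non-overlap insertion fraction p0."""
    if p0 < 0 or p0 > 1:
        raise ValueError("p0 must lie in [0, 1]")
    if p0 == 0:
        return OracleEstimate("hardcore", np.inf, np.inf, 0, converged=False)
    return OracleEstimate(
        "hardcore", float(-R_KCAL * temperature * np.log(p0)), 0.0, 0
    )
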