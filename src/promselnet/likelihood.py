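"""Felsenstein-pruning likelihood and maximum-likelihood fits on the 3-taxon star tree.

The per-column likelihood sums over the four states of the single internal
node: P(col h,c,m) = sum_x pi_x P(x->h | zeta_h t_h) P(x->c | zeta_c t_c)
P(x->m | zeta_m t_m).  Columns containing any gap or N are dropped listwise;
the surviving columns collapse to at most 64 (h,c,m) patterns, so one
likelihood evaluation costs a handful of 4x4 operations regardless of
alignment length.

Two fits are provided:

* ``fit_neutral`` — calibrates kappa and the three branch lengths on an
  intronic reference alignment (scales fixed at 1, pi fixed to the pooled
  empirical base frequencies);
* ``fit_scales`` — with neutral parameters frozen, fits region rate scalers
  zeta on a promoter alignment, optionally clamping the human-branch scaler
  to [0, 1] (the no-acceleration null).

Both use bounded L-BFGS-B with random multistarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .alignment import TripletAlignment
from .hky import NEUTRAL_SCALES, BranchLengths, HKYParams, HKYTransition, PromoterScales

__all__ = [
    "pattern_counts",
    "empirical_base_freqs",
    "alignment_loglik",
    "NeutralFit",
    "fit_neutral",
    "fit_scales",
]

_T_MAX = 5.0
_PENALTY = 1e12  # finite stand-in for -inf log-likelihoods inside optimizers
_ZETA_MAX = 100.0
_KAPPA_BOUNDS = (0.02, 200.0)


def pattern_counts(aln: TripletAlignment) -> np.ndarray:
    """64-vector of (human, chimp, macaque) base-pattern counts.

    Index is 16*h + 4*c + m in ACGT coding; columns with any gap or N are
    dropped listwise.
    """
    codes = aln.codes()
    clean = (codes < 4).all(axis=0)
    h, c, m = codes[:, clean].astype(np.int64)
    return np.bincount(16 * h + 4 * c + m, minlength=64).astype(float)


def empirical_base_freqs(aln: TripletAlignment) -> np.ndarray:
    """Base frequencies pooled across the three rows (gaps/N excluded)."""
    codes = aln.codes()
    counts = np.bincount(codes[codes < 4], minlength=4).astype(float)
    if counts.sum() == 0:
        raise ValueError("alignment has no unambiguous bases")
    # guard against zero frequencies on tiny alignments (keeps pi in (0,1))
    counts += 0.5
    return counts / counts.sum()


def _loglik_patterns(
    counts: np.ndarray,
    trans: HKYTransition,
    bl: BranchLengths,
    scales: PromoterScales,
) -> float:
    pi = trans.params.pi_array
    Ph = trans.probability(scales.zeta_h * bl.t_h)
    Pc = trans.probability(scales.zeta_c * bl.t_c)
    Pm = trans.probability(scales.zeta_m * bl.t_m)
    # site probability for every (h, c, m) pattern
    site = np.einsum("x,xh,xc,xm->hcm", pi, Ph, Pc, Pm).reshape(64)
    mask = counts > 0
    with np.errstate(divide="ignore"):
        logp = np.log(site[mask])
    return float(np.dot(counts[mask], logp))


def alignment_loglik(
    aln: TripletAlignment,
    hky: HKYParams,
    bl: BranchLengths,
    scales: PromoterScales = NEUTRAL_SCALES,
) -> float:
    """Log-likelihood of a triplet alignment under HKY on the star tree.

    Columns with gaps or N are dropped; a column whose pattern has probability
    zero (only possible at zero branch lengths) contributes -inf.
    """
    counts = pattern_counts(aln)
    if counts.sum() == 0:
        raise ValueError("no gap-free unambiguous columns to evaluate")
    return _loglik_patterns(counts, HKYTransition(hky), bl, scales)


@dataclass(frozen=True)
class NeutralFit:
    hky: HKYParams
    branch_lengths: BranchLengths
    lnL: float
    converged: bool
    n_sites: int


def _distance_inits(counts: np.ndarray) -> tuple[float, float, float]:
    """Crude branch-length starting values from pairwise mismatch fractions."""
    idx = np.arange(64)
    h, c, m = idx // 16, (idx // 4) % 4, idx % 4
    total = counts.sum()
    p_hc = counts[h != c].sum() / total
    p_hm = counts[h != m].sum() / total
    p_cm = counts[c != m].sum() / total
    t_h = max((p_hc + p_hm - p_cm) / 2.0, 1e-4)
    t_c = max(p_hc - t_h, 1e-4)
    t_m = max(p_hm - t_h, 1e-4)
    return t_h, t_c, t_m


def fit_neutral(
    intron: TripletAlignment,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
) -> NeutralFit:
    """Maximum-likelihood kappa and branch lengths on the intronic reference.

    pi is fixed at the pooled empirical base frequencies; the three branch
    lengths and kappa are optimized with all rate scalers at 1, from a
    distance-based start plus ``n_restarts - 1`` random restarts.
    """
    counts = pattern_counts(intron)
    n_sites = int(counts.sum())
    if n_sites == 0:
        raise ValueError("intron alignment has no usable columns")
    pi = empirical_base_freqs(intron)
    rng = np.random.default_rng(seed)

    def objective(theta: np.ndarray) -> float:
        kappa, t_h, t_c, t_m = theta
        trans = HKYTransition(HKYParams(kappa=float(kappa), pi=tuple(pi)))
        ll = _loglik_patterns(
            counts, trans, BranchLengths(t_h, t_c, t_m), NEUTRAL_SCALES
        )
        return -ll if np.isfinite(ll) else _PENALTY

    bounds = [_KAPPA_BOUNDS, (0.0, _T_MAX), (0.0, _T_MAX), (0.0, _T_MAX)]
    t0 = _distance_inits(counts)
    starts = [np.array([4.0, *t0])]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(
            np.array(
                [
                    np.exp(rng.uniform(np.log(0.5), np.log(20.0))),
                    *(np.array(t0) * rng.uniform(0.3, 3.0, size=3)),
                ]
            )
        )

    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": tol}
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged:
        raise RuntimeError("neutral fit failed to converge from any start")
    kappa, t_h, t_c, t_m = best.x
    return NeutralFit(
        hky=HKYParams(kappa=float(kappa), pi=tuple(pi)),
        branch_lengths=BranchLengths(float(t_h), float(t_c), float(t_m)),
        lnL=-float(best.fun),
        converged=True,
        n_sites=n_sites,
    )


def fit_scales(
    prom: TripletAlignment,
    hky: HKYParams,
    bl: BranchLengths,
    constrain_human: bool = False,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
    extra_starts: list[np.ndarray] | None = None,
) -> tuple[PromoterScales, float]:
    """Fit region rate scalers with neutral parameters frozen.

    Chimp and macaque scalers are free in [0, inf); the human scaler is
    clamped to [0, 1] when ``constrain_human`` (the null of the selection
    test) and free otherwise.  ``extra_starts`` lets the caller seed the
    optimization with, e.g., the solution of the nested model.
    """
    counts = pattern_counts(prom)
    if counts.sum() == 0:
        raise ValueError("promoter alignment has no usable columns")
    trans = HKYTransition(hky)  # decomposition shared by every evaluation
    rng = np.random.default_rng(seed)

    def objective(z: np.ndarray) -> float:
        ll = _loglik_patterns(
            counts, trans, bl, PromoterScales(float(z[0]), float(z[1]), float(z[2]))
        )
        return -ll if np.isfinite(ll) else _PENALTY

    z_h_hi = 1.0 if constrain_human else _ZETA_MAX
    bounds = [(0.0, z_h_hi), (0.0, _ZETA_MAX), (0.0, _ZETA_MAX)]
    starts = [np.array([min(1.0, z_h_hi), 1.0, 1.0])]
    if extra_starts:
        starts.extend(np.clip(s, 0.0, [z_h_hi, _ZETA_MAX, _ZETA_MAX]) for s in extra_starts)
    for _ in range(max(0, n_restarts - 1)):
        starts.append(
            np.clip(
                np.exp(rng.normal(0.0, 1.0, size=3)), 0.0, [z_h_hi, _ZETA_MAX, _ZETA_MAX]
            )
        )

    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": tol}
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_converged:
        raise RuntimeError("scale fit failed to converge from any start")
    z = best.x
    return PromoterScales(float(z[0]), float(z[1]), float(z[2])), -float(best.fun)
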