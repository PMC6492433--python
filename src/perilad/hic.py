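"""Hi-C map balancing, A/B compartments, and compartmentalization strength.

Implements the contact-map side of the pipeline: iterative correction (ICE)
of raw binned contact counts, distance normalization (observed/expected),
row-correlation matrices, compartment assignment from the leading eigenvector,
and the within-1-Mb A-versus-B interaction-strength statistic used to
quantify compartmentalization attenuation between genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContactMatrix",
    "BalancedMatrix",
    "CompartmentCall",
    "CompartmentStrengthResult",
    "ice_balance",
    "observed_over_expected",
    "correlation_matrix",
    "call_compartments",
    "compartment_agreement",
    "compartment_strength",
    "compare_compartment_strength",
    "trans_contact_fraction",
]


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts with per-bin genomic annotation."""

    counts: np.ndarray
    bin_size_bp: int
    chroms: np.ndarray
    starts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if not np.allclose(c, c.T):
            raise ValueError("counts must be symmetric")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        if len(self.chroms) != c.shape[0] or len(self.starts) != c.shape[0]:
            raise ValueError("bin annotation length must match matrix size")
        self.counts = c

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


@dataclass
class BalancedMatrix:
    values: np.ndarray           # balanced matrix, NaN on masked rows/cols
    bias_vector: np.ndarray      # per-bin multiplicative bias, NaN for masked
    masked: np.ndarray           # bool per bin
    converged: bool
    final_eps: float
    n_iter: int
    bin_size_bp: int
    chroms: np.ndarray
    starts: np.ndarray


@dataclass
class CompartmentCall:
    eigenvector: np.ndarray      # oriented leading eigenvector, NaN for masked
    labels: np.ndarray           # 'A', 'B', or 'masked'
    bin_size_bp: int
    degenerate: bool = False


@dataclass
class CompartmentStrengthResult:
    oe_values_AB: np.ndarray
    oe_values_within: np.ndarray
    mean_AB_relative: float
    max_sep_bp: int


# ----------------------------------------------------------------- balancing

def ice_balance(m: ContactMatrix, eps: float = 1e-4, max_iter: int = 200,
                mask_fraction: float = 0.02) -> BalancedMatrix:
    """Iterative correction of a contact matrix.

    Bins in the lowest ``mask_fraction`` quantile of coverage (and all
    zero-coverage bins) are masked out; the remaining matrix is repeatedly
    divided by its marginals (renormalized to mean 1) until the maximum
    relative marginal deviation drops below ``eps``.  Non-convergence within
    ``max_iter`` is reported honestly via the ``converged`` flag, not raised.
    """
    if not 0 <= mask_fraction < 0.5:
        raise ValueError("mask_fraction must lie in [0, 0.5)")
    W = m.counts.astype(float).copy()
    np.fill_diagonal(W, 0.0)
    if W.sum() == 0:
        raise ValueError("cannot balance an all-zero matrix")
    coverage = W.sum(axis=1)
    thr = np.quantile(coverage, mask_fraction) if mask_fraction > 0 else 0.0
    masked = (coverage <= thr) if mask_fraction > 0 else (coverage == 0)
    masked |= coverage == 0
    keep = ~masked
    sub = W[np.ix_(keep, keep)]
    bias = np.ones(keep.sum())
    converged = False
    delta = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        s = sub.sum(axis=1)
        if (s == 0).any():  # a retained bin lost all contacts
            break
        s = s / s.mean()
        delta = float(np.abs(s - 1).max())
        if delta < eps:
            converged = True
            break
        # square-root damping: the undamped symmetric update can enter a
        # period-2 oscillation on near-disconnected (strong checkerboard) maps
        step = np.sqrt(s)
        sub = sub / np.outer(step, step)
        bias *= step
    values = np.full_like(W, np.nan)
    values[np.ix_(keep, keep)] = sub
    bias_full = np.full(m.n_bins, np.nan)
    bias_full[keep] = bias
    return BalancedMatrix(values=values, bias_vector=bias_full, masked=masked,
                          converged=converged, final_eps=delta, n_iter=it,
                          bin_size_bp=m.bin_size_bp, chroms=m.chroms, starts=m.starts)


# ------------------------------------------------------- distance-normalized

def observed_over_expected(b: BalancedMatrix, allow_unconverged: bool = False) -> np.ndarray:
    """O/E matrix: each entry divided by the mean retained entry at its separation.

    The diagonal-mean normalization makes the per-distance average exactly 1,
    so O/E values are already 'relative to the average' interaction at that
    genomic separation.  Masked rows/columns stay NaN, as do separations with
    no retained entries.
    """
    if not b.converged and not allow_unconverged:
        raise ValueError("matrix not converged; pass allow_unconverged=True to override")
    n = b.values.shape[0]
    oe = np.full_like(b.values, np.nan)
    for d in range(n):
        diag = np.diagonal(b.values, offset=d)
        vals = diag[np.isfinite(diag)]
        if len(vals) == 0 or vals.mean() == 0:
            continue
        e = vals.mean()
        idx = np.arange(n - d)
        oe[idx, idx + d] = b.values[idx, idx + d] / e
        oe[idx + d, idx] = oe[idx, idx + d]
    return oe


def _relevel(oe: np.ndarray, max_iter: int = 100, tol: float = 1e-6) -> np.ndarray:
    """Remove residual multiplicative row/column factors from an O/E matrix.

    The true O/E matrix has flat marginals, but iterative correction of a
    finite chromosome forces uniform coverage onto a distance-decay (Toeplitz)
    expectation, leaving a smooth positional factor (edge bins inflated) that
    the per-diagonal normalization cannot remove and that induces spurious
    positive correlation between all rows.  A few damped marginal-correction
    sweeps on the O/E matrix itself eliminate it.
    """
    o = oe.copy()
    finite = np.isfinite(o)
    counts = finite.sum(axis=1)
    active = counts > 0
    for _ in range(max_iter):
        rs = np.where(finite, o, 0.0).sum(axis=1)
        means = np.full(len(rs), np.nan)
        means[active] = rs[active] / counts[active]
        s = means / np.nanmean(means)
        if np.nanmax(np.abs(s - 1)) < tol:
            break
        step = np.sqrt(np.where(np.isfinite(s) & (s > 0), s, 1.0))
        o = o / np.outer(step, step)
    return o


def correlation_matrix(oe: np.ndarray, min_periods: int = 3,
                       relevel: bool = True) -> np.ndarray:
    """Pearson correlation between O/E rows with pairwise NaN deletion.

    Rows with undefined (constant or all-NaN) profiles come back NaN; the
    diagonal is 1 for defined rows.  By default residual positional factors
    are removed first (see :func:`_relevel`), so that a map without
    compartment structure yields correlations centred on zero.
    """
    if relevel:
        oe = _relevel(oe)
    n = oe.shape[0]
    defined = np.array([np.isfinite(row).sum() >= min_periods and
                        np.nanstd(row) > 0 for row in oe])
    if defined.sum() < 3:
        raise ValueError("need at least 3 unmasked bins")
    corr = pd.DataFrame(oe.T).corr(min_periods=min_periods).to_numpy()
    corr[~defined, :] = np.nan
    corr[:, ~defined] = np.nan
    d = np.where(defined)[0]
    corr[d, d] = 1.0
    return corr


# ------------------------------------------------------------- compartments

def call_compartments(corr: np.ndarray, orientation_track: np.ndarray,
                      bin_size_bp: int = 1) -> CompartmentCall:
    """A/B compartments from the leading eigenvector of a correlation matrix.

    The eigenvector of the largest eigenvalue is sign-oriented so that it
    correlates positively with ``orientation_track`` (ground-truth labels in
    tests; gene density or an active mark on real data); bins with positive
    oriented values are labelled A.  A near-degenerate top eigenvalue
    (gap < 1e-8) is flagged but labels are still emitted.
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if len(orientation_track) != n:
        raise ValueError("orientation track length must match matrix size")
    defined = np.array([np.isfinite(corr[i]).any() for i in range(n)])
    sub = corr[np.ix_(defined, defined)]
    sub = np.nan_to_num(sub, nan=0.0)
    evals, evecs = np.linalg.eigh(sub)
    lead = evecs[:, -1]
    degenerate = bool(len(evals) >= 2 and (evals[-1] - evals[-2]) < 1e-8)
    track = np.asarray(orientation_track, dtype=float)[defined]
    finite = np.isfinite(track)
    if finite.sum() >= 2 and np.std(track[finite]) > 0 and np.std(lead[finite]) > 0:
        r = np.corrcoef(lead[finite], track[finite])[0, 1]
        if r < 0:
            lead = -lead
    ev = np.full(n, np.nan)
    ev[defined] = lead
    labels = np.full(n, "masked", dtype=object)
    labels[defined] = np.where(lead > 0, "A", "B")
    return CompartmentCall(eigenvector=ev, labels=labels,
                           bin_size_bp=bin_size_bp, degenerate=degenerate)


def compartment_agreement(call: CompartmentCall, reference: CompartmentCall) -> float:
    """Fraction of co-unmasked bins with identical A/B labels."""
    if len(call.labels) != len(reference.labels):
        raise ValueError("calls must share the bin grid")
    both = (call.labels != "masked") & (reference.labels != "masked")
    if not both.any():
        raise ValueError("no bins unmasked in both calls")
    return float(np.mean(call.labels[both] == reference.labels[both]))


def compartment_strength(oe: np.ndarray, call: CompartmentCall,
                         max_sep_bp: int = 1_000_000,
                         bin_size_bp: int | None = None) -> CompartmentStrengthResult:
    """Collect O/E of A-B vs within-compartment pairs within a separation cap.

    mean_AB_relative is the mean O/E over cross-compartment pairs; values
    near 1 mean A and B mix freely (weak compartmentalization), values well
    below 1 mean strong spatial separation.
    """
    bs = bin_size_bp if bin_size_bp is not None else call.bin_size_bp
    n = oe.shape[0]
    max_sep_bins = max(1, max_sep_bp // bs)
    ab, within = [], []
    lab = call.labels
    for d in range(1, min(max_sep_bins, n - 1) + 1):
        i = np.arange(n - d)
        vals = oe[i, i + d]
        li, lj = lab[i], lab[i + d]
        ok = np.isfinite(vals) & (li != "masked") & (lj != "masked")
        cross = ok & (li != lj)
        same = ok & (li == lj)
        ab.append(vals[cross])
        within.append(vals[same])
    ab = np.concatenate(ab) if ab else np.empty(0)
    within = np.concatenate(within) if within else np.empty(0)
    if len(ab) == 0:
        raise ValueError("no cross-compartment pairs within the separation cap")
    return CompartmentStrengthResult(oe_values_AB=ab, oe_values_within=within,
                                     mean_AB_relative=float(ab.mean()),
                                     max_sep_bp=max_sep_bp)


def compare_compartment_strength(a: CompartmentStrengthResult,
                                 b: CompartmentStrengthResult) -> float:
    """Two-sided Mann-Whitney p on the cross-compartment O/E sets of two genotypes."""
    res = stats.mannwhitneyu(a.oe_values_AB, b.oe_values_AB,
                             alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------- trans

def trans_contact_fraction(m: ContactMatrix):
    """Fraction of contacts that are inter-chromosomal, overall and per pair.

    Returns (overall_trans_fraction, per_pair) where per_pair maps each
    unordered chromosome pair (including cis pairs) to its fraction of the
    total contact mass; the per-pair fractions sum to 1.
    """
    chroms = np.asarray(m.chroms)
    uniq = list(dict.fromkeys(chroms.tolist()))
    if len(uniq) < 2:
        raise ValueError("need at least 2 chromosomes")
    total = m.counts.sum()
    if total == 0:
        return 0.0, {}
    per_pair: dict[tuple[str, str], float] = {}
    trans = 0.0
    for a in range(len(uniq)):
        ia = chroms == uniq[a]
        for b in range(a, len(uniq)):
            ib = chroms == uniq[b]
            mass = float(m.counts[np.ix_(ia, ib)].sum())
            if a != b:
                mass *= 2.0  # both triangles
                trans += mass
            per_pair[(uniq[a], uniq[b])] = mass / total
    return trans / total, per_pair
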