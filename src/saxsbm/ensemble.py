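"""Candidate scoring and minimal-ensemble fitting against SAXS data.

The workflow mirrors the standard pool-selection strategy for flexible
multi-domain proteins: every sampled conformation is scored against an
experimental curve with the reduced discrepancy

    χ² = (1/N_q) Σ_q [ (c·I_theo(q) − I_exp(q)) / σ(q) ]² ,

where c is a fitted multiplicative scale (simulated intensities are on an
arbitrary scale).  The lowest-χ² fraction (default 5%) is kept, its Rg
probability distribution P(Rg) is built, distinct low-χ² representatives
are drawn from the most prominent peaks, and every combination of one
representative per peak is fitted as a weighted mixture over the discrete
weight grid w_i = 0.1·n (n = 0..10, Σw = 1).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
from scipy.signal import find_peaks

from .curve import ScatteringCurve
from .saxs import debye_profile
from .structure import ConformationSet, rmsd_superposed

__all__ = [
    "CandidateSet",
    "RgHistogram",
    "EnsembleFit",
    "chi_square",
    "score_candidates",
    "filter_lowest",
    "prg_histogram",
    "select_representatives",
    "enumerate_weights",
    "fit_ensemble",
    "combination_search",
    "cross_table",
]


def chi_square(
    exp: ScatteringCurve, theo: ScatteringCurve, fit_scale: bool = True
) -> tuple[float, float]:
    """Reduced χ² between an experimental and a theoretical curve.

    With ``fit_scale`` the optimal multiplicative scale
    c = Σ(I_exp·I_theo/σ²) / Σ(I_theo²/σ²) is applied first (weighted
    least squares closed form); otherwise c = 1.  Returns ``(χ², c)``.
    """
    if exp.sigma is None:
        raise ValueError("experimental curve must carry errors σ(q)")
    if not exp.same_grid(theo):
        raise ValueError("q grids differ between curves")
    w = 1.0 / exp.sigma**2
    if fit_scale:
        denom = float(np.sum(w * theo.intensity**2))
        if denom == 0.0:
            raise ValueError("theoretical curve is identically zero")
        c = float(np.sum(w * exp.intensity * theo.intensity)) / denom
    else:
        c = 1.0
    resid = (c * theo.intensity - exp.intensity) / exp.sigma
    return float(np.mean(resid**2)), c


@dataclasses.dataclass
class CandidateSet:
    """Sampled conformations with per-conformation curves, Rg and χ²."""

    conformations: ConformationSet
    curves: np.ndarray  # (n, N_q) theoretical intensities on exp grid
    q: np.ndarray
    chi2: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.conformations)
        if self.curves.shape != (n, len(self.q)):
            raise ValueError("curves shape mismatch")
        if np.any(self.chi2 < 0):
            raise ValueError("negative χ²")

    def __len__(self) -> int:
        return len(self.conformations)

    @property
    def rg(self) -> np.ndarray:
        return self.conformations.rg

    @property
    def frame_index(self) -> np.ndarray:
        return self.conformations.frame_index

    def subset(self, idx: np.ndarray) -> "CandidateSet":
        idx = np.asarray(idx)
        return CandidateSet(
            self.conformations.subset(idx),
            self.curves[idx],
            self.q,
            self.chi2[idx],
            self.scale[idx],
        )


def score_candidates(
    cs: ConformationSet,
    exp: ScatteringCurve,
    mode: str = "vacuum",
    curves: np.ndarray | None = None,
) -> CandidateSet:
    """Score every conformation against ``exp`` (scale-fitted χ²).

    Theoretical curves are computed on the experimental q grid with
    :func:`saxsbm.saxs.debye_profile`, or taken from ``curves`` if the
    profiles were precomputed (they must share the experimental grid).
    """
    if curves is None:
        curves = np.stack(
            [debye_profile(cs[i], exp.q, mode=mode).intensity for i in range(len(cs))]
        )
    else:
        curves = np.asarray(curves, dtype=float)
    chi2 = np.empty(len(cs))
    scale = np.empty(len(cs))
    for i in range(len(cs)):
        chi2[i], scale[i] = chi_square(exp, ScatteringCurve(exp.q, curves[i]), True)
    return CandidateSet(cs, curves, np.asarray(exp.q, dtype=float), chi2, scale)


def filter_lowest(cands: CandidateSet, fraction: float = 0.05) -> CandidateSet:
    """Keep the ⌊fraction·N⌋ lowest-χ² conformations.

    Boundary ties are broken toward the earlier frame index.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    k = int(np.floor(fraction * len(cands)))
    if k == 0:
        raise ValueError(
            f"fraction {fraction} of {len(cands)} candidates keeps zero conformations"
        )
    order = np.lexsort((cands.frame_index, cands.chi2))
    keep = np.sort(order[:k])  # preserve original ordering
    return cands.subset(keep)


@dataclasses.dataclass
class RgHistogram:
    """Normalized P(Rg) with detected peaks (bin centers, by prominence)."""

    edges: np.ndarray  # (n_bins + 1,)
    prob: np.ndarray  # (n_bins,), sums to 1
    peak_centers: np.ndarray  # sorted by decreasing prominence
    peak_prominences: np.ndarray
    peak_bins: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def peak_window(self, peak_rank: int = 0) -> tuple[float, float]:
        """Rg interval of contiguous bins above half the peak's height."""
        b = int(self.peak_bins[peak_rank])
        half = 0.5 * self.prob[b]
        lo = b
        while lo > 0 and self.prob[lo - 1] >= half:
            lo -= 1
        hi = b
        while hi < len(self.prob) - 1 and self.prob[hi + 1] >= half:
            hi += 1
        return float(self.edges[lo]), float(self.edges[hi + 1])


def prg_histogram(
    cands: CandidateSet | np.ndarray,
    bin_width: float = 0.25,
    prominence_frac: float = 0.05,
) -> RgHistogram:
    """Normalized Rg histogram with peak detection.

    Bin edges are aligned to multiples of ``bin_width`` so that nested
    candidate subsets land on comparable grids.  Peaks are local maxima
    of the bin mass with prominence ≥ ``prominence_frac`` × the tallest
    bin (boundary bins may qualify).
    """
    rg = cands.rg if isinstance(cands, CandidateSet) else np.asarray(cands, dtype=float)
    if len(rg) == 0:
        raise ValueError("empty candidate set")
    lo = np.floor(rg.min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((rg.max() - lo) / bin_width + 1e-9)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(rg, bins=edges)
    prob = counts / counts.sum()
    padded = np.concatenate([[0.0], prob, [0.0]])
    idx, props = find_peaks(padded, prominence=prominence_frac * prob.max())
    idx = idx - 1
    order = np.argsort(-props["prominences"], kind="stable")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RgHistogram(
        edges=edges,
        prob=prob,
        peak_centers=centers[idx[order]],
        peak_prominences=props["prominences"][order],
        peak_bins=idx[order],
    )


def select_representatives(
    cands: CandidateSet,
    hist: RgHistogram,
    k_per_peak: int = 4,
    min_rmsd: float = 2.0,
    n_peaks: int = 3,
) -> list[np.ndarray]:
    """Distinct low-χ² representatives for the most prominent P(Rg) peaks.

    For each of the ``n_peaks`` top-prominence peaks, conformations inside
    the peak's half-height window are taken greedily in increasing χ²,
    skipping any conformation within ``min_rmsd`` (superposed RMSD, Å) of
    one already selected anywhere.  Returns one index array (into
    ``cands``) per peak; a warning is emitted when a peak yields fewer
    than ``k_per_peak`` admissible conformations.
    """
    n_peaks = min(n_peaks, len(hist.peak_centers))
    if n_peaks == 0:
        raise ValueError("no peaks detected in P(Rg)")
    selected_structs = []
    groups: list[np.ndarray] = []
    for rank in range(n_peaks):
        lo, hi = hist.peak_window(rank)
        in_window = np.flatnonzero((cands.rg >= lo) & (cands.rg < hi))
        in_window = in_window[np.argsort(cands.chi2[in_window], kind="stable")]
        chosen: list[int] = []
        for i in in_window:
            if len(chosen) == k_per_peak:
                break
            s = cands.conformations[int(i)]
            if all(rmsd_superposed(s, other) > min_rmsd for other in selected_structs):
                chosen.append(int(i))
                selected_structs.append(s)
        if len(chosen) < k_per_peak:
            warnings.warn(
                f"peak {rank}: only {len(chosen)} of {k_per_peak} distinct "
                f"representatives available in window [{lo:.2f}, {hi:.2f}) Å",
                stacklevel=2,
            )
        if chosen:
            groups.append(np.array(chosen, dtype=int))
    if not groups:
        raise ValueError("no peak yielded any admissible representative")
    return groups


def enumerate_weights(k: int, step: float = 0.1) -> np.ndarray:
    """All k-vectors of non-negative multiples of ``step`` summing to 1.

    Enumerated with integer arithmetic (no floating-point drift), in
    lexicographic order; zeros are allowed.  For k = 3, step = 0.1 this
    yields the C(12, 2) = 66 grid combinations.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ValueError(f"1/step must be an integer, got step={step}")

    def compositions(parts: int, total: int):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(parts - 1, total - first):
                yield (first, *rest)

    ints = np.array(sorted(compositions(k, m)), dtype=float)
    w = ints / m
    # pin the last component to the exact complement so each vector sums to
    # 1.0 bit-exactly despite the decimal step being inexact in binary
    w[:, -1] = 1.0 - w[:, :-1].sum(axis=1)
    return w


@dataclasses.dataclass
class EnsembleFit:
    """Best weighted mixture of member curves for one experimental curve."""

    member_ids: tuple[int, ...]
    weights: np.ndarray  # grid-quantized, sums to 1
    combined: ScatteringCurve  # unscaled Σ w_i I_i on the experimental grid
    chi2: float
    scale: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        self.weights = w


def fit_ensemble(
    exp: ScatteringCurve,
    member_curves: np.ndarray,
    member_ids: tuple[int, ...] | None = None,
    step: float = 0.1,
) -> EnsembleFit:
    """Exhaustive weight-grid search for the best mixture of members.

    Every enumerated weight vector w defines I_combined = Σ w_i I_i, which
    is scored with the scale-fitted χ²; the global minimum is returned,
    ties broken toward the lexicographically smallest weight vector (the
    enumeration order).
    """
    member_curves = np.atleast_2d(np.asarray(member_curves, dtype=float))
    k, nq = member_curves.shape
    if exp.sigma is None:
        raise ValueError("experimental curve must carry errors σ(q)")
    if nq != exp.n_points:
        raise ValueError("member curves not on the experimental q grid")
    if member_ids is None:
        member_ids = tuple(range(k))
    wgrid = enumerate_weights(k, step)  # (M, k), lexicographic
    combined = wgrid @ member_curves  # (M, N_q)
    wq = 1.0 / exp.sigma**2
    denom = combined**2 @ wq
    numer = combined @ (wq * exp.intensity)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(denom > 0, numer / np.maximum(denom, 1e-300), 0.0)
    resid = (scale[:, None] * combined - exp.intensity[None, :]) / exp.sigma[None, :]
    chi2 = np.mean(resid**2, axis=1)
    best = int(np.argmin(chi2))  # first minimum = lexicographically smallest
    return EnsembleFit(
        member_ids=tuple(member_ids),
        weights=wgrid[best],
        combined=ScatteringCurve(np.asarray(exp.q, dtype=float), combined[best]),
        chi2=float(chi2[best]),
        scale=float(scale[best]),
    )


def combination_search(
    exp: ScatteringCurve,
    group_curves: list[np.ndarray],
    group_ids: list[np.ndarray] | None = None,
    step: float = 0.1,
) -> tuple[EnsembleFit, int]:
    """Best ensemble over all one-per-peak representative combinations.

    ``group_curves[g]`` holds the member curves of peak group g (shape
    ``(n_g, N_q)``).  Every cross-product choice of one conformer per
    group (4×4×4 = 64 with the defaults) is fitted with
    :func:`fit_ensemble`; returns the overall best fit and the number of
    candidate ensembles evaluated.
    """
    if not group_curves or any(len(gc) == 0 for gc in group_curves):
        raise ValueError("every peak group must contain at least one conformer")
    if group_ids is None:
        group_ids = [np.arange(len(gc)) for gc in group_curves]
    best: EnsembleFit | None = None
    n_eval = 0
    for choice in itertools.product(*(range(len(gc)) for gc in group_curves)):
        curves = np.stack([group_curves[g][c] for g, c in enumerate(choice)])
        ids = tuple(int(group_ids[g][c]) for g, c in enumerate(choice))
        fit = fit_ensemble(exp, curves, ids, step)
        n_eval += 1
        if best is None or fit.chi2 < best.chi2:
            best = fit
    assert best is not None
    return best, n_eval


def cross_table(fits: list[EnsembleFit], exps: list[ScatteringCurve]) -> np.ndarray:
    """χ² of every best-fit ensemble against every experimental curve.

    Entry (i, j) is the scale-fitted χ² of fit i's combined curve against
    experimental curve j; the diagonal reproduces each fit's own χ².
    Shape is always (n_fits, n_datasets).
    """
    table = np.empty((len(fits), len(exps)))
    for i, fit in enumerate(fits):
        for j, exp in enumerate(exps):
            table[i, j], _ = chi_square(exp, fit.combined, fit_scale=True)
    return table
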