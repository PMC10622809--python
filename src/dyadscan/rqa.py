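"""Recurrence quantification analysis without embedding (D = tau = 1).

A recurrence plot of a scalar series x marks every pair of time points
whose values differ by less than a radius E: R[i, j] = 1 iff
|x(t_i) - x(t_j)| < E.  Repeated subsequences appear as diagonal lines,
stagnant (laminar) stretches as vertical lines.  Four quantifiers are
computed:

* ``RR``   = 100 * N_rec / N_p       (recurrence rate, %)
* ``DET``  = 100 * N_diag / N_rec    (points on diagonal lines >= l_min, %)
* ``ENTR`` = -sum p(l) log2 p(l)     (Shannon entropy of the diagonal
                                      line-length distribution, bits)
* ``LAM``  = 100 * N_vert / N_rec    (points on vertical lines >= v_min, %)

The line of identity (main diagonal) is trivial self-recurrence and is by
default excluded from N_p, N_rec and every line count.  Instead of fixing
E, the radius is selected per segment so that the achieved recurrence rate
matches a target (default 3%), which makes the quantifiers comparable
across subjects whose signals live on different amplitude scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist

from .synthgen import ResponseSignal


@dataclass(frozen=True)
class RQAParams:
    """Parameters of the recurrence analysis.

    Embedding is deliberately not supported: only comparisons between
    subjects matter here, not reconstructed phase-space geometry, and
    unembedded plots (D = tau = 1) compare just as well.
    """

    D: int = 1
    tau: int = 1
    target_rr: float = 3.0  # percent
    l_min: int = 2
    v_min: int = 2
    exclude_loi: bool = True

    def __post_init__(self) -> None:
        if self.D != 1 or self.tau != 1:
            raise ValueError("time-delay embedding (D or tau > 1) is not supported")
        if not 0 < self.target_rr <= 100:
            raise ValueError("target_rr must lie in (0, 100]")
        if self.l_min < 2 or self.v_min < 2:
            raise ValueError("minimum line lengths must be >= 2")


@dataclass
class RecurrencePlot:
    n: int
    matrix: np.ndarray  # boolean, LOI zeroed when excluded
    E: float
    achieved_rr: float  # percent
    exclude_loi: bool = True

    @property
    def n_p(self) -> int:
        return self.n * self.n - (self.n if self.exclude_loi else 0)

    @property
    def n_rec(self) -> int:
        return int(self.matrix.sum())


@dataclass
class RQAFeatures:
    subject_id: str
    modality: str
    segment_index: int
    window: tuple[float, float]  # (start s, length s) within the analyzed block
    RR: float
    DET: float
    ENTR: float
    LAM: float
    E: float


class ConstantSeriesError(ValueError):
    """No radius can achieve a fixed recurrence rate on a constant series."""


# ---------------------------------------------------------------------------
# Plot construction
# ---------------------------------------------------------------------------


def recurrence_matrix(
    x: np.ndarray, radius: float, params: Optional[RQAParams] = None
) -> RecurrencePlot:
    """Binary recurrence plot: R[i, j] = 1 iff |x_i - x_j| < radius."""
    params = params or RQAParams()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("series must be 1-D with length >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    R = np.abs(x[:, None] - x[None, :]) < radius
    if params.exclude_loi:
        np.fill_diagonal(R, False)
    n = x.size
    n_p = n * n - (n if params.exclude_loi else 0)
    return RecurrencePlot(
        n=n,
        matrix=R,
        E=float(radius),
        achieved_rr=100.0 * float(R.sum()) / n_p,
        exclude_loi=params.exclude_loi,
    )


def find_radius(x: np.ndarray, target_rr: float = 3.0) -> float:
    """Radius achieving a fixed recurrence rate (percent) on this series.

    E is placed at the empirical ``target_rr``-percentile of the pairwise
    absolute-difference distribution — midway between the k-th and (k+1)-th
    order statistic with k = round(target * n(n-1)/2 / 100) — so the strict
    ``|x_i - x_j| < E`` condition recurs exactly k unordered pairs and the
    achieved rate equals the target up to pair-count quantization.  When the
    quantile falls inside a tie atom (e.g. the exact-zero plateaus of
    burst-sparsified signals) E advances past the tie and the achieved rate
    exceeds the target; it is recorded on the plot either way.  Constant
    series admit no valid radius.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("series must be 1-D with length >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if not 0 < target_rr <= 100:
        raise ValueError("target_rr must lie in (0, 100]")
    d = pdist(x[:, None], metric="cityblock")
    d_max = d.max()
    if d_max == 0:
        raise ConstantSeriesError("constant series has no valid radius")
    m = d.size
    k = int(round(target_rr / 100.0 * m))
    if k >= m:
        return float(d_max * (1 + 1e-9) + 1e-12)
    if k == 0:
        return float(d[d > 0].min() / 2 if (d > 0).any() else 0.0)
    d.sort()
    lo, hi = d[k - 1], d[k]
    if hi > lo:
        return float((lo + hi) / 2)
    # tie atom straddles the quantile: advance past it
    above = d[d > hi]
    if above.size == 0:
        return float(d_max * (1 + 1e-9) + 1e-12)
    return float((hi + above.min()) / 2)


# ---------------------------------------------------------------------------
# Line structures
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _diag_layout(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Flat layout of all upper-triangle diagonals with separator gaps.

    Returns (rows, cols, positions, total_length): writing R[rows, cols]
    into a zeroed array of total_length at ``positions`` yields every
    diagonal k = 1..n-1 laid end to end with one guaranteed-False separator
    between consecutive diagonals, so maximal runs never span diagonals.
    """
    rows, cols, pos = [], [], []
    p = 0
    for k in range(1, n):
        ln = n - k
        i = np.arange(ln)
        rows.append(i)
        cols.append(i + k)
        pos.append(np.arange(p, p + ln))
        p += ln + 1
    return (
        np.concatenate(rows),
        np.concatenate(cols),
        np.concatenate(pos),
        p,
    )


def _run_lengths(flat: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a flat boolean array."""
    padded = np.empty(flat.size + 2, dtype=np.int8)
    padded[0] = padded[-1] = 0
    padded[1:-1] = flat
    edges = np.flatnonzero(np.diff(padded))
    return edges[1::2] - edges[0::2]


def _diag_run_lengths(R: np.ndarray, include_loi_line: bool) -> np.ndarray:
    """Maximal diagonal run lengths on the upper triangle (LOI optional)."""
    n = R.shape[0]
    rows, cols, pos, total = _diag_layout(n)
    flat = np.zeros(total, dtype=bool)
    flat[pos] = R[rows, cols]
    lengths = _run_lengths(flat)
    if include_loi_line:
        loi = _run_lengths(np.diagonal(R).copy())
        lengths = np.concatenate([lengths, loi])
    return lengths


def _vert_run_lengths(R: np.ndarray) -> np.ndarray:
    """Maximal vertical run lengths over all columns of the full matrix."""
    n = R.shape[0]
    padded = np.zeros((n + 1, n), dtype=bool)
    padded[:n] = R
    return _run_lengths(padded.reshape(-1, order="F"))


def diagonal_lines(
    plot: RecurrencePlot, l_min: int = 2
) -> tuple[dict[int, int], int]:
    """Histogram of maximal diagonal line lengths >= l_min, plus N_diag.

    Because the plot is symmetric every off-identity line appears mirrored;
    the histogram counts each mirrored pair once (upper triangle), and
    N_diag is the number of recurrent points inside those counted lines.
    When the line of identity is included it contributes as a single line.
    """
    lengths = _diag_run_lengths(plot.matrix, include_loi_line=not plot.exclude_loi)
    keep = lengths[lengths >= l_min]
    values, counts = np.unique(keep, return_counts=True)
    hist = {int(v): int(c) for v, c in zip(values, counts)}
    return hist, int(keep.sum())


def quantifiers(
    plot: RecurrencePlot, params: Optional[RQAParams] = None
) -> tuple[float, float, float, float]:
    """(RR, DET, ENTR, LAM) of a recurrence plot.

    DET and LAM are ratios over the full (symmetric) matrix: diagonal-line
    points found on the upper triangle are mirrored, vertical runs are
    counted in every column.  With no recurrent points DET = LAM = 0 and
    ENTR = 0; ENTR is 0 whenever at most one distinct line length occurs.
    """
    params = params or RQAParams()
    R = plot.matrix
    n_rec = plot.n_rec
    rr = 100.0 * n_rec / plot.n_p
    if n_rec == 0:
        return rr, 0.0, 0.0, 0.0

    lengths = _diag_run_lengths(R, include_loi_line=not plot.exclude_loi)
    kept = lengths[lengths >= params.l_min]
    if plot.exclude_loi:
        n_diag = 2 * int(kept.sum())
    else:
        loi_kept = _run_lengths(np.diagonal(R).copy())
        loi_kept = loi_kept[loi_kept >= params.l_min]
        n_diag = 2 * int(kept.sum()) - int(loi_kept.sum())  # LOI is its own mirror
    det = 100.0 * n_diag / n_rec

    if kept.size:
        _, counts = np.unique(kept, return_counts=True)
        p = counts / counts.sum()
        entr = float(-(p * np.log2(p)).sum())
    else:
        entr = 0.0

    v_lengths = _vert_run_lengths(R)
    n_vert = int(v_lengths[v_lengths >= params.v_min].sum())
    lam = 100.0 * n_vert / n_rec
    return rr, det, entr, lam


# ---------------------------------------------------------------------------
# Windowed analysis
# ---------------------------------------------------------------------------


def windowed_rqa(
    signal: ResponseSignal,
    window_len: float = 20.0,
    params: Optional[RQAParams] = None,
    start: float = 0.0,
    duration: Optional[float] = None,
) -> list[RQAFeatures]:
    """Fixed-rate RQA in non-overlapping windows of a signal block.

    The block [start, start+duration) is cut into floor(duration/window_len)
    full windows (a trailing partial window is dropped).  Per window the
    radius is searched for the target recurrence rate, then the quantifiers
    are computed; constant windows yield NaN features.  Window start times
    in the output are seconds relative to the block origin.
    """
    params = params or RQAParams()
    rate = signal.sample_rate
    if duration is None:
        duration = signal.values.size / rate - start
    n_windows = int(np.floor(duration / window_len))
    out: list[RQAFeatures] = []
    for w in range(n_windows):
        w_start = w * window_len
        x = signal.slice_seconds(start + w_start, window_len)
        try:
            radius = find_radius(x, params.target_rr)
            plot = recurrence_matrix(x, radius, params)
            rr, det, entr, lam = quantifiers(plot, params)
        except ConstantSeriesError:
            rr = det = entr = lam = radius = float("nan")
        out.append(
            RQAFeatures(
                subject_id=signal.subject_id,
                modality=signal.modality,
                segment_index=w,
                window=(w_start, window_len),
                RR=rr,
                DET=det,
                ENTR=entr,
                LAM=lam,
                E=radius,
            )
        )
    return out


def rr_linearity_diagnostic(
    x: np.ndarray,
    rates: tuple[float, ...] = (2.0, 3.0, 4.0),
    params: Optional[RQAParams] = None,
) -> dict:
    """Quantifiers at several target rates plus a local linearity residual.

    The fixed-rate convention is trustworthy while quantifiers scale
    roughly linearly with the recurrence rate; this diagnostic reports, for
    each quantifier, the maximum relative deviation of the middle rate's
    value from the linear interpolation of its neighbours.  Informational
    output — no thresholds are enforced.
    """
    params = params or RQAParams()
    rows = {}
    for rr_target in rates:
        radius = find_radius(x, rr_target)
        plot = recurrence_matrix(x, radius, params)
        rr, det, entr, lam = quantifiers(plot, params)
        rows[rr_target] = {"RR": rr, "DET": det, "ENTR": entr, "LAM": lam, "E": radius}
    rates_sorted = sorted(rows)
    residuals = {}
    if len(rates_sorted) >= 3:
        lo, mid, hi = rates_sorted[0], rates_sorted[len(rates_sorted) // 2], rates_sorted[-1]
        for qname in ("DET", "ENTR", "LAM"):
            y_lo, y_mid, y_hi = (rows[r][qname] for r in (lo, mid, hi))
            interp = y_lo + (y_hi - y_lo) * (mid - lo) / (hi - lo)
            scale = max(abs(y_lo), abs(y_hi), 1e-12)
            residuals[qname] = abs(y_mid - interp) / scale
    return {"by_rate": rows, "linearity_residual": residuals}
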