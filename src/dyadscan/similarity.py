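"""Inter-subject correlation, RDMs and the sliding-window model scan.

Pairwise similarity between subjects' time-locked signals is measured by
the correlation distance ``d_P = 1 + r`` (Pearson r shifted into [0, 2]:
2 = strong similarity, 1 = no correlation, 0 = strong dissimilarity).  For
one analysis window the pairwise distances form a subject-by-subject
representational dissimilarity matrix (RDM) which can be compared, via
Kendall's tau-b, against hypothesis "coupling model" RDMs:

* strong coupling — elevated similarity (cell 2) only for true dyad
  partners, 1 elsewhere;
* weak coupling — elevated similarity for every pair of paired-group (SP)
  subjects regardless of partnership, 1 elsewhere.

``rsa_scan`` slides a window across the drama block, correlates every
window's RDM with a model, applies Benjamini-Hochberg FDR across all
windows, and reports intervals of consecutive significant windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthgen import Cohort

DIAG_VALUE = 2.0  # self-correlation r=1 => d_P=2


# ---------------------------------------------------------------------------
# Elementary measures
# ---------------------------------------------------------------------------


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN when either series has zero variance.

    A zero-variance window (e.g. an all-zero stretch of a bursty AU signal)
    has no defined correlation; it is flagged as NaN rather than silently
    treated as 0, and downstream RDM comparisons drop such cells pairwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D with equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def corr_distance(r: float) -> float:
    """Correlation distance d_P = 1 + r, mapping [-1, 1] to [0, 2]."""
    if np.isnan(r):
        return float("nan")
    if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    return 1.0 + float(np.clip(r, -1.0, 1.0))


# ---------------------------------------------------------------------------
# RDMs
# ---------------------------------------------------------------------------


@dataclass
class RDM:
    """Symmetric subject-by-subject correlation-distance matrix.

    ``labels`` follow the fixed ordering convention: the SS block first,
    then SP subjects with true pairs adjacent.  Cells are d_P in [0, 2]
    (diagonal exactly 2); undefined correlations are NaN.
    """

    labels: list[str]
    matrix: np.ndarray
    window: Optional[tuple[float, float]] = None  # (start s, length s)
    modality: Optional[str] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match labels")


def subject_order(labels: pd.DataFrame) -> list[str]:
    """Canonical RDM ordering: sorted SS block, then dyads with pairs adjacent."""
    ss = sorted(labels.loc[labels.group == "SS", "subject_id"])
    sp = labels[labels.group == "SP"].sort_values(["dyad_id", "subject_id"])
    return ss + list(sp.subject_id)


def build_rdm(
    cohort: Cohort,
    modality: str,
    window: tuple[float, float],
) -> RDM:
    """Pairwise correlation-distance RDM over one window.

    ``window`` is (start, length) in seconds from recording onset,
    half-open [start, start+length).  Zero-variance subjects yield NaN
    cells (excluded downstream); the diagonal is exactly 2 regardless.
    """
    order = subject_order(cohort.labels)
    start, length = window
    data = np.vstack(
        [cohort.get(sid, modality).slice_seconds(start, length) for sid in order]
    )
    return RDM(
        labels=order,
        matrix=_distance_matrix(data),
        window=(float(start), float(length)),
        modality=modality,
    )


def _distance_matrix(data: np.ndarray) -> np.ndarray:
    """d_P matrix from an (n_subjects, n_samples) array; NaN for flat rows."""
    sd = data.std(axis=1)
    ok = sd > 0
    n = data.shape[0]
    r = np.full((n, n), np.nan)
    if ok.sum() >= 2:
        with np.errstate(invalid="ignore"):
            sub = np.corrcoef(data[ok])
        r[np.ix_(ok, ok)] = np.clip(sub, -1.0, 1.0)
    d = 1.0 + r
    np.fill_diagonal(d, DIAG_VALUE)
    return d


@dataclass
class ModelRDM:
    labels: list[str]
    kind: Literal["strong", "weak"]
    matrix: np.ndarray


def model_rdm(labels: pd.DataFrame, kind: Literal["strong", "weak"]) -> ModelRDM:
    """Hypothesis RDM with cells in {1, 2}.

    strong: cell 2 only for true dyad partners; weak: cell 2 for any pair
    of SP subjects.  Off-model cells are 1 (no correlation); the diagonal
    is set to 2 for consistency with data RDMs but is never compared.
    """
    if kind not in ("strong", "weak"):
        raise ValueError("kind must be 'strong' or 'weak'")
    order = subject_order(labels)
    meta = labels.set_index("subject_id").loc[order]
    group = meta["group"].to_numpy()
    dyad = meta["dyad_id"].to_numpy(dtype=object)
    if kind == "strong":
        missing = (group == "SP") & pd.isna(dyad)
        if missing.any():
            raise ValueError("strong model requires a dyad_id for every SP subject")
    n = len(order)
    m = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if kind == "strong":
                if dyad[i] is not None and not pd.isna(dyad[i]) and dyad[i] == dyad[j]:
                    m[i, j] = 2.0
            else:
                if group[i] == "SP" and group[j] == "SP":
                    m[i, j] = 2.0
    np.fill_diagonal(m, DIAG_VALUE)
    return ModelRDM(labels=order, kind=kind, matrix=m)


def vectorize_rdm(rdm: RDM | ModelRDM, atol: float = 1e-8) -> np.ndarray:
    """Lower-triangle cells (diagonal excluded) in row-major traversal order.

    The traversal order — rows top to bottom, within each row the columns
    left of the diagonal — is shared by every RDM built with the same label
    ordering, so vectors from data and model RDMs align cell-for-cell.
    """
    m = np.asarray(rdm.matrix, dtype=float)
    asym = np.nanmax(np.abs(m - m.T)) if m.size else 0.0
    if asym > atol:
        raise ValueError(f"matrix is asymmetric beyond tolerance ({asym:.3g})")
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def unvectorize_rdm(vec: np.ndarray, labels: list[str]) -> RDM:
    """Inverse of :func:`vectorize_rdm` (diagonal restored to 2)."""
    n = len(labels)
    if vec.size != n * (n - 1) // 2:
        raise ValueError("vector length does not match label count")
    m = np.full((n, n), DIAG_VALUE)
    i, j = np.tril_indices(n, k=-1)
    m[i, j] = vec
    m[j, i] = vec
    return RDM(labels=labels, matrix=m)


def kendall_tau(vec_a: np.ndarray, vec_b: np.ndarray) -> tuple[float, float]:
    """Kendall tau-b (tie-corrected) with two-sided p, dropping NaNs pairwise."""
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        return float("nan"), float("nan")
    res = stats.kendalltau(a[ok], b[ok], variant="b")
    return float(res.statistic), float(res.pvalue)


def compare_all_rdms(
    rdms: Sequence[tuple[str, RDM | ModelRDM]], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All pairwise Kendall-tau comparisons among a set of RDMs.

    Returns (tau, p, tau_masked) as square DataFrames indexed by RDM name;
    ``tau_masked`` hides cells with p >= alpha (diagonal tau is 1 by
    definition).  k inputs yield k(k-1)/2 unique comparisons — e.g. 10
    stimulus RDMs plus the 2 coupling models give 66.
    """
    names = [name for name, _ in rdms]
    if len(set(names)) != len(names):
        raise ValueError("RDM names must be unique")
    ref = rdms[0][1].labels
    for name, r in rdms:
        if list(r.labels) != list(ref):
            raise ValueError(f"label ordering of RDM {name!r} does not match")
    vecs = [vectorize_rdm(r) for _, r in rdms]
    k = len(rdms)
    tau = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            t, pv = kendall_tau(vecs[i], vecs[j])
            tau[i, j] = tau[j, i] = t
            p[i, j] = p[j, i] = pv
    tau_df = pd.DataFrame(tau, index=names, columns=names)
    p_df = pd.DataFrame(p, index=names, columns=names)
    masked = tau_df.where((p_df < alpha) | np.eye(k, dtype=bool))
    return tau_df, p_df, masked


# ---------------------------------------------------------------------------
# Multiple testing and the drama scan
# ---------------------------------------------------------------------------


def bh_fdr(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and strict reject mask.

    NaN p-values (undefined windows) are passed through as NaN and never
    rejected.  Rejection uses q < alpha.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum() > 0:
        _, q_ok, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        q[ok] = q_ok
    reject = np.zeros(p.shape, dtype=bool)
    reject[ok] = q[ok] < alpha
    return q, reject


@dataclass
class RSAScanResult:
    """Sliding-window RSA scan output over the drama block.

    ``window_starts`` are 0-based seconds from drama onset; each window is
    the half-open interval [start, start+window_len).  ``intervals`` are the
    merged runs of >= min_run consecutive FDR-significant windows, reported
    as (start, end, peak_tau, min_q) with end = last start + window length.
    """

    modality: str
    model_kind: str
    window_len: float
    step: float
    alpha: float
    min_run: int
    window_starts: np.ndarray
    tau: np.ndarray
    p: np.ndarray
    q: np.ndarray
    reject: np.ndarray
    intervals: list[tuple[float, float, float, float]]

    def windows_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": self.window_starts,
                "tau": self.tau,
                "p": self.p,
                "q": self.q,
                "significant": self.reject,
            }
        )

    def intervals_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.intervals, columns=["start_s", "end_s", "peak_tau", "min_q"]
        ).assign(modality=self.modality)[
            ["modality", "start_s", "end_s", "peak_tau", "min_q"]
        ]


def _significant_runs(reject: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_run, as [first, last] index pairs."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(reject):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_run:
                runs.append((start, i - 1))
            start = None
    if start is not None and len(reject) - start >= min_run:
        runs.append((start, len(reject) - 1))
    return runs


class _BinaryModelTau:
    """Kendall tau-b against a binary model vector, with a permutation null.

    Cells of an RDM are not independent observations — every subject
    contributes to n-1 cells — so the analytic tau p-value is grossly
    anticonservative for model comparisons.  Because the model vector takes
    only the values {1, 2}, tau-b against it reduces to a tie-corrected
    rank-sum comparison of the model-2 cells versus the rest, which makes a
    subject-relabeling permutation null cheap: each permutation only
    re-selects which cells count as model-2, and the statistic is a sum of
    precomputed mid-ranks.
    """

    def __init__(
        self,
        labels: pd.DataFrame,
        kind: Literal["strong", "weak"],
        n_permutations: int,
        seed: int,
    ) -> None:
        order = subject_order(labels)
        n = len(order)
        meta = labels.set_index("subject_id").loc[order]
        is_sp = (meta["group"] == "SP").to_numpy()
        dyad = meta["dyad_id"].to_numpy(dtype=object)

        cell_index = np.full((n, n), -1, dtype=np.int64)
        i, j = np.tril_indices(n, k=-1)
        cell_index[i, j] = cell_index[j, i] = np.arange(i.size)
        self.n_cells = i.size

        def model2_cells(subject_of_position: np.ndarray) -> np.ndarray:
            """Cell indices that are model-2 when position p holds subject
            subject_of_position[p] (identity = observed labelling)."""
            if kind == "weak":
                pos = np.flatnonzero(is_sp)
                subj = subject_of_position[pos]
                a, b = np.meshgrid(subj, subj, indexing="ij")
                keep = np.tril(np.ones((pos.size, pos.size), dtype=bool), k=-1)
                return cell_index[a[keep], b[keep]]
            cells = []
            for d in pd.unique(dyad[~pd.isna(dyad)]):
                pa, pb = np.flatnonzero(dyad == d)
                cells.append(cell_index[subject_of_position[pa], subject_of_position[pb]])
            return np.asarray(cells, dtype=np.int64)

        identity = np.arange(n)
        self.obs_cells = model2_cells(identity)
        rng = np.random.default_rng(seed)
        self.perm_cells = np.vstack(
            [model2_cells(rng.permutation(n)) for _ in range(n_permutations)]
        )

    def statistic(self, ranks: np.ndarray, valid: np.ndarray, tx: float,
                  cells: np.ndarray) -> np.ndarray:
        """tau-b for one or many model-2 cell selections (rows of ``cells``)."""
        cells = np.atleast_2d(cells)
        vmask = valid[cells]
        n2 = vmask.sum(axis=1).astype(float)
        nv = float(valid.sum())
        n1 = nv - n2
        r2 = np.where(vmask, ranks[cells], 0.0).sum(axis=1)
        c_minus_d = 2.0 * (r2 - n2 * (n2 + 1) / 2.0) - n1 * n2
        n0 = nv * (nv - 1) / 2.0
        ty = n1 * (n1 - 1) / 2.0 + n2 * (n2 - 1) / 2.0
        denom = np.sqrt(np.clip((n0 - tx) * (n0 - ty), 0.0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, c_minus_d / denom, np.nan)

    def tau_and_p(self, vec: np.ndarray) -> tuple[float, float]:
        valid = ~np.isnan(vec)
        nv = int(valid.sum())
        if nv < 3:
            return float("nan"), float("nan")
        ranks = np.zeros(vec.size)
        ranks[valid] = stats.rankdata(vec[valid])
        _, tie_counts = np.unique(vec[valid], return_counts=True)
        tx = float((tie_counts * (tie_counts - 1) / 2.0).sum())
        tau = float(self.statistic(ranks, valid, tx, self.obs_cells)[0])
        if np.isnan(tau):
            return tau, float("nan")
        null = self.statistic(ranks, valid, tx, self.perm_cells)
        null = null[~np.isnan(null)]
        n_extreme = int(np.sum(np.abs(null) >= np.abs(tau) - 1e-12))
        p = (1.0 + n_extreme) / (1.0 + null.size)
        return tau, float(p)


def rsa_scan(
    cohort: Cohort,
    modality: str,
    model: Literal["strong", "weak"] = "weak",
    window_len: float = 20.0,
    step: float = 1.0,
    alpha: float = 0.05,
    min_run: int = 2,
    n_permutations: int = 1000,
    perm_seed: int = 0,
) -> RSAScanResult:
    """Sliding-window RSA of the drama block against a coupling model.

    For every window (length ``window_len`` s, step ``step`` s, 0-based from
    drama onset) the data RDM is correlated with the model RDM via Kendall
    tau-b.  The per-window two-sided p-value comes from a subject-relabeling
    permutation null (``n_permutations`` draws, shared across windows) —
    the appropriate null for model-RDM comparisons, since RDM cells sharing
    a subject are dependent and the analytic tau p-value is far too
    liberal.  p-values are BH-FDR adjusted across all windows and intervals
    of >= ``min_run`` consecutive significant windows are reported in
    stimulus (drama) seconds.
    """
    timeline = cohort.timeline
    if window_len > timeline.drama_duration:
        raise ValueError("window is longer than the drama block")
    order = subject_order(cohort.labels)
    tester = _BinaryModelTau(cohort.labels, model, n_permutations, perm_seed)

    rate = timeline.sample_rate
    data = cohort.modality_matrix(modality, order)
    d0 = int(round(timeline.drama_start * rate))
    drama = data[:, d0 : d0 + int(round(timeline.drama_duration * rate))]

    n_windows = int(np.floor((timeline.drama_duration - window_len) / step)) + 1
    win_n = int(round(window_len * rate))
    step_n = int(round(step * rate))
    starts = np.arange(n_windows) * step
    tau = np.empty(n_windows)
    p = np.empty(n_windows)
    tril = np.tril_indices(len(order), k=-1)
    for w in range(n_windows):
        seg = drama[:, w * step_n : w * step_n + win_n]
        dmat = _distance_matrix(seg)
        tau[w], p[w] = tester.tau_and_p(dmat[tril])

    q, reject = bh_fdr(p, alpha)
    intervals = []
    for i0, i1 in _significant_runs(reject, min_run):
        seg_tau = tau[i0 : i1 + 1]
        peak = seg_tau[np.nanargmax(np.abs(seg_tau))]
        intervals.append(
            (
                float(starts[i0]),
                float(starts[i1] + window_len),
                float(peak),
                float(np.nanmin(q[i0 : i1 + 1])),
            )
        )
    return RSAScanResult(
        modality=modality,
        model_kind=model,
        window_len=window_len,
        step=step,
        alpha=alpha,
        min_run=min_run,
        window_starts=starts,
        tau=tau,
        p=p,
        q=q,
        reject=reject,
        intervals=intervals,
    )


def localizer_rdms(
    cohort: Cohort, modality: str, window_len: float = 20.0
) -> list[tuple[str, RDM]]:
    """One RDM per localizer clip, windowed from clip onset.

    The window runs ``window_len`` s from each clip's onset (default 20 s:
    the 12 s clip plus 8 s of the following silence, capturing lingering
    responses).
    """
    out = []
    for seg in cohort.timeline.clip_segments():
        out.append((seg.label, build_rdm(cohort, modality, (seg.start, window_len))))
    return out
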