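"""Per-hybridization detection calls and normalized expression signals.

Two independent paths share the cluster definitions:

* the detection path computes, per cluster and hybridization, discrimination
  scores ``R_i = (PM_i - MM_i) / (PM_i + MM_i)`` and a one-sided Wilcoxon
  signed-rank p-value against the discrimination threshold tau, thresholded
  into present / marginal / absent;
* the signal path quantile-normalizes the clustered PM cells across
  hybridizations, takes log2, and summarizes each cluster by a two-way
  median polish, giving one log2 expression signal per hybridization.

The signed-rank p-value is exact (full enumeration over sign assignments,
mid-ranks for ties, zeros dropped) up to n = 20 scores and switches to the
normal approximation with continuity and tie correction above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from isoprobe.cluster_builder import ProbeCluster
from isoprobe.io_formats import IntensityMatrix

EXACT_ENUMERATION_MAX_N = 20


@dataclass(frozen=True)
class CallThresholds:
    """Detection-call thresholds.

    ``alpha_present``/``alpha_absent`` bound the present and absent regions
    of the p-value scale; ``tau`` is the discrimination threshold the scores
    are tested against (default 0.015, the conventional value for this
    detection algorithm).
    """

    alpha_present: float = 0.05
    alpha_absent: float = 0.065
    tau: float = 0.015

    def __post_init__(self) -> None:
        if not (0 < self.alpha_present < self.alpha_absent < 1):
            raise ValueError(
                f"need 0 < alpha_present < alpha_absent < 1, got "
                f"{self.alpha_present}, {self.alpha_absent}"
            )
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")


@dataclass(frozen=True)
class DetectionCall:
    accession: str
    hybridization_id: str
    p_value: float
    status: Literal["present", "marginal", "absent"]


@dataclass(frozen=True)
class ExpressionSignal:
    accession: str
    hybridization_id: str
    signal: float  # log2 scale


def discrimination_scores(pm: np.ndarray, mm: np.ndarray) -> np.ndarray:
    """R_i = (PM_i - MM_i) / (PM_i + MM_i), elementwise, in (-1, 1)."""
    pm = np.asarray(pm, dtype=float)
    mm = np.asarray(mm, dtype=float)
    if pm.shape != mm.shape:
        raise ValueError(f"PM shape {pm.shape} != MM shape {mm.shape}")
    if np.any(pm <= 0) or np.any(mm <= 0):
        raise ValueError("intensities must be positive")
    return (pm - mm) / (pm + mm)


def detection_p(scores: Sequence[float], tau: float = 0.015) -> float:
    """One-sided signed-rank p-value for "median(R - tau) > 0".

    Differences equal to zero are dropped; tied absolute differences take
    mid-ranks.  For n <= 20 remaining scores the null distribution is
    enumerated exactly over all 2^n sign assignments; beyond that the
    normal approximation with continuity correction and tie-corrected
    variance is used.  All scores equal to tau degenerate to p = 1.
    """
    d = np.asarray(scores, dtype=float) - tau
    if d.size == 0:
        raise ValueError("need at least one score")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0  # degenerate: every score equals tau
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_ENUMERATION_MAX_N:
        # all subset sums of the rank vector, by doubling
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        # count >= with a tolerance: rank sums are multiples of 0.5
        return float(np.mean(sums >= w_plus - 1e-9))
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))


def call_detection(
    p_value: float, thresholds: CallThresholds = CallThresholds()
) -> str:
    """Threshold a detection p-value: present <= 0.05 < marginal < 0.065 <= absent."""
    if not (0 <= p_value <= 1):
        raise ValueError(f"p-value {p_value} outside [0, 1]")
    if p_value <= thresholds.alpha_present:
        return "present"
    if p_value >= thresholds.alpha_absent:
        return "absent"
    return "marginal"


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force every column onto the mean distribution of order statistics.

    After normalization each column's sorted values equal the across-column
    mean of order statistics; within-column ranks are preserved, with tied
    values averaged.  A single column is returned unchanged.  Idempotent.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("need a 2-D matrix with >= 1 column")
    if x.shape[1] == 1:
        return x.copy()
    n = x.shape[0]
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")
        # fractional (tied) ranks interpolate between adjacent order stats
        out[:, j] = np.interp(ranks, positions, ref)
    return out


def background_correct_conv(matrix: np.ndarray) -> np.ndarray:
    """Exponential-signal / normal-noise convolution background correction.

    Per column, noise parameters (mu, sigma) are estimated from the density
    mode and the spread below it, the signal rate alpha from the mean excess
    above the mode; the posterior-mean signal given the observed intensity
    is returned.  Output is strictly positive.  Optional — the default
    signal path runs quantile + log2 + median polish only.
    """
    x = np.asarray(matrix, dtype=float)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        # density mode via a coarse histogram of the lower bulk
        hist, edges = np.histogram(col, bins=max(10, col.size // 10))
        mu = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        below = col[col < mu]
        sigma = float(np.sqrt(np.mean((below - mu) ** 2))) if below.size else 1.0
        sigma = max(sigma, 1e-6)
        above = col[col > mu]
        alpha = 1.0 / max(float(np.mean(above - mu)) if above.size else 1.0, 1e-6)
        a = col - mu - sigma**2 * alpha
        b = sigma
        out[:, j] = a + b * stats.norm.pdf(a / b) / np.maximum(
            stats.norm.cdf(a / b), 1e-300
        )
    return np.maximum(out, 2.0 ** -20)


def median_polish(
    x: np.ndarray, tol: float = 0.01, max_iter: int = 10
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Two-way median polish: overall + row + column effects + residuals.

    Rows are swept first.  Iteration stops when the largest absolute change
    across effects in a sweep falls below ``tol`` or after ``max_iter``
    sweeps.
    """
    z = np.asarray(x, dtype=float).copy()
    nr, nc = z.shape
    overall = 0.0
    row_eff = np.zeros(nr)
    col_eff = np.zeros(nc)
    for _ in range(max_iter):
        delta = 0.0
        rmed = np.median(z, axis=1)
        z -= rmed[:, None]
        row_eff += rmed
        delta = max(delta, float(np.max(np.abs(rmed))) if nr else 0.0)
        cmed_r = np.median(row_eff)
        row_eff -= cmed_r
        overall += cmed_r
        cmed = np.median(z, axis=0)
        z -= cmed[None, :]
        col_eff += cmed
        delta = max(delta, float(np.max(np.abs(cmed))) if nc else 0.0)
        rmed_c = np.median(col_eff)
        col_eff -= rmed_c
        overall += rmed_c
        if delta < tol:
            break
    return overall, row_eff, col_eff, z


def summarize_rma(cluster: ProbeCluster, log2_matrix: np.ndarray,
                  hybridization_ids: Sequence[str]) -> list[ExpressionSignal]:
    """Median-polish summary of one cluster's log2 PM matrix.

    ``log2_matrix`` is probes x hybridizations (quantile-normalized, log2).
    The reported signal per hybridization is overall effect + hybridization
    (column) effect; a 1-probe cluster degenerates to that probe's values.
    """
    x = np.asarray(log2_matrix, dtype=float)
    if x.shape != (cluster.n_probe_pairs, len(hybridization_ids)):
        raise ValueError(
            f"cluster {cluster.accession}: matrix shape {x.shape} != "
            f"({cluster.n_probe_pairs}, {len(hybridization_ids)})"
        )
    if cluster.n_probe_pairs == 1:
        signals = x[0]
    else:
        overall, _, col_eff, _ = median_polish(x)
        signals = overall + col_eff
    return [
        ExpressionSignal(cluster.accession, hid, float(s))
        for hid, s in zip(hybridization_ids, signals)
    ]


def call_matrix(
    clusters: Sequence[ProbeCluster],
    matrix: IntensityMatrix,
    thresholds: CallThresholds = CallThresholds(),
    detection: bool = True,
    background: Literal["none", "rma-conv"] = "none",
) -> tuple[list[DetectionCall], list[ExpressionSignal]]:
    """All detection calls and expression signals for a cluster set.

    The detection path uses raw PM/MM pairs per cluster per hybridization;
    the signal path quantile-normalizes the union of clustered PM cells
    across hybridizations, then median-polishes each cluster.  A cluster
    cell missing from the matrix is a hard error.  ``detection=False``
    (PM-only arrays) skips the call path.
    """
    for c in clusters:
        for pm_cell, mm_cell, *_ in c.probe_pairs:
            if not matrix.has_cell(pm_cell):
                raise KeyError(f"cluster {c.accession}: PM cell {pm_cell} not in matrix")
            if detection and not matrix.has_cell(mm_cell):
                raise KeyError(f"cluster {c.accession}: MM cell {mm_cell} not in matrix")

    calls: list[DetectionCall] = []
    if detection:
        for c in clusters:
            pm = np.array([matrix.row(p[0]) for p in c.probe_pairs])
            mm = np.array([matrix.row(p[1]) for p in c.probe_pairs])
            scores = discrimination_scores(pm, mm)  # probes x hybs
            for j, hid in enumerate(matrix.hybridization_ids):
                p = detection_p(scores[:, j], thresholds.tau)
                calls.append(
                    DetectionCall(c.accession, hid, p, call_detection(p, thresholds))
                )

    # signal path: quantile normalization over the union of clustered PM cells
    pm_cells: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for c in clusters:
        for pm_cell, *_ in c.probe_pairs:
            if pm_cell not in seen:
                seen.add(pm_cell)
                pm_cells.append(pm_cell)
    signals: list[ExpressionSignal] = []
    if pm_cells:
        raw = np.array([matrix.row(cell) for cell in pm_cells])
        if background == "rma-conv":
            raw = background_correct_conv(raw)
        norm = np.log2(quantile_normalize(raw))
        row_of = {cell: i for i, cell in enumerate(pm_cells)}
        for c in clusters:
            sub = norm[[row_of[p[0]] for p in c.probe_pairs]]
            signals.extend(summarize_rma(c, sub, matrix.hybridization_ids))
    return calls, signals


def write_calls_tsv(calls: Sequence[DetectionCall], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "accession": c.accession,
                "hybridization_id": c.hybridization_id,
                "p_value": f"{c.p_value:.6e}",
                "status": c.status,
            }
            for c in calls
        ],
        columns=["accession", "hybridization_id", "p_value", "status"],
    ).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> list[DetectionCall]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        DetectionCall(str(r.accession), str(r.hybridization_id),
                      float(r.p_value), str(r.status))
        for r in df.itertuples(index=False)
    ]


def write_signals_tsv(signals: Sequence[ExpressionSignal], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "accession": s.accession,
                "hybridization_id": s.hybridization_id,
                "signal": f"{s.signal:.6g}",
            }
            for s in signals
        ],
        columns=["accession", "hybridization_id", "signal"],
    ).to_csv(path, sep="\t", index=False)


def read_signals_tsv(path) -> list[ExpressionSignal]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ExpressionSignal(str(r.accession), str(r.hybridization_id), float(r.signal))
        for r in df.itertuples(index=False)
    ]
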