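"""Consensus expression profiles and two-group differential analysis.

The consensus call reduces a transcript's per-hybridization detection calls
to transcribed / not-detected / no-call by majority between present and
absent calls; percentage detection is the majority share (marginal calls
count in the denominator but never vote).  Reliability ranks bin that
consistency into deciles, rank 1 anchored at >= 90%.  Between two groups,
differential regulation compares mean log2 signals by a t-test (Welch by
default), and differential detection flags transcripts transcribed in one
group but not detected in the other.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from isoprobe.expression_calling import DetectionCall, ExpressionSignal
from isoprobe.io_formats import GroupDesign


@dataclass(frozen=True)
class ConsensusProfile:
    accession: str
    status: Literal["transcribed", "not-detected", "no-call"]
    n_present: int
    n_absent: int
    n_marginal: int
    pct_detection: float
    reliability_rank: int
    gene_symbol: str = ""


@dataclass(frozen=True)
class DifferentialRecord:
    """Group comparison for one transcript: means, fold change, t-test.

    ``fold_change`` is the signed log2 difference mean_A - mean_B; writers
    also display the linear ratio 2^|fold_change|.
    """

    accession: str
    gene_symbol: str
    mean_signal_a: float
    mean_signal_b: float
    fold_change: float
    p_value: float
    status: Literal["up", "down", "not-significant"]


def consensus_call(
    statuses: Sequence[str],
    accession: str = "",
    gene_symbol: str = "",
    marginal_in_denominator: bool = True,
) -> ConsensusProfile:
    """Majority consensus across one transcript's detection calls.

    transcribed if present calls outnumber absent ones, not-detected for the
    reverse, no-call on a tie.  pct_detection = 100 * max(present, absent) /
    total, where total includes marginal calls by default (configurable).
    """
    if len(statuses) == 0:
        raise ValueError("need at least one detection call")
    valid = {"present", "absent", "marginal"}
    bad = set(statuses) - valid
    if bad:
        raise ValueError(f"unknown detection statuses: {sorted(bad)}")
    n_p = sum(s == "present" for s in statuses)
    n_a = sum(s == "absent" for s in statuses)
    n_m = sum(s == "marginal" for s in statuses)
    if n_p > n_a:
        status = "transcribed"
    elif n_a > n_p:
        status = "not-detected"
    else:
        status = "no-call"
    total = n_p + n_a + n_m if marginal_in_denominator else max(n_p + n_a, 1)
    pct = 100.0 * max(n_p, n_a) / total
    return ConsensusProfile(
        accession=accession,
        status=status,
        n_present=n_p,
        n_absent=n_a,
        n_marginal=n_m,
        pct_detection=pct,
        reliability_rank=reliability_rank(pct),
        gene_symbol=gene_symbol,
    )


def reliability_rank(consistency_pct: float) -> int:
    """Decile rank of consensus consistency: 1 for >= 90%, down to 10 for < 10%."""
    if not (0 <= consistency_pct <= 100):
        raise ValueError(f"consistency {consistency_pct} outside [0, 100]")
    if consistency_pct >= 90:
        return 1
    return min(10, 10 - math.floor(consistency_pct / 10))


def consensus_profiles(
    calls: Sequence[DetectionCall],
    hybridization_ids: Sequence[str] | None = None,
    gene_symbols: dict[str, str] | None = None,
) -> list[ConsensusProfile]:
    """Consensus per transcript over a set of hybridizations.

    ``hybridization_ids`` restricts the calls considered (e.g. one group);
    default: all calls present in the input.
    """
    keep = set(hybridization_ids) if hybridization_ids is not None else None
    by_acc: dict[str, list[str]] = {}
    for c in calls:
        if keep is not None and c.hybridization_id not in keep:
            continue
        by_acc.setdefault(c.accession, []).append(c.status)
    symbols = gene_symbols or {}
    return [
        consensus_call(sts, accession=acc, gene_symbol=symbols.get(acc, ""))
        for acc, sts in sorted(by_acc.items())
    ]


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test; closed form with Welch-Satterthwaite df."""
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0:
        return (0.0, 1.0) if diff == 0 else (math.inf, 0.0)
    t = diff / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, float(2 * stats.t.sf(abs(t), df))


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if sp2 == 0:
        return (0.0, 1.0) if diff == 0 else (math.inf, 0.0)
    t = diff / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, float(2 * stats.t.sf(abs(t), na + nb - 2))


def differential_regulation(
    signals: Sequence[ExpressionSignal],
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    gene_symbols: dict[str, str] | None = None,
    test: Literal["welch", "pooled"] = "welch",
) -> list[DifferentialRecord]:
    """Per-transcript group means, fold change and t-test between two groups.

    Each group needs >= 2 hybridizations.  Significance is p <= alpha; up
    means group A's mean log2 signal exceeds group B's.  Output is sorted by
    ascending p-value.
    """
    for name, group in (("A", group_a), ("B", group_b)):
        if len(group) < 2:
            raise ValueError(f"group {name} has fewer than 2 hybridizations")
    set_a, set_b = set(group_a), set(group_b)
    by_acc: dict[str, tuple[list[float], list[float]]] = {}
    for s in signals:
        slot = by_acc.setdefault(s.accession, ([], []))
        if s.hybridization_id in set_a:
            slot[0].append(s.signal)
        if s.hybridization_id in set_b:
            slot[1].append(s.signal)
    symbols = gene_symbols or {}
    records: list[DifferentialRecord] = []
    for acc, (va, vb) in sorted(by_acc.items()):
        if len(va) < 2 or len(vb) < 2:
            raise ValueError(
                f"transcript {acc}: signals missing for some group members"
            )
        a, b = np.asarray(va), np.asarray(vb)
        _, p = _welch_t(a, b) if test == "welch" else _pooled_t(a, b)
        fc = float(a.mean() - b.mean())
        if p <= alpha:
            status = "up" if fc > 0 else "down"
        else:
            status = "not-significant"
        records.append(
            DifferentialRecord(
                accession=acc,
                gene_symbol=symbols.get(acc, ""),
                mean_signal_a=float(a.mean()),
                mean_signal_b=float(b.mean()),
                fold_change=fc,
                p_value=p,
                status=status,
            )
        )
    records.sort(key=lambda r: (r.p_value, r.accession))
    return records


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up q-values (optional extra column; plain p <= alpha rules the
    default decision)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass(frozen=True)
class DifferentialDetection:
    accession: str
    status_a: str
    status_b: str
    pct_detection_a: float
    pct_detection_b: float
    flagged: bool


def differential_detection(
    profiles_a: Sequence[ConsensusProfile],
    profiles_b: Sequence[ConsensusProfile],
) -> list[DifferentialDetection]:
    """Flag transcripts transcribed in one group and not-detected in the other.

    Profiles with no-call in either group are reported but never flagged.
    Both inputs must cover the same transcript set.
    """
    a_by = {p.accession: p for p in profiles_a}
    b_by = {p.accession: p for p in profiles_b}
    if set(a_by) != set(b_by):
        raise ValueError("group profiles cover different transcript sets")
    out = []
    for acc in sorted(a_by):
        pa, pb = a_by[acc], b_by[acc]
        flagged = {pa.status, pb.status} == {"transcribed", "not-detected"}
        out.append(
            DifferentialDetection(
                accession=acc,
                status_a=pa.status,
                status_b=pb.status,
                pct_detection_a=pa.pct_detection,
                pct_detection_b=pb.pct_detection,
                flagged=flagged,
            )
        )
    return out


def pairwise_comparisons(design: GroupDesign) -> list[tuple[str, str]]:
    """All unordered group pairs, in group-definition order."""
    names = list(design.groups)
    if len(names) < 2:
        raise ValueError(
            "differential analysis needs >= 2 groups "
            "(a single group supports absolute calls only)"
        )
    return list(itertools.combinations(names, 2))
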