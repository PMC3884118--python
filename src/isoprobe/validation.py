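"""Candidate-transcript selection and concordance against wet-lab calls.

Selection picks transcripts worth independent verification: genes with
multiple isoforms, externally confirmed as transcribed with good
reliability, whose isoforms show opposite detection status in the array
profiles, each backed by enough probe pairs.  Concordance summarizes how
per-sample observed statuses (e.g. RT-PCR outcomes, T / ND per sample)
agree with the pipeline's per-hybridization call profile, categorizing
each transcript as complete agreement, partial, or contradiction, plus
pair-level agreement rates over (transcript, sample) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from isoprobe.profiles import ConsensusProfile

VALID_OBSERVED = {"T", "ND"}


@dataclass(frozen=True)
class HybridizationSummary:
    """Call counts across hybridizations, the "T-ND-M" triple notation.

    ``31-0-0`` reads: transcribed in all 31 hybridizations, no not-detected
    and no marginal calls.
    """

    accession: str
    n_transcribed: int
    n_notdetected: int
    n_marginal: int

    def __post_init__(self) -> None:
        if min(self.n_transcribed, self.n_notdetected, self.n_marginal) < 0:
            raise ValueError(f"{self.accession}: negative call count")

    @property
    def uniform(self) -> bool:
        """True when every hybridization agrees: no dissenting or marginal calls."""
        nz = [
            n
            for n in (self.n_transcribed, self.n_notdetected, self.n_marginal)
            if n > 0
        ]
        return len(nz) == 1 and self.n_marginal == 0

    @property
    def majority_status(self) -> str:
        if self.n_transcribed > self.n_notdetected:
            return "T"
        if self.n_notdetected > self.n_transcribed:
            return "ND"
        return "no-call"

    def __str__(self) -> str:
        return f"{self.n_transcribed}-{self.n_notdetected}-{self.n_marginal}"


@dataclass
class ConcordanceTable:
    """Per-transcript categories and summary agreement percentages.

    Percentages are rounded to the nearest integer for display parity with
    the usual reporting style; raw fractions are retained alongside.
    """

    categories: dict[str, str]  # accession -> category
    pct_complete: int
    pct_partial: int
    pct_contradiction: int
    experiment_agreement_pct: int  # over all (transcript, sample) pairs
    uniform_agreement_pct: int  # restricted to uniform pipeline profiles
    uniform_transcribed_agreement_pct: int  # restricted to uniform 'T' profiles
    n_transcripts: int
    n_pairs: int


@dataclass(frozen=True)
class Candidate:
    accession: str
    gene_id: str
    partner_accessions: tuple[str, ...]
    status: str
    reliability_rank: int
    n_probe_pairs: int


def select_candidates(
    profiles: Sequence[ConsensusProfile],
    gene_of: Mapping[str, str],
    n_probe_pairs: Mapping[str, int],
    gene_calls: Mapping[str, tuple[str, int]],
    min_probe_pairs: int = 6,
    gene_rank_max: int = 5,
    transcript_rank_max: int = 3,
) -> list[Candidate]:
    """Apply the four candidate-selection criteria.

    A transcript is retained iff (a) its gene codes for >= 2 transcripts;
    (b) the gene is externally called transcribed with reliability rank <=
    ``gene_rank_max``; (c) among the gene's transcripts, one is transcribed
    and another not-detected, both with rank <= ``transcript_rank_max``; and
    (d) its own cluster has >= ``min_probe_pairs`` probe pairs.

    ``gene_calls`` maps gene id -> (status, rank) from an external
    gene-level resource; ``n_probe_pairs`` maps accession -> cluster size.
    """
    by_gene: dict[str, list[ConsensusProfile]] = {}
    for p in profiles:
        if p.accession not in gene_of:
            raise KeyError(f"transcript {p.accession} missing from gene map")
        by_gene.setdefault(gene_of[p.accession], []).append(p)

    candidates: list[Candidate] = []
    for gene, members in sorted(by_gene.items()):
        if len(members) < 2:
            continue  # (a)
        call = gene_calls.get(gene)
        if call is None:
            continue
        g_status, g_rank = call
        if g_status != "transcribed" or g_rank > gene_rank_max:
            continue  # (b)
        reliable_t = [
            m for m in members
            if m.status == "transcribed" and m.reliability_rank <= transcript_rank_max
        ]
        reliable_nd = [
            m for m in members
            if m.status == "not-detected" and m.reliability_rank <= transcript_rank_max
        ]
        if not reliable_t or not reliable_nd:
            continue  # (c)
        for m in reliable_t + reliable_nd:
            if m.accession not in n_probe_pairs:
                raise KeyError(f"no probe-pair count for {m.accession}")
            if n_probe_pairs[m.accession] < min_probe_pairs:
                continue  # (d)
            partners = tuple(
                o.accession for o in members if o.accession != m.accession
            )
            candidates.append(
                Candidate(
                    accession=m.accession,
                    gene_id=gene,
                    partner_accessions=partners,
                    status=m.status,
                    reliability_rank=m.reliability_rank,
                    n_probe_pairs=n_probe_pairs[m.accession],
                )
            )
    candidates.sort(key=lambda c: (c.gene_id, c.accession))
    return candidates


def concordance_summary(
    pipeline: Sequence[HybridizationSummary],
    observed: Mapping[str, Sequence[str]],
) -> ConcordanceTable:
    """Categorize transcripts by agreement between profile and observations.

    complete_agreement: the pipeline profile is uniform and every observed
    sample matches it; contradiction: uniform and every sample mismatches;
    partial: everything else (including any non-uniform profile).  Summary
    percentages: per-category shares over transcripts; pair-level agreement
    over all (transcript, sample) pairs, the same restricted to uniform
    profiles, and restricted further to uniformly-transcribed profiles.
    Agreement for a pair means the sample status equals the profile's
    majority status.
    """
    categories: dict[str, str] = {}
    n_pairs = agree_pairs = 0
    uni_pairs = uni_agree = 0
    unit_pairs = unit_agree = 0
    for summary in pipeline:
        samples = observed.get(summary.accession)
        if not samples:
            raise ValueError(f"no observed samples for {summary.accession}")
        bad = set(samples) - VALID_OBSERVED
        if bad:
            raise ValueError(
                f"{summary.accession}: unknown status tokens {sorted(bad)}"
            )
        majority = summary.majority_status
        matches = [s == majority for s in samples]
        if summary.uniform and all(matches):
            cat = "complete_agreement"
        elif summary.uniform and not any(matches):
            cat = "contradiction"
        else:
            cat = "partial"
        categories[summary.accession] = cat
        n_pairs += len(samples)
        agree_pairs += sum(matches)
        if summary.uniform:
            uni_pairs += len(samples)
            uni_agree += sum(matches)
            if majority == "T":
                unit_pairs += len(samples)
                unit_agree += sum(matches)

    n = len(categories)
    if n == 0:
        raise ValueError("no transcripts to summarize")

    def pct(num: int, den: int) -> int:
        return round(100 * num / den) if den else 0

    counts = {c: sum(v == c for v in categories.values()) for c in
              ("complete_agreement", "partial", "contradiction")}
    return ConcordanceTable(
        categories=categories,
        pct_complete=pct(counts["complete_agreement"], n),
        pct_partial=pct(counts["partial"], n),
        pct_contradiction=pct(counts["contradiction"], n),
        experiment_agreement_pct=pct(agree_pairs, n_pairs),
        uniform_agreement_pct=pct(uni_agree, uni_pairs),
        uniform_transcribed_agreement_pct=pct(unit_agree, unit_pairs),
        n_transcripts=n,
        n_pairs=n_pairs,
    )


def read_observed_tsv(path) -> dict[str, list[str]]:
    """Observed-status TSV: accession <TAB> sample id <TAB> status (T/ND)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"accession", "sample_id", "status"}
    if not need.issubset(df.columns):
        raise ValueError(f"observed TSV must have columns {sorted(need)}")
    out: dict[str, list[str]] = {}
    for r in df.itertuples(index=False):
        if r.status not in VALID_OBSERVED:
            raise ValueError(f"unknown status token {r.status!r}")
        out.setdefault(r.accession, []).append(r.status)
    return out


def summaries_from_calls(calls) -> list[HybridizationSummary]:
    """Build T-ND-M triples from per-hybridization detection calls."""
    by_acc: dict[str, list[str]] = {}
    for c in calls:
        by_acc.setdefault(c.accession, []).append(c.status)
    return [
        HybridizationSummary(
            accession=acc,
            n_transcribed=sum(s == "present" for s in sts),
            n_notdetected=sum(s == "absent" for s in sts),
            n_marginal=sum(s == "marginal" for s in sts),
        )
        for acc, sts in sorted(by_acc.items())
    ]
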