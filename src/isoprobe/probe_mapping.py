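"""Exact full-length matching of 25-mer probes against a transcript set.

A short oligo probe has an alignment with 100% identity over 100% of its
length if and only if it occurs verbatim as a substring of a transcript (on
either strand).  Exact k-mer lookup is therefore a faithful replacement for
an aligner run at that operating point, and is what this module implements:
an index of every 25-mer in the reference, probe lookup on one or both
strands, and classification of probes into transcript-specific / shared /
unmatched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from isoprobe.io_formats import ProbeSequenceRecord, TranscriptRecord

logger = logging.getLogger(__name__)

WORD_LENGTH = 25

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ProbeHit:
    """One exact, full-length occurrence of a probe on a transcript.

    ``start``/``end`` are 1-based inclusive transcript coordinates;
    identity and coverage are always 100% by construction.
    """

    probe: ProbeSequenceRecord
    accession: str
    start: int
    end: int
    orientation: Literal["forward", "revcomp"]
    identity_pct: float = 100.0
    coverage_pct: float = 100.0


@dataclass(frozen=True)
class ProbeClassification:
    """Reliability and specificity status of one probe.

    A "good" probe has at least one perfect full-length hit; a
    transcript-specific probe is a good probe whose hits all fall on one
    transcript accession (possibly at several positions, flagged).
    """

    probe: ProbeSequenceRecord
    is_good: bool
    specificity: Literal["transcript_specific", "shared", "unmatched"]
    hit_accessions: tuple[str, ...]
    multi_position: bool = False


@dataclass
class MatchIndex:
    """Exact-match index: every N-free 25-mer -> list of (accession, start)."""

    word_length: int
    occurrences: dict[str, list[tuple[str, int]]]
    skipped_transcripts: list[str]


def build_match_index(
    transcripts: Sequence[TranscriptRecord], word_length: int = WORD_LENGTH
) -> MatchIndex:
    """Index every distinct ``word_length``-mer occurring in any transcript.

    Words containing N are excluded (an ambiguous base can never certify a
    100%-identity match).  Transcripts shorter than ``word_length`` are
    skipped with a warning and recorded in the skip report.
    """
    occurrences: dict[str, list[tuple[str, int]]] = {}
    skipped: list[str] = []
    for t in transcripts:
        seq = t.sequence
        if len(seq) < word_length:
            logger.warning(
                "transcript %s shorter than %d nt; skipped", t.accession, word_length
            )
            skipped.append(t.accession)
            continue
        for i in range(len(seq) - word_length + 1):
            word = seq[i : i + word_length]
            if "N" in word:
                continue
            occurrences.setdefault(word, []).append((t.accession, i + 1))
    return MatchIndex(
        word_length=word_length, occurrences=occurrences, skipped_transcripts=skipped
    )


def map_probes(
    probes: Sequence[ProbeSequenceRecord],
    index: MatchIndex,
    orientation_mode: Literal["given", "revcomp", "both"] = "both",
) -> list[ProbeHit]:
    """Emit a hit for every exact full-length occurrence of each probe.

    ``orientation_mode`` selects which strand(s) to search, mirroring a
    two-strand nucleotide alignment; a probe containing N can never match.
    Hits are sorted by (probe cell, accession, start).
    """
    hits: list[ProbeHit] = []
    w = index.word_length
    for probe in probes:
        seq = probe.sequence
        queries: list[tuple[str, str]] = []
        if orientation_mode in ("given", "both"):
            queries.append((seq, "forward"))
        if orientation_mode in ("revcomp", "both"):
            queries.append((revcomp(seq), "revcomp"))
        probe_hits = []
        for query, orientation in queries:
            for accession, start in index.occurrences.get(query, ()):
                probe_hits.append(
                    ProbeHit(
                        probe=probe,
                        accession=accession,
                        start=start,
                        end=start + w - 1,
                        orientation=orientation,
                    )
                )
        probe_hits.sort(key=lambda h: (h.accession, h.start, h.orientation))
        hits.extend(probe_hits)
    return hits


def classify_probes(
    probes: Sequence[ProbeSequenceRecord], hits: Iterable[ProbeHit]
) -> list[ProbeClassification]:
    """Classify each probe from its hit set.

    transcript_specific: good and all hits on one accession (a probe hitting
    one accession at several positions stays specific, with the
    multi-position flag raised); shared: hits on >= 2 accessions; unmatched:
    no hits.
    """
    by_probe: dict[tuple[int, int], list[ProbeHit]] = {}
    for h in hits:
        by_probe.setdefault(h.probe.cell, []).append(h)
    out: list[ProbeClassification] = []
    for probe in probes:
        phits = by_probe.get(probe.cell, [])
        accessions = tuple(sorted({h.accession for h in phits}))
        if not phits:
            spec = "unmatched"
        elif len(accessions) == 1:
            spec = "transcript_specific"
        else:
            spec = "shared"
        out.append(
            ProbeClassification(
                probe=probe,
                is_good=bool(phits),
                specificity=spec,
                hit_accessions=accessions,
                multi_position=len(accessions) == 1 and len(phits) > 1,
            )
        )
    return out


def read_hits_tsv(path, probes: Sequence[ProbeSequenceRecord]) -> list[ProbeHit]:
    """Rebuild hits from a hits TSV; probes supply the sequences the table
    does not repeat."""
    import pandas as pd

    by_cell = {p.cell: p for p in probes}
    df = pd.read_csv(path, sep="\t", comment="#")
    hits = []
    for r in df.itertuples(index=False):
        cell = (int(r.probe_x), int(r.probe_y))
        if cell not in by_cell:
            raise KeyError(f"hit references unknown probe cell {cell}")
        hits.append(
            ProbeHit(
                probe=by_cell[cell],
                accession=str(r.accession),
                start=int(r.match_start),
                end=int(r.match_end),
                orientation=str(r.orientation),
            )
        )
    return hits


def write_classes_tsv(classes: Sequence[ProbeClassification], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "probe_x": c.probe.x,
                "probe_y": c.probe.y,
                "is_good": int(c.is_good),
                "specificity": c.specificity,
                "hit_accessions": ";".join(c.hit_accessions),
                "multi_position": int(c.multi_position),
            }
            for c in classes
        ],
        columns=[
            "probe_x", "probe_y", "is_good", "specificity",
            "hit_accessions", "multi_position",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_classes_tsv(path, probes: Sequence[ProbeSequenceRecord]) -> list[ProbeClassification]:
    import pandas as pd

    by_cell = {p.cell: p for p in probes}
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        cell = (int(r.probe_x), int(r.probe_y))
        if cell not in by_cell:
            raise KeyError(f"classification references unknown probe cell {cell}")
        accs = tuple(a for a in str(r.hit_accessions).split(";") if a)
        out.append(
            ProbeClassification(
                probe=by_cell[cell],
                is_good=bool(int(r.is_good)),
                specificity=str(r.specificity),
                hit_accessions=accs,
                multi_position=bool(int(r.multi_position)),
            )
        )
    return out


def write_hits_tsv(hits: Sequence[ProbeHit], path) -> None:
    """Hits table mirroring an alignment-result display: probe cell, matched
    start/end on the transcript, percent identity and coverage."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "probe_x": h.probe.x,
                "probe_y": h.probe.y,
                "probeset_id": h.probe.probeset_id,
                "accession": h.accession,
                "match_start": h.start,
                "match_end": h.end,
                "orientation": h.orientation,
                "identity_pct": h.identity_pct,
                "coverage_pct": h.coverage_pct,
            }
            for h in hits
        ],
        columns=[
            "probe_x", "probe_y", "probeset_id", "accession", "match_start",
            "match_end", "orientation", "identity_pct", "coverage_pct",
        ],
    ).to_csv(path, sep="\t", index=False)
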