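"""Assembly of transcript-specific probe clusters.

Probes that match exactly one transcript accession are grouped into one
probe cluster per transcript — the transcript-level replacement for the
array's original probe sets.  Genes are annotated as single-transcript
(STG) or multi-transcript (MTG), a minimum-probe threshold filters weakly
covered transcripts, and a size-distribution table summarizes the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from isoprobe.probe_mapping import ProbeClassification, ProbeHit

logger = logging.getLogger(__name__)

#: probe pair tuple: (PM cell, MM cell, match start, match end, orientation)
ProbePair = tuple[tuple[int, int], tuple[int, int], int, int, str]


@dataclass
class GeneModel:
    """Mapping gene -> transcript accessions, with STG/MTG class per gene."""

    transcripts_by_gene: dict[str, set[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for gene, accs in self.transcripts_by_gene.items():
            for acc in accs:
                if acc in seen:
                    raise ValueError(
                        f"transcript {acc} assigned to both {seen[acc]} and {gene}"
                    )
                seen[acc] = gene
        self._gene_of = seen

    @classmethod
    def from_transcripts(cls, transcripts: Iterable) -> "GeneModel":
        by_gene: dict[str, set[str]] = {}
        for t in transcripts:
            gene = t.gene_id or t.accession  # orphan transcripts become their own gene
            by_gene.setdefault(gene, set()).add(t.accession)
        return cls(transcripts_by_gene=by_gene)

    def gene_of(self, accession: str) -> str:
        return self._gene_of[accession]

    def gene_class(self, gene_id: str) -> str:
        return "STG" if len(self.transcripts_by_gene[gene_id]) == 1 else "MTG"

    def __contains__(self, accession: str) -> bool:
        return accession in self._gene_of


@dataclass
class ProbeCluster:
    """The probe pairs interrogating one transcript.

    Each pair holds the PM cell, its MM partner cell, the match interval on
    the transcript (1-based inclusive) and the matched orientation.
    """

    accession: str
    gene_id: str
    gene_class: str
    probe_pairs: list[ProbePair]

    def __post_init__(self) -> None:
        if len(self.probe_pairs) < 1:
            raise ValueError(f"cluster {self.accession}: no probe pairs")

    @property
    def n_probe_pairs(self) -> int:
        return len(self.probe_pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeCluster):
            return NotImplemented
        return (
            self.accession == other.accession
            and self.gene_id == other.gene_id
            and self.gene_class == other.gene_class
            and self.probe_pairs == other.probe_pairs
        )


def build_clusters(
    classifications: Sequence[ProbeClassification],
    hits: Sequence[ProbeHit],
    gene_model: GeneModel,
    min_probes: int = 1,
    mm_offset: tuple[int, int] | None = (0, 1),
    max_y: int | None = None,
) -> list[ProbeCluster]:
    """Group transcript-specific probes into one cluster per transcript.

    The MM partner cell is derived from the PM cell by ``mm_offset``
    (default ``(0, 1)``: same column, next row, the standard 3' array
    geometry).  ``mm_offset=None`` declares a PM-only array: MM coordinates
    are set equal to PM and detection calls are unavailable downstream.
    Pairs whose MM cell would fall past ``max_y`` are dropped with a
    warning.  Transcripts with fewer than ``min_probes`` surviving pairs are
    excluded.
    """
    specific_cells = {
        c.probe.cell for c in classifications if c.specificity == "transcript_specific"
    }
    pairs_by_acc: dict[str, list[ProbePair]] = {}
    seen_pair: set[tuple[tuple[int, int], str]] = set()
    for h in hits:
        cell = h.probe.cell
        if cell not in specific_cells:
            continue
        if h.accession not in gene_model:
            raise KeyError(f"accession {h.accession} absent from gene model")
        if (cell, h.accession) in seen_pair:
            continue  # multi-position probe: keep first occurrence only
        seen_pair.add((cell, h.accession))
        if mm_offset is None:
            mm_cell = cell
        else:
            mm_cell = (cell[0] + mm_offset[0], cell[1] + mm_offset[1])
            if max_y is not None and mm_cell[1] > max_y:
                logger.warning(
                    "probe at %s: MM cell %s off the array edge; pair dropped",
                    cell, mm_cell,
                )
                continue
        pairs_by_acc.setdefault(h.accession, []).append(
            (cell, mm_cell, h.start, h.end, h.orientation)
        )
    clusters: list[ProbeCluster] = []
    for acc in sorted(pairs_by_acc):
        pairs = sorted(pairs_by_acc[acc], key=lambda p: (p[2], p[0]))
        if len(pairs) < min_probes:
            continue
        gene = gene_model.gene_of(acc)
        clusters.append(
            ProbeCluster(
                accession=acc,
                gene_id=gene,
                gene_class=gene_model.gene_class(gene),
                probe_pairs=pairs,
            )
        )
    return clusters


def write_gene_map(model: GeneModel, path) -> None:
    lines = ["gene_id\taccession"]
    for gene in sorted(model.transcripts_by_gene):
        for acc in sorted(model.transcripts_by_gene[gene]):
            lines.append(f"{gene}\t{acc}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_map(path) -> GeneModel:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    by_gene: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        by_gene.setdefault(str(r.gene_id), set()).add(str(r.accession))
    return GeneModel(transcripts_by_gene=by_gene)


#: histogram rows: exact sizes 1..11, then an open ">=12" bin
SIZE_BINS = [str(k) for k in range(1, 12)] + [">=12"]


def cluster_stats(clusters: Sequence[ProbeCluster]) -> pd.DataFrame:
    """Probes-per-cluster distribution split by STG/MTG, with totals.

    Rows are cluster sizes 1, 2, ..., 11 and >=12; the trailing rows carry
    the marginals: total transcripts, total genes, and total
    transcript-specific probes, per gene class.
    """
    counts = {b: {"STG": 0, "MTG": 0} for b in SIZE_BINS}
    totals = {
        "total_transcripts": {"STG": 0, "MTG": 0},
        "total_genes": {"STG": set(), "MTG": set()},
        "total_probes": {"STG": 0, "MTG": 0},
    }
    for c in clusters:
        b = str(c.n_probe_pairs) if c.n_probe_pairs < 12 else ">=12"
        counts[b][c.gene_class] += 1
        totals["total_transcripts"][c.gene_class] += 1
        totals["total_genes"][c.gene_class].add(c.gene_id)
        totals["total_probes"][c.gene_class] += c.n_probe_pairs
    rows = [
        {"probes_per_cluster": b, "STG": counts[b]["STG"], "MTG": counts[b]["MTG"]}
        for b in SIZE_BINS
    ]
    rows.append(
        {
            "probes_per_cluster": "total_transcripts",
            "STG": totals["total_transcripts"]["STG"],
            "MTG": totals["total_transcripts"]["MTG"],
        }
    )
    rows.append(
        {
            "probes_per_cluster": "total_genes",
            "STG": len(totals["total_genes"]["STG"]),
            "MTG": len(totals["total_genes"]["MTG"]),
        }
    )
    rows.append(
        {
            "probes_per_cluster": "total_probes",
            "STG": totals["total_probes"]["STG"],
            "MTG": totals["total_probes"]["MTG"],
        }
    )
    return pd.DataFrame(rows, columns=["probes_per_cluster", "STG", "MTG"])
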