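"""Readers and writers for every file format the pipeline touches.

All formats are plain text (FASTA, TSV, YAML).  Parsers validate strictly and
fail with the offending record named; every writer has a paired reader such
that ``read(write(x)) == x``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = set("ACGTN")

#: default FASTA header dialect: ">ACC.V|GENEID|SYMBOL" (gene fields optional)
HEADER_RE = re.compile(
    r"^(?P<accession>[^|\s]+)(?:\|(?P<gene_id>[^|\s]*)(?:\|(?P<gene_symbol>[^|\s]*))?)?$"
)


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One reference transcript: versioned accession, gene ids, DNA sequence."""

    accession: str
    gene_id: str
    gene_symbol: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise FormatError(
                f"transcript {self.accession}: non-IUPAC characters {sorted(bad)}"
            )
        if len(self.sequence) == 0:
            raise FormatError(f"transcript {self.accession}: empty sequence")


@dataclass(frozen=True)
class ProbeSequenceRecord:
    """One 25-mer PM probe with its array cell coordinates.

    ``x`` is the cell column and ``y`` the cell row (0-based), following the
    Affymetrix probe-tab convention; the MM partner of a PM probe sits at
    ``(x, y + 1)``.
    """

    probeset_id: str
    x: int
    y: int
    interrogation_position: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != 25:
            raise FormatError(
                f"probe at cell ({self.x},{self.y}): sequence length "
                f"{len(self.sequence)} != 25"
            )
        if self.x < 0 or self.y < 0 or self.interrogation_position < 0:
            raise FormatError(
                f"probe at cell ({self.x},{self.y}): negative coordinate"
            )

    @property
    def cell(self) -> tuple[int, int]:
        return (self.x, self.y)


@dataclass
class IntensityMatrix:
    """Raw probe-cell fluorescence values, cells x hybridizations.

    Stands in for the probe-level content of raw array files; rows are
    addressed by ``(x, y)`` cell coordinates and columns by hybridization id.
    """

    hybridization_ids: list[str]
    cells: list[tuple[int, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cells), len(self.hybridization_ids)):
            raise FormatError(
                f"intensity matrix shape {self.values.shape} does not match "
                f"{len(self.cells)} cells x {len(self.hybridization_ids)} hybridizations"
            )
        if len(set(self.hybridization_ids)) != len(self.hybridization_ids):
            raise FormatError("duplicate hybridization ids")
        if len(set(self.cells)) != len(self.cells):
            raise FormatError("duplicate cells")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise FormatError("intensity values must be positive and finite")
        self._cell_index = {c: i for i, c in enumerate(self.cells)}

    def row(self, cell: tuple[int, int]) -> np.ndarray:
        """Values across hybridizations for one cell; KeyError if absent."""
        return self.values[self._cell_index[cell]]

    def has_cell(self, cell: tuple[int, int]) -> bool:
        return cell in self._cell_index


@dataclass
class GroupDesign:
    """Named, ordered groups of hybridization ids."""

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, members in self.groups.items():
            if len(members) == 0:
                raise FormatError(f"group {name!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"group {name!r} lists a hybridization twice")

    def validate_against(self, matrix_ids: Sequence[str]) -> None:
        known = set(matrix_ids)
        for name, members in self.groups.items():
            missing = [m for m in members if m not in known]
            if missing:
                raise FormatError(
                    f"group {name!r} references unknown hybridizations: {missing}"
                )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, header_re: re.Pattern = HEADER_RE) -> list[TranscriptRecord]:
    """Read reference transcripts from FASTA.

    Headers follow the pipe-delimited dialect ``>ACC.V|GENEID|SYMBOL``;
    a bare ``>ACC.V`` is accepted with empty gene fields.  Sequences are
    uppercased; duplicate accessions and non-IUPAC characters are hard errors.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description.split()[0] if rec.description else rec.id
        m = header_re.match(header)
        if m is None:
            raise FormatError(f"unparseable FASTA header: {header!r}")
        accession = m.group("accession")
        if accession in seen:
            raise FormatError(f"duplicate accession {accession!r}")
        seen.add(accession)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"transcript {accession}: empty sequence")
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise FormatError(
                f"transcript {accession}: non-IUPAC characters {sorted(bad)}"
            )
        records.append(
            TranscriptRecord(
                accession=accession,
                gene_id=m.group("gene_id") or "",
                gene_symbol=m.group("gene_symbol") or "",
                sequence=seq,
            )
        )
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.accession}|{r.gene_id}|{r.gene_symbol}",
            description="",
        )
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Probe table

_PROBE_COLUMN_ALIASES = {
    "probeset_id": {"probeset_id", "probe_set_name", "probe set name", "probeset"},
    "x": {"x", "probe_x", "probe x"},
    "y": {"y", "probe_y", "probe y"},
    "interrogation_position": {
        "interrogation_position",
        "probe_interrogation_position",
        "probe interrogation position",
    },
    "sequence": {"sequence", "probe_sequence", "probe sequence"},
}


def read_probe_table(path: str | Path) -> list[ProbeSequenceRecord]:
    """Read an Affymetrix probe-tab style TSV of 25-mer PM probes.

    Column headers are matched case-insensitively against common aliases.
    Sequence length != 25 or a duplicate (x, y) cell is a hard error naming
    the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    colmap: dict[str, str] = {}
    lowered = {c.lower().strip(): c for c in df.columns}
    for canonical, aliases in _PROBE_COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                colmap[canonical] = lowered[alias]
                break
        else:
            raise FormatError(f"probe table missing a {canonical!r} column")
    records: list[ProbeSequenceRecord] = []
    seen_cells: set[tuple[int, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # row 1 = header
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        seq = str(d[colmap["sequence"]]).upper().strip()
        if len(seq) != 25:
            raise FormatError(f"probe table row {i}: sequence length {len(seq)} != 25")
        try:
            x = int(d[colmap["x"]])
            y = int(d[colmap["y"]])
            ipos = int(d[colmap["interrogation_position"]])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"probe table row {i}: non-integer coordinate") from exc
        if (x, y) in seen_cells:
            raise FormatError(f"probe table row {i}: duplicate cell ({x},{y})")
        seen_cells.add((x, y))
        records.append(
            ProbeSequenceRecord(
                probeset_id=str(d[colmap["probeset_id"]]),
                x=x,
                y=y,
                interrogation_position=ipos,
                sequence=seq,
            )
        )
    return records


def write_probe_table(records: Iterable[ProbeSequenceRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "probe_set_name": r.probeset_id,
                "x": r.x,
                "y": r.y,
                "interrogation_position": r.interrogation_position,
                "sequence": r.sequence,
            }
            for r in records
        ],
        columns=["probe_set_name", "x", "y", "interrogation_position", "sequence"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Intensity matrix

def read_intensity_matrix(path: str | Path) -> IntensityMatrix:
    """Read a cells-x-hybridizations TSV; first column holds "X:Y" addresses."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise FormatError("intensity matrix needs an address column and >=1 hybridization")
    addr_col = df.columns[0]
    hyb_ids = [str(c) for c in df.columns[1:]]
    cells: list[tuple[int, int]] = []
    for addr in df[addr_col]:
        try:
            xs, ys = str(addr).split(":")
            cells.append((int(xs), int(ys)))
        except ValueError as exc:
            raise FormatError(f"malformed cell address {addr!r}") from exc
    values = df.iloc[:, 1:].to_numpy()
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric intensity value: {exc}") from exc
    bad = np.argwhere(~(np.isfinite(values) & (values > 0)))
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"non-positive intensity at cell {cells[i][0]}:{cells[i][1]} "
            f"column {hyb_ids[j]!r}"
        )
    return IntensityMatrix(hybridization_ids=hyb_ids, cells=cells, values=values)


def write_intensity_matrix(matrix: IntensityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.values, columns=matrix.hybridization_ids,
    )
    df.insert(0, "cell", [f"{x}:{y}" for x, y in matrix.cells])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Cluster definition file (transcript-level probe-set definitions)

CLUSTER_COLUMNS = [
    "accession",
    "gene_id",
    "gene_class",
    "pm_x",
    "pm_y",
    "mm_x",
    "mm_y",
    "match_start",
    "match_end",
    "orientation",
]


def write_cluster_definition(
    clusters: Sequence["ProbeCluster"],  # noqa: F821 (cluster_builder type)
    path: str | Path,
    reference_name: str = "unknown",
    header_lines: Sequence[str] = (),
) -> None:
    """Write transcript-specific probe clusters as a probe-set definition TSV.

    The file plays the role of a chip definition file: it maps array cells to
    transcript-level probe sets.  A ``#``-prefixed header block records probe
    length, reference set name and tool version.
    """
    from isoprobe import __version__

    lines = [
        "# isoprobe cluster definition",
        "# probe_length=25",
        f"# reference={reference_name}",
        f"# version={__version__}",
    ]
    lines.extend(f"# {h}" for h in header_lines)
    lines.append("\t".join(CLUSTER_COLUMNS))
    for c in clusters:
        for pair in c.probe_pairs:
            (pm_x, pm_y), (mm_x, mm_y), start, end, orientation = pair
            lines.append(
                "\t".join(
                    map(
                        str,
                        [c.accession, c.gene_id, c.gene_class, pm_x, pm_y,
                         mm_x, mm_y, start, end, orientation],
                    )
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_cluster_definition(path: str | Path) -> list["ProbeCluster"]:  # noqa: F821
    from isoprobe.cluster_builder import ProbeCluster

    rows: list[dict] = []
    header: list[str] | None = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            if fields != CLUSTER_COLUMNS:
                raise FormatError(
                    f"cluster definition line {lineno}: unexpected columns {fields}"
                )
            header = fields
            continue
        if len(fields) != len(CLUSTER_COLUMNS):
            raise FormatError(f"cluster definition line {lineno}: malformed row")
        rows.append(dict(zip(CLUSTER_COLUMNS, fields)))
    if header is None and rows:
        raise FormatError("cluster definition has rows but no header")

    by_acc: dict[str, list[dict]] = {}
    order: list[str] = []
    for r in rows:
        if r["accession"] not in by_acc:
            order.append(r["accession"])
            by_acc[r["accession"]] = []
        by_acc[r["accession"]].append(r)
    clusters = []
    for acc in order:
        group = by_acc[acc]
        try:
            pairs = [
                (
                    (int(r["pm_x"]), int(r["pm_y"])),
                    (int(r["mm_x"]), int(r["mm_y"])),
                    int(r["match_start"]),
                    int(r["match_end"]),
                    r["orientation"],
                )
                for r in group
            ]
        except ValueError as exc:
            raise FormatError(f"cluster definition: malformed row for {acc}") from exc
        clusters.append(
            ProbeCluster(
                accession=acc,
                gene_id=group[0]["gene_id"],
                gene_class=group[0]["gene_class"],
                probe_pairs=pairs,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# Results TSV

REGULATION_COLUMNS = [
    "gene_symbol", "accession", "mean_signal_a", "mean_signal_b",
    "regulation_status", "fold_change_log2", "fold_change_linear", "p_value",
]
DETECTION_COLUMNS = [
    "gene_symbol", "accession", "detection_status", "pct_detection",
]


def _sig6(v: float) -> str:
    return f"{v:.6g}"


def write_results_tsv(records: Sequence[object], path: str | Path) -> None:
    """Write differential-regulation or consensus-detection results as TSV.

    The record kind is inferred from the first record; mixing kinds in one
    call is an error.  Numbers print with 6 significant digits, p-values in
    scientific notation.
    """
    from isoprobe.profiles import ConsensusProfile, DifferentialRecord

    if not records:
        # empty: default to detection layout
        Path(path).write_text("\t".join(DETECTION_COLUMNS) + "\n")
        return
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise FormatError(f"mixed result kinds: {sorted(k.__name__ for k in kinds)}")
    kind = kinds.pop()
    lines: list[str] = []
    if kind is DifferentialRecord:
        lines.append("\t".join(REGULATION_COLUMNS))
        for r in records:
            lines.append(
                "\t".join(
                    [
                        r.gene_symbol, r.accession,
                        _sig6(r.mean_signal_a), _sig6(r.mean_signal_b),
                        r.status,
                        _sig6(r.fold_change), _sig6(2 ** abs(r.fold_change)),
                        f"{r.p_value:.6e}",
                    ]
                )
            )
    elif kind is ConsensusProfile:
        lines.append("\t".join(DETECTION_COLUMNS))
        for r in records:
            lines.append(
                "\t".join(
                    [r.gene_symbol, r.accession, r.status, _sig6(r.pct_detection)]
                )
            )
    else:
        raise FormatError(f"unsupported result kind {kind.__name__}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Group design

def read_group_design(path: str | Path) -> GroupDesign:
    """Read a group design from YAML (mapping) or TSV (group<TAB>hyb_id rows)."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise FormatError("group design YAML must map group name -> id list")
        groups = {str(k): [str(v) for v in vs] for k, vs in data.items()}
    else:
        groups = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"group design line {lineno}: expected 2 columns")
            groups.setdefault(parts[0], []).append(parts[1])
    return GroupDesign(groups=groups)


def write_group_design(design: GroupDesign, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump({k: list(v) for k, v in design.groups.items()}, sort_keys=False)
    )
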