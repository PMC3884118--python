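"""Ground-truth simulator: transcriptomes, probe sets and PM/MM intensities.

The generator emulates the pipeline's inputs with exact, known truth:

* genes carry one constitutive block shared by all their isoforms plus one
  isoform-unique block per transcript, rejection-sampled so that no 25-mer
  of a unique block occurs anywhere else in the transcriptome — probes
  drawn from unique blocks are transcript-specific by construction;
* probe sets mix transcript-specific probes (unique blocks), shared probes
  (constitutive blocks of multi-isoform genes) and decoys (transcript
  25-mers carrying 1-2 substitutions, verified to match nothing);
* intensities follow an additive background + proportional signal model:
  each probe pair shares one log-normal background draw, the PM cell adds
  the full transcript signal (abundance x probe affinity), the MM cell adds
  only a crosstalk fraction of it, and every cell gets independent
  multiplicative log-normal noise.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from isoprobe.io_formats import (
    IntensityMatrix,
    ProbeSequenceRecord,
    TranscriptRecord,
)

BASES = np.array(list("ACGT"))
WORD = 25


@dataclass
class SimulationConfig:
    """Study conditions for the simulator.  ``seed`` is mandatory.

    Intensity parameters are in raw fluorescence units: background is
    log-normal with the given log-mean/log-sd, an expressed transcript
    contributes ``signal_multiplier`` (times per-hybridization and per-probe
    log-normal variation) on top, the MM cell receives ``crosstalk`` of the
    PM signal, and every cell carries multiplicative log-normal noise.
    """

    seed: int
    n_genes: int = 30
    isoform_probs: tuple[float, ...] = (0.6, 0.3, 0.1)  # P(1), P(2), P(3) isoforms
    length_range: tuple[int, int] = (300, 1200)
    unique_block_len: int = 150
    probes_per_transcript: int = 11
    shared_probe_fraction: float = 0.25
    n_decoys: int = 20
    n_hybridizations: int = 6
    p_expressed: float = 0.5
    background_log_mean: float = math.log(100.0)
    background_log_sd: float = 0.3
    signal_multiplier: float = 500.0
    abundance_log_sd: float = 0.25
    affinity_log_sd: float = 0.3
    crosstalk: float = 0.3
    noise_sd: float = 0.15
    grid_width: int = 64
    max_retries: int = 50

    def __post_init__(self) -> None:
        if self.unique_block_len < 50:
            raise ValueError("unique blocks must be >= 50 nt to place specific probes")
        if not math.isclose(sum(self.isoform_probs), 1.0, abs_tol=1e-9):
            raise ValueError("isoform_probs must sum to 1")
        if not (0 <= self.p_expressed <= 1 and 0 <= self.crosstalk <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class TranscriptTruth:
    accession: str
    gene_id: str
    n_isoforms: int
    unique_start: int  # 1-based inclusive, on the transcript
    unique_end: int


@dataclass
class GroundTruth:
    """Everything the generator knows: regions, probe classes, expression."""

    transcripts: dict[str, TranscriptTruth] = field(default_factory=dict)
    probe_class: dict[tuple[int, int], str] = field(default_factory=dict)  # PM cell -> class
    probe_targets: dict[tuple[int, int], tuple[str, ...]] = field(default_factory=dict)
    expressed: dict[str, bool] = field(default_factory=dict)  # accession -> flag
    abundance: dict[tuple[str, str], float] = field(default_factory=dict)  # (acc, hyb)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _kmers(seq: str, k: int = WORD):
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def generate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[TranscriptRecord], GroundTruth]:
    """Generate transcripts whose unique blocks have globally unique 25-mers.

    Multi-isoform genes share a constitutive 5' block; every transcript ends
    in a unique block (single-isoform transcripts are unique throughout
    their annotated block).  Uniqueness is enforced by rejection sampling
    against all committed sequence; exhaustion of retries is a hard error.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    records: list[TranscriptRecord] = []
    committed_kmers: set[str] = set()

    def try_unique_block(length: int) -> str:
        for _ in range(config.max_retries):
            block = _random_seq(rng, length)
            kmers = list(_kmers(block))
            if len(set(kmers)) != len(kmers):
                continue
            if any(k in committed_kmers for k in kmers):
                continue
            return block
        raise RuntimeError(
            "could not sample a globally unique block; increase unique_block_len"
        )

    for g in range(config.n_genes):
        gene_id = f"G{g + 1:04d}"
        n_iso = int(rng.choice(np.arange(1, len(config.isoform_probs) + 1),
                               p=config.isoform_probs))
        lo, hi = config.length_range
        total_len = int(rng.integers(lo, hi + 1))
        const_len = 0 if n_iso == 1 else max(total_len - config.unique_block_len, 100)
        const_block = _random_seq(rng, const_len) if const_len else ""
        # constitutive k-mers are committed so later unique blocks avoid them
        committed_kmers.update(_kmers(const_block))
        for i in range(n_iso):
            accession = f"NM_{g + 1:04d}{i + 1}.1"
            u_len = (
                config.unique_block_len if n_iso > 1
                else max(total_len, config.unique_block_len)
            )
            unique_block = try_unique_block(u_len)
            committed_kmers.update(_kmers(unique_block))
            seq = const_block + unique_block
            records.append(
                TranscriptRecord(
                    accession=accession,
                    gene_id=gene_id,
                    gene_symbol=f"SYM{g + 1}",
                    sequence=seq,
                )
            )
            truth.transcripts[accession] = TranscriptTruth(
                accession=accession,
                gene_id=gene_id,
                n_isoforms=n_iso,
                unique_start=len(const_block) + 1,
                unique_end=len(seq),
            )

    # final verification: every unique-block 25-mer occurs exactly once
    # anywhere (including across constitutive/junction sequence)
    counts: dict[str, int] = {}
    for r in records:
        for k in _kmers(r.sequence):
            counts[k] = counts.get(k, 0) + 1
    for r in records:
        t = truth.transcripts[r.accession]
        block = r.sequence[t.unique_start - 1 : t.unique_end]
        if any(counts[k] != 1 for k in _kmers(block)):
            raise RuntimeError(
                f"uniqueness violated for {r.accession}; increase unique_block_len"
            )
    return records, truth


def generate_probes(
    transcripts: list[TranscriptRecord],
    truth: GroundTruth,
    config: SimulationConfig,
) -> list[ProbeSequenceRecord]:
    """Draw specific / shared / decoy probes onto a synthetic array grid.

    Specific probes come from unique blocks, shared probes from the
    constitutive block of multi-isoform genes (one draw per gene, matching
    all its isoforms), decoys are mutated transcript 25-mers verified not
    to occur (either strand) anywhere.  PM cells occupy even rows of the
    grid so each MM partner at (x, y+1) has a free cell.  Shortage of
    placeable positions produces fewer probes, recorded in the truth.
    """
    rng = np.random.default_rng(config.seed + 1)
    seqs = {t.accession: t.sequence for t in transcripts}
    probes: list[ProbeSequenceRecord] = []
    counter = 0

    def next_cell() -> tuple[int, int]:
        nonlocal counter
        x = counter % config.grid_width
        y = 2 * (counter // config.grid_width)
        counter += 1
        return x, y

    def add_probe(seq: str, probeset: str, ipos: int, cls: str,
                  targets: tuple[str, ...]) -> None:
        x, y = next_cell()
        probes.append(
            ProbeSequenceRecord(
                probeset_id=probeset, x=x, y=y,
                interrogation_position=ipos, sequence=seq,
            )
        )
        truth.probe_class[(x, y)] = cls
        truth.probe_targets[(x, y)] = targets

    by_gene: dict[str, list[str]] = {}
    for acc, t in truth.transcripts.items():
        by_gene.setdefault(t.gene_id, []).append(acc)

    for gene_id in sorted(by_gene):
        accs = sorted(by_gene[gene_id])
        n_iso = len(accs)
        n_shared = (
            round(config.shared_probe_fraction * config.probes_per_transcript)
            if n_iso > 1 else 0
        )
        n_specific = config.probes_per_transcript - n_shared
        if n_iso > 1:
            const_len = truth.transcripts[accs[0]].unique_start - 1
            n_pos = const_len - WORD + 1
            take = min(n_shared, max(n_pos, 0))
            starts = rng.choice(n_pos, size=take, replace=False) if take else []
            for s in sorted(int(v) for v in np.atleast_1d(starts)):
                add_probe(
                    seqs[accs[0]][s : s + WORD], gene_id, s + 13,
                    "shared", tuple(accs),
                )
        for acc in accs:
            t = truth.transcripts[acc]
            u0 = t.unique_start - 1
            n_pos = (t.unique_end - WORD + 1) - u0
            take = min(n_specific, max(n_pos, 0))
            starts = rng.choice(n_pos, size=take, replace=False) if take else []
            for s in sorted(int(v) + u0 for v in np.atleast_1d(starts)):
                add_probe(seqs[acc][s : s + WORD], acc, s + 13, "specific", (acc,))

    # decoys: mutated transcript words verified absent from both strands
    comp = str.maketrans("ACGT", "TGCA")
    all_seq = list(seqs.values())
    accs = sorted(seqs)
    for d in range(config.n_decoys):
        for _ in range(config.max_retries):
            acc = accs[int(rng.integers(len(accs)))]
            seq = seqs[acc]
            s = int(rng.integers(len(seq) - WORD + 1))
            word = list(seq[s : s + WORD])
            for pos in rng.choice(WORD, size=int(rng.integers(1, 3)), replace=False):
                word[pos] = str(rng.choice([b for b in "ACGT" if b != word[pos]]))
            cand = "".join(word)
            rc = cand.translate(comp)[::-1]
            if not any(cand in t or rc in t for t in all_seq):
                add_probe(cand, f"decoy{d}", s + 13, "decoy", ())
                break
        else:
            raise RuntimeError("could not sample a non-matching decoy probe")
    return probes


def simulate_intensities(
    probes: list[ProbeSequenceRecord],
    truth: GroundTruth,
    config: SimulationConfig,
) -> IntensityMatrix:
    """Simulate PM and MM cell intensities under the expression truth.

    Expression flags are drawn once per transcript and held across
    hybridizations; abundance varies log-normally per (transcript,
    hybridization).  PM and MM of a pair share one background draw, so with
    zero crosstalk and zero noise an absent transcript gives PM == MM
    exactly.
    """
    rng = np.random.default_rng(config.seed + 2)
    hyb_ids = [f"H{h + 1:02d}" for h in range(config.n_hybridizations)]
    for acc in sorted(truth.transcripts):
        truth.expressed[acc] = bool(rng.random() < config.p_expressed)
        for hid in hyb_ids:
            a = (
                config.signal_multiplier
                * float(rng.lognormal(0.0, config.abundance_log_sd))
                if truth.expressed[acc] else 0.0
            )
            truth.abundance[(acc, hid)] = a

    cells: list[tuple[int, int]] = []
    rows: list[np.ndarray] = []
    nh = config.n_hybridizations
    for p in probes:
        affinity = float(rng.lognormal(0.0, config.affinity_log_sd))
        targets = truth.probe_targets[p.cell]
        signal = np.array(
            [sum(truth.abundance[(acc, hid)] for acc in targets) for hid in hyb_ids]
        ) * affinity
        background = rng.lognormal(config.background_log_mean,
                                   config.background_log_sd, size=nh)
        noise_pm = (
            rng.lognormal(0.0, config.noise_sd, size=nh)
            if config.noise_sd > 0 else np.ones(nh)
        )
        noise_mm = (
            rng.lognormal(0.0, config.noise_sd, size=nh)
            if config.noise_sd > 0 else np.ones(nh)
        )
        pm = (background + signal) * noise_pm
        mm = (background + config.crosstalk * signal) * noise_mm
        cells.append(p.cell)
        rows.append(pm)
        cells.append((p.x, p.y + 1))
        rows.append(mm)
    return IntensityMatrix(
        hybridization_ids=hyb_ids, cells=cells, values=np.array(rows)
    )


def simulate_study(
    config: SimulationConfig,
) -> tuple[list[TranscriptRecord], list[ProbeSequenceRecord], GroundTruth, IntensityMatrix]:
    """Convenience wrapper: transcriptome + probes + intensities in one call."""
    transcripts, truth = generate_transcriptome(config)
    probes = generate_probes(transcripts, truth, config)
    matrix = simulate_intensities(probes, truth, config)
    return transcripts, probes, truth, matrix
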