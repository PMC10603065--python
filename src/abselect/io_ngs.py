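"""Sequencing-read IO, quality filtering and inline-barcode demultiplexing.

Amplicon reads carry one 8-mer barcode at each terminus (5' barcode in
sense orientation, 3' barcode read as the reverse complement of the stored
sequence).  A read is assigned to a population only when both barcodes match
within the configured mismatch budget and the best-matching population is
unique; ambiguous reads are left unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .annotation import AnnotatedClone

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BARCODE_LENGTH = 8


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRead:
    """One sequencing read with per-base Phred scores (Phred+33 on disk)."""

    read_id: str
    nt_seq: str
    phred: Sequence[int]
    population: str | None = None

    def __post_init__(self) -> None:
        if len(self.phred) != len(self.nt_seq):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.phred)} "
                f"!= sequence length {len(self.nt_seq)}"
            )


@dataclass(frozen=True)
class BarcodeSpec:
    """Barcode pair for one population; both barcodes stored in sense orientation."""

    population: str
    bc5: str
    bc3: str
    min_identity: float = 0.70
    max_mismatches: int = 2

    def __post_init__(self) -> None:
        if len(self.bc5) != BARCODE_LENGTH or len(self.bc3) != BARCODE_LENGTH:
            raise ValueError(f"barcodes must be {BARCODE_LENGTH}-mers")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must lie in [0, 1]")

    @classmethod
    def from_identity(cls, population: str, bc5: str, bc3: str,
                      min_identity: float = 0.70) -> "BarcodeSpec":
        """Derive the mismatch budget from a fractional identity threshold."""
        max_mm = int((1.0 - min_identity) * BARCODE_LENGTH)
        return cls(population, bc5, bc3, min_identity, max_mm)


@dataclass(frozen=True)
class FilterConfig:
    """Quality-filter settings.

    ``min_phred=40`` with ``fraction_required=1.0`` keeps only reads whose
    every base reaches Phred 40 (standard relation Q = -10*log10(P)).
    """

    min_phred: int = 40
    fraction_required: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_required <= 1.0:
            raise ValueError("fraction_required must lie in (0, 1]")


def read_fastq(path: str | Path) -> list[SeqRead]:
    """Read a Sanger-encoded (Phred+33) FASTQ file, preserving record order."""
    reads: list[SeqRead] = []
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            read_id = title.split()[0] if title else ""
            if len(seq) != len(qual):
                raise ValueError(
                    f"read {read_id!r}: quality length {len(qual)} "
                    f"!= sequence length {len(seq)}"
                )
            phred = np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - 33
            reads.append(SeqRead(read_id, seq.upper(), phred))
    return reads


def write_fastq(reads: Iterable[SeqRead], path: str | Path) -> None:
    with open(path, "w") as handle:
        for r in reads:
            qual = (np.asarray(r.phred, dtype=np.uint8) + 33).tobytes().decode("ascii")
            handle.write(f"@{r.read_id}\n{r.nt_seq}\n+\n{qual}\n")


def quality_filter(reads: Sequence[SeqRead], cfg: FilterConfig = FilterConfig()) -> list[SeqRead]:
    """Retain reads whose fraction of bases at >= min_phred meets the requirement.

    With the default ``fraction_required=1.0`` every base of a retained read
    has Phred >= ``min_phred`` (threshold inclusive).  Order is preserved.
    """
    retained = []
    for r in reads:
        if len(r.phred) == 0:
            continue
        phred = np.asarray(r.phred)
        n_ok = int((phred >= cfg.min_phred).sum())
        if n_ok >= cfg.fraction_required * len(phred):
            retained.append(r)
    logger.info("quality_filter retained %d/%d reads (min_phred=%d)",
                len(retained), len(reads), cfg.min_phred)
    return retained


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Sequence[SeqRead],
    barcodes: Sequence[BarcodeSpec],
    bc3_as_given: bool = False,
) -> tuple[list[SeqRead], list[SeqRead]]:
    """Assign reads to populations by terminal 8-mer barcodes.

    The 5' barcode is matched against the first 8 bases; the 3' barcode is
    matched against the last 8 bases after reverse-complementing the stored
    barcode (disable with ``bc3_as_given``).  A read is assigned to the unique
    population minimising total mismatches among those meeting both per-end
    budgets; ties are left unassigned.  Assigned reads have barcodes trimmed.
    """
    pops = [b.population for b in barcodes]
    if len(set(pops)) != len(pops):
        raise ValueError("duplicate population labels in barcode table")
    tails = {b.population: (b.bc3 if bc3_as_given else reverse_complement(b.bc3))
             for b in barcodes}

    assigned: list[SeqRead] = []
    unassigned: list[SeqRead] = []
    for r in reads:
        if len(r.nt_seq) < 2 * BARCODE_LENGTH:
            unassigned.append(r)
            continue
        head = r.nt_seq[:BARCODE_LENGTH]
        tail = r.nt_seq[-BARCODE_LENGTH:]
        candidates: list[tuple[int, str]] = []
        for b in barcodes:
            m5 = _mismatches(head, b.bc5)
            m3 = _mismatches(tail, tails[b.population])
            if m5 <= b.max_mismatches and m3 <= b.max_mismatches:
                candidates.append((m5 + m3, b.population))
        if not candidates:
            unassigned.append(r)
            continue
        candidates.sort()
        if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
            logger.info("read %s ambiguous between %s and %s; unassigned",
                        r.read_id, candidates[0][1], candidates[1][1])
            unassigned.append(r)
            continue
        trimmed = replace(
            r,
            nt_seq=r.nt_seq[BARCODE_LENGTH:-BARCODE_LENGTH],
            phred=r.phred[BARCODE_LENGTH:-BARCODE_LENGTH],
            population=candidates[0][1],
        )
        assigned.append(trimmed)
    return assigned, unassigned


def read_barcode_table(path: str | Path) -> list[BarcodeSpec]:
    """Barcode table: TSV with columns population, bc5, bc3."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"population", "bc5", "bc3"} - set(df.columns)
    if missing:
        raise ValueError(f"barcode table missing columns: {sorted(missing)}")
    return [BarcodeSpec(row.population, row.bc5, row.bc3)
            for row in df.itertuples(index=False)]


def write_barcode_table(barcodes: Sequence[BarcodeSpec], path: str | Path) -> None:
    pd.DataFrame(
        [(b.population, b.bc5, b.bc3) for b in barcodes],
        columns=["population", "bc5", "bc3"],
    ).to_csv(path, sep="\t", index=False)


# AIRR-style rearrangement table: one row per unique full-length clone per
# population.  Region columns follow AIRR *_aa naming where one exists.
_AIRR_REGION_COLS = {
    "LCDR1": "cdr1_aa_light", "LCDR2": "cdr2_aa_light", "LCDR3": "cdr3_aa_light",
    "HCDR1": "cdr1_aa_heavy", "HCDR2": "cdr2_aa_heavy", "HCDR3": "cdr3_aa_heavy",
}
_AIRR_FW_COLS = {
    "LFR1": "fwr1_aa_light", "LFR2": "fwr2_aa_light",
    "LFR3": "fwr3_aa_light", "LFR4": "fwr4_aa_light",
    "LINKER": "linker_aa",
    "HFR1": "fwr1_aa_heavy", "HFR2": "fwr2_aa_heavy",
    "HFR3": "fwr3_aa_heavy", "HFR4": "fwr4_aa_heavy",
}
AIRR_COLUMNS = (
    ["clone_id", "sequence_aa", "v_call", "population", "consensus_count",
     "liability_count"]
    + list(_AIRR_REGION_COLS.values())
    + list(_AIRR_FW_COLS.values())
)


def write_airr_table(clones: Sequence[AnnotatedClone], path: str | Path) -> None:
    rows = []
    seen: set[tuple[str, str]] = set()
    for c in clones:
        for pop, count in sorted(c.counts.items()):
            key = (c.aa_full, pop)
            if key in seen:
                raise ValueError(
                    f"duplicate (full-length, population) row: clone {c.clone_id!r}, "
                    f"population {pop!r}"
                )
            seen.add(key)
            row = {
                "clone_id": c.clone_id,
                "sequence_aa": c.aa_full,
                "v_call": c.scaffold,
                "population": pop,
                "consensus_count": count,
                "liability_count": c.liabilities,
            }
            for region, col in _AIRR_REGION_COLS.items():
                row[col] = c.cdrs[region]
            for region, col in _AIRR_FW_COLS.items():
                row[col] = c.frameworks.get(region, "")
            rows.append(row)
    pd.DataFrame(rows, columns=AIRR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_airr_table(path: str | Path) -> list[AnnotatedClone]:
    df = pd.read_csv(path, sep="\t", dtype={"population": str}, keep_default_na=False)
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rearrangement table missing mandatory columns: {missing}")
    dup = df.duplicated(subset=["sequence_aa", "population"])
    if dup.any():
        raise ValueError(
            "duplicate (full-length, population) rows: "
            f"{df.loc[dup, 'clone_id'].tolist()}"
        )
    clones: dict[str, AnnotatedClone] = {}
    for row in df.itertuples(index=False):
        clone = clones.get(row.clone_id)
        if clone is None:
            cdrs = {region: getattr(row, col) for region, col in _AIRR_REGION_COLS.items()}
            frameworks = {region: getattr(row, col)
                          for region, col in _AIRR_FW_COLS.items()
                          if getattr(row, col)}
            clone = AnnotatedClone(
                clone_id=row.clone_id,
                aa_full=row.sequence_aa,
                scaffold=row.v_call,
                cdrs=cdrs,
                frameworks=frameworks,
                counts={},
                liabilities=int(row.liability_count),
            )
            clones[row.clone_id] = clone
        clone.counts[row.population] = int(row.consensus_count)
    return list(clones.values())
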