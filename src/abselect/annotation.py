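"""scFv annotation: translation, scaffold assignment and CDR extraction.

The library is built from a small set of fixed clinical scaffolds, so the
framework amino-acid sequences flanking each CDR are known per scaffold.
Annotation therefore locates framework anchors in the translated read
(exact match first, Hamming-tolerant scan as fallback) instead of aligning
against a germline database; the CDRs are the substrings between anchors.
Coordinates are 0-based half-open on the translated chain and the scFv
layout is VL-linker-VH.

Also houses the 11-letter physicochemical reduced alphabet used by the
clustering stage and the sequence-liability motif scan.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

AA20 = "ACDEFGHIKLMNPQRSTVWY"

CDR_ORDER = ("LCDR1", "LCDR2", "LCDR3", "HCDR1", "HCDR2", "HCDR3")

ROI_NAMES = ("HCDR3", "HCDR3+LCDR3", "CDRs", "FULL")

# Smallest/largest CDR length tolerated when scanning for the next anchor.
_MIN_CDR_LEN = 2
_MAX_CDR_LEN = 40


class AnnotationError(ValueError):
    """Raised when a read cannot be annotated; ``reason`` is a short code."""

    def __init__(self, reason: str, message: str | None = None):
        super().__init__(message or reason)
        self.reason = reason


@dataclass(frozen=True)
class ScaffoldRef:
    """Fixed framework context of one germline pair (VL-linker-VH layout)."""

    name: str
    vl_frameworks: tuple[str, str, str, str]
    vh_frameworks: tuple[str, str, str, str]
    linker: str

    def __post_init__(self) -> None:
        for fr in (*self.vl_frameworks, *self.vh_frameworks):
            if not fr:
                raise ValueError(f"scaffold {self.name!r}: empty framework segment")

    def segments(self) -> list[tuple[str, str, int, int]]:
        """Anchor segments in chain order as (name, sequence, min_gap, max_gap).

        The gap is the number of residues between the previous anchor's end
        and this anchor's start: a CDR slot for framework pairs flanking a
        CDR, zero for abutting segments (FR4-linker-FR1).
        """
        vl = self.vl_frameworks
        vh = self.vh_frameworks
        cdr = (_MIN_CDR_LEN, _MAX_CDR_LEN)
        zero = (0, 0)
        return [
            ("LFR1", vl[0], 0, 0),
            ("LFR2", vl[1], *cdr),
            ("LFR3", vl[2], *cdr),
            ("LFR4", vl[3], *cdr),
            ("LINKER", self.linker, *zero),
            ("HFR1", vh[0], *zero),
            ("HFR2", vh[1], *cdr),
            ("HFR3", vh[2], *cdr),
            ("HFR4", vh[3], *cdr),
        ]

    def assemble(self, cdrs: Mapping[str, str]) -> str:
        """Full-length scFv amino-acid sequence from this scaffold and six CDRs."""
        vl, vh = self.vl_frameworks, self.vh_frameworks
        return (
            vl[0] + cdrs["LCDR1"] + vl[1] + cdrs["LCDR2"] + vl[2]
            + cdrs["LCDR3"] + vl[3] + self.linker
            + vh[0] + cdrs["HCDR1"] + vh[1] + cdrs["HCDR2"] + vh[2]
            + cdrs["HCDR3"] + vh[3]
        )


@dataclass
class AnnotatedClone:
    """One unique full-length scFv amino-acid sequence with its annotation."""

    clone_id: str
    aa_full: str
    scaffold: str
    cdrs: dict[str, str]
    frameworks: dict[str, str]
    counts: dict[str, int] = field(default_factory=dict)
    liabilities: int = 0

    def __post_init__(self) -> None:
        missing = [r for r in CDR_ORDER if not self.cdrs.get(r)]
        if missing:
            raise ValueError(f"clone {self.clone_id!r}: missing CDRs {missing}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError(f"clone {self.clone_id!r}: negative read count")

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class RoiSpec:
    """Region of interest used for counting and clustering."""

    name: str = "HCDR3"
    separator: str = "|"

    def __post_init__(self) -> None:
        if self.name not in ROI_NAMES:
            raise ValueError(f"ROI must be one of {ROI_NAMES}, got {self.name!r}")


def roi_string(clone: AnnotatedClone, spec: RoiSpec | str) -> str:
    """Deterministic ROI string: light before heavy, CDR1 < CDR2 < CDR3."""
    if isinstance(spec, str):
        spec = RoiSpec(spec)
    if spec.name == "FULL":
        return clone.aa_full
    if spec.name == "HCDR3":
        regions: tuple[str, ...] = ("HCDR3",)
    elif spec.name == "HCDR3+LCDR3":
        regions = ("LCDR3", "HCDR3")
    else:  # concatenated CDRs
        regions = CDR_ORDER
    parts = []
    for region in regions:
        value = clone.cdrs.get(region)
        if not value:
            raise ValueError(f"clone {clone.clone_id!r}: missing region {region}")
        parts.append(value)
    return spec.separator.join(parts)


# ---------------------------------------------------------------------------
# Reduced amino-acid alphabet
# ---------------------------------------------------------------------------

#: Default 11-group physicochemical partition of the 20 amino acids.  Groups
#: (lower-case so pseudo-sequences never collide with amino-acid letters):
#: aliphatic LVIM, aromatic FYW, acidic DE, amide NQ, basic KR, hydroxyl ST,
#: and singletons for A, C, G, H, P whose chemistry is not shared.
DEFAULT_GROUPS: dict[str, str] = {
    **dict.fromkeys("LVIM", "a"),
    **dict.fromkeys("FYW", "f"),
    **dict.fromkeys("DE", "d"),
    **dict.fromkeys("NQ", "n"),
    **dict.fromkeys("KR", "k"),
    **dict.fromkeys("ST", "s"),
    "A": "b", "C": "c", "G": "g", "H": "h", "P": "p",
}


@dataclass(frozen=True)
class ReducedAlphabet:
    """Total, deterministic mapping of the 20 amino acids onto group characters.

    ``passthrough`` characters (the ROI separator by default) map to
    themselves so concatenated ROI strings can be reduced directly.
    """

    mapping: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    passthrough: frozenset[str] = frozenset("|")

    def __post_init__(self) -> None:
        missing = sorted(set(AA20) - set(self.mapping))
        if missing:
            raise ValueError(f"reduced alphabet must cover all 20 amino acids; missing {missing}")
        if set(self.mapping.values()) & set(AA20):
            raise ValueError("group characters must be disjoint from amino-acid letters")

    @property
    def n_groups(self) -> int:
        return len(set(self.mapping.values()))

    def reduce(self, seq: str) -> str:
        out = []
        for ch in seq:
            if ch in self.passthrough:
                out.append(ch)
                continue
            try:
                out.append(self.mapping[ch])
            except KeyError:
                raise ValueError(f"unknown residue character {ch!r}") from None
        return "".join(out)


DEFAULT_ALPHABET = ReducedAlphabet()


def reduce_alphabet(aa_seq: str, alphabet: ReducedAlphabet = DEFAULT_ALPHABET) -> str:
    """Length-preserving reduction of an amino-acid string to pseudo-sequence space."""
    return alphabet.reduce(aa_seq)


# ---------------------------------------------------------------------------
# Sequence liabilities
# ---------------------------------------------------------------------------

#: Default developability-risk motifs scanned over the variable region:
#: deamidation (NG, NS), aspartate isomerization (DG), N-glycosylation
#: sequon (NxS/T, x != P) and acid-labile DP cleavage.
DEFAULT_LIABILITY_MOTIFS: tuple[tuple[str, str], ...] = (
    ("deamidation_NG", "NG"),
    ("deamidation_NS", "NS"),
    ("isomerization_DG", "DG"),
    ("glycosylation_NxST", "N[^P][ST]"),
    ("cleavage_DP", "DP"),
)


def count_liabilities(
    aa_seq: str,
    motifs: Iterable[tuple[str, str]] | None = None,
) -> int:
    """Count non-overlapping liability-motif matches over ``aa_seq``.

    Each motif is scanned independently, so a site can contribute to several
    motifs.  Pass ``motifs=()`` for an empty set (always 0).
    """
    if motifs is None:
        motifs = DEFAULT_LIABILITY_MOTIFS
    return sum(len(re.findall(pattern, aa_seq)) for _, pattern in motifs)


def clone_liabilities(
    clone: AnnotatedClone,
    motifs: Iterable[tuple[str, str]] | None = None,
    flag_cdr_cys: bool = True,
    flag_cdr_met: bool = True,
) -> int:
    """Liability count for a clone: motif hits over the full sequence plus
    unpaired cysteines and oxidisable methionines inside CDRs (the scaffold
    cysteine pairs live in the frameworks)."""
    n = count_liabilities(clone.aa_full, motifs)
    for region in CDR_ORDER:
        cdr = clone.cdrs[region]
        if flag_cdr_cys:
            n += cdr.count("C")
        if flag_cdr_met:
            n += cdr.count("M")
    return n


def load_liability_motifs(path: str | Path) -> list[tuple[str, str]]:
    """Liability motif config: YAML list of ``{name: ..., pattern: ...}``."""
    import yaml

    with open(path) as handle:
        entries = yaml.safe_load(handle)
    return [(e["name"], e["pattern"]) for e in entries]


# ---------------------------------------------------------------------------
# Scaffold-anchored annotation
# ---------------------------------------------------------------------------

def _locate_anchor(
    aa: str, anchor: str, lo: int, hi: int, max_mm: int
) -> tuple[int, int] | None:
    """Best start position for ``anchor`` with start in [lo, hi]; exact match
    preferred, otherwise the Hamming-minimal placement within ``max_mm``.
    Returns (start, mismatches) or None."""
    if lo < 0 or lo + len(anchor) > len(aa):
        return None
    pos = aa.find(anchor, lo, hi + len(anchor))
    if pos != -1:
        return pos, 0
    best: tuple[int, int] | None = None
    for start in range(lo, min(hi, len(aa) - len(anchor)) + 1):
        window = aa[start:start + len(anchor)]
        mm = sum(a != b for a, b in zip(window, anchor))
        if mm <= max_mm and (best is None or mm < best[1]):
            best = (start, mm)
    return best


def _try_scaffold(aa: str, scaffold: ScaffoldRef) -> tuple[float, dict, dict] | None:
    """Anchor all segments of one scaffold on translation ``aa``.

    Returns (framework identity, cdrs, frameworks) or None if any anchor
    cannot be placed."""
    cdr_names = iter(CDR_ORDER)
    cdrs: dict[str, str] = {}
    frameworks: dict[str, str] = {}
    matches = total = 0
    prev_end = 0
    for name, anchor, min_gap, max_gap in scaffold.segments():
        max_mm = max(1, len(anchor) * 3 // 10)
        hit = _locate_anchor(aa, anchor, prev_end + min_gap, prev_end + max_gap, max_mm)
        if hit is None:
            return None
        start, mm = hit
        if min_gap > 0:  # a CDR slot precedes this anchor
            if start <= prev_end:
                return None
            cdrs[next(cdr_names)] = aa[prev_end:start]
        frameworks[name] = aa[start:start + len(anchor)]
        matches += len(anchor) - mm
        total += len(anchor)
        prev_end = start + len(anchor)
    if "*" in aa[:prev_end]:
        return None
    return matches / total, cdrs, frameworks


def _frames(nt_seq: str, try_reverse: bool) -> list[str]:
    seqs = [nt_seq]
    if try_reverse:
        seqs.append(str(Seq(nt_seq).reverse_complement()))
    out = []
    for seq in seqs:
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if sub:
                out.append(str(Seq(sub).translate()))
    return out


def annotate_clone(
    nt_seq: str,
    scaffolds: Sequence[ScaffoldRef],
    min_identity: float = 0.70,
    try_reverse: bool = False,
    clone_id: str = "",
) -> AnnotatedClone:
    """Translate a read and extract scaffold call, CDRs and frameworks.

    The scaffold whose concatenated framework anchors reach maximal identity
    to the translation wins.  Raises :class:`AnnotationError` with reason
    ``frameshift`` when no reading frame is free of internal stops, or
    ``no_scaffold`` when anchors cannot be placed at >= ``min_identity``.
    """
    nt_seq = nt_seq.upper()
    frames = _frames(nt_seq, try_reverse)
    clean = [aa for aa in frames if "*" not in aa.rstrip("*")]
    if not clean:
        raise AnnotationError("frameshift", "no reading frame without internal stop codons")
    best: tuple[float, ScaffoldRef, dict, dict] | None = None
    for aa in clean:
        for scaffold in scaffolds:
            hit = _try_scaffold(aa, scaffold)
            if hit is None:
                continue
            identity, cdrs, frameworks = hit
            if best is None or identity > best[0]:
                best = (identity, scaffold, cdrs, frameworks)
    if best is None or best[0] < min_identity:
        raise AnnotationError("no_scaffold", "no scaffold reference matched the translation")
    identity, scaffold, cdrs, frameworks = best
    # rebuild the full chain in order (each CDR precedes its 3' anchor)
    parts = []
    prev_cdr = iter(CDR_ORDER)
    for name, _, min_gap, _ in scaffold.segments():
        if min_gap > 0:
            parts.append(cdrs[next(prev_cdr)])
        parts.append(frameworks[name])
    aa_full = "".join(parts)
    return AnnotatedClone(
        clone_id=clone_id,
        aa_full=aa_full,
        scaffold=scaffold.name,
        cdrs=cdrs,
        frameworks=frameworks,
    )


def annotate_reads(
    reads: Sequence,
    scaffolds: Sequence[ScaffoldRef],
    min_identity: float = 0.70,
    try_reverse: bool = False,
    liability_motifs: Iterable[tuple[str, str]] | None = None,
) -> tuple[list[AnnotatedClone], list[tuple[str, str]], dict[str, str]]:
    """Annotate demultiplexed reads and condense them into unique clones.

    Returns (clones, rejects, read_to_clone) where each clone is one unique
    full-length amino-acid sequence with per-population read counts, rejects
    are (read_id, reason) pairs, and read_to_clone maps every annotated
    read id to its clone id.  Annotation is cached per nucleotide sequence.
    """
    cache: dict[str, AnnotatedClone | str] = {}
    by_aa: dict[str, AnnotatedClone] = {}
    rejects: list[tuple[str, str]] = []
    read_aa: dict[str, str] = {}
    for read in reads:
        pop = read.population or ""
        cached = cache.get(read.nt_seq)
        if cached is None:
            try:
                cached = annotate_clone(read.nt_seq, scaffolds, min_identity, try_reverse)
            except AnnotationError as exc:
                cached = exc.reason
            cache[read.nt_seq] = cached
        if isinstance(cached, str):
            rejects.append((read.read_id, cached))
            continue
        read_aa[read.read_id] = cached.aa_full
        clone = by_aa.get(cached.aa_full)
        if clone is None:
            clone = AnnotatedClone(
                clone_id="",
                aa_full=cached.aa_full,
                scaffold=cached.scaffold,
                cdrs=dict(cached.cdrs),
                frameworks=dict(cached.frameworks),
            )
            clone.liabilities = clone_liabilities(clone, liability_motifs)
            by_aa[clone.aa_full] = clone
        clone.counts[pop] = clone.counts.get(pop, 0) + 1
    clones = sorted(by_aa.values(), key=lambda c: (-c.total_count, c.aa_full))
    for i, clone in enumerate(clones):
        clone.clone_id = f"clone_{i:06d}"
    id_of = {c.aa_full: c.clone_id for c in clones}
    read_to_clone = {rid: id_of[aa] for rid, aa in read_aa.items()}
    return clones, rejects, read_to_clone


# ---------------------------------------------------------------------------
# Scaffold reference IO (single JSON document)
# ---------------------------------------------------------------------------

def load_scaffolds(path: str | Path) -> list[ScaffoldRef]:
    with open(path) as handle:
        doc = json.load(handle)
    return [
        ScaffoldRef(
            name=entry["name"],
            vl_frameworks=tuple(entry["vl_frameworks"]),
            vh_frameworks=tuple(entry["vh_frameworks"]),
            linker=entry["linker"],
        )
        for entry in doc["scaffolds"]
    ]


def write_scaffolds(scaffolds: Sequence[ScaffoldRef], path: str | Path) -> None:
    doc = {
        "scaffolds": [
            {
                "name": s.name,
                "vl_frameworks": list(s.vl_frameworks),
                "vh_frameworks": list(s.vh_frameworks),
                "linker": s.linker,
            }
            for s in scaffolds
        ]
    }
    with open(path, "w") as handle:
        json.dump(doc, handle, indent=1)
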