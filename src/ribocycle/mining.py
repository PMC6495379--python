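"""Rule-based mining of microcin-C-like precursor peptide ORFs.

Gene clusters producing McC-like peptide-nucleotide antibiotics encode a
short ribosomally made precursor (MccA-like) next to the adenylating enzyme
gene (MccB-like).  Given an anchor CDS (an MccB homolog supplied by the
user), this module enumerates small ORFs in its neighborhood and applies the
criteria that characterize known precursors:

* hard filters — C-terminal asparagine (required for installation of the
  N-P-linked nucleotide), a strong Shine-Dalgarno (SD) sequence at a
  plausible spacer, and proximity to the anchor (default within 300 bp);
* soft preferences — same strand as, and upstream of, the anchor, which
  enter a rank score rather than excluding candidates.

Peptide utilities used downstream (length classification into the short
7-8-residue and long 17-56-residue precursor families, and monoisotopic mass
with named modifications such as the N-terminal formyl group) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from pyteomics import mass as _ptmass
from pyteomics.auxiliary import PyteomicsError

__all__ = [
    "AnchorRegion",
    "MinerConfig",
    "Orf",
    "PrecursorCandidate",
    "SDScore",
    "find_orfs",
    "score_sd",
    "mine_precursors",
    "classify_length",
    "peptide_mass",
    "register_modification",
    "MODIFICATION_DELTAS",
    "SD_CONSENSUS",
]

_TABLE11 = unambiguous_dna_by_id[11]
_STOPS = frozenset(_TABLE11.stop_codons)

#: anti-SD complement used as the ribosome-binding-site consensus
SD_CONSENSUS = "AGGAGG"

#: spacer range scanned between SD match end and the start codon, nt
SD_SPACER_RANGE = (4, 13)

#: precursor length classes observed across McC-like clusters, residues
SHORT_CLASS = (7, 8)
LONG_CLASS = (17, 56)


@dataclass(frozen=True)
class AnchorRegion:
    """MccB-homolog CDS anchoring the search, 0-based half-open, stranded."""

    sequence_id: str
    start: int
    end: int
    strand: str = "+"
    window_nt: int = 300

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("anchor interval must satisfy 0 <= start < end")
        if self.strand not in "+-":
            raise ValueError("anchor strand must be '+' or '-'")
        if self.window_nt < 0:
            raise ValueError("window_nt must be >= 0")


@dataclass(frozen=True)
class MinerConfig:
    """Tunable thresholds of the precursor miner."""

    sd_threshold: int = 4
    min_aa: int = 3
    max_aa: int = 60
    start_codons: tuple[str, ...] = ("ATG", "GTG", "TTG")
    bonus_upstream: int = 2
    bonus_same_strand: int = 3

    def __post_init__(self) -> None:
        if self.min_aa < 2:
            raise ValueError("min_aa must be >= 2")
        if self.max_aa < self.min_aa:
            raise ValueError("max_aa must be >= min_aa")
        bad = [c for c in self.start_codons if len(c) != 3 or set(c) - set("ACGT")]
        if bad:
            raise ValueError(f"invalid start codons: {bad}")


class Orf(NamedTuple):
    """Open reading frame; forward-strand 0-based half-open interval
    including the stop codon."""

    start: int
    end: int
    strand: str
    peptide: str


class SDScore(NamedTuple):
    score: int
    spacer: int
    edge: bool


@dataclass(frozen=True)
class PrecursorCandidate:
    """A neighborhood ORF passing the hard precursor filters, with rank context."""

    sequence_id: str
    start: int
    end: int
    strand: str
    peptide: str
    length_aa: int
    sd_score: int
    sd_spacer_nt: int
    sd_edge: bool
    same_strand: bool
    upstream: bool
    distance_nt: int
    rank_score: int
    length_class: str = field(default="")

    def __post_init__(self) -> None:
        if not self.length_class:
            object.__setattr__(self, "length_class", classify_length(self.length_aa))


def _translate_codons(codons: list[str]) -> str:
    return "M" + "".join(_TABLE11.forward_table[c] for c in codons[1:])


def _scan_forward(seq: str, start_codons: tuple[str, ...], min_aa: int, max_aa: int):
    """Yield (start, end_incl_stop, peptide) on the given string's own strand."""
    max_nt = 3 * max_aa
    for i in range(len(seq) - 2):
        if seq[i : i + 3] not in start_codons:
            continue
        codons: list[str] = []
        valid = True
        for j in range(i, len(seq) - 2, 3):
            codon = seq[j : j + 3]
            if "N" in codon or len(codon) < 3:
                valid = False
                break
            if codon in _STOPS:
                if valid and min_aa <= len(codons) and 3 * len(codons) <= max_nt:
                    yield i, j + 3, _translate_codons(codons)
                valid = False
                break
            codons.append(codon)
            if 3 * len(codons) > max_nt:
                valid = False
                break
        # no in-frame stop before the sequence end: ORF not emitted


def find_orfs(
    sequence: str,
    strand: str = "+",
    min_aa: int = 3,
    max_aa: int = 60,
    start_codons: tuple[str, ...] = MinerConfig.start_codons,
) -> list[Orf]:
    """Enumerate ORFs from any configured start codon to the first in-frame stop.

    Translation uses the bacterial code (table 11) with the start codon
    rendered as Met; ORFs whose span contains an ambiguous base (N) are
    voided.  Coordinates are 0-based half-open on the forward strand
    regardless of ORF strand, and include the stop codon; ``peptide`` length
    excludes the stop.  ``strand`` may be '+', '-' or 'both'.
    """
    if strand not in ("+", "-", "both"):
        raise ValueError("strand must be '+', '-' or 'both'")
    seq = sequence.upper()
    out: list[Orf] = []
    if strand in ("+", "both"):
        for s, e, pep in _scan_forward(seq, start_codons, min_aa, max_aa):
            out.append(Orf(s, e, "+", pep))
    if strand in ("-", "both"):
        rc = str(Seq(seq).reverse_complement())
        L = len(seq)
        for s, e, pep in _scan_forward(rc, start_codons, min_aa, max_aa):
            out.append(Orf(L - e, L - s, "-", pep))
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def _score_sd_coding(coding: str, start: int, consensus: str) -> SDScore:
    """Score on the coding-strand string; ``start`` indexes the start codon."""
    k = len(consensus)
    lo, hi = SD_SPACER_RANGE
    best = SDScore(-1, lo, False)
    any_edge = False
    for spacer in range(lo, hi + 1):
        w_end = start - spacer
        w_start = w_end - k
        if w_end <= 0:
            any_edge = True
            continue
        window = coding[max(w_start, 0) : w_end]
        edge = w_start < 0
        any_edge |= edge
        cons = consensus[k - len(window) :]  # right-aligned when truncated
        run = longest = 0
        for a, b in zip(window, cons):
            run = run + 1 if a == b else 0
            longest = max(longest, run)
        if longest > best.score:
            best = SDScore(longest, spacer, edge)
    if best.score < 0:
        return SDScore(0, lo, True)
    return SDScore(best.score, best.spacer, best.edge or any_edge and best.score == 0)


def score_sd(
    sequence: str,
    start_pos: int,
    strand: str = "+",
    consensus: str = SD_CONSENSUS,
) -> SDScore:
    """Shine-Dalgarno strength upstream of a start codon.

    Scans spacer offsets 4-13 nt between the end of a putative SD element and
    the start codon, scoring each window by its longest contiguous match to
    the consensus (AGGAGG by default; score 0-6).  Returns the best
    (score, spacer) with ties broken toward the smaller spacer; ``edge`` is
    set when the scan ran off the sequence end.  For strand '-',
    ``start_pos`` is the forward coordinate of the start codon's last base
    (its first base in reverse-strand reading order).
    """
    seq = sequence.upper()
    if strand == "+":
        return _score_sd_coding(seq, start_pos, consensus)
    if strand == "-":
        rc = str(Seq(seq).reverse_complement())
        return _score_sd_coding(rc, len(seq) - 1 - start_pos, consensus)
    raise ValueError("strand must be '+' or '-'")


def _orf_sd(seq: str, orf: Orf, consensus: str) -> SDScore:
    if orf.strand == "+":
        return _score_sd_coding(seq, orf.start, consensus)
    rc = str(Seq(seq).reverse_complement())
    return _score_sd_coding(rc, len(seq) - orf.end, consensus)


def _distance(a_start: int, a_end: int, start: int, end: int) -> int:
    if end <= a_start:
        return a_start - end
    if start >= a_end:
        return start - a_end
    return 0  # overlapping


def mine_precursors(
    sequence: str,
    anchor: AnchorRegion,
    config: MinerConfig | None = None,
    consensus: str = SD_CONSENSUS,
) -> list[PrecursorCandidate]:
    """Rank candidate precursor ORFs around an MccB-homolog anchor.

    Hard filters: C-terminal Asn, sd_score >= ``config.sd_threshold``, gap to
    the nearest anchor boundary <= ``anchor.window_nt``.  Soft preferences
    (same strand as the anchor, upstream of it in the anchor's orientation)
    add rank bonuses.  Candidates are sorted by rank score, then proximity,
    then coordinates; the ordering is deterministic.
    """
    cfg = config or MinerConfig()
    seq = sequence.upper()
    if anchor.end > len(seq):
        raise ValueError("anchor interval extends beyond the sequence")

    # restrict the ORF scan to the window around the anchor, with slack so
    # ORFs straddling the window edge are still seen in full
    slack = 3 * (cfg.max_aa + 2) + len(consensus) + SD_SPACER_RANGE[1]
    lo = max(0, anchor.start - anchor.window_nt - slack)
    hi = min(len(seq), anchor.end + anchor.window_nt + slack)
    region = seq[lo:hi]

    cands: list[PrecursorCandidate] = []
    for orf in find_orfs(region, "both", cfg.min_aa, cfg.max_aa, cfg.start_codons):
        start, end = orf.start + lo, orf.end + lo
        if not orf.peptide.endswith("N"):
            continue
        dist = _distance(anchor.start, anchor.end, start, end)
        if dist > anchor.window_nt:
            continue
        sd = _orf_sd(seq, Orf(start, end, orf.strand, orf.peptide), consensus)
        if sd.score < cfg.sd_threshold:
            continue
        same = orf.strand == anchor.strand
        upstream = (
            end <= anchor.start if anchor.strand == "+" else start >= anchor.end
        )
        rank = sd.score
        rank += cfg.bonus_upstream if upstream else 0
        rank += cfg.bonus_same_strand if same else 0
        cands.append(
            PrecursorCandidate(
                sequence_id=anchor.sequence_id,
                start=start,
                end=end,
                strand=orf.strand,
                peptide=orf.peptide,
                length_aa=len(orf.peptide),
                sd_score=sd.score,
                sd_spacer_nt=sd.spacer,
                sd_edge=sd.edge,
                same_strand=same,
                upstream=upstream,
                distance_nt=dist,
                rank_score=rank,
            )
        )
    cands.sort(key=lambda c: (-c.rank_score, c.distance_nt, c.start, c.end, c.strand))
    return cands


def classify_length(length_aa: int) -> str:
    """Classify a precursor length into the two observed families.

    7-8 residues -> "short" (the dominant MccA-like family), 17-56 ->
    "long"; anything else -> "other".
    """
    if length_aa < 1:
        raise ValueError("length_aa must be >= 1")
    if SHORT_CLASS[0] <= length_aa <= SHORT_CLASS[1]:
        return "short"
    if LONG_CLASS[0] <= length_aa <= LONG_CLASS[1]:
        return "long"
    return "other"


#: named monoisotopic mass deltas, Da; extend via register_modification()
MODIFICATION_DELTAS: dict[str, float] = {
    # +CHO -H on the alpha-amine = +CO
    "formyl": 27.994915,
}


def register_modification(name: str, delta_da: float) -> None:
    """Register a named monoisotopic mass delta (e.g. adenylyl, aminopropyl)."""
    MODIFICATION_DELTAS[name] = float(delta_da)


def peptide_mass(peptide: str, modifications: tuple[str, ...] | list[str] = ()) -> float:
    """Monoisotopic mass of a peptide plus named modification deltas, Da.

    The unmodified mass is the sum of residue monoisotopic masses plus one
    water, so mass(AB) = mass(A) + mass(B) - mass(H2O).  Useful for
    predicting [MH]+ species of modified precursors (add ~1.00728 for the
    proton).
    """
    try:
        m = float(_ptmass.calculate_mass(sequence=peptide.upper()))
    except PyteomicsError as exc:
        raise ValueError(f"cannot compute mass of peptide {peptide!r}: {exc}") from exc
    for name in modifications:
        if name not in MODIFICATION_DELTAS:
            raise ValueError(
                f"unknown modification {name!r}; register it with register_modification()"
            )
        m += MODIFICATION_DELTAS[name]
    return m
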