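"""Packaged DNA templates of the in vitro translation competition assay.

The three *mccA*-based templates encode the wild-type heptapeptide precursor
(A7, MRTGNAN) and two glycine/small-residue-extended variants (A11, A15);
each carries a T7 promoter (lowercase), a strong Shine-Dalgarno element, the
precursor ORF, and a downstream stem-loop.  The competitor template encodes
MFF, whose synthesis the assay mix cannot complete (Phe withheld), so it
sequesters dissociated ribosomes irreversibly.
"""

from __future__ import annotations

from .mining import AnchorRegion

A7 = (
    "ttaatacgactcactatagGTGAATTAATCACAGTAATAGGAGGGTCGAC"
    "ATGCGTACTGGTAATGCAAACTAA"
    "TGGCAAAATATAAATGTCCATTAAATGCCACCCTGTACAGGGTGGCAT"
    "ACAAATGCATTCTGCGAGGTTTATTTATGGATTATATATTGGGTCGCTATGTC"
)

A11 = (
    "ttaatacgactcactatagGTGAATTAATCACAGTAATAGGAGGGTCGAC"
    "ATGGGTGGCGGTATGCGTACTGGTAATGCAAACTAA"
    "TGGCAAAATATAAATGTCCATTAAATGCCACCCTGTACAGGGTGGCAT"
    "ACAAATGCATTCTGCGAGGTTTATTTATGGATTATATATTGGGTCGCTATGTC"
)

A15 = (
    "ttaatacgactcactatagGTGAATTAATCACAGTAATAGGAGGGTCGAC"
    "ATGGCGAGCACCGCGGGTGGCGGTATGCGTACTGGTAATGCAAACTAA"
    "TGGCAAAATATAAATGTCCATTAAATGCCACCCTGTACAGGGTGGCAT"
    "ACAAATGCATTCTGCGAGGTTTATTTATGGATTATATATTGGGTCGCTATGTC"
)

COMPETITOR = (
    "ttaatacgactcactatagGGGAATTCGGGCCCTTGTTAACAATTAAGGAAGGTATACT"
    "ATGTTTTTCTAA"
    "CTGCAGAAAAAAAAAAAAAAAAAAAAA"
)

#: template name -> (sequence, encoded peptide)
TEMPLATES: dict[str, tuple[str, str]] = {
    "A7": (A7, "MRTGNAN"),
    "A11": (A11, "MGGGMRTGNAN"),
    "A15": (A15, "MASTAGGGMRTGNAN"),
    "competitor": (COMPETITOR, "MFF"),
}

#: recycle numbers measured for the three templates in the competition assay
REPORTED_N_REC: dict[str, float] = {"A7": 71.0, "A11": 30.0, "A15": 6.0}


def template_anchor(name: str, tail_nt: int = 60) -> AnchorRegion:
    """Dummy anchor over the template's 3' tail, for mining demonstrations.

    The templates are assay constructs, not genomic loci; anchoring on the
    downstream tail lets the miner treat the precursor ORF as "upstream of
    the anchor, same strand", mimicking a real *mccA*-*mccB* arrangement.
    """
    seq = TEMPLATES[name][0]
    return AnchorRegion(
        sequence_id=name, start=len(seq) - tail_nt, end=len(seq), strand="+"
    )
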