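"""Synthetic data generation: stochastic competition assays and genomic neighborhoods.

Two generators live here.

``simulate_assay`` emulates the in vitro translation competition assay used to
measure reiterative translation of minigene mRNAs: ribosomes preloaded on the
minigene make a first peptide with probability 1, then keep recycling on the
same message; at each completed cycle the mRNA is released with probability P.
A molar excess of competitor mRNA (whose peptide cannot be completed because
one amino acid is withheld) acts as an irreversible sink for released
ribosomes, so the peptide-per-ribosome time course saturates; without the
competitor a released ribosome reinitiates immediately on excess minigene
mRNA and the yield grows linearly.  The initiator fMet pool caps total output.

``synthesize_neighborhood`` builds a random genomic region with a planted
MccB-homolog anchor CDS and, optionally, a planted precursor ORF (strong
Shine-Dalgarno at a chosen spacer, C-terminal Asn) so the precursor miner can
be tested against known ground truth.

Both are fully deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .fitting import CompetitionCurve
from .kinetics import RecyclingParams, n_of_cycles_discrete

__all__ = [
    "DEFAULT_TIMEPOINTS",
    "AssayConfig",
    "AssayTimecourse",
    "SyntheticNeighborhood",
    "simulate_assay",
    "make_competition_curve",
    "synthesize_neighborhood",
]

#: default sampling grid, minutes; denser below the fMet ceiling (~90 cycles
#: at k = 1/min with the default 90-fold fMet excess), spanning ~200 cycles
DEFAULT_TIMEPOINTS = (5.0, 10.0, 20.0, 35.0, 50.0, 65.0, 80.0, 120.0, 160.0, 200.0)

_TABLE11 = unambiguous_dna_by_id[11]


@dataclass(frozen=True)
class AssayConfig:
    """Configuration of one paired (± competitor) competition-assay simulation.

    ``competitor_excess`` and ``fmet_excess`` are fold molar excesses over the
    minigene mRNA and the active ribosomes respectively; the competitor is
    treated as an infinite irreversible sink whenever present, its excess is
    recorded for provenance only.  ``noise_cv`` is the coefficient of
    variation of multiplicative lognormal measurement noise applied per
    time point (a stand-in for HPLC peak-integration error).
    """

    params: RecyclingParams
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_ribosomes: int = 10_000
    competitor_present: bool = True
    competitor_excess: float = 10.0
    fmet_excess: float = 90.0
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size == 0 or np.any(tp < 0) or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be nonnegative and strictly increasing")
        object.__setattr__(self, "timepoints", tuple(float(t) for t in tp))
        if self.n_ribosomes < 1:
            raise ValueError("n_ribosomes must be >= 1")
        if self.competitor_excess < 0:
            raise ValueError("competitor_excess must be >= 0")
        if self.fmet_excess < 1:
            raise ValueError("fmet_excess must be >= 1 (one initiator per ribosome)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass(frozen=True)
class AssayTimecourse:
    """Paired peptide-per-active-ribosome series, with and without competitor.

    ``plateau_*`` flags mark time points where the shared fMet pool was
    exhausted and the series plateaus; such points no longer report the true
    translational yield and are excluded from fitting by default.
    """

    timepoints: np.ndarray
    with_competitor: np.ndarray
    without_competitor: np.ndarray
    plateau_with: np.ndarray
    plateau_without: np.ndarray
    config: AssayConfig

    def __len__(self) -> int:
        return len(self.timepoints)


def _simulate_condition(
    config: AssayConfig, sequestering: bool, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One reaction: mean peptides/ribosome per timepoint and plateau flags.

    Each timepoint is measured on an independent cohort of ``n_ribosomes``
    ribosomes, mirroring the assay's sampling scheme in which a separate
    aliquot is withdrawn and quenched at every time point (so Monte-Carlo
    error is independent across points rather than shared by one tracked
    cohort)."""
    P, k = config.params.P, config.params.k
    nr = config.n_ribosomes
    # completed recycling cycles by each timepoint (cycle length 1/k)
    cycles = np.floor(k * np.asarray(config.timepoints) + 1e-9).astype(np.int64)

    if sequestering:
        # release decided once per completed peptide: the number of survived
        # steps per ribosome is geometric; peptide j+1 requires surviving step j
        totals = np.array(
            [
                nr + np.minimum(rng.geometric(P, size=nr) - 1, m).sum()
                for m in cycles
            ],
            dtype=float,
        )
    else:
        # lossless instantaneous reinitiation on excess minigene mRNA
        totals = nr * (1.0 + cycles.astype(float))

    pool = config.fmet_excess * nr  # shared initiator-substrate pool
    plateau = totals > pool
    totals = np.minimum(totals, pool)
    mean = totals / nr

    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=mean.size)
        mean = mean * noise
    return mean, plateau


def simulate_assay(config: AssayConfig) -> AssayTimecourse:
    """Simulate the paired ± competitor reactions of one competition assay.

    The two reactions use independent RNG streams derived from ``config.seed``
    so each is reproducible in isolation.  If ``config.competitor_present`` is
    False the "with competitor" reaction is also run without sequestration,
    which produces data lying on the n = N line (the never-dissociates case).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_with, rng_without = (np.random.default_rng(s) for s in ss.spawn(2))
    y_with, plat_with = _simulate_condition(
        config, sequestering=config.competitor_present and config.competitor_excess > 0,
        rng=rng_with,
    )
    y_without, plat_without = _simulate_condition(config, sequestering=False, rng=rng_without)
    return AssayTimecourse(
        timepoints=np.asarray(config.timepoints, dtype=float),
        with_competitor=y_with,
        without_competitor=y_without,
        plateau_with=plat_with,
        plateau_without=plat_without,
        config=config,
    )


def expected_with_competitor(config: AssayConfig) -> np.ndarray:
    """Noise-free discrete-model expectation of the with-competitor series."""
    cycles = np.floor(
        config.params.k * np.asarray(config.timepoints, dtype=float) + 1e-9
    )
    return 1.0 + np.asarray(n_of_cycles_discrete(config.params.P, cycles))


def make_competition_curve(
    tc_with: AssayTimecourse, tc_without: AssayTimecourse | None = None
) -> CompetitionCurve:
    """Pair the two series into the (N, n) competition curve of the assay.

    ``N = without - 1`` and ``n = with - 1`` at matched time points.  When two
    timecourses are given (e.g. separately simulated reactions), only their
    common time points are used; pairs where either series hit the fMet
    plateau are kept but flagged so the fitter can exclude them.
    """
    if tc_without is None:
        tc_without = tc_with
    t_w = np.asarray(tc_with.timepoints)
    t_wo = np.asarray(tc_without.timepoints)
    iw, iwo = [], []
    for i, t in enumerate(t_w):
        j = np.flatnonzero(np.isclose(t_wo, t, rtol=0, atol=1e-9))
        if j.size:
            iw.append(i)
            iwo.append(int(j[0]))
    if not iw:
        raise ValueError("timecourses share no common time points")
    N = tc_without.without_competitor[iwo] - 1.0
    n = tc_with.with_competitor[iw] - 1.0
    plateau = tc_with.plateau_with[iw] | tc_without.plateau_without[iwo]
    return CompetitionCurve(
        N=N,
        n=n,
        plateau=plateau,
        provenance=(
            f"simulated assay seed={tc_with.config.seed} "
            f"P={tc_with.config.params.P:.6g} k={tc_with.config.params.k:.6g}"
        ),
    )


# ---------------------------------------------------------------------------
# genomic neighborhoods


@dataclass(frozen=True)
class SyntheticNeighborhood:
    """Random genomic region with a planted anchor CDS and optional precursor ORF.

    Coordinates are 0-based half-open on the forward strand; ORF intervals
    include the stop codon.  ``planted_orf`` is None for pure-background
    fixtures used to measure the miner's false-positive rate.
    """

    sequence: str
    anchor_start: int
    anchor_end: int
    anchor_strand: str
    planted_orf: tuple[int, int, str] | None
    planted_peptide: str | None
    sd_motif: str | None
    sd_spacer: int | None
    distance_to_anchor: int | None
    upstream: bool | None
    seed: int

    def ground_truth_json(self) -> str:
        d = {k: getattr(self, k) for k in (
            "anchor_start", "anchor_end", "anchor_strand", "planted_peptide",
            "sd_motif", "sd_spacer", "distance_to_anchor", "upstream", "seed",
        )}
        d["planted_orf"] = list(self.planted_orf) if self.planted_orf else None
        return json.dumps(d, indent=2, sort_keys=True)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


_STARTS = ("ATG", "GTG", "TTG")


def _random_dna_no_start(rng: np.random.Generator, length: int) -> str:
    """Random DNA avoiding start-codon trinucleotides (for planted spacers)."""
    for _ in range(1000):
        s = _random_dna(rng, length)
        if not any(s[i:i + 3] in _STARTS for i in range(max(0, length - 2))):
            return s
    raise RuntimeError("could not sample a start-codon-free spacer")


def _codon_choices() -> dict[str, list[str]]:
    aa2codons: dict[str, list[str]] = {}
    for codon, aa in _TABLE11.forward_table.items():
        aa2codons.setdefault(aa, []).append(codon)
    for v in aa2codons.values():
        v.sort()
    return aa2codons


_AA2CODONS = _codon_choices()


def back_translate(peptide: str, rng: np.random.Generator) -> str:
    """Back-translate using table 11; uniform seeded choice among synonymous
    codons, ATG forced for the initiator Met, random stop codon appended."""
    codons = ["ATG"]
    for aa in peptide[1:]:
        if aa not in _AA2CODONS:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        codons.append(str(rng.choice(_AA2CODONS[aa])))
    codons.append(str(rng.choice(sorted(_TABLE11.stop_codons))))
    return "".join(codons)


def _dummy_anchor_cds(rng: np.random.Generator, length_nt: int) -> str:
    """Placeholder MccB-homolog CDS: ATG + random sense codons + stop.

    The last sense codon is forced non-Asn so the placeholder itself never
    satisfies the precursor criteria it anchors."""
    n_codons = max(2, length_nt // 3) - 2
    sense = sorted(set(_TABLE11.forward_table) - {"AAT", "AAC"})
    body = [str(c) for c in rng.choice(sense, size=n_codons)]
    return "ATG" + "".join(body) + str(rng.choice(sorted(_TABLE11.stop_codons)))


def synthesize_neighborhood(
    peptide: str | None,
    sd_motif: str = "AGGAGG",
    spacer: int = 6,
    distance_to_anchor: int = 50,
    strand: str = "+",
    upstream: bool = True,
    seed: int = 0,
    flank: int = 60,
    anchor_len: int = 150,
) -> SyntheticNeighborhood:
    """Build a seeded random neighborhood with a planted precursor ORF.

    The planted ORF is back-translated from ``peptide`` (which must start with
    Met and end with Asn, the two residues universally conserved in MccA-like
    precursors), preceded by ``sd_motif`` at the given spacer, and placed
    ``distance_to_anchor`` nt from the anchor CDS on the requested strand
    (anchor is always on '+').  ``peptide=None`` plants nothing, yielding a
    background-plus-anchor fixture.
    """
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    if distance_to_anchor < 0:
        raise ValueError("distance_to_anchor must be >= 0")
    rng = np.random.default_rng(seed)

    if peptide is not None:
        if not (3 <= len(peptide) <= 60):
            raise ValueError("planted peptide must be 3-60 residues")
        if not peptide.endswith("N"):
            raise ValueError("planted peptide must end in Asn (N)")
        if not peptide.startswith("M"):
            raise ValueError("planted peptide must start with Met (M)")
        orf = back_translate(peptide, rng)
        cassette = sd_motif + _random_dna_no_start(rng, spacer) + orf
        if strand == "+":
            orf_off = len(sd_motif) + spacer  # offset of ORF within cassette
        else:
            cassette = str(Seq(cassette).reverse_complement())
            orf_off = 0
        orf_len = 3 * (len(peptide) + 1)
    else:
        cassette = ""
        orf_off = orf_len = 0

    anchor = _dummy_anchor_cds(rng, anchor_len)
    left = _random_dna(rng, flank)
    right = _random_dna(rng, flank)
    gap = _random_dna(rng, distance_to_anchor) if peptide is not None else ""

    if peptide is None:
        sequence = left + anchor + right
        a0 = len(left)
        planted = None
    elif upstream:
        sequence = left + cassette + gap + anchor + right
        c0 = len(left)
        a0 = c0 + len(cassette) + len(gap)
        planted = (c0 + orf_off, c0 + orf_off + orf_len, strand)
    else:
        sequence = left + anchor + gap + cassette + right
        a0 = len(left)
        c0 = a0 + len(anchor) + len(gap)
        planted = (c0 + orf_off, c0 + orf_off + orf_len, strand)

    return SyntheticNeighborhood(
        sequence=sequence,
        anchor_start=a0,
        anchor_end=a0 + len(anchor),
        anchor_strand="+",
        planted_orf=planted,
        planted_peptide=peptide,
        sd_motif=sd_motif if peptide is not None else None,
        sd_spacer=spacer if peptide is not None else None,
        distance_to_anchor=distance_to_anchor if peptide is not None else None,
        upstream=upstream if peptide is not None else None,
        seed=seed,
    )
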