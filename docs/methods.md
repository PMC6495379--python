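# Methods

## The reiterative-translation model

Short bacterial open reading frames (minigenes, roughly 2–8 codons) can be
translated repeatedly by a single ribosome that reinitiates on the same mRNA
without dissociating. `ribocycle` models one such ribosome as a discrete
renewal process at the granularity of whole peptide-synthesis cycles:

* the first peptide is completed with probability 1 (the assay preforms
  initiation complexes before elongation starts);
* each subsequent peptide requires surviving one recycling step, at which the
  mRNA is released from the ribosome with probability `P`;
* peptide bonds accumulate at rate `k` peptides per minute per mRNA-bound
  ribosome, so one cycle lasts `1/k` minutes.

Without competing mRNA a released ribosome immediately reinitiates on
another minigene copy (the minigene is in 2–5-fold excess over ribosomes and
treated as non-limiting), so the expected yield per active ribosome is
linear:

    y(t) = 1 + k·t = 1 + N

With a sequestering competitor mRNA present, release is irreversible — the
competitor carries a strong ribosome-binding site and encodes a peptide the
reaction mix cannot finish, so a ribosome that lands there never returns —
and the expected yield saturates:

    y_c(t) = 1 + ((1−P)/P)·(1 − e^(−P·k·t)) = 1 + n

Eliminating time gives the competition curve used for fitting,

    n(N) = ((1−P)/P)·(1 − e^(−P·N)),

whose asymptote is the **recycle number** `n_rec = (1−P)/P`: the expected
number of reinitiations (extra peptides) before the ribosome leaves the
message. `n_rec = 0` means the ribosome dissociates after the first peptide
(`P = 1`); the degenerate `P = 0` case is the diagonal `n = N` and is
rejected by `recycle_number` rather than returned as infinity. For small `P`
and `N`, Taylor expansion gives `n ≈ (1−P)·N ≈ N`.

The per-step derivation also has an exact discrete form,
`E[n after m cycles] = ((1−P)/P)(1 − (1−P)^m)`, implemented as
`n_of_cycles_discrete` and used to cross-check the simulator; the
exponential expression is its large-`m`, small-`P` limit. The continuous
form, which is what the fitter uses, is taken as canonical for curve
fitting. At `P = 1/72` the two differ by well under 1%; at `P = 1/7` the
discrete mean exceeds the continuous one by a few percent at intermediate
`N`, a model-mismatch that the parameter-recovery tests deliberately absorb.

All closed forms are evaluated with `expm1`-style exponentials because the
interesting regime (`P ≈ 0.01`) loses precision in a naive `1 − e^(−PN)`.

## The synthetic competition assay

`simulate_assay` emulates the radiometric in vitro competition assay that
motivates the model, with these choices:

* **Discrete cycles.** Each ribosome's number of survived release decisions
  is geometric with parameter `P`; by time `t` it has completed
  `m = ⌊k·t⌋` cycles and made `1 + min(survived, m)` peptides. The release
  decision precedes the next peptide, giving mean
  `1 + ((1−P)/P)(1−(1−P)^m)`.
* **Independent aliquots.** Each time point is measured on an independent
  cohort of `n_ribosomes` ribosomes, mirroring the assay's scheme of
  withdrawing and quenching a separate aliquot per time point; Monte-Carlo
  error is therefore independent across points rather than shared by one
  tracked cohort.
* **Competitor as a perfect sink.** Whenever competitor is present its
  10-fold molar excess is recorded for provenance but not kinetically
  modeled: sequestration is treated as instantaneous and irreversible.
* **fMet pool.** The initiator substrate is in `fmet_excess`-fold excess
  over active ribosomes (default 90, plausible range 30–90). Total peptide
  output is capped at `fmet_excess × n_ribosomes`; capped points plateau and
  are flagged, and the fitter excludes flagged pairs by default, since a
  capped `N` no longer measures translational yield.
* **Noise.** Multiplicative lognormal noise with CV `noise_cv` (default 5%)
  per time point stands in for HPLC peak-integration error; no error model
  is published for the assay, so this is a pragmatic choice, not a
  calibrated one.
* **Defaults.** `n_ribosomes = 10⁴`, `k = 1` peptide/min (so cycles equal
  minutes), sampling grid `(5, 10, 20, 35, 50, 65, 80, 120, 160, 200)` min —
  ten points spanning ~200 cycles with extra density below the fMet ceiling
  (~90 cycles), because points beyond the ceiling carry no fit information.
  The real assay's grid and replicate structure are unpublished; these are
  package choices.

What the generator does **not** emulate: transcription and its coupling to
translation, tRNA charging kinetics, factor concentrations, chromatography,
or any real measurement-error structure. Passing the recovery tests shows
the estimator works under the stated noise model at the stated sizes — not
that real HPLC data are this well behaved.

## Fitting

`fit_competition` minimizes `Σ (n_i − n(N_i; P))²` over `P ∈ [10⁻⁶, 1]` in
`(N, n)` space, where `k` cancels and is not a parameter. The 1-D objective
is scanned on an 80-point logarithmic grid and refined by bounded scalar
minimization (`xatol = 10⁻¹²`); on model-generated curves this recovers the
generating `P` to better than one part in 10⁶, and the residual surface is
unimodal. Weights are uniform by default (an inverse-variance option
`1/max(n,1)²`, matching constant-CV noise, is exposed but off). Points with
`n > N`, possible under noise, are retained unclipped — clipping would bias
`P̂` upward. `n_rec` is always reported as the exact transform `(1−P̂)/P̂`,
never separately estimated. Degenerate data are handled explicitly: a curve
on the diagonal drives `P̂` to the lower bound and is flagged
`converged = False` with an "n_rec effectively infinite" diagnostic; all-zero
`n` with positive `N` pins `P̂ = 1` (`n_rec = 0`) with a warning diagnostic.

Uncertainty comes from a case-resampling percentile bootstrap over the
(N, n) pairs (default 1000 replicates; resamples with fewer than three
distinct pairs are skipped and counted). **Known limitation:** with the
default ten-point design (seven usable pairs at small `P`) the nominal-95%
percentile interval on `n_rec` under-covers — a calibration experiment (200
simulated assays at `P = 0.1`, CV 5%, 10⁴ ribosomes) measures ~86% coverage,
because the estimator's sampling distribution is right-skewed and the
percentile method inherits that skew. The regression test asserts the
measured calibration (≥80%), not the nominal level. Users needing stricter
coverage should sample more time points below the fMet ceiling or use a
pivotal/BCa interval downstream.

Under the default conditions (CV 5%, 10⁴ ribosomes), point recovery of
`n_rec` is within ±15% in ≥90% of seeded replicates across the tested range
(`n_rec` 1 to 71), with a small positive bias (≈ +2–4% at `n_rec = 71`)
from the estimator's convexity.

## Precursor mining

Known microcin-C-like clusters place a short precursor ORF near the
adenylating-enzyme gene (MccB homolog). The miner operationalizes the
published qualitative criteria:

* **Hard filters** — peptide ends in Asn (chemically required for N–P bond
  installation); Shine-Dalgarno score ≥ 4 (longest contiguous match, 0–6,
  between the 6-mer ending 4–13 nt before the start codon and the consensus
  `AGGAGG`, best spacer reported, ties to the smaller spacer); ORF-to-anchor
  gap ≤ 300 nt (measured nearest-edge to nearest-edge; overlap counts as 0).
* **Soft preferences** — upstream of the anchor in its reading orientation
  (+2) and on the anchor's strand (+3) are rank bonuses, not filters,
  because real clusters only *preferentially* show this arrangement.
  Candidates sort by rank score, then proximity, then coordinates.

ORFs run from any start codon in `{ATG, GTG, TTG}` (all fMet-initiating in
bacteria; configurable to ATG-only) to the first in-frame stop, translation
table 11, start rendered as Met, default length 3–60 residues; codons
containing `N` void the ORF. Coordinates are 0-based half-open on the
forward strand and include the stop codon. The miner is strand-symmetric:
mining the reverse complement with a flipped anchor yields mirrored
candidates. No SD threshold is published for "strong ribosome-binding
site"; 4 was chosen so that perfect sites (score 6, as in the packaged
templates) pass with margin while most random 6-mers fail. Random sequence
still passes the hard filters at a few candidates per kilobase scanned
(both strands), so on large windows the ranking, not the filters, carries
the discrimination; with the compact default fixtures (60-nt flanks around
a 150-nt anchor placeholder) ≥95 of 100 seeded anchor-only backgrounds
yield no candidates.

Neighborhood fixtures are built by `synthesize_neighborhood`: uniform random
background, a placeholder anchor CDS (ATG + random sense codons + stop, with
the last sense codon forced non-Asn so the placeholder can never qualify),
and optionally a planted ORF back-translated from a given peptide (table 11,
uniform seeded codon choice, ATG start — the peptide must start with Met and
end with Asn), preceded by a chosen SD motif and spacer. Spacer sequence is
rejection-sampled to avoid start-codon trinucleotides so the planted
coordinates are unambiguous. Every planted ORF is recovered top-ranked with
exact coordinates by the default miner across the seeded test fixtures.

Precursor lengths are classified into the two families seen across
McC-like clusters — 7–8 residues ("short", the dominant family) and 17–56
("long"); anything else is "other". Peptide monoisotopic masses (for
predicting [MH]⁺ of modified precursors) are computed from standard residue
masses with named modification deltas; `formyl` (+27.994915 Da) is built in
and further deltas (adenylyl, aminopropyl) are user-registered constants.

## Reproducibility and problem sizes

Every stochastic entry point takes an explicit integer seed; identical
config + seed gives bit-identical outputs, and the `demo` subcommand's
output files are byte-reproducible. Simulation-based tests use 10⁴–10⁵
ribosomes and ≤200 bootstrap replicates per curve (the bootstrap default of
1000 is used for single-curve checks), sizes at which every statistical
assertion has comfortable Monte-Carlo margin while the full suite runs in
well under a minute.
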