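# ribocycle

Kinetics of **reiterative translation** on bacterial minigenes, and
rule-based mining of **microcin-C-like precursor peptide ORFs**.

Microcin C (McC) is a peptide-nucleotide antibiotic whose ribosomally made
precursor (MccA, the heptapeptide MRTGNAN in *E. coli*) is adenylated at an
obligatory C-terminal asparagine by the MccB enzyme. Very short ORFs like
*mccA* can be translated many times by a single ribosome that reinitiates on
the same mRNA without dissociating; how many times is quantified by the
**ribosome recycle number**

    n_rec = (1 − P) / P,

where `P` is the probability that the mRNA is released from the ribosome at
any single recycling step. `ribocycle` is for researchers studying minigene
translation or McC-like biosynthetic gene clusters. It provides:

* **kinetics** — closed forms of the model: yield without competition
  `y(t) = 1 + k·t = 1 + N`, with a sequestering competitor
  `y_c(t) = 1 + ((1−P)/P)(1 − e^(−P·k·t)) = 1 + n`, the competition curve
  `n(N) = ((1−P)/P)(1 − e^(−P·N))`, and the `P ↔ n_rec` transforms;
* **simulate** — a seeded stochastic simulator of the in vitro competition
  assay (paired ± competitor time courses, fMet-pool cap, measurement
  noise) and a generator of synthetic genomic neighborhoods with planted
  precursor ORFs;
* **fitting** — nonlinear least-squares estimation of `P` (hence `n_rec`)
  from (N, n) competition curves, with case-resampling bootstrap intervals;
* **mining** — small-ORF enumeration (table 11), Shine-Dalgarno scoring
  against `AGGAGG`, and ranked precursor-candidate calling around
  MccB-homolog anchor genes, plus precursor length classes and monoisotopic
  peptide masses.

The DNA templates of the assay constructs (A7/A11/A15, encoding 7-, 11- and
15-residue MccA variants, and the MFF competitor) ship with the package.

## Worked example

End-to-end demo — simulate the competition assay for each packaged
construct at the release probability implied by its measured recycle number
(71, 30 and 6), refit `n_rec` from the simulated data, and mine each
template for its precursor ORF:

```sh
ribocycle demo --seed 1 --outdir demo_out
```

prints (and writes to `demo_out/summary.tsv`):

```
construct  peptide          length_aa  length_class  n_rec_hat  ci_low  ci_high  converged
A7         MRTGNAN          7          short         68.29      59.68   74.44    True
A11        MGGGMRTGNAN      11         other         30.54      27.03   33.95    True
A15        MASTAGGGMRTGNAN  15         other         6.19       5.97    6.45     True
```

Each row is one construct: the mined precursor peptide and its length
class, then the recycle number re-estimated from the synthetic assay with
its 95% bootstrap interval. Longer precursors recycle far less
(`n_rec` ≈ 68 ≫ 31 ≫ 6), reproducing the kinetic disadvantage of extended
MccA variants. The same stages are available separately:

```sh
ribocycle simulate --n-rec 71 --seed 1 --out a7.tsv     # paired ± competitor TSV
ribocycle fit a7.tsv --n-boot 1000 --out fit.json       # P̂, n_rec, bootstrap CI
ribocycle mine genome.fasta --anchor-bed mccB.bed --out candidates.tsv
```

or from Python:

```python
from ribocycle import (AssayConfig, RecyclingParams, simulate_assay,
                       make_competition_curve, fit_competition)

cfg = AssayConfig(params=RecyclingParams(P=1/72, k=1.0), seed=1)
fit = fit_competition(make_competition_curve(simulate_assay(cfg)))
print(fit.n_rec_hat)   # -> 68.29…
```

See `docs/methods.md` for the model's assumptions, the simulator's design,
default parameters, and known limitations.

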