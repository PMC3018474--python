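# dnabubble

Linear-time DNA duplex instability ("breathing") profiles and core
promoter element analysis.

Double-stranded DNA is not a static ladder: thermal fluctuations
transiently unpair runs of consecutive base pairs ("bubbles"), and the
propensity for such local openings is sequence-dependent — AT-rich tracts
open far more readily than GC-rich ones. Around transcription start
sites this propensity is functionally informative: core promoter
elements such as the TATA box sit in regions whose instability profiles
carry characteristic signatures. `dnabubble` computes these profiles at
genome scale and runs the downstream promoter-element analysis, for
researchers studying promoter architecture, transcription-factor binding
site context, or any setting where local duplex stability matters.

## The model

Each base pair *i* of a sequence of length *N* carries a spin
σᵢ ∈ {0, 1} (closed/open). A configuration's Boltzmann weight is

    ∏_{i=1}^{N} (δᵢ αᵢ)^{σᵢ} (δ_{i+1} ξ)^{f(σᵢ, σ_{i+1})}

with δ₁ = δ_{N+1} = 1 and σ_{N+1} = 1, where αᵢ = exp(ΔG^BP_i / RT) is
the pairing weight (AT or GC entry), δᵢ = exp(ΔG^ST_{i−1,i} / RT) is the
stacking weight of the dinucleotide step, ξ is the ring factor (an
entropic loop parameter, 1 by default), and f(σᵢ, σ_{i+1}) = σᵢ when
σ_{i+1} = 0 and 0 otherwise marks the right edge of an open run. The
partition function Z sums this weight over all 2^N configurations; the
conditional partition function Z_k(n) additionally forces base pairs
n … n+k−1 open. The *opening propensity* — the probability that a bubble
of size k starts at n — is

    P_k(n) = Z_k(n) / Z.

Z factorizes over 2×2 transfer matrices, so one left-to-right pass, one
right-to-left pass and a cumulative log-sum yield the entire profile
{P_k(n)} in O(N), with explicit log-scale rescaling so sequences of
10⁵ bp and beyond neither overflow nor underflow. An exhaustive 2^N
enumerator is kept as the ground-truth oracle for small N.

On top of the calculator sit:

* **TSS-anchored average profiles** over promoter collections
  (coordinates are TSS-relative, +1 is the TSS, there is no 0);
* **core promoter element analysis**: IUPAC scanning of TATA box
  (TATAWA, −33…−23), Inr (YYANWYY, −5…+6), DPE (RGWYV, +23…+33), BRE
  (SSRCGCC, −42…−32) and GC box (GGGCGGG, −170…−5), classification into
  functional / buffered / non-functional sites, per-site instability
  scores, random and shuffled-motif controls, and two-sample
  Kolmogorov–Smirnov comparisons of score distributions;
* a **synthetic promoter generator** (fixed length, fixed TSS offset,
  controllable GC content, planted motif instances with a ground-truth
  manifest) so the whole pipeline is testable without external data.

## Worked example

```python
from dnabubble import NucleotideSequence, opening_profile

seq = NucleotideSequence("demo", "GCGCTATAAAGCGC")
prof = opening_profile(seq, k=4)
for n, v in enumerate(prof.values, start=1):
    print(f"{n}\t{v:.3e}")
```

```
1	1.329e-05
2	1.387e-05
3	9.281e-05
4	3.919e-04
5	4.365e-03
6	4.789e-03
7	1.852e-03
8	1.506e-04
9	3.538e-05
10	4.152e-06
11	8.483e-06
```

Each line is P₄(n), the equilibrium probability that the four base pairs
starting at position n are open simultaneously at 37 °C. The profile
peaks (≈ 4.8 × 10⁻³) where the 4-windows cover the AT-rich TATAAA core
(positions 5–10) — over 300-fold above the GC flanks, the
AT-instability/GC-stability contrast that drives the promoter
signatures.

The same computation from the shell, plus a full synthetic run:

```bash
dnabubble params                       # print the active free-energy table
dnabubble profile promoters.fasta -k 4 -o tracks/   # tsv/bedGraph/wig tracks
dnabubble simulate -n 500 --plant TATAAA,-30,0.5 --seed 1 -o fix
dnabubble avg-profile fix.fasta --tss-table fix.tss.tsv -k 4 -o avg.tsv
dnabubble sites fix.fasta --tss-table fix.tss.tsv -k 4 -o sites.tsv
dnabubble compare --fasta fix.fasta --tss-table fix.tss.tsv -k 4 \
    --seed 1 -o report.json
```

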