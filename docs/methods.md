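# Methods

## Model

The duplex is modeled as a chain of two-state base pairs: spin σᵢ = 1
means base pair i is open, σᵢ = 0 closed. A configuration's statistical
weight couples each open base pair to its pairing free energy and to the
stacking free energy of the step it disrupts:

    w(σ) = ∏_{i=1}^{N} (δᵢ αᵢ)^{σᵢ} · (δ_{i+1} ξ)^{f(σᵢ, σ_{i+1})},

with αᵢ = exp(ΔG^BP_i / RT), δᵢ = exp(ΔG^ST_{i−1,i} / RT), boundary
conditions δ₁ = δ_{N+1} = 1 and σ_{N+1} = 1, and the edge function
f(σᵢ, σ_{i+1}) = σᵢ · [σ_{i+1} = 0] charging the right boundary of each
open run one extra stacking factor (times the ring factor ξ). The model
is cooperative and long-range in the weak sense that every probability
is normalized by the partition function of the *entire* sequence, but it
has no superhelical stress (cf. SIDD-type models), no continuous base
displacement (cf. Peyrard–Bishop–Dauxois), and no loop-entropy exponent
(cf. Poland–Scheraga).

The weights are implemented exactly with the printed sign convention,
α = exp(+ΔG^BP/RT): with the default tables this makes the weight of
opening a single AT pair slightly exceed 1. We deliberately preserve
this convention rather than reinterpret the sign; all downstream
statements are about *relative* propensities, which are unaffected by a
global convention choice.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| stacking ΔG^ST (16 entries) | e.g. AA −1.49, GC −2.55 | kcal/mol | dinucleotide 5'→3', reverse-complement-symmetric table |
| pairing ΔG^BP | AT 0.64, GC 0.12 | kcal/mol | per base-pair type |
| temperature | 37 | °C | pure Boltzmann parameter; no entropic re-scaling with T |
| gas constant R | 1.9872 × 10⁻³ | kcal/(mol·K) | configurable |
| ring factor ξ | 1 | — | kept as a parameter, never fitted |

The free-energy tables carry no published units or gas constant; we fix
kcal/mol with the standard R, the conventional scale for nearest-
neighbor DNA tables of this magnitude. Temperatures other than 37 °C
simply rescale the Boltzmann exponents. The stacking index convention is
ΔG^ST_{KL} with K = base i−1, L = base i along the given strand; because
the default table satisfies ΔG^ST_{KL} = ΔG^ST_{comp(L)comp(K)}, profiles
of a sequence and its reverse complement are mirror images (tested), so
single-strand scanning is strand-consistent.

## Linear-time profile computation

Z is an ordered product of 2×2 transfer matrices
M_i[σᵢ, σ_{i+1}] = (δᵢαᵢ)^{σᵢ}(δ_{i+1}ξ)^{f(σᵢ,σ_{i+1})}, contracted
with (1 1) on the left and (0 1)ᵀ (σ_{N+1} = 1) on the right. The
printed matrix form in the source material is typographically garbled;
the configuration-sum definition is treated as normative and the
exhaustive enumerator as arbiter, and the implemented contraction agrees
with it to ≈ 10⁻¹⁴ relative.

Because the forced-open window contributes a deterministic factor, the
conditional partition function factorizes as

    Z_k(n) = u_n[1] · ∏_{j=n}^{n+k−2} δⱼαⱼ · v_{n+k−1}[1],

where u is the left prefix contraction and v the right suffix
contraction. One forward pass, one backward pass and one cumulative
log-sum therefore give P_k(n) = Z_k(n)/Z for *all* n at once: O(N) for
fixed k. Every pass carries an explicit log-scale accumulator (per-step
renormalization by the component maximum), and probabilities are formed
as exp of log-space differences, so 10⁵-bp profiles are computed without
overflow or underflow (measured: ≈ 0.02 s per 10⁴ bp, empirical scaling
factor ≈ 2 when N doubles). Bubble sizes k = 1…9 are the intended
working range, but any 1 ≤ k ≤ N is accepted, including the
whole-sequence bubble k = N; k > N is rejected.

Degenerate input: bases outside {A, C, G, T} are rejected with the
offending position named (the model defines no weights for them); the
FASTA reader can alternatively skip offending records.

## Promoter coordinates and averaging

TSS-relative coordinates have no 0: the TSS base is +1 and the base
upstream is −1, matching the windows used for core promoter elements
(e.g. TATA at −33…−23). Whether position 0 exists in any given promoter
database's convention is unknowable from window definitions alone; the
no-zero convention is a declared choice. A profile value is indexed by
the bubble's *start* position; no centering, smoothing or normalization
is applied. The average profile is the per-coordinate arithmetic mean
over the collection; ragged collections are supported by tracking the
per-coordinate denominator, and coordinates a sequence does not cover
are absent, never zero-filled.

## Site analysis

Scanning is an exact IUPAC regular-expression match on the positive
strand, reported at every (possibly overlapping) start; a lookahead
pattern guarantees overlapping occurrences are not missed. A site is
**functional** when its full span lies inside the element's functional
window — full-span containment is a declared choice over
start-in-window; the windows are wider than their motifs, so it is
satisfiable for all five elements. A site that is not functional but
touches the window widened by a 10-bp buffer on each side is
**buffered** and excluded from both samples, preventing label
contamination at the window edge (the same uniform rule applies to the
wide GC-box window). Everything else is **non-functional**. Window and
buffer arithmetic is done in absolute sequence coordinates so the buffer
remains a plain base-pair margin even when the widened window crosses
the TSS. Within each label class, overlapping sites are thinned by
deterministic greedy left-to-right selection.

Scores: with site length L and bubble size k, the score is the mean of
P_k over the k-windows *contained in* the site (k < L: starts s…s+L−k),
the k-windows *containing* the site (k > L: starts s+L−k…s), or the
single window (k = L). Sites whose windows would extend past the profile
limits are dropped and counted, never zero-padded. Scores are always
recomputed from the current profile; nothing is cached across sequence
edits.

Controls: per functional site, 10 random sites of equal length are drawn
uniformly (with replacement) from the same promoter; they may overlap
motif occurrences — an exclusion flag exists for sensitivity analysis
but is off by default. Shuffled-motif controls permute the consensus
characters (multiset preserved, shuffle identical to the original
redrawn); one representative shuffle is used per run. Motifs with a
single distinct arrangement cannot be shuffled and are rejected.

Distributions are compared with the two-sample Kolmogorov–Smirnov test
(scipy, asymptotic p-values, no multiple-testing adjustment — p-values
are reported as raw); the D statistic is independently validated in the
test suite against a brute-force ECDF supremum. The sign of the mean
difference summarizes which ECDF lies below (higher scores = more
instability).

## Synthetic collections

The generator emulates promoter-database extracts: fixed-length
sequences (default 1,200 bp, TSS at 1,001, i.e. −1000…+200 — a choice
mirroring typical promoter-database extents), i.i.d. background with
controllable GC fraction, and concrete motif instances planted at chosen
TSS-relative positions with per-sequence probability, plus a
ground-truth manifest. The i.i.d. background captures composition, which
is what the instability model responds to; it does **not** reproduce
real promoters' GC-content gradient around the TSS, CpG islands,
dinucleotide correlations, or co-occurring elements. Passing tests on
synthetic collections therefore demonstrate that the pipeline recovers
planted composition signals at realistic sizes — not that real genomes
show those signals. A first-order Markov background (user-supplied
transition table) is available for dinucleotide-clustering sensitivity
checks.

Default study sizes: pipeline checks use 500 promoters of 1,200 bp with
a TATAAA instance planted at −30 in half of them; oracle checks use
hundreds of exhaustive 2^N enumerations at N ≤ 12; symmetry and
monotonicity checks use 50 sequences of 300–500 bp. These sizes make
every property measurable at high power while keeping the whole suite
fast enough to run routinely.

## Numerical choices and edge cases

* Oracle tolerance 10⁻⁹ relative (measured agreement ≈ 10⁻¹⁴).
* Monotonicity (P_{k+1}(n) ≤ P_k(n), P_k(n+1)) asserted with 10⁻¹² slack
  for floating-point round-off.
* Greedy site selection and seeded generators make every analysis
  deterministic given the seed; outputs embed the parameter fingerprint
  (SHA-256 of the canonical parameter JSON) for provenance.
* Track values are rendered with 17 significant digits, so a text
  round-trip is bit-exact.
* Empty collections, empty samples, zero-functional-site motifs, k
  outside [1, N], and coordinate ranges with no sequence overlap are
  rejected or reported as skipped rather than silently degraded.

## Known limitations

* Positive-strand scanning only; no PWM scoring or motif discovery.
* The ring factor is exposed but uncalibrated (ξ = 1 throughout).
* No melting-curve machinery: temperature enters only through RT.
* Whether the free-energy tables presume particular salt conditions is
  unspecified; results at non-default temperatures should be read as
  model extrapolations.
* Scores of sites near sequence ends are dropped, which can slightly
  bias comparisons for motifs concentrated near boundaries.
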