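# Methods

## Combinatorial barcoding model

The package models spatial barcoding by iterative, light-gated ligation.
Each *letter* is a short oligonucleotide (20 nt by default) terminating in
a photocleavable spacer; UV illumination of a region exposes a 5′
phosphate and licenses the next ligation, so a barcode grows by one letter
per illumination step and the growing end is always the 5′ end. A
codeword over an *m*-letter alphabet and *n* rounds identifies one region;
the complete codebook has *m*ⁿ codewords and can be written in *m*·*n*
steps because regions sharing a letter in a round are illuminated
together. Letter ids are 1-based (`L1..Lm`) and digit 1 is the earliest
round; this single ordering convention propagates everywhere, including
the read parser (below).

Splints are 15-nt ligation templates: the reverse complement of the
incoming letter's 3′-terminal 5-mer followed by the prior letter's
5′-terminal 10-mer, named `splint{incoming}{prior}`. A pool of *m*²
splints lets any letter extend any barcode.

Simple design arithmetic: a per-round success probability *p* gives a
full-length fraction *p*ⁿ; an *r*-repeat code (each digit ligated *r*
times, decoded if at least one repeat survives) lifts the per-digit
efficiency to 1 − (1−*p*)ʳ. Majority-vote decoding of repeat codes is
deliberately not implemented — the decode rule is fixed as "at least one
surviving repeat", applied codebook-side so disagreeing repeats are
resolved against the assigned codewords.

## Scheduling

`build_schedule` groups regions by (round, digit). Steps within a round
are ordered by ascending letter id — the chemistry does not constrain
this order, but a deterministic order makes schedules diffable. Letters
unused in a round emit no step (an empty illumination would waste a wet
step), so the *m*·*n* step count is asserted only for complete codebooks.
`reconstruct_assignment` is the consistency check: a schedule is valid iff
every (region, round) pair appears in exactly one step, and round-tripping
returns the original assignment.

Masks use image conventions: origin top-left, x rightward, y downward,
pixel centers at integer coordinates; a pixel is lit iff its center falls
inside any illuminated region's rectangle or disc. Masks are written as
plain-text PGM (P2), one file per step.

## Length distribution and (d, c) estimation

With `n_L` reactions per round over `R` rounds, on-target additions are
Binomial(R, d) and off-target additions Binomial((n_L−1)R, c); the length
pmf is their convolution (computed as an explicit product-form binomial
convolution, which is stable for extreme probabilities). The estimator
`estimate_dc` minimizes squared deviations between the closed form and
observed fractions at the chosen lengths, under box bounds [0, 1]², with
a 5×5 grid of starting points; ties are broken by residual, then by lower
c. With two observed fractions the system is exactly identified and the
residual is ~0; extra lengths over-determine it and the fit becomes a
least-squares compromise. When a fraction is only an upper bound (an
undetectable over-length gel band), the bound is fit as an equality —
this matches how such bounds are produced by the constrained trace fit
and keeps the estimator deterministic; it slightly overstates c when the
true value is below the bound.

The simulator draws each reaction independently, reactions within a round
in ascending letter order. An optional `blocking` mode suppresses every
addition after the first failed on-target reaction (modelling an
unphotocleaved terminus that cannot ligate); it intentionally does *not*
match the closed form and is excluded from oracle comparisons. Rounds are
otherwise independent — the model's central simplification; real chemistry
couples rounds through incomplete photocleavage.

## Electropherogram fitting

Products with k letters migrate near `base_bp + k·letter_bp`
(letter_bp = 20 by default), so a trace is fit as a sum of K = R + 1
Gaussians, components representing 1..R+1 letters. The constrained mode
ties μ_{R+1} = μ_R + letter_bp and σ_{R+1} = σ_R, which pins the
over-length component to physically meaningful parameters when its peak
is invisible and turns its fitted weight into an upper bound.
Initialization is deterministic: means at the expected positions (base_bp
inferred by anchoring the trace's strongest peak at the full-length
position when not given), σ from the dominant peak's FWHM, amplitudes
from the trace value at each expected position. A constant-offset
baseline term is available but off by default; synthetic traces have no
background, and whether real gel fits need one depends on the instrument.

Peak proportions are area-based (A_k·σ_k, normalized): species abundance
is proportional to integrated signal, not peak height. With the σ-tying
constraint both conventions coincide for the constrained component; an
amplitude mode is kept for comparison.

## Demultiplexing

Read 1 = 5′ handle + concatenated letters + padding. Because each letter
ligates 5′ of the previous one, the *last*-ligated letter is adjacent to
the handle: the parser decodes fixed-width windows in read order and then
reverses them into round order. This is the most error-prone convention
in the pipeline and is pinned by an explicit worked-fixture test.

Letters are called by minimum Hamming distance with a per-letter mismatch
budget (default 2); the alphabet is validated at load time to have
pairwise distance > 2·budget, which makes ties impossible within budget.
Indels are not handled — windows are fixed width — a stated limitation
appropriate for substitution-dominated short reads over 20-nt letters.
Region assignment policies: `exact` (any letter error is detected and
rejected), `nearest-unique` (accept a unique Hamming-1 neighbour), and
`repeat-collapse` (repeat-code decoding against the unexpanded codebook).
Species calling on synthetic data is exact transcript-tag lookup;
alignment to real genomes is out of scope.

## Synthetic experiments

`generate_experiment` runs the forward process end to end: molecules per
region from the ligation simulator; Read 1 assembled from each molecule's
*actual* (possibly erroneous) barcode; Read 2 a transcript tag; traces
synthesized from the empirical molecule-length histogram (not the closed
form), so trace-fit tests exercise the full stochastic path. Sequencing
error is iid per-base substitution (default 0.1%, always to a different
base); quality strings are constant.

Two synthetic species emulate a mixed-species (human/mouse-style)
culture. Each species owns a pool of 500 random 60-mer tags; a read
draws from its partner species' pool with probability h (default 4.7%),
so the measured per-region foreign-species fraction ≈ h. This surrogate
reproduces the *statistical* signature of cross-species transcriptome
homology — an irreducible misassignment floor independent of barcoding —
but none of its sequence structure: real homologous reads are similar,
not identical, and real aligners lose reads to mapping quality, so
passing tests here validate the demultiplexer and the bookkeeping, not
genome alignment.

All randomness flows from the spec seed through named child generators
(pools, molecules, tags, errors), so equal specs give byte-identical
outputs.

## Default parameters and problem sizes

| Parameter | Default | Why |
|---|---|---|
| letter length | 20 nt | standard letter size for this chemistry |
| d, c (examples) | 0.845, 0.025 | rates estimated from the two-letter/two-round experiment |
| trace σ | 5 bp | narrow enough to resolve 20-bp-spaced peaks, like a high-sensitivity screen tape |
| trace noise | 2% of max | typical relative noise for fit-robustness studies |
| read error rate | 0.1% | short-read substitution scale |
| tag pools | 2 × 500 × 60-mers | large enough that random collisions are negligible |
| shared tag fraction h | 4.7% | observed cross-species mapping floor for separately processed cultures |
| molecules per region | 10⁴ (experiments), 10⁵ (rate-recovery studies) | binomial error ≪ the tolerances being checked |
| Monte-Carlo size | 2×10⁵ | total-variation check at the 0.01 level |

Test oracles: the length pmf is checked against exhaustive enumeration of
all 2^(n_L·R) reaction-outcome vectors (n_L·R ≤ 12) and against
Monte-Carlo histograms; the efficiency arithmetic against enumeration
over {success, fail}^r; mask areas against per-pixel brute force.

## Known limitations

- Off-target probability c is a single scalar: no distance dependence to
  the illuminated region, and no distinction between first and later
  reactions of a round.
- Letter-competition effects (unequal ligation efficiencies when several
  letters are pooled) are not modelled; observed barcode diversity in
  pooled ligations can therefore fall below m^n in ways this model does
  not predict.
- The trace fitter models products of 1..R+1 letters only; 0-letter
  products (bare primer) fall outside the fitted support and slightly
  inflate the remaining fractions after renormalization.
- No UMI handling, PCR bias, capture-efficiency, or quality-profile
  modelling in the read generator.
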