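# Methods

This note records the models behind `mt5c`, the parameters that matter,
what the simulator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Modification states and chemistry model

A cytosine on the transcript strand is in one of four states: unmodified
C, m⁵C, hm⁵C or f⁵C. Bisulfite-family treatment is modelled as an
independent per-position Bernoulli event: state *s* is read as T with
probability

| state | BS | RedBS | fCAB |
|-------|----|-------|------|
| C     | 1 − γ | 1 − γ | 1 − γ |
| m⁵C   | 0  | 0     | 0    |
| hm⁵C  | 0  | 0     | 0    |
| f⁵C   | 1  | 1 − ρ | 1 − π |

* **γ** — bisulfite non-conversion probability of unmodified C
  (default 0.005). Typical RNA bisulfite non-conversion is a few per mil;
  γ is the background every level estimate sits on.
* **ρ** — NaBH₄ reduction efficiency of f⁵C → hm⁵C in RedBS
  (default 0.9, configurable).
* **π** — *O*-ethylhydroxylamine protection efficiency of f⁵C in fCAB
  (default 0.9, configurable).

γ, ρ and π are not quantified in the source protocols; the defaults are
plausible mid-range values chosen once. Incomplete reduction/protection
biases f⁵C estimates downward, which is why the deconvolution offers
efficiency-corrected estimates (division by ρ or π) alongside the raw
differences.

The non-conversion **level** at a site is
`ℓ = n_unconverted / (n_unconverted + n_converted)` over reads covering
the site; bases other than C/T are treated as sequencing error and
excluded from the denominator. Levels are reported only at coverage ≥ 5.
The stated filter (">5 reads (5 ×)") is internally inconsistent about the
boundary; the parenthetical is read as the intended floor, so the
implementation uses ≥ 5 and exposes `--min-coverage`.

The deconvolution is a clamped point-estimate difference
(`est_f5c = clamp(ℓ_RedBS|fCAB − ℓ_BS, 0, 1)`), not a joint likelihood
across chemistries: with three chemistries and three identifiable
quantities the difference estimator is exact in expectation under the
table above with γ = 0, and its binomial standard error
(`se² = se_BS² + se_chem²`) is what the tests propagate. hm⁵C is carried
inside the m⁵C(+hm⁵C) bundle throughout; no chemistry here resolves it.

A site is *called* methylated when its level exceeds 0.1 — an own choice
(no cutoff is stated in the source analyses); at the coverages used
(≥ 200×) this is > 10 standard errors above the γ background and well
below any genuine modification level simulated.

## miCLIP geometry and calling

The crosslinked methyltransferase leaves a peptide adduct on the target
cytosine; reverse transcription stalls there, so the cDNA 5′ end marks
the site. Neither the stall offset nor its jitter is published, so one
convention is fixed and shared between simulator and caller: the read
starts one base 3′ (transcript sense) of the adduct, jittered by
δ ∈ {−2…+2} (default probabilities 0.05/0.20/0.50/0.20/0.05). The caller
inverts this: stall = first aligned base − 1 (transcript sense), and the
count is assigned to the nearest transcript-sense cytosine within ±2 nt
of the stall, ties broken toward the 5′ side (the adduct sits 5′ of the
stall, so an upstream C is the more probable origin).

Raw reads are `UMI(3) + sample barcode(4) + UMI(3) + insert + adapter`.
PCR duplicates are byte-identical copies; deduplication counts distinct
UMIs per unique insert ("cDNA counts"). Because UMIs are drawn uniformly
from the 4⁶ = 4096 space, UMI collisions undercount truly distinct cDNAs;
this is a property of the design, kept observable rather than corrected.

Simulated insert 3′ ends are uniform between 20 nt and 50 nt past the
start, and may run past the mature tRNA 3′ end into downstream genomic
sequence: mitochondrial transcription is polycistronic and the assay
captures precursor RNA. This matters statistically as well as
biologically — without 3′-end diversity, loci whose crosslink site lies
~20 nt from the tRNA end would funnel thousands of cDNAs into a handful
of insert sequences and saturate the UMI space differentially.

Alignment emulates best-stratum unique mapping with ≤ 1 mismatch
(`-m 1 -v 1 --best --strata` semantics): every position of both strands
is scanned exhaustively (toy-scale genomes make this exact and fast), and
a read is kept iff its best non-empty mismatch stratum contains exactly
one hit. Adapter trimming is a mismatch-only emulation of the cited
trimmer: the longest insert suffix matching an adapter prefix with ≥ 4
matched bases and ≤ floor(0.06·L) mismatches is removed; no indels. Both
emulations approximate the cited tools' documented behaviour, not their
byte output.

RPM is computed per replicate against that replicate's uniquely mapped
cDNA total (the pooled-vs-per-replicate denominator is ambiguous in the
source description; per-replicate is the choice here since the 2-of-3
rule is inherently per-replicate). The high-confidence filter is a strict
`RPM > 50` in ≥ 2 of 3 replicates.

## Bisulfite alignment

Directional three-letter alignment: the read and the forward genome are
C→T collapsed for forward-strand transcripts, and the reverse-complemented
read and the G→A collapsed genome for reverse-strand transcripts, reusing
the same best-stratum unique scan; original bases are restored for
calling. Non-directional library layouts are out of scope (the simulator
only emits transcript-strand reads). PCR-duplicate handling for level
compilation is a toggle (`with`/`without` collapsing identical
(start, sequence) pairs), since full-length tRNA reads are expected to be
legitimately identical.

## HITS-CLIP exact test

Reads > 20 nt are uniquely aligned and assigned to the gene with maximal
overlap (ties unassigned). For a gene with counts (a, b) in case and
control, both modelled NB(μ, φ) under the null with fixed dispersion
φ = 0.1, the test conditions on s = a + b; the conditional law is free of
μ and depends only on r = 1/φ:

    P(x | s) ∝ Γ(x+r)/x! · Γ(s−x+r)/(s−x)!

The two-sided p-value sums P(x|s) over all x whose probability does not
exceed the observed one. As φ → 0 this converges to the exact
binomial(s, ½) test; both limits are property-tested against independent
enumerations. Unequal library sizes are rescaled to the geometric-mean
effective size before testing (an approximation of the cited tool's
quantile adjustment; documented, not byte-identical). Dispersion is fixed,
never estimated — the design has no replicates. Fold changes use
library-size normalisation with a 0.5 pseudocount and Benjamini–Hochberg
adjustment.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the callers rely on:
state mixtures at chosen cytosines, chemistry truth tables with γ/ρ/π,
truncation geometry with jitter, split UMIs with realistic collision
behaviour, PCR duplication, adapter read-through, NB-dispersed per-gene
CLIP counts and 30–60 nt fragments. It does **not** emulate quality-score
error models (constant Q40; quality trimming is not simulated),
indels, RNA secondary-structure-driven coverage bias, M-bias, precursor
vs mature modification differences (pool structure is a knob, not an
inference target), or non-directional libraries. Passing recovery tests
therefore demonstrates correctness of the pipeline logic under the
modelled noise sources, not robustness to artefacts absent from the
model.

The bundled toy reference is a deterministic ~3 kb synthetic
mitochondrial mini-genome (nine loci: six tRNAs, two mRNAs, one rRNA).
Designated crosslink sites of single-site loci are placed in locally
C-free context (±4 nt) so truncation assignment is unambiguous, matching
the observation that miCLIP reads truncate predominantly at single
cytosines. The default crosslink composition encodes the reported
mitochondrial read shares (MT-TM 26% of mtDNA-mapped reads and 60% of
mt-tRNA loci, MT-ND1 15%, MT-TL1 5%, MT-TS2 4.5%); the residual tRNA mass
is split equally over MT-TE/MT-TH/MT-TF and the non-tRNA remainder over
MT-RNR1/MT-CO1. The default wild-type composition at MT-TM C34 is
30% m⁵C / 37% f⁵C / 33% C — the f⁵C value is the midpoint of the ~36–38%
range the two f⁵C chemistries report — and the NSun3-null condition is
100% unmodified C.

A separate synthetic stand-in carries the real rCRS MT-TM gene boundaries
(mtDNA 4402–4469, wobble index 30 → position 4432) over placeholder
sequence for coordinate checks; sequence-level work on the real gene
requires the user to supply NC_012920.

## Problem sizes and numerics

Default analysis sizes — 10⁴ molecules and 10⁴ reads per chemistry for
deconvolution recovery, 5×10⁴ cDNAs for composition recovery, 200× for
site-catalogue recovery — put the printed percentages many standard
errors above background while keeping every simulation in seconds; these
are the package's chosen study conditions, also used by
`scripts/acceptance.py`. All recovery tests use 3-standard-error bands,
with two-stage designs (population draw, then read draw) propagating both
variance components. Degenerate inputs are defined throughout: empty
strata → unmapped, no C in the ±2 window → unassigned (logged),
coverage < 5 → missing level, missing chemistry levels → missing
estimates, a + b = 0 → p = 1. Seeds: every stochastic entry point takes
one; library writers are byte-deterministic under it, and the CLI derives
per-stage seeds from the single configured seed via a seed sequence.

## Known limitations

* The unique-alignment scan is exhaustive and exact but only suited to
  references up to tens of kilobases — mitochondria-scale, by design.
* The difference estimator cannot separate hm⁵C from m⁵C, and negative
  chemistry differences are clamped to zero, so f⁵C estimates are biased
  upward at true-zero sites by half a standard error.
* The exact test's library-size rescaling rounds to integer counts;
  p-values for very unequal sizes are approximate.
* UMI-collision undercounting is left uncorrected (observable via truth
  sidecars).
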