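# Methods

## The model

`evoslope` measures the *regularity* of a DNA string through a wavelet
spectral slope computed on an indicator-matrix representation of the
sequence.

**Encoding.** Under an assignment code (a letter ordering such as
`ACGT`, meaning A→e1, C→e2, G→e3, T→e4) a sequence of length N becomes a
4×N binary matrix Y whose column j is the unit vector of residue j.  The
cumulative matrix Y\* takes running sums along each row of Y, turning the
spike trains into monotone counting paths.

**Transform.** The 2-D scale-mixing transform is

    Z = W_r · Y* · W_N'

with W_r a depth-2 Haar analysis matrix over the rows and W_N a depth-2
Haar matrix over the positions.  Both are orthogonal, so Z preserves the
Frobenius energy of Y\*.  Row ordering is coarsest-first (scaling rows,
then detail levels coarse→fine); this ordering is load-bearing because
the slope reads fixed sub-blocks of Z.

**Slope.** With Z1 the next-to-finest detail block and Z2 the finest
(1-based, width N):

* 4-row mode: Z1 = Z(2, N/4+1:N/2), Z2 = Z(3:4, N/2+1:N)
* 16-row mode: Z1 = Z(5:7, N/4+1:N/2), Z2 = Z(9:14, N/2+1:N)

the slope is `s = log(mean Z2²) − log(mean Z1²)`.  Negative s = energy
decays toward fine scales = regularity/persistence; s ≈ 0 matches iid
letters; positive s = anti-persistent zig-zagging.  Only two spectral
points exist because the row dimension admits only two detail levels.
For a monofractal of Hurst exponent H in dimension d the dyadic Haar
levels calibrate the slope to −(2H + d); a homopolymer window (H = 1,
d = 1, a perfect linear ramp in Y\*) therefore gives exactly −log 8,
which the tests pin in closed form.

**Equivalence classes and invariance.** The 24 assignment codes fall
into 3 classes of 8 (amino/keto AC|GT, purine/pyrimidine AG|CT,
weak/strong AT|CG): permuting letters within a code's two pairs, or the
pairs themselves, flips signs of detail rows or permutes rows within a
detail block of Z, leaving both block energies unchanged.  Stacking one
single-code encoding per class (12 rows, zero-padded to 16) yields a
slope invariant to the representative choice and to block order — the
padding rows never enter Z1/Z2 (rows 8, 15, 16 are excluded), so with
the Haar basis the "arbitrary" padding is provably inert.

**Windowed ("cumulative evolutionary") slope.** A width-k window slides
along the sequence with a fixed step (defaults k = 32, step = 8, both
divisible by 4 as Haar depth-2 alignment requires); each window gets its
own slope.  Whether the cumulative sums are restarted inside each window
or the global Y\* is sliced is immaterial: the two differ by a per-row
constant, and both Z1 and Z2 live in detail-column blocks, which
annihilate constants.  Both engines are implemented and tested to agree
to 1e-8; the sliced engine is the vectorised default.

## A structural fact worth knowing

For any window consisting only of A/C/G/T, the finest-level mean energy
is **exactly 1/8**, in both single-code and invariant modes: each finest
detail coefficient equals ±½ × (did the even-position residue belong to
this row's letter pair), and every residue belongs to exactly one pair
per encoding block.  Consequently `s = −log(8·e1)` — all sequence
information enters through the coarser level — and `e2 = 0` (hence
s = −∞) is only reachable for windows containing unmapped letters (N
runs and other IUPAC codes).  Real assemblies contain such runs, which
is how infinite slopes arise in practice; fully unmapped windows make
both energies zero and are reported as *missing*.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| window k | 32 | nt | small enough to resolve short exons (~50 nt); smaller windows get noisy, larger lose locality |
| step | 8 | nt | 4× overlap at k = 32; must be divisible by 4 |
| log base | natural | — | the defining formula says "log" and reference numbers (−1.7…) are consistent with natural log; base-2 available, and every output carries its base |
| mallat_threshold | 2^11 | nt | column transform switches from explicit matrix product to pyramidal filtering above this; paths agree to 1e-8 |
| representatives | (ACGT, AGCT, ATCG) | — | first row of the class table; any other choice gives the identical slope (tested over all 512 triples) |

Global slopes need a dyadic width, so sequences are truncated to their
longest power-of-two *prefix* (the tail is dropped); windowed series
simply discard the trailing partial window.

## Degenerate inputs and numerical choices

* e2 = 0 < e1 → s = −∞; e1 = 0 < e2 → s = +∞; both zero → missing.
  Non-finite slopes are retained in series (serialized as `+inf`,
  `-inf`, `NA`) so downstream exclusion is explicit and countable.
* Windows or prefixes containing non-ACGT letters yield missing slopes
  by default; `strict` mode raises instead, naming the position.
  Lowercase input is uppercased.
* √2/2 is computed, never a hard-coded decimal.  Orthogonality is
  asserted to 1e-10, path equivalences to 1e-8 relative.
* Sections (maximal runs of equally-labelled windows) are excluded from
  pooled samples when any window slope is non-finite; section means are
  taken over finite slopes only.  Pooled "observations" are section
  means, not raw windows.
* Youden threshold search uses midpoints between consecutive distinct
  pooled slope values plus outer sentinels; ties break toward the
  smallest threshold.  A brute-force scan over perturbed sample values
  guards this choice in tests.
* Resampling ASL / empirical p is left-tail tie-inclusive
  (#{null ≤ observed}/n); non-finite null slopes stay in the
  denominator.  The two-sample t-test is pooled-variance by default
  (Welch behind a flag); KDE is Gaussian with Silverman bandwidth on a
  100-point grid over the data range.

## What the synthetic generator emulates — and what it does not

`simulate` produces genes as alternating blocks: exons drawn iid
multinomial (GC ≈ 32 %, lengths 50–400) and introns from a persistent
first-order Markov chain (GC ≈ 25 %, lengths 500–3000, self-persistence
ρ = 0.95).  The chain's transition matrix is `ρ·I + (1−ρ)·𝟙p′`: it keeps
the stationary marginal exactly, and adjacent letters agree with
probability ρ + (1−ρ)Σp² (tested against chain algebra).  ρ = 0 is iid.

Persistence is the *simplest* mechanism that drives windowed slopes
negative; it is not a claim about the true source of intron regularity
(which is unknown).  Passing the end-to-end fixture test shows the
pipeline separates persistent from iid blocks under honest noise — it
does not show that real introns are first-order Markov, and exon/intron
slope differences in real genomes are far smaller than the fixture's
separation.  The fixture also contains no
N runs, splice motifs or codon structure, so no infinite slopes arise
in it (consistent with the structural fact above).

## Problem sizes used in tests and the acceptance script

Invariance is verified exhaustively (all 512 representative triples × 10
random length-256 sequences, plus block orderings); the filtering/matrix
equivalence up to N = 4096; resampling calibration with a few hundred
replicates over ~60 seeds (the uniformity check is a KS test at 0.01);
the fixture test uses the default 20 genes.  The acceptance script
groups all 24 assignment codes by slope equality on 5 freshly simulated
length-256 sequences and reports the number of groups.

## Known limitations

* The slope uses exactly two spectral points; no multi-level regression
  or confidence intervals for the slope are provided (out of scope).
* Only the Haar family is supported: the cumulative rows are piecewise
  constant, Haar needs no boundary handling, and the padding-inertness
  argument is Haar-specific.
* Annotation handling resolves CDS → (mRNA) → gene one level deep and
  rejects overlapping CDS rather than resolving isoforms.
* Pooled samples count *section means*, one observation per maximal run
  of equally-labelled windows; window-level pooling would weight long
  sections more heavily and is deliberately not the default.
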