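# Methods

## Split-site model

A split at position k breaks the peptide bond between residues k and k+1
(1-based). The scored context is the 6-mer window of residues k−2..k+3,
labelled by their role relative to the junction: N-3, N-2, N-1 on the
N-extein side and C+1, C+2, C+3 on the C-extein side. A protein of length N
therefore has exactly N−5 scannable sites (k ∈ [3, N−3]); terminal positions
without a complete window are not scored.

The impact matrix M is a 6-position × 20-residue table of each amino acid's
measured effect on trans-splicing at its window position. The site score is
the **sum** of the six per-position entries. Additivity is the simplest rule
consistent with a per-residue impact table; it makes scores covariant in the
obvious ways (adding a constant c to every cell shifts every site score by
6c and preserves the ranking, row permutations are irrelevant), which the
property suite checks against a brute-force oracle. Missing matrix rows are
imputed as 0 with a warning rather than rejected, so partially measured
screens remain usable.

Ranking sorts by descending score with ties broken by ascending position;
ranks are a permutation of 1..N−5. The C+1 chemical constraint (cysteine for
DnaE-family inteins; configurable, e.g. {C,S,T,M} for families that accept
any free-thiol/hydroxyl nucleophile) is deliberately applied at **selection
time, not during scanning**: constraint-failing sites keep their ranks, both
because a ranked table of all sites is the useful report and because the
recommended experimental design includes one low-scoring, constraint-failing
site as a negative control for the splicing reaction. The default negative
control is the lowest-ranked constraint-failing site; it can be overridden by
position.

Secondary structure is annotation only — it never enters the numeric score,
because the available impact data cannot capture conformational effects; the
annotation (majority 3-state label over the six window residues, ties
resolving to unstructured; DSSP 8-state input collapsed G/H/I→H, E/B→E,
rest→C) flags sites whose windows sit inside helices or strands so the
experimenter can weigh the conformational risk.

### The GFP fixture

The packaged worked-example target is a 238-residue GFP in avGFP numbering
carrying the F64L/S65T chromophore substitutions (the common
expression-optimized variant at avGFP coordinates, without the N-terminal
valine insertion that would shift numbering). On this sequence the reference
windows sit at GVQCFS 69/70, KFICTT 47/48, LPVPWP 55/56, LVELDG 17/18,
TTLTYG 64/65, and the canonical non-splicing control window KGIDFK has
aspartate at C+1. Window strings are treated as authoritative over any
printed index when cross-checking external tables, since published site
tables are not always internally consistent about the k/k+1 label. The
average molecular weight of the fixture is 26.87 kDa, i.e. 27 kDa at gel
resolution.

## Construct design

For a chosen split k with intein pair (I_N, I_C) and tag T (6×His default,
placed at the C-terminus of both precursors; optional linker, none by
default):

    N-precursor = extein[1..k] ++ I_N ++ T
    C-precursor = I_C ++ extein[k+1..N] ++ T

The invariant `extein_N ++ extein_C == target` is enforced for every design,
and predicted products (both precursors, the spliced full-length extein, the
excised joined intein) carry average molecular weights from the packaged
residue-mass table, satisfying the bookkeeping identity
MW(Nprec) + MW(Cprec) = MW(spliced) + MW(excised) + 2·MW(tag) − 2·H₂O.
Average rather than monoisotopic masses are used because the intended
comparison is band position on a gel. A C+1 residue outside the intein's
tolerated set triggers a warning, not an error — that is exactly how a
negative-control construct is made. The 2:1 N:C plasmid mass-ratio
recommendation is surfaced as advisory text on the design report, never as
computation.

Back-translation is deterministic: `max-frequency` takes each residue's most
frequent codon; `gc-minimize` takes the lowest-GC codon among those with
relative frequency ≥ 0.10 (floor configurable; rare codons would hurt
expression more than GC content does), breaking ties toward the more
frequent codon. Both modes are exact right-inverses of translation. The
packaged human codon-usage table is a standard relative-frequency table
normalized to sum to 1 per residue.

Overlap-PCR tiling cuts the gene at ⌊i·n/f⌉ boundaries and extends every
fragment except the last by the overlap length (default 20 nt) into its
successor, so every junction overlap has the configured length except
possibly the last when the tail is short; overlap-merge reassembly is exact
by construction and verified property-style. Junction-oligo melting
temperatures use the two simple closed forms — Wallace 2(A+T)+4(G+C) below
14 nt, 64.9 + 41·(GC−16.4)/len otherwise — because the assembly protocol
only needs a sanity check against a 60 °C annealing program, not
nearest-neighbor thermodynamics; overlaps melting below the target are
warned about.

## Assay models

**4PL dose–response.** y(x) = d + (a−d)/(1+(x/c)^b) with a, d the dose→0 and
dose→∞ asymptotes, c the inflection dose, b the Hill slope. The fit is
unweighted nonlinear least squares on log₁₀ dose internally (the dose ladder
spans ~2 decades; log-parameterizing c conditions the Jacobian), reported on
the natural dose scale, initialized at a = min y, d = max y, c = geometric
mean dose, b = 1. R² = 1 − SSres/SStot is computed on the response scale
against the raw points. Inverse prediction
x = c·((a−d)/(y−d) − 1)^(1/b) is defined on the open asymptote interval.
Fitting the packaged six-point AAV5 transduction ladder gives R² = 0.993 and
a predicted 51.2% GFP⁺ at 3.5×10⁴ Vg/cell; note that 0.993 is the global
least-squares optimum for these six mean responses — a higher R² for the
same points would require either replicate-level data or additional anchor
points (e.g. a zero-dose control on a linear axis), neither of which is part
of the packaged dataset.

**qPCR standard curve.** Replicate Cts are averaged per dilution level
before ordinary least squares of mean Ct on log₁₀ copies (per-level SD is
retained); efficiency E = 10^(−1/slope) − 1 is reported as a percentage.
Run acceptance requires r² > 0.9, E ∈ [85%, 100%] (inclusive bounds), and
max per-level Ct SD ≤ 0.2; each failed criterion is named. Quantification
10^((Ct−intercept)/slope) × dilution × volume-scale attaches a warning, not
an error, to an unaccepted curve. Unit conversions between mass
concentration and copies are left to the caller via the two scale factors.

**Densitometry / folds.** Target-band intensity over housekeeping-band
intensity; fold changes are reported rounded to 1 decimal, the usual
reporting precision.

## Synthetic data

The generators are pure functions of their seed. `gen_random_protein` draws
residues uniformly — it emulates sequence diversity, not real amino-acid
composition or structure, so scanning tests exercise the algorithm, not
biology. `gen_impact_matrix` draws cells N(0, σ) (default σ = 5, a spread
comparable to real screens where single-residue effects range over tens of
score units) and can plant a window: each planted cell gets a bonus
exceeding 12× the largest absolute background cell, which guarantees rank 1
because a non-identical window can share at most 5 of the 6 boosted cells —
this makes planted-site tests deterministic rather than probabilistic.
`gen_dose_response` defaults to the six-dose AAV ladder 5×10³..2×10⁵ Vg/cell
with ground truth (a, d, c, b) = (2, 90, 4×10⁴, 1.5) and Gaussian response
noise (sd 2, the replicate-level scatter scale of flow-cytometry
percentages); `gen_standard_curve` defaults to six 10-fold dilutions
spanning 10⁴–10⁹ copies with slope −1/log₁₀(1+E). Passing tests on these
fixtures demonstrate correctness of the algorithms and estimators under the
stated noise models; they do not validate biological predictivity of any
particular impact matrix, which only the experimental screen data can.

The packaged intein registry contains synthetic stand-in Ssp/Npu/Ava DnaE
pairs with family-appropriate half lengths (Ssp N-half 21 residues longer
than Npu/Ava), an N-terminal catalytic cysteine on each N-half and a
terminal asparagine on each C-half; they are placeholders for the curated
database entries, which users should substitute for real designs.

## Numerical and interface choices

- Residue numbering 1-based everywhere; DNA features 1-based inclusive.
- Scan tie-break: ascending position. Structure tie: unstructured.
- 4PL solver: scipy `curve_fit` (Levenberg–Marquardt), maxfev 20 000;
  degenerate inputs (constant response, < 4 points, non-positive doses) are
  rejected up front.
- Standard-curve degenerate inputs (constant Ct, constant copies, < 3
  levels) are rejected; a zero slope cannot define an efficiency.
- Restriction scanning is single-strand exact matching; the default
  BamHI/HindIII sites are palindromic so no reverse-strand pass is needed.
- Problem sizes in the test suite (proteins ≤ 50 aa for oracle comparisons,
  1000/500/200/100-case property batteries, 200 noisy fit replicates) were
  chosen to pin the algorithms' behaviour tightly while keeping the suite
  fast to run routinely.

## Known limitations

- The additive score cannot model interactions between window positions or
  any effect of global fold; structure annotation is heuristic context, not
  prediction.
- The shipped impact-matrix path is synthetic unless the user supplies the
  measured extein-screen table (`data/npu_extein_impact.tsv`); ranking
  quality on real targets is entirely determined by that table.
- Tm formulas ignore salt and oligo concentration; they are adequate for
  60 °C-program sanity checks only.
- Titer quantification assumes the sample Ct lies in the curve's linear
  range; no extrapolation guard is applied beyond the acceptance warning.
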