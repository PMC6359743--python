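# Methods

## Duplex model

Strands are 5'→3' strings over {A, C, G, T}, length 2–16. Two equal-length
strands hybridize antiparallel, ungapped and end-to-end: target position
*i* pairs with candidate position *N−1−i*. Duplex stability is the sum of
dinucleotide stacking free energies

ΔG°(duplex) = Σ over stacks ( ΔH°(stack) − T·ΔS°(stack) ),

where a stack (two adjacent base pairs) contributes **iff both of its base
pairs are Watson–Crick**. There are no initiation, terminal-pair, dangling-
end, mismatch-specific or salt terms. This "mismatch-gated" model is not a
melting-temperature predictor; it is a cheap, monotone scoring function
over the complete 4^N candidate space with two exact properties used by
the tests:

* every duplex ΔG ≤ 0 (all stacking terms are stabilizing), and
* for a fixed target, converting any candidate position to the
  Watson–Crick base can only switch stacks on, so the unique global
  minimizer is the perfect reverse complement.

Stacking parameters are the SantaLucia 1998 unified DNA/DNA set
(`data/nn_unified.tsv`; ΔH in kcal/mol, ΔS in cal/(mol·K), all 16 steps
with the reverse-complement symmetry of the 10 unique values). Any table
with those columns can be substituted. Default temperature is **310.15 K**
(37 °C), the reporting convention of the unified set; it is configurable
(`ThermoConfig`), and all results here use the default. R = 1.987×10⁻³
kcal/(mol·K).

## Candidate space

Candidates are enumerated exhaustively and indexed by a base-4 code (A=0,
C=1, G=2, T=3, most-significant base first, strand read 5'→3'). The
profile of a target is the length-4^N vector of duplex ΔG values; it is
accumulated stack-by-stack with array slicing, so a 10-mer profile
(1,048,576 entries) takes milliseconds. Exhaustive enumeration refuses
lengths above 10 unless explicitly overridden (4^16 does not fit in
memory on ordinary machines; the cap is about honesty, not policy).

Rankings sort by ascending ΔG with **ties broken by ascending code**.
Ties are frequent (profile entries are sums drawn from a small set of
stack energies) and are resolved exactly: scores equal to the k-th
smallest are compared bit-for-bit, which is safe because every profile
entry is accumulated in the same floating-point order.

## Competitive equilibrium

One shared candidate strand (total *C*) binds *n* analogs (totals Aᵢ,
binding constants Kᵢ = exp(−ΔGᵢ/RT)). Eliminating the duplexes through
mass action leaves a scalar balance for the free candidate c_f,

g(c_f) = c_f + Σᵢ Aᵢ Kᵢ c_f / (1 + Kᵢ c_f) − C = 0,

which is strictly increasing on (0, C) with a sign change across the
bracket, so the physical root is unique. The solver is Brent's method at
machine-precision tolerances polished with up to three Newton steps
(residual target 10⁻¹⁴); the batch variant used to score a whole
candidate shortlist is an 80-step vectorized bisection of the same
function, cross-checked against the scalar path in the tests. For n = 1
the solution matches the mass-action quadratic in closed form to 10⁻¹²
relative; for general n it agrees with an independent damped fixed-point
iteration to 10⁻⁸ relative over the moderate-K regime (K ≤ ~300 per
unit) where that oracle is a contraction with practical convergence
rates. An analog supplied at zero concentration is dropped with a warning
and reported with zero duplex and yield.

**Units.** Concentrations are dimensionless "units" (nominally 1 unit =
1 μM at the CLI boundary) of order 1, with K = exp(−ΔG/RT) applied to
those numbers directly, and the candidate total defaulting to the summed
analog total. This convention places short-oligo mixtures in the nearly-
but not fully-saturated regime — per-analog yields of ~0.99 with
informative shortfalls of 10⁻⁵–10⁻³ units — where candidates are
meaningfully distinguished by their summed yield. (At, say, molar-scale
K against 10⁻⁶ M totals the same sequences sit far from saturation and
every comparison compresses; the units convention is part of the model,
not a cosmetic choice.)

## CS, RS and the equivalent concentration

The **CS** is selected in two stages: the 1000 candidates with the lowest
concentration-free summed ΔG form the shortlist (pool size configurable;
concentrations deliberately do not enter the ranking), then the shortlist
member with the highest summed equilibrium yield at the analogs' actual
concentrations wins. Argmax ties break toward the lower summed ΔG, then
the lower code. Exhaustive-versus-pooled agreement is verified in the
acceptance tests at N = 6, where the full space can be scored.

The **RS** is the reverse complement of the CS. Its equivalent
concentration solves the plain two-strand equilibrium CS + RS for the RS
total c that binds exactly the amount x of CS the analog mixture bound:
from K(c − x)(C − x) = x,

c = x + x / (K (C − x)),

with K the perfect CS/RS duplex constant. x < C always holds at a solved
equilibrium; x → 0 gives c → 0.

## Closeness-ordered merging

**Closeness** of two strands is the overlap of their top-k lowest-ΔG
complement lists (k = 1000 for merge ordering and matrices, 100 for
sociogram edges; both configurable). Groups of ≥3 analogs are reduced
pairwise: each round recomputes closeness among the current members,
merges the closest pair into its RS (which re-enters at its equivalent
concentration under the name "a/b"), and repeats. Closeness ties break by
the tied pairs' best-candidate equilibrium yield, then lexicographic
names, making the reduction order-invariant. The final result re-evaluates
the last CS against the *original* analogs at their concentrations.

This greedy pairwise scheme is the K-means-centroid analogy, not a joint
optimization: no simultaneous multi-strand partition function is
attempted, and the merge path can matter for the final RS.

## Synthetic data and what passing tests show

Generators produce uniform random origins, cumulative mutant ladders
(Mut-k differs from the origin at exactly k never-repeating positions),
independent-mutation analog sets, and mutual-mismatch pairs (a strand and
a copy differing at exactly m positions). Substitutions are uniform over
the three non-identical bases; there are no indels, no composition bias,
no transition/transversion asymmetry, and concentrations default to equal
— so passing replicate statistics demonstrate the pipeline's behaviour
under idealized sequence drift, not under any biological mutation
process. A root seed spawns one recorded child seed per replicate set
(all < 2³¹), so any row of a replicate table can be regenerated exactly.

Study designs exercised by the test suite and the acceptance script, at
the problem sizes the package adopts as its reference conditions:

* two-analog study: 100 sets, 10-mers, pair design with 2 mutual
  mismatches, 1 unit each;
* five-analog study: 100 sets, 8-mer origin, 5 analogs × 3 mutations;
* mutation sweep: mutation loads 1–4, 30 sets each, 8-mer origin,
  5 analogs;
* worked examples: the frozen synthetic sets in `oligorep.examples`
  (generated once at seed 2019), chosen to match the canonical
  demonstration designs (10-mer pair with three mutual mismatches; 8-mer
  origin with three two-mutation analogs).

## Known limitations

* Exhaustive 4^N enumeration caps practical lengths at ~10 nt; the
  18–25 nt scale of real microRNAs needs a non-exhaustive search.
* No secondary structure, hairpins, self-dimers, candidate–candidate or
  analog–analog duplexes: one shared complement strand is the entire
  reaction network.
* Absolute ΔG values are not calibrated against melting experiments (no
  initiation/salt terms); only comparisons within the model are
  meaningful.
* The yield-fraction-sum objective has a counterintuitive consequence
  under strong concentration bias: the dominant analog saturates under
  any reasonable binder, so the selection is differentiated mostly by the
  minority analog's affinity (discontinuously so as the minority
  concentration reaches zero, where the member is dropped).
* Pearson correlations of ΔG profiles are computed over vectors dominated
  by near-zero entries (most candidates share no WC stack with a short
  target), which inflates all correlations toward a common baseline;
  comparisons between correlations are informative, absolute values less
  so.
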