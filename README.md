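# oligorep

Distilling a single **representative sequence (RS)** from a group of
similar short DNA oligonucleotides — the kind of few-mismatch analog
families seen in microRNA-like regulation — using nearest-neighbor
hybridization thermodynamics and competitive multi-strand binding
equilibrium.

## The idea

Every strand's most basic function is hybridization, so a group of analogs
is summarized by the complement that serves *all* of them best:

1. **Score the whole candidate space.** For analogs of length *N*, every
   one of the 4^N possible complementary strands gets a duplex free energy
   against each analog from a simplified nearest-neighbor model: stacking
   terms ΔG°(stack) = ΔH° − TΔS° (SantaLucia unified parameters, T =
   310.15 K) are summed only over adjacent positions where **both** base
   pairs are Watson–Crick; mismatched stacks contribute nothing, and no
   initiation/terminal corrections are applied.
2. **Shortlist and compete.** The 1000 candidates with the lowest summed
   ΔG enter a competitive mass-action equilibrium: one shared candidate
   strand (total concentration *C* = Σᵢ Aᵢ) binds *n* analogs (totals
   Aᵢ, constants Kᵢ = exp(−ΔGᵢ/RT)), with duplexes xᵢ solving
   xᵢ = Kᵢ(Aᵢ − xᵢ)c_f and c_f = C − Σᵢ xᵢ. The **common complement
   sequence (CS)** is the candidate maximizing the summed hybridization
   yield Σᵢ xᵢ/Aᵢ.
3. **Derive the RS.** The RS is the reverse complement of the CS, carried
   with an *equivalent concentration*: the amount of RS that would bind
   exactly as much CS as the analog mixture did.
4. **Merge iteratively for larger groups.** With three or more analogs,
   the pair with the highest **closeness** (shared members of the two
   top-1000 lowest-ΔG complement lists) is merged into its RS first, the
   intermediate RS re-enters as a new analog, and the process repeats —
   the sequence-space analogue of updating a K-means centroid.

Profile similarity is measured throughout as the Pearson correlation of
two strands' full 4^N ΔG vectors, and as closeness counts; a bipartite
"sociogram" (strands vs their top-k complements) can be exported to
GraphML/SIF for network visualization.

## Worked example

The package bundles two small synthetic demonstration sets (see
`oligorep.examples`). The two-analog set is a random 10-mer pair
differing at three positions, at 1 μM each:

```sh
$ printf '>A\nCACCGCCTGA\n>B\nAACCGCCGTA\n' > pair.fa
$ oligorep rs pair.fa
CS      TCCGGCGGTG
RS      CACCGCCGGA
rs_concentration        1.999910
total_yield     1.999909
wrote rs_summary.json
```

The CS is a compromise strand: it is the perfect complement of neither
analog, but at equilibrium it leaves only 2.5·10⁻⁵ μM of analog A and
6.6·10⁻⁵ μM of analog B unbound (total yield 1.9999 of a possible 2),
whereas either analog's own anti-strand starves the other analog by an
order of magnitude more. The RS — the strand the CS represents — binds
the CS like the whole analog mixture did when supplied at ≈2 μM, and its
ΔG profile correlates with each analog (r ≈ 0.80, 0.83) more strongly
than the analogs correlate with each other (r ≈ 0.71).

The same from Python, for the three-analog set (8-mer origin, three
analogs with two mutations each):

```python
>>> from oligorep import iterative_rs
>>> from oligorep.examples import three_analog_example
>>> result = iterative_rs(three_analog_example())
>>> [(s.merged, s.closeness, s.rs) for s in result.merge_tree]
[(('Analog 2', 'Analog 3'), 221, 'AACGGTGT'),
 (('Analog 1', 'Analog 2/Analog 3'), 6, 'TGCGGTTT')]
>>> result.rs, round(result.rs_concentration, 4), round(result.total_yield, 4)
('TGCGGTTT', 2.9766, 2.7355)
```

Analogs 2 and 3 share 221 of their 1000 best complements, so they merge
first; their intermediate RS then merges with Analog 1 to give the final
RS at an equivalent concentration of ≈2.98 units.

Other subcommands: `profile`, `cs`, `cluster`, `sweep` (yield tables
under varying analog ratios), `simulate` (replicate studies), and
`sociogram`.

## Scope and caveats

The model is deliberately minimal: no secondary structure, dangling ends,
salt correction or analog–analog cross-hybridization, and exhaustive
enumeration is the point — which caps practical strand lengths at ~10 nt
(hard limit 16). See `docs/methods.md` for the full model description,
parameter choices and limitations.
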