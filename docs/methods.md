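# Methods

## The model

An RRBS-style experiment is modelled in four deterministic steps:

1. **Digestion.** Each isoschizomer family has one IUPAC recognition
   motif and one top-strand cut offset; scanning the genome (both
   strands; one strand when the motif equals its own IUPAC reverse
   complement) yields a sorted list of 0-based cut coordinates per
   chromosome. A cut at coordinate `c` severs the bond between
   positions `c−1` and `c`. For an enzyme pair the cut set is the union
   of both families' sets. Only the family representative is scanned —
   isoschizomers produce identical digests by construction.
2. **Fragmentation.** Fragments are the half-open intervals between
   consecutive cuts. Chromosome-terminal stretches are excluded: a
   library fragment needs two enzyme-generated ends for adapter
   ligation. Fragment ends use top-strand cut coordinates only; the
   ≤4 bp shift from sticky-end overhangs is far below the size-selection
   error δ and is absorbed into it.
3. **Size selection.** A window is parameterised by its lower limit `a`
   and breadth `b` and keeps fragments with `a ≤ length ≤ a+b`,
   inclusive at both ends — this matches gel-excision intuition and
   tiles the (a, b) grid without gaps when b is a multiple of δ. `NF`
   is the number of fragments kept. The *experimental* window reported
   to the user is the theoretical one shifted by the adapter length.
4. **Site recovery.** A site is recovered (`γ = 1`) when it lies inside
   a selected fragment `[s, e)` and within one read of an end:
   `coord − s < r` or `e − coord ≤ r`. The asymmetry (strict at the
   start, inclusive at the end) makes the two reads cover exactly `r`
   bases each in 0-based half-open coordinates; it matters only for a
   site exactly `r` bases from a fragment start.

The protocol metrics (`Score`, `EV`, `CRF`, robustness `R`) are defined
in the README. Two filters gate every window: `Score ≥ c·max_Score`
and `NF ≤ k·g/1000` (so the minimum acceptable cost-reduction factor is
`1000/(k·r)`). Among surviving windows of a combination the one with
the lowest EV wins; combinations are then ranked by EV.

## Search strategy and numerics

* The window grid uses resolution δ (the assumed size-selection error):
  lower limits `min_lower..max_lower` step δ, breadths `δ..max_breadth`
  step δ. Sampling finer than δ would distinguish windows a gel cannot.
  The grid origin is configurable; the default `min_lower = 20` bp
  reflects that shorter fragments are not reliably mappable, and
  `max_lower = 1000` bp that longer fragments are rarely size-selected.
* Per combination, fragment lengths are sorted once; `NF` is a range
  count (binary search) and `Score` a prefix-sum difference over the
  sites that can ever be read (within `r` of an end — a property
  independent of the window). A test verifies this fast path against
  the naive filter-and-scan evaluation over the entire grid.
* EV is undefined when `NF = 0` or `Score = 0`; such windows carry a
  `+inf` sentinel and always compare worse than any feasible window.
  Inside the robustness stencil an undefined neighbour contributes the
  full relative deviation 1 to θ, which keeps `R ∈ (0,1]` and penalises
  optima adjacent to empty windows. Stencil lower limits below 1 bp
  are clamped to 1 so the stencil always has 9 points. Robustness is
  computed only for each combination's winning window.
* Ties in EV (absolute tolerance 1e−12) break deterministically:
  smaller lower limit, then smaller breadth within a combination;
  robustness descending, then NF ascending, then family names across
  combinations. Results are therefore byte-identical across runs.
* Genome `N` bases match only the pattern letter `N`, so motifs are
  never asserted inside assembly gaps. Soft-masked (lowercase) bases
  are treated as ordinary bases.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `read_length` (r, bp) | readable span from each fragment end | — | typical 30–300 |
| `adapters_size` (s, bp) | shift of the experimental window | 0 | |
| `score_threshold` (c) | min Score as fraction of max_Score | 0.25 | |
| `nf_constant` (k) | NF ceiling = k·g/1000 | 0.2 | calibrated for Gb-scale genomes; see below |
| `experimental_error` (δ, bp) | size-selection error & grid step | 20 | plausible 5–500 |
| `max_breadth` (bp) | widest window | 980 | 49 breadths at δ=20 |
| `output_size` (t) | protocols reported | 30 | |
| `genome_size` (g, bp) | for CRF | FASTA total | |

On a mammalian genome (`g ≈ 3·10⁹`) the default `k = 0.2` caps NF at
600 000 fragments. On the ~150 kb synthetic scenes used in the tests
and the acceptance script the same formula yields a ceiling of 30
fragments, which forbids nearly every window; those runs therefore set
`k = 1.0`, scaling the ceiling to the toy genome while exercising the
identical filtering logic.

## Synthetic fixtures

The fixture generator emulates only what the machinery needs: a random
uniform-composition background, rejection-cleaned of every planted
motif (and its reverse complement), with motifs written in at recorded
positions. Ground truth is derived by re-scanning the finished
sequence, because one planted motif may legitimately contain another
(CCCGGG nests CCGG); a match not explained by a planted interval, or a
planted position that fails to match, aborts generation rather than
silently shifting the truth. Sites of interest can be placed in
declared classes (near a fragment end, fragment interior, terminal
stretch, out-of-window fragment) with analytically known recovery.

What these fixtures do **not** model: CpG islands and isochores,
repeat content, assembly gaps at realistic scale, bisulfite strand
asymmetry, methylation-state-dependent cutting, or sequencing noise.
Passing tests show the bookkeeping — digestion coordinates, window
arithmetic, metric formulas, threshold logic, ranking — is correct;
they do not certify enrichment numbers for any real genome, which
depend entirely on that genome's motif landscape.

## Scale of the shipped analyses

Tests and the acceptance script run on seeded scenes of ~150 kb with 3
enzyme families (6 combinations) and 50 sites, chosen so an exhaustive
brute-force evaluation of every combination × every grid window can
serve as an independent oracle in seconds. All machinery is
size-agnostic; real-genome runs simply supply a larger FASTA and
catalog, with per-family digests cached via the pre-computed cut-site
files.

## Known limitations

* Combinations of more than two enzymes are out of scope.
* Type IIS enzymes cutting outside their motif (offset > motif length),
  nicking enzymes, and enzymes cleaving twice per recognition event are
  rejected at catalog parse time; the model assumes one double-strand
  cut per match.
* Methylation sensitivity is handled categorically (a family is usable
  or not in a given context), not as state-dependent digestion of a
  partially methylated genome.
* Buffer compatibility, star activity and sequential-digestion
  practicality are experimental concerns left to the user, who can
  encode them by editing the enzyme annotation file.
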