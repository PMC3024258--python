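# Methods

`sibz` computes the equilibrium propensity of every base pair in a
superhelically stressed DNA molecule to adopt the left-handed Z conformation,
with all Z-susceptible sites competing for the limited torsional stress.
This note records the model, the algorithm, the numerical choices, and what
the synthetic fixtures do and do not probe.

## The model

A topological domain of N base pairs at superhelix density σ carries a
linking difference α = σN/A_B (A_B = 10.4 bp/turn).  A *state* assigns each
base pair to B-form or to a Z-form dinucleotide unit: Z-DNA has a two-base
repeat in which one base is *syn* and the other *anti*.  States are
equivalent to placements of non-overlapping, non-abutting runs of even length
(two abutting runs would be the same maximal segment).  The number of such
states follows the Fibonacci recursion S(N) = S(N−1) + S(N−2) — about
φ^(N+1)/√5 — so exhaustive treatment of a multi-kilobase molecule is
impossible and the algorithm works with the thermally relevant subset.

The free energy of a state with n_Z transformed base pairs in r runs is

    G = Σ_i δg_i + 2b·r + (K/2)·α_r²,
    α_r = α + n_Z·(1/A_B + 1/A_Z) + 2·r·a,

with the three terms:

1. **Sequence-dependent transition energy.**  Each dinucleotide unit costs
   its tabulated AS (5′-anti-3′-syn) or SA energy; every break in the
   syn/anti alternation between adjacent units costs the tabulated Z-Z
   junction energy of the spanning doublet.  The ten dinucleotide classes
   are shipped as a plain-text table (`sibz/data/bz_energies.tsv`, kcal/mol,
   reverse-complement symmetric, one decimal, no temperature scaling — the
   B-Z transition is reported to be nearly temperature-independent).  Unit
   and junction energies are split evenly between their two base pairs to
   give the per-bp shares δg_i.
2. **Nucleation.**  Each run pays 2b = 10.0 kcal/mol for its two B-Z
   junctions (b = 5.0 kcal/mol per junction).
3. **Residual superhelicity.**  Flipping n_Z bp to the left-handed Z-helix
   (A_Z = 12 bp/turn) and untwisting a = 0.4 turns at each of the 2r B-Z
   junctions leaves residual linking α_r, which costs a quadratic stress
   energy with K = C·RT/N, C = 2200 (R = 1.9872×10⁻³ kcal/mol/K, T = 310 K).

σ is held constant during an analysis, and Z-DNA is treated as torsionally
rigid.  All constants are user-overridable (`PhysicalConstants`); a and C
enter the model only through literature values, so they are deliberately
exposed rather than baked in.

Equilibrium quantities follow from the Boltzmann distribution: state s has
relative frequency exp(−G_s/RT)/Z, the per-bp transition probability p(x)
sums the frequencies of states in which x is transformed, and ⟨n_Z⟩, ⟨r⟩ are
the corresponding ensemble averages.

## Syn/anti assignment

The conformation of each base pair in a candidate run is assigned by a
four-pass heuristic applied left to right: (1) purines → syn, pyrimidines →
anti (the cheap assignments); (2) flip any base pair whose label matches
both neighbours (removes label runs longer than two); (3) flip the central
two of any AASS/SSAA quartet; (4) for a unit whose two base pairs share a
label, flip the one giving the lower Z-Z junction energy against its current
neighbours (ties: lower unit energy, then the 3′ base pair).

Two properties of this heuristic were established by exhaustive comparison
with brute-force minimization over all valid label vectors (all 4096 6-mers,
plus seeded samples at 8–12 bp):

- it never scores below the brute-force minimum (it always produces a valid
  labelling), and
- it is *exactly* optimal whenever its result contains no Z-Z junction.

When the assignment does contain a junction the greedy pass order can exceed
the optimum (the junction-versus-unit-flip trade-off); these junction-bearing
windows are intrinsically expensive and occupy correspondingly little of the
ensemble.  Because a left-to-right scan is not symmetric under reverse
complementation in those same ambiguous patterns, `run_transition_energy`
evaluates both orientations and keeps the cheaper assignment; window energies
are therefore exactly reverse-complement symmetric, as the physics requires.

## The search algorithm

Candidate runs are every window of even length between 8 and 250 bp
(min/max configurable; 8 bp because shorter Z-runs are not observed, 250 bp
as a practical ceiling).  Their energies are computed once per sequence —
vectorized across all windows of a length, in both orientations — and reused
across σ values, sweeps and onset bisections.

The search then:

1. finds the minimum free energy G_min by branch-and-bound over runs in
   start order (the untransformed state always competes; exact ties resolve
   to the lexicographically smallest (r, start, length, …) state, a
   determinism device only);
2. enumerates every state with G ≤ G_min + θ (θ = 12 kcal/mol by default;
   neglected states have relative weight ≤ e^(−θ/RT) ≈ 3×10⁻⁹, and θ in the
   10–12 range reproduces exact small-system results to more than four
   digits);
3. streams the enumerated states into sufficient statistics — the relative
   weight sum Z_rel, the state count, and per-candidate totals T[i] = Σ of
   weights of states containing candidate i.  Everything downstream (p(x),
   ⟨n_Z⟩ = Σ L_i·T[i]/Z, ⟨r⟩ = Σ T[i]/Z, all-Z region probabilities) derives
   from these; states are never stored, which is what makes ensembles of
   ~10⁹ states tractable in bounded memory.

For a fixed composition class (n_Z, r) the nucleation and stress terms are a
constant B(n_Z, r), so the threshold is a budget on the summed run energies.
The enumeration recurses over runs in start order; at every node the final
one or two runs of a state are closed in vectorized batches (a
globally-precomputed table of admissible ordered pairs serves the two-run
closings).  Pruning uses optimistic completion bounds f(r, n): the cheapest
way to add k more runs totalling m bp, with the run-energy part taken from
per-length minimum energies, refined first by first-plus-second minima
(two runs cannot reuse one candidate) and then by true disjoint-pair minima
extracted from the pair table.  All bounds are relaxations, so no admissible
state is ever missed — exhaustiveness is certified against a brute-force
oracle (below).

Circularity is handled by anchoring each state at its smallest-start run;
wrapped runs carry unwrapped ends and the last run must leave at least one
B-form base pair before the first.  Linear molecules are analyzed on an
augmented circle: the ends are joined through a 50-T joint (TT units are the
most Z-resistant), the *same σ applies to the augmented N* (for a 5-kb input
the distinction from the raw length is ~1%), and the joint is excluded from
all reporting.  The reported ⟨n_Z⟩ is the expected number of Z base pairs
within the user's sequence (= Σ p(x) over reported positions).

Weights are computed relative to the ground state (the deepest state has
weight 1), so no exponential under/overflows occur at any θ.

## Oracle certification

`sibz.oracle` contains an independent exact reference: Fibonacci state
counts (verified against direct dimer-tiling enumeration for N ≤ 25, both
topologies) and `brute_force_ensemble`, which enumerates *every* admissible
run placement of a tiny molecule with plain set arithmetic and re-derived
topology formulas.  On the 60-bp twin-island fixture the production search
reproduces the oracle's state multiset, partition function, per-bp
probabilities and ensemble averages to machine precision with no threshold,
and within e^(−θ/RT) when thresholded.  In relaxed-bound counting mode
(2-bp runs, unlimited run count) the production enumerator reproduces the
tiling counts exactly; the two all-Z phasings of an even circle — valid
tilings with no B-form base pair, hence not representable as gap-separated
runs — are counted analytically.

## Synthetic fixtures and what they show

Poly-T backgrounds isolate designed inserts as the only Z-susceptible sites
(one caveat: at a G|T boundary a phase-shifted run can end in a syn-anti GT
unit at only 1.3 kcal/mol, so the first flanking T of a CG insert carries
non-negligible Z-probability; "background" assertions therefore probe
positions away from insert boundaries):

- `seq1_insert` (CG)₁₆, `seq2_insert` (CG)₈(GC)₈ (one GG junction, +4.0
  kcal/mol), `seq3_insert` (CG)₄GA(CG)₃TC(CG)₄ (26 bp, +6.8 kcal/mol over
  perfect alternation) mirror the classic engineered-plasmid experiments.
  Their documented energy gaps are locked by the energy table alone.  The
  published experiments specify insert length, junction content and unit
  energies; these fixtures are the minimal sequences consistent with those
  properties, and onset densities depend only on (length, total energy,
  junction count).
- `competition5000`: a 5000-bp poly-T circle with a short perfect insert
  ((CG)₁₀, 20 bp) and a longer insert of seven phase-alternating 14-bp
  blocks (98 bp, exactly six GG Z-Z junctions, +24 kcal/mol over perfect
  alternation).  The geometry was chosen by a design study of the model's
  own free-energy crossings: insert 1 must be longer than any junction-free
  block of insert 2 (so it is the single cheapest site and transforms
  first) yet much shorter than insert 2, whose full transition relieves
  ~18 turns of stress — enough to revert insert 1 before the deepest
  densities re-transform both.  The four logically possible regimes then
  occur in order across σ ∈ [−0.07, −0.03].  The reversion is starkest in
  the flip-entirely (all-Z) observable, which is what the corresponding
  published experiment plots; the mean-per-bp observable dips less deeply
  because short sub-runs of insert 1 retain some weight.
- `twin_islands60`: two identical (CG)₄ islands exactly equidistant on a
  60-bp circle — small enough for the exact oracle, symmetric enough that
  degeneracy is testable.  Note that a 60-bp domain needs exaggerated |σ|
  (and sometimes a widened θ) for any transition to be thermally visible:
  K ∝ 1/N makes small circles torsionally stiff.  Those settings are test
  instrumentation, not physiological claims.
- `tss_cohort`: 2-kb poly-T "genes", half carrying a (CG)₁₂ insert upstream
  of a nominal transcription start site, for the profile-aggregation path.
  2 kb is the shortest length at which the insert flips decisively at
  transcription-scale σ = −0.07.

None of these fixtures contain the mixed-composition, correlated sequence of
real genomes, so passing tests demonstrate correctness of the energetics,
topology and enumeration — not genome-scale predictive accuracy.  The checks
against published plasmid results (onset densities of engineered pBR322
derivatives, ensemble benchmarks on pBR322 itself) require the user to
supply the pBR322 sequence (GenBank J01749), which is not distributed with
the package; `fixtures.pbr322_derivative` builds the insertion constructs
from it by locating the unique BamHI (G^GATCC) or PvuII (CAG^CTG) site.

## Region probabilities and onset

The probability that a region is "in Z-form" is computed two ways: `all_z`
(the summed weight of states in which the entire region is transformed —
the observable of a two-state gel experiment) and `mean_p` (the mean per-bp
probability).  For a single cooperative insert they nearly coincide;
`mean_p` is the default and both are always reported.  The onset density
σ_c of a region at a level (default 80%) is found by bisection on σ to
|Δσ| ≤ 0.0005 and reported to 3 decimals.  No density-of-states correction
is applied for the states beyond θ; at θ = 12 their aggregate weight is
negligible for every quantity reported here.

## Problem sizes and costs

Candidate-energy generation is O(Σ_L N·L) and takes a few seconds for a
5-kb molecule (~600k windows, both orientations); it is done once per
sequence.  Enumeration cost scales with the number of thermally relevant
states: designed fixtures at physiological σ run in well under a second per
σ; heavily competitive mixed sequences deepen rapidly beyond σ ≈ −0.07,
where state counts grow combinatorially — there the per-σ cost can reach
minutes, dominated by genuinely occupied states rather than search
overhead.  The test suite therefore exercises paper-scale physics on
fixtures built to be decisive yet fast, and certifies exactness on small
systems where the oracle is feasible.

## Known limitations

- Stress-induced strand separation and other alternative conformations do
  not compete in this model; a molecule analyzed here can only trade B for Z.
- The transition energetics carry no explicit salt or temperature
  dependence (none is established for B-Z), so T enters only through RT
  and the stress coefficient.
- The greedy syn/anti heuristic can overprice junction-bearing windows by
  up to a few kcal/mol relative to the true optimum (see above); such
  windows are high-energy and contribute negligibly at the default θ.
- The quadratic stress coefficient C = 2200 and junction untwist a = 0.4
  turns are literature defaults, not fitted here; both are exposed in the
  configuration and echoed into every output header.
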