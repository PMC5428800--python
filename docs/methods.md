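# Methods

## Model representation

The network is a bipartite Petri net. Places carry a class
(`transcription_factor`, `complex`, `dna_element`, `output_gene`,
`process_output`), an optional entry group (IRF1/IRF4/IRF8/AP1/ETS) and
entry/output flags; transitions carry activating inputs, inhibitory inputs
and outputs. Three representational choices keep the semantics simple:

- **Transitions are pure AND gates.** An "or" interaction is compiled into
  parallel transitions converging on the same place, so a transition always
  means "all of these inputs together". This keeps the firing rule (minimum
  over activating inputs) exact for every transition.
- **Inhibition is an arc kind**, not a place attribute: an inhibitory input
  subtracts its token count from a transition's flow capacity. The bundled
  model ships no inhibitory arcs — which regulatory edges are inhibitory in
  Langerhans cells is not settled — but the file format and engine support
  them.
- **Composite binding is a two-stage path.** An interaction record naming a
  DNA element compiles to partner(s) → element transitions plus one
  element → target transition per regulated gene, with the element place
  acting as the shared pool for all complexes binding that sequence. The
  element→target transitions are deduplicated across records, which is what
  makes compiling an OR record identical to compiling its single-partner
  halves.

Family partners expand member-wise: an "IRF8 AND ETS" record produces one
transition per ETS member, reflecting the assumption that an IRF can pair
with any expressed family member. Records supported by fewer than two
independent reports are dropped at compile time (with a logged warning);
the threshold is an argument so sub-threshold wiring can be inspected.

The bundled default model is the Langerhans-cell IRF network: 50 places
(3 IRFs, 4 AP-1 and 11 ETS partners, ISRE/EICE/AICE, 17 Programme A and
6 Programme B output genes — grouped figure nodes such as (HLA A–F, B2M)
are single places — and 6 process outputs) wired through 74 transitions.
Routing IRF8:ETS complexes to ISRE is a reconstruction choice: it is the
wiring under which Th1/class-I behaviour requires IRF1 ∨ (IRF8 ∧ ETS),
which is the constraint the network is built to satisfy.

## Simulation semantics

One *time block* fires every transition once in a fresh uniform-random
order; a firing moves `f ~ U{0..cap}` tokens with
`cap = max(0, min(activating) − Σ inhibitory)`, consuming `f` from each
non-clamped activating input and adding `f` to every output. Entry places
are clamped (non-depleting) by default: an expression level is a sustained
supply, and depleting sources would make every 0/100 knockout outcome decay
to zero regardless of wiring. `entry_mode="depleting"` treats entries like
any other place, for token-conservation studies.

Token counts are integers throughout; per-place means and standard
deviations across runs (population sd) are real-valued. Defaults are 100
blocks × 500 runs, with outputs summarised as the mean token count over the
final 10 blocks.

Randomness: run `r` draws from `SeedSequence(seed, spawn_key=(r,))`; within
a run the block-wise transition permutations are drawn first, then a matrix
of flow uniforms, and `f = min(int(u·(cap+1)), cap)` inverts the uniform.
This makes traces bit-identical for a given seed, independent of the
numba/pure-Python execution path, and appending runs never reshuffles
earlier ones. The knockout screen reuses the same seed for all 32 rows —
rows are independent simulations of different markings, and sharing the
stream makes rows comparable under a single seed.

## Boolean oracle

`reachable_places` computes the least fixpoint of "a place is ON if it is
an entry with tokens, or some transition with all activating inputs ON
feeds it", then applies a **single demotion pass**: a non-entry place is
demoted if every enabled transition feeding it has an ON inhibitor.
Iterating demotion would re-introduce the non-monotone-fixpoint ambiguity
of Boolean networks with negation; a single pass is exact for inhibition-
free nets and for single-layer inhibition, and inhibition cycles are a
documented limitation (none exist in the bundled model). The oracle is the
deterministic twin used to cross-check the simulator: with clamped entries
the expected summary of a place is positive exactly when the oracle marks
it reachable.

## Expression parameterisation

Intensities are taken on the linear RMA-like scale and mapped to tokens by
half-up rounding, uncapped — the marking is the expression level, with no
transform. Partner-family members must *exceed* the inclusion threshold
(default 150 intensity units) to receive tokens; entry IRFs always
contribute. The default analysis uses the 2 h time point (the induction
peak); per-time-point runs are available through the CLI's `--time-point`.

Programme classification compares output-gene summaries between conditions:
inactive if both ≤ ε (default 1.0 token), Programme A if
TNFα/TSLP ≥ 1.5, else Programme B. The 1.5 ratio and ε are package
defaults, CLI-exposed — "preferential induction" has no canonical numeric
criterion, and 1.5 separates the two regimes by a wide margin in both the
synthetic data and the network's response (condition ratios land around
3 for ISRE-driven genes and 0.3 for EICE-driven genes). The observed
programme applies the same rule to a gene's own peak post-stimulation
intensity per condition; concordance is the fraction of genes where
predicted and observed calls agree.

## Synthetic data generator

`generate_expression` emulates a two-cytokine Langerhans-cell time course:
`intensity(g, c, t) = baseline(g) · fold(g, c, t) · LogNormal(0, σ)` over
{0, 2, 8, 24} h. TNFα induces IRF1 6.7-fold and IRF8 13.5-fold at 2 h;
TSLP induces IRF4 4-fold — the IRF4 fold is a synthetic choice (the
underlying induction is established qualitatively, without a published fold
value). Inductions peak at 2 h and decay geometrically towards baseline
(multipliers 1, 0.5, 0.25 at 2, 8, 24 h). Partner baselines deliberately
straddle the 150 inclusion threshold (BATF3, ELK3, EHF, ETV3 below), so the
exclusion filter is exercised; IRF baselines sit near 100–120 intensity
units, typical for moderately expressed TFs on this scale. Programme A
output genes rise 8-fold under TNFα only, Programme B genes 5-fold under
both, which is what their ISRE/EICE wiring predicts.

The generator does **not** emulate probe-level noise, probeset redundancy,
batch effects, RMA preprocessing or donor variability. Passing the recovery
tests therefore shows that the pipeline is self-consistent — markings
derived from data with the assumed structure reproduce the generating
programme labels through the full stochastic simulation — not that the
classifier is robust to real microarray artefacts.

`generate_random_small_net` builds acyclic-from-entries, inhibitor-free
bipartite nets (entries at the lowest indices, transitions pointing only
towards higher indices) as fixtures for the oracle-equivalence property.

## Numerical and testing choices

- Flow inversion guards the floating-point edge `int(u·(cap+1)) == cap+1`
  (probability ~2⁻⁵³) by clamping to `cap`.
- The oracle-equivalence tests mark random-net entries with 10⁴ tokens:
  expected flow roughly halves per network level, and the equivalence claim
  concerns positivity of the *expected* summary, so the supply is chosen to
  make a false zero at depth ~10 vanishingly unlikely.
- Monte-Carlo error scaling is checked two ways: standard errors of the
  run-mean estimated from independent simulations at 100/400/1600 runs
  (ratios ≈ 2), and a direct replication of the run-mean at 100 runs
  against the predicted standard error. Problem sizes (a two-place chain,
  5 blocks, 60 replications) give ≥3σ statistical margin at the 25%
  tolerance.
- Truth-table "active" calls use ε = 0 conjoined with oracle reachability
  rather than a token cutoff; disagreements between the two criteria are
  reported, never silently resolved.

## Known limitations

- Qualitative wiring only: no binding affinities, cooperativity or
  chromatin state; token throughput is an arbitrary-unit proxy for
  transcriptional output.
- The bundled output-gene roster is the published core set; extended
  ChIP-seq-derived rosters can be supplied via the model TSV format.
- Inhibition semantics are single-pass in the oracle; models with
  inhibition cycles need care from the user.
- mRNA level is taken as a proxy for protein function, and process outputs
  (Th1, class-I presentation, …) aggregate gene-level token flow linearly.
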