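# Methods

## Problem and model assumptions

The package solves inverse folding for pseudoknot-free RNA secondary
structures: given a target `y*` of length n, find sequences over
{A,C,G,U} whose Boltzmann ensemble concentrates on `y*`.  Admissible
pairs are the Watson–Crick pairs plus the G–U wobble; structures are
properly nested pair sets (no two pairs interleave), and every pair must
enclose at least `min_hairpin` positions.  Pseudoknots, non-canonical
pairs, and structures of unequal length are out of scope.

Two facts shape the method.  First, a sequence can satisfy the MFE
criterion (its minimum-free-energy structure equals the target) while
folding into the target with arbitrarily low equilibrium probability, so
the objective optimized here is an ensemble quantity, not structure
distance.  Second, the objective optimum and the MFE criterion are not
the same thing, so the search *harvests* every intermediate sequence
that passes the MFE/uMFE check instead of optimizing for it.

## Objectives

Both objectives live in [0, 1] and vanish exactly when the ensemble is
the target alone:

* probability deficit: `1 − p(y*|x)`;
* normalized ensemble defect (NED): the expected per-position structure
  distance between the ensemble and the target.  Internally the
  *unnormalized* defect `n − 2·Σ p_ij − Σ q_j` is used, because its
  positional decomposition `ε_i` (1 − q_i for target-unpaired i,
  1 − p_ij for a target pair (i, j)) is what drives position sampling at
  its natural scale; the reported and optimized objective divides by n
  so values are comparable across lengths.  Positional defects are read
  off the base-pair probability matrix of one fold; nothing is refolded
  per position.

## Search

* **Frontier.** The k lowest-objective *distinct* sequences in the whole
  history (default k = 10).  A new sequence enters only if absent and
  strictly better than the current worst; ties are kept in favor of the
  earlier entry, which makes runs deterministic under the seed.
* **Candidate sampling.** Boltzmann over the frontier,
  p(l) ∝ exp((1 − f_l)/T), T = 1 by default.  The exponent uses
  (1 − f) as a "score"; any affine shift cancels in the normalization,
  and the implementation subtracts the max exponent before
  exponentiating for numerical stability.
* **Position sampling.** p(i) ∝ exp(ε_i/T′) with T′ = 2T.  Separate
  temperatures are supported, but performance is insensitive to T, so
  T′ is tied to T by default.
* **Structured mutation.** The sampled position selects a local unit on
  the *target* structure (never on a predicted structure, so proposals
  stay target-compatible):
  - paired position, inner neighbor also paired, both next-inner
    positions unpaired → stack + double mismatch (6·6·4·4 − 1 = 575
    joint proposals);
  - paired position, inner neighbor paired → stack (6·6 − 1 = 35);
  - paired position, both interior-adjacent positions unpaired →
    pair + double mismatch (6·4·4 − 1 = 95);
  - unpaired position just inside a pair, with the opposite interior
    position unpaired → unpaired double mismatch (4·4·6 − 1 = 95), or
    paired → single 5′/3′ mismatch (4·6 − 1 = 23);
  - otherwise → trivial single-base change (3 proposals).
  Precedence for paired positions tests the largest defined unit first
  (stack+mismatches, then stack, then pair+mismatches).  A paired
  position whose inner context fits none of these (e.g. a multiloop
  branch point) falls back to resampling the single pair among the
  other 5 pair types; an unpaired position adjacent to a helix only on
  its exterior side is treated as trivial.  The "− 1" exclusion removes
  only the identical *joint* assignment — individual slots may keep
  their value.  The trivial move excludes the current base (a no-op
  would waste a cubic-time evaluation).  Draws are uniform over the
  proposal space via rejection of the current assignment.
* **Updating.** Each mutant is folded once; its objective, positional
  defects and criterion verdict are cached by sequence so revisits cost
  a dictionary lookup instead of a refold (this changes no trajectory,
  only its cost).  MFE/uMFE byproducts accumulate as ordered unique
  lists.
* **Convergence.** Stop when the frontier minimum drops below
  `converge_eps` (default 0.01), when it has not strictly decreased for
  `patience` iterations (default 2000), or at `max_iters` (default
  5000).  The patience counter watches the frontier minimum (not the
  newest sequence), which is monotone by construction, so the reported
  trace never increases.
* **Ablations.** Five switches disable exactly one stage: targeted
  initialization (→ random compatible sequences), Boltzmann sampling
  (→ uniform candidate *and* position draws), structured mutation
  (→ single base / single pair moves), the multifrontier (→ k = 1), and
  byproduct collection (→ only the final best sequence is
  criterion-checked).  A single RNG stream drives all stages in a fixed
  call order, so ablated and full runs are comparable seed for seed.

## Toy energy model and its oracles

The built-in model assigns per-pair energies CG/GC −3, AU/UA −2, GU/UG
−1 (arbitrary units), a −1 bonus per stacked pair, hairpin minimum 3,
and RT = 1.  The values are fixed repository constants chosen so that
GC-rich helices and stacks dominate, qualitatively as in
nearest-neighbor models; the model exists so that every ensemble
quantity has an exhaustive-enumeration oracle inside the repository
(enumeration is capped at 16 nt).

* Partition function and pair probabilities: inside–outside dynamic
  program over two inside items (general region; region closed by a
  pair, carrying the conditional stacking term) and their outside
  counterparts, O(n³) time.  Intermediates are rescaled by
  `exp(−G_mfe/(n·RT))` per nucleotide — the MFE structure then has
  scaled weight 1 — and `log Q` undoes the scaling, so long sequences
  do not overflow; pair probabilities are scale-invariant ratios.
* MFE set and uMFE check: min-plus analogue of the same recursions,
  with a co-optimal *counting* table.  The uMFE test is "target energy
  equals the minimum and the co-optimal count is 1" — the DP equivalent
  of enumerating the zero-slack suboptimal set, with energy ties
  compared at 1e−9.  A full zero-slack traceback (`mfe_structures`)
  returns the entire argmin set when it is needed explicitly.
* The ViennaRNA adapter implements the same contract with the engine's
  partition function, `pr_structure`, and `subopt(0)`; engine options
  (temperature, dangle model) pass through unmodified.  The toy DP is
  practical to a few hundred nucleotides; the thermodynamic engine is
  the intended backend for long targets.

## Synthetic target generator

Targets are built recursively from helices, hairpin loops, internal
loops/bulges, and multiloop branches, with helix lengths and loop sizes
drawn from configurable ranges (defaults: helices 2–8 stacked pairs,
loops 3–8 nt, branching probability 0.2) and exact total length by
construction.  Hairpin loops never fall below 3 nt, so both backends
accept every fixture.  Internal loops always include at least one
unpaired base, so generated helix runs cannot merge past the requested
maximum.  When the requested length leaves no room for an in-range
loop, the generator closes the region as a loop of the forced size —
fully constrained specs therefore yield their unique shape.  The
generator emulates the *shape* statistics of design targets only; it
does not mimic the base composition, motif usage, or length
distribution of any natural RNA family, so passing tests say nothing
about performance on, e.g., ribosomal RNA targets.

## Problem sizes used in the tests and acceptance script

Oracle-equivalence checks run 200 random sequences of 5–14 nt (where
exhaustive enumeration is exact); end-to-end design checks use the
20-nt worked example and random 15–40 nt targets with iteration caps of
60–500.  The acceptance script designs the worked example (500 toy /
1000 engine iterations) and eight fresh 30-nt synthetic targets at 300
iterations each.  These sizes were chosen so the whole suite re-runs in
minutes on one CPU while still exercising every stage at full fidelity;
the algorithm itself has no small-n specialization.

## Known limitations

* The toy model omits loop-length terms, dangles, and coaxial stacking;
  its probabilities are not comparable to thermodynamic ones, only to
  its own enumeration oracle.
* Objective evaluation is cubic per iteration; very long targets
  (≳1000 nt) are better served by the engine backend and patience, and
  nothing here decomposes the target hierarchically.
* Multiple runs aggregate by union/average only; there is no
  cross-run deduplication of byproducts in the FASTA outputs beyond the
  per-run uniqueness guarantee.
* GC-content or other sequence-composition constraints are not
  supported; the design space is constrained only by target
  compatibility.
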