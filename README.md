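# rnadesign

RNA inverse folding by ensemble-objective multifrontier search.

Given a pseudoknot-free target secondary structure *y\** (dot-bracket
notation), the package searches for RNA sequences *x* whose thermodynamic
ensemble concentrates on the target.  It is written for people who need
*many* successful designs per target — e.g. to screen designs under extra
sequence constraints, or to generate training data for learning-based
design — rather than a single locally optimal sequence.

## The method

The design problem is posed as constrained minimization of an ensemble
objective

```
minimize_x  f(x, y*)      subject to  y* ∈ Y(x)
```

where `Y(x)` is the ensemble of structures `x` can form and `f` is either

* `1 − p(y*|x)` — one minus the target's equilibrium probability
  `p(y|x) = e^(−ΔG(x,y)/RT) / Q(x)`, or
* `NED(x, y*)` — the normalized ensemble defect, the mean probability
  that a position is incorrectly structured, computable from the
  base-pair probability matrix as
  `(n − 2·Σ_{(i,j)∈pairs(y*)} p_ij − Σ_{j∈unpaired(y*)} q_j) / n`.

The search keeps a *frontier*: the k lowest-objective distinct sequences
seen over the whole run (a priority queue, not a population with
crossover).  Each iteration:

1. draws a frontier sequence with probability ∝ `exp((1 − f)/T)`,
2. draws a position with probability ∝ `exp(ε_i / T′)`, where `ε_i` is
   the positional ensemble defect and `T′ = 2T`,
3. applies a **structured mutation**: the local structural unit
   containing the position — a stack, a loop-closing pair with its
   interior mismatches, or both — is jointly resampled, uniformly over
   all joint assignments except the current one,
4. evaluates the mutant and checks the MFE/uMFE criterion; every
   intermediate sequence whose minimum-free-energy structure equals the
   target (MFE criterion), or equals it *uniquely* (uMFE criterion), is
   harvested as a **byproduct**, independent of whether it is the
   objective optimum.

Initialization is targeted: unpaired positions start as A and every pair
draws GC or CG at random, so helix sides are complementary but distinct
helices are unlikely to cross-pair.  The run stops when the best
objective falls below 0.01, after 2000 non-improving iterations, or at
the iteration cap.

Two folding backends implement the same contract:

* `toy` — a self-contained nearest-pair energy model (CG −3, AU −2,
  GU −1, stacking bonus −1, RT = 1) with exact O(n³) dynamic programs
  and an exhaustive-enumeration oracle; every quantity is testable to
  machine precision.
* `vienna` — the ViennaRNA nearest-neighbor engine (used when the
  `RNA` Python bindings are installed); uMFE checks use the zero-slack
  suboptimal set.

## Worked example

```python
from rnadesign import parse_dotbracket, DesignConfig, design, get_backend

target = parse_dotbracket("(((...)))..(((...)))")
result = design(target, DesignConfig(objective="probability", seed=0, max_iters=500),
                get_backend("toy"))
print(f"iterations:      {result.iterations_run} ({result.stop_reason})")
print(f"MFE solutions:   {len(result.x_mfe)}")
print(f"uMFE solutions:  {len(result.x_umfe)}")
best = result.best
print(f"best sequence:   {best.sequence}")
print(f"best objective:  {best.objective:.4f}  (target probability {1-best.objective:.4f})")
```

prints

```
iterations:      500 (max_iters)
MFE solutions:   451
uMFE solutions:  423
best sequence:   CGGAAACCGAACGCAAAGCG
best objective:  0.1189  (target probability 0.8811)
```

In 500 iterations on the 20-nt two-hairpin target the search harvested
451 distinct sequences whose MFE structure is the target (423 of them
uniquely so), and the best sequence folds into the target with
equilibrium probability 0.88 under the toy model — the byproduct sets
are orders of magnitude larger than the frontier itself, which is the
point of the method.

The same workflow from the shell:

```bash
rnadesign make-fixtures --n 40 --count 5 --seed 7 --out puzzles.txt
rnadesign design --puzzles puzzles.txt --objective prob --backend toy \
    --max-iters 500 --seed 0 --runs 2 --out results/
rnadesign eval --puzzles puzzles.txt --designs results/designs_run0.fasta \
    --backend toy --out eval.tsv
```

`design` writes per-run FASTA files of the harvested solutions, TSV
metric reports (solved status, solution counts, best probability, best
NED, mean positional entropy), an aggregate report with union/average
semantics across runs, and a reproducibility manifest.  `eval`
recomputes every metric for any FASTA of designs, so external tools can
be scored identically.

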