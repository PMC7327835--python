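# threeform

Tools for designing and evaluating **three-form planned missing data designs
(PMDDs)** — the matrix-sampling survey design in which the item pool is split
into four blocks (a common X-block plus rotating A-, B-, C-blocks) and each
participant answers one of the three forms XAB, XAC, XBC. Every participant
skips exactly one rotating block, so roughly a third of each rotating item's
responses are missing *completely at random by construction*, which keeps the
design friendly to principled missing-data methods (multiple imputation, FIML)
while cutting questionnaire length by about a third.

The package is aimed at survey methodologists and applied researchers in
psychology, epidemiology, and the health sciences who want to

1. **construct** a three-form design — in particular via *random item
   allocation* (RIA), which assigns scale items to blocks uniformly at random
   subject only to target counts, and its *hybrid* variant for small scales
   (5–11 items), which conditions the randomization so every block receives at
   least one item from each small scale; the classical deterministic
   between-/within-block assignments and the even-split rule for very small
   scales (≤ 4 items) are included;
2. **impose** the resulting planned missingness on participant-by-item data
   tables and diagnose the pattern and covariance-coverage structure; and
3. **evaluate** design variants in a self-contained Monte-Carlo resampling
   harness: a synthetic population with three correlated constructs (13/14/13
   quasi-continuous items plus demographics), bootstrap samples recursively
   trimmed across sample sizes, EM + normal-model multiple imputation, parcel
   construction, per-scale one-factor fits, and Rubin pooling.

## Outcome statistics

Design performance against a complete-data control is summarized with

- **latent reliability**
  ρ(Y) = (Σᵢ λᵢ)² ψ / [ (Σᵢ λᵢ)² ψ + Σᵢ θᵢᵢ ],
  the squared correlation between a scale's sum score and its true score
  (λ loadings, ψ latent variance, θ residual variances);
- **relative efficiency**
  RE = R⁻¹ Σᵣ SE(θ)ᵣ / SE(θ̂)ᵣ,
  the mean over replications of the ratio of complete-data to planned-missing
  standard errors (RE = 1 means no efficiency loss; the mean of ratios, not
  the ratio of means);
- **percent relative bias**
  PRB = 100 · (θ̂̄ − θ) / θ, with |PRB| > 10 flagged by convention.

## Worked example

Allocate a 40-item questionnaire (scales of 13, 14, and 13 items, plus three
demographic variables forced into the X-block) with four randomly chosen scale
items in X:

```python
from threeform import (Scale, ItemPool, DesignSpec, build_design, build_forms,
                       coverage_theoretical)

pool = ItemPool(
    scales=[
        Scale("ego",    [f"ego{i:02d}"  for i in range(1, 14)]),
        Scale("task",   [f"task{i:02d}" for i in range(1, 15)]),
        Scale("caring", [f"car{i:02d}"  for i in range(1, 14)]),
    ],
    singletons=["sex", "age", "race"],
    forced_x=["sex", "age", "race"],
)
alloc = build_design(pool, DesignSpec(p_x=4, seed=2026))
forms = build_forms(alloc)
print("block sizes:", alloc.block_counts())
print("form lengths:", {k: len(v) for k, v in forms.forms.items()})
print("X-block:", alloc.items_in("X"))
```

prints

```
block sizes: {'X': 7, 'A': 12, 'B': 12, 'C': 12}
form lengths: {'XAB': 31, 'XAC': 31, 'XBC': 31}
X-block: ('ego02', 'ego12', 'task09', 'car07', 'sex', 'age', 'race')
```

With P = 40 scale items and P_X = 4, the remaining 36 items split 12/12/12, so
all three forms have equal length (31 of the 43 fielded variables — a 28%
shorter questionnaire). `coverage_theoretical(forms)` gives the implied
covariance coverage: 1.0 for X–X pairs (e.g. sex–age), 2/3 for X–A pairs, and
1/3 for A–B pairs — the price the design pays on cross-block associations.

Running a small resampling study (RIA condition vs the complete-data control
at N = 500, R = 10 replications, M = 20 imputations):

```python
from threeform.simulation import StudyConfig, default_population, run_study, summarize

cfg = StudyConfig(x_levels=("random",), parcel_levels=("random",),
                  sizes=(500,), reps=10, imputations=20, seed=7)
table = summarize(run_study(cfg, default_population()))
```

yields, for the RIA condition (excerpt):

```
        parameter statistic     value  flag
 latcor[ego,task]       PRB -0.182946 False
 latcor[ego,task]        RE  0.966713 False
  loading[ego,p1]       PRB  1.955476 False
  loading[ego,p1]        RE  0.930811 False
     class:latcor        RE  0.961915 False
    class:loading        RE  0.932879 False
```

Biases stay well under the 10% convention and efficiency losses are mild
(RE ≈ 0.93–0.97) even though a third of every rotating item is missing.

The same functionality is available from the shell via the `threeform`
console script (`design`, `forms`, `impose`, `coverage`, `simulate`,
`summarize` subcommands; see `threeform --help`). Every command logs the seed
it used and writes a `.meta.json` sidecar with the seed and a config hash.

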