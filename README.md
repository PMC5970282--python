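# symtrans

Semi-automated, symmetry-targeting variable transformations for clinical
tabular data — and the clustering simulation that shows why they matter.

## The problem

Clinical datasets mix measurement types: serum concentrations, adverse-event
counts, questionnaire scores bounded between 0 and 30, proportions, ranks,
ordered severity grades.  Many of these are strongly right-skewed, and
z-scoring cannot help: linear maps leave asymmetry exactly as it was.  A
skewed feature distorts every distance-based analysis — in a Manhattan or
Euclidean dissimilarity matrix the stretched upper tail dominates, hiding
differences in the bulk of the patients — and it breaks variance
homogeneity and linearity in ordinary models.  Transforming every variable
toward a *symmetric* distribution at the preprocessing stage, before any
particular model is chosen, fixes most of this at a cost that is linear in
the number of variables.

`symtrans` implements that workflow for data scientists preprocessing
medical (or any mixed-type) tables:

1. a **ten-kind taxonomy** (amount, count, ratio, fraction, counted
   fraction, bounded amount, bounded count, difference, rank, ordinal)
   declared in a per-variable *metafile*, which determines the admissible
   transformation family for each column;
2. a **skew scan** using the quartile (Yule/Bowley) skewness
   `sk = [½(m₁+m₃) − m₂] / [½(m₃−m₁)]`, flagging a variable when |sk|
   exceeds a sample-size-dependent threshold *c* (0.10 for n > 180, 0.12
   around n = 120, 0.15 below);
3. a **ladder search** over the discrete powers
   p ∈ {−2, −1, −⅔, −½, −⅓, 0 (= log), ⅓, ½, ⅔, 1, 2}, composed with each
   kind's re-expression (logit for fractions, the started logit
   `log((n+⅓)/(m−n+⅓))` for counted kinds, component-wise transforms for
   ratios and differences), ranking candidates by post-transform |sk|;
4. a reviewable **registry** of the chosen transform per variable — the
   automated choice plus ranked alternatives and histogram panels, with
   manual overrides kept in an audit trail — so the preprocessing is
   reproducible to the byte.

The simulation component demonstrates the payoff: six simulated disease
subgroups (A1, A2, B, C, BC, Normal; 200 subjects each; 100 mixed features
of which 7 jointly informative) are recovered almost perfectly by
FDR-screened K-medoids clustering when the features are symmetric
(adjusted Rand ≈ 0.99) and lost when the informative features are damaged
by a monotone skewing map (adjusted Rand ≈ 0.7) — even though the damage
is rank-preserving and the feature *selection* is unaffected.
Re-symmetrizing with the automatic search restores the recovery.

## Worked example

```python
import numpy as np, pandas as pd
from symtrans import SymmetryModel

rng = np.random.default_rng(42)
n = 658
table = pd.DataFrame({
    "NPITOTAL": rng.poisson(rng.gamma(1.2, 2.5, n)),   # inventory score
    "serum_protein": rng.lognormal(4.0, 0.5, n),
    "MMSE": rng.binomial(30, 0.92, n),                 # 0..30 test score
    "age": rng.normal(72, 6, n),
})
table.to_csv("data.csv", index=False)
with open("meta.csv", "w") as fh:
    fh.write(
        "variable,type,lower,upper,denominator,components,reverse,order\n"
        "NPITOTAL,count,,,,,,\n"
        "serum_protein,amount,,,,,,\n"
        "MMSE,bounded_count,0,30,,,,\n"
        "age,amount,30,,,,,\n")

model = SymmetryModel.from_csv("data.csv", "meta.csv")
res = model.fit()
print(res.summary())
```

```
Symmetry transformation summary (4 variables, 2 flagged)
=====================================================
   variable    n    sk   thresh flag  chosen  post sk
-----------------------------------------------------
     NPITOTAL 658 +0.333   0.10    *      log  +0.070
serum_protein 658 +0.136   0.10    *      log  -0.024
          age 658 -0.039   0.10      identity  -0.039
         MMSE 658 +0.000   0.10      identity  +0.000
-----------------------------------------------------
```

Reading the table: the two right-skewed variables are flagged (|sk| ≥ 0.10
at n = 658) and the search settles on the logarithm for both — a *started*
log for `NPITOTAL`, whose zeros get a start of half the smallest positive
count.  `age` is symmetric and passes through, and this particular `MMSE`
draw happens to have symmetric quartiles, so it is not flagged.
`res.transform()` returns the re-expressed table (`NPITOTAL` drops from
sk = +0.33 to +0.07); `res.registry` holds the exact specs, serializable
with `res.registry.to_file(...)`; `res.plot_variable("NPITOTAL")` shows
the histogram panel of raw data and candidates; `res.override(...)`
replaces an automatic choice, keeping the prior one in the audit trail.

The same workflow is available from the shell:

```bash
symtrans scan data.csv meta.csv
symtrans suggest data.csv meta.csv -o report/
symtrans apply data.csv meta.csv report/registry.txt -o transformed.csv
symtrans simulate --seed 1
```

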