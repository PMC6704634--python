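# bgsc

Bayesian Gene Selection Criterion (BGSC): prediction of genes regulated
through specific receptor isoforms from a *nested* RNAi knockdown design.

## The problem

Splice-variant-specific knockdowns are often nested: an siRNA against all
EGFR splice variants silences a superset of what the variant-I-specific
siRNA silences, so the effect of the truncated isoforms II–IV is never
observed in isolation. Standard per-contrast differential-expression tools
do not answer the question "which genes respond to EGF via isoforms II–IV
and not via other receptors?". BGSC does, in two steps:

1. **Design reduction.** With regulator channels {isoform I, isoforms
   II–IV, other EGF receptors}, each of the 2³ = 8 regulation modes A–H
   (subsets of channels driving a gene) predicts a binary
   responds/doesn't-respond profile across the treatments (no RNAi,
   siRNA_I, siRNA_ALL): a mode responds under a treatment iff at least one
   of its channels survives the knockdown. Only four profiles are
   distinguishable, giving the simplified groups a = {A}, b = {B,E,F,G},
   c = {C,H}, d = {D}, each with an indicator vector g₁..g₆ over the six
   conditions (2 EGF levels × 3 treatments). Group **c** — response lost
   only under the all-variant knockdown — is the isoform II–IV target group.

2. **Per-gene Bayesian classification.** A gene's six log2 expression
   values x₁..x₆ are modeled as independent normals with a shared variance
   and group-specific means: one mean μ_a for group a, two means μ_{z0},
   μ_{z1} (following the indicator) for z ∈ {b,c,d}. With the
   closed-form estimates (class means; variance denominators n−1 and n−2),
   the maximized likelihood p(x|z, θ̂_z) is penalized into a BIC
   approximate marginal likelihood

       p(x|z) ∝ p(x|z, θ̂_z) / √n^{|θ_z|},   |θ_a| = 2, |θ_z| = 3,

   and posteriors follow from Bayes' formula with priors
   p(a)=0.70, p(b)=p(c)=p(d)=0.1. Each gene is assigned to its
   posterior-maximizing group; genes assigned to c with p(c|x) > 0.75
   are the selected targets, annotated with the log2-fold change
   μ̂_{c1} − μ̂_{c0} and its Welch–Satterthwaite standard error.

A synthetic-data module generates matrices from this model with known
labels for calibration and recovery studies, and the whole pipeline is
scriptable from the `bgsc` command line. Arbitrary channel/treatment
panels are supported, not just the EGFR design.

## Worked example

The published single-gene example: for gene *TPR* the maximized
likelihoods of the four groups are (0.004, 0.035, 4.22, 0.012).

```python
import math
from bgsc import bic_log_marginal, posteriors, Priors

liks = {"a": 0.004, "b": 0.035, "c": 4.22, "d": 0.012}
k = {"a": 2, "b": 3, "c": 3, "d": 3}
lm = {z: bic_log_marginal(math.log(l), k[z], 6) for z, l in liks.items()}
print({z: round(math.exp(v), 3) for z, v in lm.items()})
# {'a': 0.001, 'b': 0.002, 'c': 0.287, 'd': 0.001}
post = posteriors(lm, Priors({"a": 0.7, "b": 0.1, "c": 0.1, "d": 0.1}))
print({z: round(p, 3) for z, p in post.items()})
# {'a': 0.016, 'b': 0.008, 'c': 0.973, 'd': 0.003}
```

The marginal penalty removes the spurious advantage of the 3-parameter
models, and the posterior 0.973 > 0.75 selects *TPR* as an isoform II–IV
target. Note that 0.973 requires carrying the marginals at full
precision; renormalizing the 3-decimal printed values gives 0.966.

End to end on synthetic data:

```sh
bgsc simulate --n-genes 500 --seed 7 --out-matrix m.tsv --out-truth t.tsv
bgsc classify --input m.tsv --out calls.tsv --priors 0.7,0.1,0.1,0.1
# INFO group c: 77 assigned, 63 above posterior 0.75
bgsc evaluate --matrix m.tsv --truth t.tsv
# overall_accuracy  0.8880
# accuracy_a        0.8367
# accuracy_b        1.0000
# accuracy_c        1.0000
# accuracy_d        1.0000
```

`calls.tsv` holds one row per gene: the four posteriors, the assigned
group, and — for genes assigned to the requested group — the log2-fold
change, its standard error, the up/down/none direction call (±0.5 cut)
and the selection flag. At these settings (effects 1–2 log2 units,
noise sd 0.2) every regulated gene is recovered; the unregulated genes
are assigned liberally (the n = 6 BIC penalty is mild), which is why the
posterior threshold, not the assignment, defines the final target list.

`bgsc design` prints the mode table and pattern-group table for any
design (`--design my_design.yaml` or the built-in `egfr-default`).

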