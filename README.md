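# socioscope

Social-network and multimodal-communication-network analysis for
scan-sampled animal behavior data.

Behavioral ecologists studying stable social groups (the motivating system
is plains zebra harems followed across contrasting field seasons) routinely
collect three kinds of data: nearest-neighbor **scan samples** of every
group member, video-coded **multimodal interactions** (sequences of
postures, each a set of concurrent visual/acoustic/tactile/chemical signal
components), and focal-follow **activity intervals**. `socioscope` turns
these into reproducible quantitative answers to three questions: who
associates with whom (and do those bonds change between periods), how is
the signal repertoire organized (and does it shrink or simplify), and how
do individuals budget their time.

## Methods at the core

**Association.** Two individuals are *in association* in a sampling period
if either named the other as nearest neighbor (within one body length).
Dyadic bond strength is the simple ratio index

```
SRI = x / (y_a + y_b + y_ab + x)
```

where, over sampling periods, `x` counts periods with the pair in
association, `y_a` (`y_b`) periods with only `a` (only `b`) observed, and
`y_ab` periods with both observed but not in association. Per harem and
period the package computes degree, per-individual mean SRI and CV of SRI,
network density, and the harem-level CV of dyadic SRIs, and tests for
*preferred associates* by permutation: is the observed CV of bond strengths
higher than expected when association partners are random? Two null models
are provided (see `docs/methods.md`); the default shuffles identities
within each sampling period (a data-stream permutation). Dyadic SRIs are
compared across periods by OLS regression and paired long-format tables.

**Communication.** Signal components are nodes; an edge weight counts the
postures in which two components co-occurred. Components within one
morphological group (e.g. the ear positions) are mutually exclusive, so the
*adjusted density* divides observed edges by `C(n,2) − Σ_g n_g(n_g−1)/2`,
the possible pairs minus impossible within-group pairs. *Component
diversity* is the number of connected nodes. Cleaning removes postures
containing components seen in fewer than two interactions. Cross-period
tests resample the reference period: a posture-subsampling (jackknife) null
for diversity and a node-subsampling null for adjusted density, both with
two-tailed 0.025/0.975 percentile decisions. Context modules come from
greedy (Clauset–Newman–Moore) modularity maximization; the modularity score
`Q` (with the conventional `> 0.3` annotation for discrete repertoires) and
a module-flow table track reorganization between periods.

**Budgets.** Activity proportions over a configurable taxonomy
(self-maintenance / passive social / active social) within 5-minute
subsample windows, steps per minute, active interactions per 30-minute
block, and juvenile partner-shift contingency tables.

**Synthetic data.** Generators with planted ground truth (preferred dyads
with a controlled association-probability multiplier, planted context
modules, masked "lost" components, target budget proportions) make every
stage testable end to end without field data.

## Worked example

Run the full pipeline on a simulated two-period campaign (6 harems, 80 scan
periods split into two 40-period halves with one planted preferred dyad per
harem; an 81-component repertoire observed for 120 vs 40 interactions, with
a sixth of the repertoire lost in the late period):

```
socioscope run --simulate --seed 7 --nperm 200 --out demo_out
```

`demo_out/results.json` then contains (abridged):

```
communication.periods.pre:   diversity 76, adjusted_density 0.468, n_modules 3
communication.periods.late:  diversity 55, adjusted_density 0.353, n_modules 3
communication.diversity_test: observed 55, null_mean 70.4, significant "less"
communication.density_test:   observed 0.353, null_mean 0.467, significant "less"
association.cross_period_regression: slope 0.742, r_squared 0.604, n_dyads 164
association.harems.H00.pre:  density 1.0, cv_harem 0.507, preferred_associate_p 0.015
```

Reading this: the late period's 55 connected signal components are far
below the 66–75 band expected from subsampling the pre-period posture
stream at equal effort, so the repertoire genuinely shrank; adjusted
density also fell beyond what a pure repertoire-size reduction explains, so
the surviving signals were combined less flexibly. Dyadic bond strength in
the first half predicts the second (R² ≈ 0.6), and harem H00's bond-strength
CV is higher than its permutation null (p = 0.015) — its planted preferred
dyad is detected.

Subcommands `assoc`, `comm`, `budget`, and `simulate` expose the individual
stages; every stage is also a plain library call (`socioscope.tally_dyads`,
`build_comm_network`, `diversity_jackknife`, ...).

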