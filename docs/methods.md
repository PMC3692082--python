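# Methods

This note records the model implemented by `comir`, every parameter default
with its rationale, the numerical choices, and the known limitations.

## 1. Sequence conventions

Sequences are handled internally in the DNA alphabet `{A, C, G, T, N}`; RNA
input (`U`) is mapped to `T` on ingestion. Coordinates are 0-based,
half-open, on the sense strand of the target. miRNA positions are counted
1-based from the 5′ end, as is conventional: the **seed** is positions 2–8.

## 2. Seed-site taxonomy (TargetScan-like channel)

A site is anchored at a match to the reverse complement of miRNA positions
2–7 (the 6mer core at target offset `s`). Flanks refine the class:

| class | requirement | reported interval |
| --- | --- | --- |
| 8mer | m8 match at `s−1` **and** `A` at `s+6` | `[s−1, s+7)` |
| 7mer-m8 | m8 match at `s−1` | `[s−1, s+6)` |
| 7mer-A1 | `A` at `s+6` | `[s, s+7)` |
| 6mer | core only | `[s, s+6)` |

Each core occurrence is reported **once**, as the strongest class accepted by
the policy; the default policy accepts `{7mer-A1, 7mer-m8, 8mer}` (6mers are
mostly noise). The A1 position is an `A` in the *target* regardless of miRNA
position 1, matching the biological observation that Argonaute reads the
adenosine directly. The per-gene channel score is the number of accepted
sites, weighted by miRNA concentration at aggregation time.

## 3. Duplex energy model (miRanda-like channel)

Seed-anchored, ungapped hybridization energy from a nearest-neighbor stack
table. The miRNA 3′-anchored window `t[max(0, s+7−L_m) : s+7]` is aligned
antiparallel to the miRNA; position `i` of the miRNA pairs position
`L_w−1−i` of the window. Pairing is Watson–Crick or G:U wobble. Energy is

```
ΔG = ΔG_init + Σ over consecutive paired positions of ΔG_stack
```

with `ΔG_init = +4.09 kcal/mol` (duplex initiation) and the ten
Watson–Crick RNA:RNA stacking free energies at 37 °C (Turner-style values,
−0.93 to −3.42 kcal/mol), closed under reversal of the duplex. Stacks
involving one wobble pair use a coarse single value of −1.3 kcal/mol, and
−0.5 kcal/mol when both pairs are wobbles; these are deliberate
simplifications (the true values depend on context) chosen to keep wobbles
stabilizing but weaker than any Watson–Crick stack. Only sites with `ΔG < 0`
are emitted. This is not a full secondary-structure fold: no bulges, no
internal loops, no target accessibility — accessibility is the role of the
imported ΔΔG channel.

## 4. Imported channels

PITA-like ΔΔG and mirSVR-like scores are imported from 5-column TSV
(`gene_id  mirna_id  start  end  score`). Rows that fail to parse or violate
the coordinate invariant are rejected and counted (`n_rejected`); a strict
mode raises instead. Imported tables take precedence over built-in
computation for their channel and are validated against the sequence universe
(site intervals must fit inside the named gene).

## 5. Expression preprocessing

* **log→linear**: `x ← base^x`, only when the table declares log input;
  default base 2 (microarray convention).
* **ID resolution**: alias map renames to canonical miRBase-style IDs;
  unknown IDs are dropped and reported as `(id, "unknown_id")`; two aliases
  colliding onto one canonical ID is an error (silent merging would corrupt
  concentrations).
* **Concentrations**: `c_i = x_i / Σ_j x_j` per sample; an all-zero sample is
  an error naming the sample.
* **Filtering**: miRNAs are sorted by descending concentration (ties broken
  lexicographically by ID for determinism). The coverage filter keeps the
  minimal prefix whose cumulative concentration reaches `coverage_percent`
  of the **original** sample total — the threshold is absolute
  (`coverage_percent/100`), which makes the filter idempotent: reapplying it
  to its own output changes nothing. The `min_level` filter (on raw levels)
  intersects with it; `always_keep` IDs are added back afterwards.
  Concentrations are **not** renormalized after filtering by default: the
  removed mass represents real miRNAs that still titrate nothing, and
  renormalizing would inflate the survivors' occupancies. An explicit
  `renormalize=True` is available.
* **Modes**: `set` mode yields one concentration vector per sample
  (combinatorial scoring); `single_mirna` mode yields one vector per miRNA
  with `c = 1` (classical one-miRNA-at-a-time scoring, for comparison).

## 6. Channel aggregation

**Fermi–Dirac (energy channels).** Each site of energy `E` for miRNA `i`
contributes an occupancy

```
p = 1 / (1 + exp((E − μ_i) / kT)),   μ_i = μ₀ + kT · ln(max(c_i, ε))
```

computed via `scipy.special.expit` for overflow safety. Defaults:
`kT = 0.593 kcal/mol` (RT at 310 K — energies are physical, so the
temperature factor should be too), `μ₀ = 0` (reference chemical potential at
unit concentration; concentrations are dimensionless fractions, so the
offset is a free scale absorbed downstream by rank normalization),
`ε = 1e−9` (guards `ln 0` for a zero-concentration miRNA, pushing μ to
−∞ in practice: occupancy ≈ 0, as it should be). The per-gene score is the
sum of occupancies over all sites of all expressed miRNAs; sites naming
miRNAs absent from the concentration vector are ignored and counted.

**Weighted sum (count/score channels).** `S_g = Σ_i c_i · s_{gi}` where
`s_{gi}` is the site count (TargetScan channel) or the sum of site scores
(mirSVR channel) for gene `g`, miRNA `i`.

Both combiners are additive over sites, monotone in concentration
(increasing a miRNA's level, holding others fixed, cannot lower the score of
a gene it targets), and exactly reproducible by a double loop over sites —
the property the test-suite oracles exploit.

## 7. Rank normalization and SVM integration

Each channel is converted to fractional ranks `r = rank/n ∈ [1/n, 1]` with
midranks for ties, oriented so larger = more target-like (`mirsvr` is
negated in orientation: more negative scores mean stronger predicted
repression). Fractional ranks were chosen over z-scores because the channel
distributions are heavy-tailed and on incommensurate scales; ranks are
invariant to any monotone recalibration of a channel, which the tests assert
exactly.

The integrator is an RBF-kernel SVC (`C = 1`, `gamma = "scale"`) wrapped in
`CalibratedClassifierCV(method="sigmoid", ensemble=False)` with stratified
K-fold calibration (default 5 folds, reduced to the minority-class count
when the training set is tiny; fewer than 2 minority examples is an error).
RBF was chosen because channel evidence is complementary rather than
redundant — the decision surface in rank space is not linear — and sigmoid
(Platt) calibration turns the margin into the probability-like ComiR score.
All randomness (fold shuffling, SVC tie-breaking) is seeded; retraining with
the same seed reproduces the model bit-for-bit in its reported metadata.
`cv_auroc` in the metadata is computed with a separate stratified K-fold
(seeded with `seed+1`) so the reported number is not the calibration fit.

No trained model binary ships with the package; `default_model()` trains on
the default synthetic fixture at call time, deterministically.

## 8. Differential targeting

Per-gene scores across two disjoint groups of sample labels (each ≥ 3) are
compared with a two-sided Wilcoxon rank-sum test.

* **Exact path** (`min(n, m) ≤ 8` and `C(n+m, n) ≤ 50 000`): midranks are
  assigned to the pooled values and the null distribution of the rank sum is
  enumerated over all `C(n+m, n)` group labelings; the p-value is the
  fraction of labelings at least as extreme (`|W − μ| ≥ observed − 1e−9`,
  the tolerance guarding float equality of midrank sums). This handles ties
  exactly, which off-the-shelf exact implementations do not.
* **Asymptotic path** otherwise: normal approximation with tie-corrected
  variance `σ² = (nm/12)·((N+1) − Σ(t³−t)/(N(N−1)))` and continuity
  correction 0.5.

The exact test is discrete and therefore conservative at the smallest group
sizes: at `n = m = 5` the largest attainable level below 0.05 is ≈ 0.032, so
the empirical type-I error sits below α by construction — a property of all
exact rank tests, not a defect. At `n = m = 8` the attainable level is
≈ 0.055 and empirical calibration at α = 0.05 is observed within binomial
error. Optional Benjamini–Hochberg correction uses
`scipy.stats.false_discovery_control`. The score-difference report is
`mean(A) − mean(B)`; `use_ranks=True` applies per-label rank normalization
first, making the comparison robust to per-sample calibration differences.

## 9. Synthetic fixture generator

The generator emulates the *statistical structure* the method exploits, not
biology:

* UTRs are uniform random sequences (default 300–800 nt, GC 0.5); real UTRs
  have composition bias and conserved elements — not modeled.
* Expression follows a power law `x_rank ∝ rank^{−1}` with lognormal
  per-sample jitter (σ = 0.25), reproducing the dominance of a few miRNA
  species in real small-RNA profiles.
* Half the genes (the target class) receive 2–4 planted, non-overlapping
  exact 8mer sites (`revcomp(m[1:8]) + "A"`) for miRNAs drawn from the top 5
  expressed — so target-ness is only detectable *through* expression
  weighting, which is the point of the method.
* Imported-channel tables are generated to track planted-site strength with
  Gaussian noise (PITA ΔΔG ≈ −(6 + 3·strength) ± 1.0, capped below −0.1;
  mirSVR ≈ −(0.1 + 0.12·strength) ± 0.05, capped below −0.001), plus a
  Poisson background of weak sites on all genes, so the channels are
  informative but imperfect and the SVM has real integration work to do.
* Decoy genes still contain chance seed matches at the analytic background
  rate `(L−6)·4^{−7}` per miRNA, verified in tests.
* `snp_pair(gene, position)` substitutes the target base inside a planted
  site with the base the miRNA itself carries at the paired position — a
  substitution that can never form a Watson–Crick or wobble pair with it,
  guaranteeing seed disruption without tuning.

Everything is driven by one integer seed through `numpy.random.default_rng`;
identical seeds give bit-identical bundles, and bundles round-trip through
plain-text files (FASTA, CSV, TSV).

## 10. Numerical and engineering choices

* Occupancies via `expit`; no `exp` overflow anywhere in the FD path.
* Ranking via `scipy.stats.rankdata(method="average")`.
* Sorting tie-breaks are always lexicographic by ID, so every pipeline stage
  is deterministic under hash randomization.
* Seeds derived for sub-tasks stay below 2³¹ (`SeedSequence.generate_state`
  reduced mod 2³¹) for portability.
* Model persistence is joblib at run time only; the repository itself is
  text-only.

## 11. Limitations

* The energy model is seed-anchored and ungapped: no 3′-supplementary
  pairing, bulges, or target accessibility (delegated to the imported ΔΔG
  channel).
* Wobble stack energies are coarse constants.
* The default model is trained on synthetic data; on real data it should be
  retrained on a curated positive/negative gene set via `train_model`.
* Concentration fractions ignore absolute miRNA abundance and Argonaute
  loading; `μ₀` is a free parameter that a real calibration would fit.
* The exact rank-sum p-value is conservative for groups of ≤ 5 samples, as
  all exact discrete tests are.
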