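# microsyntax

Higher-order syntax analysis of discrete label sequences, built for EEG
microstate research.

Microstate analysis compresses multichannel EEG into a sequence of class
labels (conventionally A–D, here 0..K−1).  Classical "syntax" analysis of
such sequences stops at first-order statistics: the state distribution
**p** and the transition matrix **T**, with joint matrix
P<sub>ij</sub> = p<sub>i</sub> T<sub>ij</sub>.  `microsyntax` quantifies
structure *beyond* first order using two entropy families over word
lengths k:

* **Entropy rate** — the plug-in conditional entropy of the next label
  given the preceding k-word,
  ER(k) = H(X<sub>t+1</sub> | X<sub>t</sub><sup>(k)</sup>), a measure of
  short-range predictability;
* **Sample entropy** — the negative log probability that a recurring
  k-word's recurrence extends one step further,
  SE(k) = −log₂ Pr(X<sub>t+1</sub>=X<sub>s+1</sub> |
  X<sub>t</sub><sup>(k)</sup>=X<sub>s</sub><sup>(k)</sup>), a
  whole-sequence recurrence (collision) statistic.  For discrete labels a
  collision is exact word equality — no tolerance radius is involved.

For a first-order Markov chain both curves are flat in k with closed-form
levels

    ER = −E(log₂ T) = −Σ_ij P_ij log₂ T_ij
    SE ≈ −log₂ E(T)  = −log₂ Σ_ij P_ij T_ij

linked by Jensen's inequality ER ≥ SE; the zero-order (i.i.d.) levels are
the Shannon entropy H(**p**) and the order-2 Rényi entropy
−log₂ Σ p<sub>i</sub>².  Deviations of the empirical curves from these
baselines — tested against seeded Markov surrogates with matching **p**
and **T** — are the signature of genuine higher-order syntax.  The
normalized measures

    σ_C(h) = log(h/h0) / log(h1/h0)      (continuous sequences)
    σ_J(h) = 1 + log₂(h1/h)              (jump sequences)

rescale any coefficient h so that 0 means zero-order, 1 first-order and
σ > 1 more structure than a first-order chain, making curve *shapes*
comparable across groups whose absolute entropy levels differ.

The package covers the full pipeline: sequence containers (continuous
per-sample sequences and jump sequences with duplicates collapsed),
transition-model fitting, ER/SE estimation, closed-form baselines, seeded
surrogate generation, normalized σ profiles, and group statistics
(Wilcoxon real-vs-surrogate within group, Mann-Whitney between groups,
Benjamini–Hochberg FDR across the tested k values, α = 0.05), plus
synthetic generators of known syntactic order for validation.

## Worked example

```python
import microsyntax as ms

# a microstate-like continuous chain: K=4, mean dwell 12 samples,
# 100,000 samples at 500 Hz (200 s)
seq = ms.generate_microstate_like(
    n_states=4, T_jump=ms.random_jump_matrix(4, seed=0),
    dwell_mean_samples=12.0, length=100_000, fs_hz=500.0, seed=1,
)
profile = ms.syntax_profile(seq, kmax=6)
print(profile.to_frame().round(4).to_string(index=False))
```

```
 k     er     se  er_mc0  er_mc1  se_mc0  se_mc1
 0 1.9909 1.9814  1.9909  0.5303  1.9814  0.2478
 1 0.5303 0.2472  1.9909  0.5303  1.9814  0.2478
 2 0.5300 0.2467  1.9909  0.5303  1.9814  0.2478
 3 0.5292 0.2465  1.9909  0.5303  1.9814  0.2478
 4 0.5275 0.2456  1.9909  0.5303  1.9814  0.2478
 5 0.5250 0.2447  1.9909  0.5303  1.9814  0.2478
 6 0.5213 0.2450  1.9909  0.5303  1.9814  0.2478
```

The chain is first-order by construction, so the empirical ER curve sits
on the theoretical first-order level (`er_mc1` = 0.5303 bits; −E log₂ T of
the fitted model) and the SE curve on the collision approximation
(`se_mc1` = 0.2478 bits), with ER ≥ SE at every k.  The k = 0 slots hold
the zero-order levels: Shannon entropy of the label distribution (1.9909
bits, near log₂ 4 = 2) and its Rényi-2 counterpart.  The normalized curve
confirms first-order behaviour:

```python
print(ms.normalized_profile(profile, "ER").sigma.round(3))
# [1.    1.    1.001 1.004 1.007 1.013]
```

Values of σ ≈ 1 for all k mean "no structure beyond the transition
matrix"; on a genuinely second-order chain
(`ms.second_order_jump_table`) σ rises above 1 from k = 2 on.  Collapsing
the sequence (`ms.to_jump_sequence`) yields the ~8,400-label jump
sequence; its ER(6) estimate (1.215 bits) falls visibly below the
first-order level (1.361 bits) purely because 4·3⁵ = 972 six-letter jump
words are undersampled at that length — the profile records a bias
warning, and regenerating surrogates at 10⁵ samples removes the gap.

## Command line

```bash
microsyntax generate --preset continuous -n 100000 --n-sequences 24 --seed 1 --out-dir cohort_a
microsyntax analyze cohort_a/synthetic_continuous_order1_000.txt --kmax 6
microsyntax surrogate cohort_a/synthetic_continuous_order1_000.txt --order 1 --n-surrogates 10
microsyntax compare cohort_a/manifest.json cohort_b/manifest.json --seed 1 --out comparison
```

`analyze` writes a JSON + CSV profile report (ER/SE curves, baselines,
σ, warnings); `compare` consumes two JSON manifests (group label, K,
kind, file list) and writes per-family test tables with raw and
FDR-adjusted p-values.

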