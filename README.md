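# slmcnv

Shifting-level-model segmentation of genomic copy-number profiles.

Copy-number variants (CNVs) appear in read-depth and array data as runs of
consecutive windows whose signal shifts up (duplication) or down (deletion)
relative to the diploid baseline. Finding them reduces to segmenting a noisy
ordered signal — window read counts or log2-ratios — into runs of constant
mean and locating the breakpoints. `slmcnv` implements two segmenters built
on the shifting level model, plus the surrounding plumbing a CNV analysis
needs: read-count normalization, synthetic profiles with known truth, and
breakpoint/CNV scoring.

## The model

A log2-ratio profile x₁,…,x_N is modeled as the sum of two independent
processes

    x_i = m_i + ε_i,                         ε_i ~ N(0, σ²_ε)
    m_i = (1 − z_{i−1})·m_{i−1} + z_{i−1}·(μ + δ_i),   δ_i ~ N(0, σ²_m)

where m_i is an unobserved piecewise-constant mean level: with probability
η = Pr(z_i = 1) it jumps to a fresh draw from N(μ, σ²_m), otherwise it stays
put, and the observation adds white noise σ²_ε. Discretizing the level
process onto a grid of K data-quantile levels with prior π turns this into a
hidden Markov model with the stay-or-jump transition matrix

    A[j,k] = (1 − η)·1[j = k] + η·π_k

and Viterbi decoding of that HMM yields the segmentation
(`ShiftingLevelModel`).

For spatially sparse data (exome targets separated by large unsequenced
gaps) the heterogeneous variant (`HeterogeneousShiftingLevelModel`) makes
the jump probability a function of the genomic distance d_i between
consecutive windows:

    Pr(z_i = 1) = η(d_i) = θ + (1 − θ)·exp[ log(θ) / (d_i / d_Norm) ]

η(d) rises continuously from its baseline θ (dense data, d → 0) toward 1
(d → ∞); d_Norm sets the distance at which the rise begins. With all gaps
zero the heterogeneous model reduces bit-identically to the homogeneous one
with η = θ.

## Worked example

```python
from slmcnv import ShiftingLevelModel, SimulationConfig, simulate_profile

cfg = SimulationConfig(total_windows=10_000, n_altered=100, noise_sd=0.2, seed=1)
profile, truth = simulate_profile(cfg)      # one-copy loss, 100 windows
res = ShiftingLevelModel(profile).fit()
print(res.summary())
```

```
ShiftingLevelModel segmentation
==============================================
windows:      10000
segments:     3
breakpoints:  2
mu:           -0.00607414
sigma2_m:     0.0913621
sigma2_eps:   0.0391552
omega:        0.3
grid levels:  41
degenerate:   False
----------------------------------------------
chrom        start       end  n_win  mean_level
chrS             0    153000    153  +0.0013
chrS        153000    253000    100  -0.9881
chrS        253000  10000000   9747  -0.0031
```

The simulated event spans windows 153–252 (`truth.breakpoints == [153, 253]`)
with a true shift of −1 (one-copy loss on the log2 scale); the fit recovers
both breakpoints exactly, estimates the noise variance σ²_ε ≈ 0.039 (truth
0.04), and reports the event's empirical mean level −0.988.
`res.call_cnvs()` then classifies the middle segment as a LOSS call spanning
153 000–253 000 bp:

```
CNVCall(chrom='chrS', start=153000, end=253000, copy_state=LOSS, mean_level=-0.988)
```

The same pipeline is available from the shell:

```sh
slmcnv simulate --total 10000 --n-altered 100 --noise-sd 0.2 --seed 1 --out sim
slmcnv segment sim.profile.tsv sim.segments.tsv --mode slm --cnv-bed sim.calls.bed
slmcnv evaluate --calls sim.calls.bed --truth sim.truth.bed
```

## File formats

Profiles are tab-delimited tables (gzip-transparent) with columns
chromosome, start, end, value — coordinates 0-based half-open (BED
convention) — plus optional GC-fraction and mappability columns consumed by
`slmcnv normalize`. Segment tables carry chrom, start, end, n_windows,
mean_level; CNV calls are BED rows with the copy state in column 4. Floats
are written with full round-trip precision, so reading back a written table
is bit-exact.

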