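# scedrand

Randomization tests for **single-case experimental designs (SCEDs)** with
**response-function test statistics**.

In a single-case experiment one case is measured repeatedly across baseline
(A) and intervention (B) conditions, and randomization of the design — the
intervention start point, the tier order of a multiple baseline, the phase
changes of an ABAB reversal, the block order of an alternating treatments
design — licenses an exact significance test without any distributional
assumptions. Classical applications quantify only the simplest effect, an
immediate and sustained change in level. Real intervention effects are often
**delayed** (a latency of L occasions before anything happens), **gradual**
(a ramp rather than a step), or **temporary** (the effect wears off after d
occasions).

`scedrand` encodes any such expectation as a *response function*: a vector
of predicted-response constants, one per measurement occasion — e.g.
`{0,0,0,0,0, 1,1,1,1,1}` for an immediate abrupt permanent effect, or
`{0,0,0,0,0, 1,2,3,2,1}` for an immediate gradual effect lasting three
occasions and fading gradually. The test statistic is **Pearson's r**
between the observed scores and the response function,

    T = corr(y, f),

which with a binary response function is the point-biserial correlation.
For every admissible data division of the randomization scheme the response
function is rebuilt for that division's phase lengths, giving the exact
randomization distribution of T; the one-sided p value is

    p = #{divisions with T >= T_obs} / m,

with m the number of admissible divisions, so the smallest attainable p is
1/m. Exploratory scans over latencies (L = 1..L_max) and effect durations
(d = 1..d_max, plus the permanent case) report one test per scenario, with
optional Bonferroni/Holm adjustment.

## Worked example

Input files are two-column text files with a `phase` column of condition
letters and a `score` column of measurements, one row per occasion. The
`fixtures` subcommand writes synthetic example datasets:

```sh
scedrand fixtures --out fx --seed 3
scedrand test --data fx/immediate_abrupt.txt --min-a 4 --max-a 10 --min-b 8 --out run1
```

prints

```
r_obs=0.9729 rank=1/6 p=0.1667 (min attainable 0.1667)
```

The series has 17 occasions; baselines of 4–10 occasions with an
intervention of at least 8 leave 6 admissible start points, the observed
correlation 0.973 is the largest of the 6 pseudovalues (rank 1), and the p
value is the smallest this single A-B comparison can produce, 1/6 ≈ 0.167.
`run1/` also holds a time-series plot, the randomization-distribution plot
(observed statistic in green when favorable, red otherwise), and the full
pseudovalue table `divisions.tsv`.

An exploratory latency scan on a series generated with a true delay of two
occasions:

```sh
scedrand scan --data fx/delayed_abrupt.txt --min-a 3 --min-b 3 \
              --scan latency --latency-max 5 --out run2
```

```
L=1: r_obs=0.8646 rank=2/9 p=0.2222
L=2: r_obs=0.9788 rank=1/9 p=0.1111
L=3: r_obs=0.8252 rank=3/9 p=0.3333
L=4: r_obs=0.7127 rank=4/9 p=0.4444
L=5: r_obs=0.6265 rank=4/9 p=0.4444
```

The statistic peaks at L=2 — the scan recovers the generating latency.

The same machinery is available as a library:

```python
from scedrand import ABStartScheme, EffectSpec, randomization_distribution, read_sced_file

series = read_sced_file("fx/immediate_abrupt.txt")
scheme = ABStartScheme(n=series.n, min_A=4, max_A=10, min_B=8)
result = randomization_distribution(series, scheme, EffectSpec())
print(result.r_obs, result.rank, result.p)
```

Multiple-baseline designs (Wampold–Worsham and Koehler–Levin
randomization), ABAB reversal designs, and block-randomized alternating
treatments designs are supported through the same interface; see
`docs/methods.md` for the statistical details, and the `simulate`
subcommand for Monte-Carlo validity and power estimates.

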