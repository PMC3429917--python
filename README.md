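# ldtscan

Permutation-based significance thresholds for QTL genome scans in
two-genotype crosses (backcross / doubled haploid), for geneticists who
map quantitative trait loci with single-marker regression and want
control of **both** the genome-wide and the local Type-I error rate.

## The statistics

A genome scan computes a LOD score at each of `n_m` markers,
`LOD = −(n/2)·log₁₀(1 − R²)` from the regression of phenotype on the
0/1 genotype class. Under the no-QTL null, the max-LOD statistic is the
pair `M = (δ, λ)`: the magnitude and the marker index of the scan
maximum, sampled empirically by permuting the phenotype vector `n_p`
times.

Two thresholds for a target genome-wide error rate (GWER) `γ`:

* **CD (Churchill–Doerge)** — the constant `(1 − γ)` quantile of the
  marginal `δ` distribution: `P{δ > T_CD} = γ`. Controls the GWER, but
  when the location distribution `P{λ = i}` is non-uniform (*location
  bias* — e.g. dense marker clusters attain the maximum less often per
  marker than sparse regions), false positives concentrate unevenly.
* **LDT (location-dependent threshold)** — per-marker quantiles of the
  `λ`-conditioned `δ` distribution at exceedance level `γ·α_i`, where
  `α_i = 1/(n_m·P{λ = i})` is the bias factor. This achieves
  `P{δ > T_LDT,i, λ = i} = γ/n_m` at every marker: same GWER `γ`,
  constant local error rate. Exists iff `γ < min_i{1/α_i}`; with no
  bias (`α_i ≡ 1`) it collapses onto the CD threshold.

Both methods come with adjusted P-values (`(r+1)/(n_p+1)` convention;
the LDT one is `n_m ×` the joint exceedance count at the peak's marker).
See `docs/methods.md` for derivations, conventions and limitations.

## Worked example

A 200-line doubled-haploid cross on the packaged 34-marker map (dense
2-cM clusters flanking a sparse 16-cM region — a layout with strong
location bias):

```python
import ldtscan as L

gmap = L.dense_sparse_demo_map()
pop = L.simulate_population(gmap, n_obs=200, cross_type="doubled_haploid", seed=42)
sample = L.sample_max_lod(pop, n_p=L.required_permutations(gmap.n_markers), seed=7)
ld = L.location_distribution(sample)

t_cd = L.cd_threshold(sample, 0.20)     # constant 20% genome-wide threshold
t_ldt = L.ldt_threshold(sample, 0.20)   # location-dependent 20% threshold

scan = L.genome_scan(pop)
peak = L.max_lod(scan, rng=0)
p_cd = L.cd_adjusted_p(sample, peak.delta)
p_ldt, _, p_max = L.ldt_adjusted_p_detail(sample, peak.delta, peak.lam)
```

Output (printed by the snippet above with f-strings):

```
n_p = 170000, validity upper bound = 0.356
CD threshold (constant): 1.216
LDT threshold range:     0.715 (dense) .. 1.564 (sparse)
observed peak: LOD 1.543 at marker 5 (m005)
CD-adjusted P = 0.0986, LDT-adjusted P = 0.0384 (attainable max 0.389)
alpha range: 0.44 (marker 15) .. 2.81 (marker 32)
```

Reading it: `n_p = 5000·n_m` permutations estimate the conditional
max-LOD distributions; the LDT construction is valid for any
`γ < 0.356`. The CD threshold is one number (1.216) for the whole
genome, while the LDT threshold rises to 1.564 in the sparse region
(which attains the null maximum more than its uniform share,
`α < 1`) and drops to 0.715 inside the dense clusters (`α > 1`). The
observed peak at marker 5 sits in a dense cluster, so its
location-adjusted P-value (0.038) is smaller than the marginal CD one
(0.099): at this marker, null maxima of that size are rare. The
"attainable max" 0.389 is `1/α` at that marker — the GWER level beyond
which the LDT family no longer covers it.

The same pipeline is available from the shell:

```sh
ldtscan simulate --n-obs 200 --seed 42 --out cross.csv      # packaged map
ldtscan scan     --cross cross.csv --out scan.csv
ldtscan permute  --cross cross.csv --n-p auto --seed 7 --out sample.csv
ldtscan threshold --sample sample.csv --gamma 0.2 --method both --out thresholds.csv
ldtscan adjust   --sample sample.csv --scan scan.csv --out adjusted_p.csv
ldtscan biastest --sample sample.csv
ldtscan sweep    --replicates 30 --out sweep.csv --plot sweep.png
```

Cross files use the R/qtl "csv" layout (phenotype column first, marker
columns with chromosome and cM rows, genotype codes `A`/`H`); permutation
samples persist as `delta,lambda` CSV plus a JSON sidecar and can be
reused across `γ` levels.

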