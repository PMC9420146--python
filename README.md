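# instarfit

Determining how many larval instars an insect passes through from
head-capsule-width (HCW) measurements. Entomologists collect larvae in the
field, measure each head capsule under a stereo microscope, and face a
mixture problem: the widths cluster by instar (head size is fixed within an
instar and jumps at each moult), but the clusters overlap. `instarfit`
resolves the multi-peak frequency distribution into weighted normal
components, places the instar dividing points where adjacent curves
intersect, and validates the resulting instar count with the classical
morphometric criteria. The motivating case is the oak leaf-mining weevil
*Rhynchaenus maculosus*, whose 401 measured larvae resolve into three
instars.

## The model

The HCW sample x₁…x_n is modelled as a k-component univariate Gaussian
mixture,

    f(x) = Σⱼ wⱼ · N(x | μⱼ, σⱼ²),   Σ wⱼ = 1,

fitted by maximum likelihood (EM) on the raw values, with k chosen by BIC
over a user-set range. Each component is one instar. The boundary between
instars j and j+1 is the solution of

    wⱼ N(x | μⱼ, σⱼ²) = wⱼ₊₁ N(x | μⱼ₊₁, σⱼ₊₁²)

lying between the two means (quadratic in x, closed form). The partition is
then validated by:

* **coefficient of variation** — within-instar CV = 100·s/x̄ below 15 %;
* **Brooks' index** — the growth ratio bₙ = x̄ₙ / x̄ₙ₋₁ of successive mean
  widths;
* **Crosby's growth rule** — |(bₙ − bₙ₋₁)/bₙ₋₁| below 0.1, i.e. a
  near-constant growth ratio, the signature that no instar was missed or
  split;
* **Dyar's rule** — OLS regression of ln(x̄ₙ) on instar number n; under
  geometric growth R² ≈ 1 and exp(slope) estimates the common growth
  factor.

Because the raw measurements behind the published three-instar
determination were never deposited, the package ships a seedable generator
(`instarfit.simulate`) that draws synthetic samples from the published
per-instar summaries (counts 65/145/191; means 365.0/473.7/578.0 μm;
CVs 5.30/5.26/4.38 %; observed range 300–650 μm) for parameter-recovery
testing.

## Worked example

```sh
instarfit simulate --preset table1 --seed 1 --out hcw.csv
instarfit analyze --input hcw.csv --seed 1 --k-min 1 --k-max 5 --format text
```

prints

```
Instar analysis (n = 401)
Selected components: k = 3
  k = 1: BIC = 4665.2753
  k = 2: BIC = 4525.2516
  k = 3: BIC = 4429.1377
  k = 4: BIC = 4444.0116
  k = 5: BIC = 4463.4671
Instar boundaries (μm): 405.6134, 523.8382
instar	n	mean±SE (μm)	CV%	Brooks	Crosby
1	64	363.0012 ± 1.9744	4.3512	—	—
2	145	471.1152 ± 1.9921	5.0918	1.2978	—
3	192	574.6751 ± 1.5278	3.6837	1.2198	-0.0601
Criteria (CV < 15%, |Crosby| < 0.1): PASS
Dyar regression: slope = 0.2297 (growth factor 1.2582), R² = 0.9940, F = 164.7378, p = 0.0495
```

BIC bottoms out at k = 3: three instars. The two boundaries (≈406 and
≈524 μm) split the 401 simulated larvae into 64/145/192 — the generating
truth is 65/145/191, with the one swap occurring right at a boundary. Every
within-instar CV is far below 15 %, the growth ratios (≈1.30, ≈1.22) are
nearly constant so Crosby's index is small, and the log-linear Dyar fit has
R² = 0.994: all criteria agree on three instars. `--format json` emits the
same content machine-readably; `--plot DIR` adds the fitted-histogram and
Dyar-regression figures.

The same pipeline runs on real data: any CSV/TSV with a numeric width
column (μm, or mm with `unit="mm"` through the API) works via
`instarfit analyze --input file.csv --column <name>`.

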