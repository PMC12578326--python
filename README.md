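# parallign

Quantify **parallel growth of dendritic branches** in 2D fluorescence
micrographs — and decide whether the parallelism you see could have arisen
by chance.

Cultured neurons labeled with a dendritic marker (e.g. MAP2) form dense 2D
networks in which neighboring branches often run side by side.  `parallign`
automates the whole measurement chain:

1. **Segmentation** — grayscale conversion, multi-scale Frangi vesselness
   filtering (σ = 0.25 … 3.5 in steps of 0.25) to enhance curvilinear
   structures, slider-style intensity thresholding (1–10 → 0–255),
   small-object removal, and topology-preserving skeletonization.
2. **Branch extraction** — branch points found by 8-neighbor pixel
   connectivity; the skeleton is split into maximal paths; each branch gets
   an arc length (px) and a principal-axis orientation in [0°, 180°)
   relative to the horizontal axis; branches shorter than a length threshold
   (slider 1–10 → 5–200 px, default 50 px) are discarded.
3. **Parallel grouping** — branches whose orientations agree within ±10°
   (circular, period 180°) are clustered into parallel groups; group sizes
   are tabulated as a frequency table `freq[k]`.
4. **Null model** — for an image with *n* branches, the chance that a branch
   aligns with others is modeled as Bernoulli with *p* = 1/*n*, so the size
   of a parallel group follows Binomial(*n*, 1/*n*):

   P(k) = C(n, k) · (1/n)ᵏ · (1 − 1/n)ⁿ⁻ᵏ,

   and *n*·P(k) is the expected number of groups of size *k* in a randomly
   oriented image of the same complexity.
5. **Statistics** — per image: measured parallelism PM = Σₖ k·freq[k] / n,
   its null-model analogue PS, the ratio PMS = PM/PS, and group-weighted
   parallelism Σₖ k²·freq[k] with its measured/simulated ratio.  Across
   images: means/SDs and the least-squares slope of parallel-line counts
   regressed on branch counts.

No biological data is needed to exercise any of this: the
`parallign.synthetic` module renders micrograph-like images of planted
parallel-line groups, distractor lines, point-spread blur and noise, with
exact ground truth.

## Worked example

```python
from parallign import FixtureSpec, NullModelConfig, expected_counts, render_fixture, run_single

img, truth = render_fixture(FixtureSpec(seed=3))   # groups {2,3,4} + 5 distractors
rec = run_single(img).record
print(rec.n_branches, rec.measured.freq, rec.pm, rec.ps, rec.pms)

null61 = expected_counts(61, NullModelConfig(mode="integerized"))
print(null61.expected_groups_by_k, null61.groups_total)
```

prints (formatted):

```
branches detected : 14 (planted 14)
group sizes       : {2: 1, 3: 1, 4: 1} (planted {2: 1, 3: 1, 4: 1})
PM  (measured)    : 64.3%
PS  (null model)  : 92.9%
PMS (PM / PS)     : 0.692
null model n=61   : {2: 12.0, 3: 4.0, 4: 1.0, 5: 1.0} -> 18 groups
```

The fixture plants 9 of 14 lines in parallel groups, and the pipeline
recovers exactly that (PM = 9/14 ≈ 64.3%).  PMS < 1 here because at small
*n* the integerized null model is generous: a 14-branch random image is
*expected* to produce ~13 parallel lines, so this particular fixture is no
more parallel than chance.  For the 61-branch worked example the null model
predicts 18 parallel groups (twelve pairs, four triples, one quartet, one
quintet).

## Command line

```bash
parallign run images/ --threshold 2 --min-length 3 --tol-deg 10 \
    --null-mode integerized --out results/
```

processes every PNG/TIFF/JPG/BMP in `images/` (lexicographic order), prints
the per-image summary table plus cross-image aggregates, and writes
`branches.csv` (per-branch measurements), `summary.csv` (per-image S1-style
rows) and `*_overlay.png` (branches colored by parallel group).  A YAML
config file of `key: value` pairs can replace any flag (`--config`).

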