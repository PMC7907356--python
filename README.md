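# evofoodweb

A spatially extended evolutionary food web model, with the macroecological
analysis suite to study the biodiversity patterns it generates.

Ecological pattern formation — species abundance distributions, species–area
relationships (SAR), distance decay of community similarity, range-size
distributions (RSD), species lifetime distributions, and the waxing and
waning of geographic ranges — is usually modelled for a single trophic
layer.  `evofoodweb` implements an evolutionary *food web* metacommunity:
local multi-trophic communities on a periodic square lattice of habitats,
coupled by dispersal, driven by speciation, with all extinctions emerging
from the trophic dynamics (no extrinsic extinction rate).  Because local
biomasses come from an algebraic donor-controlled equilibrium instead of
simulated population dynamics, evolutionary time scales on hundreds of
habitats are cheap to simulate, and spatial and temporal patterns can be
studied together, stratified by trophic level.  It is aimed at theoretical
and community ecologists studying how trophic structure shapes
macroecological patterns.

## Model

A species is a triple *(m, f, s)*: log body mass, feeding center and
feeding width on a common (natural) log mass axis.  Consumer *i* attacks
prey *j* with a truncated Gaussian kernel

    a_ij = exp( −(f_i − m_j)² / (2 s_i) ),    a_ij = 0 for |f_i − m_j| > c·s_i ,

and consumers of a shared prey split it by competitive handicap
*F = exp(−((a\* − a)/δ)²)* (with *a\** the best consumer's strength),
normalized to feeding shares γ_ij that sum to 1 over each prey's consumer
set.  Biomass densities solve the donor-controlled transport relation

    B(i) = γ_i0 R + λ Σ_j [ γ_ij B(j) − γ_ji B(i) ] ,

where *R* is the external resource supplied to every habitat and λ the
transfer efficiency; flows depend only on the prey's standing biomass (no
top-down effects), and share normalization makes total community biomass
exactly *R*.  A population persists only if *B ≥ 1* (the extinction
threshold); sub-threshold populations are removed one at a time with
re-equilibration in between, which can trigger secondary extinctions.

Events: speciation (rate 1 per habitat per time unit — the model's clock)
draws a child with *m* within a factor *q* of its parent, *f* uniform in
*[m−dm₁, m−dm₂]*, *s* uniform in *[s_min, s_max]*; dispersal (rate *d* per
habitat per time unit) copies a biomass-weighted source population to a
random lattice neighbor.  Default parameters: λ=0.65, δ=0.25, R=25, q=5,
dm₁=3, dm₂=1, s∈[0.5,1], d=10, threshold 1, kernel cutoff c=1.

The analysis suite computes trophic levels, rank-abundance curves,
lifetime distributions with power-law fits, nested-shell SARs, Jaccard
similarity decay split into basal (trophic level 1) and higher strata,
range-size distributions, range-trajectory shape classification
(hat-shaped vs multi-peaked), and extinction-cause attribution.
See `docs/methods.md` for the full model description and all analysis
conventions.

## Worked example

Simulate a 6×6 lattice for 500 speciation events per habitat and analyze
the run:

```bash
evofoodweb simulate --width 6 --height 6 --steps 500 --seed 1 \
    --out runs/demo --quiet
evofoodweb analyze --run runs/demo
python -m json.tool runs/demo/metrics.json
```

```json
{
    "mean_local_richness": 22.3988490482498,
    "lifetime_exponent": -1.9082486468645041,
    "sar_slope": 0.24951142624791067,
    "similarity_plateau_basal": 0.8598982947880006,
    "similarity_plateau_higher": 0.3395509587354972,
    "range_lifetime_slope": 0.9056174285153723,
    "biomass_ratio_median": 1.812527477791201,
    "rsd_slope_average_range": -2.020811768244132,
    "n_species_total": 18001,
    "n_extinct_established": 2169,
    "hat_fractions": {"1": 0.7346938775510204, "2": 0.5342465753424658,
                      "3": 0.4583333333333333, "4": 0.0},
    "hat_sample_sizes": {"1": 49, "2": 73, "3": 24, "4": 8}
}
```

Reading the output: each habitat carries about 22 coexisting species —
close to the hard cap R/threshold = 25 imposed by biomass conservation.
Species lifetimes are power-law distributed (tail exponent ≈ −1.9 on this
small, short run; ≈ −2.3 at the 8×8–10×10 scales the acceptance script
uses), and a species' time-averaged range grows almost linearly with its
lifetime (log-log slope ≈ 0.91).  The species–area curve has a mid-range
slope ≈ 0.25, in the empirically typical 0.2–0.4 band.  Distant habitats
share most of their basal species (Jaccard plateau ≈ 0.86) but far fewer
of their higher-level species (≈ 0.34 on this glued 6×6 grid; ≈ 0.23 at
10×10) — the basal layer sees the same resource everywhere, while
consumers depend on the local species configuration below them.  Of the
species that ever occupied half the grid, about 73% of basal species show
a single rise-and-fall "hat" range trajectory against about 53% of
level-2 consumers (the basal-vs-higher contrast widens with grid size).
Run times: the demo takes about half a minute; a 10×10 grid for 5000
steps (≈5.5 million events) takes a few minutes.

Named scaled-down scenarios (`richness`, `lifetimes`, `similarity`,
`ranges`) bundle the grid sizes and run lengths used in our analyses:

```bash
evofoodweb reproduce similarity --seed 1 --out runs/similarity
```

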