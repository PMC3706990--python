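# isopure

Computational purification of bulk tumor expression profiles.

A bulk tumor sample mixes mRNA from cancerous cells with mRNA from the
healthy tissue it was embedded in, and the healthy fraction varies
widely between samples. That variation blurs downstream analyses —
inter-tumor comparisons, signature discovery, prognosis models — because
part of every measured profile is not cancer at all. `isopure`
decomposes each tumor profile into a tumor-specific cancer expression
profile and a combination of healthy-tissue profiles, and estimates
each sample's *tumor purity* (the fraction of its mRNA contributed by
cancer cells) along the way.

It is intended for anyone with a cohort of linear-scale bulk expression
profiles (microarray intensities or abundance estimates, normalized but
not log-transformed) plus a panel of healthy profiles from the same
tissue: no matched normal per tumor is required.

## The model

Each discretized tumor profile x_n (G transcript counts, total S_n) is
modeled as a single multinomial draw from a convex mixture of the
R column-normalized healthy profiles b_1..b_R and a tumor-specific
cancer profile c_n:

    x_n ~ Multinomial(S_n,  Σ_r θ_{n,r} b_r + α_n c_n),
    α_n + Σ_r θ_{n,r} = 1

with Dirichlet regularization tying the pieces together:

    θ_n ~ Dir(ν)            mixing weights (ν estimated)
    c_n ~ Dir(k_n m)        cancer profiles cluster around a shared
                            reference cancer profile m
    m   ~ Dir(k' B ω)       the reference profile stays near the span
                            of the healthy panel

All parameters are fitted by two-stage MAP estimation (block coordinate
ascent with Polak-Ribière conjugate-gradient steps, 35 outer
iterations, 10 random restarts): stage 1 pins every c_n to m and
estimates the purities α_n and the reference profile; stage 2 freezes
those and estimates the per-tumor cancer profiles. An *even-prior*
variant (`--evenprior`) replaces the stage-2 prior mean m with the
uniform vector, isolating what the clustered-profile assumption
contributes. A per-tumor subtraction baseline (Spearman-matched normal,
algebraic deconvolution) is included for comparison.

See `docs/methods.md` for assumptions, parameter choices, numerical
details, and known limitations.

## Worked example

Simulate a cohort with known ground truth, then purify it:

```sh
isopure simulate --genes 500 --samples 12 --normals 4 \
    --depth 100000 --seed 7 --out-dir sim
isopure run --tumors sim/tumors.tsv --normals sim/normals.tsv \
    --out-dir fit --seed 1
```

`fit/purities.tsv` holds one row per sample: the estimated purity
`alpha` and the weight `theta_r` each healthy-panel profile contributes
to the contamination. Against the generator's truth for this seed:

```
sample_id  alpha  true_alpha  theta_1  theta_2  theta_3  theta_4
   tumor1  0.457       0.488    0.039    0.329    0.089    0.086
   tumor2  0.887       0.830    0.113    0.000    0.000    0.000
   tumor3  0.450       0.484    0.040    0.000    0.398    0.113
   tumor4  0.335       0.346    0.363    0.000    0.257    0.044
   tumor5  0.798       0.753    0.091    0.053    0.058    0.000
   tumor6  1.000       0.859    0.000    0.000    0.000    0.000
   tumor7  1.000       0.854    0.000    0.000    0.000    0.000
   tumor8  0.364       0.380    0.018    0.090    0.185    0.343
   tumor9  0.548       0.633    0.042    0.078    0.045    0.287
  tumor10  0.737       0.700    0.183    0.048    0.000    0.032
  tumor11  0.478       0.488    0.272    0.043    0.163    0.044
  tumor12  0.780       0.738    0.035    0.048    0.134    0.002
```

Mean absolute purity error here is 0.055. Note the two most-pure
samples saturate at α = 1: purity estimates for nearly-pure tumors run
high (the likelihood constrains only how much normal signal is
*present*), so ranks are more trustworthy than absolute values at the
top end — a property to keep in mind when comparing against pathologist
cellularity.

`fit/purified.tsv` contains the per-tumor cancer profiles rescaled to
each sample's original total, `fit/model.json` every fitted parameter
(m, θ, ν, ω, k', per-sample k_n, restart log-likelihoods), and
`fit/manifest.json` the configuration echo and input checksums needed
to reproduce the run.

Other subcommands: `isopure step1` / `isopure step2 [--evenprior]` run
the stages separately; `isopure baseline clarke` runs the subtraction
baseline; `isopure features` exports learner-ready tables (purified
profiles, baseline profiles, or the R+1 mixture proportions per
sample). The same functionality is available as a library
(`isopure.step1_fit`, `isopure.step2_fit`, `isopure.generate_dataset`,
...).

## Input format

Delimited text (TSV by default, CSV accepted): first column transcript
IDs, header row sample IDs, body non-negative linear-scale values.
Tumor and normal matrices are aligned on shared transcript IDs.
Discretized tumor totals should be ~1e6 or more (use `--rescale-to` if
your platform's totals are smaller).

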