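# dualenrich

Modelling and analysis toolkit for **dual-enrichment selection of
N2O-respiring bacteria (NRB)** — organisms that reduce the greenhouse gas
N2O to N2 and can be grown in organic waste digestate for use as soil
inoculants.  The dual-enrichment strategy passages a microbial community
through sequential batch cultures alternating between two sterilized
substrates (soil and digestate), transferring a fraction *f* = 0.1 of the
enriched material each time, with limited O2 and sustained N2O in the
headspace.  Organisms competitive in **both** substrates ("generalists")
are progressively enriched; substrate specialists and non-growers are
diluted out.

The package provides, for modellers and microbial ecologists working with
such enrichment series:

* **`dualenrich.competition`** — a serial-transfer Lotka-Volterra
  competition model.  Within one batch on substrate *s* each species obeys
  logistic growth on a shared substrate pool plus first-order death,

  dN_i/dt = μ_i(s) · N_i · (1 − B/K_s) − d_i(s) · N_i,  B = Σ_j N_j,

  chained across enrichments by multiplying every abundance by *f* at each
  transfer.  Includes dominance timing, bisection of the critical
  generalist:specialist growth-rate ratio for washout, and a calibrated
  default parameter set.
* **`dualenrich.gas`** — closed-vial headspace gas calculus: correction of
  measured amounts for sampling dilution (He replacement) and leakage,
  production/consumption rates, two-population decomposition of N2
  production curves r(t) = A·e^{μ1 t} + B·e^{μ2 t} (μ1 < 0 < μ2),
  transfer survival fractions, electron flows per acceptor, N mass
  balance, and the emission index
  I_N2O = ∫N2O-N dt / ∫(N2O-N + N2-N + NO-N) dt up to a chosen
  N-oxyanion recovery fraction (40% or 100%).
* **`dualenrich.community`** — OTU statistics: rarefaction (9,000 reads),
  ddPCR-scaled absolute abundances, the per-enrichment ratio
  R_i = ln(N(i)/(N(i−1)·f)), niche classification
  (generalist / soil specialist / digestate specialist / washout), Ward
  clade clustering of the 500 most abundant OTUs, SIMPER, PCA.
* **`dualenrich.synth`** — synthetic datasets with planted ground truth
  (specialists, generalists, washout taxa, relic-DNA pools; simulated
  headspace series with sampling and N2O reinjection), so every pipeline
  stage is testable without external data.
* **`dualenrich` CLI** — `simulate`, `regime`, `gas`, `community`,
  `synth`, and `run` (end-to-end pipeline with a JSON config).

## Worked example

Run the default end-to-end pipeline (competition regime → synthetic
community → community statistics → synthetic gas series → gas calculus):

```sh
printf '{"seed": 3}' > pipeline.json
dualenrich run --config pipeline.json --out out/
cat out/summary.json
```

The summary (abridged) reads:

```json
{
  "regime": {
    "generalist_ratio": 0.5,
    "passages_to_dominance": 3,
    "critical_ratio_percent": 26
  },
  "community": {
    "niche_census": {"washout": 369, "digestate_specialist": 58,
                     "soil_specialist": 50, "generalist": 23},
    "dropped_samples": []
  },
  "gas": {
    "cumulative_N2_umol_N": 448.49,
    "two_population_fit": {"rate_decline_per_h": -0.03,
                           "rate_growth_per_h": 0.1},
    "survival_fraction_percent": 80.0
  }
}
```

Reading these numbers: a generalist growing at half the specialists' rates,
starting 10^4-fold below them, needs **3 full soil+digestate passages** to
exceed 50% relative abundance under the calibrated default parameters, and
the washout boundary sits at a growth-rate ratio of **26%** — below it the
generalist's per-cycle fold change drops under 1 and it is eliminated.  The
niche census is the classifier's output on a 500-OTU synthetic community
(the generator planted 50/50/25/375 specialists/generalists/washouts; the
small discrepancies are sequencing and ddPCR noise).  The gas stage
recovers the planted two-population structure of the N2 production rate —
a population declining at −0.03 h⁻¹ and one growing at 0.1 h⁻¹ — from the
dilution-corrected rate curve, and the transfer survival estimate recovers
the planted 80% survival.

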