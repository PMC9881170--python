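# mitoinit

Computational analyses for studying translation initiation in human
mitochondria: whether leaderless mitochondrial mRNAs are loaded onto
intact 55S monosomes rather than onto the small subunit, and how often
the large subunit (mtLSU) is exchanged during initiation.

The package is aimed at single-molecule fluorescence and mitochondrial
gene-expression labs and provides four tool families:

* **`mitoinit.photon_sim`** — a simulator of two-color confocal
  photon-count traces: fluorophore-labeled molecules (Cy5 ribosomes, Cy3
  mRNA) diffuse through a confocal volume in the single-molecule regime
  (occupancy *N* ≤ 0.01), producing Poisson photon bursts with
  configurable labeling efficiency, multi-dye brightness, bleaching,
  crosstalk and background — plus FCS-style autocorrelation
  *G*(τ) = ⟨δ*F*(t) δ*F*(t+τ)⟩ / ⟨*F*⟩² and a diffusion-time fit
  *G*(τ) = *A* / (1 + τ/τ_D).
* **`mitoinit.btccd`** — brightness-gated two-color coincidence detection
  (BTCCD): burst search by count threshold, brightness gating to central
  transits, the coincident-burst fraction with a circular-shift chance
  control and a percentile-bootstrap confidence interval.
* **`mitoinit.initiation_calc`** — the assay arithmetic: the labeled-pool
  exchange model (with a *k*-fold labeled-LSU excess the labeled pool
  fraction is *k*/(*k*+1); full exchange predicts coincidence
  *f*_pos · *k*/(*k*+1); the exchanged fraction is
  *f*_obs / *f*_pred), fluorescence calibration lines, fraction-bound and
  dipeptide elongation-competence ratios.
* **`mitoinit.riboseq`** — mitoribosome-profiling (MitoRibo-seq)
  quantification: 30–35 nt footprint filter, 5′-end window counting from
  the start codon to 30 nt before the stop codon, exclusion of the
  bicistronic ATP8/ATP6 (46 nt) and ND4L/ND4 (7 nt) overlap regions,
  percent-of-total tables and knockout/wild-type comparisons, with a
  seeded synthetic footprint generator and a packaged human mtDNA
  annotation.

## Worked example: does initiation require subunit exchange?

A positive control (every ribosome carries an mRNA) measures 43%
coincident bursts; an exchange experiment with a 5-fold excess of
labeled large subunits measures 27%. If every initiation event exchanged
its large subunit:

```sh
mitoinit exchange --f-positive 43 --f-observed 27 --excess 5
```

```json
{
  "clamped": false,
  "exchanged_fraction": 0.7534883720930232,
  "f_predicted_full": 35.833333333333336,
  "f_predicted_full_display": 36,
  "labeled_pool_fraction": 0.8333333333333334,
  "monosome_fraction": 0.24651162790697678
}
```

Reading: a 5-fold excess labels 5/6 ≈ 83% of the free large-subunit
pool, so complete exchange would give 43 × 5/6 ≈ 36% coincidence. The
observed 27% is only ~75% of that, so about 25% of initiation events
kept their original large subunit — initiation can occur on the intact
monosome.

The same question can be posed *in silico* end to end: simulate an
exchange sample and measure it with BTCCD,

```sh
python - <<'EOF'
from mitoinit import ConfocalSimConfig, SpeciesMix, simulate_trace, analyze_trace
cfg = ConfocalSimConfig(duration=1800.0, occupancy=0.01,
                        labeling_efficiency_red=0.43, seed=0)
trace = simulate_trace(cfg, SpeciesMix.exchange_experiment(0.628))
result = analyze_trace(trace, reference="green", seed=0)
print(f"{100 * result.fraction:.1f}% coincident "
      f"({result.n_coincident}/{result.n_reference_bursts} gated bursts, "
      f"chance {100 * result.chance_fraction:.1f}%)")
EOF
```

which prints `29.4% coincident (420/1430 gated bursts, chance 0.7%)` —
the detected coincidence of a sample in which 62.8% of mRNA-bound
ribosomes carry a labeled subunit, with detection losses calibrated on
the positive control.

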