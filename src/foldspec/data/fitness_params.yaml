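# Yeast configuration of the three-component elongation fitness model.
# Reproduces the cited published model's configuration at the order of
# magnitude of its reported selection coefficients; all values are
# configuration, not code.
#
# baseline_error_rate   mistranslation probability per codon at baseline speed
# trade_off_slope       relative error change per relative elongation-speed change
# misfolded_fraction    fraction of mistranslated proteins that misfold
# misfolding_cost       fitness cost per misfolded protein molecule per cell
# proteome_size_aa      amino acids synthesized per cell cycle
# proteome_time_cost    fitness cost per relative increase in proteome synthesis time
# ne                    effective population size (yeast)
baseline_error_rate: 5.0e-4
trade_off_slope: 1.0
misfolded_fraction: 0.5
misfolding_cost: 1.2e-3
proteome_size_aa: 2.0e10
proteome_time_cost: 1.0
ne: 1.0e7
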