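# Default pipeline configuration for the pale-lager sensory weighting analysis.
# Regenerate with: python -c "import lagerscale as ls; ls.save_config(ls.default_config(), 'examples/pipeline.yml')"
hierarchy:
  dimensions:
    appearance: [beer_color, clarity, foam_abundance]
    aroma: [malt, hop, fruit, floral, sweet_aroma, fermentation]
    taste: [sourness, sweetness, bitterness, umami, astringency]
    drinking_sensation: [smoothness, fullness, refreshment, body_coordination,
                         prickliness, alcohol_warmth, aftertaste, persistence,
                         foam_fineness]
  merge_map:
    hop_flower: [hop, floral]
    fruity_fermentation: [fruit, fermentation]
    aftertaste_persistence: [aftertaste, persistence]
  exclusions: [alcohol_warmth, appearance]
cohorts:
  - {label: low, min_occasions: 1, max_occasions: 3, frequency_factor: 2.0}
  - {label: mid, min_occasions: 4, max_occasions: 8, frequency_factor: 6.0}
  - {label: high, min_occasions: 9, max_occasions: null, frequency_factor: 14.0}
fusion_alpha: 0.7
aggregate_layer: ahp
top_k: 3
survey_scale: [1, 5]
tasting_scale: [1, 9]
seed: 0
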