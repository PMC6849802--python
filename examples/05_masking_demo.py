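"""The masking demonstration in miniature.

Two qualitatively different community reorganisations — bird-like loss of
cold-associated species and butterfly-like gain of warm-associated
species — are simulated end to end and analysed. Aggregate CTI moves the
same way in both; only the four STI-quartile assemblage trends tell the
regimes apart.
"""

from ctiscape.experiments import masking_study

res = masking_study(seed=5, n_replicates=2, n_sites=50, n_species=40)
cols = ["scenario", "cti_slope", "slope_low", "slope_medium_low",
        "slope_medium_high", "slope_high"]
print(res.replicates[cols].round(4).to_string(index=False))
for scenario in ("bird_like", "butterfly_like"):
    print(f"\n{scenario}: generating assemblage trends {res.scenario_truth[scenario]}")
    print(f"  sign pattern recovered in {res.sign_match_fraction(scenario):.0%} of replicates")
print("\nBoth regimes push CTI upward, but the assemblage decomposition shows"
      "\nwhether that reflects cold-species loss (declining slope_low) or"
      "\nwarm-species gain (rising slope_high).")
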