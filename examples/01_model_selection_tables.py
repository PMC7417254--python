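"""Akaike-weight model selection for denning-site indicators.

Builds the candidate-model comparison for the question "which movement
variable best predicts a successful birth?" from the models' AIC values
(k parameters, n = 20 collared females), and prints the AICc / delta /
weight table. The 50% core range carries ~74% of the total weight: core
contraction is by far the most informative single indicator of a
denning event.
"""

from liondens import ModelFit, akaike_table

N_FEMALES = 20

fits = [
    ModelFit("50% Core", k=1, n=N_FEMALES, aic=14.0),
    ModelFit("Core + Total", k=2, n=N_FEMALES, aic=16.73),
    ModelFit("90% Total", k=1, n=N_FEMALES, aic=17.9),
    ModelFit("Biomass", k=1, n=N_FEMALES, aic=30.0),
    ModelFit("SL Wet", k=1, n=N_FEMALES, aic=30.0),
    ModelFit("SL Dry", k=1, n=N_FEMALES, aic=30.9),
    ModelFit("BTb", k=1, n=N_FEMALES, aic=33.36),
]

table = akaike_table(fits)
print(table.table.round(5).to_string(index=False))
print(f"\nbest-supported model: {table.best} "
      f"(weight {table.weight(table.best):.3f})")
print("interpretation: the weight is each model's relative likelihood; "
      "core-range size dominates the candidate set.")
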