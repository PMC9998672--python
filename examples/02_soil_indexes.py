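"""Soil index formulas and the index-index correlation matrix.

Computes microbial biomass C and N from fumigation-extraction measurements,
a respiration rate, and the 9x9 correlation matrix among the soil and
microbial indexes of a synthetic gradient.
"""

from rhizometab import (
    FumigationMeasurement,
    SimConfig,
    generate_index_table,
    index_correlation_matrix,
    microbial_biomass_carbon,
    microbial_biomass_nitrogen,
    respiration_rate,
)

m = FumigationMeasurement(c_fumigated=215.2, c_unfumigated=131.3,
                          n_fumigated=80.13, n_unfumigated=37.75)
print(f"MBC = (215.2 - 131.3) / 0.38 = {microbial_biomass_carbon(m):.2f} mg/kg")
print(f"MBN = (80.13 - 37.75) / 0.54 = {microbial_biomass_nitrogen(m):.2f} mg/kg")
print(f"respiration = 36.5 mg CO2 / (0.25 kg x 8 h) = {respiration_rate(36.5, 0.25, 8):.2f} mg CO2/kg.h")

table = generate_index_table(SimConfig(seed=1))
corr = index_correlation_matrix(table)
print("\nr(pH, organic matter) = %.3f %s" % (corr.r.loc["ph", "organic_matter"],
                                             corr.stars.loc["ph", "organic_matter"]))
print("r(pH, fungi)          = %.3f %s" % (corr.r.loc["ph", "fungi"],
                                           corr.stars.loc["ph", "fungi"]))
# Fungi is the one index that moves against the gradient: it correlates
# negatively with pH and with every co-varying index; ** marks p < 0.01.
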