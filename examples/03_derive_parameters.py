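"""Genetic parameters from published posterior-mean (co)variance components.

Feeds the direct + maternal genetic covariance block, permanent-environment
and residual variances estimated for pasture-raised Polled Nellore growth
traits into the Willham parameter formulas: direct heritabilities around
0.43 (W120) up to 0.72 (W365), direct-maternal correlations -0.42/-0.48,
and direct genetic correlations 0.73-0.98.  (Deriving once from posterior-
mean components can differ in the last decimal from a posterior mean of the
derived parameter; W240's h2 is 0.62 here versus a published posterior
summary of 0.61.)
"""

from willham.gibbs import CovarianceComponents
from willham.posterior import derive_parameters
from willham.simulate import DEFAULT_G, DEFAULT_P, DEFAULT_R

TRAITS = ("w120", "w240", "w365", "w450")
comp = CovarianceComponents(
    G=DEFAULT_G, P=DEFAULT_P, R=DEFAULT_R,
    g_labels=[(t, "direct") for t in TRAITS] + [("w120", "maternal"), ("w240", "maternal")],
    pe_traits=("w120", "w240"), traits=TRAITS,
)

pars = derive_parameters(comp)
table = pars.to_frame()
table["value"] = table["value"].round(3)
print(table.to_string(index=False))
print("\nh2_direct = direct genetic / phenotypic variance;")
print("r_am = direct-maternal genetic correlation (negative: antagonism);")
print("h2_total = (sigma2_a + 0.5 sigma2_m + 1.5 sigma_am) / sigma2_p.")
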