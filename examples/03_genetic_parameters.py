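"""Derived genetic parameters from (co)variance components.

Shows the closed-form arithmetic linking variance components to total
heritable variance, phenotypic variance, and the two heritabilities, using
component values of the magnitude reported for pig average daily gain.
"""

from sgeblup.genparams import population_report

# direct variance, social variance, their covariance, pen, litter, residual
# variance (all (g/day)^2), and the average pen size
report = population_report(
    sigma2_aD=1377.0,
    sigma2_aS=75.0,
    cov_aD_aS=9.6,
    sigma2_d=800.0,
    sigma2_l=900.0,
    sigma2_e=5558.0,
    n=3.0,
)

print("purebred-scale example (g/day)^2, n_bar = 3:")
for key in ("sigma2_aD", "sigma2_aS", "sigma2_p", "sigma2_TBV", "h2", "T2", "r_DS"):
    v = report[key]
    print(f"  {key:12s} {v:10.2f}" if v > 1 else f"  {key:12s} {v:10.3f}")

print(
    "\nsigma2_TBV exceeds sigma2_aD because each animal's social effect is\n"
    "expressed in (n-1) pen mates; T2 > h2 by the same margin over sigma2_p."
)
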