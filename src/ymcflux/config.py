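"""Numeric tolerances shared across the package.

Stated once here and imported everywhere so that results are reproducible
bit-for-bit and every solver output is judged against the same yardsticks.
"""

#: Slack allowed on variable bounds when checking solver output (lb - TOL <= v <= ub + TOL).
FEASIBILITY_TOL = 1e-9

#: Maximum tolerated steady-state residual max_i |sum_j S_ij v_j| for any returned flux vector.
MASS_BALANCE_TOL = 1e-6

#: Fluxes with |v| below this are treated as zero when classifying reaction activity.
ZERO_FLUX_TOL = 1e-6
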