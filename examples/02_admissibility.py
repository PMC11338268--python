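"""Admissible setpoints and disturbances under saturating actuation.

Admissibility is a purely algebraic property of the open-loop process: a
setpoint is admissible when some feasible constant input supports it at
steady state.  With actuation saturating at k=8 and a basal production
(disturbance) of 5, the gene-expression process can only be steered to
outputs in [5, 13]; a Hill sensor with half-saturation 5 maps that band to
admissible *input* setpoints, and for a fixed output setpoint the same
calculus yields the disturbances that keep it feasible.
"""

from antithetic import (
    GeneExpressionProcess,
    Interval,
    admissible_disturbances,
    admissible_input_setpoints,
    admissible_setpoints,
    hill,
)

process = GeneExpressionProcess(delta=5.0)
io = process.io_map()
print(f"steady-state map: y = {io.alpha:g}*u + {io.beta:g}")

U = Interval(0.0, 8.0)  # actuation is a production rate saturating at k=8
out_set = admissible_setpoints(io, U)
print(f"admissible output setpoints for u in {U}: {out_set}")

hs = hill(5.0)
in_set = admissible_input_setpoints(out_set, hs)
print(f"admissible input setpoints (through the Hill sensor): {in_set}")
theta = 15.0
print(f"equivalently mu = theta*r_in must lie in "
      f"[{theta * in_set.lo:.3f}, {theta * in_set.hi:.3f}]")

r_out = 10.0
D = admissible_disturbances(lambda d: GeneExpressionProcess(delta=d).io_map(),
                            r_out, U, Interval.nonnegative())
print(f"disturbances preserving the output setpoint {r_out:g}: {D}")
print("outside that interval no controller of any structure can hold the "
      "setpoint — the loop winds up instead.")
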