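"""Non-monotone convergence of the projected Barzilai-Borwein solver.

Solves a small random bound-constrained quadratic program and prints the
objective every few iterations: the value oscillates (there is no line
search) yet the iteration terminates at the constrained optimum, certified
by a vanishing KKT violation.
"""

import numpy as np

from jointdeconv import QuadraticProblem, solve_pbb

rng = np.random.default_rng(0)
n = 30
M = rng.normal(size=(n, n))
Q = M @ M.T + 0.5 * np.eye(n)
problem = QuadraticProblem(
    apply_Q=lambda v: Q @ v,
    q=rng.normal(size=n),
    lower=np.zeros(n),
    upper=np.full(n, np.inf),
)

report = solve_pbb(problem, tol=1e-10)

print("iter  objective")
for k in range(0, len(report.objective_trace), 5):
    print(f"{k:4d}  {report.objective_trace[k]: .6f}")
print(f"\nconverged = {report.converged} after {report.iterations} "
      f"iterations, final KKT violation = {report.kkt_residual:.2e}")
print(f"active bounds: {int(np.sum(report.solution == 0.0))} of {n} "
      "components sit at zero")
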