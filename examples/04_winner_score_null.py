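"""Winner scores and their random-retention permutation null.

For three equal-scoring UCNEs over two orthologs the exact null
probability of W = 100 is 2/2^3 = 0.25 (all rows must land in one
column); the 500-shuffle estimate agrees within sampling error.
"""
import numpy as np

from grbcontext.retention import ScoreMatrix, permutation_null, winner_score

case = ScoreMatrix(
    "geneX", "fish", ["u1", "u2", "u3"], ["copy1", "copy2"],
    np.array([[100.0, 0.0], [100.0, 0.0], [100.0, 0.0]]),
)
ws = winner_score(case)
print(f"observed winner score: W = {ws.w:.0f} "
      f"(C_major={ws.c_major:.0f} / C_total={ws.c_total:.0f})")

null = permutation_null([case], n_shuffles=500, seed=1)
top = null.mean_freq[-1]
print(f"null P(W in [95,100]) = {top:.3f} +/- {null.sd_freq[-1]:.3f} "
      f"(exact enumeration: 0.250)")
print("\nThe observed W=100 is what random retention produces only 25% "
      "of the time for one such gene; across hundreds of genes the "
      "excess of W=100 cases is the cooperativity signal.")
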