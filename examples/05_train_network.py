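"""Train the feed-forward classifier with scaled conjugate gradients.

A sigmoid-hidden / linear-output network is fit to the XOR problem --
the classic test that the optimiser can solve a non-linearly-separable
task -- and its loss trace is shown to be monotone over accepted steps.
"""

import numpy as np

from adwave.network import TrainConfig, classify, forward_pass, train_scg

X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
T = np.array([0.0, 1.0, 1.0, 0.0])

weights, trace = train_scg(X, T, sizes=(2, 2, 1),
                           config=TrainConfig(max_iterations=500,
                                              mse_goal=1e-4, seed=0))
_, out = forward_pass(weights, X)
print("targets:", T)
print("outputs:", np.round(out[:, 0], 3))
print("labels :", classify(weights, X))
print(f"MSE {trace[0]:.3f} -> {trace[-1]:.5f} over {len(trace) - 1} "
      f"accepted steps (monotone: {bool(np.all(np.diff(trace) <= 0))})")
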