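"""The soft-margin kernel SVM on two classic toy problems.

The solver optimizes the dual of min 1/2||N||^2 + C sum(theta_r) by SMO;
the decision function is f(x) = sum beta_r y_r W(x_r, x) + a.
"""

import numpy as np

from tacerad import KernelSpec, decision, predict, train

# 1D two-point problem: the maximum-margin boundary is the midpoint x = 1
model = train(np.array([[0.0], [2.0]]), np.array([-1.0, 1.0]),
              KernelSpec("linear"), C=10.0)
print(f"two-point problem: weight N = {model.N[0]:.3f}, bias a = {model.a:.3f}")
print(f"  decision(1.0) = {decision(model, [[1.0]])[0]:+.3f}  (on the boundary)")
print(f"  decision(2.0) = {decision(model, [[2.0]])[0]:+.3f}  (on the +1 margin)")

# XOR is not linearly separable; the RBF kernel solves it
X = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]])
y = np.array([1.0, 1, -1, -1])
rbf = train(X, y, KernelSpec("rbf", gamma=1.0), C=10.0)
print(f"\nXOR with rbf kernel: predictions {predict(rbf, X)} (true {y.astype(int)})")
print(f"  support vectors: {len(rbf.support)} of 4, dual box 0 <= beta <= C holds:",
      bool((rbf.beta >= 0).all() and (rbf.beta <= 10).all()))
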