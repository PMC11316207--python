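"""The F(beta) overlap loss and the three-head training objective.

    F(beta) = 1 - ((1 + beta) * sum_i y_i yhat_i + eps)
                  / (beta * sum_i y_i + sum_i yhat_i + eps)

y_i in {0, 1} is the manual label, yhat_i in [0, 1] the predicted
probability, and eps (1e-3) keeps the empty case finite.  beta = 10 drives
a recall-oriented head, beta = 0.1 a precision-oriented head, and beta = 1
balances the two (the Dice loss).  The three heads' losses are combined as
an unweighted sum; the L2 weight penalty is applied by the optimizer, not
here.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, add, fbeta_loss_op

DEFAULT_EPSILON = 1e-3


def fbeta_loss(y, yhat, beta: float, epsilon: float = DEFAULT_EPSILON):
    """F(beta) loss; accepts arrays (returns float) or a Tensor prediction."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    y = np.asarray(y, dtype=np.float32)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary")
    if isinstance(yhat, Tensor):
        return fbeta_loss_op(y, yhat, beta, epsilon)
    yhat = np.asarray(yhat, dtype=np.float32)
    if np.any(yhat < 0) or np.any(yhat > 1):
        raise ValueError("predictions must lie in [0, 1]")
    return float(fbeta_loss_op(y, Tensor(yhat), beta, epsilon).data)


def total_loss(y, yhat_a, yhat_b, yhat_c, betas=(10.0, 0.1, 1.0), epsilon: float = DEFAULT_EPSILON):
    """Sum of the three per-head F(beta) losses (recall, precision, balance)."""
    terms = [fbeta_loss(y, p, b, epsilon) for p, b in zip((yhat_a, yhat_b, yhat_c), betas)]
    if all(isinstance(t, Tensor) for t in terms):
        return add(add(terms[0], terms[1]), terms[2])
    return float(sum(float(t.data) if isinstance(t, Tensor) else t for t in terms))
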