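"""Train the two-hidden-layer softmax classifier with RMSprop.

The network is ReLU -> ReLU -> softmax; RMSprop scales each parameter's
step by the inverse root of an exponentially decaying average of its
squared gradients (decay 0.9).
"""
import numpy as np

import weedfs as w
from weedfs import dnn

rng = np.random.default_rng(0)
X = np.vstack([rng.normal([-2, -2], 0.5, size=(50, 2)),
               rng.normal([2, 2], 0.5, size=(50, 2))])
y = np.r_[np.zeros(50, int), np.ones(50, int)]

spec = dnn.NetworkSpec(layer_sizes=(2, 64, 32, 2), init_seed=1)
params, history = dnn.train(spec, X, y, dnn.TrainingOptions(epochs=200, shuffle_seed=1))

print(f"epoch   1: loss {history.train_loss[0]:.4f} acc {history.train_accuracy[0]:.2%}")
print(f"epoch 200: loss {history.train_loss[-1]:.4f} acc {history.train_accuracy[-1]:.2%}")
labels, probs = dnn.predict(params, X)
print(f"training accuracy: {(labels == y).mean():.2%}")
print(f"softmax rows sum to one: {np.allclose(probs.sum(axis=1), 1.0)}")
# A linearly separable cloud is learned essentially perfectly; the loss
# trace is what a training-curve figure would plot.
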