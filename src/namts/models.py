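"""Additive and blackbox time-series classifiers plus feature-based baselines.

The core model is :class:`NAMClassifier`, a neural additive model whose logit
is an exact sum of one scalar per signal modality plus a bias::

    p = sigmoid( sum_i f_i(x_i) + beta )

Each ``f_i`` is a small fully convolutional network (three conv layers with
batch normalization and ReLU, "same" zero padding), followed by a per-timepoint
linear combination of the hidden channels into a single *activation map* and
global average pooling of that map into the scalar ``f_i(x_i)``.  Two exact
architectural identities hold for every input (and are enforced by tests):
the logit equals the sum of the per-modality contributions plus the bias, and
each contribution equals the time-mean of its activation map.  The classical
formulation weights subnetworks as ``alpha_i * f_i``; here the ``alpha_i`` are
absorbed into each subnetwork's final linear-combination layer, which is
expressively equivalent, and the reported contribution is the combined scalar.

:class:`BlackboxFCNClassifier` uses the same convolutional feature extractors
but skips the additive collapse: per-channel pooled features from all
modalities are concatenated and passed through a two-hidden-layer MLP, giving
an uninterpretable reference point of (at least) equal capacity.

Both models train with Adam on class-balanced data for a fixed number of
epochs (defaults: 10 epochs, learning rate 1e-4, weight decay 0.01).
Predictions, contributions and activation maps are always computed in
evaluation mode (batch-norm running statistics), so they are deterministic
and per-window.

Estimators follow scikit-learn conventions (``fit``/``predict_proba``/
``get_params``; fitted attributes end in an underscore) and accept the flat
stacked window matrix produced by :func:`namts.preprocess.stack_inputs`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils import check_array, check_X_y, column_or_1d

from ._nn import (
    Adam,
    Conv1d,
    Param,
    Sequential,
    bce_with_logits,
    fcn_stack,
    sigmoid,
)
from .preprocess import MODALITIES, modality_slices, n_features


@dataclass(frozen=True)
class HyperParams:
    """Architecture hyperparameters searched by nested cross-validation."""

    kernel_size: int = 9
    hidden_channels: int = 20
    n_conv_layers: int = 3
    modalities: tuple[str, ...] = MODALITIES

    def __post_init__(self) -> None:
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.n_conv_layers < 1:
            raise ValueError("need at least one conv layer")


@dataclass(frozen=True)
class NAMPrediction:
    """One window's prediction with its additive decomposition."""

    probability: float
    logit: float
    contributions: dict[str, float]
    activation_maps: dict[str, np.ndarray]
    bias: float


@dataclass
class NAMExplanation:
    """Vectorized predictions + decompositions for a batch of windows."""

    probabilities: np.ndarray  # (n,)
    logits: np.ndarray  # (n,)
    contributions: np.ndarray  # (n, n_modalities)
    modalities: tuple[str, ...]
    activation_maps: dict[str, np.ndarray]  # modality -> (n, L_modality)
    bias: float
    patient_ids: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.logits)

    def __getitem__(self, i: int) -> NAMPrediction:
        return NAMPrediction(
            probability=float(self.probabilities[i]),
            logit=float(self.logits[i]),
            contributions={
                m: float(self.contributions[i, j])
                for j, m in enumerate(self.modalities)
            },
            activation_maps={m: a[i] for m, a in self.activation_maps.items()},
            bias=self.bias,
        )


class _FCNBase(ClassifierMixin, BaseEstimator):
    """Shared training loop for the NumPy FCN models."""

    def _rng(self) -> np.random.Generator:
        return np.random.default_rng(self.random_state)

    def _check_fit_inputs(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        expected = n_features(self.window_len_s)
        if X.shape[1] != expected:
            raise ValueError(f"expected {expected} columns, got {X.shape[1]}")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("both classes must be present in y")
        self.n_features_in_ = X.shape[1]
        return X.astype(np.float32), (y == self.classes_[1]).astype(np.float64)

    def fit(self, X, y):
        X, y01 = self._check_fit_inputs(X, y)
        self.initialize()
        opt = Adam(self._params(), lr=self.lr, weight_decay=self.weight_decay)
        rng = self._train_rng_
        n = len(X)
        bs = min(self.batch_size, n)
        self.loss_curve_ = []
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for i0 in range(0, n, bs):
                idx = order[i0 : i0 + bs]
                if len(idx) < 2:
                    continue  # batch norm needs batch statistics
                z = self._forward_batch(X[idx], training=True)
                losses.append(bce_with_logits(z, y01[idx]))
                dz = (sigmoid(z) - y01[idx]) / len(idx)
                self._backward_batch(dz)
                opt.step()
                opt.zero_grad()
            self.loss_curve_.append(float(np.mean(losses)) if losses else np.nan)
        return self

    def decision_function(self, X) -> np.ndarray:
        X = check_array(X, dtype=np.float64).astype(np.float32)
        out = np.empty(len(X))
        for i0 in range(0, len(X), 512):
            out[i0 : i0 + 512] = self._forward_batch(X[i0 : i0 + 512], training=False)
        return out

    def predict_proba(self, X) -> np.ndarray:
        p = sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


class NAMClassifier(_FCNBase):
    """Neural additive model over the six preprocessed signal modalities.

    Parameters
    ----------
    kernel_size : odd int, convolution kernel length (the grid searched in
        nested cross-validation spans 5-17).
    hidden_channels : hidden channels per conv layer (default 20).
    n_conv_layers : depth of each modality subnetwork (default 3).
    modalities : subset of ``("NP","TA","PPG","HR","SPO2","PCO2")``; a
        single-element tuple gives a single-modality network, a proper subset
        the "reduced" additive model.  Input X always carries all six
        modality blocks; unused blocks are ignored.
    epochs, lr, weight_decay, batch_size : training schedule (defaults
        10 / 1e-4 / 0.01 / 4); weight decay applies to convolution weights
        only.  The small default batch keeps the optimizer step count under
        the fixed 10-epoch schedule comparable to training on cohort sizes an
        order of magnitude larger.
    """

    def __init__(self, kernel_size: int = 9, hidden_channels: int = 20,
                 n_conv_layers: int = 3, modalities: tuple[str, ...] | None = None,
                 window_len_s: float = 30.0, epochs: int = 10, lr: float = 1e-4,
                 weight_decay: float = 0.01, batch_size: int = 4,
                 random_state: int | None = None):
        self.kernel_size = kernel_size
        self.hidden_channels = hidden_channels
        self.n_conv_layers = n_conv_layers
        self.modalities = modalities
        self.window_len_s = window_len_s
        self.epochs = epochs
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.random_state = random_state

    @property
    def modalities_(self) -> tuple[str, ...]:
        return MODALITIES if self.modalities is None else tuple(self.modalities)

    def initialize(self) -> "NAMClassifier":
        """Build (seeded) initial parameters without fitting."""
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if not self.modalities_:
            raise ValueError("empty modality set")
        unknown = set(self.modalities_) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}")
        rng = self._rng()
        self.slices_ = modality_slices(self.window_len_s)
        self.subnets_ = {}
        for m in self.modalities_:
            stack = fcn_stack(1, self.hidden_channels, self.kernel_size,
                              self.n_conv_layers, rng)
            combine = Conv1d(self.hidden_channels, 1, 1, rng)
            # zero-initialized combination layer: contributions start at
            # exactly zero (unbiased p=0.5 model) and only grow where
            # gradients support discrimination, so the spread of a modality's
            # contributions reflects learned signal, not initialization noise
            for p in combine.params:
                p.value[...] = 0.0
            self.subnets_[m] = (stack, combine)
        self.bias_ = Param(np.zeros(1, dtype=np.float32), False)
        self._train_rng_ = rng
        if not hasattr(self, "classes_"):
            self.classes_ = np.array([0, 1])
        self.n_features_in_ = n_features(self.window_len_s)
        return self

    def _params(self):
        out = [self.bias_]
        for stack, combine in self.subnets_.values():
            out += stack.params + combine.params
        return out

    def _forward_batch(self, X: np.ndarray, training: bool,
                       collect_maps: bool = False):
        contribs = np.empty((len(X), len(self.modalities_)))
        maps = {}
        for j, m in enumerate(self.modalities_):
            stack, combine = self.subnets_[m]
            x = X[:, self.slices_[m]][:, None, :]  # (N, 1, L)
            amap = combine.forward(stack.forward(x, training), training)[:, 0, :]
            amap = amap.astype(np.float64)
            contribs[:, j] = amap.mean(axis=1)
            if collect_maps:
                maps[m] = amap
        logits = contribs.sum(axis=1) + float(self.bias_.value[0])
        if collect_maps:
            return logits, contribs, maps
        return logits

    def _backward_batch(self, dz: np.ndarray) -> None:
        self.bias_.grad += dz.sum()
        for m in self.modalities_:
            stack, combine = self.subnets_[m]
            length = self.slices_[m].stop - self.slices_[m].start
            dmap = np.repeat(dz[:, None, None], length, axis=2).astype(np.float32)
            dmap /= length
            stack.backward(combine.backward(dmap))

    def explain(self, X) -> NAMExplanation:
        """Predictions with per-modality contributions and activation maps."""
        X = check_array(X, dtype=np.float64).astype(np.float32)
        logits, contribs, maps = [], [], []
        for i0 in range(0, len(X), 512):
            z, c, a = self._forward_batch(X[i0 : i0 + 512], training=False,
                                          collect_maps=True)
            logits.append(z)
            contribs.append(c)
            maps.append(a)
        amaps = {
            m: np.concatenate([a[m] for a in maps]) for m in self.modalities_
        }
        logits = np.concatenate(logits)
        return NAMExplanation(
            probabilities=sigmoid(logits),
            logits=logits,
            contributions=np.concatenate(contribs),
            modalities=self.modalities_,
            activation_maps=amaps,
            bias=float(self.bias_.value[0]),
        )

    def zero_parameters(self) -> "NAMClassifier":
        """Zero every weight and the bias (diagnostic helper)."""
        for p in self._params():
            p.value[...] = 0.0
        return self


class BlackboxFCNClassifier(_FCNBase):
    """Non-additive reference model sharing the NAM's feature extractors.

    Per-modality conv stacks are pooled channel-wise (``hidden_channels``
    features per modality), concatenated, and passed through a two-hidden-layer
    MLP.  Trained end-to-end with the same schedule as the NAM.
    """

    def __init__(self, kernel_size: int = 9, hidden_channels: int = 20,
                 n_conv_layers: int = 3, modalities: tuple[str, ...] | None = None,
                 mlp_hidden: tuple[int, int] = (64, 64), window_len_s: float = 30.0,
                 epochs: int = 10, lr: float = 1e-4, weight_decay: float = 0.01,
                 batch_size: int = 4, random_state: int | None = None):
        self.kernel_size = kernel_size
        self.hidden_channels = hidden_channels
        self.n_conv_layers = n_conv_layers
        self.modalities = modalities
        self.mlp_hidden = mlp_hidden
        self.window_len_s = window_len_s
        self.epochs = epochs
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.random_state = random_state

    @property
    def modalities_(self) -> tuple[str, ...]:
        return MODALITIES if self.modalities is None else tuple(self.modalities)

    def initialize(self) -> "BlackboxFCNClassifier":
        if not self.modalities_:
            raise ValueError("empty modality set")
        rng = self._rng()
        self.slices_ = modality_slices(self.window_len_s)
        self.subnets_ = {
            m: fcn_stack(1, self.hidden_channels, self.kernel_size,
                         self.n_conv_layers, rng)
            for m in self.modalities_
        }
        from ._nn import Linear, ReLU

        n_feat = self.hidden_channels * len(self.modalities_)
        h1, h2 = self.mlp_hidden
        self.head_ = Sequential([
            Linear(n_feat, h1, rng), ReLU(),
            Linear(h1, h2, rng), ReLU(),
            Linear(h2, 1, rng),
        ])
        self._train_rng_ = rng
        if not hasattr(self, "classes_"):
            self.classes_ = np.array([0, 1])
        self.n_features_in_ = n_features(self.window_len_s)
        return self

    def _params(self):
        out = list(self.head_.params)
        for stack in self.subnets_.values():
            out += stack.params
        return out

    def _forward_batch(self, X: np.ndarray, training: bool) -> np.ndarray:
        feats = []
        self._lengths = []
        for m in self.modalities_:
            x = X[:, self.slices_[m]][:, None, :]
            h = self.subnets_[m].forward(x, training)  # (N, C, L)
            feats.append(h.mean(axis=2))
            self._lengths.append(h.shape[2])
        self._feat = np.concatenate(feats, axis=1)
        return self.head_.forward(self._feat, training)[:, 0].astype(np.float64)

    def _backward_batch(self, dz: np.ndarray) -> None:
        dfeat = self.head_.backward(dz[:, None].astype(np.float32))
        c = self.hidden_channels
        for j, m in enumerate(self.modalities_):
            length = self._lengths[j]
            dpool = dfeat[:, j * c : (j + 1) * c]
            dh = np.repeat(dpool[:, :, None], length, axis=2) / length
            self.subnets_[m].backward(dh.astype(np.float32))


def fit_baseline(kind: str, features: np.ndarray, labels: np.ndarray,
                 seed: int = 0) -> Pipeline:
    """Fit a feature-based baseline on the 24 engineered features.

    ``logreg``: L2-regularized logistic regression; ``mlp``: one-hidden-layer
    (width 64) perceptron.  Both standardize features column-wise on the
    training set and emit probabilities.
    """
    features = check_array(features)
    labels = column_or_1d(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    if kind == "logreg":
        clf = LogisticRegression(max_iter=2000)
    elif kind == "mlp":
        clf = MLPClassifier(hidden_layer_sizes=(64,), max_iter=800,
                            random_state=seed)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    pipe = make_pipeline(StandardScaler(), clf)
    return pipe.fit(features, labels)


# -- thin functional wrappers over the estimators -----------------------------

def build_nam(hp: HyperParams = HyperParams(), seed: int = 0,
              **train_kwargs) -> NAMClassifier:
    """Seeded, initialized (untrained) neural additive model."""
    return NAMClassifier(
        kernel_size=hp.kernel_size, hidden_channels=hp.hidden_channels,
        n_conv_layers=hp.n_conv_layers, modalities=hp.modalities,
        random_state=seed, **train_kwargs,
    ).initialize()


def build_blackbox(hp: HyperParams = HyperParams(), seed: int = 0,
                   **train_kwargs) -> BlackboxFCNClassifier:
    """Seeded, initialized (untrained) blackbox FCN model."""
    return BlackboxFCNClassifier(
        kernel_size=hp.kernel_size, hidden_channels=hp.hidden_channels,
        n_conv_layers=hp.n_conv_layers, modalities=hp.modalities,
        random_state=seed, **train_kwargs,
    ).initialize()


def train_model(model, X: np.ndarray, y: np.ndarray):
    """Train an initialized model in place on (class-balanced) windows."""
    return model.fit(X, y)


def nam_forward(model: NAMClassifier, X: np.ndarray) -> NAMExplanation:
    """Evaluation-mode forward pass with additive decomposition."""
    return model.explain(X)
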