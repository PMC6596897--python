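"""scikit-learn style estimator facade over the network module."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import network as N


class RCEquivariantClassifier(BaseEstimator, ClassifierMixin):
    """Binary DNA-sequence classifier with exact reverse-complement symmetry.

    A one-convolution CNN whose filter bank obeys the RC weight tie and whose
    dropout masks are RC-symmetric, so that ``predict_proba`` returns exactly
    the same value for a sequence and its reverse complement.  With
    ``bayesian=True`` prediction averages ``mc_samples`` stochastic
    (MC-dropout) forward passes; otherwise a single deterministic
    weight-averaged pass is used.

    Parameters
    ----------
    n_filters : even number of convolution filters (free filters = half).
    filter_len : convolution filter length in bp.
    activation : 'elu' (default), 'srelu', 'relu' or 'linear'.
    keep_p : dropout keep probability; 1.0 disables dropout.
    orbit_mode : RC orbit pooling reduction, 'max', 'sum' or 'avg'.
    pool_width : spatial max-pool width (= stride).
    equivariant : tie weights and symmetrize masks for exact RC invariance.
    bayesian : use MC-dropout averaging at prediction time.
    l2 : L2 penalty on free convolution and dense weights.
    mc_samples : number of MC-dropout passes K.
    learning_rate, batch_size, epochs, optimizer : first-order training setup.
    random_state : seed controlling initialization, batching, masks.

    Attributes
    ----------
    model_ : the fitted parameter container (`equivnet.network.Model`).
    classes_ : ndarray [0, 1].
    input_length_ : training sequence length.
    loss_curve_ : mean training loss per epoch.
    """

    def __init__(
        self,
        n_filters: int = 16,
        filter_len: int = 12,
        activation: str = "elu",
        keep_p: float = 0.7,
        orbit_mode: str = "max",
        pool_width: int = 8,
        equivariant: bool = True,
        bayesian: bool = True,
        l2: float = 0.0,
        mc_samples: int = 16,
        learning_rate: float = 3e-3,
        batch_size: int = 64,
        epochs: int = 10,
        optimizer: str = "adam",
        random_state: int | None = None,
    ):
        self.n_filters = n_filters
        self.filter_len = filter_len
        self.activation = activation
        self.keep_p = keep_p
        self.orbit_mode = orbit_mode
        self.pool_width = pool_width
        self.equivariant = equivariant
        self.bayesian = bayesian
        self.l2 = l2
        self.mc_samples = mc_samples
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.optimizer = optimizer
        self.random_state = random_state

    def _config(self) -> N.NetworkConfig:
        return N.default_config(
            n_filters=self.n_filters,
            filter_len=self.filter_len,
            activation=self.activation,
            keep_p=self.keep_p,
            orbit_mode=self.orbit_mode,
            pool_width=self.pool_width,
            equivariant=self.equivariant,
            bayesian=self.bayesian,
            l2_coeff=self.l2,
            mc_samples=self.mc_samples,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            optimizer=self.optimizer,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        """Fit on sequences (list of equal-length strings, a LabeledDataset,
        or a pre-encoded ``[n, 4, N]`` array) with binary labels ``y``."""
        if isinstance(X, N.LabeledDataset):
            data = X
        else:
            arr = np.asarray(X)
            if arr.dtype.kind in "UO":
                data = N.LabeledDataset(list(X), np.asarray(y))
            else:
                if y is None:
                    raise ValueError("labels y are required")
                data = (arr.astype(np.float64), np.asarray(y, dtype=np.int64))
        cfg = self._config()
        rng = np.random.default_rng(self.random_state)
        self.model_ = N.build_model(cfg, rng)
        N.train(self.model_, data, rng)
        self.classes_ = np.array([0, 1])
        self.input_length_ = (
            len(data.sequences[0]) if isinstance(data, N.LabeledDataset) else data[0].shape[-1]
        )
        self.loss_curve_ = list(getattr(self.model_, "loss_curve_", []))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        if self.bayesian and self.keep_p < 1.0:
            rng = np.random.default_rng(self.random_state)
            p1 = N.predict_mc(self.model_, X, self.mc_samples, rng)
        else:
            p1 = N.predict_weight_avg(self.model_, X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(np.int64)

    def score(self, X, y, sample_weight=None) -> float:
        from sklearn.metrics import accuracy_score

        return accuracy_score(np.asarray(y), self.predict(X), sample_weight=sample_weight)
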