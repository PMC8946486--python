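"""Scikit-learn style estimators wrapping the waveform regressors.

Both estimators follow the fit/predict contract, expose their
hyperparameters through ``get_params``/``set_params`` and store fitted
state in trailing-underscore attributes, so they compose with sklearn
model selection and pipelines (the inputs are 3-D frame stacks, so use
them with pipeline steps that accept such arrays).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .models import CANSpec, LSTMSpec, build_can, build_lstm
from .train import TrainConfig, train_model

__all__ = ["CANRegressor", "LSTMRegressor"]


class _WaveformRegressor(RegressorMixin, BaseEstimator):
    """Shared fit/predict plumbing for the two sequence regressors."""

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learn_rate=self.learn_rate,
            drop_factor=self.drop_factor,
            drop_period=self.drop_period,
            l2_regularization=self.l2_regularization,
            gradient_clip=self.gradient_clip,
            max_epochs=self.max_epochs,
            mini_batch=self.mini_batch,
            shuffle=self.shuffle,
            seed=0 if self.random_state is None else int(self.random_state),
            validation_fraction=self.validation_fraction,
        )

    def fit(self, X, y, *, abp_stats=(0.0, 1.0), X_val=None, y_val=None,
            augment=None):  # noqa: N803
        X, y = self._check_Xy(X, y)
        self.model_ = self._build_model()
        cfg = self._train_config()
        self.history_ = train_model(
            self.model_, X, y, cfg,
            abp_stats=abp_stats,
            val_inputs=X_val, val_labels=y_val,
            augment=augment,
        )
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict(self, X):  # noqa: N803
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")
        return self.model_.predict(np.asarray(X, dtype=np.float64))


class CANRegressor(_WaveformRegressor):
    """Context aggregation network regressor: (N, 4, L) -> (N, L).

    Inputs are the z-scored spectral frames (|ECG|, phase ECG, |PPG|,
    phase PPG); targets are z-scored time-domain pressure frames.
    Defaults are the desk-scale training configuration; the published
    full-scale settings are ``channels=32, learn_rate=1e-4,
    max_epochs=7000, mini_batch=1``.
    """

    def __init__(
        self,
        channels: int = 8,
        in_rows: int = 4,
        in_cols: int = 250,
        pre_regression_channels: int = 3,
        leaky_slope: float = 0.2,
        learn_rate: float = 3e-3,
        drop_factor: float = 0.01,
        drop_period: int = 125_000,
        l2_regularization: float = 1e-4,
        gradient_clip: float = 1.0,
        max_epochs: int = 40,
        mini_batch: int = 8,
        shuffle: str = "every-epoch",
        validation_fraction: float = 0.05,
        random_state: int | None = None,
    ) -> None:
        self.channels = channels
        self.in_rows = in_rows
        self.in_cols = in_cols
        self.pre_regression_channels = pre_regression_channels
        self.leaky_slope = leaky_slope
        self.learn_rate = learn_rate
        self.drop_factor = drop_factor
        self.drop_period = drop_period
        self.l2_regularization = l2_regularization
        self.gradient_clip = gradient_clip
        self.max_epochs = max_epochs
        self.mini_batch = mini_batch
        self.shuffle = shuffle
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _build_model(self):
        spec = CANSpec(
            in_rows=self.in_rows,
            in_cols=self.in_cols,
            channels=self.channels,
            pre_regression_channels=self.pre_regression_channels,
            leaky_slope=self.leaky_slope,
        )
        seed = 0 if self.random_state is None else int(self.random_state)
        return build_can(spec, seed=seed)

    def _check_Xy(self, X, y):  # noqa: N803
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim == 4 and X.shape[-1] == 1:
            X = X[..., 0]
        if X.ndim != 3 or X.shape[1] != self.in_rows or X.shape[2] != self.in_cols:
            raise ValueError(
                f"expected X of shape (N, {self.in_rows}, {self.in_cols}), got {X.shape}"
            )
        if y.shape != (X.shape[0], self.in_cols):
            raise ValueError(
                f"expected y of shape (N, {self.in_cols}), got {y.shape}"
            )
        return X, y


class LSTMRegressor(_WaveformRegressor):
    """Time-domain LSTM baseline: (N, T, 2) -> (N, T).

    Inputs are raw (standardized) ECG/PPG sequences; targets are
    z-scored pressure sequences.  Defaults are desk scale; the
    published settings are ``hidden_units=400, learn_rate=5e-3,
    max_epochs=7000, mini_batch=2, shuffle='once'``.
    """

    def __init__(
        self,
        hidden_units: int = 32,
        input_dims: int = 2,
        learn_rate: float = 5e-3,
        drop_factor: float = 0.01,
        drop_period: int = 125_000,
        l2_regularization: float = 1e-4,
        gradient_clip: float = 1.0,
        max_epochs: int = 40,
        mini_batch: int = 8,
        shuffle: str = "once",
        validation_fraction: float = 0.05,
        random_state: int | None = None,
    ) -> None:
        self.hidden_units = hidden_units
        self.input_dims = input_dims
        self.learn_rate = learn_rate
        self.drop_factor = drop_factor
        self.drop_period = drop_period
        self.l2_regularization = l2_regularization
        self.gradient_clip = gradient_clip
        self.max_epochs = max_epochs
        self.mini_batch = mini_batch
        self.shuffle = shuffle
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _build_model(self):
        spec = LSTMSpec(input_dims=self.input_dims, hidden_units=self.hidden_units)
        seed = 0 if self.random_state is None else int(self.random_state)
        return build_lstm(spec, seed=seed)

    def _check_Xy(self, X, y):  # noqa: N803
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 3 or X.shape[2] != self.input_dims:
            raise ValueError(
                f"expected X of shape (N, T, {self.input_dims}), got {X.shape}"
            )
        if y.shape != X.shape[:2]:
            raise ValueError(f"expected y of shape {X.shape[:2]}, got {y.shape}")
        return X, y
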