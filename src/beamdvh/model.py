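"""Composite-plan DVH prediction from nine per-beam DVHs.

The estimator follows the Model/Results idiom: :class:`DVHSequenceModel`
holds the training data and configuration, ``fit()`` runs Adam on the
stacked-GRU regressor and returns a :class:`DVHSequenceResults` carrying the
fitted parameters, the training log, prediction, persistence and plotting.

Sequence arrangement
--------------------
The sequence axis is the volume-bin index (1000 steps for 0.1% bins); each
step carries nine features, the per-beam doses at that volume fraction,
divided by the normalization dose (70 Gy, the highest prescription level).
The single-unit last GRU layer's state sequence is the predicted composite
curve on the same grid; predictions are rescaled, clipped at zero and
projected onto the monotone cone by a running maximum so that every output
is a valid cumulative DVH.

One model is trained pooled across all organs; the remaining organ-specific
bias is handled downstream by the c_OAR correction factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dvh import BeamDVHSet, DVHCurve
from .gru import Adam, GRUStack, mse_loss

__all__ = [
    "PredictorConfig",
    "DVHSequenceModel",
    "DVHSequenceResults",
    "assemble_sequence",
]

CHECKPOINT_SCHEMA = "beamdvh-gru-checkpoint-v1"


@dataclass(frozen=True)
class PredictorConfig:
    """Architecture, normalization and training hyper-parameters.

    ``hidden_sizes`` are the GRU state sizes; the final size must be 1 (that
    state sequence is the output).  ``dose_norm_gy`` scales doses into ~[0, 1]
    before the network sees them.  ``loss_tol`` (> 0) stops training early
    once the epoch MSE on the normalized scale falls below it.
    """

    hidden_sizes: Tuple[int, ...] = (18, 9, 1)
    dv: float = 0.001
    dose_norm_gy: float = 70.0
    learning_rate: float = 5e-3
    epochs: int = 60
    batch_size: int = 160
    seed: int = 0
    loss_tol: float = 0.0
    lr_decay: str = "cosine"  # "cosine" or "constant"
    grad_clip: float = 0.0  # global gradient-norm clip; 0 disables

    def __post_init__(self):
        if self.hidden_sizes[-1] != 1:
            raise ValueError("last hidden size must be 1 (state sequence is output)")
        if self.dose_norm_gy <= 0:
            raise ValueError("dose_norm_gy must be positive")


def assemble_sequence(beam_set: BeamDVHSet, config: PredictorConfig) -> np.ndarray:
    """(n_bins, 9) network input: normalized beam doses per volume grid point."""
    n_expected = round(1.0 / config.dv)
    if beam_set.n_bins != n_expected or abs(beam_set.dv - config.dv) > 1e-12:
        raise ValueError(
            f"beam set grid (dv={beam_set.dv}, n={beam_set.n_bins}) does not "
            f"match config (dv={config.dv}, n={n_expected})"
        )
    return beam_set.dose_matrix() / config.dose_norm_gy


class DVHSequenceModel:
    """Pooled sequence regressor from nine beam DVHs to the plan DVH."""

    def __init__(
        self,
        beam_sets: Sequence[BeamDVHSet],
        plan_curves: Sequence[DVHCurve],
        config: Optional[PredictorConfig] = None,
    ):
        if len(beam_sets) == 0:
            raise ValueError("empty dataset")
        if len(beam_sets) != len(plan_curves):
            raise ValueError("beam_sets and plan_curves must pair one-to-one")
        self.config = config or PredictorConfig()
        n_expected = round(1.0 / self.config.dv)
        for bs, pc in zip(beam_sets, plan_curves):
            if bs.n_bins != n_expected or pc.n_bins != n_expected:
                raise ValueError(
                    f"sample ({bs.patient_id}, {bs.structure_id}) grid does not "
                    f"match config dv={self.config.dv}"
                )
        self.beam_sets = list(beam_sets)
        self.plan_curves = list(plan_curves)

    @classmethod
    def from_samples(
        cls,
        samples: Sequence[Tuple[BeamDVHSet, DVHCurve]],
        config: Optional[PredictorConfig] = None,
    ) -> "DVHSequenceModel":
        beam_sets = [s[0] for s in samples]
        plans = [s[1] for s in samples]
        return cls(beam_sets, plans, config)

    def _design(self) -> Tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        X = np.stack([assemble_sequence(bs, cfg) for bs in self.beam_sets])
        Y = np.stack([pc.doses / cfg.dose_norm_gy for pc in self.plan_curves])
        return X, Y  # (N, T, 9), (N, T)

    def fit(self, verbose: bool = False) -> "DVHSequenceResults":
        """Train with Adam on the pooled MSE between predicted and true curves."""
        cfg = self.config
        X, Y = self._design()
        N = X.shape[0]
        rng = np.random.default_rng(cfg.seed)
        net = GRUStack((9, *cfg.hidden_sizes), rng)
        opt = Adam(net.params, lr=cfg.learning_rate)
        bs = min(cfg.batch_size, N)
        training_log: List[float] = []
        for epoch in range(cfg.epochs):
            if cfg.lr_decay == "cosine":
                opt.lr = cfg.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * epoch / max(1, cfg.epochs))
                )
            order = rng.permutation(N)
            epoch_loss = 0.0
            n_seen = 0
            for start in range(0, N, bs):
                idx = order[start : start + bs]
                xb = X[idx].transpose(1, 0, 2)  # (T, B, 9)
                yb = Y[idx].T[:, :, None]  # (T, B, 1)
                out, state = net.forward(xb, cache=True)
                loss, dy = mse_loss(out, yb)
                grads = net.backward(state, dy)
                if cfg.grad_clip > 0:
                    gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
                    if gnorm > cfg.grad_clip:
                        scale = cfg.grad_clip / gnorm
                        grads = {k: g * scale for k, g in grads.items()}
                opt.step(grads)
                epoch_loss += loss * idx.size
                n_seen += idx.size
            epoch_loss /= n_seen
            training_log.append(epoch_loss)
            if verbose and (epoch % 10 == 0 or epoch == cfg.epochs - 1):
                print(f"epoch {epoch:4d}  mse {epoch_loss:.3e}")
            if cfg.loss_tol > 0 and epoch_loss < cfg.loss_tol:
                break
        return DVHSequenceResults(
            params={k: v.copy() for k, v in net.params.items()},
            config=cfg,
            training_log=training_log,
            n_samples=N,
        )


@dataclass
class DVHSequenceResults:
    """Fitted predictor: parameters, training history, prediction, persistence."""

    params: Dict[str, np.ndarray]
    config: PredictorConfig
    training_log: List[float]
    n_samples: int

    @property
    def fitted(self) -> bool:
        return len(self.training_log) > 0

    def _net(self) -> GRUStack:
        net = GRUStack((9, *self.config.hidden_sizes), np.random.default_rng(0))
        for k in net.params:
            net.params[k] = self.params[k]
        return net

    def predict(self, beam_set: BeamDVHSet) -> DVHCurve:
        """Predicted composite-plan DVH for one patient-organ beam set."""
        if not self.fitted:
            raise ValueError("model is not fitted")
        x = assemble_sequence(beam_set, self.config)[:, None, :]  # (T, 1, 9)
        out, _ = self._net().forward(x)
        doses = out[:, 0, 0] * self.config.dose_norm_gy
        doses = np.maximum.accumulate(np.clip(doses, 0.0, None))
        return DVHCurve(
            structure_id=beam_set.structure_id,
            doses=doses,
            dv=self.config.dv,
            source="predicted",
        )

    def predict_many(self, beam_sets: Sequence[BeamDVHSet]) -> List[DVHCurve]:
        if not self.fitted:
            raise ValueError("model is not fitted")
        if len(beam_sets) == 0:
            return []
        cfg = self.config
        X = np.stack([assemble_sequence(bs, cfg) for bs in beam_sets])
        out, _ = self._net().forward(X.transpose(1, 0, 2))
        preds = []
        for j, bs in enumerate(beam_sets):
            doses = np.maximum.accumulate(
                np.clip(out[:, j, 0] * cfg.dose_norm_gy, 0.0, None)
            )
            preds.append(
                DVHCurve(
                    structure_id=bs.structure_id,
                    doses=doses,
                    dv=cfg.dv,
                    source="predicted",
                )
            )
        return preds

    def summary(self) -> str:
        cfg = self.config
        n_params = sum(v.size for v in self.params.values())
        lines = [
            "DVH sequence regressor (stacked GRU)",
            "=" * 44,
            f"layers (input -> hidden):  9 -> {' -> '.join(map(str, cfg.hidden_sizes))}",
            f"parameters:                {n_params}",
            f"volume bins (dv):          {round(1 / cfg.dv)} ({cfg.dv})",
            f"dose normalization:        {cfg.dose_norm_gy} Gy",
            f"training samples:          {self.n_samples}",
            f"epochs run:                {len(self.training_log)}",
            f"learning rate / batch:     {cfg.learning_rate} / {cfg.batch_size}",
            f"first-epoch MSE:           {self.training_log[0]:.4e}"
            if self.training_log
            else "unfitted",
            f"final MSE:                 {self.training_log[-1]:.4e}"
            if self.training_log
            else "",
        ]
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Write a self-contained JSON checkpoint (schema, config, parameters)."""
        payload = {
            "schema": CHECKPOINT_SCHEMA,
            "config": asdict(self.config),
            "n_samples": self.n_samples,
            "training_log": self.training_log,
            "params": {
                k: {"shape": list(v.shape), "data": v.ravel().tolist()}
                for k, v in sorted(self.params.items())
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "DVHSequenceResults":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(
                f"checkpoint schema mismatch: expected {CHECKPOINT_SCHEMA!r}, "
                f"found {payload.get('schema')!r}"
            )
        cfg_dict = dict(payload["config"])
        cfg_dict["hidden_sizes"] = tuple(cfg_dict["hidden_sizes"])
        config = PredictorConfig(**cfg_dict)
        params = {}
        expected = GRUStack((9, *config.hidden_sizes), np.random.default_rng(0)).params
        for k, blob in payload["params"].items():
            arr = np.array(blob["data"], dtype=float).reshape(blob["shape"])
            if k not in expected or expected[k].shape != arr.shape:
                raise ValueError(
                    f"checkpoint schema mismatch: parameter {k!r} has shape "
                    f"{arr.shape}, expected {expected.get(k, np.empty(0)).shape}"
                )
            params[k] = arr
        if set(params) != set(expected):
            raise ValueError("checkpoint schema mismatch: missing parameters")
        return cls(
            params=params,
            config=config,
            training_log=list(payload["training_log"]),
            n_samples=int(payload["n_samples"]),
        )

    # -- plotting ---------------------------------------------------------

    def plot_prediction(self, beam_set: BeamDVHSet, true_curve: Optional[DVHCurve] = None, ax=None):
        """Plot predicted (and optionally true) plan DVH with the beam inputs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pred = self.predict(beam_set)
        v = pred.volume_grid * 100
        for i, b in enumerate(beam_set.beams):
            ax.plot(b.doses, v, color="0.8", lw=0.7,
                    label="beams" if i == 0 else None)
        ax.plot(pred.doses, v, color="C1", lw=1.6, label="predicted plan")
        if true_curve is not None:
            ax.plot(true_curve.doses, v, color="C0", lw=1.6, ls="--", label="true plan")
        ax.set_xlabel("Dose (Gy)")
        ax.set_ylabel("Volume (%)")
        ax.set_title(f"{beam_set.patient_id} / {beam_set.structure_id}")
        ax.legend()
        return ax
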