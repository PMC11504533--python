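"""End-to-end joint-angle regression: dual-branch model + LSTM + training.

The full model chains the multi-scale sEMG autoencoder, the depth-image
pose network, the gated pyramid fusion block and a single-layer LSTM with a
linear head producing per-frame hip/knee/ankle angles.  Training minimizes
the angle MSE plus ``lambda_recon`` times the sEMG reconstruction error,
jointly over all four submodules.  Angle targets are z-scored per joint
during optimisation; predictions are mapped back to degrees, so the public
interface always speaks degrees.

Single-modality ablations reuse the same architecture: in ``semg`` mode the
vision feature vector is identically zero (depth frames are never touched);
in ``vision`` mode the sEMG latents are zero and the gate sees a zero
latent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .nn import Adam, LSTM, Linear, Module, Tensor, no_grad
from .semg_encoder import EncoderSpec, MultiScaleAutoencoder, reconstruction_loss
from .vision_net import PoseNet, VisionSpec
from .fusion import FusionNet, FusionSpec, FusedFeature
from .gaitsim import SyncedDataset
from .types import JointAngleSample

__all__ = ["TrainConfig", "JointAngleModel", "train_full", "predict_sequence",
           "predict_dataset", "save_checkpoint", "load_checkpoint"]

MODALITIES = ("fused", "semg", "vision")


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 6          # sequences per optimisation step
    lr: float = 1e-3
    lambda_recon: float = 0.1
    seq_len: int = 30            # frames per LSTM sequence (~1 s at 30 fps)
    seq_stride: int = 30         # non-overlapping sequences
    recon_subsample: int = 60    # frames per step used for the recon term
    val_frac: float = 0.2
    seed: int = 0
    modality: str = "fused"
    lstm_hidden: int = 64
    pretrain_ae_epochs: int = 0  # optional two-stage variant

    def __post_init__(self):
        if not 0 < self.val_frac < 1:
            raise ValueError("val_frac must be in (0, 1)")
        if self.lambda_recon < 0:
            raise ValueError("lambda_recon must be nonnegative")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")


class JointAngleModel(Module):
    """sEMG autoencoder + pose net + fusion + LSTM regression head."""

    def __init__(self, encoder_spec: EncoderSpec = None,
                 vision_spec: VisionSpec = None,
                 fusion_spec: FusionSpec = None,
                 lstm_hidden: int = 64, modality: str = "fused",
                 seed: int = 0):
        super().__init__()
        if modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        self.encoder_spec = encoder_spec or EncoderSpec()
        self.vision_spec = vision_spec or VisionSpec()
        self.fusion_spec = fusion_spec or FusionSpec(
            latent_dim=self.encoder_spec.latent_dim,
            vision_dim=self.vision_spec.feature_dim
            if vision_spec is not None else FusionSpec().vision_dim)
        self.modality = modality
        self.lstm_hidden = lstm_hidden
        self.autoencoder = MultiScaleAutoencoder(self.encoder_spec, seed=seed)
        self.vision = PoseNet(self.vision_spec, seed=seed)
        self.fusion = FusionNet(self.fusion_spec, seed=seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x157]))
        self.lstm = LSTM(rng, self.fusion_spec.fused_dim, lstm_hidden)
        self.head = Linear(rng, lstm_hidden, 3)
        self.add_buffer("target_mean", np.zeros(3))
        self.add_buffer("target_std", np.ones(3))

    # -- forward -------------------------------------------------------------
    def fused_sequence(self, windows: tuple, frames: np.ndarray,
                       recon_max: int | None = None):
        """windows: three [B, T, L_s, 9]; frames [B, T, H, W] (mm).

        Returns (fused [B, T, fused_dim] Tensor, recon_loss Tensor or None).
        When ``recon_max`` is set, the reconstruction term is estimated on an
        evenly spaced subsample of at most that many frames (a cheaper but
        unbiased-in-practice stand-in for the full-batch term).
        """
        b, t = frames.shape[:2]
        bt = b * t
        recon = None
        if self.modality in ("fused", "semg"):
            xs = [Tensor(np.ascontiguousarray(w, dtype=np.float32)
                         .reshape(bt, w.shape[2], w.shape[3]))
                  for w in windows]
            latents = self.autoencoder.encode_batch(xs)
            if recon_max is not None and bt > recon_max:
                sub = np.linspace(0, bt - 1, recon_max).round().astype(int)
                rec = self.autoencoder.decode_batch([z[sub] for z in latents])
                recon = reconstruction_loss([x[sub] for x in xs], rec)
            else:
                rec = self.autoencoder.decode_batch(latents)
                recon = reconstruction_loss(xs, rec)
        else:
            latents = [Tensor(np.zeros((bt, self.encoder_spec.latent_dim),
                                       np.float32)) for _ in range(3)]
        if self.modality in ("fused", "vision"):
            _, vis_feat = self.vision.forward_frames(
                np.ascontiguousarray(frames).reshape(bt, *frames.shape[2:]))
        else:
            vis_feat = Tensor(np.zeros((bt, self.fusion_spec.vision_dim),
                                       np.float32))
        gated = self.fusion.gate_vision_batch(latents[-1], vis_feat)
        fused = self.fusion.fuse_batch(latents, gated)
        return fused.reshape(b, t, self.fusion_spec.fused_dim), recon

    def angles_from_fused(self, fused: Tensor) -> Tensor:
        """[B, T, fused_dim] -> normalized angle outputs [B, T, 3]."""
        h = self.lstm(fused)
        b, t, hd = h.shape
        out = self.head(h.reshape(b * t, hd))
        return out.reshape(b, t, 3)

    def denormalize(self, out: np.ndarray) -> np.ndarray:
        return out * self.target_std + self.target_mean

    def predict_arrays(self, windows: tuple, frames: np.ndarray) -> np.ndarray:
        """Sequences in, degrees out ([B, T, 3]); eval mode, no autodiff."""
        self.eval()
        with no_grad():
            fused, _ = self.fused_sequence(windows, frames)
            out = self.angles_from_fused(fused)
        return self.denormalize(out.data.astype(np.float64))


def predict_sequence(fused_seq: list, model: JointAngleModel,
                     ts: list | None = None) -> list:
    """Run the LSTM head over a sequence of fused features.

    The LSTM state carries across the sequence and is reset at the start;
    output is one ``JointAngleSample`` per step, in degrees.
    """
    if len(fused_seq) == 0:
        raise ValueError("empty fused sequence")
    vecs = np.stack([f.vector if isinstance(f, FusedFeature) else np.asarray(f)
                     for f in fused_seq]).astype(np.float32)
    model.eval()
    with no_grad():
        out = model.angles_from_fused(Tensor(vecs[None, :, :]))
    deg = model.denormalize(out.data[0].astype(np.float64))
    if ts is None:
        ts = [float(i) for i in range(len(fused_seq))]
    return [JointAngleSample(*deg[i], ts[i]) for i in range(len(fused_seq))]


def _sequence_starts(n: int, seq_len: int, stride: int) -> np.ndarray:
    if n < seq_len:
        raise ValueError("dataset shorter than one sequence")
    starts = np.arange(0, n - seq_len + 1, stride)
    if starts[-1] != n - seq_len:
        starts = np.append(starts, n - seq_len)
    return starts


def _gather(dataset: SyncedDataset, starts, seq_len):
    idx = np.stack([np.arange(s, s + seq_len) for s in starts])
    windows = tuple(w[idx] for w in (dataset.windows_full, dataset.windows_mid,
                                     dataset.windows_short))
    return windows, dataset.frames[idx], dataset.angles[idx]


def train_full(dataset: SyncedDataset, cfg: TrainConfig,
               model: JointAngleModel | None = None):
    """Joint end-to-end training; returns (model, history).

    History records per-epoch train loss, validation regression loss (MSE in
    normalized units) and per-joint validation RMSE in degrees; the returned
    model carries the best-validation parameters.
    """
    n = len(dataset)
    starts = _sequence_starts(n, cfg.seq_len, cfg.seq_stride)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7A1]))
    perm = rng.permutation(len(starts))
    n_val = max(1, int(round(cfg.val_frac * len(starts))))
    if len(starts) - n_val < 1:
        raise ValueError("dataset too small for the requested split")
    val_starts, train_starts = starts[perm[:n_val]], starts[perm[n_val:]]
    if len(train_starts) < 1 or cfg.batch_size < 1:
        raise ValueError("dataset smaller than one batch")

    if model is None:
        from .vision_net import VisionSpec
        vspec = VisionSpec(resolution=tuple(dataset.frames.shape[1:]))
        model = JointAngleModel(vision_spec=vspec,
                                lstm_hidden=cfg.lstm_hidden,
                                modality=cfg.modality, seed=cfg.seed)
    tr_angles = dataset.angles[np.concatenate(
        [np.arange(s, s + cfg.seq_len) for s in train_starts])]
    model.target_mean[...] = tr_angles.mean(axis=0)
    model.target_std[...] = np.maximum(tr_angles.std(axis=0), 1e-6)

    if cfg.pretrain_ae_epochs > 0 and cfg.modality in ("fused", "semg"):
        from .semg_encoder import fit_autoencoder
        fit_autoencoder(model.autoencoder,
                        (dataset.windows_full, dataset.windows_mid,
                         dataset.windows_short),
                        epochs=cfg.pretrain_ae_epochs, seed=cfg.seed)
        model.autoencoder.train()

    opt = Adam(model.parameters(), lr=cfg.lr)
    wv, fv, av = _gather(dataset, val_starts, cfg.seq_len)
    hist = {"train_loss": [], "val_loss": [], "val_rmse": []}
    best = (np.inf, None)
    model.train()
    for _ in range(cfg.epochs):
        order = rng.permutation(len(train_starts))
        losses = []
        for i0 in range(0, len(train_starts), cfg.batch_size):
            batch = train_starts[order[i0:i0 + cfg.batch_size]]
            wb, fb, ab = _gather(dataset, batch, cfg.seq_len)
            tgt = Tensor(((ab - model.target_mean) / model.target_std)
                         .astype(np.float32))
            fused, recon = model.fused_sequence(
                wb, fb, recon_max=cfg.recon_subsample or None)
            out = model.angles_from_fused(fused)
            loss = ((out - tgt) ** 2).mean()
            if recon is not None and cfg.lambda_recon > 0:
                loss = loss + cfg.lambda_recon * recon
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        hist["train_loss"].append(float(np.mean(losses)))

        model.eval()
        with no_grad():
            fused, _ = model.fused_sequence(wv, fv)
            out = model.angles_from_fused(fused)
        model.train()
        pred_deg = model.denormalize(out.data.astype(np.float64))
        vloss = float(np.mean(((pred_deg - av) / model.target_std) ** 2))
        vrmse = np.sqrt(np.mean((pred_deg - av) ** 2, axis=(0, 1)))
        hist["val_loss"].append(vloss)
        hist["val_rmse"].append(vrmse.tolist())
        if vloss < best[0]:
            best = (vloss, model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])
    model.eval()
    return model, hist


def predict_dataset(model: JointAngleModel, dataset: SyncedDataset,
                    seq_len: int = 30) -> np.ndarray:
    """Predict angles (degrees, [N, 3]) for every record, in chunks of
    ``seq_len`` frames (LSTM state resets between chunks)."""
    n = len(dataset)
    out = np.empty((n, 3))
    for s in range(0, n, seq_len):
        e = min(s + seq_len, n)
        sl = np.arange(s, e)
        windows = tuple(w[sl][None] for w in (dataset.windows_full,
                                              dataset.windows_mid,
                                              dataset.windows_short))
        out[s:e] = model.predict_arrays(windows, dataset.frames[sl][None])[0]
    return out


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(model: JointAngleModel, path):
    """Single-file checkpoint: all parameters/buffers + architecture echo."""
    spec = {
        "encoder_spec": asdict(model.encoder_spec),
        "vision_spec": asdict(model.vision_spec),
        "fusion_spec": asdict(model.fusion_spec),
        "lstm_hidden": model.lstm_hidden,
        "modality": model.modality,
    }
    arrays = {f"param:{k}": v for k, v in model.state_dict().items()}
    arrays["spec"] = np.frombuffer(
        json.dumps(spec, sort_keys=True).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def load_checkpoint(path) -> JointAngleModel:
    z = np.load(path)
    spec = json.loads(bytes(z["spec"]).decode())
    enc = EncoderSpec(**_tuplify(spec["encoder_spec"]))
    vis = VisionSpec(**{k: tuple(v) if isinstance(v, list) else v
                        for k, v in spec["vision_spec"].items()})
    fus = FusionSpec(**spec["fusion_spec"])
    model = JointAngleModel(enc, vis, fus, spec["lstm_hidden"],
                            spec["modality"])
    state = {k[len("param:"):]: z[k] for k in z.files if k.startswith("param:")}
    model.load_state_dict(state)
    model.eval()
    return model
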