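"""Conditional-GAN electrical-properties reconstruction (DL-EPT).

A U-Net generator maps a 3-channel acquisition — normalized transmit
magnitude, transmit phase, and an auxiliary channel (binary mask for the
cGAN_mask variant, pseudo spin-echo tissue contrast for cGAN_tissue) —
to a conductivity or permittivity map.  A convolutional PatchGAN
discriminator scores local patches of (input, map) pairs as real or
generated.  Training minimizes

    F = arg min_G max_D  lambda_GAN * L_GAN(G, D)
                         + lambda_L1 * L1(G) + lambda_L2 * L2(G)

with default weights lambda_GAN = 2, lambda_L1 = 100, lambda_L2 = 200
(the combination selected on the validation phantoms); setting
lambda_GAN = 0 degrades gracefully to plain supervised U-Net training.
Separate networks are trained for conductivity and permittivity.

Input normalization: the magnitude channel is divided by its in-mask
mean; the phase channel is centered on its in-mask mean and expressed
in quarter-turn units; targets are scaled linearly to [0, 1] over
configured physical ranges and inverted at inference.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .em_forward import Acquisition, solve_fields, make_acquisition
from .hept import EpsMaps
from .models import TissueModel
from .noise import NoiseSpec, corrupt_acquisition

__all__ = ["NetworkConfig", "TrainingExample", "DatasetSplit", "TrainedModel",
           "count_dataset_slices", "assemble_dataset", "cgan_objective",
           "train", "select_model", "predict"]

F32 = np.float32


@dataclass
class NetworkConfig:
    """Architecture, loss weights and training hyper-parameters."""

    target: str = "sigma"              # {"sigma", "epsr"}
    aux: str = "mask"                  # {"mask", "tissue_contrast"}
    lambda_gan: float = 2.0
    lambda_l1: float = 100.0
    lambda_l2: float = 200.0
    image_size: int = 64
    base_channels: int = 16
    depth: int = 3
    patch_gan_field: int = 34          # receptive field of D, voxels
    epochs: int = 60
    batch_size: int = 8
    learning_rate: float = 4e-4
    beta1: float = 0.5
    seed: int = 0
    swa_fraction: float = 0.25         # weight-average over final epochs
    sigma_range: tuple = (0.0, 2.5)    # S/m, target scaling
    epsr_range: tuple = (1.0, 100.0)   # target scaling

    def __post_init__(self):
        if self.target not in ("sigma", "epsr"):
            raise ValueError("target must be 'sigma' or 'epsr'")
        if self.aux not in ("mask", "tissue_contrast"):
            raise ValueError("aux must be 'mask' or 'tissue_contrast'")
        if min(self.lambda_gan, self.lambda_l1, self.lambda_l2) < 0:
            raise ValueError("loss weights must be non-negative")

    @property
    def target_range(self):
        return self.sigma_range if self.target == "sigma" else self.epsr_range

    @property
    def method_name(self):
        return "cGAN_mask" if self.aux == "mask" else "cGAN_tissue"


@dataclass
class TrainingExample:
    """One (input channels, ground-truth map) pair with provenance."""

    inputs: np.ndarray        # (3, H, W) float32, normalized
    target: np.ndarray        # (H, W) physical units
    mask: np.ndarray          # (H, W) bool
    provenance: str = ""      # "model<id>/slice<j>"


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test model-id lists."""

    train: list
    validation: list = field(default_factory=list)
    test: list = field(default_factory=list)

    def __post_init__(self):
        tr, va, te = map(set, (self.train, self.validation, self.test))
        if tr & va or tr & te or va & te:
            raise ValueError("dataset splits must be pairwise disjoint")


def count_dataset_slices(n_phantoms: int, slices_per_phantom: int,
                         n_heads: int, slices_per_head: int) -> int:
    """Total number of 2D field distributions in a database."""
    if min(n_phantoms, slices_per_phantom, n_heads, slices_per_head) < 0:
        raise ValueError("counts must be non-negative")
    return n_phantoms * slices_per_phantom + n_heads * slices_per_head


# ----------------------------------------------------------------------
# Dataset assembly
# ----------------------------------------------------------------------

PHASE_UNIT = np.pi / 4.0  # phase channel in quarter-turn units


def normalize_channels(acq: Acquisition) -> np.ndarray:
    """Network input channels as float32.

    Magnitude is divided by its in-mask mean; the phase is centered on
    its in-mask mean and expressed in quarter-turn units (rad / (pi/4))
    so its dynamic range matches the magnitude channel's — with a
    full-turn unit the early convolutions under-use the phase and the
    conductivity estimate degrades measurably.
    """
    mask = acq.mask
    mag = acq.magnitude / max(acq.magnitude[mask].mean(), 1e-12)
    phase = (acq.phase - acq.phase[mask].mean()) / PHASE_UNIT
    return np.stack([mag, phase, acq.aux]).astype(F32)


def scale_target(target_map: np.ndarray, config: NetworkConfig) -> np.ndarray:
    lo, hi = config.target_range
    return ((target_map - lo) / (hi - lo)).astype(F32)


def unscale_target(scaled: np.ndarray, config: NetworkConfig) -> np.ndarray:
    lo, hi = config.target_range
    return scaled.astype(float) * (hi - lo) + lo


def _example_from(acq: Acquisition, model: TissueModel, target: str,
                  provenance: str) -> TrainingExample:
    tmap = model.sigma_map if target == "sigma" else model.epsr_map
    return TrainingExample(inputs=normalize_channels(acq),
                           target=tmap.copy(), mask=model.mask.copy(),
                           provenance=provenance)


def assemble_dataset(models, split: DatasetSplit, noise: NoiseSpec,
                     aux: str = "mask", target: str = "sigma",
                     slices_per_model: int = 5, solutions=None):
    """Build training/validation/test example sets.

    One field solve per model; the per-model 2D "slices" of the
    desk-scale configuration are generated by re-seeding the noise model
    (validation/test models get one noisy slice each).  ``solutions`` may
    carry precomputed ``FieldSolution``s keyed by model id to avoid
    re-solving.
    """
    for ids in (split.train, split.validation, split.test):
        for i in ids:
            if not 0 <= i < len(models):
                raise ValueError(f"split references unknown model id {i}")
    out = {"train": [], "validation": [], "test": []}
    for part, ids, n_slices in (("train", split.train, slices_per_model),
                                ("validation", split.validation, 1),
                                ("test", split.test, 1)):
        for mid in ids:
            model = models[mid]
            sol = solutions[mid] if solutions else solve_fields(model)
            clean = make_acquisition(sol, model, aux=aux)
            for j in range(n_slices):
                spec = dataclasses.replace(
                    noise, seed=noise.seed + 104729 * mid + 13 * j)
                acq = corrupt_acquisition(clean, spec)
                out[part].append(_example_from(acq, model, target,
                                               f"model{mid}/slice{j}"))
    return out


# ----------------------------------------------------------------------
# Networks
# ----------------------------------------------------------------------

class UNet:
    """3-level U-Net with skip connections; linear single-channel output."""

    def __init__(self, cin=3, base=16, rng=None):
        rng = rng or np.random.default_rng(0)
        b = base
        self.cin = cin
        self.e1 = nn.Sequential(nn.Conv2d(cin, b, 4, 2, 1, rng=rng),
                                nn.LeakyReLU())
        self.e2 = nn.Sequential(nn.Conv2d(b, 2 * b, 4, 2, 1, rng=rng),
                                nn.InstanceNorm(2 * b), nn.LeakyReLU())
        self.e3 = nn.Sequential(nn.Conv2d(2 * b, 4 * b, 4, 2, 1, rng=rng),
                                nn.InstanceNorm(4 * b), nn.LeakyReLU())
        self.bott = nn.Sequential(nn.Conv2d(4 * b, 4 * b, 3, 1, rng=rng),
                                  nn.InstanceNorm(4 * b), nn.LeakyReLU())
        self.d3 = nn.Sequential(nn.Conv2d(6 * b, 2 * b, 3, 1, rng=rng),
                                nn.InstanceNorm(2 * b), nn.LeakyReLU())
        self.d2 = nn.Sequential(nn.Conv2d(3 * b, b, 3, 1, rng=rng),
                                nn.InstanceNorm(b), nn.LeakyReLU())
        self.d1 = nn.Sequential(nn.Conv2d(b + cin, b // 2, 3, 1, rng=rng),
                                nn.LeakyReLU(),
                                nn.Conv2d(b // 2, 1, 3, 1, rng=rng))
        self.up = nn.Upsample2x()
        self._b = b
        self.blocks = [self.e1, self.e2, self.e3, self.bott,
                       self.d3, self.d2, self.d1]
        self.params = tuple(p for blk in self.blocks for p in blk.params)

    def forward(self, x, train=True):
        x = x.astype(F32, copy=False)
        a1 = self.e1.forward(x, train)
        a2 = self.e2.forward(a1, train)
        a3 = self.e3.forward(a2, train)
        bt = self.bott.forward(a3, train)
        u3 = self.d3.forward(np.concatenate([self.up.forward(bt), a2], axis=1),
                             train)
        u2 = self.d2.forward(np.concatenate([self.up.forward(u3), a1], axis=1),
                             train)
        return self.d1.forward(np.concatenate([self.up.forward(u2), x],
                                              axis=1), train)

    def backward(self, grad):
        b = self._b
        g = self.d1.backward(grad)
        g_u2 = self.up.backward(g[:, :b])         # rest flows into x (dropped)
        g = self.d2.backward(g_u2)
        g_u3, g_a1 = g[:, :2 * b], g[:, 2 * b:]
        g = self.d3.backward(self.up.backward(g_u3))
        g_bt, g_a2 = g[:, :4 * b], g[:, 4 * b:]
        g_a3 = self.bott.backward(self.up.backward(g_bt))
        g_a2 = g_a2 + self.e3.backward(g_a3)
        g_a1 = g_a1 + self.e2.backward(g_a2)
        return self.e1.backward(g_a1)


class PatchGAN(nn.Sequential):
    """Convolutional patch classifier on (input, map) channel stacks."""

    def __init__(self, cin=4, base=16, rng=None):
        rng = rng or np.random.default_rng(0)
        b = base
        super().__init__(
            nn.Conv2d(cin, b, 4, 2, 1, rng=rng), nn.LeakyReLU(),
            nn.Conv2d(b, 2 * b, 4, 2, 1, rng=rng),
            nn.InstanceNorm(2 * b), nn.LeakyReLU(),
            nn.Conv2d(2 * b, 4 * b, 4, 2, 1, rng=rng),
            nn.InstanceNorm(4 * b), nn.LeakyReLU(),
            nn.Conv2d(4 * b, 1, 3, 1, rng=rng))


# ----------------------------------------------------------------------
# Objective, training, inference
# ----------------------------------------------------------------------

def cgan_objective(G_output, target, D_scores, config: NetworkConfig):
    """Weighted generator / discriminator loss pair.

    ``D_scores`` maps "fake" (and, for the discriminator side, "real")
    to PatchGAN logit arrays.  L1/L2 are mean absolute/squared distances
    between the generated and ground-truth maps.
    """
    G_output = np.asarray(G_output, dtype=float)
    target = np.asarray(target, dtype=float)
    if G_output.shape != target.shape:
        raise ValueError("shape mismatch between output and target")
    l1 = float(np.abs(G_output - target).mean())
    l2 = float(((G_output - target) ** 2).mean())
    g_loss = config.lambda_l1 * l1 + config.lambda_l2 * l2
    if config.lambda_gan > 0 and D_scores and "fake" in D_scores:
        adv, _ = nn.bce_with_logits(np.asarray(D_scores["fake"], dtype=F32),
                                    1.0)
        g_loss += config.lambda_gan * adv
    d_loss = 0.0
    if D_scores and "fake" in D_scores and "real" in D_scores:
        lr_, _ = nn.bce_with_logits(np.asarray(D_scores["real"], dtype=F32),
                                    1.0)
        lf_, _ = nn.bce_with_logits(np.asarray(D_scores["fake"], dtype=F32),
                                    0.0)
        d_loss = 0.5 * (lr_ + lf_)
    return g_loss, d_loss


@dataclass
class TrainedModel:
    """Generator with its config and training history."""

    config: NetworkConfig
    generator: UNet
    discriminator: PatchGAN | None = None
    history: dict = field(default_factory=dict)

    def predict_channels(self, channels: np.ndarray) -> np.ndarray:
        """Scaled-map prediction for one (3, H, W) input stack."""
        out = self.generator.forward(channels[None], train=False)
        return out[0, 0]


def _stack_examples(examples, config):
    X = np.stack([ex.inputs for ex in examples]).astype(F32)
    Y = np.stack([scale_target(ex.target, config) for ex in examples])
    return X, Y[:, None].astype(F32)


def train(dataset, config: NetworkConfig, validation=None,
          callback=None) -> TrainedModel:
    """Alternating G/D updates on the weighted objective.

    ``dataset`` is a list of TrainingExample (or the dict returned by
    ``assemble_dataset``, whose "train"/"validation" parts are used).
    Per-epoch generator/discriminator losses and, when a validation set
    is given, the validation NRMSE are logged to ``history``.  Fully
    deterministic under ``config.seed``.
    """
    if isinstance(dataset, dict):
        validation = validation or dataset.get("validation") or None
        dataset = dataset["train"]
    if not dataset:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    G = UNet(cin=3, base=config.base_channels, rng=rng)
    D = PatchGAN(cin=4, base=config.base_channels, rng=rng)
    optG = nn.Adam(G.params, lr=config.learning_rate, beta1=config.beta1)
    optD = nn.Adam(D.params, lr=config.learning_rate, beta1=config.beta1)
    X, Y = _stack_examples(dataset, config)
    n = X.shape[0]
    bs = min(config.batch_size, n)
    history = {"g_loss": [], "d_loss": [], "l1": [], "val_nrmse": []}
    use_gan = config.lambda_gan > 0
    # stochastic weight averaging over the final epochs irons out the
    # residual adversarial oscillation of the generator
    swa_start = int(np.ceil(config.epochs * (1.0 - config.swa_fraction)))
    swa_sum = None
    swa_n = 0
    # with a validation set, the epoch with the lowest validation NRMSE
    # is selected (the study's model-selection rule); snapshots are only
    # considered once the learning rate starts decaying
    best_val = np.inf
    best_params = None
    select_start = config.epochs // 2

    for epoch in range(config.epochs):
        # constant rate for the first half, then linear decay to zero —
        # settles the adversarial dynamics onto the supervised optimum
        frac = (epoch + 1) / config.epochs
        decay = min(1.0, 2.0 * (1.0 - frac) + 1e-3)
        optG.lr = config.learning_rate * decay
        optD.lr = config.learning_rate * decay
        order = rng.permutation(n)
        g_ep = d_ep = l1_ep = 0.0
        nb = 0
        for start in range(0, n - bs + 1, bs):
            idx = order[start:start + bs]
            x, y = X[idx], Y[idx]
            fake = G.forward(x, train=True)

            d_loss = 0.0
            if use_gan:
                optD.zero_grad()
                z_real = D.forward(np.concatenate([x, y], axis=1), train=True)
                lr_, gr = nn.bce_with_logits(z_real, 1.0)
                D.backward(gr)
                z_fake = D.forward(np.concatenate([x, fake], axis=1),
                                   train=True)
                lf_, gf = nn.bce_with_logits(z_fake, 0.0)
                D.backward(gf)
                for _, g in D.params:
                    g *= 0.5
                optD.step()
                d_loss = 0.5 * (lr_ + lf_)

            # generator update: supervised gradient plus, if adversarial,
            # the gradient of fooling D routed back through the fake input
            diff = fake - y
            l1 = float(np.abs(diff).mean())
            l2 = float((diff ** 2).mean())
            grad_total = ((config.lambda_l1 * np.sign(diff)
                           + 2.0 * config.lambda_l2 * diff)
                          / diff.size).astype(F32)
            g_loss = config.lambda_l1 * l1 + config.lambda_l2 * l2
            if use_gan:
                z_fake = D.forward(np.concatenate([x, fake], axis=1),
                                   train=True)
                adv, gz = nn.bce_with_logits(z_fake, 1.0)
                g_loss += config.lambda_gan * adv
                optD.zero_grad()
                grad_total = grad_total \
                    + D.backward(config.lambda_gan * gz)[:, 3:]
                optD.zero_grad()
            optG.zero_grad()
            G.backward(grad_total)
            optG.step()

            if not np.isfinite(g_loss):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            g_ep += g_loss
            d_ep += d_loss
            l1_ep += l1
            nb += 1
        history["g_loss"].append(g_ep / nb)
        history["d_loss"].append(d_ep / nb)
        history["l1"].append(l1_ep / nb)
        if epoch + 1 > swa_start and config.swa_fraction > 0:
            if swa_sum is None:
                swa_sum = [p.astype(np.float64) for p, _ in G.params]
            else:
                for acc, (p, _) in zip(swa_sum, G.params):
                    acc += p
            swa_n += 1
        if validation:
            val = _validation_nrmse(G, validation, config)
            history["val_nrmse"].append(val)
            if epoch + 1 > select_start and val < best_val:
                best_val = val
                best_params = [p.copy() for p, _ in G.params]
        if callback:
            callback(epoch, history, G)
    if swa_sum is not None and swa_n > 0:
        swa_params = [(acc / swa_n).astype(F32) for acc in swa_sum]
        if validation and best_params is not None:
            # pick whichever of (best epoch, weight average) validates best
            for p_arr, (p, _) in zip(swa_params, G.params):
                p[...] = p_arr
            swa_val = _validation_nrmse(G, validation, config)
            chosen = swa_params if swa_val <= best_val else best_params
            history["selected"] = "swa" if swa_val <= best_val else "best-epoch"
        else:
            chosen = swa_params
        for p_arr, (p, _) in zip(chosen, G.params):
            p[...] = p_arr
    elif validation and best_params is not None:
        for p_arr, (p, _) in zip(best_params, G.params):
            p[...] = p_arr
    return TrainedModel(config=config, generator=G, discriminator=D,
                        history=history)


def _validation_nrmse(G, examples, config):
    from .evaluate import nrmse
    errs = []
    for ex in examples:
        pred = unscale_target(G.forward(ex.inputs[None], train=False)[0, 0],
                              config)
        errs.append(nrmse(pred, ex.target, ex.mask))
    return float(np.mean(errs))


def select_model(candidates, validation_sigma, validation_epsr=None):
    """Pick the candidate with the lowest average validation NRMSE.

    A candidate is either a single TrainedModel (scored on the
    validation set matching its target) or a (sigma-model, epsr-model)
    pair scored on the mean of the two NRMSEs.  Ties break to the
    lowest-index candidate (np.argmin convention).  Returns the winner
    and the score list.
    """
    if not candidates:
        raise ValueError("no candidates")
    scores = []
    for cand in candidates:
        if isinstance(cand, TrainedModel):
            val = validation_sigma if cand.config.target == "sigma" \
                else (validation_epsr or validation_sigma)
            scores.append(_validation_nrmse(cand.generator, val, cand.config))
        else:
            ms, me = cand
            scores.append(0.5 * (
                _validation_nrmse(ms.generator, validation_sigma, ms.config)
                + _validation_nrmse(me.generator,
                                    validation_epsr or validation_sigma,
                                    me.config)))
    best = int(np.argmin(scores))
    return candidates[best], scores


def predict(model: TrainedModel, acq: Acquisition) -> EpsMaps:
    """Reconstruct a map from one acquisition with a trained generator.

    The acquisition's auxiliary channel must match the channel the model
    was trained with; air is forced to (sigma = 0, epsr = 1).
    """
    if acq.aux_kind != model.config.aux:
        raise ValueError(
            f"model expects aux channel {model.config.aux!r}, "
            f"acquisition carries {acq.aux_kind!r}")
    channels = normalize_channels(acq)
    out = unscale_target(model.predict_channels(channels), model.config)
    mask = acq.mask
    if model.config.target == "sigma":
        sigma = np.where(mask, out, 0.0)
        epsr = np.where(mask, 1.0, 1.0)
    else:
        epsr = np.where(mask, out, 1.0)
        sigma = np.where(mask, 0.0, 0.0)
    return EpsMaps(sigma_map=sigma, epsr_map=epsr,
                   method=model.config.method_name, valid_mask=mask.copy())
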