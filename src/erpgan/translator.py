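"""1-D conditional GAN translating ERPs between task conditions.

The generator is a 1-D U-Net: eight kernel-2 stride-2 convolutions halving a
256-sample signal down to a length-1 bottleneck, mirrored by eight
transposed convolutions doubling back up, with skip connections between
every encoder layer and its mirrored decoder layer. The channel widths
follow C'64-C128-C256-C512x5 down and CD512x4-C256-C128-C64-final up
(C' = no batch-norm, CD = 50% dropout), the final layer mapping to one
channel through a tanh. The discriminator is a 1-D PatchGAN: four stride-2
blocks C'64-C128-C256-C512 followed by a one-to-one convolution and a
sigmoid, scoring 16 temporal patches of a 256-sample channel-concatenated
(input, candidate) pair.

Training minimizes, over generator parameters, and maximizes, over
discriminator parameters,

    L = E[log D(x, y)] + E[log(1 - D(x, G(x)))] + lambda * E[|y - G(x)|]

with batch size 1, 15 epochs, lambda = 100, Adam (lr 2e-4, beta1 0.5), one
independent model per EEG channel, and subject-level K-fold cross-validation
so every reported generated signal comes from a test fold.

``base_filters`` scales all channel widths together; the published width is
64, and narrower banks are used for desk-scale experiments (the patch/
bottleneck arithmetic is width-independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import GO, NOGO, ERPDataset
from .nn import (
    Adam,
    BatchNorm,
    ConvDown,
    ConvOne,
    ConvUp,
    Dropout,
    LeakyReLU,
    Param,
    ReLU,
    Sequential,
    Sigmoid,
    Tanh,
)

DIRECTIONS = {"go2nogo": (GO, NOGO), "nogo2go": (NOGO, GO)}
SCORE_EPS = 1e-7


@dataclass(frozen=True)
class GeneratorSpec:
    input_length: int = 256
    base_filters: int = 64
    depth: int = 8
    kernel: int = 2
    stride: int = 2
    dropout: float = 0.5
    leaky_slope: float = 0.2
    batchnorm: bool = True

    def __post_init__(self):
        if self.input_length % 2**self.depth:
            raise ValueError(
                f"input_length {self.input_length} not divisible by 2^{self.depth}"
            )

    @property
    def encoder_channels(self) -> list[int]:
        bf = self.base_filters
        return [min(bf * 2**i, 8 * bf) for i in range(self.depth)]

    @property
    def bottleneck_length(self) -> int:
        return self.input_length // 2**self.depth


@dataclass(frozen=True)
class DiscriminatorSpec:
    input_length: int = 256
    base_filters: int = 64
    n_layers: int = 4
    leaky_slope: float = 0.2

    def __post_init__(self):
        if self.input_length % 2**self.n_layers:
            raise ValueError(
                f"input_length {self.input_length} not divisible by 2^{self.n_layers}"
            )

    @property
    def n_patches(self) -> int:
        return self.input_length // 2**self.n_layers


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 1  # the translation operates on one subject pair at a time
    epochs: int = 15
    lambda_l1: float = 100.0
    k_folds: int = 10
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    seed: int = 0
    base_filters: int = 64
    normalization: str = "minmax"

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")
        if self.batch_size != 1:
            raise ValueError("only batch size 1 is supported")


class Generator:
    """Bank of per-channel U-Net generators with shared architecture."""

    def __init__(self, spec: GeneratorSpec, seed: int, bank: int = 1, init_sd: float = 0.02,
                 dtype=np.float32):
        self.dtype = dtype
        self.spec = spec
        self.bank = bank
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 11]))
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 12])
        )
        ch = spec.encoder_channels
        self.enc: list[Sequential] = []
        c_prev = 1
        for i, c in enumerate(ch):
            layers: list = [ConvDown(bank, c_prev, c, rng, init_sd, dtype)]
            if spec.batchnorm and i > 0:
                layers.append(BatchNorm(bank, c, rng, dtype=dtype))
            layers.append(LeakyReLU(spec.leaky_slope))
            self.enc.append(Sequential(layers))
            c_prev = c
        # decoder: inputs concatenate the previous decoder output with the
        # mirrored encoder output
        self.dec: list[Sequential] = []
        dec_out = [ch[-1]] * 4 + [ch[2], ch[1], ch[0]]
        self.skip_channels = []
        c_prev = ch[-1]
        for j, c in enumerate(dec_out):
            layers = [ConvUp(bank, c_prev, c, rng, init_sd, dtype)]
            if spec.batchnorm:
                layers.append(BatchNorm(bank, c, rng, dtype=dtype))
            if j < 4 and spec.dropout > 0:
                layers.append(Dropout(spec.dropout, self.dropout_rng))
            layers.append(ReLU())
            self.dec.append(Sequential(layers))
            skip_c = ch[spec.depth - 2 - j]
            self.skip_channels.append(skip_c)
            c_prev = c + skip_c
        self.final = Sequential([ConvUp(bank, c_prev, 1, rng, init_sd, dtype), Tanh()])

    def params(self) -> list[Param]:
        out = []
        for block in self.enc + self.dec + [self.final]:
            out.extend(block.params())
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[-1] != self.spec.input_length:
            raise ValueError(f"expected length {self.spec.input_length}, got {x.shape[-1]}")
        skips = []
        h = np.ascontiguousarray(x, dtype=self.dtype)
        for block in self.enc:
            h = block.forward(h, train)
            skips.append(h)
        self._skip_count = len(skips)
        h = skips[-1]
        for j, block in enumerate(self.dec):
            h = block.forward(h, train)
            h = np.concatenate([h, skips[self.spec.depth - 2 - j]], axis=1)
        return self.final.forward(h, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        skip_grads = [None] * self.spec.depth
        d = self.final.backward(dy)
        for j in reversed(range(len(self.dec))):
            c_main = d.shape[1] - self.skip_channels[j]
            d_main, d_skip = d[:, :c_main], d[:, c_main:]
            idx = self.spec.depth - 2 - j
            skip_grads[idx] = d_skip if skip_grads[idx] is None else skip_grads[idx] + d_skip
            d = self.dec[j].backward(d_main)
        # gradient reaching the bottleneck output flows into the last encoder block
        skip_grads[-1] = d
        d = skip_grads[-1]
        for i in reversed(range(self.spec.depth)):
            if i < self.spec.depth - 1 and skip_grads[i] is not None:
                d = d + skip_grads[i]
            d = self.enc[i].backward(d)
        return d


class Discriminator:
    """Bank of 1-D PatchGAN discriminators on (x, y) channel pairs."""

    def __init__(self, spec: DiscriminatorSpec, seed: int, bank: int = 1, init_sd: float = 0.02,
                 dtype=np.float32):
        self.dtype = dtype
        self.spec = spec
        self.bank = bank
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 21]))
        bf = spec.base_filters
        ch = [min(bf * 2**i, 8 * bf) for i in range(spec.n_layers)]
        layers: list = []
        c_prev = 2
        for i, c in enumerate(ch):
            layers.append(ConvDown(bank, c_prev, c, rng, init_sd, dtype))
            if i > 0:
                layers.append(BatchNorm(bank, c, rng, dtype=dtype))
            layers.append(LeakyReLU(spec.leaky_slope))
            c_prev = c
        layers.append(ConvOne(bank, c_prev, 1, rng, init_sd, dtype))
        layers.append(Sigmoid())
        self.net = Sequential(layers)

    def params(self) -> list[Param]:
        return self.net.params()

    def forward(self, x: np.ndarray, y: np.ndarray, train: bool) -> np.ndarray:
        """Patch scores in (0, 1), shape (bank, 1, n_patches)."""
        pair = np.concatenate([x, y], axis=1).astype(self.dtype, copy=False)
        return self.net.forward(pair, train)

    def backward(self, dscores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = self.net.backward(dscores)
        return d[:, :1], d[:, 1:]


def build_generator(spec: GeneratorSpec = GeneratorSpec(), seed: int = 0, bank: int = 1) -> Generator:
    return Generator(spec, seed, bank)


def build_discriminator(spec: DiscriminatorSpec = DiscriminatorSpec(), seed: int = 0,
                        bank: int = 1) -> Discriminator:
    return Discriminator(spec, seed, bank)


# ---------------------------------------------------------------------------
# loss


def cgan_loss(d_real: np.ndarray, d_fake: np.ndarray, y: np.ndarray, g_x: np.ndarray,
              lambda_l1: float) -> tuple[float, float, float]:
    """(total, adversarial part, lambda-scaled L1 part) of the cGAN objective.

    Expectations are realized as means over patches and samples. Scores at
    exactly 0 or 1 are clamped at 1e-7 before the logarithms.
    """
    if y.shape != g_x.shape:
        raise ValueError("y and G(x) must have the same shape")
    d_real = np.clip(d_real, SCORE_EPS, 1.0 - SCORE_EPS)
    d_fake = np.clip(d_fake, SCORE_EPS, 1.0 - SCORE_EPS)
    adv = float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))
    l1 = float(lambda_l1 * np.mean(np.abs(y - g_x)))
    return adv + l1, adv, l1


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormalizationParams:
    """Per-channel affine map between µV-space and [-1, 1].

    Fitted as a min-max over the training split (both conditions jointly,
    so the between-condition amplitude effect survives normalization).
    Values outside the training range map outside [-1, 1]; nothing is
    clipped.
    """

    lo: np.ndarray  # (n_ch,)
    hi: np.ndarray

    def normalize(self, data: np.ndarray) -> np.ndarray:
        span = (self.hi - self.lo)[:, None]
        return 2.0 * (data - self.lo[:, None]) / span - 1.0

    def denormalize(self, data: np.ndarray) -> np.ndarray:
        span = (self.hi - self.lo)[:, None]
        return (data + 1.0) / 2.0 * span + self.lo[:, None]


def fit_normalizer(dataset: ERPDataset, subject_indices=None,
                   conditions=None) -> NormalizationParams:
    """Per-channel min-max over the given (training) subjects."""
    if subject_indices is None:
        subject_indices = np.arange(dataset.n_subjects)
    conditions = list(conditions or dataset.conditions)
    stacked = np.concatenate(
        [dataset.data[c][subject_indices] for c in conditions], axis=0
    )  # (n, ch, t)
    if stacked.shape[0] == 0:
        raise ValueError("training split is empty")
    lo = stacked.min(axis=(0, 2))
    hi = stacked.max(axis=(0, 2))
    flat = np.flatnonzero(hi - lo == 0)
    if flat.size:
        names = [dataset.layout.names[i] for i in flat]
        raise ValueError(f"zero-variance channel(s): {names}")
    return NormalizationParams(lo, hi)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class FoldAssignment:
    folds: list[np.ndarray]  # test-subject indices per fold
    fold_of: np.ndarray  # (n_subjects,) fold index per subject

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def kfold_plan(subject_ids, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Balanced random partition of subjects into K test folds."""
    n = len(subject_ids)
    if n < k:
        raise ValueError(f"{n} subjects cannot fill {k} folds")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 31]))
    order = rng.permutation(n)
    folds = [np.sort(f) for f in np.array_split(order, k)]
    fold_of = np.empty(n, dtype=int)
    for i, f in enumerate(folds):
        fold_of[f] = i
    return FoldAssignment(folds, fold_of)


# ---------------------------------------------------------------------------
# training


def _score_grad_real(s):
    s = np.clip(s, SCORE_EPS, 1.0 - SCORE_EPS)
    return -1.0 / (s * s.shape[-1])


def _score_grad_fake_d(s):
    s = np.clip(s, SCORE_EPS, 1.0 - SCORE_EPS)
    return 1.0 / ((1.0 - s) * s.shape[-1])


def _score_grad_fake_g(s):
    # non-saturating heuristic: G maximizes log D(x, G(x))
    s = np.clip(s, SCORE_EPS, 1.0 - SCORE_EPS)
    return -1.0 / (s * s.shape[-1])


def train_fold(
    x_train: np.ndarray,
    y_train: np.ndarray,
    config: TrainConfig,
    seed: int,
    gen_spec: GeneratorSpec | None = None,
    disc_spec: DiscriminatorSpec | None = None,
) -> tuple[Generator, Discriminator, dict]:
    """Train one bank of per-channel models on normalized training pairs.

    ``x_train``/``y_train``: (n_subjects, n_channels, n_times) in [-1, 1].
    Alternates one discriminator and one generator update per subject, batch
    size 1, shuffling subject order each epoch. Returns the trained networks
    and per-epoch mean loss parts (total / adversarial / L1, per the cGAN
    objective).
    """
    n_subj, bank, length = x_train.shape
    gen_spec = gen_spec or GeneratorSpec(input_length=length, base_filters=config.base_filters)
    disc_spec = disc_spec or DiscriminatorSpec(input_length=length, base_filters=config.base_filters)
    gen = Generator(gen_spec, seed, bank)
    disc = Discriminator(disc_spec, seed + 1, bank)
    opt_g = Adam(gen.params(), config.learning_rate, config.beta1, config.beta2)
    opt_d = Adam(disc.params(), config.learning_rate, config.beta1, config.beta2)
    order_rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 41]))
    curves = {"total": [], "adversarial": [], "l1": []}
    for _ in range(config.epochs):
        totals, advs, l1s = [], [], []
        for s in order_rng.permutation(n_subj):
            x = x_train[s][:, None, :]  # (bank, 1, L)
            y = y_train[s][:, None, :]
            g = gen.forward(x, train=True)

            # discriminator ascends E[log D(x,y)] + E[log(1 - D(x,G(x)))]
            opt_d.zero_grad()
            s_real = disc.forward(x, y, train=True)
            disc.backward(_score_grad_real(s_real))
            s_fake = disc.forward(x, g, train=True)
            disc.backward(_score_grad_fake_d(s_fake))
            opt_d.step()

            # generator descends -E[log D(x,G(x))] + lambda E[|y - G(x)|]
            opt_g.zero_grad()
            opt_d.zero_grad()
            s_fake = disc.forward(x, g, train=True)
            _, dg_adv = disc.backward(_score_grad_fake_g(s_fake))
            dg = dg_adv.astype(gen.dtype) + gen.dtype(config.lambda_l1) * np.sign(g - y, dtype=gen.dtype) / gen.dtype(g[0].size)
            if not np.isfinite(dg).all():
                raise FloatingPointError("non-finite generator gradient")
            gen.backward(dg)
            opt_g.step()
            opt_d.zero_grad()

            total, adv, l1 = cgan_loss(s_real, s_fake, y, g, config.lambda_l1)
            totals.append(total)
            advs.append(adv)
            l1s.append(l1)
        curves["total"].append(float(np.mean(totals)))
        curves["adversarial"].append(float(np.mean(advs)))
        curves["l1"].append(float(np.mean(l1s)))
    return gen, disc, curves


def generate(gen: Generator, x: np.ndarray) -> np.ndarray:
    """Deterministic inference for (n_subjects, n_channels, n_times) input."""
    out = np.empty_like(x)
    for s in range(x.shape[0]):
        out[s] = gen.forward(x[s][:, None, :], train=False)[:, 0, :]
    return out


# ---------------------------------------------------------------------------
# cohort-level translation


@dataclass
class TranslationReport:
    """Generated cohort (test folds only) plus fidelity metrics."""

    direction: str
    source: str
    target: str
    generated: np.ndarray  # (n_subjects, n_channels, n_times), µV-space
    subjects: list[str]
    fold_of: np.ndarray
    folds: list[np.ndarray]
    curves: list[dict]
    per_channel_r: np.ndarray
    per_channel_l1: np.ndarray  # µV-space, per-subject mean
    mean_r: float = 0.0
    test_l1_normalized: float = 0.0  # per-subject L1, normalized units
    cohort_l1_normalized: float = 0.0  # grand-average L1, normalized units
    meta: dict = field(default_factory=dict)


def translate_cohort(dataset: ERPDataset, direction: str,
                     config: TrainConfig = TrainConfig()) -> TranslationReport:
    """K-fold conditional-GAN translation of a paired cohort.

    Per fold: fit the normalizer on the training subjects only, train one
    model per channel, generate the held-out subjects, denormalize.
    Every subject is generated exactly once, from the fold where it was
    held out.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}")
    src, tgt = DIRECTIONS[direction]
    for cond in (src, tgt):
        if cond not in dataset.data:
            raise ValueError(f"dataset lacks condition {cond!r}")
    plan = kfold_plan(dataset.subjects, config.k_folds, config.seed)
    generated = np.full_like(dataset.data[tgt], np.nan)
    gen_norm = np.full_like(generated, np.nan)
    real_norm = np.full_like(generated, np.nan)
    curves = []
    for fold, test_idx in enumerate(plan.folds):
        train_idx = plan.train_indices(fold)
        norm = fit_normalizer(dataset, train_idx, conditions=[src, tgt])
        x_train = np.stack([norm.normalize(dataset.data[src][i]) for i in train_idx])
        y_train = np.stack([norm.normalize(dataset.data[tgt][i]) for i in train_idx])
        fold_seed = (int(config.seed) * 1000 + fold) & 0x7FFFFFFF
        gen, _, fold_curves = train_fold(x_train, y_train, config, fold_seed)
        curves.append(fold_curves)
        x_test = np.stack([norm.normalize(dataset.data[src][i]) for i in test_idx])
        g = generate(gen, x_test)
        for j, i in enumerate(test_idx):
            gen_norm[i] = g[j]
            real_norm[i] = norm.normalize(dataset.data[tgt][i])
            generated[i] = norm.denormalize(g[j])
    real = dataset.data[tgt]
    per_channel_r = _per_channel_pearson(generated, real)
    per_channel_l1 = np.mean(np.abs(generated - real), axis=(0, 2))
    report = TranslationReport(
        direction=direction,
        source=src,
        target=tgt,
        generated=generated,
        subjects=list(dataset.subjects),
        fold_of=plan.fold_of,
        folds=plan.folds,
        curves=curves,
        per_channel_r=per_channel_r,
        per_channel_l1=per_channel_l1,
        mean_r=float(per_channel_r.mean()),
        test_l1_normalized=float(np.mean(np.abs(gen_norm - real_norm))),
        cohort_l1_normalized=float(
            np.mean(np.abs(gen_norm.mean(axis=0) - real_norm.mean(axis=0)))
        ),
        meta={"config": config, "units": dataset.units},
    )
    return report


def _per_channel_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Mean over subjects of the per-(subject, channel) correlation in time."""
    am = a - a.mean(axis=-1, keepdims=True)
    bm = b - b.mean(axis=-1, keepdims=True)
    num = (am * bm).sum(axis=-1)
    den = np.sqrt((am**2).sum(axis=-1) * (bm**2).sum(axis=-1))
    r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return r.mean(axis=0)


def generated_dataset(dataset: ERPDataset, report: TranslationReport) -> ERPDataset:
    """Wrap the generated signals as a one-condition ERPDataset."""
    return ERPDataset(
        report.subjects,
        {report.target: report.generated},
        dataset.fs,
        dataset.t0_ms,
        dataset.layout,
        dataset.units,
        meta={"generated_from": report.source, "direction": report.direction},
    )
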