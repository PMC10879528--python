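"""Conditional GAN backend (desk scale).

A single generator/discriminator pair over all cell types; the condition is
the one-hot cell type appended to the latent vector (generator) and to the
expression vector (discriminator).  Training data are ``log1p`` + per-gene
min-max scaled to [-1, 1]; the generator output activation is tanh.  The
loss is the standard non-saturating GAN objective, optimized with Adam.

The generator carries a condition-to-output skip connection initialized at
the per-type mean profile (in transform space): early samples are cell-type
prototypes and adversarial training only has to learn the variation around
them, which keeps short training runs on-distribution.
"""

from __future__ import annotations

from typing import List

import numpy as np

from ..datamodel import DataError, LabeledCounts
from .. import nn
from .base import GeneratorConfig, GeneratorModel, MinMaxLog1p, _check_fit_input


class _CondGenerator:
    """tanh(body(z ++ c) + P c): MLP body plus a conditional output skip."""

    def __init__(self, zdim: int, k: int, n_genes: int, hidden_dims,
                 prototypes: np.ndarray, rng: np.random.Generator):
        self.zdim, self.k = zdim, k
        self.body = nn.mlp([zdim + k, *hidden_dims, n_genes], rng, hidden="relu")
        last = [l for l in self.body.layers if isinstance(l, nn.Dense)][-1]
        last.w *= 0.1  # start close to the prototypes
        self.skip = nn.Dense(k, n_genes, rng)
        self.skip.w[...] = prototypes
        self.skip.b[...] = 0.0
        self.out = nn.Tanh()

    @property
    def params(self):
        return self.body.params + self.skip.params

    @property
    def grads(self):
        return self.body.grads + self.skip.grads

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0.0

    def forward(self, z: np.ndarray, cond: np.ndarray) -> np.ndarray:
        self._cond = cond
        h = self.body.forward(np.concatenate([z, cond], axis=1))
        return self.out.forward(h + self.skip.forward(cond))

    def backward(self, grad: np.ndarray) -> None:
        grad = self.out.backward(grad)
        self.skip.backward(grad)
        self.body.backward(grad)


class GANModel(GeneratorModel):
    backend = "gan"

    def __init__(self, gene_ids, cell_types, config, loss_trace,
                 generator: _CondGenerator, transform: MinMaxLog1p):
        super().__init__(gene_ids, cell_types, config, loss_trace)
        self._g = generator
        self._transform = transform
        self._type_idx = {t: i for i, t in enumerate(cell_types)}

    @classmethod
    def fit(cls, train: LabeledCounts, config: GeneratorConfig) -> "GANModel":
        _check_fit_input(train)
        types = train.cell_types
        k = len(types)
        transform = MinMaxLog1p.fit(train.counts)
        x = transform.transform(train.counts)  # cells x genes
        type_idx = {t: i for i, t in enumerate(types)}
        cond = np.zeros((train.n_cells, k))
        for j, c in enumerate(train.cell_ids):
            cond[j, type_idx[train.cell_type[c]]] = 1.0

        rng = np.random.default_rng(config.seed)
        n_genes = train.n_genes
        zdim = config.latent_dim
        prototypes = np.stack(
            [
                np.arctanh(np.clip(x[cond[:, i] == 1].mean(axis=0), -0.99, 0.99))
                for i in range(k)
            ]
        )
        g = _CondGenerator(zdim, k, n_genes, config.hidden_dims, prototypes, rng)
        d = nn.mlp([n_genes + k, *config.hidden_dims, 1], rng, hidden="lrelu")
        opt_g = nn.Adam(g.params, g.grads, lr=config.learning_rate)
        opt_d = nn.Adam(d.params, d.grads, lr=config.learning_rate)
        # exponential moving average of generator weights; sampling from the
        # averaged generator damps step-to-step oscillation of the samples
        ema_decay = 0.99
        ema = [p.copy() for p in g.params]

        n = train.n_cells
        bs = min(config.batch_size, n)
        trace: List[float] = []
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            d_losses, g_losses = [], []
            for start in range(0, n, bs):
                batch = order[start:start + bs]
                xb, cb = x[batch], cond[batch]
                m = len(batch)
                z = rng.standard_normal((m, zdim))

                # discriminator step: real -> 1, fake -> 0
                fake = g.forward(z, cb)
                d.zero_grad()
                logits_r = d.forward(np.concatenate([xb, cb], axis=1))
                loss_r, dr = nn.bce_with_logits(logits_r, 1.0)
                d.backward(dr)
                logits_f = d.forward(np.concatenate([fake, cb], axis=1))
                loss_f, df = nn.bce_with_logits(logits_f, 0.0)
                d.backward(df)
                opt_d.step()

                # generator step: non-saturating, push fakes toward 1
                z = rng.standard_normal((m, zdim))
                g.zero_grad()
                d.zero_grad()
                fake = g.forward(z, cb)
                logits = d.forward(np.concatenate([fake, cb], axis=1))
                loss_g, dl = nn.bce_with_logits(logits, 1.0)
                g.backward(d.backward(dl)[:, :n_genes])
                opt_g.step()
                for e, p in zip(ema, g.params):
                    e *= ema_decay
                    e += (1.0 - ema_decay) * p

                d_losses.append(loss_r + loss_f)
                g_losses.append(loss_g)
            epoch_loss = float(np.mean(d_losses) + np.mean(g_losses))
            if not np.isfinite(epoch_loss):
                raise DataError(f"non-finite GAN loss at epoch {epoch}")
            trace.append(epoch_loss)
        for p, e in zip(g.params, ema):
            p[...] = e
        model = cls(train.gene_ids, types, config, trace, g, transform)
        model._fit_calibration(x, cond, rng)
        return model

    def _fit_calibration(self, x: np.ndarray, cond: np.ndarray,
                         rng: np.random.Generator, n_cal: int = 256) -> None:
        """Per-type, per-gene multiplicative mean correction in count space.

        The log1p/tanh pipeline makes short training runs land near the
        geometric rather than the arithmetic per-gene mean; rescaling sample
        means onto the training means (computed here once, from training
        data only) removes that bias.  Factors are clipped to [0.05, 20].
        """
        self._calibration = {}
        for t in self.cell_types:
            i = self._type_idx[t]
            train_mean = self._transform.inverse(x[cond[:, i] == 1]).mean(axis=0)
            zc = rng.standard_normal((n_cal, self.config.latent_dim))
            cc = np.zeros((n_cal, len(self.cell_types)))
            cc[:, i] = 1.0
            gen_mean = self._transform.inverse(self._g.forward(zc, cc)).mean(axis=0)
            factor = train_mean / np.maximum(gen_mean, 1e-9)
            factor[train_mean == 0] = 1.0
            self._calibration[t] = np.clip(factor, 0.05, 20.0)

    def _sample_type(self, cell_type: str, n: int, rng: np.random.Generator) -> np.ndarray:
        if cell_type not in self._type_idx:
            raise DataError(f"unknown cell type {cell_type!r}")
        cond = np.zeros((n, len(self.cell_types)))
        cond[:, self._type_idx[cell_type]] = 1.0
        z = rng.standard_normal((n, self.config.latent_dim))
        out = self._transform.inverse(self._g.forward(z, cond))
        return out * self._calibration[cell_type]
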