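"""Conditional VAE backend (desk scale).

Encoder and decoder are small dense nets on the shared ``log1p`` + min-max
transform; the latent is diagonal Gaussian and the objective is the ELBO
with a unit-variance Gaussian likelihood (mean squared reconstruction plus
the analytic KL term).  The cell-type condition is one-hot, appended to both
the encoder input and the latent vector.
"""

from __future__ import annotations

from typing import List

import numpy as np

from ..datamodel import DataError, LabeledCounts
from .. import nn
from .base import GeneratorConfig, GeneratorModel, MinMaxLog1p, _check_fit_input


class VAEModel(GeneratorModel):
    backend = "vae"

    def __init__(self, gene_ids, cell_types, config, loss_trace,
                 decoder: nn.Sequential, transform: MinMaxLog1p):
        super().__init__(gene_ids, cell_types, config, loss_trace)
        self._dec = decoder
        self._transform = transform

    @classmethod
    def fit(cls, train: LabeledCounts, config: GeneratorConfig) -> "VAEModel":
        _check_fit_input(train)
        types = train.cell_types
        k = len(types)
        transform = MinMaxLog1p.fit(train.counts)
        x = transform.transform(train.counts)
        type_idx = {t: i for i, t in enumerate(types)}
        cond = np.zeros((train.n_cells, k))
        for j, c in enumerate(train.cell_ids):
            cond[j, type_idx[train.cell_type[c]]] = 1.0

        rng = np.random.default_rng(config.seed)
        n_genes, zdim = train.n_genes, config.latent_dim
        enc = nn.mlp([n_genes + k, *config.hidden_dims, 2 * zdim], rng, hidden="relu")
        dec = nn.mlp([zdim + k, *config.hidden_dims, n_genes], rng,
                     hidden="relu", out="tanh")
        opt = nn.Adam(enc.params + dec.params, enc.grads + dec.grads,
                      lr=config.learning_rate, beta1=0.9)

        n = train.n_cells
        bs = min(config.batch_size, n)
        trace: List[float] = []
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                batch = order[start:start + bs]
                xb, cb = x[batch], cond[batch]
                m = len(batch)

                enc.zero_grad()
                dec.zero_grad()
                h = enc.forward(np.concatenate([xb, cb], axis=1))
                mu, logvar = h[:, :zdim], np.clip(h[:, zdim:], -10.0, 10.0)
                std = np.exp(0.5 * logvar)
                eps = rng.standard_normal((m, zdim))
                z = mu + std * eps
                recon = dec.forward(np.concatenate([z, cb], axis=1))

                # ELBO pieces, averaged over the batch
                rec_loss = 0.5 * np.sum((recon - xb) ** 2) / m
                kl = -0.5 * np.sum(1 + logvar - mu ** 2 - np.exp(logvar)) / m
                loss = float(rec_loss + kl)
                losses.append(loss)

                drecon = (recon - xb) / m
                dz = dec.backward(drecon)[:, :zdim]
                dmu = dz + mu / m
                dlogvar = dz * eps * 0.5 * std - 0.5 * (1 - np.exp(logvar)) / m
                enc.backward(np.concatenate([dmu, dlogvar], axis=1))
                opt.step()
            epoch_loss = float(np.mean(losses))
            if not np.isfinite(epoch_loss):
                raise DataError(f"non-finite VAE loss at epoch {epoch}")
            trace.append(epoch_loss)
        model = cls(train.gene_ids, types, config, trace, dec, transform)
        model._type_idx = type_idx
        return model

    def _sample_type(self, cell_type: str, n: int, rng: np.random.Generator) -> np.ndarray:
        if cell_type not in self._type_idx:
            raise DataError(f"unknown cell type {cell_type!r}")
        k = len(self.cell_types)
        cond = np.zeros((n, k))
        cond[:, self._type_idx[cell_type]] = 1.0
        z = rng.standard_normal((n, self.config.latent_dim))
        t = self._dec.forward(np.concatenate([z, cond], axis=1))
        return self._transform.inverse(t)
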