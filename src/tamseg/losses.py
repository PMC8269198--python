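"""Loss assemblies for the three segmentation strategies.

* ``vanilla`` — plain pixel softmax cross-entropy.
* ``weighted`` — the same cross-entropy, multiplied per pixel by a gap/edge
  weight map (see :mod:`tamseg.weight_maps`).
* ``instance`` — cross-entropy plus a discriminative pull/push embedding
  loss: pixels of one instance are pulled within ``delta_v`` of their
  centroid, centroids of different instances are pushed at least
  ``2·delta_d`` apart, and a small regularizer keeps centroids near the
  origin.  Instances are taken from the ground truth during training;
  clustering happens only at prediction time.

For ``K`` instances with pixel embeddings ``e`` and centroids ``μ_k``::

    L = α · mean_k mean_{e∈k} max(0, ‖e − μ_k‖ − δ_v)²
      + β · mean_{j<k}        max(0, 2δ_d − ‖μ_j − μ_k‖)²
      + γ · mean_k ‖μ_k‖
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, stack, weighted_softmax_ce
from .masks import as_label_mask
from .models import NetworkOutput
from .weight_maps import WeightMap

__all__ = ["DiscriminativeLossParams", "discriminative_loss", "assemble_loss",
           "STRATEGIES"]

STRATEGIES = ("vanilla", "weighted", "instance")

_EPS = 1e-12


@dataclass
class DiscriminativeLossParams:
    """Margins and term weights of the pull/push embedding loss.

    ``delta_d > 2·delta_v`` is recommended so clusters tighter than the pull
    margin are still separable by the push margin.
    """

    delta_v: float = 0.5
    delta_d: float = 1.5
    alpha: float = 1.0  # within-instance variance (pull)
    beta: float = 1.0   # between-centroid distance (push)
    gamma: float = 0.001  # centroid norm regularizer

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("term weights must be >= 0")


def discriminative_loss(embeddings, truth,
                        params: DiscriminativeLossParams | None = None) -> Tensor:
    """Pull/push loss of one embedding field against one label mask.

    ``embeddings`` is (E, H, W) (Tensor or array), ``truth`` an (H, W) label
    mask with at least one instance.  Differentiable when given a Tensor.
    """
    params = params or DiscriminativeLossParams()
    emb = embeddings if isinstance(embeddings, Tensor) else Tensor(embeddings)
    labels = as_label_mask(truth)
    e, h, w = emb.shape
    if labels.shape != (h, w):
        raise ValueError(f"labels {labels.shape} do not match embeddings {(h, w)}")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("discriminative loss needs at least one instance")

    flat = emb.reshape(e, h * w)
    lab_flat = labels.ravel()
    mus = []
    var_terms = []
    for k in ids:
        idx = np.nonzero(lab_flat == k)[0]
        pix = flat[:, idx]                      # (E, n_k)
        mu = pix.mean(axis=1)                   # (E,)
        mus.append(mu)
        d = pix - mu.reshape(e, 1)
        norms = ((d * d).sum(axis=0) + _EPS).sqrt()
        hinge = (norms - params.delta_v).relu()
        var_terms.append((hinge * hinge).mean())

    var_term = stack(var_terms).mean()

    if len(mus) > 1:
        pair_terms = []
        for j in range(len(mus)):
            for k in range(j + 1, len(mus)):
                diff = mus[j] - mus[k]
                dist = ((diff * diff).sum() + _EPS).sqrt()
                hinge = (2.0 * params.delta_d - dist).relu()
                pair_terms.append(hinge * hinge)
        dist_term = stack(pair_terms).mean()
    else:
        dist_term = Tensor(0.0)

    reg_term = stack([((m * m).sum() + _EPS).sqrt() for m in mus]).mean()

    return (params.alpha * var_term + params.beta * dist_term
            + params.gamma * reg_term)


def _weights_array(weight_maps, shape) -> np.ndarray:
    out = np.empty(shape, dtype=np.float32)
    for i, wm in enumerate(weight_maps):
        out[i] = wm.weights if isinstance(wm, WeightMap) else np.asarray(wm)
    return out


def assemble_loss(
    strategy: str,
    network_output: NetworkOutput,
    truth,
    weight_maps=None,
    disc_params: DiscriminativeLossParams | None = None,
    disc_weight: float = 1.0,
) -> Tensor:
    """Total training loss for a batch under the given strategy.

    ``truth`` is a (N, H, W) batch of label masks.  ``weighted`` requires one
    weight map per sample; ``instance`` requires embeddings in the network
    output.  The discriminative term averages over the batch samples that
    contain at least one instance.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    truth = np.asarray(truth)
    if truth.ndim == 2:
        truth = truth[None]
    target = (truth > 0).astype(np.int64)
    scores = network_output.class_scores
    n = scores.shape[0]

    if strategy == "weighted":
        if weight_maps is None:
            raise ValueError("weighted strategy requires weight_maps")
        wt = _weights_array(weight_maps, target.shape)
        ce = weighted_softmax_ce(scores, target, wt)
    else:
        ce = weighted_softmax_ce(scores, target)

    if strategy != "instance":
        return ce

    if network_output.embeddings is None:
        raise ValueError("instance strategy requires embeddings in the "
                         "network output (embedding decoder missing)")
    disc_terms = []
    for i in range(n):
        if (truth[i] > 0).any():
            disc_terms.append(
                discriminative_loss(network_output.embeddings[i], truth[i],
                                    disc_params)
            )
    if disc_terms:
        return ce + disc_weight * stack(disc_terms).mean()
    return ce
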