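"""Multi-atlas segmentation: label propagation and probabilistic STAPLE.

STAPLE (Simultaneous Truth and Performance Level Estimation) treats the true
voxel label as a hidden categorical variable and each input segmentation as a
rater characterized by a row-stochastic confusion matrix theta_j[l, m] =
P(rater j observes m | truth is l). EM alternates a posterior over the true
label per voxel (E-step) with maximum-likelihood confusion updates (M-step);
the observed-data log-likelihood is non-decreasing at every iteration. The
multi-category formulation is used: a full L x L confusion matrix per rater.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fields import Diffeo, IncompatibleGridError, InvalidInputError, LabelMap3D
from .diffeo import exp_svf, warp
from .phantom import Subject
from .registration import RegistrationConfig, register

logger = logging.getLogger(__name__)

__all__ = ["ConfusionMatrix", "StapleResult", "NoAtlasError",
           "propagate", "staple_fuse", "mas_segment", "atlas_label_bank"]

#: gestational-age window for atlas selection, weeks
AGE_WINDOW_WEEKS = 1.0


class NoAtlasError(ValueError):
    """No atlas lies within the age-selection window of the query."""


@dataclass
class ConfusionMatrix:
    """Per-rater performance parameters: theta[l, m] = P(observed m | true l)."""

    theta: np.ndarray
    label_ids: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.label_ids = np.asarray(self.label_ids)
        L = len(self.label_ids)
        if self.theta.shape != (L, L):
            raise InvalidInputError(f"theta must be {L}x{L}, got {self.theta.shape}")
        if np.any(self.theta < -1e-12) or not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-8):
            raise InvalidInputError("theta rows must be nonnegative and sum to 1")


@dataclass
class StapleResult:
    consensus: LabelMap3D
    confusions: list
    posterior: np.ndarray          # (voxels..., L) in label_ids order
    label_ids: np.ndarray
    log_likelihood: list = field(default_factory=list)
    n_iterations: int = 0


def propagate(atlas_labels: LabelMap3D, mapping: Diffeo) -> LabelMap3D:
    """Propagate labels through a deformation by nearest-neighbor resampling
    (background fill 0)."""
    if atlas_labels.shape != mapping.shape:
        raise IncompatibleGridError(
            f"labels {atlas_labels.shape} vs map {mapping.shape}")
    return warp(atlas_labels, mapping, mode="nearest", cval=0)


def staple_fuse(maps: list, prior: np.ndarray | str = "empirical",
                tol: float = 1e-5, max_iter: int = 200,
                init_diag: float = 0.9) -> StapleResult:
    """Fuse rater segmentations with multi-category STAPLE EM.

    Parameters
    ----------
    maps : >= 2 LabelMap3D on one grid.
    prior : per-label prior probabilities in sorted-label order (kept fixed),
        or 'empirical' / 'uniform', which only initialize the prior: the
        class prevalences are then re-estimated from the posterior at every
        M-step. Pooled observed frequencies overestimate the prevalence of
        rare classes whenever raters are imperfect, so treating them as a
        fixed prior biases the confusion estimates; joint EM over prior and
        confusions removes that bias.
    tol : EM stops when max |Delta theta| < tol.
    init_diag : initial diagonal confusion value; off-diagonal mass uniform.

    Returns the consensus (argmax posterior, ties to the smallest label id),
    the estimated confusion matrices, the voxelwise posterior, and the
    log-likelihood trace (non-decreasing).
    """
    if len(maps) < 2:
        raise InvalidInputError("STAPLE needs at least 2 input segmentations")
    shape = maps[0].shape
    for m in maps[1:]:
        if m.shape != shape:
            raise IncompatibleGridError("all rater maps must share one grid")
    label_ids = np.unique(np.concatenate([np.unique(m.labels) for m in maps]))
    L = len(label_ids)
    R = len(maps)
    if L == 1:
        # unanimous single label: degenerate but well-defined
        consensus = maps[0].copy()
        theta = [ConfusionMatrix(np.ones((1, 1)), label_ids) for _ in range(R)]
        post = np.ones(shape + (1,))
        return StapleResult(consensus, theta, post, label_ids, [0.0], 0)

    lut = np.zeros(int(label_ids.max()) + 1, dtype=np.int64)
    lut[label_ids] = np.arange(L)
    obs = np.stack([lut[m.labels.ravel()] for m in maps], axis=1)  # (V, R)
    V = obs.shape[0]

    update_prior = isinstance(prior, str)
    if isinstance(prior, str):
        if prior == "uniform":
            pri = np.full(L, 1.0 / L)
        elif prior == "empirical":
            counts = np.bincount(obs.ravel(), minlength=L).astype(float)
            pri = counts / counts.sum()
        else:
            raise InvalidInputError(f"unknown prior {prior!r}")
    else:
        pri = np.asarray(prior, dtype=float)
        if pri.shape != (L,) or np.any(pri < 0):
            raise InvalidInputError(f"prior must be {L} nonnegative values")
        pri = pri / pri.sum()

    off = (1.0 - init_diag) / (L - 1)
    theta = np.full((R, L, L), off)
    for j in range(R):
        np.fill_diagonal(theta[j], init_diag)

    ll_trace = []
    tiny = 1e-300
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: posterior(v, l) ∝ prior(l) * prod_j theta_j[l, obs_vj]
        log_theta = np.log(np.maximum(theta, tiny))
        log_post = np.log(np.maximum(pri, tiny))[None, :].repeat(V, axis=0)
        for j in range(R):
            log_post += log_theta[j][:, obs[:, j]].T
        mx = log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post - mx)
        norm = post.sum(axis=1, keepdims=True)
        ll = float((np.log(norm) + mx).sum())
        ll_trace.append(ll)
        post /= norm

        # M-step: theta_j[l, m] = sum_v post(v, l) 1[obs_vj = m] / sum_v post(v, l)
        new_theta = np.empty_like(theta)
        col = post.sum(axis=0)  # (L,)
        for j in range(R):
            num = np.zeros((L, L))
            for m in range(L):
                sel = obs[:, j] == m
                if np.any(sel):
                    num[:, m] = post[sel].sum(axis=0)
            new_theta[j] = num / np.maximum(col, tiny)[:, None]
        delta = float(np.abs(new_theta - theta).max())
        theta = new_theta
        if update_prior:
            pri = col / V
        if delta < tol:
            break

    # final posterior under converged parameters
    log_theta = np.log(np.maximum(theta, tiny))
    log_post = np.log(np.maximum(pri, tiny))[None, :].repeat(V, axis=0)
    for j in range(R):
        log_post += log_theta[j][:, obs[:, j]].T
    mx = log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post - mx)
    norm = post.sum(axis=1, keepdims=True)
    ll_trace.append(float((np.log(norm) + mx).sum()))
    post /= norm

    consensus_idx = post.argmax(axis=1)  # argmax takes the first (smallest) on ties
    consensus = LabelMap3D(label_ids[consensus_idx].reshape(shape).astype(np.int32),
                           maps[0].spacing.copy(), maps[0].origin.copy(),
                           dict(maps[0].key) if maps[0].key else None)
    confusions = [ConfusionMatrix(theta[j], label_ids) for j in range(R)]
    return StapleResult(consensus, confusions, post.reshape(shape + (L,)),
                        label_ids, ll_trace, it)


def atlas_label_bank(atlas_result, subjects: list, label_maps: list,
                     fuse_kwargs: dict | None = None) -> list:
    """Build (AtlasTimepoint, LabelMap3D) pairs by propagating every
    supporting subject's labels into atlas space through the inverse total
    transforms and fusing them with STAPLE (single contributor: propagated
    directly)."""
    bank = []
    for tp in atlas_result.timepoints:
        props = []
        for subj, lab in zip(subjects, label_maps):
            tr = atlas_result.transforms[subj.id]
            if tp.t in tr.total:
                inv = exp_svf(-tr.total[tp.t].svf)
                props.append(propagate(lab, inv))
        if not props:
            raise NoAtlasError(f"no subject supports atlas age {tp.t}")
        fused = staple_fuse(props, **(fuse_kwargs or {})).consensus if len(props) > 1 else props[0]
        bank.append((tp, fused))
    return bank


def mas_segment(query: Subject, atlas_bank: list,
                reg_config: RegistrationConfig | None = None,
                age_window: float = AGE_WINDOW_WEEKS,
                fuse_kwargs: dict | None = None) -> LabelMap3D:
    """Multi-atlas segmentation of a query subject.

    Selects atlases within ``age_window`` weeks of the query's gestational
    age, registers each template to the query, propagates its labels through
    the estimated deformation, and fuses with STAPLE (a single selected atlas
    is propagated directly).

    ``atlas_bank`` holds (AtlasTimepoint, LabelMap3D) pairs.
    """
    reg_config = reg_config or RegistrationConfig()
    selected = [(tp, lab) for tp, lab in atlas_bank
                if abs(tp.t - query.age) <= age_window]
    if not selected:
        available = sorted(tp.t for tp, _ in atlas_bank)
        raise NoAtlasError(
            f"no atlas within +/-{age_window} weeks of query age {query.age}; "
            f"bank ages: {available}")
    propagated = []
    for tp, lab in selected:
        v = register(tp.template, query.image, reg_config)
        propagated.append(propagate(lab, exp_svf(v)))
    if len(propagated) == 1:
        return propagated[0]
    fused = staple_fuse(propagated, **(fuse_kwargs or {}))
    return fused.consensus
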