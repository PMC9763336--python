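"""Shapley-value attributions, channel importance and PCA projection.

Attributions follow the additive-explanation contract: for a model output
f and a sample x, a base value phi_0 plus per-feature Shapley values
phi_i reconstruct f(x).  Features are the (position, channel) cells of
the encoded peptide matrix; an "absent" feature is replaced by the mean
of a background sample set.

The estimator is model-agnostic permutation sampling: for each random
ordering of the features, walking from the all-background baseline to the
full sample and crediting each feature its marginal change telescopes to
f(x) - f(baseline), so additivity holds by construction for any number of
permutations; averaging permutations converges to the exact Shapley
value.  An exhaustive-enumeration variant is provided for small feature
counts and serves as the oracle in tests.

Channel importance is the mean absolute Shapley value per channel,
aggregated over positions and samples, ranked descending.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .network import TrainedModel


@dataclass
class AttributionReport:
    """Per-sample Shapley values with channel-level importance ranking."""

    phi: np.ndarray              # (N, Lmax, d)
    phi0: float                  # base value: model output on the baseline
    channel_names: list[str]
    sample_ids: list[str]
    model_outputs: np.ndarray    # (N,) f(x) for each explained sample

    @property
    def channel_importance(self) -> np.ndarray:
        """Mean |phi| per channel over samples and positions."""
        return np.abs(self.phi).mean(axis=(0, 1))

    @property
    def ranking(self) -> list[tuple[str, float]]:
        """Channels sorted by importance (descending; ties by channel index)."""
        imp = self.channel_importance
        order = np.lexsort((np.arange(len(imp)), -imp))
        return [(self.channel_names[i], float(imp[i])) for i in order]

    def additivity_errors(self) -> np.ndarray:
        """|phi0 + sum(phi) - f(x)| per sample; small by construction."""
        return np.abs(self.phi0 + self.phi.sum(axis=(1, 2)) - self.model_outputs)

    def to_long_tsv(self, path: str | Path) -> None:
        n, L, d = self.phi.shape
        rows = {
            "sample": np.repeat(self.sample_ids, L * d),
            "position": np.tile(np.repeat(np.arange(1, L + 1), d), n),
            "channel": np.tile(self.channel_names, n * L),
            "phi": self.phi.reshape(-1),
        }
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def importance_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.ranking, columns=["channel", "importance"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Core estimators on flat feature vectors
# ---------------------------------------------------------------------------

def permutation_shapley(
    f: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    baseline: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 256,
) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley values of f at x against one baseline.

    `f` maps a (B, M) batch of flat feature vectors to B outputs.
    Returns (phi (M,), phi0 = f(baseline)).
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    baseline = np.asarray(baseline, dtype=float).reshape(-1)
    M = x.shape[0]
    phi = np.zeros(M)
    phi0 = float(f(baseline[None])[0])
    for _ in range(n_perm):
        order = rng.permutation(M)
        rank = np.empty(M, dtype=int)
        rank[order] = np.arange(M)
        # row k of the coalition matrix has the first k features (in this
        # permutation's order) switched from baseline to x
        mask = rank[None, :] < np.arange(M + 1)[:, None]
        inputs = np.where(mask, x[None, :], baseline[None, :])
        outputs = np.empty(M + 1)
        for lo in range(0, M + 1, chunk):
            outputs[lo: lo + chunk] = f(inputs[lo: lo + chunk])
        phi[order] += np.diff(outputs)
    return phi / n_perm, phi0


def exact_shapley(
    f: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    baseline: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Exact Shapley values by enumerating all 2^M coalitions (M <= 20)."""
    x = np.asarray(x, dtype=float).reshape(-1)
    baseline = np.asarray(baseline, dtype=float).reshape(-1)
    M = x.shape[0]
    if M > 20:
        raise ValueError(f"exact enumeration limited to 20 features, got {M}")
    n_coal = 1 << M
    members = (np.arange(n_coal)[:, None] >> np.arange(M)[None, :]) & 1
    inputs = np.where(members.astype(bool), x[None, :], baseline[None, :])
    values = np.asarray(f(inputs), dtype=float)
    sizes = members.sum(axis=1)
    factorial = [math.factorial(k) for k in range(M + 1)]
    phi = np.zeros(M)
    for s in range(n_coal):
        size = int(sizes[s])
        for i in range(M):
            if members[s, i]:
                continue
            weight = factorial[size] * factorial[M - size - 1] / factorial[M]
            phi[i] += weight * (values[s | (1 << i)] - values[s])
    return phi, float(values[0])


# ---------------------------------------------------------------------------
# Model-level attribution
# ---------------------------------------------------------------------------

def shapley_attributions(
    model: TrainedModel | Callable[[np.ndarray], np.ndarray],
    samples: np.ndarray,
    background: np.ndarray,
    n_perm: int = 4,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> AttributionReport:
    """Shapley attributions of the ACP-class probability.

    Parameters
    ----------
    model:
        A :class:`TrainedModel` (explained on P(ACP)) or any callable
        mapping an (B, Lmax, d) batch to B scalar outputs.
    samples:
        (N, Lmax, d) encoded peptides to explain.
    background:
        (Nb, Lmax, d) encoded training peptides; absent features take the
        background mean.
    """
    samples = np.asarray(samples, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background must be non-empty")
    if samples.ndim != 3:
        raise ValueError("samples must be (N, Lmax, d)")
    N, L, d = samples.shape
    baseline = background.mean(axis=0).reshape(-1)

    if isinstance(model, TrainedModel):
        def f(flat: np.ndarray) -> np.ndarray:
            return model.forward(flat.reshape(-1, L, d))[:, 1]
    else:
        def f(flat: np.ndarray) -> np.ndarray:
            return np.asarray(model(flat.reshape(-1, L, d)), dtype=float)

    rng = np.random.default_rng(seed)
    phi = np.empty((N, L, d))
    phi0 = float(f(baseline[None])[0])
    for i in range(N):
        phi_i, _ = permutation_shapley(
            f, samples[i].reshape(-1), baseline, n_perm=n_perm, rng=rng
        )
        phi[i] = phi_i.reshape(L, d)
    if isinstance(model, TrainedModel):
        names = model.channel_names
    else:
        names = [f"channel_{j}" for j in range(d)]
    return AttributionReport(
        phi=phi,
        phi0=phi0,
        channel_names=list(names),
        sample_ids=list(sample_ids) if sample_ids else [f"sample_{i}" for i in range(N)],
        model_outputs=f(samples.reshape(N, -1)),
    )


def channel_importance(report: AttributionReport) -> list[tuple[str, float]]:
    """Ranked (channel, mean |phi|) list, most important first."""
    return report.ranking


# ---------------------------------------------------------------------------
# PCA projection of penultimate features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProjectionResult:
    coordinates: np.ndarray              # (N, k)
    explained_variance_ratio: np.ndarray  # (k,)


def pca_project(features: np.ndarray, k: int = 2) -> ProjectionResult:
    """Project per-sample feature vectors onto the top-k principal axes."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be a 2-D (samples x width) array")
    if features.shape[0] < k or features.shape[1] < k:
        raise ValueError(
            f"need at least {k} samples and {k} feature dimensions; "
            f"got {features.shape}"
        )
    if np.allclose(features, features[0]):
        raise ValueError(
            "degenerate input: all feature vectors are identical, "
            "no variance to project"
        )
    pca = PCA(n_components=k)
    coords = pca.fit_transform(features)
    return ProjectionResult(
        coordinates=coords,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
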