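"""Multiscale network analysis of the four isolated series of one component.

At each coarse-graining scale a weighted 4-node network is inferred from the
isolated series Δr, Δf, Δw, Δe (edge weight = absolute Pearson correlation),
and summarised by the clustering-coefficient entropy E_c: the Shannon entropy
of the node clustering coefficients normalised to a probability distribution.
Strong inter-channel coupling makes all coefficients large and equal, pushing
E_c toward its maximum ln 4; heterogeneous, weakly coupled channels give an
uneven distribution and a smaller E_c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .entropy import coarse_grain
from .io_preprocess import ComponentSeries, KinematicRecording, isolated_series

N_NODES = 4
MIN_COARSE_LENGTH = 30
ISOLATED_JOINTS = (1, 2, 3, 4)  # Δr, Δf, Δw, Δe


@dataclass(frozen=True)
class NetworkEntropyCurve:
    scales: np.ndarray
    E_c: np.ndarray
    degenerate: np.ndarray  # bool per scale
    component: str
    channel_labels: tuple[str, ...] = ("Δr", "Δf", "Δw", "Δe")


def infer_network(channels: list[np.ndarray]) -> np.ndarray:
    """Symmetric 4x4 adjacency of absolute pairwise correlations (zero diagonal)."""
    if len(channels) != N_NODES:
        raise ValueError(f"expected {N_NODES} channels, got {len(channels)}")
    arrs = [np.asarray(c, float) for c in channels]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("channels must share a common length")
    if n < MIN_COARSE_LENGTH:
        raise ValueError(f"channels shorter than {MIN_COARSE_LENGTH} samples")
    W = np.zeros((N_NODES, N_NODES))
    const = [np.ptp(a) == 0 for a in arrs]
    if any(const):
        warnings.warn("constant channel: its edges set to 0")
    for i in range(N_NODES):
        for j in range(i + 1, N_NODES):
            if const[i] or const[j]:
                continue
            r = np.corrcoef(arrs[i], arrs[j])[0, 1]
            W[i, j] = W[j, i] = abs(r) if np.isfinite(r) else 0.0
    return W


def clustering_entropy(adjacency: np.ndarray) -> tuple[float, bool]:
    """Shannon entropy of the normalised weighted clustering coefficients.

    Node coefficients use the geometric-mean triangle-weight convention
    (weights rescaled by the maximum weight), which makes E_c invariant under
    a uniform rescaling of all weights.  When every coefficient vanishes the
    distribution is undefined; E_c is reported as ln 4 with a degenerate flag.
    """
    A = np.asarray(adjacency, float)
    if A.shape != (N_NODES, N_NODES):
        raise ValueError("adjacency must be 4x4")
    if not np.allclose(A, A.T) or np.any(np.diag(A) != 0):
        raise ValueError("adjacency must be symmetric with zero diagonal")
    G = nx.from_numpy_array(A)
    coeffs = np.array([nx.clustering(G, weight="weight")[i] for i in range(N_NODES)])
    total = coeffs.sum()
    if total <= 0:
        return float(np.log(N_NODES)), True
    p = coeffs / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum()), False


def multiscale_network_entropy(
    recording: KinematicRecording, component: str, tau_max: int = 15
) -> NetworkEntropyCurve:
    """E_c(tau) of the four isolated series of one component, tau = 1..tau_max.

    The recording must be high-pass filtered.  Scales whose coarse-grained
    length falls below 30 samples are dropped with a warning.
    """
    base = [
        np.asarray(isolated_series(recording, j, component).values)
        for j in ISOLATED_JOINTS
    ]
    fs = recording.sampling_rate
    scales, ecs, degs = [], [], []
    for tau in range(1, tau_max + 1):
        if base[0].size // tau < MIN_COARSE_LENGTH:
            warnings.warn(
                f"scale {tau} leaves fewer than {MIN_COARSE_LENGTH} samples; curve truncated"
            )
            break
        cg = [
            coarse_grain(ComponentSeries(b, fs), tau).values for b in base
        ]
        adj = infer_network(cg)
        e, deg = clustering_entropy(adj)
        scales.append(tau)
        ecs.append(e)
        degs.append(deg)
    return NetworkEntropyCurve(
        np.asarray(scales), np.asarray(ecs), np.asarray(degs, dtype=bool), component
    )
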