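"""Similarity and complementarity metrics on Zernike descriptor triples.

All metrics are cosine distances D(x, y) = 1 - x.y / (|x||y|) between
(n, l)-ordered invariant vectors.  Similarity compares like channels
(shape with shape, elec+ with elec+); complementarity compares the shape
channels directly -- rotation invariance makes a surface and its mold look
alike -- and crosses the electrostatic channels (elec+ of one against
elec- of the other), so oppositely charged facing surfaces score as
complementary.

For the decoy experiment, distances of a paratope to its native epitope
and to SASA-matched decoys are z-scored within each complex and pooled
into a native-vs-decoy ROC.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .zernike import DescriptorTriple, ZernikeDescriptor

__all__ = [
    "cosine_distance", "similarity_shape", "similarity_elec",
    "complementarity_shape", "complementarity_elec", "swap_elec",
    "zscore_table", "decoy_roc", "mann_whitney_auc",
]


def _as_vector(x) -> tuple[np.ndarray, int | None]:
    if isinstance(x, ZernikeDescriptor):
        return x.values, x.order_max
    return np.asarray(x, dtype=float), None


def cosine_distance(x, y) -> float:
    """1 - cosine similarity; in [0, 1] for non-negative vectors."""
    xv, xo = _as_vector(x)
    yv, yo = _as_vector(y)
    if xv.shape != yv.shape:
        raise ValueError(f"descriptor lengths differ: {xv.shape} vs {yv.shape}")
    if xo is not None and yo is not None and xo != yo:
        raise ValueError(f"descriptor orderings differ: order {xo} vs {yo}")
    nx, ny = np.linalg.norm(xv), np.linalg.norm(yv)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cosine distance undefined for a zero-norm descriptor "
                         "(apolar patch? exclude it or use the shape metric)")
    if np.array_equal(xv, yv):
        return 0.0  # identity holds exactly, free of rounding
    d = float(1.0 - np.dot(xv, yv) / (nx * ny))
    return 0.0 if -1e-12 < d < 0.0 else d


def similarity_shape(a: DescriptorTriple, b: DescriptorTriple) -> float:
    """Shape-channel cosine distance; smaller = more similar."""
    return cosine_distance(a.shape, b.shape)


def similarity_elec(a: DescriptorTriple, b: DescriptorTriple) -> float:
    """Mean of the same-sign electrostatic channel distances."""
    return 0.5 * (cosine_distance(a.elec_pos, b.elec_pos)
                  + cosine_distance(a.elec_neg, b.elec_neg))


def complementarity_shape(a: DescriptorTriple, b: DescriptorTriple) -> float:
    """Shape-channel cosine distance; smaller = more complementary."""
    return cosine_distance(a.shape, b.shape)


def complementarity_elec(a: DescriptorTriple, b: DescriptorTriple) -> float:
    """Mean of the opposite-sign electrostatic channel distances."""
    return 0.5 * (cosine_distance(a.elec_pos, b.elec_neg)
                  + cosine_distance(a.elec_neg, b.elec_pos))


def swap_elec(t: DescriptorTriple) -> DescriptorTriple:
    """The triple with its electrostatic channels exchanged (the 'mold')."""
    return DescriptorTriple(shape=t.shape, elec_pos=t.elec_neg,
                            elec_neg=t.elec_pos)


_METRICS = {"shape": complementarity_shape, "elec": complementarity_elec}


def zscore_table(paratope: DescriptorTriple, native: DescriptorTriple,
                 decoys: Sequence[DescriptorTriple], metric: str = "shape",
                 reference: str = "combined") -> pd.DataFrame:
    """Complementarity distances of a paratope to its native epitope and to
    each decoy, z-scored over the chosen reference population.

    ``reference='combined'`` (default) normalises over {native + decoys};
    ``'decoys'`` uses the decoy population only.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    if len(decoys) < 2:
        raise ValueError("need at least 2 decoys to define a z-score")
    fn = _METRICS[metric]
    labels = ["native"] + [f"decoy_{i}" for i in range(len(decoys))]
    dists = np.array([fn(paratope, native)] + [fn(paratope, d) for d in decoys])
    ref = dists if reference == "combined" else dists[1:]
    sd = ref.std(ddof=0)
    if sd == 0.0:
        z = np.zeros_like(dists)
    else:
        z = (dists - ref.mean()) / sd
    return pd.DataFrame({"label": labels, "distance": dists, "zscore": z,
                         "is_native": [lbl == "native" for lbl in labels]})


def mann_whitney_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """ROC AUC via the rank-statistic (Mann-Whitney) identity, with ties
    contributing half."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both positive and negative examples")
    ranks = rankdata(scores)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(scores: np.ndarray, positive: np.ndarray) -> pd.DataFrame:
    """(FPR, TPR) curve at every score threshold, descending."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    tp = np.concatenate([[0], np.cumsum(positive[order])])
    fp = np.concatenate([[0], np.cumsum(~positive[order])])
    return pd.DataFrame({"fpr": fp / max(fp[-1], 1), "tpr": tp / max(tp[-1], 1)})


def decoy_roc(tables: Iterable[pd.DataFrame], mode: str = "pooled",
              ) -> tuple[float, pd.DataFrame]:
    """Native-vs-decoy ROC over per-complex z-score tables.

    The score is -z (natives should be the most complementary, hence the
    most negative z).  ``pooled`` concatenates all complexes into one ROC;
    ``per_complex`` averages per-complex AUCs.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no z-score tables given")
    if mode == "pooled":
        cat = pd.concat(tables, ignore_index=True)
        scores = -cat["zscore"].to_numpy()
        pos = cat["is_native"].to_numpy()
        return mann_whitney_auc(scores, pos), roc_points(scores, pos)
    if mode == "per_complex":
        aucs = [mann_whitney_auc(-t["zscore"].to_numpy(),
                                 t["is_native"].to_numpy()) for t in tables]
        cat = pd.concat(tables, ignore_index=True)
        scores = -cat["zscore"].to_numpy()
        pos = cat["is_native"].to_numpy()
        return float(np.mean(aucs)), roc_points(scores, pos)
    raise ValueError(f"unknown mode {mode!r}")
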